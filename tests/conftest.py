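import numpy as np
import pandas as pd
import pytest

from mrmediate.summary_io import HarmonizedSet, SummaryStats


def make_harmonized(gamma, se_gamma, gamma_out, se_gamma_out, ids=None) -> HarmonizedSet:
    gamma = np.asarray(gamma, float)
    n = len(gamma)
    df = pd.DataFrame(
        {
            "variant_id": ids or [f"rs{i + 1}" for i in range(n)],
            "gamma": gamma,
            "se_gamma": np.broadcast_to(np.asarray(se_gamma, float), n).copy(),
            "gamma_out": np.asarray(gamma_out, float),
            "se_gamma_out": np.broadcast_to(np.asarray(se_gamma_out, float), n).copy(),
        }
    )
    return HarmonizedSet(df, "exposure", "outcome")


def random_harmonized(rng: np.random.Generator, n_snp: int, beta: float = 0.3) -> HarmonizedSet:
    gamma = rng.normal(0.1, 0.03, n_snp)
    se_gamma = rng.uniform(0.002, 0.01, n_snp)
    se_out = rng.uniform(0.005, 0.02, n_snp)
    gamma_out = beta * gamma + rng.normal(0, se_out)
    return make_harmonized(gamma, se_gamma, gamma_out, se_out)


def make_stats(rows, label="trait", trait_type="continuous") -> SummaryStats:
    """rows: list of (variant_id, chrom, pos, ea, oa, eaf, beta, se, pval, n)."""
    df = pd.DataFrame(
        rows,
        columns=[
            "variant_id", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "pval", "n",
        ],
    )
    df["chrom"] = df["chrom"].astype(str)
    return SummaryStats(df, label, trait_type)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
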