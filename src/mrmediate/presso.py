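"""MR-PRESSO: pleiotropy residual sum and outlier test.

The global test compares the observed weighted residual sum of squares
around leave-one-out IVW fits with a simulated null in which each SNP's
effects are redrawn from their sampling distributions about the fitted
model; the outlier test compares each SNP's residual contribution with
its own simulated null.  Outliers (Bonferroni-adjusted per-SNP p <
0.05) are removed and the IVW estimate recomputed.

All randomness flows from one master seed through a single generator
with a fixed draw order, so identical seeds give bitwise-identical
p-values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import InsufficientInstrumentsError, ValidationError
from .summary_io import HarmonizedSet
from .uvmr import MREstimate, ivw

DEFAULT_N_SIM = 5000


def _loo_betas(g: np.ndarray, G: np.ndarray, wG: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, vectorized.

    IVW in regression form: beta = sum(wG·g·G)/sum(wG·g²); dropping SNP j
    just removes its terms from both sums.  Supports 1-D data vectors or
    2-D simulation matrices (rows = simulations).
    """
    num = wG * g * G
    den = wG * g * g
    s_num = num.sum(axis=-1, keepdims=True)
    s_den = den.sum(axis=-1, keepdims=True)
    return (s_num - num) / (s_den - den)


def _rss_terms(g: np.ndarray, G: np.ndarray, wG: np.ndarray) -> np.ndarray:
    """Per-SNP weighted residual contribution wG_j·(Gamma_j - beta_(-j)·gamma_j)²."""
    b_loo = _loo_betas(g, G, wG)
    return wG * (G - b_loo * g) ** 2


def _check(H: HarmonizedSet, n_sim: int) -> None:
    if len(H) < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs at least 4 variants")
    if n_sim < 1000:
        raise ValidationError("n_sim must be at least 1000")


def _simulate_terms(
    H: HarmonizedSet, n_sim: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Observed and simulated per-SNP residual contributions.

    Null draws: gamma* ~ N(gamma, se_gamma²) and
    Gamma* ~ N(beta_(-j)·gamma_j, se_Gamma²); the leave-one-out slopes
    are recomputed on each simulated dataset.
    """
    # work in sorted-variant order so results are invariant to row order
    order = np.argsort(np.asarray(H.variant_ids))
    g, sg = H.gamma[order], H.se_gamma[order]
    G, sG = H.gamma_out[order], H.se_gamma_out[order]
    wG = sG**-2
    obs = _rss_terms(g, G, wG)
    expected = _loo_betas(g, G, wG) * g
    rng = np.random.default_rng(seed)
    g_star = g + rng.standard_normal((n_sim, len(g))) * sg
    G_star = expected + rng.standard_normal((n_sim, len(g))) * sG
    sim = _rss_terms(g_star, G_star, wG)
    # map back to the input row order; totals stay summed in canonical
    # (sorted) order so they are bitwise order-invariant
    inverse = np.argsort(order)
    return obs[inverse], sim[:, inverse], float(obs.sum()), sim.sum(axis=1)


def presso_global(H: HarmonizedSet, n_sim: int = DEFAULT_N_SIM, seed: int = 0) -> tuple[float, float]:
    """Global heterogeneity test: observed RSS against its simulated null.

    Returns (rss_observed, global_p) with the add-one empirical p-value
    (1 + #{RSS* >= RSS_obs}) / (n_sim + 1).
    """
    _check(H, n_sim)
    _, _, rss_obs, rss_sim = _simulate_terms(H, n_sim, seed)
    p = (1 + int(np.sum(rss_sim >= rss_obs))) / (n_sim + 1)
    return rss_obs, p


def presso_outlier(
    H: HarmonizedSet, n_sim: int = DEFAULT_N_SIM, seed: int = 0
) -> dict[str, float]:
    """Per-SNP outlier p-values from each SNP's simulated null contribution."""
    _check(H, n_sim)
    obs, sim, _, _ = _simulate_terms(H, n_sim, seed)
    counts = np.sum(sim >= obs[None, :], axis=0)
    pvals = (1 + counts) / (n_sim + 1)
    return dict(zip(H.variant_ids, pvals.astype(float)))


def flag_outliers(outlier_p: dict[str, float], alpha: float = 0.05) -> list[str]:
    """Bonferroni-adjusted outlier call: p_j · J < alpha."""
    J = len(outlier_p)
    return sorted(v for v, p in outlier_p.items() if p * J < alpha)


def presso_correct(H: HarmonizedSet, outliers: list[str]) -> MREstimate:
    """Multiplicative-random IVW on the instruments retained after outlier removal."""
    unknown = set(outliers) - set(H.variant_ids)
    if unknown:
        raise ValidationError(f"outliers not in instrument set: {sorted(unknown)}")
    if len(H) - len(set(outliers)) < 2:
        raise InsufficientInstrumentsError("outlier removal leaves fewer than 2 variants")
    kept = H.drop_variants(outliers, reason="presso_outlier") if outliers else H
    est = ivw(kept, model="multiplicative_random")
    est.method = "MRPRESSO_corrected"
    return est


@dataclass
class PressoResult:
    """Bundle of the global test, per-SNP tests and corrected estimate."""

    global_rss_observed: float
    global_p: float
    outlier_p: dict[str, float]
    outliers: list[str]
    corrected: MREstimate
    n_sim: int
    seed: int
    distortion_note: str = field(
        default="distortion test not computed", repr=False
    )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "rss_obs": self.global_rss_observed,
            "global_p": self.global_p,
            "n_sim": self.n_sim,
            "seed": self.seed,
            "outliers": self.outliers,
            "per_snp": [{"snp": s, "p": p} for s, p in self.outlier_p.items()],
            "corrected": {
                "beta": self.corrected.beta,
                "se": self.corrected.se,
                "pval": self.corrected.pval,
                "n_snp": self.corrected.n_snp,
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def mr_presso(
    H: HarmonizedSet, n_sim: int = DEFAULT_N_SIM, seed: int = 0, alpha: float = 0.05
) -> PressoResult:
    """Run the global test, the outlier test and the corrected IVW in one pass.

    The global and outlier tests share a single simulated null (same
    seed, one draw), matching the one-pass construction of the original
    procedure.
    """
    _check(H, n_sim)
    obs, sim, rss_obs, rss_sim = _simulate_terms(H, n_sim, seed)
    global_p = (1 + int(np.sum(rss_sim >= rss_obs))) / (n_sim + 1)
    pvals = (1 + np.sum(sim >= obs[None, :], axis=0)) / (n_sim + 1)
    outlier_p = dict(zip(H.variant_ids, pvals.astype(float)))
    outliers = flag_outliers(outlier_p, alpha)
    if len(H) - len(outliers) < 2:  # refuse to correct away the whole set
        outliers = []
    corrected = presso_correct(H, outliers)
    return PressoResult(
        global_rss_observed=rss_obs,
        global_p=global_p,
        outlier_p=outlier_p,
        outliers=outliers,
        corrected=corrected,
        n_sim=n_sim,
        seed=seed,
    )
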