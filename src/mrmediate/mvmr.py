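"""Multivariable MR: joint instruments and MV-IVW / MVMR-Egger.

The instrument set is the union of variants genome-wide significant
for *any* exposure, clumped on the smallest p-value across exposures,
with every trait's effects oriented to the first exposure's allele
convention.  MV-IVW is weighted multiple regression of the outcome
effects on the K exposure-effect columns without intercept (weights
se_Gamma^-2); MVMR-Egger adds a free intercept after orienting SNPs so
the first exposure's effects are non-negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    CollinearExposuresError,
    InsufficientInstrumentsError,
    UnderIdentifiedError,
)
from .summary_io import (
    HarmonizedSet,
    InstrumentCriteria,
    PairwiseLD,
    SummaryStats,
    clump,
    orient_alleles,
)
from .uvmr import MREstimate, _normal_p

CONDITION_LIMIT = 1e8


@dataclass
class MVHarmonizedSet:
    """Per-SNP effects for K exposures and one outcome, shared orientation."""

    variant_ids: list[str]
    gammas: np.ndarray  # (J, K)
    se_gammas: np.ndarray  # (J, K)
    gamma_out: np.ndarray  # (J,)
    se_gamma_out: np.ndarray  # (J,)
    exposure_labels: list[str]
    outcome_label: str = ""
    outcome_trait_type: str = "binary"
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "reason"])
    )

    def __post_init__(self) -> None:
        if self.gammas.ndim != 2 or self.gammas.shape[1] < 2:
            raise UnderIdentifiedError("multivariable MR needs at least 2 exposures")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise UnderIdentifiedError("duplicate variant ids in MVMR set")

    def __len__(self) -> int:
        return len(self.variant_ids)

    @property
    def n_exposures(self) -> int:
        return self.gammas.shape[1]

    def reorder_exposures(self, order: list[int]) -> "MVHarmonizedSet":
        return MVHarmonizedSet(
            variant_ids=list(self.variant_ids),
            gammas=self.gammas[:, order],
            se_gammas=self.se_gammas[:, order],
            gamma_out=self.gamma_out,
            se_gamma_out=self.se_gamma_out,
            exposure_labels=[self.exposure_labels[i] for i in order],
            outcome_label=self.outcome_label,
            outcome_trait_type=self.outcome_trait_type,
        )

    def univariable(self, exposure_index: int = 0) -> HarmonizedSet:
        """Project one exposure out as a univariable harmonized set."""
        df = pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "gamma": self.gammas[:, exposure_index],
                "se_gamma": self.se_gammas[:, exposure_index],
                "gamma_out": self.gamma_out,
                "se_gamma_out": self.se_gamma_out,
            }
        )
        return HarmonizedSet(
            df,
            exposure_label=self.exposure_labels[exposure_index],
            outcome_label=self.outcome_label,
            outcome_trait_type=self.outcome_trait_type,
        )


def build_mvmr_set(
    exposures: list[SummaryStats],
    outcome: SummaryStats,
    ld: PairwiseLD | None = None,
    criteria: InstrumentCriteria | None = None,
    palindrome_policy: str = "drop_ambiguous",
    eaf_window: float = 0.08,
) -> MVHarmonizedSet:
    """Joint instrument construction for K >= 2 exposures.

    Union of genome-wide significant variants across exposures, clumped
    by the minimum p across exposures, harmonized to the first
    exposure's allele convention; variants missing in any trait (or
    with irreconcilable alleles) are dropped with a logged reason.
    """
    if len(exposures) < 2:
        raise UnderIdentifiedError("multivariable MR needs at least 2 exposures")
    criteria = criteria or InstrumentCriteria()
    indexed = [e.df.set_index("variant_id") for e in exposures]
    out_idx = outcome.df.set_index("variant_id")

    # union of significant variants, keyed by min-across-exposures p
    union: dict[str, float] = {}
    for df in indexed:
        sig = df[df["pval"] < criteria.p_threshold]
        for vid, p in sig["pval"].items():
            union[vid] = min(p, union.get(vid, 1.0))
    dropped: list[tuple[str, str]] = []
    if not union:
        raise UnderIdentifiedError("no variant is genome-wide significant in any exposure")

    # positions for clumping come from whichever exposure carries the SNP
    rows = []
    for vid, p in union.items():
        for df in indexed:
            if vid in df.index:
                rows.append((vid, df.loc[vid, "chrom"], int(df.loc[vid, "pos"]), p))
                break
    union_stats = SummaryStats(
        pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "pval"]).assign(
            effect_allele="A", other_allele="G", eaf=np.nan, beta=0.0, se=1.0, n=1
        ),
        trait_label="mvmr-union",
    )
    kept = clump(union_stats, ld, criteria)

    # harmonize every trait to the first exposure's convention
    ref = indexed[0]
    variant_ids, g_rows, sg_rows, G, sG = [], [], [], [], []
    for vid in kept:
        tables = indexed + [out_idx]
        if any(vid not in t.index for t in tables):
            reason = "missing_in_outcome" if vid not in out_idx.index else "missing_in_trait"
            dropped.append((vid, reason))
            continue
        e0 = ref.loc[vid]
        signs, ok = [], True
        for t in tables[1:]:
            row = t.loc[vid]
            s, reason = orient_alleles(
                e0["effect_allele"], e0["other_allele"], e0["eaf"],
                row["effect_allele"], row["other_allele"], row["eaf"],
                palindrome_policy, eaf_window,
            )
            if s == 0:
                dropped.append((vid, reason))
                ok = False
                break
            signs.append(s)
        if not ok:
            continue
        betas = [e0["beta"]] + [s * t.loc[vid, "beta"] for s, t in zip(signs[:-1], indexed[1:])]
        ses = [e0["se"]] + [t.loc[vid, "se"] for t in indexed[1:]]
        variant_ids.append(vid)
        g_rows.append(betas)
        sg_rows.append(ses)
        G.append(signs[-1] * out_idx.loc[vid, "beta"])
        sG.append(out_idx.loc[vid, "se"])

    K = len(exposures)
    if len(variant_ids) < K + 2:
        raise UnderIdentifiedError(
            f"only {len(variant_ids)} joint instruments for {K} exposures (need >= {K + 2})"
        )
    return MVHarmonizedSet(
        variant_ids=variant_ids,
        gammas=np.asarray(g_rows, float),
        se_gammas=np.asarray(sg_rows, float),
        gamma_out=np.asarray(G, float),
        se_gamma_out=np.asarray(sG, float),
        exposure_labels=[e.trait_label for e in exposures],
        outcome_label=outcome.trait_label,
        outcome_trait_type=outcome.trait_type,
        dropped=pd.DataFrame(dropped, columns=["variant_id", "reason"]),
    )


def write_mvmr_tsv(estimates: list[MREstimate], path) -> None:
    """One row per exposure: direct effect, OR presentation, intercept for Egger rows."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "exposure": e.label,
                "beta": e.beta,
                "se": e.se,
                "pval": e.pval,
                "or": e.or_point,
                "or_lo95": e.or_lo,
                "or_hi95": e.or_hi,
                "method": e.method,
                "n_snp": e.n_snp,
                "intercept": "" if e.intercept is None else e.intercept,
                "intercept_p": "" if e.intercept_p is None else e.intercept_p,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _wls(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, df_resid: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least squares with multiplicative residual inflation.

    Returns (coefficients, SEs, weighted RSS); SEs are
    sqrt(diag((X'WX)^-1)) scaled by max(1, sqrt(RSS/df_resid)).
    """
    Xw = X * w[:, None]
    A = X.T @ Xw
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise CollinearExposuresError(cond)
    beta = np.linalg.solve(A, Xw.T @ y)
    resid = y - X @ beta
    rss = float(np.sum(w * resid**2))
    inflation = max(1.0, math.sqrt(rss / df_resid)) if df_resid > 0 else 1.0
    se = np.sqrt(np.diag(np.linalg.inv(A))) * inflation
    return beta, se, rss


def mv_ivw(M: MVHarmonizedSet) -> list[MREstimate]:
    """MV-IVW direct effects: weighted no-intercept multiple regression."""
    J, K = len(M), M.n_exposures
    if J < K + 2:
        raise InsufficientInstrumentsError(f"MV-IVW needs at least {K + 2} variants, got {J}")
    w = M.se_gamma_out**-2
    beta, se, rss = _wls(M.gammas, M.gamma_out, w, J - K)
    q_p = float(sps.chi2.sf(rss, J - K))
    return [
        MREstimate(
            method="MV-IVW",
            beta=float(b),
            se=float(s),
            pval=float(_normal_p(b / s)),
            n_snp=J,
            label=lab,
            q_stat=rss,
            q_df=J - K,
            q_p=q_p,
        )
        for b, s, lab in zip(beta, se, M.exposure_labels)
    ]


def mv_egger(M: MVHarmonizedSet) -> list[MREstimate]:
    """MVMR-Egger: free intercept, SNPs oriented so the first exposure's gamma >= 0.

    Each returned estimate carries the shared intercept and its
    pleiotropy p-value.
    """
    J, K = len(M), M.n_exposures
    if J < K + 3:
        raise InsufficientInstrumentsError(f"MVMR-Egger needs at least {K + 3} variants, got {J}")
    flip = np.where(M.gammas[:, 0] < 0, -1.0, 1.0)
    X = np.column_stack([np.ones(J), M.gammas * flip[:, None]])
    y = M.gamma_out * flip
    w = M.se_gamma_out**-2
    coef, se, rss = _wls(X, y, w, J - K - 1)
    intercept, int_se = float(coef[0]), float(se[0])
    int_p = float(_normal_p(intercept / int_se))
    q_p = float(sps.chi2.sf(rss, J - K - 1))
    return [
        MREstimate(
            method="MVMR-Egger",
            beta=float(b),
            se=float(s),
            pval=float(_normal_p(b / s)),
            n_snp=J,
            label=lab,
            intercept=intercept,
            intercept_se=int_se,
            intercept_p=int_p,
            q_stat=rss,
            q_df=J - K - 1,
            q_p=q_p,
        )
        for b, s, lab in zip(coef[1:], se[1:], M.exposure_labels)
    ]
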