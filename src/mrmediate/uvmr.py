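"""Univariable two-sample MR estimators and diagnostics.

All estimators consume a :class:`~mrmediate.summary_io.HarmonizedSet`
of per-SNP exposure effects (gamma, se_gamma) and outcome effects
(gamma_out, se_gamma_out) on a shared allele convention, and return an
:class:`MREstimate` on the scale of the outcome per unit exposure
(log-odds for binary outcomes).

Estimators
----------
- Wald ratio and inverse-variance weighted (IVW) meta-analysis, with a
  multiplicative random-effects variance inflated by
  max(1, sqrt(Q/(J-1))).
- MR-Egger regression (free intercept as a directional-pleiotropy
  indicator) with SNPs oriented so gamma >= 0.
- Weighted median (50% weighted percentile of the ratio estimates,
  robust to <50% invalid weight) with a parametric-bootstrap SE.
- Simple and weighted mode (kernel-density mode of the ratios).
- Cochran's Q, per-SNP F statistics, leave-one-out IVW.

P-values are two-sided normal throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateInstrumentError, InsufficientInstrumentsError
from .summary_io import HarmonizedSet

logger = logging.getLogger(__name__)

Z95 = 1.96


@dataclass
class MREstimate:
    """One method's causal estimate with its diagnostics."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    label: str | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    q_stat: float | None = None
    q_df: int | None = None
    q_p: float | None = None
    mean_f: float | None = None

    @property
    def ci(self) -> tuple[float, float]:
        return self.beta - Z95 * self.se, self.beta + Z95 * self.se

    # Odds-ratio presentation for binary outcomes (log-odds beta scale).
    @property
    def or_point(self) -> float:
        return math.exp(self.beta)

    @property
    def or_lo(self) -> float:
        return math.exp(self.beta - Z95 * self.se)

    @property
    def or_hi(self) -> float:
        return math.exp(self.beta + Z95 * self.se)


@dataclass
class RatioEstimate:
    """Per-SNP Wald ratio beta_j = Gamma_j / gamma_j with its weight."""

    variant_id: str
    ratio: float
    se_ratio: float

    @property
    def weight(self) -> float:
        return self.se_ratio ** -2


def _normal_p(z: float | np.ndarray) -> float | np.ndarray:
    # floored away from 0 so downstream FDR sees p in (0, 1]
    return np.clip(2.0 * sps.norm.sf(np.abs(z)), 1e-300, 1.0)


def wald_ratio(
    gamma: float,
    se_gamma: float,
    gamma_out: float,
    se_gamma_out: float,
    se_order: str = "first",
    variant_id: str = "",
) -> RatioEstimate:
    """Single-SNP causal estimate Gamma/gamma.

    First-order SE is se_Gamma/|gamma|; second-order propagates the
    exposure-side uncertainty as well:
    sqrt(se_Gamma²/gamma² + Gamma²·se_gamma²/gamma⁴).
    """
    if gamma == 0:
        raise DegenerateInstrumentError(
            f"variant {variant_id or '<unnamed>'} has zero exposure effect"
        )
    ratio = gamma_out / gamma
    if se_order == "first":
        se = se_gamma_out / abs(gamma)
    elif se_order == "second":
        se = math.sqrt(
            se_gamma_out**2 / gamma**2 + gamma_out**2 * se_gamma**2 / gamma**4
        )
    else:
        raise ValueError(f"unknown se_order {se_order!r}")
    return RatioEstimate(variant_id, ratio, se)


def ratio_arrays(H: HarmonizedSet, se_order: str = "first") -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Wald ratios and their SEs for a harmonized set."""
    g, sg = H.gamma, H.se_gamma
    G, sG = H.gamma_out, H.se_gamma_out
    if np.any(g == 0):
        bad = [v for v, x in zip(H.variant_ids, g) if x == 0]
        raise DegenerateInstrumentError(f"zero exposure effect for {', '.join(bad)}")
    r = G / g
    if se_order == "first":
        se = sG / np.abs(g)
    else:
        se = np.sqrt(sG**2 / g**2 + G**2 * sg**2 / g**4)
    return r, se


def mean_f_statistic(H: HarmonizedSet) -> float:
    """Mean instrument-strength F statistic, mean_j gamma_j²/se_gamma_j²."""
    return float(np.mean(H.gamma**2 / H.se_gamma**2))


def cochran_q(
    H: HarmonizedSet, beta_ref: float, se_order: str = "first"
) -> tuple[float, int, float]:
    """Heterogeneity Q = sum_j w_j (beta_j - beta_ref)², df = J-1, chi² p."""
    if len(H) < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs at least 2 variants")
    r, se = ratio_arrays(H, se_order)
    w = se**-2
    q = float(np.sum(w * (r - beta_ref) ** 2))
    df = len(r) - 1
    return q, df, float(sps.chi2.sf(q, df))


def ivw(
    H: HarmonizedSet,
    model: str = "multiplicative_random",
    se_order: str = "first",
) -> MREstimate:
    """Inverse-variance weighted meta-analysis of the Wald ratios.

    Equivalent to weighted regression of the outcome effects on the
    exposure effects through the origin with weights se_Gamma^-2.  The
    random-effects flavour inflates the fixed-effect SE by
    max(1, sqrt(Q/(J-1))) (multiplicative over-dispersion).
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    if len(H) < 2:
        logger.warning(
            "IVW called with %d variant(s); falling back to the single Wald ratio", len(H)
        )
        row = H.df.iloc[0]
        est = wald_ratio(
            row["gamma"], row["se_gamma"], row["gamma_out"], row["se_gamma_out"],
            se_order, row["variant_id"],
        )
        return MREstimate(
            method="WaldRatio",
            beta=est.ratio,
            se=est.se_ratio,
            pval=float(_normal_p(est.ratio / est.se_ratio)),
            n_snp=1,
            mean_f=mean_f_statistic(H),
        )
    r, se = ratio_arrays(H, se_order)
    w = se**-2
    beta = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (r - beta) ** 2))
    df = len(r) - 1
    inflation = max(1.0, math.sqrt(q / df))
    se_hat = se_fixed if model == "fixed" else se_fixed * inflation
    return MREstimate(
        method="IVW",
        beta=beta,
        se=se_hat,
        pval=float(_normal_p(beta / se_hat)),
        n_snp=len(r),
        q_stat=q,
        q_df=df,
        q_p=float(sps.chi2.sf(q, df)),
        mean_f=mean_f_statistic(H),
    )


def _oriented(H: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Flip SNP signs so every exposure effect is non-negative."""
    s = np.where(H.gamma < 0, -1.0, 1.0)
    return s * H.gamma, s * H.gamma_out


def mr_egger(H: HarmonizedSet) -> MREstimate:
    """MR-Egger: weighted regression of Gamma on gamma with a free intercept.

    SNPs are oriented so gamma >= 0 first (Egger is not
    orientation-invariant).  The intercept estimates the mean
    directional pleiotropic effect; both SEs carry the multiplicative
    residual inflation max(1, sqrt(Q_egger/(J-2))).
    """
    J = len(H)
    if J < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least 3 variants")
    g, G = _oriented(H)
    w = H.se_gamma_out**-2
    # closed-form weighted least squares on [1, gamma]
    sw, swg = np.sum(w), np.sum(w * g)
    swgg, swG, swgG = np.sum(w * g * g), np.sum(w * G), np.sum(w * g * G)
    det = sw * swgg - swg**2
    intercept = (swgg * swG - swg * swgG) / det
    slope = (sw * swgG - swg * swG) / det
    resid = G - intercept - slope * g
    q = float(np.sum(w * resid**2))
    df = J - 2
    inflation = max(1.0, math.sqrt(q / df))
    se_int = math.sqrt(swgg / det) * inflation
    se_slope = math.sqrt(sw / det) * inflation
    return MREstimate(
        method="Egger",
        beta=float(slope),
        se=se_slope,
        pval=float(_normal_p(slope / se_slope)),
        n_snp=J,
        intercept=float(intercept),
        intercept_se=se_int,
        intercept_p=float(_normal_p(intercept / se_int)),
        q_stat=q,
        q_df=df,
        q_p=float(sps.chi2.sf(q, df)),
        mean_f=mean_f_statistic(H),
    )


# ---------------------------------------------------------------------------
# Weighted median / mode

def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """50% weighted percentile of the ratio estimates.

    The estimate is the ratio whose normalized cumulative-weight
    interval strictly contains 0.5; when 0.5 falls exactly on an
    interval boundary the two adjacent ratios are averaged.  Any group
    of SNPs sharing a ratio and holding more than half the total weight
    therefore returns that shared ratio exactly.
    """
    order = np.argsort(ratios, kind="mergesort")
    r = np.asarray(ratios, float)[order]
    c = np.cumsum(np.asarray(weights, float)[order])
    c /= c[-1]
    i = int(np.searchsorted(c, 0.5, side="left"))
    if c[i] == 0.5:
        return float(0.5 * (r[i] + r[i + 1]))
    return float(r[i])


def _weighted_median_rows(R: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Row-wise weighted median for bootstrap matrices (ties ignored)."""
    order = np.argsort(R, axis=1, kind="mergesort")
    Rs = np.take_along_axis(R, order, axis=1)
    Ws = np.take_along_axis(W, order, axis=1)
    C = np.cumsum(Ws, axis=1)
    C /= C[:, -1:]
    idx = (C < 0.5).sum(axis=1)
    return Rs[np.arange(len(Rs)), idx]


def _parametric_bootstrap(
    H: HarmonizedSet, n_boot: int, seed: int, se_order: str
) -> tuple[np.ndarray, np.ndarray]:
    """Resample (gamma*, Gamma*) from their normal sampling distributions.

    Returns bootstrap matrices of ratios and weights, shape (n_boot, J).
    """
    rng = np.random.default_rng(seed)
    J = len(H)
    g = H.gamma + rng.standard_normal((n_boot, J)) * H.se_gamma
    G = H.gamma_out + rng.standard_normal((n_boot, J)) * H.se_gamma_out
    g = np.where(g == 0, np.finfo(float).tiny, g)
    R = G / g
    if se_order == "first":
        se = H.se_gamma_out / np.abs(g)
    else:
        se = np.sqrt(H.se_gamma_out**2 / g**2 + G**2 * H.se_gamma**2 / g**4)
    return R, se**-2


def weighted_median(
    H: HarmonizedSet,
    n_boot: int = 1000,
    seed: int = 0,
    se_order: str = "first",
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Consistent when more than 50% of the weight comes from valid
    instruments.
    """
    if len(H) < 3:
        raise InsufficientInstrumentsError("weighted median needs at least 3 variants")
    if n_boot < 100:
        logger.warning("n_boot=%d is small; SE will be noisy", n_boot)
    r, se = ratio_arrays(H, se_order)
    point = weighted_median_point(r, se**-2)
    Rb, Wb = _parametric_bootstrap(H, n_boot, seed, se_order)
    boot = _weighted_median_rows(Rb, Wb)
    se_hat = float(np.std(boot, ddof=1))
    return MREstimate(
        method="WeightedMedian",
        beta=point,
        se=se_hat,
        pval=float(_normal_p(point / se_hat)),
        n_snp=len(r),
        mean_f=mean_f_statistic(H),
    )


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    """Modified Silverman rule with a MAD scale: phi·0.9·min(sd, 1.4826·MAD)·J^(-1/5)."""
    sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
    mad = 1.4826 * float(np.median(np.abs(ratios - np.median(ratios))))
    scale = min(x for x in (sd, mad) if x > 0) if max(sd, mad) > 0 else 0.0
    return phi * 0.9 * scale * len(ratios) ** (-1 / 5)


MODE_GRID_SIZE = 512


def mode_point(ratios: np.ndarray, kernel_weights: np.ndarray, h: float) -> float:
    """Argmax of a normal-kernel density over a fixed 512-point grid.

    The grid spans the ratio range extended by three bandwidths; the
    first maximum wins on exact ties.
    """
    if h <= 0:
        return float(ratios[0])
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, MODE_GRID_SIZE)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ kernel_weights
    return float(grid[int(np.argmax(dens))])


def mode_estimate(
    H: HarmonizedSet,
    weighted: bool = False,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    se_order: str = "first",
) -> MREstimate:
    """Mode-based estimate: the kernel-density mode of the Wald ratios.

    Consistent when the largest cluster of instruments is valid.  The
    weighted variant scales each kernel by the inverse-variance weight
    share; the simple variant weights kernels equally.
    """
    if len(H) < 3:
        raise InsufficientInstrumentsError("mode estimator needs at least 3 variants")
    if phi <= 0:
        raise ValueError("phi must be positive")
    r, se = ratio_arrays(H, se_order)
    w = se**-2

    def kernel_w(weights: np.ndarray) -> np.ndarray:
        return weights / weights.sum() if weighted else np.full(len(weights), 1.0 / len(weights))

    point = mode_point(r, kernel_w(w), _mode_bandwidth(r, phi))
    Rb, Wb = _parametric_bootstrap(H, n_boot, seed, se_order)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        boot[i] = mode_point(Rb[i], kernel_w(Wb[i]), _mode_bandwidth(Rb[i], phi))
    se_hat = float(np.std(boot, ddof=1))
    return MREstimate(
        method="WeightedMode" if weighted else "SimpleMode",
        beta=point,
        se=se_hat,
        pval=float(_normal_p(point / se_hat)),
        n_snp=len(r),
        mean_f=mean_f_statistic(H),
    )


def leave_one_out(H: HarmonizedSet, se_order: str = "first") -> pd.DataFrame:
    """One multiplicative-random IVW fit per excluded SNP.

    Returns a frame with columns excluded_snp, beta, se, p — exactly
    one row per variant.
    """
    if len(H) < 3:
        raise InsufficientInstrumentsError("leave-one-out needs at least 3 variants")
    rows = []
    for vid in H.variant_ids:
        est = ivw(H.drop_variants([vid]), "multiplicative_random", se_order)
        rows.append((vid, est.beta, est.se, est.pval))
    return pd.DataFrame(rows, columns=["excluded_snp", "beta", "se", "p"])
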