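"""Seeded generator of multi-trait GWAS summary statistics.

Summary statistics are simulated directly (no individual-level
genotypes) under an explicit exposure → mediator → outcome causal
diagram.  For each variant j with minor-allele frequency maf_j and true
per-allele exposure effect γ_j:

- true mediator effect  = β_XM·γ_j (plus the variant's own mediator
  effect for mediator-specific instruments),
- true outcome effect   = β_XY_direct·γ_j + β_MY·(mediator effect)
  + α_j (pleiotropy) + any planted outlier displacement,
- observed betas are drawn from Normal(truth, se²) with
  se = 1/sqrt(2·maf·(1-maf)·n_trait), the sampling variance of a
  per-allele regression coefficient for a standardized trait.

Exposure, mediator and outcome samples are treated as non-overlapping
(independent noise), the two-sample MR assumption.  Exposure
instruments carry a fetal-only / maternal-only / shared class label so
genome-specific instrument subsets can be exercised.  The same seed
produces bitwise-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats as sps

from .exceptions import ValidationError
from .summary_io import PairwiseLD, SummaryStats

_P_FLOOR = 1e-300  # keep simulated p-values inside (0, 1]


class EffectDist(BaseModel):
    """Normal distribution of true per-allele instrument effects."""

    mean: float = 0.10
    sd: float = Field(default=0.025, ge=0)


class PleiotropyConfig(BaseModel):
    """Direct (not via exposure) instrument effects on the outcome.

    ``balanced`` draws α_j ~ N(0, sd) (satisfies InSIDE);
    ``directional`` draws α_j ~ N(mean, sd).  ``frac`` is the fraction
    of exposure instruments carrying a pleiotropic effect.
    """

    kind: Literal["none", "balanced", "directional"] = "none"
    mean: float = 0.0
    sd: float = Field(default=0.01, ge=0)
    frac: float = Field(default=1.0, ge=0, le=1)


class OutlierConfig(BaseModel):
    count: int = Field(default=0, ge=0)
    displacement_sd: float = 10.0


class ClassFractions(BaseModel):
    """Partition of exposure instruments by originating genome.

    Defaults echo the fetal-only/maternal-only/shared split of
    birthweight instruments (63/31 of 205).
    """

    fetal_only: float = 0.31
    maternal_only: float = 0.15
    shared: float = 0.54

    @model_validator(mode="after")
    def _sums_to_one(self) -> "ClassFractions":
        total = self.fetal_only + self.maternal_only + self.shared
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")
        return self


class SimulationConfig(BaseModel):
    """Full generative model for one exposure/mediator/outcome triplet.

    Defaults describe the reference study conditions: 120 exposure
    instruments, a mediation chain with β_XM = 0.5, β_MY = 0.168 and a
    direct effect 0.252, hence a true total effect of
    0.252 + 0.5·0.168 = 0.336 = ln(1.40) and a 25% mediated share.
    """

    n_snp: int = Field(default=120, ge=4)
    n_snp_mediator: int = Field(default=100, ge=0)
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_dist: EffectDist = Field(default_factory=EffectDist)
    n_exposure: int = Field(default=1_200_000, gt=0)
    n_mediator: int = Field(default=300_000, gt=0)
    n_outcome: int = Field(default=20_000, gt=0)
    beta_xm: float = 0.5
    beta_my: float = 0.168
    beta_xy_direct: float = 0.252
    pleiotropy: PleiotropyConfig = Field(default_factory=PleiotropyConfig)
    outlier: OutlierConfig = Field(default_factory=OutlierConfig)
    class_fractions: ClassFractions = Field(default_factory=ClassFractions)
    noiseless: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _valid(self) -> "SimulationConfig":
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo < hi <= 0.5")
        if self.outlier.count >= self.n_snp / 4:
            raise ValueError("outlier count must be below n_snp/4")
        return self

    @property
    def true_indirect(self) -> float:
        return self.beta_xm * self.beta_my

    @property
    def true_total(self) -> float:
        return self.beta_xy_direct + self.true_indirect


@dataclass
class SyntheticTruth:
    """Ground truth backing a simulated study."""

    true_total: float
    true_indirect: float
    true_proportion: float
    per_snp: pd.DataFrame  # variant_id, class, gamma, fetal, maternal, mediator, outcome, pleiotropy
    outlier_ids: list[str]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "true_total": self.true_total,
            "true_indirect": self.true_indirect,
            "true_proportion": self.true_proportion,
            "outlier_ids": self.outlier_ids,
            "per_snp": self.per_snp.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class SimulatedStudy:
    exposure: SummaryStats
    mediator: SummaryStats
    outcome: SummaryStats
    truth: SyntheticTruth

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.exposure.write(out / "exposure.tsv")
        self.mediator.write(out / "mediator.tsv")
        self.outcome.write(out / "outcome.tsv")
        self.truth.to_json(out / "truth.json")


def _se(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _observe(
    truth: np.ndarray, se: np.ndarray, rng: np.random.Generator, noiseless: bool
) -> tuple[np.ndarray, np.ndarray]:
    beta = truth.copy() if noiseless else truth + rng.standard_normal(truth.shape) * se
    p = np.clip(2.0 * sps.norm.sf(np.abs(beta) / se), _P_FLOOR, 1.0)
    return beta, p


def _stats_frame(
    ids: list[str], chrom: np.ndarray, pos: np.ndarray, maf: np.ndarray,
    beta: np.ndarray, se: np.ndarray, p: np.ndarray, n: int,
    label: str, trait_type: str, unit_note: str,
) -> SummaryStats:
    df = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": maf,
            "beta": beta,
            "se": se,
            "pval": p,
            "n": n,
        }
    )
    return SummaryStats(df, label, trait_type, unit_note)


def simulate_summary_stats(config: SimulationConfig) -> SimulatedStudy:
    """Generate exposure, mediator and outcome tables plus the ground truth.

    All three tables contain every simulated variant (exposure
    instruments and mediator-specific instruments), so instrument
    selection has to run exactly as it would on real data.
    """
    rng = np.random.default_rng(config.seed)
    J, M = config.n_snp, config.n_snp_mediator
    total = J + M
    ids = [f"rs{i + 1:06d}" for i in range(total)]
    chrom = np.array([str(i % 22 + 1) for i in range(total)])
    pos = np.array([1_000_000 + 20_000_000 * (i // 22) for i in range(total)], dtype=int)
    maf = rng.uniform(*config.maf_range, size=total)

    cls = rng.choice(
        ["fetal_only", "maternal_only", "shared"],
        size=J,
        p=[
            config.class_fractions.fetal_only,
            config.class_fractions.maternal_only,
            config.class_fractions.shared,
        ],
    )
    gamma = rng.normal(config.gamma_dist.mean, config.gamma_dist.sd, size=J)
    delta = rng.normal(config.gamma_dist.mean, config.gamma_dist.sd, size=M)

    alpha = np.zeros(J)
    if config.pleiotropy.kind != "none":
        affected = rng.random(J) < config.pleiotropy.frac
        mean = config.pleiotropy.mean if config.pleiotropy.kind == "directional" else 0.0
        alpha[affected] = rng.normal(mean, config.pleiotropy.sd, size=int(affected.sum()))

    exp_true = np.concatenate([gamma, np.zeros(M)])
    med_true = np.concatenate([config.beta_xm * gamma, delta])
    out_true = np.concatenate(
        [
            config.beta_xy_direct * gamma + config.beta_my * config.beta_xm * gamma + alpha,
            config.beta_my * delta,
        ]
    )

    se_exp = _se(maf, config.n_exposure)
    se_med = _se(maf, config.n_mediator)
    se_out = _se(maf, config.n_outcome)
    b_exp, p_exp = _observe(exp_true, se_exp, rng, config.noiseless)
    b_med, p_med = _observe(med_true, se_med, rng, config.noiseless)
    b_out, p_out = _observe(out_true, se_out, rng, config.noiseless)

    fetal = np.where(cls == "fetal_only", gamma, np.where(cls == "shared", gamma / 2, 0.0))
    maternal = np.where(cls == "maternal_only", gamma, np.where(cls == "shared", gamma / 2, 0.0))
    per_snp = pd.DataFrame(
        {
            "variant_id": ids,
            "class": list(cls) + ["mediator_specific"] * M,
            "gamma": exp_true,
            "fetal_effect": np.concatenate([fetal, np.zeros(M)]),
            "maternal_effect": np.concatenate([maternal, np.zeros(M)]),
            "mediator_effect": med_true,
            "outcome_effect": out_true,
            "pleiotropy": np.concatenate([alpha, np.zeros(M)]),
        }
    )
    truth = SyntheticTruth(
        true_total=config.true_total,
        true_indirect=config.true_indirect,
        true_proportion=(
            config.true_indirect / config.true_total if config.true_total != 0 else float("nan")
        ),
        per_snp=per_snp,
        outlier_ids=[],
    )
    outcome = _stats_frame(
        ids, chrom, pos, maf, b_out, se_out, p_out, config.n_outcome,
        "outcome", "binary", "log-odds",
    )
    study = SimulatedStudy(
        exposure=_stats_frame(
            ids, chrom, pos, maf, b_exp, se_exp, p_exp, config.n_exposure,
            "exposure", "continuous", "1-SD",
        ),
        mediator=_stats_frame(
            ids, chrom, pos, maf, b_med, se_med, p_med, config.n_mediator,
            "mediator", "continuous", "1-SD",
        ),
        outcome=outcome,
        truth=truth,
    )
    if config.outlier.count > 0:
        # outliers are planted among the exposure instruments only
        study.outcome, truth.outlier_ids = plant_outliers(
            study.outcome,
            candidate_ids=ids[:J],
            count=config.outlier.count,
            displacement_sd=config.outlier.displacement_sd,
            seed=int(rng.integers(2**31 - 1)),
        )
    return study


def plant_outliers(
    stats: SummaryStats,
    candidate_ids: list[str],
    count: int,
    displacement_sd: float,
    seed: int,
) -> tuple[SummaryStats, list[str]]:
    """Displace ``count`` outcome betas by displacement_sd·se each.

    Returns the modified table and the chosen variant ids.  ``count``
    must stay below a quarter of the candidate pool so the outliers
    remain a minority the detection step can isolate.
    """
    if count == 0:
        return stats, []
    if count >= len(candidate_ids) / 4:
        raise ValidationError("outlier count must be below a quarter of the candidates")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(candidate_ids, size=count, replace=False).tolist())
    df = stats.df.copy()
    sel = df["variant_id"].isin(chosen)
    df.loc[sel, "beta"] = df.loc[sel, "beta"] + displacement_sd * df.loc[sel, "se"]
    df["pval"] = np.clip(2.0 * sps.norm.sf(np.abs(df["beta"] / df["se"])), _P_FLOOR, 1.0)
    return SummaryStats(df, stats.trait_label, stats.trait_type, stats.unit_note), chosen


# ---------------------------------------------------------------------------
# LD block generator

class LDBlockConfig(BaseModel):
    """Block-diagonal LD: within-block r² ~ Beta(a, b), between-block 0."""

    block_sizes: list[int] = Field(default_factory=lambda: [1] * 10)
    r2_alpha: float = 8.0
    r2_beta: float = 2.0
    within_window: bool = True
    window_kb: int = 10_000
    seed: int = 0

    @model_validator(mode="after")
    def _valid(self) -> "LDBlockConfig":
        if any(s < 1 for s in self.block_sizes):
            raise ValueError("block sizes must be >= 1")
        return self


def simulate_ld_blocks(config: LDBlockConfig) -> tuple[PairwiseLD, pd.DataFrame]:
    """Pairwise r² records plus variant positions for a block structure.

    With ``within_window`` true, the variants of a block sit a few kb
    apart (inside the clumping window); otherwise consecutive block
    members are separated by more than the window so clumping ignores
    their correlation.
    """
    rng = np.random.default_rng(config.seed)
    ld = PairwiseLD()
    rows = []
    step = 5_000 if config.within_window else config.window_kb * 1000 + 1_000_000
    pos = 1_000_000
    for b, size in enumerate(config.block_sizes):
        ids = [f"ldrs{b + 1:03d}_{i + 1:02d}" for i in range(size)]
        for i in range(size):
            rows.append((ids[i], "1", pos))
            pos += step
            for j in range(i + 1, size):
                ld.set(ids[i], ids[j], float(rng.beta(config.r2_alpha, config.r2_beta)))
        pos += config.window_kb * 1000 + 1_000_000  # gap between blocks
    positions = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos"])
    return ld, positions


# ---------------------------------------------------------------------------
# Multi-candidate battery for screening studies

class CandidateSpec(BaseModel):
    """One candidate mediator in a screening battery."""

    label: str
    beta_xm: float = 0.0
    beta_my: float = 0.0
    n_snp_specific: int = Field(default=60, ge=4)


@dataclass
class BatterySim:
    exposure: SummaryStats
    outcome: SummaryStats
    mediators: dict[str, SummaryStats]
    truth: dict[str, SyntheticTruth]
    true_total: float


def simulate_mediation_battery(
    config: SimulationConfig, candidates: list[CandidateSpec]
) -> BatterySim:
    """Simulate one exposure/outcome pair with several candidate mediators.

    Each candidate has its own specific instruments; the single outcome
    table accumulates every candidate's mediated path, so the total
    effect is β_XY_direct + Σ_c β_XM,c·β_MY,c.
    """
    rng = np.random.default_rng(config.seed)
    J = config.n_snp
    counts = [c.n_snp_specific for c in candidates]
    total = J + sum(counts)
    ids = [f"rs{i + 1:06d}" for i in range(total)]
    chrom = np.array([str(i % 22 + 1) for i in range(total)])
    pos = np.array([1_000_000 + 20_000_000 * (i // 22) for i in range(total)], dtype=int)
    maf = rng.uniform(*config.maf_range, size=total)
    gamma = rng.normal(config.gamma_dist.mean, config.gamma_dist.sd, size=J)

    # per-candidate specific effect vectors over the full variant panel
    med_true: dict[str, np.ndarray] = {}
    offset = J
    out_true = np.zeros(total)
    out_true[:J] = config.beta_xy_direct * gamma
    for cand, m in zip(candidates, counts):
        delta = rng.normal(config.gamma_dist.mean, config.gamma_dist.sd, size=m)
        vec = np.zeros(total)
        vec[:J] = cand.beta_xm * gamma
        vec[offset : offset + m] = delta
        med_true[cand.label] = vec
        out_true += cand.beta_my * vec
        offset += m

    se_exp = _se(maf, config.n_exposure)
    se_out = _se(maf, config.n_outcome)
    exp_true = np.concatenate([gamma, np.zeros(total - J)])
    b_exp, p_exp = _observe(exp_true, se_exp, rng, config.noiseless)
    b_out, p_out = _observe(out_true, se_out, rng, config.noiseless)

    exposure = _stats_frame(
        ids, chrom, pos, maf, b_exp, se_exp, p_exp, config.n_exposure,
        "exposure", "continuous", "1-SD",
    )
    outcome = _stats_frame(
        ids, chrom, pos, maf, b_out, se_out, p_out, config.n_outcome,
        "outcome", "binary", "log-odds",
    )
    mediators: dict[str, SummaryStats] = {}
    truths: dict[str, SyntheticTruth] = {}
    true_total = config.beta_xy_direct + sum(c.beta_xm * c.beta_my for c in candidates)
    for cand in candidates:
        se_med = _se(maf, config.n_mediator)
        b_med, p_med = _observe(med_true[cand.label], se_med, rng, config.noiseless)
        mediators[cand.label] = _stats_frame(
            ids, chrom, pos, maf, b_med, se_med, p_med, config.n_mediator,
            cand.label, "continuous", "1-SD",
        )
        indirect = cand.beta_xm * cand.beta_my
        truths[cand.label] = SyntheticTruth(
            true_total=true_total,
            true_indirect=indirect,
            true_proportion=indirect / true_total if true_total != 0 else float("nan"),
            per_snp=pd.DataFrame(),
            outlier_ids=[],
        )
    return BatterySim(exposure, outcome, mediators, truths, true_total)
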