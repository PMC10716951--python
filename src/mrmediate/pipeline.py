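"""Two-phase MR pipeline orchestration.

Phase 1 estimates the total effect of each exposure variant (overall /
fetal-specific / maternal-specific instrument lists) on each outcome
with the full sensitivity battery: IVW, MR-Egger, weighted median,
simple and weighted mode, MR-PRESSO, Cochran's Q, mean F and
leave-one-out.  Phase 2 screens candidate mediators with two-step MR
(UVMR exposure→mediator, MVMR mediator→outcome adjusted for exposure),
applies Benjamini-Hochberg FDR across the candidate battery — one
family per (exposure, outcome) pair — and quantifies mediation
proportions for qualified candidates.

Reports are TSVs with a JSON sidecar carrying every estimate, so each
table cell is traceable to a machine-readable record.  Effects on
binary outcomes stay on the log-odds scale internally; odds ratios are
produced only at the report layer, where a sign-flip display flag can
present the effect per 1-SD *lower* exposure.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field

from .exceptions import EmptyInstrumentError, MRError
from .mediation import (
    EvidenceGrade,
    MediationCandidate,
    MediationResult,
    bh_fdr,
    grade_evidence,
    screen_mediators,
)
from .mvmr import build_mvmr_set, mv_egger, mv_ivw, write_mvmr_tsv
from .presso import PressoResult, mr_presso
from .summary_io import (
    HarmonizedSet,
    InstrumentCriteria,
    PairwiseLD,
    SummaryStats,
    harmonize,
    read_gwas_table,
    read_ld_table,
    select_instruments,
)
from .uvmr import MREstimate, ivw, leave_one_out, mode_estimate, mr_egger, weighted_median

logger = logging.getLogger(__name__)

#: the method roster of a phase-1 report row set
PHASE1_METHODS = ("IVW", "Egger", "SimpleMode", "WeightedMedian", "WeightedMode", "MRPRESSO_corrected")


class EstimatorSettings(BaseModel):
    """Shared estimator configuration; the seed must be set explicitly."""

    seed: int
    n_boot: int = 1000
    n_sim: int = 5000
    phi: float = 1.0
    se_order: str = "first"
    palindrome_policy: str = "drop_ambiguous"
    eaf_window: float = 0.08
    sensitivity: tuple[str, ...] = ("Egger", "WeightedMedian", "SimpleMode", "WeightedMode")


class TraitFile(BaseModel):
    label: str
    path: str
    trait_type: str = "continuous"
    unit_note: str = ""
    dialect: Optional[dict[str, str]] = None


class ExposureSpec(TraitFile):
    #: optional file listing instrument ids (e.g. fetal-only variants), one per line
    instrument_list: Optional[str] = None


class PipelineConfig(BaseModel):
    exposures: list[ExposureSpec]
    outcomes: list[TraitFile]
    mediators: list[TraitFile] = Field(default_factory=list)
    ld: Optional[str] = None
    proxy_map: Optional[str] = None
    criteria: InstrumentCriteria = Field(default_factory=InstrumentCriteria)
    estimators: EstimatorSettings
    out_dir: str = "mr_out"
    #: outcome label -> present ORs per 1-SD *lower* exposure
    sign_flip_display: dict[str, bool] = Field(default_factory=dict)

    def config_hash(self) -> str:
        # the output directory does not influence any analysis result
        payload = self.model_dump_json(exclude={"out_dir"})
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate_json(Path(path).read_text())


def sensitivity_battery(
    H: HarmonizedSet, settings: EstimatorSettings
) -> dict[str, MREstimate]:
    """Run the configured subset of sensitivity estimators."""
    out: dict[str, MREstimate] = {}
    for name in settings.sensitivity:
        if name == "Egger":
            out[name] = mr_egger(H)
        elif name == "WeightedMedian":
            out[name] = weighted_median(H, settings.n_boot, settings.seed, settings.se_order)
        elif name == "SimpleMode":
            out[name] = mode_estimate(
                H, False, settings.phi, settings.n_boot, settings.seed, settings.se_order
            )
        elif name == "WeightedMode":
            out[name] = mode_estimate(
                H, True, settings.phi, settings.n_boot, settings.seed, settings.se_order
            )
        else:
            raise MRError(f"unknown sensitivity estimator {name!r}")
    return out


@dataclass
class TotalEffectResult:
    """Phase-1 outputs for one (exposure, outcome) pair."""

    exposure_label: str
    outcome_label: str
    estimates: dict[str, MREstimate]
    presso: PressoResult
    loo: pd.DataFrame
    harmonized: HarmonizedSet
    grade: EvidenceGrade | None = None

    @property
    def ivw(self) -> MREstimate:
        return self.estimates["IVW"]


def total_effect_analysis(
    H: HarmonizedSet, settings: EstimatorSettings
) -> TotalEffectResult:
    """IVW plus the full sensitivity battery, PRESSO and leave-one-out."""
    estimates = {"IVW": ivw(H, "multiplicative_random", settings.se_order)}
    estimates.update(sensitivity_battery(H, settings))
    presso = mr_presso(H, settings.n_sim, settings.seed)
    estimates["MRPRESSO_corrected"] = presso.corrected
    return TotalEffectResult(
        exposure_label=H.exposure_label,
        outcome_label=H.outcome_label,
        estimates=estimates,
        presso=presso,
        loo=leave_one_out(H, settings.se_order),
        harmonized=H,
    )


def _estimate_row(est: MREstimate, binary: bool, flip: bool) -> dict:
    sign = -1.0 if flip else 1.0
    row = {
        "method": est.method,
        "n_snp": est.n_snp,
        "beta": sign * est.beta,
        "se": est.se,
        "pval": est.pval,
        "or": "",
        "or_lo95": "",
        "or_hi95": "",
        "q": est.q_stat if est.q_stat is not None else "",
        "q_df": est.q_df if est.q_df is not None else "",
        "q_p": est.q_p if est.q_p is not None else "",
        "egger_intercept": est.intercept if est.intercept is not None else "",
        "egger_intercept_p": est.intercept_p if est.intercept_p is not None else "",
        "mean_f": est.mean_f if est.mean_f is not None else "",
    }
    if binary:
        import math

        b, s = sign * est.beta, est.se
        row["or"] = math.exp(b)
        row["or_lo95"] = math.exp(b - 1.96 * s)
        row["or_hi95"] = math.exp(b + 1.96 * s)
    return row


def _write_tsv(df: pd.DataFrame, path: Path, header_meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in header_meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def _load_trait(spec: TraitFile) -> SummaryStats:
    return read_gwas_table(
        spec.path, spec.dialect, spec.label, spec.trait_type, spec.unit_note
    )


def _load_instruments(
    spec: ExposureSpec,
    ld: PairwiseLD | None,
    criteria: InstrumentCriteria,
    proxy_map: dict[str, str] | None,
) -> SummaryStats:
    stats = _load_trait(spec)
    if proxy_map:
        stats = stats.rename_variants(proxy_map)
    restrict = None
    if spec.instrument_list:
        restrict = [
            line.strip()
            for line in Path(spec.instrument_list).read_text().splitlines()
            if line.strip()
        ]
        if proxy_map:
            restrict = [proxy_map.get(v, v) for v in restrict]
    return select_instruments(stats, ld, criteria, restrict)


def read_proxy_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


@dataclass
class Phase1Report:
    results: dict[tuple[str, str], TotalEffectResult] = field(default_factory=dict)

    def get(self, exposure: str, outcome: str) -> TotalEffectResult:
        return self.results[(exposure, outcome)]


def run_phase1(config: PipelineConfig) -> Phase1Report:
    """Total-effect analyses for every exposure-variant × outcome pair.

    Writes one report TSV (six method rows) and one leave-one-out TSV
    per pair, plus a JSON sidecar; any stage error is re-raised with
    the trait-pair context attached.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ld = read_ld_table(config.ld) if config.ld else None
    proxy = read_proxy_map(config.proxy_map) if config.proxy_map else None
    meta = {"config_hash": config.config_hash(), "seed": config.estimators.seed}
    report = Phase1Report()
    for exp_spec in config.exposures:
        try:
            instruments = _load_instruments(exp_spec, ld, config.criteria, proxy)
        except MRError as err:
            raise MRError(f"[phase1 exposure={exp_spec.label}] {err}") from err
        # grade each outcome against an FDR family spanning the outcomes
        pair_results = []
        for out_spec in config.outcomes:
            try:
                outcome = _load_trait(out_spec)
                H = harmonize(
                    instruments, outcome,
                    config.estimators.palindrome_policy, config.estimators.eaf_window,
                )
                res = total_effect_analysis(H, config.estimators)
            except MRError as err:
                raise MRError(
                    f"[phase1 exposure={exp_spec.label} outcome={out_spec.label}] {err}"
                ) from err
            pair_results.append((out_spec, res))
        qvals = bh_fdr([r.ivw.pval for _, r in pair_results])
        for (out_spec, res), q in zip(pair_results, qvals):
            sens = [res.estimates[m] for m in config.estimators.sensitivity]
            res.grade = grade_evidence(res.ivw.pval, float(q), res.ivw.beta, sens)
            flip = config.sign_flip_display.get(out_spec.label, False)
            binary = out_spec.trait_type == "binary"
            rows = [
                _estimate_row(res.estimates[m], binary, flip)
                for m in PHASE1_METHODS
                if m in res.estimates
            ]
            stem = f"phase1_{exp_spec.label}_{out_spec.label}"
            pair_meta = dict(meta, exposure=exp_spec.label, outcome=out_spec.label,
                             grade=res.grade.label, sign_flip_display=flip)
            _write_tsv(pd.DataFrame(rows), out_dir / f"{stem}.tsv", pair_meta)
            _write_tsv(res.loo, out_dir / f"{stem}_loo.tsv", pair_meta)
            res.presso.to_json(out_dir / f"{stem}_presso.json")
            sidecar = {
                m: {
                    "beta": e.beta, "se": e.se, "pval": e.pval, "n_snp": e.n_snp,
                    "intercept": e.intercept, "intercept_p": e.intercept_p,
                    "q": e.q_stat, "q_df": e.q_df, "q_p": e.q_p, "mean_f": e.mean_f,
                }
                for m, e in res.estimates.items()
            }
            sidecar["_meta"] = pair_meta
            (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
            report.results[(exp_spec.label, out_spec.label)] = res
            logger.info("phase1 %s -> %s: IVW beta=%.4f p=%.3g",
                        exp_spec.label, out_spec.label, res.ivw.beta, res.ivw.pval)
    return report


def run_phase2(config: PipelineConfig, phase1: Phase1Report) -> dict[tuple[str, str], list[MediationResult]]:
    """Candidate screening and mediation quantification.

    For each (exposure, outcome) pair: per candidate, step-1 UVMR
    (exposure→mediator) and step-2 MV-IVW (mediator→outcome adjusted
    for exposure, MVMR-Egger as a check); FDR across the candidate
    battery; proportions for qualified candidates.  Candidates whose
    instruments cannot be built are excluded with a logged reason.
    """
    if not config.mediators:
        raise MRError("phase 2 requires at least one candidate mediator")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ld = read_ld_table(config.ld) if config.ld else None
    proxy = read_proxy_map(config.proxy_map) if config.proxy_map else None
    all_results: dict[tuple[str, str], list[MediationResult]] = {}
    for exp_spec in config.exposures:
        instruments = _load_instruments(exp_spec, ld, config.criteria, proxy)
        exposure_full = _load_trait(exp_spec)
        if proxy:
            exposure_full = exposure_full.rename_variants(proxy)
        for out_spec in config.outcomes:
            total = phase1.get(exp_spec.label, out_spec.label).ivw
            outcome = _load_trait(out_spec)
            candidates: list[MediationCandidate] = []
            for med_spec in config.mediators:
                try:
                    mediator = _load_trait(med_spec)
                    if proxy:
                        mediator = mediator.rename_variants(proxy)
                    H1 = harmonize(
                        instruments, mediator,
                        config.estimators.palindrome_policy, config.estimators.eaf_window,
                    )
                    step1 = ivw(H1, "multiplicative_random", config.estimators.se_order)
                    sens = list(sensitivity_battery(H1, config.estimators).values())
                    M = build_mvmr_set(
                        [exposure_full, mediator], outcome, ld, config.criteria,
                        config.estimators.palindrome_policy, config.estimators.eaf_window,
                    )
                    mv_estimates = mv_ivw(M)
                    step2 = mv_estimates[1]  # the mediator's direct effect
                    mv_egger_est = mv_egger(M)  # robustness check
                    write_mvmr_tsv(
                        mv_estimates + mv_egger_est,
                        out_dir / f"phase2_{exp_spec.label}_{out_spec.label}_mvmr_{med_spec.label}.tsv",
                    )
                except MRError as err:
                    logger.warning(
                        "phase2 %s -> %s: candidate %s excluded (%s)",
                        exp_spec.label, out_spec.label, med_spec.label, err,
                    )
                    continue
                candidates.append(
                    MediationCandidate(
                        label=med_spec.label,
                        step1=step1,
                        step2=step2,
                        total=total,
                        step1_sensitivity=sens,
                    )
                )
            results = screen_mediators(candidates)
            all_results[(exp_spec.label, out_spec.label)] = results
            rows = [
                {
                    "mediator": r.mediator_label,
                    "beta1": r.beta1,
                    "se1": r.se1,
                    "beta2": r.beta2,
                    "se2": r.se2,
                    "indirect": r.indirect,
                    "se_indirect": r.se_indirect,
                    "total": r.total,
                    "proportion_pct": "" if r.proportion_pct is None else r.proportion_pct,
                    "proportion_se_pct": "" if r.se_proportion is None else 100 * r.se_proportion,
                    "truncated": r.truncated,
                    "qualified": r.qualified,
                    "failed_criteria": ",".join(map(str, sorted(r.failed_criteria))),
                    "grade": r.step1_grade.label if r.step1_grade else "",
                }
                for r in results
            ]
            columns = [
                "mediator", "beta1", "se1", "beta2", "se2", "indirect", "se_indirect",
                "total", "proportion_pct", "proportion_se_pct", "truncated",
                "qualified", "failed_criteria", "grade",
            ]
            stem = f"phase2_{exp_spec.label}_{out_spec.label}"
            _write_tsv(
                pd.DataFrame(rows, columns=columns),
                out_dir / f"{stem}.tsv",
                {"config_hash": config.config_hash(), "seed": config.estimators.seed,
                 "exposure": exp_spec.label, "outcome": out_spec.label},
            )
            (out_dir / f"{stem}.json").write_text(
                json.dumps(rows, indent=2, default=str)
            )
    return all_results
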