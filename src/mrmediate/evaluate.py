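"""Monte-Carlo evaluation studies for the MR estimators.

Each function runs a replicated simulation study under the reference
synthetic conditions (see :class:`~mrmediate.synthetic.SimulationConfig`
defaults) and returns summary metrics: parameter recovery and CI
coverage, Egger intercept calibration and power, robustness of the
weighted median under invalid instruments, MR-PRESSO detection and
null calibration, mediation-proportion recovery and screening
operating characteristics.

Replicate counts are arguments so studies can be scaled; the defaults
are the sizes used throughout the documentation.  Every study derives
its per-replicate seeds from one master seed.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps

from .mediation import MediationCandidate, mediation_effect, mediation_proportion, screen_mediators
from .mvmr import build_mvmr_set, mv_ivw
from .presso import mr_presso
from .summary_io import HarmonizedSet, harmonize, select_instruments
from .synthetic import (
    CandidateSpec,
    OutlierConfig,
    PleiotropyConfig,
    SimulationConfig,
    simulate_mediation_battery,
    simulate_summary_stats,
)
from .uvmr import ivw, mr_egger, ratio_arrays, weighted_median, weighted_median_point
from .uvmr import _mode_bandwidth, mode_point  # point estimators for replicate loops


def _seeds(master_seed: int, n: int) -> np.ndarray:
    """Per-replicate seeds below 2^31, derived from one master seed."""
    return np.random.default_rng(master_seed).integers(1, 2**31 - 1, size=n)


def _simulate_harmonized(config: SimulationConfig) -> tuple[HarmonizedSet, float]:
    study = simulate_summary_stats(config)
    instruments = select_instruments(study.exposure)
    H = harmonize(instruments, study.outcome)
    return H, study.truth.true_total


def estimator_recovery(n_rep: int = 500, seed: int = 0, config: SimulationConfig | None = None) -> dict:
    """Parameter recovery of IVW, weighted median and both modes.

    Replicates the reference study (J = 120 instruments, true total
    effect 0.336, no pleiotropy), records each estimator's point
    estimate per replicate and whether the IVW 95% CI covers the truth.
    """
    base = config or SimulationConfig(seed=0)
    est = {"IVW": [], "WeightedMedian": [], "SimpleMode": [], "WeightedMode": []}
    covered = 0
    truth = base.true_total
    for s in _seeds(seed, n_rep):
        H, truth = _simulate_harmonized(base.model_copy(update={"seed": int(s)}))
        fit = ivw(H)
        est["IVW"].append(fit.beta)
        lo, hi = fit.ci
        covered += lo <= truth <= hi
        r, se = ratio_arrays(H)
        w = se**-2
        est["WeightedMedian"].append(weighted_median_point(r, w))
        h = _mode_bandwidth(r, 1.0)
        est["SimpleMode"].append(mode_point(r, np.full(len(r), 1 / len(r)), h))
        est["WeightedMode"].append(mode_point(r, w / w.sum(), h))
    out = {"true_total": truth, "n_rep": n_rep, "ivw_coverage": covered / n_rep}
    for k, v in est.items():
        v = np.asarray(v)
        out[k] = {
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)),
            "mc_se": float(v.std(ddof=1) / math.sqrt(n_rep)),
        }
    return out


def egger_calibration(
    n_rep: int = 1000, seed: int = 0, kind: str = "balanced", alpha: float = 0.05
) -> dict:
    """Rejection rate of the MR-Egger intercept test.

    ``balanced`` pleiotropy (zero mean, InSIDE satisfied) measures the
    type-I error; ``directional`` (mean = 2× the sd) measures power.
    """
    pleio = PleiotropyConfig(
        kind=kind, mean=0.02 if kind == "directional" else 0.0, sd=0.01
    )
    base = SimulationConfig(seed=0, pleiotropy=pleio)
    rejections = 0
    for s in _seeds(seed, n_rep):
        H, _ = _simulate_harmonized(base.model_copy(update={"seed": int(s)}))
        rejections += mr_egger(H).intercept_p < alpha
    return {"kind": kind, "n_rep": n_rep, "rejection_rate": rejections / n_rep}


def robustness_contamination(n_rep: int = 500, seed: int = 0, frac_invalid: float = 0.4) -> dict:
    """IVW versus weighted-median bias with invalid instruments.

    A ``frac_invalid`` share of instruments carries strong directional
    pleiotropy; the weighted median should stay close to the truth
    while IVW drifts.
    """
    pleio = PleiotropyConfig(kind="directional", mean=0.05, sd=0.01, frac=frac_invalid)
    base = SimulationConfig(seed=0, pleiotropy=pleio)
    truth = base.true_total
    ivw_b, wm_b = [], []
    for s in _seeds(seed, n_rep):
        H, _ = _simulate_harmonized(base.model_copy(update={"seed": int(s)}))
        ivw_b.append(ivw(H).beta)
        r, se = ratio_arrays(H)
        wm_b.append(weighted_median_point(r, se**-2))
    return {
        "n_rep": n_rep,
        "true_total": truth,
        "ivw_mean_bias": float(np.mean(ivw_b) - truth),
        "weighted_median_mean_bias": float(np.mean(wm_b) - truth),
    }


def presso_detection(
    n_rep: int = 200, seed: int = 0, n_sim: int = 1000, n_snp: int = 8
) -> dict:
    """Planted-outlier detection and correction with MR-PRESSO.

    One instrument's outcome effect is displaced by 10 sampling SDs;
    reports how often it is flagged with the minimum outlier p, and how
    often the corrected estimate lands closer to the truth than raw
    IVW.  The study uses a small instrument set (default 8) where a
    single outlier is influential: with many instruments one outlier
    barely moves IVW and "correction improves the estimate" is decided
    by estimator noise rather than by the outlier.
    """
    base = SimulationConfig(
        seed=0, n_snp=n_snp, n_snp_mediator=0,
        outlier=OutlierConfig(count=1, displacement_sd=10.0),
    )
    truth = base.true_total
    flagged = min_p = improved = 0
    for s in _seeds(seed, n_rep):
        study = simulate_summary_stats(base.model_copy(update={"seed": int(s)}))
        H = harmonize(select_instruments(study.exposure), study.outcome)
        planted = study.truth.outlier_ids[0]
        res = mr_presso(H, n_sim=n_sim, seed=int(s))
        flagged += planted in res.outliers
        min_p += planted == min(res.outlier_p, key=res.outlier_p.get)
        raw = ivw(H).beta
        improved += abs(res.corrected.beta - truth) < abs(raw - truth)
    return {
        "n_rep": n_rep,
        "detection_rate": flagged / n_rep,
        "min_p_rate": min_p / n_rep,
        "correction_improvement_rate": improved / n_rep,
    }


def presso_null_calibration(
    n_rep: int = 500, seed: int = 0, n_sim: int = 1000, n_snp: int = 25
) -> dict:
    """Uniformity of the MR-PRESSO global p under the null generator.

    Returns the Kolmogorov–Smirnov statistic of the global p-values
    against Uniform(0,1), plus the fraction of replicates with any
    outlier flagged (false-positive rate of the outlier test).
    """
    base = SimulationConfig(seed=0, n_snp=n_snp, n_snp_mediator=0)
    pvals, any_flagged = [], 0
    for s in _seeds(seed, n_rep):
        study = simulate_summary_stats(base.model_copy(update={"seed": int(s)}))
        H = harmonize(select_instruments(study.exposure), study.outcome)
        res = mr_presso(H, n_sim=n_sim, seed=int(s))
        pvals.append(res.global_p)
        any_flagged += bool(res.outliers)
    ks = sps.kstest(pvals, "uniform").statistic
    return {
        "n_rep": n_rep,
        "ks_statistic": float(ks),
        "outlier_false_positive_rate": any_flagged / n_rep,
    }


def mediation_recovery(n_rep: int = 500, seed: int = 0) -> dict:
    """Two-step mediation recovery under the reference chain.

    True proportion 25% (β_XM = 0.5, β_MY = 0.168, direct 0.252); the
    per-replicate estimate is (β̂1·β̂2)/total with β̂1 from UVMR and β̂2
    from MV-IVW.  Reports the mean estimated proportion, the ratio of
    the mean delta-method SE to the empirical SD, and whether
    truncation ever fired without a negative raw proportion.
    """
    base = SimulationConfig(seed=0)
    props, prop_ses, bad_truncations = [], [], 0
    for s in _seeds(seed, n_rep):
        study = simulate_summary_stats(base.model_copy(update={"seed": int(s)}))
        instruments = select_instruments(study.exposure)
        H1 = harmonize(instruments, study.mediator)
        beta1 = ivw(H1)
        M = build_mvmr_set([study.exposure, study.mediator], study.outcome)
        beta2 = mv_ivw(M)[1]
        H_tot = harmonize(instruments, study.outcome)
        total = ivw(H_tot)
        indirect, se_ind = mediation_effect(beta1.beta, beta1.se, beta2.beta, beta2.se)
        prop, se_prop, truncated = mediation_proportion(
            indirect, se_ind, total.beta, total.se
        )
        if truncated and indirect / total.beta >= 0:
            bad_truncations += 1
        props.append(prop)
        prop_ses.append(se_prop)
    props = np.asarray(props)
    return {
        "n_rep": n_rep,
        "true_proportion_pct": 100 * base.true_indirect / base.true_total,
        "mean_proportion_pct": float(100 * props.mean()),
        "empirical_sd_pct": float(100 * props.std(ddof=1)),
        "mean_delta_se_pct": float(100 * np.mean(prop_ses)),
        "bad_truncations": bad_truncations,
    }


DEFAULT_BATTERY = (
    CandidateSpec(label="true_mediator", beta_xm=0.5, beta_my=0.168),
    CandidateSpec(label="null_1"),
    CandidateSpec(label="null_2"),
    CandidateSpec(label="null_3"),
    CandidateSpec(label="null_4"),
    CandidateSpec(label="null_5"),
)


def screening_performance(
    n_rep: int = 200,
    seed: int = 0,
    candidates: tuple[CandidateSpec, ...] = DEFAULT_BATTERY,
    n_boot: int = 200,
) -> dict:
    """Operating characteristics of the three-criterion mediator screen.

    With the default battery (one true mediator among six candidates)
    reports how often exactly the true mediator qualifies; null
    candidates' qualification events are pooled into a false-positive
    rate per candidate-replicate.
    """
    base = SimulationConfig(seed=0, n_snp_mediator=0)
    exactly_true = 0
    null_qualifications = null_tests = 0
    true_labels = {c.label for c in candidates if c.beta_xm * c.beta_my != 0}
    for s in _seeds(seed, n_rep):
        sim = simulate_mediation_battery(
            base.model_copy(update={"seed": int(s)}), list(candidates)
        )
        instruments = select_instruments(sim.exposure)
        H_tot = harmonize(instruments, sim.outcome)
        total = ivw(H_tot)
        cands = []
        for spec in candidates:
            med = sim.mediators[spec.label]
            H1 = harmonize(instruments, med)
            step1 = ivw(H1)
            sens = [weighted_median(H1, n_boot, int(s)), mr_egger(H1)]
            M = build_mvmr_set([sim.exposure, med], sim.outcome)
            step2 = mv_ivw(M)[1]
            cands.append(
                MediationCandidate(spec.label, step1, step2, total, sens)
            )
        results = screen_mediators(cands)
        qualified = {r.mediator_label for r in results if r.qualified}
        exactly_true += qualified == true_labels
        null_tests += len(candidates) - len(true_labels)
        null_qualifications += len(qualified - true_labels)
    return {
        "n_rep": n_rep,
        "exact_qualification_rate": exactly_true / n_rep,
        "null_qualification_rate": null_qualifications / max(null_tests, 1),
    }
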