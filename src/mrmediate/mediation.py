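"""Two-step MR mediation: screening, product of coefficients, FDR, grading.

Step 1 estimates the exposure→mediator effect (β1, univariable MR);
step 2 estimates the mediator→outcome effect adjusted for the exposure
(β2, multivariable MR).  The indirect effect is the product β1·β2 with
a first-order delta-method SE, and the mediation proportion is the
indirect effect divided by the total effect, truncated below at 0%.

Candidates qualify as mediators when
(1) the exposure is causally associated with the mediator — graded at
    least suggestive after Benjamini-Hochberg FDR across the candidate
    battery;
(2) the mediator has a direct effect on the outcome independent of the
    exposure (MV-IVW p < 0.05); and
(3) the indirect effect and the total effect share a sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import UndefinedProportionError, ValidationError
from .uvmr import MREstimate


def mediation_effect(
    beta1: float, se1: float, beta2: float, se2: float
) -> tuple[float, float]:
    """Indirect effect β1·β2 with the first-order delta-method SE.

    se = sqrt(β1²·se2² + β2²·se1²); the second-order se1²·se2² cross
    term is omitted (the dominant convention in two-step MR).
    """
    if se1 < 0 or se2 < 0:
        raise ValidationError("standard errors must be non-negative")
    indirect = beta1 * beta2
    se = math.sqrt(beta1**2 * se2**2 + beta2**2 * se1**2)
    return indirect, se


def mediation_proportion(
    indirect: float, se_indirect: float, total: float, se_total: float
) -> tuple[float, float, bool]:
    """Mediation proportion indirect/total, truncated below at 0.

    The SE uses the first-order ratio delta method treating the
    indirect and total effects as independent:
    |raw| · sqrt(se_ind²/ind² + se_tot²/tot²), and 0 when the indirect
    effect is exactly 0.  Returns (proportion, se, truncated).
    """
    if total == 0:
        raise UndefinedProportionError("total effect is zero; proportion undefined")
    raw = indirect / total
    if indirect == 0:
        se = 0.0
    else:
        se = abs(raw) * math.sqrt(
            se_indirect**2 / indirect**2 + se_total**2 / total**2
        )
    truncated = raw < 0
    return (0.0 if truncated else raw), se, truncated


def bh_fdr(pvals: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    q_i = min over j with p_(j) >= p_(i) of m·p_(j)/j; monotone
    non-decreasing in p and order-equivariant.
    """
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class EvidenceGrade:
    """Strength-of-evidence label for one IVW estimate."""

    label: str  # causal | suggestive | none
    ivw_p: float
    fdr_q: float
    n_sensitivity_support: int


def grade_evidence(
    ivw_p: float,
    fdr_q: float,
    ivw_beta: float,
    sensitivity_estimates: list[MREstimate],
) -> EvidenceGrade:
    """Grade an IVW estimate against FDR and its sensitivity battery.

    A sensitivity analysis "supports" the IVW estimate when its p is
    below 0.05 and its beta shares the IVW sign.  Causal evidence needs
    ivw_p < 0.05, q < 0.05 and at least one support; ivw_p < 0.05
    without both is suggestive; ivw_p >= 0.05 is none.
    """
    support = sum(
        1
        for e in sensitivity_estimates
        if e.pval < 0.05 and np.sign(e.beta) == np.sign(ivw_beta)
    )
    if ivw_p < 0.05 and fdr_q < 0.05 and support >= 1:
        label = "causal"
    elif ivw_p < 0.05:
        label = "suggestive"
    else:
        label = "none"
    return EvidenceGrade(label, ivw_p, fdr_q, support)


@dataclass
class MediationCandidate:
    """Inputs for one candidate mediator in the screening battery."""

    label: str
    step1: MREstimate  # exposure -> mediator (UVMR)
    step2: MREstimate  # mediator -> outcome | exposure (MV-IVW)
    total: MREstimate  # exposure -> outcome (UVMR)
    step1_sensitivity: list[MREstimate] = field(default_factory=list)


@dataclass
class MediationResult:
    """Screening outcome and (for qualified candidates) the proportion."""

    mediator_label: str
    beta1: float
    se1: float
    beta2: float
    se2: float
    indirect: float
    se_indirect: float
    total: float
    se_total: float
    proportion: float | None
    se_proportion: float | None
    truncated: bool
    qualified: bool
    failed_criteria: set[int]
    step1_grade: EvidenceGrade | None = None

    @property
    def proportion_pct(self) -> float | None:
        return None if self.proportion is None else 100.0 * self.proportion


def screen_mediators(candidates: list[MediationCandidate]) -> list[MediationResult]:
    """Apply the three mediation criteria across a candidate battery.

    FDR is computed once across the whole battery (one family).  Only
    qualified candidates receive a mediation proportion; all candidates
    report which criteria failed.
    """
    if not candidates:
        return []
    qvals = bh_fdr([c.step1.pval for c in candidates])
    results = []
    for cand, q in zip(candidates, qvals):
        grade = grade_evidence(
            cand.step1.pval, float(q), cand.step1.beta, cand.step1_sensitivity
        )
        indirect, se_indirect = mediation_effect(
            cand.step1.beta, cand.step1.se, cand.step2.beta, cand.step2.se
        )
        failed: set[int] = set()
        if grade.label == "none":
            failed.add(1)
        if not cand.step2.pval < 0.05:
            failed.add(2)
        if np.sign(indirect) != np.sign(cand.total.beta) or indirect == 0:
            failed.add(3)
        qualified = not failed
        if qualified:
            prop, se_prop, truncated = mediation_proportion(
                indirect, se_indirect, cand.total.beta, cand.total.se
            )
        else:
            prop, se_prop, truncated = None, None, False
        results.append(
            MediationResult(
                mediator_label=cand.label,
                beta1=cand.step1.beta,
                se1=cand.step1.se,
                beta2=cand.step2.beta,
                se2=cand.step2.se,
                indirect=indirect,
                se_indirect=se_indirect,
                total=cand.total.beta,
                se_total=cand.total.se,
                proportion=prop,
                se_proportion=se_prop,
                truncated=truncated,
                qualified=qualified,
                failed_criteria=failed,
                step1_grade=grade,
            )
        )
    return results
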