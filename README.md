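# mrmediate

Two-sample Mendelian randomization (MR) with two-step mediation, built
for studies that ask not only *whether* an early-life exposure (such as
birthweight) causally affects a later disease (such as myocardial
infarction or atrial fibrillation), but *through which modifiable
pathways* the effect flows. Everything runs on GWAS summary statistics
— no individual-level genotypes — and a seeded simulator generates
complete synthetic studies with known ground truth so every stage is
testable by parameter recovery.

## What it implements

For an exposure X, outcome Y and candidate mediator M, with per-SNP
summary associations γ̂_j (SNP→exposure) and Γ̂_j (SNP→outcome):

- **Instrument selection** — genome-wide significance filter
  (p < 5×10⁻⁸ by default) and greedy LD clumping (r² < 0.001 within a
  10,000 kb window), with support for restricted instrument lists
  (e.g. fetal-only or maternal-only birthweight variants).
- **Harmonization** — aligning exposure and outcome tables to one
  effect-allele convention, with configurable handling of palindromic
  (A/T, C/G) variants.
- **Univariable MR** — Wald ratios β_j = Γ̂_j/γ̂_j combined by
  inverse-variance weighting (β_IVW = Σw_jβ_j/Σw_j, multiplicative
  random effects), MR-Egger regression (free intercept as a
  directional-pleiotropy test), weighted median, simple/weighted mode,
  Cochran's Q, per-SNP F statistics and leave-one-out.
- **MR-PRESSO** — simulation-based global heterogeneity test, per-SNP
  outlier test (Bonferroni-flagged) and outlier-corrected IVW.
- **Multivariable MR** — MV-IVW and MVMR-Egger on the union of
  instruments significant for any exposure, estimating each trait's
  direct effect conditional on the others.
- **Two-step mediation** — β₁ (X→M, UVMR) and β₂ (M→Y adjusted for X,
  MVMR); indirect effect β₁β₂ with delta-method SE
  √(β₁²se₂² + β₂²se₁²); mediation proportion β₁β₂/β_total truncated
  below at 0%; Benjamini-Hochberg FDR across the candidate battery and
  a three-criterion screen with causal/suggestive evidence grading.
- **Synthetic data** — seeded multi-trait GWAS generator under an
  explicit X→M→Y diagram with configurable pleiotropy, planted
  outliers, LD blocks and fetal/maternal instrument classes.

## Worked example

```python
from mrmediate import (SimulationConfig, simulate_summary_stats,
                       select_instruments, harmonize, ivw)

study = simulate_summary_stats(SimulationConfig(seed=1))
H = harmonize(select_instruments(study.exposure), study.outcome)
est = ivw(H, model="multiplicative_random")
```

Running `python examples/01_total_effect.py` (which does exactly this)
prints:

```
instruments selected : 120
IVW log-odds effect  : 0.3271 (SE 0.0106, p = 7.49e-209)
IVW odds ratio       : 1.39 (1.36-1.42)
true total effect    : 0.3360 (OR 1.40)
Cochran's Q          : 128.7 on 119 df (p = 0.26)
mean F statistic     : 4807
Egger intercept      : 0.0018 (p = 0.72)
```

The simulator planted a true total effect of ln(1.40) = 0.336 on the
log-odds scale; IVW recovers OR 1.39 with a covering confidence
interval, Q/df ≈ 1.08 shows no excess heterogeneity, the large mean F
confirms strong instruments, and the near-zero Egger intercept shows
no directional pleiotropy (none was simulated). The remaining example
scripts walk through the sensitivity battery with a planted outlier
(`02`), multivariable direct effects (`03`), the two-step mediation
decomposition recovering the planted 25% mediated share (`04`) and the
full two-phase file pipeline with a candidate battery (`05`).

A thin CLI wraps the pipeline for shell use:

```bash
mrmediate simulate --config sim.json --out data/
mrmediate all --config pipeline.json --out reports/
```

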