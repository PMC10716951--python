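# Methods

## Model and notation

Two-sample MR treats genetic variants as instruments for an exposure.
For variant j, γ_j is the per-allele effect on the exposure (with SE
σ_γj, from one GWAS) and Γ_j the per-allele effect on the outcome
(σ_Γj, from an independent GWAS). Under the instrumental-variable
assumptions (relevance, independence from confounders, no effect on
the outcome except through the exposure), each Wald ratio
β_j = Γ_j/γ_j estimates the same causal effect β, on the outcome's
scale per unit of exposure — log-odds per 1-SD exposure when the
outcome is binary, so exp(β) is an odds ratio.

All estimator p-values are two-sided normal. This is a deliberate
large-J asymptotic choice (instrument counts in this setting are
typically 20–120); no t correction is applied anywhere, which keeps
every estimator's inference internally consistent.

## Univariable estimators

**IVW.** β̂ = Σw_jβ_j/Σw_j with first-order weights
w_j = γ_j²/σ_Γj² (equivalently, weighted regression of Γ on γ through
the origin with weights σ_Γj⁻²). The fixed-effect SE (Σw_j)^(-1/2) is
inflated by max(1, √(Q/(J−1))) — multiplicative over-dispersion, the
behaviour of mainstream two-sample MR software. Additive random
effects are out of scope. Wald-ratio SEs default to first order
(σ_Γj/|γ_j|); the second-order form (adding Γ_j²σ_γj²/γ_j⁴) is
available by flag but does not feed the default weights.

**MR-Egger.** Weighted regression of Γ on γ *with* intercept, after
flipping SNPs so γ_j ≥ 0 (Egger is not orientation-invariant; this is
the canonical convention). The intercept estimates the mean
directional pleiotropic effect; its test is consistent under InSIDE
(instrument strength independent of direct effects). Both SEs carry
the multiplicative inflation max(1, √(Q_egger/(J−2))).

**Weighted median.** The 50% weighted percentile of the ratio
estimates, consistent while valid instruments hold >50% of the weight.
The percentile convention is the type-2 weighted quantile: the ratio
whose normalized cumulative-weight interval strictly contains 0.5,
averaging the two adjacent ratios when 0.5 falls exactly on an
interval boundary. This convention (rather than midpoint
interpolation) makes the >50%-weight breakdown property exact in
finite samples: any group of SNPs sharing a ratio and holding more
than half the weight returns that ratio identically. SEs come from a
parametric bootstrap — γ*_j ~ N(γ_j, σ_γj²), Γ*_j ~ N(Γ_j, σ_Γj²),
re-estimate, SD over n_boot = 1000 draws; the seed is mandatory (no
clock seeding anywhere in the package).

**Mode estimators.** Normal-kernel density over the ratios with
bandwidth h = φ·0.9·min(sd, 1.4826·MAD)·J^(−1/5) (modified Silverman
rule with a MAD scale, φ default 1.0); the estimate is the density
argmax over 512 evenly spaced grid points spanning the ratio range ± 3
bandwidths, first maximum on ties. The weighted variant scales each
kernel by w_j/Σw_j. If all ratios coincide the common ratio is
returned. SEs use the same parametric bootstrap.

**Diagnostics.** Cochran's Q = Σw_j(β_j − β̂)² with a χ²_{J−1} tail;
per-SNP instrument strength F_j = γ_j²/σ_γj² reported as the mean;
leave-one-out refits the multiplicative-random IVW once per excluded
SNP.

## MR-PRESSO

The observed statistic is RSS = Σ_j σ_Γj⁻²(Γ_j − β̂_(−j)γ_j)², where
β̂_(−j) is the IVW slope with SNP j held out. The null distribution is
built by drawing, n_sim times, γ*_j ~ N(γ_j, σ_γj²) and
Γ*_j ~ N(β̂_(−j)γ_j, σ_Γj²), recomputing the leave-one-out slopes on
the starred data and re-evaluating RSS. Global and per-SNP p-values
use the add-one estimator (1 + #{exceedances})/(n_sim + 1), so the
attainable floor is 1/(n_sim+1); n_sim defaults to 5000 and both γ and
Γ are resampled. A SNP is an outlier when its Bonferroni-adjusted
per-SNP p is below 0.05; the corrected estimate is the
multiplicative-random IVW on the survivors. The distortion test
(significance of the raw-vs-corrected shift) is intentionally not
computed. Draws happen in sorted-variant order through a single
seeded generator, so results are bitwise identical for a given seed
and invariant to input row order.

## Multivariable MR

The joint instrument set is the union of variants genome-wide
significant for *any* exposure, clumped on the minimum p across
exposures (union-then-clump; the ranking statistic was an open choice
and min-p is declared here), harmonized to the first exposure's allele
convention, and dropped when absent or irreconcilable in any trait.
MV-IVW solves the weighted normal equations of Γ on the K exposure
columns without intercept (weights σ_Γ⁻², inflation
max(1, √(RSS/(J−K)))); MVMR-Egger adds a free intercept after
orienting SNPs on the first exposure's axis. A condition number of
X'WX above 1e8 raises a collinearity error reporting the number; note
an exposure column that is exactly zero is singular by this rule and
is reported as collinear rather than silently reduced to the
univariable fit.

## Two-step mediation

β₁ is the UVMR (IVW) effect of the exposure on the mediator using the
exposure's instruments; β₂ is the mediator's MV-IVW direct effect on
the outcome adjusted for the exposure. The indirect effect is the
product β₁β₂ with first-order delta SE √(β₁²se₂² + β₂²se₁²) — the
se₁²se₂² cross term is omitted, the dominant convention. The mediation
proportion is indirect/total with total from UVMR; negative raw
proportions are truncated to 0% and flagged. Its SE is the first-order
ratio delta method treating indirect and total as independent,
|raw|·√(se_ind²/ind² + se_tot²/tot²); the covariance between the two
(they share the outcome GWAS) is ignored, a stated approximation that
the recovery study below bounds empirically (delta SE within a few
percent of the replicate SD at the reference conditions). Binary
mediators carry log-odds units through the product; proportions are
computed on whatever scale the inputs carry and unit notes are
propagated rather than converted.

Candidates qualify as mediators when (1) the exposure→mediator IVW is
graded at least suggestive after Benjamini-Hochberg FDR across the
candidate battery — one FDR family per (exposure, outcome) pair, never
per candidate; (2) the mediator's MV-IVW direct effect has p < 0.05;
and (3) the indirect and total effects share a sign. Evidence grading:
*causal* = IVW p < 0.05 and q < 0.05 and at least one sensitivity
estimator agreeing in sign with p < 0.05; *suggestive* = IVW p < 0.05
without both; *none* otherwise.

## Synthetic studies

The generator draws summary statistics directly (no individual-level
genotypes — the pipeline consumes only summary data and direct
simulation keeps runtimes at desk scale). Per variant: maf ~
U(0.05, 0.5); true exposure effect γ ~ N(0.10, 0.025); mediator effect
β_XM·γ plus, for mediator-specific instruments, an own effect from the
same distribution; outcome effect β_XY_direct·γ + β_MY·(mediator
effect) + α (pleiotropy) + any planted outlier displacement. Observed
coefficients are Normal(truth, se²) with se = 1/√(2·maf·(1−maf)·n),
the sampling SD of a per-allele coefficient for a standardized trait —
this reproduces realistic maf-driven weight heterogeneity. Exposure,
mediator and outcome samples are non-overlapping by construction (the
two-sample assumption); sample overlap, winner's curse and population
stratification are deliberately not modelled, so passing recovery
tests demonstrate estimator correctness under the two-sample ideal,
not robustness to those real-data violations. A `noiseless` flag gives
the n→∞ limit for exact-recovery checks.

Reference conditions (the defaults): 120 exposure instruments and 100
mediator-specific instruments; β_XM = 0.5, β_MY = 0.168,
β_XY_direct = 0.252, hence a total effect of 0.336 = ln(1.40) and a
25% mediated share; n_exposure = 1.2×10⁶, n_mediator = 3×10⁵,
n_outcome = 2×10⁴ (an effective case-control size of a modest outcome
GWAS; the exposure size is at the scale of the largest biobank
meta-analyses). These sizes give mean F ≈ 5000. The choice is driven
by a finite-sample property of ratio-form IVW: with first-order
weights the estimator is attenuated by roughly 3β/F̄ (the familiar
β/F̄ from E[γ̂²] = γ² + σ_γ², tripled by the correlation between the
weights and the ratios), and the recovery studies compare a
500-replicate mean against the truth at Monte-Carlo precision, so the
instruments must be strong enough that this attenuation sits well
inside the Monte-Carlo error. Weaker, more lifelike instruments
(F ≈ 30–100) would shift the mean by several Monte-Carlo SEs — a real
property of IVW, not a bug, and one reason applied MR reports F
statistics.

Pleiotropy regimes: `balanced` α ~ N(0, 0.01) satisfies InSIDE;
`directional` α ~ N(0.02, 0.01) (mean = 2× sd) on a configurable
fraction of instruments. Planted outliers displace the observed
outcome beta by displacement·se (default 10). Instrument classes
(fetal-only 0.31 / maternal-only 0.15 / shared 0.54, echoing the
63/31/205 partition of published birthweight instruments) are recorded
in the truth object with per-path effects; exclusive classes carry a
single path by construction. LD is generated as block-diagonal r²
(within-block r² ~ Beta(8, 2), between-block 0) with positions placed
inside or beyond the clumping window as configured.

The MR-PRESSO evaluation scenario uses 8 instruments: a single outlier
must carry enough relative weight that removing it dominates estimator
noise, otherwise "correction moves the estimate toward the truth" is
decided by noise (the outlier's influence on IVW scales as 1/J while
the raw/corrected noise difference scales as 1/√J).

## Numerical choices and degenerate inputs

- Positions are 1-based; the clumping window is inclusive at both ends
  (|Δpos| ≤ window_kb·1000); ties on p break lexicographically on
  variant id; an LD pair absent from the input is r² = 0.
- Palindromic variants: `drop_ambiguous` (default) keeps them only
  when the exposure EAF is outside [0.5−w, 0.5+w] (w = 0.08) and then
  trusts the reported allele letters; `infer_by_eaf` requires both
  EAFs informative and orients by minor-allele side agreement.
  Non-palindromic alleles match directly, after swap, or after strand
  complement; anything else is dropped as a mismatch, never raised.
- Estimator p-values are floored at 1e-300 so downstream FDR always
  sees p in (0, 1].
- IVW with one instrument falls back to the Wald ratio with a logged
  notice; Egger needs 3, PRESSO 4, MV-IVW K+2, MVMR-Egger K+3.
- A zero bandwidth (all ratios identical) returns the common ratio.
- Every stochastic routine takes an explicit seed; replicate studies
  derive per-replicate seeds (< 2³¹) from one master seed.

## Evaluation studies and their sizes

`mrmediate.evaluate` packages the replicated studies used by the test
suite and `scripts/acceptance.py`: 50 random instances for the
WLS-oracle equivalence; 500 replicates for estimator recovery/coverage,
contamination robustness, PRESSO null calibration and mediation
recovery; 1000 for Egger calibration and power; 200 for PRESSO
detection and the 6-candidate screening study (which uses n_boot = 200
and the weighted-median + Egger sensitivity pair for its grading step).
These sizes put Monte-Carlo error comfortably below the properties
being checked while keeping the whole battery at a few minutes on one
CPU.

## Known limitations

- No Steiger directionality filtering, contamination-mixture or CAUSE
  estimators, correlated-instrument IVW, conditional F/Q_x MVMR
  diagnostics, or MR-PRESSO distortion test.
- Proxy lookup against an LD reference service is out of scope: proxy
  variants must be pre-resolved in the input tables (a proxy-map file
  of id renames is applied before harmonization).
- Mediation proportions are per-mediator and not additive across
  mediators; exposure–mediator interactions are not modelled.
- The delta-method proportion SE ignores the indirect–total
  covariance (see above).
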