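"""Two-step MR mediation: product of coefficients and mediation proportion.

Step 1 estimates the exposure -> mediator effect (UVMR); step 2
estimates the mediator -> outcome effect adjusted for the exposure
(MV-IVW).  The indirect effect is their product with a delta-method SE,
and the mediation proportion divides it by the total effect (truncated
below at 0%).
"""

from mrmediate import (
    SimulationConfig,
    build_mvmr_set,
    harmonize,
    ivw,
    mediation_effect,
    mediation_proportion,
    mv_ivw,
    select_instruments,
    simulate_summary_stats,
)

cfg = SimulationConfig(seed=11)  # true proportion 25%
study = simulate_summary_stats(cfg)
instruments = select_instruments(study.exposure)

beta1 = ivw(harmonize(instruments, study.mediator))          # exposure -> mediator
beta2 = mv_ivw(build_mvmr_set([study.exposure, study.mediator], study.outcome))[1]
total = ivw(harmonize(instruments, study.outcome))           # exposure -> outcome

indirect, se_ind = mediation_effect(beta1.beta, beta1.se, beta2.beta, beta2.se)
prop, se_prop, truncated = mediation_proportion(indirect, se_ind, total.beta, total.se)

print(f"beta1 (X->M)        : {beta1.beta:.4f} (SE {beta1.se:.4f})   truth {cfg.beta_xm}")
print(f"beta2 (M->Y | X)    : {beta2.beta:.4f} (SE {beta2.se:.4f})   truth {cfg.beta_my}")
print(f"indirect beta1*beta2: {indirect:.4f} (SE {se_ind:.4f})   truth {cfg.true_indirect:.4f}")
print(f"total effect        : {total.beta:.4f} (SE {total.se:.4f})   truth {cfg.true_total:.4f}")
print(f"mediation proportion: {100*prop:.1f}% (SE {100*se_prop:.1f}%), truncated={truncated}")

# The proportion says how much of the exposure's total log-odds effect on the
# outcome flows through this mediator; here the generator plants a 25% share.
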