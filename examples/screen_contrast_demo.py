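"""Positive-rate screening versus the fold-change baseline.

The motivating contrast: a marker elevated in nearly all patients but by
only ~1.3-fold is exactly what a blood test wants (high positive rate,
hence high sensitivity) yet is invisible to a fold-change > 2 gate. Runs
both screens on the same simulated cohorts and reports their sensitivity
against the planted truth.
"""

from posrate import (
    ScreeningSimConfig,
    compare_screens,
    run_deg_screen,
    run_positive_rate_screen,
    simulate_paired_cohorts,
)

cohorts, planted = simulate_paired_cohorts(ScreeningSimConfig(seed=4))
pr = run_positive_rate_screen(cohorts, top_fraction=0.05)
de = run_deg_screen(cohorts)

report = compare_screens(pr["intersection"].genes, de["intersection"].genes, planted)
print(f"planted markers: {len(planted)} (shift 0.4 log2 units, positive in ~95% of pairs)")
print(f"positive-rate screen sensitivity: {report['positive_rate_sensitivity']:.2f}")
print(f"fold-change (FC > 2) screen sensitivity: {report['deg_sensitivity']:.2f}")
print(f"sensitivity gap: {report['sensitivity_gap']:.2f}")
# The rate-based screen recovers essentially all planted markers; the
# fold-change gate requires a mean log2 difference above 1.0 and recovers
# none of them, so the gap approaches 1.
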