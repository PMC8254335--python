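# Methods

## The positive-rate statistic

For a paired cohort with subjects `i = 1..N`, each contributing one tumor
and one adjacent non-cancer sample on a log2 expression scale, gene `g` is
*positive* in pair `i` when `x_g(tumor_i) > x_g(adjacent_i)` strictly; ties
count as not positive. The positive rate `r_g = k_g / N` is a rank
statistic of the within-pair difference and is therefore invariant under
any strictly monotone transform applied to both members of a pair —
normalization choices that preserve within-pair order cannot change it.
With continuous intensities ties are measure-zero, so the strict-inequality
convention is inert in practice; it exists to make the statistic
deterministic on degenerate input.

Screening keeps the top fraction `q` (default 0.05) of genes per cohort by
`r_g`. The selection size is `ceil(q * G)`, which guarantees a non-empty
selection and reproduces the familiar cohort-scale count (1070 genes from a
~21,400-gene array). Because many genes share the same attainable rates
`k/N`, boundary ties are broken by mean paired log2 difference
(descending), then gene identifier (ascending). This tie-break is a
declared convention of this package, not an inference about how any
particular published list was ordered; exact reproduction of external
per-cohort lists is not attempted. The cross-cohort candidate set is the
intersection of all per-cohort selections (a `min_cohorts`-style relaxation
is deliberately not defaulted), ordered by mean within-selection rank. The
extracellular filter keeps genes whose annotated cellular-component terms
intersect a target set (default `{GO:0005576}`); genes missing from the
annotation table are reported separately from genes annotated with
non-matching terms, because the two say different things about the
annotation coverage. The annotation is consumed as already propagated — no
GO graph traversal is performed.

## Diagnostic ROC gating

The per-gene AUC is computed in its Mann–Whitney form (fraction of
(tumor, normal) sample pairs ordered correctly, ties counting one half),
with the standard error of Hanley & McNeil (1982) and a normal 95% CI
clipped to [0, 1]. Orientation is fixed tumor-high; markers that run the
other way earn AUC < 0.5 and fail the gate — nothing is auto-flipped,
matching how low-AUC candidates are simply dropped in practice. The gate
is strict (`AUC > threshold` in **every** dataset; a gene at exactly the
threshold fails). The Youden cutoff is reported at an attained marker value
under the rule `value >= cutoff -> tumor`, with ties in the Youden index
resolved toward higher specificity. Whether published CIs of this kind are
Hanley–McNeil or exact-binomial is generally unstated; bit-exact
reproduction of external CI tables is out of scope.

## Cox signature construction

Partial-likelihood maximization is delegated to statsmodels `PHReg`, with
Breslow tie handling by default and Efron selectable (`cox_tie_method`);
the two coincide on untied data, and with moderate ties Breslow matches the
default of the major clinical-statistics packages. This module owns the
surface: identifiability checks (constant covariates rejected), convergence
verification (the score norm at the returned estimate must vanish to within
1e-6 relative tolerance), and monotone-likelihood detection (estimates past
|beta| = 15 — a hazard ratio above e^15 per unit — are treated as
divergence and raised as errors rather than reported).

Signature selection is two-stage with a refit: univariate Cox per candidate
(keep Wald p < 0.05), one joint multivariate fit on the survivors, retain
multivariately significant genes, and refit on the retained set. The refit
coefficients define the risk score; the full audit trail (univariate table,
joint fit, refit) is returned so the no-refit reading — taking coefficients
from the larger joint model — remains inspectable. The refit was chosen
because reporting coefficients of a model other than the one finally used
conflates two estimands; on simulated data the two differ negligibly.

The risk score is the linear predictor `sum_g beta_g x_g` with no
intercept, median-split into low/high risk with ties at the cutoff assigned
low (deterministic; inert for continuous scores). Kaplan–Meier curves come
from lifelines (subjects censored at an event time remain at risk for that
event), the two-group log-rank test from lifelines' implementation, and its
equivalence with the Cox partial-likelihood score test on a binary group
indicator (exact for untied times) is verified in the tests rather than
assumed.

### Time-dependent ROC

The time-dependent AUC(t) uses the cumulative-case / dynamic-control
definition: at horizon `t`, cases are subjects with an observed event by
`t` and controls are subjects under observation beyond `t`. Censoring is
handled by inverse-probability-of-censoring weights `1/G(T_i-)`, with `G`
the Kaplan–Meier estimate of the censoring survival function (the common
control weight cancels in the ratio). The binding contract is the
no-censoring reduction: with complete follow-up every weight is 1 and
AUC(t) equals the empirical ROC AUC of the event-by-t dichotomy exactly,
which the tests assert to 1e-12. Smoothed (nearest-neighbour) estimators of
the same quantity exist; this package's KM-weighted variant was chosen for
its exact reduction property, and agreement with an independent IPCW
implementation (scikit-survival) is checked in the tests.

### Covariate independence

Clinical covariates enter as binary contrasts — age <=65 vs >65, stage
I–II vs III–IV, T1–T2 vs T3–T4, node/metastasis negative vs positive,
grade low vs high — matching the groupings used for the serum association
tables. Both inclusion rules for the multivariate model are exposed:
univariately significant variables only (default, risk score always
retained) or all variables, since published practice varies.

## Clinical statistics

The 2x2 association test is the uncorrected Pearson chi-square
`n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))` on 1 df. No continuity correction is
applied — this was *verified*, not assumed: all six published serum-marker
association statistics (9.008, 4.281, 5.961, 5.979, 9.854, 7.013)
recompute exactly to 3 decimal places from their contingency counts with
the uncorrected formula. No multiple-testing correction is applied across
association cells, matching the analysis the tables summarize. Median
splits assign values equal to the median to the low group; with 132
subjects splitting 66/66 the cutoff sits between order statistics, so the
rule is inert there.

Mann–Whitney uses midrank tie handling, exact enumeration for small
(< 8 per group) tie-free samples and the tie-corrected normal approximation
otherwise. The paired pre/post-operative comparison is a two-sided paired
t-test; zero-variance differences raise rather than return an undefined
statistic. Pearson correlation p-values come from the t-transform on n-2
df.

The combined serum scores follow their published definitions exactly:
score 1 is the weighted concentration sum with weights (0.180, 0.544,
0.135) applied to the raw mixed-unit concentrations (AGT ng/mL, SERPINH1
pg/mL, MMP7 ng/mL — deliberately no unit normalization, since the weights
were published for exactly these units), median-split for group
assignment; score 2 is high-risk when at least two of the three markers
exceed their own medians. How the published three-protein *diagnostic*
panel was combined is unstated; this package treats ROC on score 1 with a
Youden cutoff as the natural reading.

## Fold-change baseline

The comparison screen tests each gene with a paired t-test on the
tumor - adjacent log2 differences and gates on mean log2 difference >
log2(2) (tumor-high only, matching the one-sidedness of the positive-rate
definition) and Benjamini–Hochberg adjusted p < 0.05 per cohort, then
intersects and filters identically to the rate-based screen. A plain paired
t-test was chosen over a moderated-variance test: the generator produces
Gaussian differences with homogeneous variance, so moderation would change
nothing there, and the plain test keeps the two screens' assumptions
symmetric. Genes with exactly constant differences get p = 1 and a flag
instead of an undefined statistic.

## Synthetic data: what it emulates and what it does not

**Paired cohorts.** Tumor - adjacent differences are Normal: background
genes centred so that P(diff > 0) equals the background positive
probability (default 0.5), planted genes shifted by `planted_shift`
(default 0.4 log2 units ~ 1.3-fold) with the noise SD derived from the
planted positive probability via `sd = shift / PhiInv(p+)` (default p+ =
0.95) — screening difficulty is thus specified on the scale the statistic
sees. Defaults are 3 cohorts x 50 pairs x 2,000 genes with 30 planted
markers shared across cohorts. A planted positive probability of exactly 1
is realized by reflecting the difference distribution. Probe-level noise,
batch effects, inter-gene correlation and normalization artifacts are *not*
modelled: passing screens here shows the statistic behaves as designed, not
that any particular array pipeline is reproduced.

**Survival cohorts.** Expression is standard Normal per gene; event times
are exponential with rate `lambda0 * exp(beta' x)` (default lambda0 = 0.02
per month, giving a median survival near 3 years at the null; default beta
= (0.180, 0.544, 0.135)). Censoring is an independent uniform time whose
scale is calibrated by bisection so the expected censored fraction hits the
target (default 30%); at n = 5,000 the realized fraction lands within 0.02.
Clinical covariates, when enabled, link an adverse stage to the linear
predictor through a logistic model. The exponential baseline means no
late-time hazard structure; proportionality is exact by construction, so
these data cannot probe proportional-hazards violations (diagnostics for
which are out of scope).

**Serum panels.** Concentrations are truncated-at-zero Normals with the
published group means/SDs (GC: 34.51 +/- 22.35 ng/mL AGT, 733.90 +/- 204.65
pg/mL SERPINH1, 4.67 +/- 1.30 ng/mL MMP7; controls: 25.90 +/- 16.08,
604.41 +/- 185.04, 3.80 +/- 2.27), n = 132 GC / 86 controls. Truncation
was preferred over log-Normal because only means and SDs are published and
truncation adds positivity with no further shape assumptions; a log-Normal
variant matched to the same moments is available by flag. Clinical
categories are Bernoulli with the adverse-level odds multiplied by a
configurable odds ratio (default 3) for subjects above the median weighted
score; post-operative values are pre-operative values shrunk by a common
factor (default 0.75) times multiplicative noise. Real serum panels have
heavier tails and assay floors/ceilings that are not modelled.

## Numerical conventions and degenerate inputs

- All expression input is assumed log2 already; the readers never
  re-transform (a `log2(x+1)` flag exists for count-scale input).
- Duplicate gene rows collapse to the row with the highest mean expression
  (deterministic; the upstream probe-collapse rule for any given external
  dataset is unknowable, so the policy is declared rather than inferred).
- Missing expression values are rejected by default; an explicit reader
  flag deletes affected genes and logs the count. Survival rows missing
  time or event are dropped and counted.
- Survival tables are read with round-trip float parsing so write-read
  cycles preserve times exactly.
- Constant markers yield AUC 0.5 with a degeneracy warning; constant
  covariates, all-identical scores, zero-variance paired differences and
  zero-margin contingency tables raise errors rather than return
  conventional values.

## Problem sizes

The test suite and acceptance script run the stochastic checks at the
study-condition sizes: 100 replicates for Cox CI coverage and signature
recovery at n = 600, 200 replicates for the screening contrast at 3 x 50
pairs x 2,000 genes, 200 replicates for the null calibrations at n = 400
(Cox) and 30/30 (Mann–Whitney), and single large cohorts (n = 1,500–5,000)
for closed-form convergence checks. These sizes give binomial standard
errors of 2–4 percentage points on the reported rates.

## Known limitations

- The two-stage signature selection inherits the usual selection-inference
  caveat: refit p-values are not corrected for the selection that produced
  the gene set. Its long-run exact-recovery rate under the default planted
  conditions is ~0.78, with the dominant failure mode being a single noise
  gene surviving both stages (~16% of replicates).
- The log-rank/score-test equivalence is exact only for untied event
  times; with heavy ties the hypergeometric variance and the Breslow
  information differ.
- The IPCW time-dependent AUC becomes unstable when the censoring
  Kaplan–Meier estimate approaches zero near the evaluation horizon;
  horizons beyond the last observed follow-up are rejected.
- External published gene lists, AUC tables and hazard-ratio tables from
  clinical accessions are not reproducible without those data and are not
  targeted; the package reproduces the *method* and the in-text statistics
  that are computable from printed tables.
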