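"""Cox proportional-hazards signature construction and survival stratification.

The prognostic pipeline mirrors common two-stage signature building:
univariate Cox per candidate gene, a joint multivariate fit on the
univariately significant genes, retention of the multivariately significant
ones, and a refit on the retained set whose coefficients define the risk
score ``sum_g beta_g * expression_g``. Patients are split at the median
score into low- and high-risk groups, compared by Kaplan–Meier / log-rank,
and the score's discrimination over time is measured with a
cumulative-case / dynamic-control time-dependent ROC.

Cox partial-likelihood maximization is delegated to
:class:`statsmodels.duration.hazard_regression.PHReg` (Breslow or Efron tie
handling); this module owns the model surface: identifiability checks,
convergence verification, Wald summaries on the hazard-ratio scale, and
monotone-likelihood detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from statsmodels.duration.hazard_regression import PHReg

from .types import SurvivalCohort

logger = logging.getLogger("posrate")

__all__ = [
    "CoxFit",
    "RiskModel",
    "RiskStratification",
    "KMCurve",
    "TdRocResult",
    "SignatureReport",
    "fit_cox",
    "cox_score_test",
    "build_signature",
    "compute_risk_scores",
    "stratify_by_median",
    "km_curve",
    "logrank_test",
    "time_dependent_roc",
    "encode_clinical_covariates",
    "covariate_independence",
]

# |beta| beyond this is treated as monotone-likelihood divergence (a log
# hazard ratio of 15 per unit covariate is far outside any plausible fit)
_BETA_CAP = 15.0
_SCORE_TOL = 1e-6


@dataclass
class CoxFit:
    """Wald summary of one Cox PH fit.

    ``summary`` is indexed by covariate with columns ``coef`` (log hazard
    ratio), ``hr`` = exp(coef), ``se``, ``ci_low``/``ci_high`` (95% CI on
    the HR scale, exp(coef -/+ 1.96 se)) and ``p`` (two-sided Wald).
    """

    summary: pd.DataFrame
    loglik: float
    loglik_null: float
    converged: bool
    tie_method: str
    n: int
    n_events: int


@dataclass
class RiskModel:
    """Ordered signature genes and their risk-score coefficients."""

    genes: list[str]
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.genes) != len(self.coefficients):
            raise ValueError("genes and coefficients must have equal length")
        if not np.isfinite(self.coefficients).all():
            raise ValueError("non-finite coefficient")


@dataclass
class RiskStratification:
    scores: pd.Series
    cutoff: float
    group: pd.Series  # "low" / "high" per patient

    @property
    def n_low(self) -> int:
        return int((self.group == "low").sum())

    @property
    def n_high(self) -> int:
        return int((self.group == "high").sum())


@dataclass
class KMCurve:
    """Product-limit survival estimate.

    ``times`` are the distinct observed event times; ``survival`` the step
    values S(t_k) = prod_{j<=k} (1 - d_j / n_j). Subjects censored exactly
    at an event time remain at risk for that event.
    """

    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class TdRocResult:
    times: np.ndarray
    auc: np.ndarray
    method: str = "cumulative-dynamic-ipcw-km"


@dataclass
class LogrankResult:
    statistic: float
    p_value: float


@dataclass
class SignatureReport:
    """Audit trail of the two-stage signature selection."""

    univariate: pd.DataFrame
    stage1_genes: list[str]
    multivariate: CoxFit | None
    final_genes: list[str]
    final_fit: CoxFit | None


def _design_matrix(cohort: SurvivalCohort, covariates) -> pd.DataFrame:
    """Assemble a patients x covariates design from expression and/or
    clinical columns, or pass a DataFrame through aligned to the cohort."""
    if isinstance(covariates, pd.DataFrame):
        return covariates.loc[cohort.patient_id]
    cols = {}
    for name in covariates:
        if cohort.expression is not None and name in cohort.expression.columns:
            cols[name] = cohort.expression[name]
        elif cohort.covariates is not None and name in cohort.covariates.columns:
            cols[name] = cohort.covariates[name]
        else:
            raise KeyError(f"covariate {name!r} not found in cohort expression or covariates")
    return pd.DataFrame(cols, index=pd.Index(cohort.patient_id))


def fit_cox(cohort: SurvivalCohort, covariates, tie_method: str = "breslow") -> CoxFit:
    """Fit a Cox proportional-hazards model by partial likelihood.

    ``covariates`` is a list of column names (resolved against the cohort's
    expression then clinical covariates) or a ready design DataFrame.
    Raises on zero events, on a constant covariate (non-identifiable), and
    on monotone likelihood (coefficient diverging past |beta| = 20).
    """
    if tie_method not in ("breslow", "efron"):
        raise ValueError("tie_method must be 'breslow' or 'efron'")
    if cohort.n_events < 1:
        raise ValueError("Cox fit requires at least one observed event")
    X = _design_matrix(cohort, covariates).astype(float)
    const = [c for c in X.columns if np.ptp(X[c].to_numpy()) == 0]
    if const:
        raise ValueError(f"non-identifiable: constant covariate(s) {const}")

    model = PHReg(cohort.time, X.to_numpy(), status=cohort.event, ties=tie_method)
    with np.errstate(all="ignore"):
        res = model.fit(disp=False)
    params = np.asarray(res.params, dtype=float)
    if not np.isfinite(params).all() or np.abs(params).max() > _BETA_CAP:
        raise ValueError(
            "monotone partial likelihood (perfect separation): "
            f"coefficients {dict(zip(X.columns, params.round(2)))} diverged"
        )
    score = model.score(params)
    converged = bool(np.max(np.abs(score)) < _SCORE_TOL * max(1.0, abs(model.loglike(params))))
    se = np.asarray(res.bse, dtype=float)
    z = params / se
    from scipy.stats import norm

    p = 2.0 * norm.sf(np.abs(z))
    summary = pd.DataFrame(
        {
            "coef": params,
            "hr": np.exp(params),
            "se": se,
            "ci_low": np.exp(params - 1.96 * se),
            "ci_high": np.exp(params + 1.96 * se),
            "p": p,
        },
        index=pd.Index(X.columns, name="covariate"),
    )
    return CoxFit(
        summary=summary,
        loglik=float(model.loglike(params)),
        loglik_null=float(model.loglike(np.zeros_like(params))),
        converged=converged,
        tie_method=tie_method,
        n=cohort.n_patients,
        n_events=cohort.n_events,
    )


def cox_score_test(cohort: SurvivalCohort, covariates, tie_method: str = "breslow") -> LogrankResult:
    """Cox partial-likelihood score test at beta = 0.

    With a single binary group indicator and untied event times this is
    algebraically the two-group log-rank test.
    """
    from scipy.stats import chi2

    X = _design_matrix(cohort, covariates).astype(float)
    model = PHReg(cohort.time, X.to_numpy(), status=cohort.event, ties=tie_method)
    beta0 = np.zeros(X.shape[1])
    u = model.score(beta0)
    info = -model.hessian(beta0)
    stat = float(u @ np.linalg.solve(info, u))
    return LogrankResult(stat, float(chi2.sf(stat, df=X.shape[1])))


def build_signature(
    cohort: SurvivalCohort,
    candidate_genes: list[str],
    alpha1: float = 0.05,
    alpha2: float = 0.05,
    tie_method: str = "breslow",
) -> tuple[RiskModel, SignatureReport]:
    """Two-stage Cox gene-signature selection with a final refit.

    Stage 1 fits each candidate univariately and keeps genes with Wald
    p < ``alpha1``. Stage 2 fits all survivors jointly; genes with
    multivariate p < ``alpha2`` are retained, and the model is refit on the
    retained genes — the refit coefficients define the risk score. The full
    audit trail (univariate table, joint fit, refit) is returned alongside.
    """
    if cohort.expression is None:
        raise ValueError("cohort has no expression matrix")
    missing = [g for g in candidate_genes if g not in cohort.expression.columns]
    if missing:
        raise KeyError(f"candidate genes absent from cohort expression: {missing}")

    uni_rows = []
    for gene in candidate_genes:
        fit = fit_cox(cohort, [gene], tie_method=tie_method)
        row = fit.summary.loc[gene].to_dict()
        row["gene_id"] = gene
        uni_rows.append(row)
    univariate = pd.DataFrame(uni_rows).set_index("gene_id")
    stage1 = [g for g in candidate_genes if univariate.loc[g, "p"] < alpha1]
    logger.info("signature stage 1: %d of %d genes univariately significant", len(stage1), len(candidate_genes))
    if not stage1:
        raise ValueError("empty signature: no candidate gene passed the univariate stage")

    multi = fit_cox(cohort, stage1, tie_method=tie_method)
    final_genes = [g for g in stage1 if multi.summary.loc[g, "p"] < alpha2]
    if not final_genes:
        raise ValueError("empty signature: no gene passed the multivariate stage")
    final_fit = fit_cox(cohort, final_genes, tie_method=tie_method)
    logger.info("signature final: %s", final_genes)

    model = RiskModel(final_genes, final_fit.summary["coef"].to_numpy())
    report = SignatureReport(
        univariate=univariate,
        stage1_genes=stage1,
        multivariate=multi,
        final_genes=final_genes,
        final_fit=final_fit,
    )
    return model, report


def compute_risk_scores(model: RiskModel, expression: pd.DataFrame) -> pd.Series:
    """Linear risk score sum_g beta_g * expression_g (no intercept).

    ``expression`` is patients x genes; every signature gene must be
    present.
    """
    missing = [g for g in model.genes if g not in expression.columns]
    if missing:
        raise KeyError(f"signature genes absent from expression: {missing}")
    scores = expression[model.genes].to_numpy(dtype=float) @ model.coefficients
    return pd.Series(scores, index=expression.index, name="risk_score")


def stratify_by_median(scores: pd.Series) -> RiskStratification:
    """Split patients at the median score: strictly above -> high risk,
    at or below -> low risk (ties to low; inert for continuous scores)."""
    scores = pd.Series(scores)
    if len(scores) < 2:
        raise ValueError("need at least 2 patients to stratify")
    if np.ptp(scores.to_numpy(dtype=float)) == 0:
        raise ValueError("all risk scores identical: stratification undefined")
    cutoff = float(scores.median())
    group = pd.Series(np.where(scores > cutoff, "high", "low"), index=scores.index, name="risk_group")
    strat = RiskStratification(scores=scores, cutoff=cutoff, group=group)
    logger.info("median split at %.4g: %d low, %d high", cutoff, strat.n_low, strat.n_high)
    return strat


def km_curve(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimate of the survival function."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty input")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    event_times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].reindex(ev.index).to_numpy(dtype=float)
    return KMCurve(
        times=event_times,
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        events=ev["observed"].to_numpy(dtype=int),
        survival=surv,
        censor_times=np.sort(times[events == 0]),
    )


def logrank_test(times, events, groups) -> LogrankResult:
    """Two-group log-rank chi-square test (1 df)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {len(levels)}")
    m = groups == levels[0]
    if m.sum() == 0 or (~m).sum() == 0:
        raise ValueError("each group must be non-empty")
    res = _ll_logrank(times[m], times[~m], events[m], events[~m])
    return LogrankResult(float(res.test_statistic), float(res.p_value))


def _km_censoring_left(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Step representation of the censoring-distribution KM estimate G."""
    kmf = KaplanMeierFitter()
    kmf.fit(times, 1 - events)
    sf = kmf.survival_function_["KM_estimate"]
    return sf.index.to_numpy(dtype=float), sf.to_numpy(dtype=float)


def _g_left(step_t: np.ndarray, step_v: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Left-continuous evaluation G(t-) of a right-continuous step function."""
    idx = np.searchsorted(step_t, t, side="left") - 1
    out = np.ones_like(t, dtype=float)
    pos = idx >= 0
    out[pos] = step_v[idx[pos]]
    return out


def time_dependent_roc(times, events, marker, eval_times) -> TdRocResult:
    """Cumulative-case / dynamic-control AUC(t) under right censoring.

    At horizon t, cases are subjects with an observed event by t and
    controls are subjects still event-free (under observation) beyond t.
    Cases are weighted by inverse probability of censoring, 1/G(T_i-), with
    G the Kaplan–Meier estimate of the censoring survival function; the
    common control weight cancels. With zero censoring every weight is 1
    and AUC(t) reduces exactly to the empirical ROC AUC of the
    event-by-t / event-after-t dichotomy.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    marker = np.asarray(marker, dtype=float)
    eval_times = np.atleast_1d(np.asarray(eval_times, dtype=float))
    if eval_times.max() > times.max():
        raise ValueError(
            f"evaluation time {eval_times.max()} beyond last observed follow-up {times.max()}"
        )
    step_t, step_v = _km_censoring_left(times, events)
    aucs = np.empty(len(eval_times))
    for k, t in enumerate(eval_times):
        case = (times <= t) & (events == 1)
        ctrl = times > t
        if case.sum() == 0 or ctrl.sum() == 0:
            aucs[k] = np.nan
            continue
        w = 1.0 / _g_left(step_t, step_v, times[case])
        ctrl_sorted = np.sort(marker[ctrl])
        below = np.searchsorted(ctrl_sorted, marker[case], side="left")
        ties = np.searchsorted(ctrl_sorted, marker[case], side="right") - below
        wins = below + 0.5 * ties
        aucs[k] = float((w * wins).sum() / (w.sum() * ctrl.sum()))
    return TdRocResult(times=eval_times, auc=aucs)


# Binary contrasts used for the clinical-covariate independence analysis.
# Each maps the reference level to 0 and the adverse level to 1.
_COVARIATE_CODINGS: dict[str, dict[str, int]] = {
    "gender": {"female": 0, "male": 1},
    "age_group": {"<=65": 0, ">65": 1},
    "stage": {"I-II": 0, "III-IV": 1},
    "tumor_invasion": {"T1-T2": 0, "T3-T4": 1},
    "lymph_node_invasion": {"negative": 0, "positive": 1},
    "metastasis": {"negative": 0, "positive": 1},
    "histological_grade": {"low": 0, "high": 1},
}


def encode_clinical_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Encode clinical variables as 0/1 contrasts (age <=65 vs >65, stage
    I–II vs III–IV, T1–T2 vs T3–T4, node/metastasis negative vs positive,
    grade low vs high). Numeric columns pass through unchanged."""
    out = {}
    for col in covariates.columns:
        series = covariates[col]
        if pd.api.types.is_numeric_dtype(series):
            out[col] = series.astype(float)
            continue
        coding = _COVARIATE_CODINGS.get(col)
        if coding is None:
            raise KeyError(f"no binary coding defined for clinical variable {col!r}")
        unknown = set(series.dropna().unique()) - set(coding)
        if unknown:
            raise ValueError(f"unknown level(s) {sorted(unknown)} in variable {col!r}")
        out[col] = series.map(coding).astype(float)
    return pd.DataFrame(out, index=covariates.index)


def covariate_independence(
    cohort: SurvivalCohort,
    risk_scores: pd.Series,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    mode: str = "significant",
    tie_method: str = "breslow",
) -> dict:
    """Test whether the risk score predicts survival independently of
    clinical covariates.

    Fits each variable (risk score plus each encoded clinical covariate)
    univariately, then a joint multivariate model on either the
    univariately significant variables (``mode='significant'``) or all of
    them (``mode='all'``). Returns ``{'univariate': DataFrame,
    'multivariate': CoxFit, 'variables': list}``.
    """
    if mode not in ("significant", "all"):
        raise ValueError("mode must be 'significant' or 'all'")
    if covariates is None:
        if cohort.covariates is None:
            raise ValueError("cohort has no clinical covariates")
        covariates = cohort.covariates
    encoded = encode_clinical_covariates(covariates)
    design = pd.concat(
        [pd.Series(risk_scores, name="risk_score").loc[cohort.patient_id], encoded], axis=1
    )
    uni_rows = []
    for var in design.columns:
        fit = fit_cox(cohort, design[[var]], tie_method=tie_method)
        row = fit.summary.loc[var].to_dict()
        row["variable"] = var
        uni_rows.append(row)
    univariate = pd.DataFrame(uni_rows).set_index("variable")
    if mode == "significant":
        selected = [v for v in design.columns if univariate.loc[v, "p"] < alpha]
        if "risk_score" not in selected:
            selected = ["risk_score", *selected]
    else:
        selected = list(design.columns)
    multivariate = fit_cox(cohort, design[selected], tie_method=tie_method) if len(selected) else None
    return {"univariate": univariate, "multivariate": multivariate, "variables": selected}
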