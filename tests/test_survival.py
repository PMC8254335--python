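import numpy as np
import pandas as pd
import pytest

from posrate import (
    RiskModel,
    SurvivalCohort,
    SurvivalSimConfig,
    build_signature,
    compute_risk_scores,
    covariate_independence,
    cox_score_test,
    encode_clinical_covariates,
    fit_cox,
    km_curve,
    logrank_test,
    simulate_survival_cohort,
    stratify_by_median,
    time_dependent_roc,
)


def simple_cohort(time, event, X=None, covariates=None):
    n = len(time)
    patients = [f"p{i}" for i in range(n)]
    expr = None
    if X is not None:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != n:
            X = X.T
        expr = pd.DataFrame(X, index=patients, columns=[f"x{i}" for i in range(X.shape[1])])
    return SurvivalCohort(patients, np.asarray(time, float), np.asarray(event), expr, covariates)


class TestFitCox:
    def test_hazard_ratio_identity_and_likelihood_gain(self):
        rng = np.random.default_rng(31)
        n = 200
        x = rng.normal(size=n)
        t = rng.exponential(1 / (0.05 * np.exp(0.5 * x)))
        cohort = simple_cohort(t, np.ones(n), x)
        fit = fit_cox(cohort, ["x0"])
        assert fit.converged
        s = fit.summary.loc["x0"]
        assert s["hr"] == pytest.approx(np.exp(s["coef"]), abs=1e-12)
        assert s["ci_low"] <= s["hr"] <= s["ci_high"]
        assert fit.loglik >= fit.loglik_null

    def test_two_group_rate_ratio_limit(self):
        # exponential groups with hazard ratio 2: beta-hat approaches log 2
        rng = np.random.default_rng(32)
        n = 2000
        g = np.repeat([0.0, 1.0], n // 2)
        t = rng.exponential(1 / (0.1 * np.exp(np.log(2) * g)))
        fit = fit_cox(simple_cohort(t, np.ones(n), g), ["x0"])
        assert fit.summary.loc["x0", "coef"] == pytest.approx(np.log(2), abs=0.1)

    def test_estimate_within_three_se(self):
        cfg = SurvivalSimConfig(seed=33, n_patients=2000, signature_genes=("g",),
                                true_betas=(0.5,), censoring_fraction=0.3)
        cohort, _ = simulate_survival_cohort(cfg)
        fit = fit_cox(cohort, ["g"])
        s = fit.summary.loc["g"]
        assert abs(s["coef"] - 0.5) < 3 * s["se"]

    def test_constant_covariate_rejected(self):
        cohort = simple_cohort([1, 2, 3, 4], [1, 1, 1, 1], np.ones(4))
        with pytest.raises(ValueError, match="constant"):
            fit_cox(cohort, ["x0"])

    def test_zero_events_rejected(self):
        cohort = simple_cohort([1, 2, 3, 4], [0, 0, 0, 0], np.arange(4.0))
        with pytest.raises(ValueError, match="event"):
            fit_cox(cohort, ["x0"])

    def test_monotone_likelihood_detected(self):
        # marker perfectly reverse-ranks the event times: partial likelihood
        # is maximized at beta -> infinity
        t = np.arange(1.0, 21.0)
        x = -t
        with pytest.raises(ValueError, match="monotone|separation"):
            fit_cox(simple_cohort(t, np.ones(20), x), ["x0"])

    def test_efron_ties_available(self):
        rng = np.random.default_rng(34)
        t = np.repeat(np.arange(1.0, 11.0), 3)  # heavy ties
        x = rng.normal(size=30)
        fit_b = fit_cox(simple_cohort(t, np.ones(30), x), ["x0"], tie_method="breslow")
        fit_e = fit_cox(simple_cohort(t, np.ones(30), x), ["x0"], tie_method="efron")
        assert fit_b.summary.loc["x0", "coef"] != fit_e.summary.loc["x0", "coef"]


class TestSignature:
    def test_planted_genes_selected(self):
        cfg = SurvivalSimConfig(seed=101, n_patients=600, true_betas=(0.3, 0.5, 0.2),
                                signature_genes=("a", "b", "c"), n_noise_genes=7)
        cohort, truth = simulate_survival_cohort(cfg)
        model, report = build_signature(cohort, truth["genes"])
        assert set(model.genes) == {"a", "b", "c"}
        assert len(report.stage1_genes) >= 3
        assert report.final_fit.converged
        # refit coefficients are the model's coefficients
        assert np.allclose(model.coefficients, report.final_fit.summary["coef"].to_numpy())

    def test_no_passing_gene_raises(self):
        cfg = SurvivalSimConfig(seed=36, n_patients=80, true_betas=(0.0, 0.0),
                                signature_genes=("a", "b"))
        cohort, truth = simulate_survival_cohort(cfg)
        with pytest.raises(ValueError, match="empty signature"):
            build_signature(cohort, ["a", "b"], alpha1=1e-6)


class TestRiskScores:
    def test_published_coefficient_arithmetic(self):
        model = RiskModel(["AGT", "SERPINH1", "MMP7"], [0.180, 0.544, 0.135])
        expr = pd.DataFrame([[1.0, 1.0, 1.0]], columns=model.genes, index=["p0"])
        assert compute_risk_scores(model, expr).iloc[0] == pytest.approx(0.859)
        zeros = pd.DataFrame([[0.0, 0.0, 0.0]], columns=model.genes, index=["p0"])
        assert compute_risk_scores(model, zeros).iloc[0] == 0.0

    def test_matches_dot_product_oracle(self):
        rng = np.random.default_rng(37)
        genes = [f"g{i}" for i in range(5)]
        model = RiskModel(genes, rng.normal(size=5))
        expr = pd.DataFrame(rng.normal(size=(20, 5)), columns=genes)
        scores = compute_risk_scores(model, expr)
        for i in range(20):
            expected = sum(model.coefficients[j] * expr.iloc[i, j] for j in range(5))
            assert scores.iloc[i] == pytest.approx(expected, abs=1e-12)

    def test_affine_equivariance(self):
        rng = np.random.default_rng(38)
        genes = ["a", "b"]
        model = RiskModel(genes, [0.4, -0.2])
        expr = pd.DataFrame(rng.normal(size=(10, 2)), columns=genes)
        base = compute_risk_scores(model, expr)
        shifted = expr.copy()
        shifted["a"] += 3.0
        assert np.allclose(compute_risk_scores(model, shifted) - base, 0.4 * 3.0, atol=1e-12)

    def test_missing_gene_listed(self):
        model = RiskModel(["a", "b"], [1.0, 2.0])
        expr = pd.DataFrame(np.zeros((3, 1)), columns=["a"])
        with pytest.raises(KeyError, match="b"):
            compute_risk_scores(model, expr)


class TestStratification:
    @pytest.mark.parametrize("n", [190, 348])
    def test_even_split_of_distinct_scores(self, n):
        rng = np.random.default_rng(39)
        strat = stratify_by_median(pd.Series(rng.permutation(n).astype(float)))
        assert strat.n_low == n // 2 and strat.n_high == n // 2

    def test_ties_go_to_low(self):
        strat = stratify_by_median(pd.Series([1.0, 2.0, 2.0, 3.0, 4.0]))
        assert strat.cutoff == 2.0
        assert strat.n_low == 3 and strat.n_high == 2

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            stratify_by_median(pd.Series([1.0, 1.0, 1.0]))


class TestKaplanMeier:
    def test_uniform_product(self):
        km = km_curve([1, 2, 3, 4], [1, 1, 1, 1])
        assert np.allclose(km.survival, [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_flat(self):
        km = km_curve([1, 2, 3], [0, 0, 0])
        assert km.survival_at(3.0) == 1.0 and len(km.times) == 0

    def test_matches_hand_product_oracle(self):
        times = np.array([2.0, 3.0, 3.0, 5.0, 6.0, 7.0, 8.0, 9.0])
        events = np.array([1, 1, 0, 1, 0, 1, 0, 1])
        km = km_curve(times, events)
        # hand expansion of prod(1 - d_j/n_j); a subject censored at an
        # event time remains at risk for that event
        s = 1.0
        expected = []
        for t in km.times:
            d = int(((times == t) & (events == 1)).sum())
            n_j = int((times >= t).sum())
            s *= 1 - d / n_j
            expected.append(s)
        assert np.allclose(km.survival, expected, atol=1e-12)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(40)
        times = rng.exponential(10, 60)
        km = km_curve(times, np.ones(60, int))
        for t in np.quantile(times, [0.2, 0.5, 0.8]):
            assert km.survival_at(t) == pytest.approx((times > t).mean(), abs=1e-12)


class TestLogrank:
    def test_identical_groups_null(self):
        t = np.array([1.0, 2, 3, 4, 5])
        res = logrank_test(np.tile(t, 2), np.ones(10, int), np.repeat(["a", "b"], 5))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_equals_cox_score_test(self):
        # with a binary group indicator and untied times the log-rank
        # statistic is the Cox partial-likelihood score test
        rng = np.random.default_rng(41)
        n = 40
        g = np.repeat([0.0, 1.0], 20)
        t = rng.exponential(1 / np.exp(0.6 * g))
        assert len(np.unique(t)) == n
        cohort = simple_cohort(t, np.ones(n), g)
        lr = logrank_test(t, np.ones(n, int), g)
        sc = cox_score_test(cohort, ["x0"])
        assert lr.statistic == pytest.approx(sc.statistic, abs=1e-6)
        assert lr.p_value == pytest.approx(sc.p_value, abs=1e-6)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(42)
        t = rng.exponential(5, 30)
        e = (rng.random(30) < 0.8).astype(int)
        g = rng.choice(["x", "y"], 30)
        g2 = np.where(g == "x", "y", "x")
        assert logrank_test(t, e, g).statistic == pytest.approx(
            logrank_test(t, e, g2).statistic, abs=1e-12
        )

    def test_power_under_strong_hazard_ratio(self):
        rng = np.random.default_rng(43)
        hits = 0
        reps = 30
        for _ in range(reps):
            g = np.repeat([0.0, 1.0], 100)
            lam = 0.05 * np.exp(np.log(3) * g)
            latent = rng.exponential(1 / lam)
            cens = rng.exponential(1 / (0.25 * lam))  # ~20% censoring
            t = np.minimum(latent, cens)
            e = (latent <= cens).astype(int)
            if logrank_test(t, e, g).p_value < 0.0001:
                hits += 1
        assert hits >= 0.9 * reps


class TestTimeDependentRoc:
    def test_perfect_ranking_marker(self):
        rng = np.random.default_rng(44)
        t = np.sort(rng.exponential(10, 50))
        marker = -t
        eval_times = (t[:-1] + t[1:])[::10] / 2
        res = time_dependent_roc(t, np.ones(50, int), marker, eval_times)
        assert np.allclose(res.auc, 1.0)

    def test_null_marker_near_half(self):
        rng = np.random.default_rng(45)
        t = rng.exponential(60, 1000)
        marker = rng.normal(size=1000)
        res = time_dependent_roc(t, np.ones(1000, int), marker, [60.0])
        assert abs(res.auc[0] - 0.5) < 0.05

    def test_no_censoring_reduces_to_static_roc(self):
        from posrate import roc_auc

        rng = np.random.default_rng(46)
        n = 300
        marker = rng.normal(size=n)
        t = rng.exponential(1 / (0.05 * np.exp(0.8 * marker)))
        horizon = float(np.median(t))
        res = time_dependent_roc(t, np.ones(n, int), marker, [horizon])
        labs = np.where(t <= horizon, "tumor", "normal")
        assert res.auc[0] == pytest.approx(roc_auc(marker, labs).auc, abs=1e-12)

    def test_censoring_consistency_with_uncensored_oracle(self):
        rng = np.random.default_rng(47)
        n = 2000
        marker = rng.normal(size=n)
        latent = rng.exponential(1 / (0.03 * np.exp(0.7 * marker)))
        cens = rng.exponential(1 / 0.011, n)  # ~25% censoring
        t = np.minimum(latent, cens)
        e = (latent <= cens).astype(int)
        horizon = float(np.quantile(latent, 0.4))
        censored = time_dependent_roc(t, e, marker, [horizon]).auc[0]
        uncensored = time_dependent_roc(latent, np.ones(n, int), marker, [horizon]).auc[0]
        assert abs(censored - uncensored) < 0.03

    def test_matches_independent_ipcw_implementation(self):
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        rng = np.random.default_rng(48)
        n = 500
        marker = rng.normal(size=n)
        latent = rng.exponential(1 / (0.05 * np.exp(0.6 * marker)))
        cens = rng.exponential(1 / 0.02, n)
        t = np.minimum(latent, cens)
        e = latent <= cens
        horizon = float(np.quantile(t, 0.5))
        ours = time_dependent_roc(t, e.astype(int), marker, [horizon]).auc[0]
        y = Surv.from_arrays(e, t)
        theirs = cumulative_dynamic_auc(y, y, marker, [horizon])[0][0]
        assert ours == pytest.approx(theirs, abs=0.02)

    def test_horizon_beyond_follow_up_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            time_dependent_roc([1.0, 2.0], [1, 1], [0.1, 0.2], [5.0])


class TestCovariateIndependence:
    def test_stage_encoding_matches_hand_coding(self):
        df = pd.DataFrame(
            {"stage": ["I-II", "III-IV", "I-II", "III-IV", "III-IV", "I-II"]},
            index=[f"p{i}" for i in range(6)],
        )
        enc = encode_clinical_covariates(df)
        assert enc["stage"].tolist() == [0.0, 1.0, 0.0, 1.0, 1.0, 0.0]

    def test_constant_risk_score_rejected(self):
        cfg = SurvivalSimConfig(seed=49, n_patients=50, clinical_covariates=True)
        cohort, _ = simulate_survival_cohort(cfg)
        const = pd.Series(1.0, index=cohort.patient_id)
        with pytest.raises(ValueError, match="constant"):
            covariate_independence(cohort, const, mode="all")

    def test_risk_score_signal_and_noise_covariates(self):
        # hazard depends only on the risk score; the clinical covariates are
        # pure noise and should rarely reach multivariate significance
        rng = np.random.default_rng(50)
        reps, score_hits, noise_hits = 30, 0, 0
        for r in range(reps):
            n = 300
            score = rng.normal(size=n)
            t = rng.exponential(1 / (0.05 * np.exp(0.8 * score)))
            patients = [f"p{i}" for i in range(n)]
            covs = pd.DataFrame(
                {
                    "gender": rng.choice(["male", "female"], n),
                    "age_group": rng.choice(["<=65", ">65"], n),
                    "stage": rng.choice(["I-II", "III-IV"], n),
                },
                index=patients,
            )
            cohort = SurvivalCohort(patients, t, np.ones(n, int), covariates=covs)
            out = covariate_independence(cohort, pd.Series(score, index=patients), mode="all")
            if out["multivariate"].summary.loc["risk_score", "p"] < 0.05:
                score_hits += 1
            noise_hits += sum(
                out["multivariate"].summary.loc[v, "p"] < 0.05
                for v in ("gender", "age_group", "stage")
            )
        assert score_hits >= 0.9 * reps
        # 90 noise tests at the 5% level: allow a generous margin
        assert noise_hits <= 12

    def test_significant_mode_keeps_risk_score(self):
        cfg = SurvivalSimConfig(seed=51, n_patients=300, clinical_covariates=True)
        cohort, _ = simulate_survival_cohort(cfg)
        scores = compute_risk_scores(
            RiskModel(list(cfg.signature_genes), np.array(cfg.true_betas)), cohort.expression
        )
        out = covariate_independence(cohort, scores, mode="significant")
        assert "risk_score" in out["multivariate"].summary.index
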