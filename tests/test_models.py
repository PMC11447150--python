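"""Multiplicity arithmetic, percent-change transform, and the robust
random-intercept estimator (cross-checked against an independent ML fit)."""

import numpy as np
import pandas as pd
import pytest

from hypodiary.errors import EstimationError, UndefinedStatisticError
from hypodiary.models import (
    ModelSpec,
    MultiplicityPlan,
    bonferroni_threshold,
    count_tests,
    fit_domain_model,
    fit_random_intercept,
    percent_change,
    run_model_family,
)
from hypodiary.simulate import simulate_interval_scores


def _design(df):
    X = np.column_stack(
        [np.ones(len(df))] + [(df["category"] == c).to_numpy(float) for c in "BCD"]
    )
    return df["score"].to_numpy(), X, df["participant_id"].to_numpy(), df["order"].to_numpy()


class TestMultiplicityArithmetic:
    @pytest.mark.parametrize(
        "args, expected",
        [((10, 9, 2, 7), 266), ((1, 0, 1, 1), 1), ((10, 9, 1, 1), 19)],
    )
    def test_count_tests(self, args, expected):
        assert count_tests(*args) == expected

    def test_count_tests_rejects_empty_family(self):
        with pytest.raises(ValueError):
            count_tests(0, 0, 2, 7)

    @pytest.mark.parametrize(
        "alpha, n, expected",
        [(0.05, 1, 0.05), (0.05, 2, 0.025), (0.05, 266, 0.05 / 266)],
    )
    def test_bonferroni_threshold(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected)

    def test_bonferroni_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)

    def test_plan_alpha_per_test_never_exceeds_family_alpha(self):
        plan = MultiplicityPlan(alpha_family=0.05, n_tests=266)
        assert plan.alpha_per_test <= plan.alpha_family
        assert plan.alpha_per_test == pytest.approx(0.05 / 266)


class TestPercentChange:
    @pytest.mark.parametrize(
        "coef, intercept, expected",
        [(-0.5, 5.0, -10.0), (0.0, 7.3, 0.0), (0.25, 5.0, 5.0)],
    )
    def test_values(self, coef, intercept, expected):
        assert percent_change(coef, intercept) == pytest.approx(expected)

    def test_zero_intercept_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            percent_change(1.0, 0.0)


class TestRandomInterceptEstimator:
    def test_agrees_with_independent_ml_fit(self):
        """Robust weighting off, zero AR: coefficients match an ordinary
        maximum-likelihood random-intercept fit to 1e-6 relative tolerance."""
        sm = pytest.importorskip("statsmodels.api")
        df = simulate_interval_scores(50, 20, effects={"D": -1.0}, seed=42)
        y, X, groups, order = _design(df)
        fit = fit_random_intercept(y, X, groups, order, robust=False, ar1=False)
        ml = sm.MixedLM(y, X, groups=groups).fit(reml=False, method="powell")
        np.testing.assert_allclose(fit.params, ml.fe_params, rtol=1e-6)

    def test_translation_equivariance(self):
        df = simulate_interval_scores(40, 15, effects={"D": -0.8}, seed=3, clip=None)
        y, X, groups, order = _design(df)
        base = fit_random_intercept(y, X, groups, order)
        shifted = fit_random_intercept(y + 2.5, X, groups, order)
        assert shifted.params[0] == pytest.approx(base.params[0] + 2.5, abs=1e-6)
        np.testing.assert_allclose(shifted.params[1:], base.params[1:], atol=1e-6)

    def test_single_participant_rejected(self):
        y = np.arange(10.0)
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(EstimationError):
            fit_random_intercept(y, X, np.zeros(10, int))

    def test_recovers_variance_components(self):
        df = simulate_interval_scores(
            150, 40, seed=9, clip=None, intercept_sd=1.0, residual_sd=1.2, rho=0.0
        )
        y, X, groups, order = _design(df)
        fit = fit_random_intercept(y, X, groups, order, robust=False, ar1=False)
        assert fit.sigma_u == pytest.approx(1.0, abs=0.15)
        assert fit.sigma_e == pytest.approx(1.2, abs=0.1)

    def test_ar_parameter_estimated_from_residuals(self):
        df = simulate_interval_scores(150, 40, seed=10, clip=None, rho=0.4)
        y, X, groups, order = _design(df)
        fit = fit_random_intercept(y, X, groups, order, robust=False, ar1=True)
        assert fit.rho == pytest.approx(0.4, abs=0.08)


def _domain_frame(seed=5, n=60, k=20, effects=None):
    df = simulate_interval_scores(n, k, effects=effects or {"D": -1.0}, seed=seed)
    df = df.rename(columns={"score": "sleep_quality"})
    rng = np.random.default_rng(seed)
    age = dict(zip(range(n), rng.normal(50, 10, n)))
    df["age"] = df["participant_id"].map(age)
    return df


class TestFitDomainModel:
    def test_reference_level_absent_and_cis_ordered(self):
        spec = ModelSpec("type1", "night", "sleep_quality", "category", ("age",))
        res = fit_domain_model(_domain_frame(), spec)
        levels = {lv.level for lv in res.levels}
        assert "A" not in levels and levels == {"B", "C", "D"}
        for lv in res.levels:
            assert lv.ci_low <= lv.coef <= lv.ci_high
            assert lv.percent_ci_low <= lv.percent_change <= lv.percent_ci_high
        assert res.converged and res.n_participants == 60

    def test_percent_change_sign_follows_coefficient(self):
        spec = ModelSpec("type1", "night", "sleep_quality")
        res = fit_domain_model(_domain_frame(), spec)
        assert res.intercept > 0
        for lv in res.levels:
            assert np.sign(lv.percent_change) == np.sign(lv.coef)

    def test_pairwise_deletion_counts_missing_rows(self):
        df = _domain_frame()
        df.loc[df.index[:25], "sleep_quality"] = np.nan
        spec = ModelSpec("type1", "night", "sleep_quality")
        res = fit_domain_model(df, spec)
        assert res.n_dropped_missing == 25
        assert res.n_obs == len(df) - 25

    def test_unobserved_level_warns_and_is_omitted(self):
        df = _domain_frame()
        df = df[df["category"] != "C"]
        spec = ModelSpec("type1", "night", "sleep_quality")
        with pytest.warns(UserWarning, match="'C' unobserved"):
            res = fit_domain_model(df, spec)
        assert {lv.level for lv in res.levels} == {"B", "D"}

    def test_single_exposure_level_rejected(self):
        df = _domain_frame()
        df["category"] = "A"
        with pytest.raises(EstimationError):
            fit_domain_model(df, ModelSpec("type1", "night", "sleep_quality"))


class TestRunModelFamily:
    @pytest.fixture(scope="class")
    def tidy_table(self):
        rows = []
        for cohort in ("type1", "type2"):
            for phase, domains in (("night", ("sleep_quality", "mood")),
                                   ("day", ("mood",))):
                for domain in domains:
                    df = _domain_frame(seed=hash((cohort, phase, domain)) % 2**31, n=40, k=12)
                    df = df.rename(columns={"sleep_quality": "score"})
                    df["cohort"] = cohort
                    df["phase"] = phase
                    df["domain"] = domain
                    df["prh_combined"] = np.where(
                        df["category"].isin(["C", "D"]), "symptomatic-treated", "none"
                    )
                    df["sdh_subtype"] = np.where(
                        df["category"].isin(["B", "D"]), "SDH_3.9", "none"
                    )
                    df["prh_present"] = df["category"].isin(["C", "D"]).astype(int)
                    df["sdh_present"] = df["category"].isin(["B", "D"]).astype(int)
                    rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def test_one_model_per_cell_and_flagging(self, tidy_table):
        from hypodiary.ema import DomainCatalogue

        cat = DomainCatalogue(morning=("sleep_quality", "mood"), evening=("mood",))
        results, plan = run_model_family(
            tidy_table, catalogue=cat, covariates=("age",), exposures=("category", "sdh")
        )
        primary = [r for r in results if r.spec.exposure_family == "category"]
        explor = [r for r in results if r.spec.exposure_family == "sdh"]
        assert len(primary) == 2 * 3  # cohorts x (2 morning + 1 evening domains)
        assert plan.n_tests == count_tests(2, 1, 2, 7)
        for r in primary:
            assert r.multiplicity == "bonferroni"
            for lv in r.levels:
                assert lv.significant == (lv.p_value < plan.alpha_per_test)
        for r in explor:
            assert r.multiplicity == "unadjusted"
            for lv in r.levels:
                assert lv.significant == (lv.p_value < 0.05)
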