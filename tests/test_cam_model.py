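import math

import numpy as np
import pytest

from camgfr import constants
from camgfr.cam_model import (
    CapabilityError,
    FittedModel,
    FittingError,
    build_design_matrix,
    build_design_row,
    default_model,
    fit_sqrt_model,
    load_model,
    predict_interval,
    predict_point,
    predict_sqrt,
    prob_below_threshold,
    save_model,
)
from camgfr.data_model import MG_DL, Cohort
from camgfr.synthetic_cohort import CohortSimConfig, generate_development_cohort
from camgfr.terms import EQ1_TERMS, INTERCEPT
from conftest import make_record


def _intercept_model(intercept=9.0, sigma2=None, n_obs=None, xtx=None):
    beta = np.zeros(len(EQ1_TERMS) + 1)
    beta[0] = intercept
    return FittedModel(
        beta=beta,
        term_names=(INTERCEPT,) + EQ1_TERMS,
        creatinine_unit=MG_DL,
        sigma2=sigma2,
        n_obs=n_obs,
        xtx_inverse=xtx,
    )


class TestDesignRow:
    def test_female_record_zeroes_sex_terms(self):
        row = build_design_row(make_record(sex="F"))
        names = (INTERCEPT,) + EQ1_TERMS
        assert row[names.index("male")] == 0.0
        assert row[names.index("male_age")] == 0.0

    def test_log_root_zeroes_creatinine_terms(self):
        row = build_design_row(make_record(cre_mgdl=1.0))  # ln(1) = 0
        names = (INTERCEPT,) + EQ1_TERMS
        for t in ("ln_cre", "ln_cre2", "ln_cre3"):
            assert row[names.index(t)] == pytest.approx(0.0, abs=1e-12)

    def test_interaction_consistency(self):
        r = make_record(sex="M", age=63.0)
        row = build_design_row(r)
        names = (INTERCEPT,) + EQ1_TERMS
        assert row[names.index("male_age")] == row[names.index("male")] * r.age
        assert row[names.index("age_bsa")] == pytest.approx(r.age * r.bsa)

    def test_nonpositive_creatinine_rejected(self):
        r = make_record()
        bad = type(r)(**{**r.__dict__, "creatinine": 0.0})
        with pytest.raises(ValueError):
            build_design_row(bad)


class TestFit:
    def test_matches_normal_equations_oracle_on_toy_cohort(self, toy_cohort):
        model = fit_sqrt_model(toy_cohort)
        X = build_design_matrix(toy_cohort)
        y = np.sqrt(toy_cohort.measured_gfr)
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(model.beta, beta_oracle, rtol=1e-8)
        xtx_oracle = np.linalg.inv(X.T @ X)
        assert np.allclose(model.xtx_inverse, xtx_oracle, rtol=1e-6)
        n, p = X.shape
        rss = float(np.sum((y - X @ model.beta) ** 2))
        assert model.sigma2 == pytest.approx(rss / (n - p))

    def test_matches_statsmodels_cross_check(self, toy_cohort):
        sm = pytest.importorskip("statsmodels.api")
        X = build_design_matrix(toy_cohort)
        y = np.sqrt(toy_cohort.measured_gfr)
        fit = sm.OLS(y, X).fit()
        model = fit_sqrt_model(toy_cohort)
        assert np.allclose(model.beta, fit.params, rtol=1e-8)
        assert model.sigma2 == pytest.approx(fit.mse_resid)

    def test_mean_residual_zero_with_intercept(self):
        cohort = generate_development_cohort(CohortSimConfig(n=300, seed=21))
        model = fit_sqrt_model(cohort)
        X = build_design_matrix(cohort)
        resid = np.sqrt(cohort.measured_gfr) - X @ model.beta
        assert abs(float(np.mean(resid))) < 1e-10

    def test_parameter_recovery_within_three_se(self):
        cfg = CohortSimConfig(n=1977, seed=77)
        model = fit_sqrt_model(generate_development_cohort(cfg))
        truth = np.array([cfg.beta[k] for k in model.term_names])
        se = np.sqrt(model.sigma2 * np.diag(model.xtx_inverse))
        assert np.all(np.abs(model.beta - truth) <= 3.0 * se)

    def test_rank_deficiency_names_collinear_term(self, toy_cohort):
        with pytest.raises(FittingError, match="ln_cre"):
            fit_sqrt_model(toy_cohort, ("age", "ln_cre", "ln_cre"))

    def test_too_few_records(self, toy_cohort):
        small = Cohort(toy_cohort.records[:5], creatinine_unit=toy_cohort.creatinine_unit)
        with pytest.raises(FittingError):
            fit_sqrt_model(small)


class TestPredictPoint:
    def test_intercept_only_squares_the_intercept(self, grid_records):
        model = _intercept_model(9.0)
        assert all(predict_point(model, r) == pytest.approx(81.0) for r in grid_records)

    def test_sex_contribution_on_sqrt_scale(self):
        model = default_model()
        names = model.term_names
        b6 = model.beta[names.index("male")]
        b7 = model.beta[names.index("male_age")]
        m = make_record(sex="M", age=58.0)
        f = make_record(sex="F", age=58.0)
        assert predict_sqrt(model, m) - predict_sqrt(model, f) == pytest.approx(
            b6 + b7 * 58.0
        )

    def test_matches_term_by_term_arithmetic_oracle(self, grid_records):
        """Coefficients applied by hand to each record reproduce the point
        estimate to 0.01 mL/min."""
        model = default_model()
        b = constants.DEFAULT_BETA
        for r in grid_records:
            L = math.log(r.creatinine_in(MG_DL))
            sqrt_gfr = (
                b["intercept"]
                + b["age"] * r.age
                + b["bsa"] * r.bsa
                + b["ln_cre"] * L
                + b["ln_cre2"] * L**2
                + b["ln_cre3"] * L**3
                + (b["male"] + b["male_age"] * r.age) * (1 if r.is_male else 0)
                + b["age_bsa"] * r.age * r.bsa
            )
            expected = max(0.0, sqrt_gfr) ** 2
            assert predict_point(model, r) == pytest.approx(expected, abs=0.01)

    def test_negative_sqrt_prediction_clamped(self):
        model = _intercept_model(-1.0)
        assert predict_point(model, make_record()) == 0.0

    def test_decreasing_in_creatinine_over_clinical_range(self):
        # strictly decreasing on the sqrt scale across 0.2-10 mg/dL; the
        # squared scale is only non-increasing once the zero clamp engages
        model = default_model()
        grid = np.linspace(0.2, 10.0, 120)
        sqrt_vals = [predict_sqrt(model, make_record(cre_mgdl=c)) for c in grid]
        assert all(b < a for a, b in zip(sqrt_vals, sqrt_vals[1:]))
        vals = [predict_point(model, make_record(cre_mgdl=c)) for c in grid]
        assert all(b <= a for a, b in zip(vals, vals[1:]))
        assert all(b < a for a, b in zip(vals, vals[1:]) if a > 0)


@pytest.fixture(scope="module")
def fitted():
    return fit_sqrt_model(generate_development_cohort(CohortSimConfig(n=1977, seed=5)))


class TestIntervals:
    def test_zero_variance_degenerates_to_point(self):
        p = len(EQ1_TERMS) + 1
        model = _intercept_model(9.0, sigma2=0.0, n_obs=100, xtx=np.zeros((p, p)))
        r = make_record()
        lo, hi = predict_interval(model, r, 0.95)
        assert lo == hi == pytest.approx(predict_point(model, r))

    def test_nesting_and_bracketing(self, fitted):
        r = make_record(age=66.0, cre_mgdl=1.4)
        lo95, hi95 = predict_interval(fitted, r, 0.95)
        lo99, hi99 = predict_interval(fitted, r, 0.99)
        point = predict_point(fitted, r)
        assert lo99 <= lo95 <= point <= hi95 <= hi99

    def test_width_nondecreasing_in_sigma2(self, fitted):
        r = make_record()
        inflated = FittedModel(
            beta=fitted.beta,
            term_names=fitted.term_names,
            creatinine_unit=fitted.creatinine_unit,
            sigma2=fitted.sigma2 * 4.0,
            n_obs=fitted.n_obs,
            xtx_inverse=fitted.xtx_inverse,
        )
        lo1, hi1 = predict_interval(fitted, r)
        lo2, hi2 = predict_interval(inflated, r)
        assert hi2 - lo2 > hi1 - lo1

    def test_coefficients_only_model_errors_clearly(self):
        model = default_model()
        with pytest.raises(CapabilityError):
            predict_interval(model, make_record())
        with pytest.raises(CapabilityError):
            prob_below_threshold(model, make_record(), 50.0)

    def test_bad_level_rejected(self, fitted):
        with pytest.raises(ValueError):
            predict_interval(fitted, make_record(), level=1.0)


class TestProbBelowThreshold:
    def test_half_at_the_point_prediction(self, fitted):
        r = make_record(age=70.0, cre_mgdl=1.6)
        cutoff = predict_sqrt(fitted, r) ** 2
        assert prob_below_threshold(fitted, r, cutoff) == pytest.approx(0.5, abs=1e-12)

    def test_limits_and_monotonicity(self, fitted):
        r = make_record()
        cutoffs = [10.0, 50.0, 120.0, 1e5]
        probs = [prob_below_threshold(fitted, r, c) for c in cutoffs]
        assert probs == sorted(probs)
        assert probs[-1] > 0.9999

    def test_complementarity(self, fitted):
        r = make_record()
        p_below = prob_below_threshold(fitted, r, 50.0)
        # P(below) + P(above) = 1 by construction of the t CDF
        assert 0.0 <= p_below <= 1.0

    def test_agrees_with_monte_carlo_frequency(self, fitted):
        """10^5 draws from the fitted error model reproduce the probability
        within 0.005."""
        from scipy import stats

        r = make_record(age=72.0, cre_mgdl=1.8, sex="F")
        x = build_design_row(r, fitted.term_names[1:], fitted.creatinine_unit)
        m = float(fitted.beta @ x)
        s = math.sqrt(fitted.sigma2 * (1.0 + float(x @ fitted.xtx_inverse @ x)))
        rng = np.random.default_rng(1234)
        draws = m + s * stats.t.rvs(df=fitted.df_resid, size=100_000, random_state=rng)
        for cutoff in (40.0, 60.0):
            mc = float(np.mean(draws < math.sqrt(cutoff)))
            assert prob_below_threshold(fitted, r, cutoff) == pytest.approx(mc, abs=0.005)


class TestSerialization:
    def test_round_trip_reproduces_predictions_bit_for_bit(self, tmp_path, toy_cohort):
        model = fit_sqrt_model(toy_cohort)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        r = make_record(age=44.0, cre_mgdl=1.2, sex="F")
        assert predict_point(back, r) == predict_point(model, r)
        assert predict_interval(back, r) == predict_interval(model, r)
        assert prob_below_threshold(back, r, 50.0) == prob_below_threshold(model, r, 50.0)

    def test_coefficients_only_round_trip_degrades_gracefully(self, tmp_path):
        model = default_model()
        path = tmp_path / "coef.json"
        save_model(model, path)
        back = load_model(path)
        assert not back.has_interval_support
        assert predict_point(back, make_record()) == predict_point(model, make_record())
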