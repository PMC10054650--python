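"""Unit tests for the quantal dose-response core."""

import math
import warnings

import numpy as np
import pytest

from btassay.errors import (
    DegenerateDataError,
    InvalidControlError,
    MissingDataError,
    NonMonotoneFitError,
    UnboundedLimitsError,
)
from btassay.quantal import (
    abbott_correct,
    activity_screen,
    confidence_limits,
    fit_quantal,
    goodness_of_fit,
    lc_p,
    pool_observations,
)
from btassay.simulate import design_for_truth, simulate_assay
from btassay.types import BioassayObservation, LethalConcentration, QuantalFit, TrueModel

from conftest import grid_ml_oracle


def make_fit(intercept, slope, cov=None, link="logit", chi2=0.0, df=4, het=1.0):
    return QuantalFit(
        link=link, slope=slope, intercept=intercept,
        covariance=np.zeros((2, 2)) if cov is None else np.asarray(cov, float),
        k_doses=df + 2, chi2=chi2, df=df, heterogeneity=het,
        converged=True, iterations=1,
    )


class TestAbbott:
    @pytest.mark.parametrize(
        "p_treated,p_control,expected",
        [
            (0.50, 0.00, 0.50),   # zero control mortality is the identity
            (0.10, 0.10, 0.00),   # treated equals control
            (0.55, 0.10, 0.50),   # (0.55-0.10)/0.90
            (0.05, 0.10, 0.00),   # clamped at 0
            (1.00, 0.30, 1.00),
        ],
    )
    def test_examples(self, p_treated, p_control, expected):
        assert abbott_correct(p_treated, p_control) == pytest.approx(expected)

    def test_total_control_mortality_is_invalid(self):
        with pytest.raises(InvalidControlError):
            abbott_correct(0.5, 1.0)

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            abbott_correct(1.5, 0.0)
        with pytest.raises(ValueError):
            abbott_correct(0.5, -0.1)


class TestFitQuantal:
    def test_two_dose_saturated_design_solves_exactly(self):
        # line through logit(0.25) at log10(10) and logit(0.75) at log10(1000)
        obs = [
            BioassayObservation("t", 10.0, 100, 25),
            BioassayObservation("t", 1000.0, 100, 75),
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_quantal(obs)
        logit3 = math.log(3.0)  # logit(0.75) = -logit(0.25)
        assert fit.slope == pytest.approx(logit3, abs=1e-6)
        assert fit.intercept == pytest.approx(-2.0 * logit3, abs=1e-6)

    def test_flat_response_is_degenerate(self):
        obs = [BioassayObservation("t", d, 20, 10) for d in (10, 100, 1000)]
        with pytest.raises(DegenerateDataError):
            fit_quantal(obs)

    @pytest.mark.parametrize("dead", [0, 20])
    def test_all_alive_or_all_dead_is_degenerate(self, dead):
        obs = [BioassayObservation("t", d, 20, dead) for d in (10, 100, 1000)]
        with pytest.raises(DegenerateDataError):
            fit_quantal(obs)

    def test_complete_separation_is_degenerate(self):
        obs = [
            BioassayObservation("t", 10.0, 20, 0),
            BioassayObservation("t", 100.0, 20, 0),
            BioassayObservation("t", 1000.0, 20, 20),
        ]
        with pytest.raises(DegenerateDataError):
            fit_quantal(obs)

    def test_controls_never_enter_the_regression(self, standard_assay):
        controls = [o for o in standard_assay if o.is_control]
        assert controls
        with_ctrl = fit_quantal(standard_assay)
        without_ctrl = fit_quantal([o for o in standard_assay if not o.is_control])
        assert with_ctrl.slope == pytest.approx(without_ctrl.slope)
        assert with_ctrl.intercept == pytest.approx(without_ctrl.intercept)

    @pytest.mark.parametrize("link", ["logit", "probit"])
    def test_matches_grid_search_oracle(self, standard_assay, link):
        fit = fit_quantal(standard_assay, link=link)
        doses, n, y = pool_observations(standard_assay)
        a, b = grid_ml_oracle(doses, n, y, link=link)
        assert fit.intercept == pytest.approx(a, abs=1e-4)
        assert fit.slope == pytest.approx(b, abs=1e-4)

    @pytest.mark.parametrize("link", ["logit", "probit"])
    def test_matches_statsmodels_glm(self, standard_assay, link):
        sm = pytest.importorskip("statsmodels.api")
        doses, n, y = pool_observations(standard_assay)
        X = sm.add_constant(np.log10(doses))
        family = sm.families.Binomial(
            link=sm.families.links.Logit() if link == "logit"
            else sm.families.links.Probit()
        )
        res = sm.GLM(np.column_stack([y, n - y]), X, family=family).fit()
        fit = fit_quantal(standard_assay, link=link)
        assert fit.intercept == pytest.approx(res.params[0], rel=1e-5)
        assert fit.slope == pytest.approx(res.params[1], rel=1e-5)
        if link == "logit":  # canonical link: observed == expected information
            assert np.allclose(fit.covariance, res.cov_params(), rtol=1e-4)

    def test_covariance_is_symmetric_psd(self, standard_assay):
        fit = fit_quantal(standard_assay)
        cov = fit.covariance
        assert np.allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) >= 0)
        assert fit.slope_se == pytest.approx(math.sqrt(cov[1, 1]))


class TestLcP:
    @pytest.mark.parametrize(
        "intercept,slope,printed",
        [
            (-4.04, 1.80, 178.0),   # Cry4Aa
            (-1.95, 1.17, 46.0),    # Cry4Ba
            (-2.61, 1.11, 228.0),   # Cry11Aa
            (-4.12, 1.85, 171.0),   # Cyt1Aa
        ],
    )
    def test_lc50_consistent_with_reported_coefficients(self, intercept, slope, printed):
        lc = lc_p(make_fit(intercept, slope), 0.5)
        assert lc.estimate == pytest.approx(printed, rel=0.02)

    def test_unit_fit_gives_unit_lc50(self):
        assert lc_p(make_fit(0.0, 1.0), 0.5).estimate == pytest.approx(1.0)

    @pytest.mark.parametrize("link", ["logit", "probit"])
    def test_lc50_closed_form(self, link):
        fit = make_fit(-3.3, 1.7, link=link)
        assert lc_p(fit, 0.5).estimate == pytest.approx(10 ** (3.3 / 1.7), rel=1e-12)

    def test_non_positive_slope_rejected(self):
        with pytest.raises(NonMonotoneFitError):
            lc_p(make_fit(0.0, -1.0), 0.5)


class TestConfidenceLimits:
    def test_zero_covariance_collapses_to_point(self):
        for method in ("fieller", "delta"):
            lc = confidence_limits(make_fit(-4.0, 2.0), method=method)
            assert lc.lower == lc.estimate == lc.upper

    def test_fieller_brackets_point_and_is_wider_than_zero(self, standard_assay):
        fit = fit_quantal(standard_assay)
        lc = confidence_limits(fit, method="fieller")
        assert 0 < lc.lower < lc.estimate < lc.upper

    def test_unbounded_when_slope_not_significant(self):
        # huge slope variance: g >= 1
        cov = np.array([[1.0, 0.0], [0.0, 100.0]])
        with pytest.raises(UnboundedLimitsError):
            confidence_limits(make_fit(-2.0, 1.0, cov), method="fieller")

    def test_delta_matches_parametric_bootstrap(self, standard_assay, cyt1aa_truth):
        """Delta-method 95% limits vs a 2000-draw parametric-bootstrap
        percentile interval, within 15% relative on each limit."""
        fit = fit_quantal(standard_assay)
        lc = confidence_limits(fit, method="delta")
        doses, n, y = pool_observations(standard_assay)
        p = np.asarray(fit.predict(doses))
        rng = np.random.default_rng(777)
        draws = []
        for _ in range(2000):
            yb = rng.binomial(n.astype(int), p)
            obs = [
                BioassayObservation("b", d, int(ni), int(yi))
                for d, ni, yi in zip(doses, n, yb)
            ]
            try:
                fb = fit_quantal(obs)
                draws.append(lc_p(fb, 0.5).estimate)
            except Exception:
                continue
        assert len(draws) > 1800
        lo, hi = np.percentile(draws, [2.5, 97.5])
        assert lc.lower == pytest.approx(lo, rel=0.15)
        assert lc.upper == pytest.approx(hi, rel=0.15)

    def test_reported_coefficients_give_limits_of_reported_order(self):
        """With slope SE 0.182 and a design-shaped covariance, Fieller limits
        around LC50 46 are of the same order as the reported 30.4-65.7."""
        a, b, se_b = -1.95, 1.17, 0.182
        # information-matrix shape from the 6-dose 1:2 design topped at 500 ng/mL
        doses = np.array([500.0 / 2**i for i in range(6)])
        x = np.log10(doses)
        p = 1 / (1 + np.exp(-(a + b * x)))
        w = p * (1 - p)
        X = np.column_stack([np.ones_like(x), x])
        info = X.T @ (w[:, None] * X)
        cov = np.linalg.inv(info)
        cov *= se_b**2 / cov[1, 1]  # scale so the slope SE matches
        lc = confidence_limits(make_fit(a, b, cov), method="fieller")
        assert lc.lower < 46 < lc.upper
        assert 20 < lc.lower < 46
        assert 46 < lc.upper < 120


class TestGoodnessOfFit:
    def test_six_dose_design_has_four_df(self, standard_assay):
        fit = fit_quantal(standard_assay)
        chi2, df, het = goodness_of_fit(fit, standard_assay)
        assert df == 4
        assert het >= 1.0

    def test_perfect_fit_has_zero_chi2(self):
        fit = make_fit(0.0, 1.0)
        doses = [0.1, 1.0, 10.0]
        p = np.asarray(fit.predict(doses))
        obs = [
            BioassayObservation("t", d, 1000, float(1000 * pi))
            for d, pi in zip(doses, p)
        ]
        chi2, df, het = goodness_of_fit(fit, obs)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert het == 1.0

    def test_hand_computed_pearson_sum(self):
        # predicted 0.2 / 0.5 / 0.8 at the three doses; observed 3, 5, 7 of 10
        fit = make_fit(0.0, 1.0)
        logit = lambda p: math.log(p / (1 - p))
        doses = [10 ** logit(p) for p in (0.2, 0.5, 0.8)]
        obs = [
            BioassayObservation("t", d, 10, dead)
            for d, dead in zip(doses, (3, 5, 7))
        ]
        chi2, df, _ = goodness_of_fit(fit, obs)
        assert chi2 == pytest.approx(1.0 / 1.6 + 0.0 + 1.0 / 1.6)
        assert df == 1

    def test_extreme_dose_excluded_with_warning(self):
        fit = make_fit(0.0, 2.0)
        doses = [1e-20, 0.1, 1.0, 10.0]  # first dose has predicted p ~ 0
        obs = [BioassayObservation("t", d, 10, dead) for d, dead in zip(doses, (0, 3, 5, 8))]
        with pytest.warns(UserWarning, match="expected count"):
            chi2, df, _ = goodness_of_fit(fit, obs)
        assert df == 1  # 3 usable doses - 2


class TestActivityScreen:
    def test_inactive_at_screen_dose_censors_lc50(self):
        res = activity_screen({1e5: 0.0}, 1e5)
        assert res.verdict == "non_active"
        assert res.lc50.censored
        assert res.lc50.censor_bound == 1e5
        assert res.lc50.censor_direction == "greater_than"

    @pytest.mark.parametrize("mortality", [1.00, 0.7333])
    def test_active_at_high_dose(self, mortality):
        res = activity_screen({1000.0: mortality}, 1000.0)
        assert res.verdict == "active"
        assert res.lc50 is None

    def test_threshold_is_strict_below(self):
        assert activity_screen({10.0: 0.10}, 10.0).verdict == "active"
        assert activity_screen({10.0: 0.0999}, 10.0).verdict == "non_active"

    def test_missing_data_errors(self):
        with pytest.raises(MissingDataError):
            activity_screen({}, 10.0)
        with pytest.raises(MissingDataError):
            activity_screen({1.0: 0.5}, 10.0)


class TestObservationInvariants:
    def test_rejects_inconsistent_counts(self):
        with pytest.raises(ValueError):
            BioassayObservation("t", 10.0, 10, 11)
        with pytest.raises(ValueError):
            BioassayObservation("t", 10.0, 0, 0)

    def test_control_flag_tied_to_zero_concentration(self):
        with pytest.raises(ValueError):
            BioassayObservation("t", 10.0, 10, 0, is_control=True)
        with pytest.raises(ValueError):
            BioassayObservation("t", 0.0, 10, 0, is_control=False)

    def test_censored_lc_carries_no_estimate(self):
        lc = LethalConcentration.censored_above(1e5)
        assert lc.estimate is None and lc.lower is None and lc.upper is None
        with pytest.raises(ValueError):
            LethalConcentration(estimate=10.0, censored=True,
                                censor_bound=1e5, censor_direction="greater_than")
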