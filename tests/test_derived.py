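"""Predictions, first-return curve, variance components, sensitivities,
de-standardization and the fledging-mass ANOVA."""

import dataclasses

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from mscmr.data import standardize
from mscmr.derived import (
    annual_survival_estimates,
    cumulative_first_return,
    destandardize_slope,
    mass_year_anova,
    predict_survival,
    sensitivity,
    sensitivity_table,
    variance_components,
)
from mscmr.model import fit_model


@pytest.fixture(scope="module")
def mass_fit(small_sim):
    ds, _ = small_sim
    return ds, fit_model("phi(a2 mass) p(T3) psi(4 ln)", ds, n_restarts=1, seed=0)


class TestCumulativeFirstReturn:
    def test_certain_first_age(self):
        assert cumulative_first_return([1.0])[0] == 1.0

    def test_product_arithmetic(self):
        C = cumulative_first_return([0.1, 0.5, 0.78])
        assert C[0] == pytest.approx(0.1)
        assert C[2] == pytest.approx(1 - 0.9 * 0.5 * 0.22)

    def test_nondecreasing_and_reaches_one(self):
        C = cumulative_first_return([0.1, 0.5, 0.78, 1.0])
        assert np.all(np.diff(C) >= 0)
        assert C[-1] == pytest.approx(1.0)

    def test_matches_first_return_age_enumeration(self):
        # P(returned by age a) as an explicit sum over first-return ages
        psi = np.array([0.2, 0.4, 0.9, 1.0])
        C = cumulative_first_return(psi)
        prob_first = []
        stay = 1.0
        for v in psi:
            prob_first.append(stay * v)
            stay *= 1 - v
        assert np.allclose(C, np.cumsum(prob_first))


class TestVarianceComponents:
    def test_identical_estimates_zero_process_variance(self):
        out = variance_components([0.4] * 6, [0.01] * 6)
        assert out.sigma2_process == 0.0
        assert out.mean == pytest.approx(0.4)

    def test_tiny_sampling_variance_limit(self):
        rng = np.random.default_rng(0)
        theta = rng.normal(0.5, 0.1, 12)
        out = variance_components(theta, [1e-12] * 12)
        assert out.sigma2_process == pytest.approx(np.var(theta, ddof=1), rel=1e-3)

    def test_scale_consistency(self):
        rng = np.random.default_rng(1)
        theta = rng.normal(0.5, 0.08, 8)
        v = rng.uniform(0.001, 0.003, 8)
        a = variance_components(theta, v).sigma2_process
        b = variance_components(np.sqrt(3) * theta, 3 * v).sigma2_process
        assert b == pytest.approx(3 * a, rel=1e-6)

    def test_shrunken_estimates_between_raw_and_mean(self):
        rng = np.random.default_rng(2)
        theta = rng.normal(0.5, 0.1, 7)
        out = variance_components(theta, [0.004] * 7)
        lo = np.minimum(theta, out.mean) - 1e-12
        hi = np.maximum(theta, out.mean) + 1e-12
        assert np.all((out.shrunken >= lo) & (out.shrunken <= hi))

    def test_needs_three_estimates(self):
        with pytest.raises(ValueError):
            variance_components([0.5, 0.6], [0.01, 0.01])


class TestSensitivity:
    def test_zero_slope_gives_zero(self, mass_fit):
        ds, res = mass_fit
        res2 = dataclasses.replace(res, params=res.params.copy())
        res2.params[res.design.index_of("phi:mass")] = 0.0
        assert sensitivity(res2, 0, "mass") == 0.0

    def test_logistic_maximum_quarter(self, mass_fit):
        ds, res = mass_fit
        params = res.params.copy()
        params[res.design.index_of("phi:int:c0")] = 0.0  # phi = 0.5
        params[res.design.index_of("phi:mass")] = 1.0
        res2 = dataclasses.replace(res, params=params)
        assert sensitivity(res2, 0, "mass") == pytest.approx(0.25)

    def test_matches_finite_difference_of_prediction(self, mass_fit):
        ds, res = mass_fit
        h = 1e-6
        up = predict_survival(res, 0, {"mass": h})[0]
        dn = predict_survival(res, 0, {"mass": -h})[0]
        fd = (up - dn) / (2 * h)
        assert sensitivity(res, 0, "mass") == pytest.approx(fd, abs=1e-6)

    def test_absent_covariate_errors(self, mass_fit):
        ds, res = mass_fit
        with pytest.raises(KeyError):
            sensitivity(res, 1, "mass")  # mass enters the fledgling class only
        with pytest.raises(KeyError):
            sensitivity(res, 0, "sam_lag0")

    def test_table_marks_absent_cells(self, mass_fit):
        ds, res = mass_fit
        tab = sensitivity_table(res, [0, 1], ["mass"])
        assert np.isfinite(tab.loc[0, "mass"])
        assert np.isnan(tab.loc[1, "mass"])


class TestPredictSurvival:
    def test_at_means_equals_intercept_inverse_logit(self, mass_fit):
        ds, res = mass_fit
        phi, lo, hi = predict_survival(res, 1)
        assert phi == pytest.approx(float(expit(res.param("phi:int:c1"))))
        assert lo < phi < hi

    def test_one_sd_shift_moves_logit_by_slope(self, mass_fit):
        ds, res = mass_fit
        from scipy.special import logit

        phi0 = predict_survival(res, 0)[0]
        phi1 = predict_survival(res, 0, {"mass": 1.0})[0]
        assert logit(phi1) - logit(phi0) == pytest.approx(res.param("phi:mass"), abs=1e-10)

    def test_monotone_in_mass_with_positive_slope(self, mass_fit):
        ds, res = mass_fit
        std = ds.mass_standardizer
        masses = np.linspace(2.5, 4.2, 25)
        preds = [
            predict_survival(res, 0, {"mass": m}, standardizers={"mass": std})[0]
            for m in masses
        ]
        slope = res.param("phi:mass")
        diffs = np.diff(preds) * np.sign(slope)
        assert np.all(diffs > 0)

    def test_unknown_covariate_errors(self, mass_fit):
        ds, res = mass_fit
        with pytest.raises(KeyError):
            predict_survival(res, 0, {"nope": 1.0})


class TestAnnualEstimates:
    def test_additive_time_estimates_and_exclusion_rule(self, small_sim):
        ds, _ = small_sim
        res = fit_model("phi(a2 a+t) p(T3) psi(4 ln)", ds, n_restarts=1, seed=0)
        ests, variances, intervals = annual_survival_estimates(res, 1)
        assert len(ests) == len(variances) == len(intervals)
        assert np.all((ests > 0) & (ests < 1))
        assert np.all(variances > 0)

    def test_requires_additive_time(self, mass_fit):
        ds, res = mass_fit
        with pytest.raises(ValueError, match="additive"):
            annual_survival_estimates(res, 0)


class TestDestandardize:
    def test_unit_scale_identity(self):
        std = standardize([0.0, 1.0, 2.0])
        assert destandardize_slope(0.7, std) == pytest.approx(0.7)

    def test_quarter_kg_scale(self):
        std = dataclasses.replace(standardize([1.0, 2.0, 3.0]), scale=0.25)
        assert destandardize_slope(0.5, std) == pytest.approx(2.0)

    def test_round_trip(self):
        std = standardize([3.1, 3.3, 2.9, 3.6, 3.2])
        beta = 0.42
        assert destandardize_slope(beta, std) * std.scale == pytest.approx(beta)


class TestMassAnova:
    def test_identical_group_means_give_zero_f(self):
        groups = {y: [3.0, 3.2, 3.4] for y in range(2003, 2008)}
        F, _, _, p = mass_year_anova(groups)
        assert F == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_df_structure_eight_cohorts(self):
        rng = np.random.default_rng(3)
        sizes = [103, 103, 103, 103, 103, 103, 102, 102]  # 822 birds
        groups = {y: rng.normal(3.3, 0.3, s) for y, s in zip(range(8), sizes)}
        _, dfb, dfw, _ = mass_year_anova(groups)
        assert (dfb, dfw) == (7, 814)

    def test_two_groups_match_t_squared(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(3.2, 0.3, 30), rng.normal(3.5, 0.3, 25)
        F, dfb, dfw, p_f = mass_year_anova({1: a, 2: b})
        t, p_t = stats.ttest_ind(a, b)
        assert F == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            mass_year_anova({1: [3.0, 3.1]})
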