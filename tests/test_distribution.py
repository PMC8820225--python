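import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from deltalogcv import (
    DegenerateSampleError,
    DeltaLNParams,
    SampleSummary,
    common_cv,
    common_log_cv,
    delta_ln_cv,
    delta_ln_density,
    delta_ln_moments,
    log_cv_phi,
    sample_delta_ln,
    summarize,
    var_phi_hat,
)

PARAM_SWEEP = [
    DeltaLNParams(0.2, 0.0, 0.1),
    DeltaLNParams(0.5, 0.0, 1.0),
    DeltaLNParams(0.5, 2.0, 3.4),
    DeltaLNParams(0.8, -1.0, 2.0),
    DeltaLNParams(1.0, 1.0, 0.5),
]


class TestDensity:
    def test_point_mass_at_zero(self):
        assert delta_ln_density(0.0, DeltaLNParams(0.7, 0.0, 1.0)) == pytest.approx(0.3)

    def test_standard_lognormal_at_median(self):
        val = delta_ln_density(1.0, DeltaLNParams(1.0, 0.0, 1.0))
        assert val == pytest.approx(1.0 / math.sqrt(2.0 * math.pi), rel=1e-12)

    @pytest.mark.parametrize("params", PARAM_SWEEP, ids=str)
    def test_total_mass_is_one(self, params):
        cont, _ = integrate.quad(
            lambda x: delta_ln_density(x, params), 0.0, np.inf, limit=200
        )
        assert cont == pytest.approx(params.delta, abs=1e-6)
        assert (1.0 - params.delta) + cont == pytest.approx(1.0, abs=1e-6)

    def test_negative_x_rejected(self):
        with pytest.raises(ValueError):
            delta_ln_density(-0.1, DeltaLNParams(0.5, 0.0, 1.0))


class TestMoments:
    def test_delta_one_reduces_to_lognormal(self):
        mu, s2 = 0.3, 0.7
        mean, var = delta_ln_moments(DeltaLNParams(1.0, mu, s2))
        assert mean == pytest.approx(math.exp(mu + s2 / 2), rel=1e-12)
        assert var == pytest.approx(
            math.exp(2 * mu + s2) * (math.exp(s2) - 1.0), rel=1e-12
        )

    def test_half_delta_example(self):
        mean, _ = delta_ln_moments(DeltaLNParams(0.5, 0.0, 1.0))
        assert mean == pytest.approx(0.5 * math.exp(0.5), rel=1e-9)

    def test_monte_carlo_mean(self, rng):
        params = DeltaLNParams(0.6, 0.5, 1.2)
        n = 400_000
        x = sample_delta_ln(params, n, rng)
        mean, var = delta_ln_moments(params)
        se = math.sqrt(var / n)
        assert abs(x.mean() - mean) < 3 * se


class TestCV:
    def test_lognormal_reduction(self):
        assert delta_ln_cv(DeltaLNParams(1.0, 0.0, 1.0)) == pytest.approx(
            math.sqrt(math.e - 1.0), rel=1e-12
        )

    def test_direct_example(self):
        assert delta_ln_cv(DeltaLNParams(0.5, 0.0, 1.0)) == pytest.approx(
            math.sqrt((math.e - 0.5) / 0.5), rel=1e-12
        )

    @pytest.mark.parametrize("params", PARAM_SWEEP, ids=str)
    def test_cv_equals_sd_over_mean(self, params):
        mean, var = delta_ln_moments(params)
        assert delta_ln_cv(params) == pytest.approx(math.sqrt(var) / mean, rel=1e-12)

    @given(
        delta=st.floats(1e-3, 1.0),
        sigma2=st.floats(1e-3, 50.0),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_cv_matches_exp_phi(self, delta, sigma2):
        direct = math.sqrt((math.exp(sigma2) - delta) / delta)
        assert math.exp(log_cv_phi(sigma2, delta)) == pytest.approx(direct, rel=1e-12)


class TestLogCvPhi:
    def test_example_value(self):
        phi = log_cv_phi(1.0, 0.5)
        assert phi == pytest.approx(0.5 * (math.log(math.e - 0.5) - math.log(0.5)))
        assert math.exp(phi) == pytest.approx(2.1063, abs=5e-5)

    def test_stable_for_huge_sigma2(self):
        # the naive form exp(800) overflows; the log-space form stays finite
        phi = log_cv_phi(800.0, 0.5)
        assert phi == pytest.approx(0.5 * (800.0 + math.log(2.0)), rel=1e-12)

    def test_cv_to_zero_limit(self):
        assert log_cv_phi(1e-12, 1.0) < -10.0

    def test_delta_zero_rejected(self):
        with pytest.raises(ValueError):
            log_cv_phi(1.0, 0.0)


class TestSamplingAndSummaries:
    def test_no_zeros_when_delta_one(self, rng):
        x = sample_delta_ln(DeltaLNParams(1.0, 0.0, 1.0), 1000, rng)
        assert np.all(x > 0)

    def test_zero_fraction_binomial(self, rng):
        n = 100_000
        x = sample_delta_ln(DeltaLNParams(0.5, 0.0, 1.0), n, rng)
        frac0 = np.mean(x == 0)
        assert abs(frac0 - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_estimator_consistency(self, rng):
        params = DeltaLNParams(0.7, 1.5, 2.0)
        n = 100_000
        s = summarize(sample_delta_ln(params, n, rng))
        n1 = s.n1
        assert abs(s.delta_hat - 0.7) < 4 * math.sqrt(0.7 * 0.3 / n)
        assert abs(s.mu_hat - 1.5) < 4 * math.sqrt(2.0 / n1)
        assert abs(s.sigma2_hat - 2.0) < 4 * 2.0 * math.sqrt(2.0 / (n1 - 1))

    def test_hand_computed_summary(self):
        s = summarize([0.0, 0.0, 2.0, 4.0])
        assert (s.n, s.n1, s.n0) == (4, 2, 2)
        assert s.delta_hat == 0.5
        assert s.mu_hat == pytest.approx(1.0397, abs=1e-4)
        assert s.sigma2_hat == pytest.approx(0.2402, abs=1e-3)

    def test_all_positive_input(self):
        s = summarize([1.0, 2.0, 3.0])
        assert s.delta_hat == 1.0 and s.n0 == 0 and not s.degenerate

    def test_single_positive_is_degenerate(self):
        s = summarize([0.0, 0.0, 5.0])
        assert s.degenerate
        assert math.isnan(s.sigma2_hat)
        with pytest.raises(DegenerateSampleError):
            s.require_nondegenerate()


class TestVarPhiHat:
    def test_rainfall_station_value(self, rainfall_summaries):
        # n=62, n1=45, sigma2_hat=1.7857 evaluates to about 0.03776
        assert var_phi_hat(rainfall_summaries[0]) == pytest.approx(0.03776, abs=5e-5)

    def test_zero_when_no_zeros_and_no_spread(self):
        # delta_hat = 1 kills the first term; sigma2_hat -> 0 kills the second
        s = SampleSummary(n=50, n1=50, mu_hat=0.0, sigma2_hat=1e-9)
        assert var_phi_hat(s) == pytest.approx(0.0, abs=1e-12)

    def test_second_term_quartic_in_sigma(self):
        lo = SampleSummary(n=50, n1=50, mu_hat=0.0, sigma2_hat=1.0)
        hi = SampleSummary(n=50, n1=50, mu_hat=0.0, sigma2_hat=2.0)
        assert var_phi_hat(hi) == pytest.approx(4.0 * var_phi_hat(lo), rel=1e-9)

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateSampleError):
            var_phi_hat(summarize([0.0, 0.0, 5.0]))


class TestCommonCV:
    def test_weighted_mean_example(self):
        assert common_log_cv([0.5, 0.7], [1.0, 1.0]) == pytest.approx(0.6)

    def test_single_group_identity(self):
        assert common_log_cv([0.42], [17.0]) == pytest.approx(0.42)

    def test_weight_rescaling_invariance(self):
        phis = [0.2, 0.9, 1.4]
        w = np.array([1.0, 2.5, 0.3])
        assert common_log_cv(phis, w) == pytest.approx(common_log_cv(phis, 100 * w))

    def test_identical_groups_collapse(self):
        s = SampleSummary(n=62, n1=45, mu_hat=2.1, sigma2_hat=1.79)
        assert common_cv([s, s, s]) == pytest.approx(s.cv_hat, rel=1e-12)

    def test_single_group_is_exp_phi(self):
        s = SampleSummary(n=40, n1=30, mu_hat=0.0, sigma2_hat=0.8)
        assert common_cv([s]) == pytest.approx(math.exp(s.phi_hat), rel=1e-12)

    def test_rainfall_point_estimate_regression(self, rainfall_summaries):
        # frozen value of the precision-weighted combination of the three
        # printed station summaries
        assert common_cv(rainfall_summaries) == pytest.approx(3.0233, abs=1e-4)
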