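"""Unit and property tests for the discrete lognormal interval model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from firefreq import (
    CensorStatus,
    DiscreteLognormalParams,
    IntervalObservation,
    derived_descriptors,
    fit_mle,
    hazard,
    interval_pmf,
    log_likelihood,
    survival,
)
from firefreq.model import expected_interval

from conftest import draw_intervals

params_st = st.builds(
    DiscreteLognormalParams,
    mu=st.floats(-1.0, 3.0),
    sigma=st.floats(0.2, 2.0),
)


class TestPointValues:
    """Spot values of f, A and lambda at published parameter sets."""

    def test_pmf_published_values(self, table_params):
        assert round(interval_pmf(2, table_params["SS"]), 2) == 0.32
        assert round(interval_pmf(2, table_params["SS"]), 4) == pytest.approx(0.3167, abs=2e-4)
        assert round(interval_pmf(3, table_params["DW"]), 2) == 0.11

    def test_pmf_t1_equals_normal_cdf(self, ss_params):
        # f(1) = Phi((ln 1 - mu)/sigma): the lower cut-point term vanishes
        from scipy.stats import norm

        assert interval_pmf(1, ss_params) == pytest.approx(norm.cdf(-0.82 / 0.66), abs=1e-12)
        assert interval_pmf(1, ss_params) == pytest.approx(0.1071, abs=1e-4)

    def test_survival_published_values(self, table_params):
        dw = table_params["DW"]
        assert round(survival(5, dw), 2) == 0.57
        assert survival(5, dw) == pytest.approx(0.5684, abs=1e-4)
        assert round(survival(10, dw), 2) == 0.30
        assert survival(0, dw) == 1.0

    def test_survival_derived_value(self, ss_params):
        assert survival(2, ss_params) == pytest.approx(0.5762, abs=1e-4)

    def test_hazard_published_peaks(self, table_params):
        assert round(hazard(4, table_params["SS"]), 2) == 0.42
        assert hazard(4, table_params["SS"]) == pytest.approx(0.419, abs=1e-3)
        assert round(hazard(3, table_params["GF"]), 2) == 0.24
        assert hazard(3, table_params["GF"]) == pytest.approx(0.2368, abs=1e-3)

    def test_hazard_at_1_is_pmf(self, ss_params):
        assert hazard(1, ss_params) == pytest.approx(interval_pmf(1, ss_params), abs=1e-15)

    def test_domain_errors(self, ss_params):
        with pytest.raises(ValueError):
            interval_pmf(0, ss_params)
        with pytest.raises(ValueError):
            survival(-1, ss_params)
        with pytest.raises(ValueError):
            hazard(0, ss_params)
        with pytest.raises(ValueError):
            interval_pmf(2.5, ss_params)

    def test_hazard_underflow_raises(self):
        # far beyond the support the denominator underflows; this must be
        # reported, not silently returned as 0/0
        p = DiscreteLognormalParams(0.0, 0.1)
        with pytest.raises(FloatingPointError):
            hazard(10000, p)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DiscreteLognormalParams(0.5, 0.0)
        with pytest.raises(ValueError):
            DiscreteLognormalParams(math.nan, 1.0)


class TestDistributionIdentities:
    @settings(deadline=None, max_examples=40)
    @given(params=params_st, T=st.integers(1, 60))
    def test_telescoping_sum(self, params, T):
        # sum_{t<=T} f(t) + A(T) = 1 exactly (telescoping of CDF differences)
        t = np.arange(1, T + 1)
        total = float(np.sum(interval_pmf(t, params))) + survival(T, params)
        assert total == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, max_examples=40)
    @given(params=params_st)
    def test_survival_non_increasing_and_pmf_nonnegative(self, params):
        t = np.arange(0, 80)
        s = np.asarray(survival(t, params))
        assert np.all(np.diff(s) <= 1e-15)
        f = np.asarray(interval_pmf(np.arange(1, 80), params))
        assert np.all(f >= 0)

    @settings(deadline=None, max_examples=30)
    @given(params=params_st, T=st.integers(1, 40))
    def test_hazard_product_identity(self, params, T):
        # prod_{u<=T} (1 - lambda(u)) = A(T)
        t = np.arange(1, T + 1)
        lam = np.asarray(hazard(t, params))
        assert float(np.prod(1.0 - lam)) == pytest.approx(survival(T, params), rel=1e-9, abs=1e-12)

    def test_hazard_unimodal_given_turning_point(self, table_params):
        for params in table_params.values():
            _, _, tp = derived_descriptors(params)
            lam = np.asarray(hazard(np.arange(1, 101), params))
            assert np.all(np.diff(lam[: tp]) > 0) or tp == 1
            assert np.all(np.diff(lam[tp - 1 :]) < 0)


class TestDerivedDescriptors:
    # median, mode, turning point as published per class
    EXPECTED = {
        "SS": (3, 2, 4),
        "OW": (3, 2, 4),
        "DW": (6, 3, 4),
        "VR": (3, 2, 3),
        "GF": (4, 2, 3),
        "CF": (5, 2, 4),
        "SC": (3, 2, 3),
    }

    @pytest.mark.parametrize("code", sorted(EXPECTED))
    def test_published_descriptor_columns(self, table_params, code):
        assert derived_descriptors(table_params[code]) == self.EXPECTED[code]

    def test_median_ceiling_boundary(self):
        # mu = ln 4 exactly: median is 4, not 5 (>= in the ceiling rule)
        assert derived_descriptors(DiscreteLognormalParams(math.log(4.0), 0.5))[0] == 4

    @settings(deadline=None, max_examples=40)
    @given(params=params_st)
    def test_descriptor_rules_and_bounds(self, params):
        median, mode, tp = derived_descriptors(params)
        assert median >= 1 and mode >= 1 and tp >= 1
        assert median - 1 < math.exp(params.mu) <= median
        assert mode - 1 <= math.exp(params.mu - params.sigma**2) < mode


class TestLogLikelihood:
    def test_single_complete_matches_log_pmf(self, ss_params):
        obs = [IntervalObservation(2, CensorStatus.COMPLETE)]
        assert log_likelihood(obs, ss_params) == pytest.approx(math.log(0.3167), abs=2e-4)
        assert log_likelihood(obs, ss_params) == pytest.approx(-1.150, abs=1e-3)

    def test_zero_length_censored_contributes_zero(self, ss_params):
        obs = [
            IntervalObservation(3, CensorStatus.COMPLETE),
            IntervalObservation(0, CensorStatus.RIGHT_CENSORED),
        ]
        only = [IntervalObservation(3, CensorStatus.COMPLETE)]
        assert log_likelihood(obs, ss_params) == log_likelihood(only, ss_params)

    def test_mixed_sample_term_by_term_oracle(self, ss_params):
        # brute-force sum of per-term logs, independent of the implementation
        sample = [
            IntervalObservation(1, CensorStatus.COMPLETE),
            IntervalObservation(2, CensorStatus.COMPLETE),
            IntervalObservation(2, CensorStatus.COMPLETE),
            IntervalObservation(4, CensorStatus.COMPLETE),
            IntervalObservation(7, CensorStatus.COMPLETE),
            IntervalObservation(3, CensorStatus.RIGHT_CENSORED),
            IntervalObservation(5, CensorStatus.RIGHT_CENSORED),
            IntervalObservation(0, CensorStatus.RIGHT_CENSORED),
            IntervalObservation(2, CensorStatus.LEFT_CENSORED),
            IntervalObservation(6, CensorStatus.LEFT_CENSORED),
        ]
        expected = 0.0
        for o in sample:
            if o.status == CensorStatus.COMPLETE:
                expected += math.log(interval_pmf(o.length, ss_params))
            elif o.status == CensorStatus.RIGHT_CENSORED and o.length > 0:
                expected += math.log(survival(o.length, ss_params))
            elif o.status == CensorStatus.LEFT_CENSORED and o.length > 1:
                expected += math.log(survival(o.length - 1, ss_params))
        assert log_likelihood(sample, ss_params) == pytest.approx(expected, rel=1e-12)

    def test_stationary_correction_subtracts_log_mean_interval(self, ss_params):
        sample = [
            IntervalObservation(2, CensorStatus.COMPLETE),
            IntervalObservation(3, CensorStatus.LEFT_CENSORED),
        ]
        plain = log_likelihood(sample, ss_params)
        stat = log_likelihood(sample, ss_params, stationary=True)
        assert stat == pytest.approx(plain - math.log(expected_interval(ss_params)), rel=1e-10)

    def test_empty_and_uninformative_samples_raise(self, ss_params):
        with pytest.raises(ValueError):
            log_likelihood([], ss_params)
        with pytest.raises(ValueError):
            log_likelihood([IntervalObservation(0, CensorStatus.RIGHT_CENSORED)], ss_params)


class TestExpectedInterval:
    def test_matches_direct_pmf_sum(self, table_params):
        for params in table_params.values():
            ts = np.arange(1, 5000)
            direct = float(np.sum(ts * np.asarray(interval_pmf(ts, params))))
            assert expected_interval(params) == pytest.approx(direct, rel=1e-6)


class TestFitMle:
    def test_recovery_iid_complete(self, ss_params):
        rng = np.random.default_rng(11)
        draw = draw_intervals(ss_params, 5000, rng)
        sample = [IntervalObservation(int(t), CensorStatus.COMPLETE) for t in draw]
        fit = fit_mle(sample)
        assert fit.converged
        assert abs(fit.params.mu - ss_params.mu) < 0.05
        assert abs(fit.params.sigma - ss_params.sigma) < 0.05
        assert fit.n_complete == 5000

    def test_bias_shrinks_with_sample_size(self, ss_params):
        errs = []
        for n in (500, 5000):
            rng = np.random.default_rng(5)
            draw = draw_intervals(ss_params, n, rng)
            fit = fit_mle([IntervalObservation(int(t), CensorStatus.COMPLETE) for t in draw])
            errs.append(math.hypot(fit.params.mu - ss_params.mu, fit.params.sigma - ss_params.sigma))
        assert errs[1] < errs[0]

    def test_descriptors_filled_in(self, ss_params):
        rng = np.random.default_rng(2)
        draw = draw_intervals(ss_params, 2000, rng)
        fit = fit_mle([IntervalObservation(int(t), CensorStatus.COMPLETE) for t in draw])
        assert (fit.median, fit.mode, fit.turning_point) == derived_descriptors(fit.params)

    def test_identical_intervals_flagged_degenerate(self):
        sample = [IntervalObservation(3, CensorStatus.COMPLETE)] * 20
        fit = fit_mle(sample)
        assert fit.degenerate
        assert fit.params.sigma <= 0.2  # driven toward the lower bound

    def test_too_few_complete_raises(self):
        with pytest.raises(ValueError, match="complete"):
            fit_mle([IntervalObservation(4, CensorStatus.RIGHT_CENSORED)] * 30)

    def test_deterministic(self, ss_params):
        rng = np.random.default_rng(3)
        draw = draw_intervals(ss_params, 500, rng)
        sample = [IntervalObservation(int(t), CensorStatus.COMPLETE) for t in draw]
        f1, f2 = fit_mle(sample), fit_mle(sample)
        assert f1.params == f2.params
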