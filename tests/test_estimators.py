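"""Estimator unit and property tests against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eatr
from eatr.estimators import (
    FitConfig,
    loglik_general,
    opes_slope_fit,
    scaling_eatr,
    scaling_imetad,
    scaling_ktr,
    survival_theoretical,
)
from eatr.model import BiasTrace, Ensemble, NoDataError, UnidentifiableRateError
from eatr.simulator import synthetic_biased_ensemble
from conftest import (
    constant_trace,
    make_record,
    random_biased_ensemble,
    unbiased_ensemble,
    zero_trace,
)

RECT = FitConfig(quadrature="rectangle")


class TestUnbiasedMLE:
    def test_complete_sample_is_inverse_mean(self):
        est = eatr.rate_mle_unbiased([make_record(t) for t in (1.0, 2.0, 3.0)])
        assert est.k0 == pytest.approx(0.5)
        assert est.gamma == 1.0

    def test_censoring_enters_denominator(self):
        recs = [make_record(2.0), make_record(3.0, transitioned=False)]
        assert eatr.rate_mle_unbiased(recs).k0 == pytest.approx(0.2)

    def test_no_events_unidentifiable(self):
        with pytest.raises(UnidentifiableRateError):
            eatr.rate_mle_unbiased([make_record(1.0, transitioned=False)])

    def test_exponential_recovery(self, rng):
        # closed-form MLE sampling distribution: sd(log k-hat) ~ 1/sqrt(M)
        k0, n = 0.01, 10_000
        recs = [make_record(float(t)) for t in rng.exponential(1 / k0, size=n)]
        est = eatr.rate_mle_unbiased(recs)
        assert abs(np.log(est.k0 / k0)) < 3.0 / np.sqrt(n)


class TestImetadScaling:
    def test_zero_bias_no_acceleration(self):
        alpha, rescaled = scaling_imetad(zero_trace(5.0), 3.0)
        assert alpha == pytest.approx(1.0)
        assert rescaled == pytest.approx(3.0)

    def test_constant_bias(self):
        # beta V = ln 2 over [0, 3] doubles the clock
        _, rescaled = scaling_imetad(constant_trace(np.log(2.0), 3.0), 3.0)
        assert rescaled == pytest.approx(6.0)

    def test_piecewise_step_hand_integral(self):
        # beta V = 0 on [0,1), ln 3 on [1,2]: integral = 1 + 3 (left rule)
        tr = BiasTrace(np.array([0.0, 1.0, 2.0]), np.array([0.0, np.log(3.0), np.log(3.0)]))
        _, rescaled = scaling_imetad(tr, 2.0, RECT)
        assert rescaled == pytest.approx(4.0)

    def test_short_grid_rejected(self):
        with pytest.raises(ValueError, match="grid ends"):
            scaling_imetad(zero_trace(1.0), 2.0)


class TestImetadRate:
    def test_zero_bias_reduces_to_unbiased(self):
        ens = unbiased_ensemble([1.0, 2.0, 3.0])
        assert eatr.rate_imetad(ens).k0 == pytest.approx(0.5)

    def test_constant_bias_closed_form(self):
        # two trajectories at constant beta V = 1, events at 1 and 2:
        # k0 = 2 / (e*1 + e*2) = 2/(3e)
        ens = Ensemble(
            [make_record(1.0), make_record(2.0)],
            [constant_trace(1.0, 1.0), constant_trace(1.0, 2.0)],
        )
        assert eatr.rate_imetad(ens).k0 == pytest.approx(2.0 / (3.0 * np.e))

    def test_inverse_transform_oracle(self, rng):
        # waiting times exponential in rescaled time, mapped back through a
        # known bias schedule -- the generating k0 must come back
        k0, n = 5e-3, 600
        bt = np.arange(0.0, 2001.0, 1.0)
        ens = synthetic_biased_ensemble(k0, 1.0, n, rng, bt, 0.002 * bt)
        est = eatr.rate_imetad(ens)
        assert abs(np.log(est.k0 / k0)) < 3.0 / np.sqrt(n)


class TestScalingFunctions:
    def test_gamma_zero_is_flat(self, rng):
        ens = random_biased_ensemble(rng)
        for build in (scaling_ktr, scaling_eatr):
            sf = build(ens, 0.0)
            assert np.allclose(sf.f, 1.0)

    def test_single_monotone_trace_ktr(self):
        tr = BiasTrace(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 2.5]))
        ens = Ensemble([make_record(2.0)], [tr])
        sf = scaling_ktr(ens, 0.5)
        grid_vals = tr.value_at(sf.times)
        assert np.allclose(sf.f, np.exp(0.5 * grid_vals))

    def test_two_constant_traces(self):
        ens = Ensemble(
            [make_record(2.0), make_record(2.0)],
            [constant_trace(1.0, 2.0), constant_trace(3.0, 2.0)],
        )
        ktr = scaling_ktr(ens, 1.0)
        eatr_sf = scaling_eatr(ens, 1.0)
        assert np.allclose(ktr.f, np.exp(2.0))  # mean of maxima {1, 3}
        assert np.allclose(eatr_sf.f, 0.5 * (np.e + np.e**3))

    @settings(derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000), gamma=st.floats(0.1, 1.0))
    def test_jensen_bound(self, seed, gamma):
        # <exp(g b V)> >= exp(g b <V>) under the same (here: uniform) weights
        ens = random_biased_ensemble(np.random.default_rng(seed))
        cfg = FitConfig(tail="freeze")
        sf = scaling_eatr(ens, gamma, config=cfg)
        from eatr.estimators import _bias_matrix

        rows, w = _bias_matrix(ens, sf.times)
        mean_bias = w @ rows / ens.n
        assert np.all(sf.f >= np.exp(gamma * mean_bias) - 1e-12)


class TestLoglikGeneral:
    def test_flat_scaling_hand_value(self):
        ens = unbiased_ensemble([1.0])
        sf = eatr.ScalingFunction.from_f(np.array([0.0, 2.0]), np.ones(2))
        assert loglik_general(ens, sf, 1.0) == pytest.approx(-1.0)

    def test_flat_scaling_argmax_is_unbiased_mle(self):
        ens = unbiased_ensemble([0.7, 1.3, 2.9, 4.1])
        sf = eatr.ScalingFunction.from_f(np.array([0.0, 10.0]), np.ones(2))
        k_grid = np.linspace(1e-3, 2.0, 4001)
        lls = [loglik_general(ens, sf, k) for k in k_grid]
        k_best = k_grid[int(np.argmax(lls))]
        assert k_best == pytest.approx(eatr.rate_mle_unbiased(ens.records).k0, abs=1e-3)

    def test_stationary_point_matches_grid_search(self, rng):
        # dlogL/dk0 = 0  =>  k0* = M / sum Gamma(tau_i), for any scaling
        ens = random_biased_ensemble(rng, n=8, complete=False)
        sf = scaling_eatr(ens, 0.7)
        m = ens.n_transitioned
        k_star = m / float(sf.Gamma_at(ens.times).sum())
        k_grid = k_star * np.logspace(-1, 1, 4001)
        lls = [loglik_general(ens, sf, k) for k in k_grid]
        assert k_grid[int(np.argmax(lls))] == pytest.approx(k_star, rel=2e-3)

    def test_nonpositive_rate_rejected(self):
        ens = unbiased_ensemble([1.0])
        sf = eatr.ScalingFunction.from_f(np.array([0.0, 2.0]), np.ones(2))
        with pytest.raises(ValueError):
            loglik_general(ens, sf, 0.0)


class TestProfileEstimators:
    def test_zero_bias_degenerate_flag(self):
        ens = unbiased_ensemble([1.0, 2.0, 3.0])
        for fn in (eatr.rate_ktr_mle, eatr.rate_eatr_mle):
            est = fn(ens)
            assert est.degenerate
            assert est.k0 == pytest.approx(0.5)

    def test_zero_bias_rate_independent_of_gamma(self):
        ens = unbiased_ensemble([1.0, 2.0, 3.0], censored=[4.0])
        for g in (0.0, 0.4, 1.0):
            assert eatr.rate_ktr_mle(ens, gamma=g).k0 == pytest.approx(0.3, rel=1e-12)
            assert eatr.rate_eatr_mle(ens, gamma=g).k0 == pytest.approx(0.3, rel=1e-12)

    def test_eatr_gamma1_equals_imetad_exactly(self, rng):
        for _ in range(10):
            ens = random_biased_ensemble(rng, complete=True)
            a = eatr.rate_eatr_mle(ens, gamma=1.0).k0
            b = eatr.rate_imetad(ens).k0
            assert a == b  # bitwise: shared code path

    def test_k0_profile_nonincreasing_in_gamma(self, rng):
        # more assumed efficiency => more acceleration attributed to bias
        ens = random_biased_ensemble(rng, n=12, complete=True)
        ks = [eatr.rate_eatr_mle(ens, gamma=g).k0 for g in np.linspace(0, 1, 21)]
        assert np.all(np.diff(ks) <= 1e-12)

    def test_recovery_with_censoring(self, rng):
        # inverse-CDF samples at known parameters, ~15% censored
        bt = np.arange(0.0, 4001.0, 2.0)
        ens = synthetic_biased_ensemble(
            1e-3, 0.5, 400, rng, bt, 0.01 * bt, max_time=500.0
        )
        assert 0 < ens.n_transitioned < ens.n
        est = eatr.rate_eatr_mle(ens)
        assert abs(est.log10_k0 + 3.0) < 0.15
        assert abs(est.gamma - 0.5) < 0.15


class TestSurvivalTheoretical:
    def test_flat_unit_rate(self):
        ens = unbiased_ensemble([1.0])
        s = survival_theoretical(ens, "unbiased", 1.0)
        assert s(0.5) == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_constant_scaling_doubles_exponent(self):
        ens = Ensemble([make_record(2.0)], [constant_trace(np.log(2.0), 2.0)])
        s = survival_theoretical(ens, "eatr", 1.0, gamma=1.0)
        assert s(0.5) == pytest.approx(np.exp(-1.0), rel=1e-6)

    @pytest.mark.parametrize("method", ["unbiased", "imetad", "ktr", "eatr"])
    def test_nonincreasing_from_one(self, method, rng):
        ens = random_biased_ensemble(rng, n=6)
        s = survival_theoretical(ens, method, 0.05, gamma=0.8)
        grid = np.linspace(0.0, 80.0, 300)
        vals = s(grid)
        assert vals[0] == pytest.approx(1.0)
        assert np.all(np.diff(vals) <= 1e-12)

    def test_unknown_method(self):
        ens = unbiased_ensemble([1.0])
        with pytest.raises(ValueError):
            survival_theoretical(ens, "nope", 1.0)


class TestCdfFit:
    def test_exponential_no_bias_free_gamma(self, rng):
        k0, n = 0.01, 1000
        bt = np.array([0.0, 1.0])
        ens = synthetic_biased_ensemble(k0, 1.0, n, rng, bt, np.zeros(2))
        est = eatr.fit_cdf(ens, "eatr")
        assert est.fit == "cdf"
        assert abs(np.log(est.k0 / k0)) < 3.0 / np.sqrt(n)

    def test_noise_free_self_consistency(self):
        # event times at exact model quantiles: fit must return the
        # generating parameters (up to ECDF discretization ~1/n)
        k0, gamma, n = 1e-3, 0.6, 4000
        bt = np.arange(0.0, 5001.0, 1.0)
        bv = 0.01 * bt
        from eatr.simulator import sample_first_passage_times

        class _QuantileRng:
            def uniform(self, size):
                return 1.0 - (np.arange(1, size + 1) - 0.5) / size

        times, _ = sample_first_passage_times(
            k0, n, _QuantileRng(), gamma=gamma, bias_times=bt, bias_values=bv
        )
        shared = BiasTrace(bt, bv)
        recs = [make_record(float(t)) for t in times]
        traces = [
            shared if t <= bt[-1] else BiasTrace(np.append(bt, t), np.append(bv, bv[-1]))
            for t in times
        ]
        est = eatr.fit_cdf(Ensemble(recs, traces), "eatr")
        assert est.k0 == pytest.approx(k0, rel=1e-2)
        assert est.gamma == pytest.approx(gamma, abs=1e-2)

    def test_needs_two_distinct_events(self):
        ens = unbiased_ensemble([1.0], censored=[2.0])
        with pytest.raises(NoDataError):
            eatr.fit_cdf(ens, "eatr")


class TestOpesSlopeFit:
    @staticmethod
    def _exact_ensembles(k0, gamma, vbars, n=10):
        out = []
        for v in vbars:
            k_obs = k0 * np.exp(gamma * v)
            recs = [make_record(1.0 / k_obs) for _ in range(n)]
            tr = constant_trace(v, 1.0 / k_obs)
            out.append(Ensemble(recs, [tr] * n))
        return out

    def test_exact_log_linear_identity(self):
        res = opes_slope_fit(self._exact_ensembles(1e-3, 0.7, (1.0, 2.0, 3.0)))
        assert res.k0 == pytest.approx(1e-3, rel=1e-9)
        assert res.gamma == pytest.approx(0.7, abs=1e-9)

    def test_noisy_recovery_within_regression_errors(self, rng):
        k0, gamma, n = 1e-3, 0.5, 200
        enss = []
        for v in (1.0, 2.0, 3.0):
            k_obs = k0 * np.exp(gamma * v)
            times = rng.exponential(1.0 / k_obs, size=n)
            recs = [make_record(float(t)) for t in times]
            traces = [constant_trace(v, float(t)) for t in times]
            enss.append(Ensemble(recs, traces))
        res = opes_slope_fit(enss)
        assert abs(res.gamma - gamma) < 3 * res.gamma_err
        assert abs(np.log10(res.k0 / k0)) < 3 * res.k0_log10_err

    def test_zero_efficiency(self, rng):
        k0, n = 2e-3, 300
        enss = []
        for v in (1.0, 2.0, 3.0):
            times = rng.exponential(1.0 / k0, size=n)
            recs = [make_record(float(t)) for t in times]
            enss.append(Ensemble(recs, [constant_trace(v, float(t)) for t in times]))
        res = opes_slope_fit(enss)
        assert abs(res.gamma) < 3 * res.gamma_err + 1e-9
        pooled = eatr.rate_mle_unbiased(
            [r for e in enss for r in e.records]
        ).k0
        assert np.log(res.k0 / pooled) == pytest.approx(0.0, abs=0.2)

    def test_input_validation(self):
        enss = self._exact_ensembles(1e-3, 0.7, (1.0, 2.0))
        with pytest.raises(NoDataError):
            opes_slope_fit(enss)
        flat = self._exact_ensembles(1e-3, 0.7, (2.0, 2.0, 2.0))
        with pytest.raises(NoDataError):
            opes_slope_fit(flat)
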