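"""Simulated neural signals: boxcar support, ensemble averaging, Model-1
coefficient time courses, peak latencies."""

import numpy as np
import pytest

from valudyn.ddm import DDMParameters, code_attributes
from valudyn.regression import BetaTimecourse
from valudyn.signals import (
    SignalConfig,
    build_trial_signals,
    compare_peak_latencies,
    ensemble_average_signals,
    model1_timecourses,
    peak_latency,
)
from conftest import EXAMPLE_PARAMS


@pytest.fixture(scope="module")
def ratings():
    rng = np.random.default_rng(21)
    taste = rng.integers(1, 7, 120)
    health = rng.integers(1, 7, 120)
    return code_attributes(taste, health)


class TestBuildTrialSignals:
    def test_onset_from_motor_constant(self):
        # onset = ndt - 80 ms motor preparation
        cfg = SignalConfig(rng_seed=0)
        s = build_trial_signals(EXAMPLE_PARAMS, 1.0, 0.0, cfg)
        onset_idx = int(round((EXAMPLE_PARAMS.ndt - cfg.motor_prep) / cfg.grid_dt))
        assert onset_idx == 382
        for name in ("taste_ac", "health_ac", "ea"):
            assert np.all(s[name][:onset_idx] == 0.0)

    def test_zero_at_epoch_ends(self):
        s = build_trial_signals(EXAMPLE_PARAMS, 1.5, -0.5, SignalConfig(rng_seed=3))
        assert s["rt"] < 2.0
        for name in ("taste_ac", "health_ac", "ea"):
            assert s[name][0] == 0.0
            assert s[name][-1] == 0.0

    def test_support_is_onset_to_rt(self):
        cfg = SignalConfig(rng_seed=5)
        s = build_trial_signals(EXAMPLE_PARAMS, 2.0, 1.0, cfg)
        i_rt = int(round(s["rt"] / cfg.grid_dt))
        onset_idx = int(round((EXAMPLE_PARAMS.ndt - cfg.motor_prep) / cfg.grid_dt))
        active = s["taste_ac"] != 0
        assert active[onset_idx + 1] and active[i_rt]
        assert not active[i_rt + 1:].any()

    def test_ea_reaches_boundary(self):
        p = EXAMPLE_PARAMS
        cfg = SignalConfig(rng_seed=7)
        s = build_trial_signals(p, 1.0, 1.0, cfg)
        i_rt = int(round(s["rt"] / cfg.grid_dt))
        up, lo = p.threshold * (1 - p.sp_bias), -p.threshold * p.sp_bias
        # |ea| at response equals the distance to the absorbing boundary
        # within one Euler step's noise scale
        end_val = s["ea"][i_rt]
        tol = 4 * np.sqrt(cfg.grid_dt)
        assert min(abs(end_val - up), abs(end_val - lo)) < tol


class TestEnsemble:
    def test_single_dataset_equals_build(self):
        cfg = SignalConfig(n_datasets=1, rng_seed=9)
        s = build_trial_signals(EXAMPLE_PARAMS, 1.2, -0.8, cfg)
        ens = ensemble_average_signals(EXAMPLE_PARAMS, [1.2], [-0.8], cfg)
        assert np.allclose(ens.taste_ac[0], s["taste_ac"])
        assert np.allclose(ens.ea[0], s["ea"])

    def test_deterministic_under_seed(self, ratings):
        t_c, h_c = ratings
        cfg = SignalConfig(n_datasets=20, rng_seed=4)
        a = ensemble_average_signals(EXAMPLE_PARAMS, t_c[:10], h_c[:10], cfg)
        b = ensemble_average_signals(EXAMPLE_PARAMS, t_c[:10], h_c[:10], cfg)
        assert np.array_equal(a.ea, b.ea)
        assert np.array_equal(a.mean_sim_rt, b.mean_sim_rt)

    def test_mean_rt_at_least_ndt(self, ratings):
        t_c, h_c = ratings
        ens = ensemble_average_signals(EXAMPLE_PARAMS, t_c[:20], h_c[:20], SignalConfig(n_datasets=50, rng_seed=1))
        assert np.all(ens.mean_sim_rt >= EXAMPLE_PARAMS.ndt)

    def test_early_slope_matches_drift(self, ratings):
        # law of large numbers: averaged EA slope just after onset ~ drift
        t_c, h_c = ratings
        cfg = SignalConfig(n_datasets=800, rng_seed=2)
        ens = ensemble_average_signals(EXAMPLE_PARAMS, t_c[:40], h_c[:40], cfg)
        i0 = int(round((EXAMPLE_PARAMS.ndt - cfg.motor_prep) / cfg.grid_dt))
        slope = (ens.ea[:, i0 + 30] - ens.ea[:, i0 + 5]) / (25 * cfg.grid_dt)
        drift = EXAMPLE_PARAMS.drift(t_c[:40], h_c[:40])
        assert np.corrcoef(slope, drift)[0, 1] > 0.95
        assert np.mean(np.abs(slope - drift)) < 0.25

    def test_boxcar_height_is_attribute_times_survival(self, ratings):
        # averaged boxcar at t = coded attribute x P(rt > t), against the
        # empirical survival from the recorded simulated RTs
        t_c, h_c = ratings
        cfg = SignalConfig(n_datasets=500, rng_seed=6)
        ens = ensemble_average_signals(EXAMPLE_PARAMS, t_c[:1], h_c[:1], cfg)
        frac = ens.taste_ac[0] / t_c[0]
        assert np.all((frac >= 0) & (frac <= 1 + 1e-12))
        i_mid = 900
        t_mid = ens.times[i_mid]
        assert frac[i_mid] == pytest.approx(
            max(0.0, 1.0 - 0.5), abs=0.5
        )  # loose sanity: a probability
        # survival decreases monotonically after onset
        i0 = int(round((EXAMPLE_PARAMS.ndt - cfg.motor_prep) / cfg.grid_dt))
        assert np.all(np.diff(frac[i0 + 1:]) <= 1e-12)

    def test_variance_shrinks_with_n_datasets(self):
        # pointwise variance of the ensemble mean scales ~ 1/n
        t_mid = 700
        var = {}
        for n in (10, 100):
            vals = []
            for rep in range(12):
                ens = ensemble_average_signals(
                    EXAMPLE_PARAMS, [1.0], [0.0], SignalConfig(n_datasets=n, rng_seed=100 * n + rep)
                )
                vals.append(ens.ea[0, t_mid])
            var[n] = np.var(vals)
        assert var[10] / var[100] > 3.0  # ~10 expected; loose for 12 reps


class TestModel1:
    def test_identity_when_all_active(self, ratings):
        t_c, h_c = ratings
        ens = ensemble_average_signals(EXAMPLE_PARAMS, t_c, h_c, SignalConfig(n_datasets=30, rng_seed=8))
        tcs = model1_timecourses(ens, t_c, h_c)
        # just after onset every simulation is still active: taste-AC equals
        # the coded rating exactly, so b_tastiness = 1 and b_healthiness = 0
        i = int(round((EXAMPLE_PARAMS.ndt - 0.080) / 0.001)) + 3
        assert tcs["taste_ac"]["b_tastiness"][i] == pytest.approx(1.0, abs=1e-6)
        assert tcs["taste_ac"]["b_healthiness"][i] == pytest.approx(0.0, abs=1e-6)

    def test_matches_normal_equations(self, ratings):
        t_c, h_c = ratings
        ens = ensemble_average_signals(EXAMPLE_PARAMS, t_c, h_c, SignalConfig(n_datasets=10, rng_seed=12))
        tcs = model1_timecourses(ens, t_c, h_c)
        X = np.column_stack([np.ones(t_c.size), t_c, h_c, ens.mean_sim_rt])
        rng = np.random.default_rng(0)
        for i in rng.integers(300, 1500, 5):
            b = np.linalg.solve(X.T @ X, X.T @ ens.ea[:, i])
            assert tcs["ea"]["b_tastiness"][i] == pytest.approx(b[1], abs=1e-8)
            assert tcs["ea"]["b0"][i] == pytest.approx(b[0], abs=1e-8)

    def test_too_few_trials(self, ratings):
        t_c, h_c = ratings
        ens = ensemble_average_signals(EXAMPLE_PARAMS, t_c[:5], h_c[:5], SignalConfig(n_datasets=5, rng_seed=1))
        with pytest.raises(ValueError, match="at least 10"):
            model1_timecourses(ens, t_c[:5], h_c[:5])


class TestPeakLatency:
    def _tc(self, vals, times=None):
        times = np.arange(len(vals)) * 0.01 if times is None else times
        return BetaTimecourse(times=times, coefs={"b": np.asarray(vals, float)}, ses={"b": np.zeros(len(vals))})

    def test_triangular_peak(self):
        t = np.arange(0, 1.0, 0.01)
        v = 1.0 - np.abs(t - 0.5) * 2
        assert peak_latency(self._tc(v, t), "b", (0, 1)) == pytest.approx(0.5)

    def test_flat_series_earliest(self):
        tc = self._tc(np.ones(50))
        assert peak_latency(tc, "b", (0.1, 0.4)) == pytest.approx(0.1)

    def test_sign_modes(self):
        t = np.arange(0, 1.0, 0.01)
        v = np.sin(2 * np.pi * t)  # max at .25, min at .75
        assert peak_latency(self._tc(v, t), "b", (0, 1), "max") == pytest.approx(0.25)
        assert peak_latency(self._tc(v, t), "b", (0, 1), "min") == pytest.approx(0.75)

    def test_all_nan_errors(self):
        tc = self._tc(np.full(20, np.nan))
        with pytest.raises(ValueError, match="NaN"):
            peak_latency(tc, "b", (0, 0.1))

    def test_compare_identical_inputs(self):
        t = np.arange(0, 1.0, 0.01)
        tcs = [self._tc(np.exp(-((t - 0.4) ** 2) / 0.01), t) for _ in range(5)]
        res = compare_peak_latencies(tcs, tcs, "b", (0, 1))
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_compare_constant_shift(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 1.5, 0.01)
        a_tcs, b_tcs = [], []
        for _ in range(20):
            c = rng.uniform(0.4, 0.9)
            a_tcs.append(self._tc(np.exp(-((t - (c - 0.1)) ** 2) / 0.005), t))
            b_tcs.append(self._tc(np.exp(-((t - c) ** 2) / 0.005), t))
        res = compare_peak_latencies(a_tcs, b_tcs, "b", (0, 1.5))
        assert res["t"] < 0
        assert res["p"] < 0.01
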