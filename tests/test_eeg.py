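"""ERP / time-frequency feature extraction."""

import numpy as np
import pytest

from valudyn.eeg import (
    DEFAULT_BANDS,
    EpochArray,
    TFPowerArray,
    band_bin_power,
    bin_erp,
    condition_average_power,
    morlet_power,
    preprocess_epochs,
    response_lock,
)
from valudyn.regression import BinGrid

FS = 256.0


def make_epochs(x):
    x = np.atleast_3d(x)
    return EpochArray(x, FS, -1.0, [f"ch{i}" for i in range(x.shape[1])])


@pytest.fixture(scope="module")
def times():
    return -1.0 + np.arange(int(2.5 * FS)) / FS


class TestPreprocess:
    def test_baseline_mean_zero(self, times):
        rng = np.random.default_rng(0)
        ep = make_epochs(rng.normal(size=(4, 3, times.size)))
        out = preprocess_epochs(ep)
        bl = (out.times >= -0.2) & (out.times <= 0)
        assert np.allclose(out.data[..., bl].mean(axis=-1), 0.0, atol=1e-10)

    def test_line_noise_attenuated(self, times):
        ep = make_epochs(np.sin(2 * np.pi * 60 * times)[None, None, :])
        out = preprocess_epochs(ep)
        mid = (times > -0.5) & (times < 1.0)
        atten = 20 * np.log10(np.std(out.data[0, 0, mid]) / np.std(ep.data[0, 0, mid]))
        assert atten <= -20

    def test_dc_removed(self, times):
        ep = make_epochs(np.full((1, 1, times.size), 5.0))
        out = preprocess_epochs(ep)
        mid = (times > -0.5) & (times < 1.0)
        assert np.abs(out.data[0, 0, mid]).max() < 0.05

    def test_low_fs_rejected(self, times):
        ep = EpochArray(np.zeros((1, 1, 100)), 150.0, -0.25, ["a"])
        with pytest.raises(ValueError, match="too low"):
            preprocess_epochs(ep)


class TestMorlet:
    def test_stationary_sinusoid_zero_db(self, times):
        ep = make_epochs(np.sin(2 * np.pi * 10 * times)[None, None, :])
        tf = morlet_power(ep, freqs=np.arange(8, 13.0))
        mid = (tf.times > -0.5) & (tf.times < 1.0)
        assert np.abs(tf.power_db[0, 0, 2, mid]).max() < 0.5

    def test_amplitude_doubling_db(self, times):
        amp = np.where(times >= 0, 2.0, 1.0)
        ep = make_epochs((amp * np.sin(2 * np.pi * 10 * times))[None, None, :])
        tf = morlet_power(ep, freqs=np.arange(5, 16.0), baseline=(-0.9, -0.5))
        sel = (tf.times > 0.4) & (tf.times < 0.9)
        assert tf.power_db[0, 0, 5, sel].mean() == pytest.approx(10 * np.log10(4), abs=0.3)

    def test_burst_peak_frequency(self, times):
        rng = np.random.default_rng(0)
        burst = np.where((times > 0.2) & (times < 0.6), 3 * np.sin(2 * np.pi * 23 * times), 0.0)
        x = rng.standard_normal((20, 1, times.size)) * 0.5 + burst[None, None, :]
        tf = morlet_power(make_epochs(x), freqs=np.arange(10, 41.0))
        sel = (tf.times > 0.3) & (tf.times < 0.5)
        spec = tf.power_db[:, 0][:, :, sel].mean(axis=(0, 2))
        assert abs(tf.freqs[np.argmax(spec)] - 23) <= 1

    def test_power_flat_in_time(self, times):
        # unit sinusoid: power away from edges has small coefficient of variation
        ep = make_epochs(np.sin(2 * np.pi * 20 * times)[None, None, :])
        tf = morlet_power(ep, freqs=np.array([20.0]))
        mid = (tf.times > -0.6) & (tf.times < 1.1)
        p = 10 ** (tf.power_db[0, 0, 0, mid] / 10)
        assert np.std(p) / np.mean(p) < 0.05

    def test_average_baseline_mode(self, times):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((6, 2, times.size))
        tf = morlet_power(make_epochs(x), freqs=np.array([10.0]), baseline_mode="average")
        # per-trial baselines differ, so dB over baseline need not vanish per
        # trial, but the trial-mean baseline dB should be ~0 in linear power
        bl = (tf.times >= -0.2) & (tf.times <= 0)
        lin = 10 ** (tf.power_db[..., bl] / 10)
        assert lin.mean() == pytest.approx(1.0, abs=0.05)


class TestBandsAndBins:
    def _tf(self, power_db, times):
        return TFPowerArray(
            power_db=power_db, freqs=np.arange(1.0, power_db.shape[2] + 1.0),
            times=times, channels=[f"c{i}" for i in range(power_db.shape[1])],
            cycle_map=np.ones(power_db.shape[2]),
        )

    def test_constant_field(self, times):
        tf = self._tf(np.full((2, 2, 12, times.size), 3.0), times)
        out = band_bin_power(tf, BinGrid(), bands={"alpha": (9, 12)})
        assert np.allclose(out, 3.0)

    def test_alpha_is_mean_of_rows(self, times):
        rng = np.random.default_rng(1)
        p = rng.normal(size=(3, 2, 16, times.size))
        tf = self._tf(p, times)
        grid = BinGrid()
        out = band_bin_power(tf, grid, bands={"alpha": (9, 12)})
        idx = grid.assign(times)
        hand = p[:, :, 8:12, :].mean(axis=2)
        for b in (0, 12, 24):
            assert np.allclose(out[..., 0, b], hand[..., idx == b].mean(axis=-1), atol=1e-12)

    def test_empty_band_errors(self, times):
        tf = self._tf(np.zeros((1, 1, 5, times.size)), times)
        with pytest.raises(ValueError, match="no analysed frequencies"):
            band_bin_power(tf, BinGrid(), bands={"gamma2": (61, 80)})

    def test_bin_then_average_commutes(self, times):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(10, 3, times.size))
        grid = BinGrid()
        binned = bin_erp(make_epochs(x), grid)
        avg_first = bin_erp(make_epochs(x.mean(axis=0, keepdims=True)), grid)
        assert np.allclose(binned.mean(axis=0), avg_first[0], atol=1e-10)

    def test_default_bands_partition_sensibly(self):
        # bands are non-overlapping and exclude the 60 Hz line frequency
        edges = list(DEFAULT_BANDS.values())
        for (l1, h1), (l2, h2) in zip(edges[:-1], edges[1:]):
            assert h1 < l2
        assert all(not (lo <= 60 <= hi) for lo, hi in DEFAULT_BANDS.values())


class TestResponseLock:
    def test_impulse_alignment(self, times):
        rng = np.random.default_rng(4)
        rts = rng.uniform(0.4, 1.0, 8)
        x = np.zeros((8, 1, times.size))
        for i, rt in enumerate(rts):
            x[i, 0, np.argmin(np.abs(times - rt))] = 1.0
        locked, new_t, kept, dropped = response_lock(x, times, rts, FS, window=(-0.3, 0.1))
        assert dropped == 0
        i0 = np.argmin(np.abs(new_t))
        assert np.all(locked[:, 0, i0] == 1.0)

    def test_drop_bookkeeping(self, times):
        rts = np.array([0.5, 1.45, np.nan, 0.8])
        x = np.zeros((4, 1, times.size))
        locked, _, kept, dropped = response_lock(x, times, rts, FS, window=(-0.2, 0.2))
        assert dropped == 2  # nan rt and the rt whose window exceeds the epoch
        assert list(kept) == [0, 3]

    def test_ramp_peaks_at_zero(self, times):
        rng = np.random.default_rng(5)
        rts = rng.uniform(0.5, 1.0, 10)
        x = np.zeros((10, 1, times.size))
        for i, rt in enumerate(rts):
            ramp = np.clip((times - 0.0) / rt, 0, 1)
            ramp[times > rt] = 0
            x[i, 0] = ramp
        locked, new_t, _, _ = response_lock(x, times, rts, FS, window=(-0.4, 0.2))
        m = locked.mean(axis=0)[0]
        assert abs(new_t[np.argmax(m)]) < 2.5 / FS

    def test_all_dropped_errors(self, times):
        with pytest.raises(ValueError, match="all trials dropped"):
            response_lock(np.zeros((2, 1, times.size)), times, np.array([np.nan, np.nan]), FS)


class TestConditionAverage:
    def _tf(self, p, times):
        return TFPowerArray(p, np.arange(1.0, p.shape[2] + 1), times, ["c"], np.ones(p.shape[2]))

    def test_single_trial_identity(self, times):
        rng = np.random.default_rng(6)
        p = rng.normal(size=(3, 1, 4, times.size))
        tf = self._tf(p, times)
        out = condition_average_power(tf, {"a": [True, False, False], "b": [False, True, True]})
        assert np.allclose(out["a"], p[0])
        assert np.allclose(out["b"], p[1:].mean(axis=0))

    def test_masks_must_partition(self, times):
        tf = self._tf(np.zeros((3, 1, 2, times.size)), times)
        with pytest.raises(ValueError, match="partition"):
            condition_average_power(tf, {"a": [True, True, False], "b": [False, True, True]})
        with pytest.raises(ValueError, match="no trials"):
            condition_average_power(tf, {"a": [True, True, True], "b": [False, False, False]})


def test_plotting_smoke(tmp_path, times):
    import matplotlib
    matplotlib.use("Agg")
    from valudyn.plotting import plot_beta_timecourse, plot_power_map
    from valudyn.regression import BetaTimecourse

    tc = BetaTimecourse(
        times=np.linspace(0, 1, 25),
        coefs={"b_tastiness": np.random.default_rng(0).normal(size=25),
               "b_healthiness": np.zeros(25)},
        ses={"b_tastiness": np.full(25, 0.1), "b_healthiness": np.full(25, 0.1)},
    )
    ax = plot_beta_timecourse(tc)
    ax.figure.savefig(tmp_path / "tc.png")
    ax2 = plot_power_map(np.zeros((2, 10, times.size)), times, np.arange(1, 11.0))
    ax2.figure.savefig(tmp_path / "map.png")
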