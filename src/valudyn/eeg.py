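"""Food-locked ERP and time-frequency features.

Epochs (trials x channels x samples) are band-pass filtered, baselined to
the 200 ms pre-stimulus window, and decomposed with complex Morlet wavelets
(1-80 Hz, 3-10 cycles increasing linearly with frequency).  Power is
expressed in dB relative to the pre-stimulus baseline, averaged within six
canonical bands (delta 1-3, theta 4-8, alpha 9-12, beta 13-35, gamma1
36-59, gamma2 61-80 Hz) and within ~49 ms time bins for the mass-univariate
regressions.  Response-locked realignment and condition-average power maps
are provided for descriptive analyses.

Artifact handling (ICA, interpolation, re-referencing) is out of scope:
epochs are assumed clean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from mne.time_frequency import tfr_array_morlet
from scipy import signal as sps

from .regression import BinGrid

__all__ = [
    "EpochArray",
    "TFPowerArray",
    "DEFAULT_BANDS",
    "preprocess_epochs",
    "morlet_power",
    "band_bin_power",
    "bin_erp",
    "response_lock",
    "condition_average_power",
]

logger = logging.getLogger(__name__)

#: canonical frequency bands, Hz, inclusive; gamma2 starts above the 60 Hz
#: line frequency by design
DEFAULT_BANDS = {
    "delta": (1, 3),
    "theta": (4, 8),
    "alpha": (9, 12),
    "beta": (13, 35),
    "gamma1": (36, 59),
    "gamma2": (61, 80),
}

BAND_NAMES = tuple(DEFAULT_BANDS)


@dataclass
class EpochArray:
    """Food-locked epoched EEG: trials x channels x samples, microvolts."""

    data: np.ndarray
    fs: float
    t0: float  # time of the first sample relative to food onset, seconds
    channels: list
    trial_index: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if len(self.channels) != self.data.shape[1]:
            raise ValueError("channel labels must match the channel axis")
        if self.trial_index is None:
            self.trial_index = np.arange(self.data.shape[0])
        self.trial_index = np.asarray(self.trial_index)
        if self.trial_index.size != self.data.shape[0]:
            raise ValueError("trial index must match the trial axis")
        if self.trial_index.size != np.unique(self.trial_index).size:
            raise ValueError("trial alignment must be bijective")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.shape[2]) / self.fs

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class TFPowerArray:
    """Time-frequency power in dB re pre-stimulus baseline:
    trials x channels x frequencies x samples."""

    power_db: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channels: list
    cycle_map: np.ndarray
    edge_mask: np.ndarray | None = None  # freqs x samples; True where edge-contaminated

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if not np.all(np.isfinite(self.power_db)):
            raise ValueError("non-finite dB power")


def default_cycle_map(freqs) -> np.ndarray:
    """Cycles per wavelet: linear from 3 at 1 Hz to 10 at 80 Hz."""
    f = np.asarray(freqs, float)
    return 3.0 + 7.0 * (f - 1.0) / 79.0


def preprocess_epochs(
    epochs: EpochArray,
    l_freq: float = 0.5,
    h_freq: float = 100.0,
    notch: float | None = 60.0,
    notch_width: float = 2.0,
    baseline=(-0.200, 0.0),
    order: int = 4,
) -> EpochArray:
    """Zero-phase band-pass + notch filtering and pre-stimulus baselining.

    Band-pass is a 4th-order Butterworth applied forward-backward; the
    notch is an IIR notch of the given width.  The per-trial, per-channel
    mean over the baseline interval is subtracted.
    """
    fs = epochs.fs
    if fs < 2 * h_freq:
        raise ValueError(f"sampling rate {fs} Hz too low for a {h_freq} Hz low-pass")
    x = epochs.data
    sos = sps.butter(order, [l_freq, h_freq], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x, axis=-1)
    if notch is not None and notch < fs / 2:
        b, a = sps.iirnotch(notch, notch / notch_width, fs=fs)
        y = sps.filtfilt(b, a, y, axis=-1)
    times = epochs.times
    bl = (times >= baseline[0]) & (times <= baseline[1])
    if not bl.any():
        raise ValueError("epoch window does not cover the baseline interval")
    y = y - y[..., bl].mean(axis=-1, keepdims=True)
    return EpochArray(y, fs, epochs.t0, list(epochs.channels), epochs.trial_index.copy())


def morlet_power(
    epochs: EpochArray,
    freqs=None,
    cycle_map=None,
    baseline=(-0.200, 0.0),
    baseline_mode: str = "per_trial",
    decim: int = 1,
) -> TFPowerArray:
    """Complex Morlet decomposition with dB normalisation.

    Power is ``10 * log10(A_t / A_baseline)`` where the baseline is the mean
    power over the pre-stimulus interval, per trial (default) or averaged
    over trials (``baseline_mode='average'``).  Epochs are
    reflection-padded so low-frequency wavelets fit, and samples inside a
    wavelet half-length of the (unpadded) epoch edges are flagged.
    """
    if freqs is None:
        freqs = np.arange(1.0, 81.0)
    freqs = np.asarray(freqs, float)
    n_cycles = default_cycle_map(freqs) if cycle_map is None else np.asarray(cycle_map, float)
    fs = epochs.fs
    n_samp = epochs.data.shape[2]
    # pad so the longest wavelet fits inside the signal (wavelets span
    # +/- 5 sigma_t with sigma_t = n_cycles / (2 pi f))
    max_len = int(np.ceil((10.0 * n_cycles / (2.0 * np.pi * freqs)).max() * fs)) + 2
    pad = max(0, (max_len - n_samp) // 2 + 1)
    data = np.pad(epochs.data, ((0, 0), (0, 0), (pad, pad)), mode="reflect")
    power = tfr_array_morlet(
        data, sfreq=fs, freqs=freqs, n_cycles=n_cycles, output="power", zero_mean=True, decim=1
    )
    if pad:
        power = power[..., pad:-pad]
    times = epochs.times
    bl = (times >= baseline[0]) & (times <= baseline[1])
    if not bl.any():
        raise ValueError("epoch window does not cover the baseline interval")
    base = power[..., bl].mean(axis=-1, keepdims=True)
    if baseline_mode == "average":
        base = base.mean(axis=0, keepdims=True)
    elif baseline_mode != "per_trial":
        raise ValueError("baseline_mode must be 'per_trial' or 'average'")
    power_db = 10.0 * np.log10(np.maximum(power, 1e-300) / np.maximum(base, 1e-300))
    half_len = n_cycles / (2.0 * freqs)
    edge = (times[None, :] < times[0] + half_len[:, None]) | (times[None, :] > times[-1] - half_len[:, None])
    if decim > 1:
        power_db = power_db[..., ::decim]
        times = times[::decim]
        edge = edge[:, ::decim]
    return TFPowerArray(
        power_db=power_db,
        freqs=freqs,
        times=times,
        channels=list(epochs.channels),
        cycle_map=n_cycles,
        edge_mask=edge,
    )


def band_bin_power(tf: TFPowerArray, grid: BinGrid, bands: dict | None = None, warn_edges: bool = True) -> np.ndarray:
    """Average dB power over in-band frequencies, then over in-bin samples.

    Returns trials x channels x bands x bins.  Band membership is
    inclusive of both band edges.
    """
    bands = DEFAULT_BANDS if bands is None else bands
    bin_idx = grid.assign(tf.times)
    if np.all(bin_idx < 0):
        raise ValueError("bin grid outside the epoch window")
    n_tr, n_ch = tf.power_db.shape[:2]
    out = np.empty((n_tr, n_ch, len(bands), grid.n_bins))
    for bi, (name, (lo, hi)) in enumerate(bands.items()):
        fm = (tf.freqs >= lo) & (tf.freqs <= hi)
        if not fm.any():
            raise ValueError(f"band {name} contains no analysed frequencies")
        band_pow = tf.power_db[:, :, fm, :].mean(axis=2)
        if warn_edges and tf.edge_mask is not None:
            contaminated = tf.edge_mask[fm][:, bin_idx >= 0].any()
            if contaminated:
                logger.warning("band %s: some in-grid samples are inside the wavelet edge region", name)
        for b in range(grid.n_bins):
            sm = bin_idx == b
            if not sm.any():
                raise ValueError(f"bin {b} contains no samples")
            out[:, :, bi, b] = band_pow[:, :, sm].mean(axis=-1)
    return out


def band_bin_features(
    epochs: EpochArray,
    grid: BinGrid,
    freqs=None,
    bands: dict | None = None,
    baseline=(-0.200, 0.0),
    chunk: int = 8,
    warn_edges: bool = True,
) -> np.ndarray:
    """Memory-bounded band-power bins: trials x channels x bands x bins.

    Runs the Morlet decomposition on small trial chunks and reduces each to
    band x bin means immediately, so the full trials x channels x
    frequencies x samples power array is never materialised.
    """
    bands = DEFAULT_BANDS if bands is None else bands
    n_tr = epochs.n_trials
    parts = []
    for i0 in range(0, n_tr, chunk):
        sl = slice(i0, min(i0 + chunk, n_tr))
        sub = EpochArray(epochs.data[sl], epochs.fs, epochs.t0, list(epochs.channels), epochs.trial_index[sl])
        tf = morlet_power(sub, freqs=freqs, baseline=baseline)
        parts.append(band_bin_power(tf, grid, bands=bands, warn_edges=warn_edges and i0 == 0))
    return np.concatenate(parts, axis=0)


def bin_erp(epochs: EpochArray, grid: BinGrid) -> np.ndarray:
    """Average raw amplitude per ~49 ms bin: trials x channels x bins."""
    bin_idx = grid.assign(epochs.times)
    out = np.empty((epochs.data.shape[0], epochs.data.shape[1], grid.n_bins))
    for b in range(grid.n_bins):
        sm = bin_idx == b
        if not sm.any():
            raise ValueError(f"bin {b} contains no samples")
        out[:, :, b] = epochs.data[:, :, sm].mean(axis=-1)
    return out


def response_lock(array: np.ndarray, times: np.ndarray, rts, fs: float, window=(-0.5, 0.2)):
    """Realign trials so t = 0 is the response sample.

    ``array`` is trials x channels x (freqs x) samples on ``times``
    (food-locked).  Trials whose realigned window exceeds the epoch are
    dropped and counted.  Returns (realigned, new_times, kept_idx,
    n_dropped).
    """
    array = np.asarray(array)
    times = np.asarray(times, float)
    rts = np.asarray(rts, float)
    if rts.size != array.shape[0]:
        raise ValueError("one RT per trial required")
    w0 = int(round(window[0] * fs))
    w1 = int(round(window[1] * fs))
    offs = np.arange(w0, w1 + 1)
    kept, chunks = [], []
    for i, rt in enumerate(rts):
        if not np.isfinite(rt):
            continue
        c = int(np.argmin(np.abs(times - rt)))
        if c + w0 < 0 or c + w1 >= times.size:
            continue
        kept.append(i)
        chunks.append(array[i, ..., c + w0 : c + w1 + 1])
    if not kept:
        raise ValueError("all trials dropped in response locking")
    return np.stack(chunks), offs / fs, np.array(kept), int(rts.size - len(kept))


def condition_average_power(tf: TFPowerArray, trial_masks: dict) -> dict:
    """Mean dB map per condition: channels x frequencies x samples.

    ``trial_masks`` must partition the trials (disjoint and exhaustive).
    """
    n = tf.power_db.shape[0]
    total = np.zeros(n, dtype=int)
    for name, m in trial_masks.items():
        m = np.asarray(m, bool)
        if m.size != n:
            raise ValueError(f"mask {name} has wrong length")
        if not m.any():
            raise ValueError(f"mask {name} selects no trials")
        total += m
    if np.any(total != 1):
        raise ValueError("masks must partition the trials")
    return {name: tf.power_db[np.asarray(m, bool)].mean(axis=0) for name, m in trial_masks.items()}
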