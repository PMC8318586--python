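"""Simple diagnostic plots: coefficient time courses and power maps."""

from __future__ import annotations

import numpy as np

from .regression import BetaTimecourse


def plot_beta_timecourse(beta_tc: BetaTimecourse, coefficients=("b_tastiness", "b_healthiness"), ax=None):
    """Coefficient course(s) with +/-1 SE bands versus time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name in coefficients:
        b = np.asarray(beta_tc[name])
        se = np.asarray(beta_tc.ses[name])
        ax.plot(beta_tc.times, b, label=name)
        ax.fill_between(beta_tc.times, b - se, b + se, alpha=0.25)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.axvline(0.0, color="k", lw=0.5, ls="--")
    ax.set_xlabel("time re food onset (s)")
    ax.set_ylabel("coefficient")
    ax.legend()
    return ax


def plot_power_map(power_db: np.ndarray, times, freqs, ax=None, vlim=None):
    """Channel-averaged time-frequency map in dB."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    power_db = np.asarray(power_db)
    if power_db.ndim == 3:  # channels x freqs x samples
        power_db = power_db.mean(axis=0)
    v = vlim if vlim is not None else np.nanmax(np.abs(power_db))
    im = ax.pcolormesh(times, freqs, power_db, cmap="RdBu_r", vmin=-v, vmax=v, shading="auto")
    ax.set_xlabel("time re food onset (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.figure.colorbar(im, ax=ax, label="power (dB re baseline)")
    return ax
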