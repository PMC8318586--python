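"""Model-simulated neural time courses: attribute construction and evidence
accumulation.

From a fitted parameter set, each trial yields three predicted signals on a
millisecond grid locked to food onset:

* taste-AC / health-AC: boxcars whose support starts at the end of the
  perceptual part of the non-decision time (ndt minus an 80 ms motor
  preparation constant) and ends at the response, with height equal to the
  coded attribute value;
* EA: the evidence path relative to its starting point over the same
  support, held at the absorbing boundary through the motor window.

Because each simulation is stochastic, the per-trial signals are averaged
over many simulated datasets (1000 by default).  A per-timepoint regression
of the averaged signals on coded tastiness, coded healthiness and mean
simulated RT gives the model-predicted coefficient time courses whose peak
latencies order the attribute-construction and accumulation stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ddm import DDMParameters
from .regression import BetaTimecourse, mass_ols, COEF_NAMES

__all__ = [
    "SignalConfig",
    "TrialSignalEnsemble",
    "build_trial_signals",
    "ensemble_average_signals",
    "model1_timecourses",
    "peak_latency",
    "compare_peak_latencies",
]

SIGNAL_NAMES = ("taste_ac", "health_ac", "ea")


@dataclass(frozen=True)
class SignalConfig:
    """Geometry and ensemble size of the simulated signals.

    ``motor_prep`` is the 80 ms motor-preparation constant subtracted from
    the non-decision time to place the signal onset; ``n_datasets`` the
    number of simulated datasets averaged per trial.
    """

    grid_dt: float = 0.001
    grid_end: float = 2.0
    motor_prep: float = 0.080
    n_datasets: int = 1000
    ac_noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.grid_dt <= 0 or self.motor_prep < 0 or self.n_datasets < 1:
            raise ValueError("invalid signal configuration")

    @property
    def times(self) -> np.ndarray:
        return np.arange(0.0, self.grid_end + self.grid_dt / 2, self.grid_dt)


@dataclass
class TrialSignalEnsemble:
    """Per-trial ensemble-averaged taste-AC / health-AC / EA signals."""

    times: np.ndarray
    taste_ac: np.ndarray  # trials x time
    health_ac: np.ndarray
    ea: np.ndarray
    mean_sim_rt: np.ndarray  # per trial, seconds
    n_datasets: int

    def signal(self, name: str) -> np.ndarray:
        if name not in SIGNAL_NAMES:
            raise KeyError(name)
        return getattr(self, name)


def _simulate_signal_batch(params, taste_c, health_c, config, rng, n_datasets, collect_per_dataset=False):
    """Core vectorised simulation of signal ensembles.

    Simulates ``n_datasets`` independent DDM trials per input trial on the
    signal grid and accumulates the three signals.  The evidence path is
    clipped at the boundaries, held at the absorbing boundary through the
    motor window, and zero outside [onset, rt].
    """
    taste_c = np.atleast_1d(np.asarray(taste_c, float))
    health_c = np.atleast_1d(np.asarray(health_c, float))
    n_trials = taste_c.size
    dt = config.grid_dt
    T = config.times.size
    a, z, ndt = params.threshold, params.sp_bias, params.ndt
    onset = max(0.0, ndt - config.motor_prep)
    i0 = int(round(onset / dt))
    ms = int(round(min(config.motor_prep, ndt) / dt))
    T_sim = max(T - i0 - 1, 1)
    up_bar, lo_bar = a * (1.0 - z), -a * z
    drift = params.drift(taste_c, health_c)

    sum_ea = np.zeros((n_trials, T))
    sum_active = np.zeros((n_trials, T))
    sum_ac_noise = None
    if config.ac_noise_sd > 0:
        sum_ac_noise = np.zeros((n_trials, T))
    sum_rt = np.zeros(n_trials)

    batch = max(1, min(n_datasets, int(4e6 // (n_trials * T_sim)) or 1))
    done = 0
    jj = np.arange(T_sim + 1)
    while done < n_datasets:
        B = min(batch, n_datasets - done)
        P = B * n_trials
        inc = rng.standard_normal((P, T_sim), dtype=np.float32) * np.float32(np.sqrt(dt))
        inc += np.tile(drift, B)[:, None].astype(np.float32) * np.float32(dt)
        path = np.cumsum(inc, axis=1, dtype=np.float32)
        hit = (path >= up_bar) | (path <= lo_bar)
        crossed = hit.any(axis=1)
        k = np.where(crossed, np.argmax(hit, axis=1), T_sim - 1)  # censored at grid end
        bound = np.where(path[np.arange(P), k] >= up_bar, up_bar, lo_bar).astype(np.float32)
        pathz = np.concatenate([np.zeros((P, 1), np.float32), np.clip(path, lo_bar, up_bar)], axis=1)
        # grid col i0 + j: evidence after j accumulation steps, then the
        # boundary value for the motor window, then 0
        in_path = jj[None, :] <= (k + 1)[:, None]
        in_motor = (jj[None, :] > (k + 1)[:, None]) & (jj[None, :] <= (k + 1 + ms)[:, None])
        active = np.where(crossed[:, None], in_path | in_motor, np.ones_like(in_path))
        ea = np.where(in_path, pathz, 0.0) + np.where(crossed[:, None] & in_motor, bound[:, None], 0.0)

        ea_r = ea.reshape(B, n_trials, T_sim + 1).sum(axis=0)
        act_r = active.reshape(B, n_trials, T_sim + 1).sum(axis=0)
        sum_ea[:, i0 : i0 + T_sim + 1] += ea_r
        sum_active[:, i0 : i0 + T_sim + 1] += act_r
        if sum_ac_noise is not None:
            noise = rng.standard_normal((P, T_sim + 1), dtype=np.float32) * np.float32(config.ac_noise_sd)
            sum_ac_noise[:, i0 : i0 + T_sim + 1] += (noise * active).reshape(B, n_trials, T_sim + 1).sum(axis=0)
        rt = ndt + (k + 1) * dt
        sum_rt += rt.reshape(B, n_trials).sum(axis=0)
        done += B

    frac = sum_active / n_datasets
    taste_ac = taste_c[:, None] * frac
    health_ac = health_c[:, None] * frac
    if sum_ac_noise is not None:
        taste_ac = taste_ac + sum_ac_noise / n_datasets
        health_ac = health_ac + sum_ac_noise / n_datasets
    ea_mean = sum_ea / n_datasets
    # enforce exact zeros outside the possible support
    for arr in (taste_ac, health_ac, ea_mean):
        arr[:, :i0] = 0.0
    return taste_ac, health_ac, ea_mean, sum_rt / n_datasets


def build_trial_signals(params: DDMParameters, tastiness_coded: float, healthiness_coded: float, config: SignalConfig, rng=None, max_retries: int = 20):
    """One simulated trial's signals on the grid plus its simulated RT.

    Trials that fail to reach a boundary before the grid end are
    re-simulated up to ``max_retries`` times, then flagged (rt = NaN).
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    for attempt in range(max_retries + 1):
        t_ac, h_ac, ea, rt = _simulate_signal_batch(
            params, [tastiness_coded], [healthiness_coded], config, rng, n_datasets=1
        )
        # censored simulations sit at the grid end; accept crossings only
        if rt[0] < params.ndt + (config.times.size - int(round(max(0.0, params.ndt - config.motor_prep) / config.grid_dt)) - 1) * config.grid_dt - 1e-12:
            return {
                "times": config.times,
                "taste_ac": t_ac[0],
                "health_ac": h_ac[0],
                "ea": ea[0],
                "rt": float(rt[0]),
            }
    return {"times": config.times, "taste_ac": t_ac[0], "health_ac": h_ac[0], "ea": ea[0], "rt": float("nan")}


def ensemble_average_signals(params: DDMParameters, tastiness_coded, healthiness_coded, config: SignalConfig, rng=None) -> TrialSignalEnsemble:
    """Per-trial signals averaged pointwise over ``config.n_datasets``
    independent simulations; deterministic given ``config.rng_seed``."""
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    t_ac, h_ac, ea, mean_rt = _simulate_signal_batch(
        params, tastiness_coded, healthiness_coded, config, rng, config.n_datasets
    )
    return TrialSignalEnsemble(
        times=config.times,
        taste_ac=t_ac,
        health_ac=h_ac,
        ea=ea,
        mean_sim_rt=mean_rt,
        n_datasets=config.n_datasets,
    )


def model1_timecourses(ensemble: TrialSignalEnsemble, tastiness_coded, healthiness_coded) -> dict:
    """Per-timepoint regression of each averaged signal on coded attributes
    and mean simulated RT (with intercept); one BetaTimecourse per signal."""
    t_c = np.asarray(tastiness_coded, float)
    h_c = np.asarray(healthiness_coded, float)
    n = t_c.size
    if n < 10:
        raise ValueError("need at least 10 trials")
    X = np.column_stack([np.ones(n), t_c, h_c, ensemble.mean_sim_rt])
    if np.linalg.cond(X.T @ X) > 1e12:
        raise ValueError("collinear predictors in the signal regression (tastiness/healthiness/rt)")
    out = {}
    for name in SIGNAL_NAMES:
        beta, se, _, _ = mass_ols(ensemble.signal(name), X)
        out[name] = BetaTimecourse(
            times=ensemble.times,
            coefs={c: beta[i] for i, c in enumerate(COEF_NAMES)},
            ses={c: se[i] for i, c in enumerate(COEF_NAMES)},
            meta={"signal": name},
        )
    return out


def peak_latency(beta_tc: BetaTimecourse, coefficient: str, window=(0.0, 2.0), sign_mode: str = "abs") -> float:
    """Latency (s) of the coefficient extremum inside the window.

    ``sign_mode``: 'max' (largest value), 'min' (smallest), or 'abs'
    (largest magnitude, default).  Ties resolve to the earliest sample.
    """
    times = np.asarray(beta_tc.times)
    vals = np.asarray(beta_tc[coefficient], float)
    m = (times >= window[0]) & (times <= window[1])
    if not m.any():
        raise ValueError("window outside the grid")
    v = vals[m]
    if np.all(np.isnan(v)):
        raise ValueError("all-NaN coefficient series in window")
    if sign_mode == "abs":
        v = np.abs(v)
    elif sign_mode == "min":
        v = -v
    elif sign_mode != "max":
        raise ValueError("sign_mode must be max, min or abs")
    return float(times[m][np.nanargmax(v)])


def compare_peak_latencies(subject_betas_a, subject_betas_b, coefficient: str, window=(0.0, 2.0), sign_mode: str = "abs"):
    """Paired two-sided t-test of per-subject peak latencies between two
    signal templates (e.g. taste-AC vs taste-EA)."""
    if len(subject_betas_a) != len(subject_betas_b):
        raise ValueError("same subjects required in both sets")
    if len(subject_betas_a) < 3:
        raise ValueError("need at least 3 subjects")
    lat_a = np.array([peak_latency(b, coefficient, window, sign_mode) for b in subject_betas_a])
    lat_b = np.array([peak_latency(b, coefficient, window, sign_mode) for b in subject_betas_b])
    diff = lat_a - lat_b
    if np.ptp(diff) < 1e-15:
        t, p = (0.0, 1.0) if np.allclose(diff, 0) else (np.inf * np.sign(diff.mean()), np.finfo(float).tiny)
    else:
        t, p = stats.ttest_rel(lat_a, lat_b)
    return {
        "t": float(t),
        "df": len(lat_a) - 1,
        "p": float(p),
        "latencies_a": lat_a,
        "latencies_b": lat_b,
    }
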