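"""Multi-attribute drift-diffusion model of dietary choice.

The decision on each trial is modelled as a Wiener diffusion with unit
diffusion coefficient between an absorbing lower boundary at 0 (reject) and
an upper boundary at ``threshold`` (accept), starting from
``sp_bias * threshold``.  The drift rate on a trial is a linear function of
the food's attribute ratings::

    drift = w_tastiness * tastiness + w_healthiness * healthiness + val_const

Response time is the first-passage time plus a non-decision time ``ndt``
(perceptual encoding plus motor execution).  Six free parameters per
subject and condition: two attribute weights, the value constant, the
boundary separation, the relative starting point, and the non-decision time.

Fitting is per-subject x condition maximum likelihood with multi-start
bounded optimisation over the exact Wiener first-passage-time density
(small-time / large-time series with an accuracy-based switching rule).
An optional random-walk Metropolis hierarchical sampler with group-normal
priors is provided for fidelity experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CONDITIONS",
    "DDMParameters",
    "FitResult",
    "absorption_probability",
    "wiener_fpt_density",
    "simulate_trial",
    "simulate_trials",
    "code_attributes",
    "negative_log_likelihood",
    "fit_subject_condition",
    "DriftDiffusionModel",
    "DDMResults",
    "fit_cohort",
    "posterior_predictive_check",
    "behaviour_summary",
    "HierarchicalDDM",
]

CONDITIONS = ("NATURAL", "HEALTH", "DECREASE")

#: parameter order used by the optimiser
PARAM_NAMES = ("w_tastiness", "w_healthiness", "val_const", "threshold", "sp_bias", "ndt")

#: decision-time floor used by the likelihood (seconds)
RT_EPS = 1e-4


@dataclass(frozen=True)
class DDMParameters:
    """Decision-model parameters for one subject x condition.

    ``threshold`` is the boundary separation ``a`` (evidence units),
    ``sp_bias`` the relative starting point ``z`` in (0, 1), ``ndt`` the
    non-decision time in seconds.
    """

    w_tastiness: float
    w_healthiness: float
    val_const: float
    threshold: float
    sp_bias: float
    ndt: float

    def __post_init__(self) -> None:
        vals = asdict(self)
        for k, v in vals.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite parameter {k}={v}")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if not 0 < self.sp_bias < 1:
            raise ValueError("sp_bias must lie in (0, 1)")
        if self.ndt < 0:
            raise ValueError("ndt must be >= 0")

    def drift(self, tastiness_coded, healthiness_coded):
        """Trial drift rate from coded attribute values."""
        return (
            self.w_tastiness * np.asarray(tastiness_coded)
            + self.w_healthiness * np.asarray(healthiness_coded)
            + self.val_const
        )

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES])

    @classmethod
    def from_array(cls, x) -> "DDMParameters":
        return cls(**dict(zip(PARAM_NAMES, np.asarray(x, float))))


@dataclass
class FitResult:
    """Outcome of one subject x condition maximum-likelihood fit."""

    params: DDMParameters
    nll: float
    n_trials_used: int
    converged: bool
    excluded_no_response: int
    message: str = ""

    def to_dict(self) -> dict:
        d = asdict(self.params)
        d.update(
            nll=self.nll,
            n_trials_used=self.n_trials_used,
            converged=self.converged,
            excluded_no_response=self.excluded_no_response,
        )
        return d


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def absorption_probability(threshold: float, sp_bias: float, drift: float) -> float:
    """Probability that the diffusion is absorbed at the upper (accept) boundary.

    Standard scale-function result for a Wiener process with unit diffusion,
    boundaries at 0 and ``threshold`` and start at ``sp_bias * threshold``;
    continuous at drift = 0 where it equals ``sp_bias``.
    """
    a, z, v = float(threshold), float(sp_bias), float(drift)
    if not (np.isfinite(a) and np.isfinite(z) and np.isfinite(v)):
        raise ValueError("non-finite input to absorption_probability")
    if a <= 0 or not 0 < z < 1:
        raise ValueError("require threshold > 0 and 0 < sp_bias < 1")
    x = 2.0 * v * a
    if abs(x) < 1e-9:
        # first-order expansion around v = 0
        return z + 0.5 * x * z * (1.0 - z)
    if x > 700:  # strong positive drift: exp underflow territory
        return 1.0 - math.exp(-x * z) if x * z < 700 else 1.0
    if x < -700:
        return math.exp(x * (1.0 - z))
    return math.expm1(-x * z) / math.expm1(-x)


def _f0_lower(tt: np.ndarray, w: float, err: float = 1e-7) -> np.ndarray:
    """Density of first passage through 0 for a zero-drift unit-boundary Wiener
    process started at relative position ``w``, at normalised times ``tt``.

    Evaluates whichever of the small-time and large-time series needs fewer
    terms for accuracy ``err`` at each time point.
    """
    tt = np.asarray(tt, float)
    out = np.empty_like(tt)
    pos = tt > 0
    t = tt[pos]

    with np.errstate(divide="ignore", invalid="ignore"):
        arg = 2.0 * np.sqrt(2.0 * np.pi * t) * err
        ks = np.where(arg < 1, 2.0 + np.sqrt(np.maximum(-2.0 * t * np.log(arg), 0.0)) / np.sqrt(t), 2.0)
        ks = np.maximum(ks, np.sqrt(t) + 1.0)
        argl = np.pi * t * err
        kl = np.where(
            argl < 1,
            np.sqrt(np.maximum(-2.0 * np.log(argl), 0.0) / (np.pi**2 * t)),
            0.0,
        )
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(t)))

    use_small = ks < kl
    res = np.zeros_like(t)

    if np.any(use_small):
        ts = t[use_small]
        K = int(np.ceil(ks[use_small].max()))
        ks_range = np.arange(-((K - 1) // 2), ((K - 1) // 2) + K % 2 + 1)
        terms = (w + 2.0 * ks_range[:, None]) * np.exp(
            -((w + 2.0 * ks_range[:, None]) ** 2) / (2.0 * ts[None, :])
        )
        res[use_small] = terms.sum(axis=0) / np.sqrt(2.0 * np.pi * ts**3)

    if np.any(~use_small):
        tl = t[~use_small]
        K = int(np.ceil(kl[~use_small].max()))
        k = np.arange(1, K + 1)
        terms = k[:, None] * np.exp(-(k[:, None] ** 2) * np.pi**2 * tl[None, :] / 2.0) * np.sin(
            k[:, None] * np.pi * w
        )
        res[~use_small] = np.pi * terms.sum(axis=0)

    out[pos] = np.maximum(res, 0.0)
    out[~pos] = np.nan
    return out


def wiener_fpt_density(t, threshold: float, sp_bias: float, drift: float, boundary: str = "upper"):
    """First-passage-time density (per second) at the named boundary.

    ``t`` is decision time (RT minus non-decision time); the caller handles
    the ndt shift.  Scalar or array ``t``; ``t <= 0`` raises.
    """
    a, z, v = float(threshold), float(sp_bias), float(drift)
    if a <= 0 or not 0 < z < 1:
        raise ValueError("require threshold > 0 and 0 < sp_bias < 1")
    t_arr = np.atleast_1d(np.asarray(t, float))
    if np.any(t_arr <= 0):
        raise ValueError("decision time must be > 0")
    if boundary == "upper":
        w, vv = 1.0 - z, -v
    elif boundary == "lower":
        w, vv = z, v
    else:
        raise ValueError("boundary must be 'upper' or 'lower'")
    tt = t_arr / a**2
    f0 = _f0_lower(tt, w)
    # exponential tilt for drift; clip the exponent to avoid spurious overflow
    expo = np.clip(-vv * a * w - vv**2 * t_arr / 2.0, -745.0, 700.0)
    dens = f0 / a**2 * np.exp(expo)
    return dens if np.ndim(t) else float(dens[0])


def _wfpt_density_trials(t: np.ndarray, a: float, z: float, v: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Vectorised density across trials with per-trial drift and boundary."""
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    upper = np.asarray(upper, bool)
    w = np.where(upper, 1.0 - z, z)
    vv = np.where(upper, -v, v)
    # _f0_lower depends on w, which takes two values; evaluate each group
    out = np.empty_like(t)
    for wu in (True, False):
        m = upper == wu
        if not np.any(m):
            continue
        out[m] = _f0_lower(t[m] / a**2, float(w[m][0]))
    expo = np.clip(-vv * a * w - vv**2 * t / 2.0, -745.0, 700.0)
    return out / a**2 * np.exp(expo)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_trials(
    params: DDMParameters,
    tastiness_coded,
    healthiness_coded,
    dt: float = 0.001,
    horizon: float = 10.0,
    rng: np.random.Generator | None = None,
):
    """Euler-Maruyama simulation of many trials at once.

    Returns ``(choice, rt)`` arrays; ``choice`` is +1 (accept), -1 (reject)
    or 0 when no boundary is crossed within ``horizon`` seconds of
    accumulation (rt is then NaN).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = np.random.default_rng() if rng is None else rng
    drift = np.atleast_1d(params.drift(tastiness_coded, healthiness_coded)).astype(float)
    n = drift.size
    n_steps = int(np.ceil(horizon / dt))
    a, z = params.threshold, params.sp_bias
    up_bar, lo_bar = a * (1.0 - z), -a * z  # relative to start

    choice = np.zeros(n, dtype=int)
    rt = np.full(n, np.nan)
    active = np.arange(n)
    state = np.zeros(n)
    block = max(1, min(n_steps, int(2e7 // max(n, 1)) or 1))
    done_steps = 0
    while active.size and done_steps < n_steps:
        m = min(block, n_steps - done_steps)
        inc = rng.standard_normal((active.size, m), dtype=np.float32) * np.float32(np.sqrt(dt))
        inc += (drift[active, None] * dt).astype(np.float32)
        path = state[active, None].astype(np.float32) + np.cumsum(inc, axis=1, dtype=np.float32)
        prev = np.concatenate([state[active, None].astype(np.float32), path[:, :-1]], axis=1)
        # exact within-step crossing via the Brownian-bridge first-passage
        # probability; removes the Euler discretisation bias in the
        # absorption probability (endpoint-crossed steps have p = 1)
        hit_up = path >= up_bar
        hit_dn = path <= lo_bar
        e_up = np.maximum(up_bar - prev, 0.0) * np.maximum(up_bar - path, 0.0)
        e_dn = np.maximum(prev - lo_bar, 0.0) * np.maximum(path - lo_bar, 0.0)
        cu = np.nonzero(~hit_up & (e_up < 15.0 * dt / 2.0))
        hit_up[cu] = rng.random(cu[0].size) < np.exp(-2.0 * e_up[cu] / dt)
        cd = np.nonzero(~hit_dn & (e_dn < 15.0 * dt / 2.0))
        hit_dn[cd] = rng.random(cd[0].size) < np.exp(-2.0 * e_dn[cd] / dt)
        hit = hit_up | hit_dn
        crossed = hit.any(axis=1)
        first = np.argmax(hit, axis=1)
        idx = active[crossed]
        fu = hit_up[crossed, first[crossed]]
        fd = hit_dn[crossed, first[crossed]]
        both = fu & fd  # both bridges fired in one step: break by proximity
        sign = np.where(fu, 1, -1)
        if np.any(both):
            mid = 0.5 * (prev[crossed, first[crossed]] + path[crossed, first[crossed]])
            sign[both] = np.where(mid[both] > (up_bar + lo_bar) / 2.0, 1, -1)
        choice[idx] = sign
        rt[idx] = (done_steps + first[crossed] + 1) * dt + params.ndt
        state[active] = path[:, -1]
        active = active[~crossed]
        done_steps += m
    return choice, rt


def simulate_trial(
    params: DDMParameters,
    tastiness_coded: float,
    healthiness_coded: float,
    dt: float = 0.001,
    rng: np.random.Generator | None = None,
    keep_trajectory: bool = False,
    horizon: float = 10.0,
):
    """Simulate one trial; optionally return the evidence trajectory.

    The trajectory is the evidence path relative to the starting point,
    sampled at ``dt``, truncated at the first boundary crossing.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = np.random.default_rng() if rng is None else rng
    drift = float(params.drift(tastiness_coded, healthiness_coded))
    a, z = params.threshold, params.sp_bias
    up_bar, lo_bar = a * (1.0 - z), -a * z
    n_steps = int(np.ceil(horizon / dt))
    inc = drift * dt + rng.standard_normal(n_steps) * np.sqrt(dt)
    path = np.cumsum(inc)
    hit = (path >= up_bar) | (path <= lo_bar)
    if not hit.any():
        return (0, np.nan, path if keep_trajectory else None)
    k = int(np.argmax(hit))
    choice = 1 if path[k] >= up_bar else -1
    rt = (k + 1) * dt + params.ndt
    return (choice, rt, path[: k + 1] if keep_trajectory else None)


# ---------------------------------------------------------------------------
# coding, likelihood, fitting
# ---------------------------------------------------------------------------

def code_attributes(tastiness, healthiness, centred: bool = True):
    """Code ratings before they enter the drift / regressions.

    Default mean-centres each attribute within the supplied trial set
    (one subject x condition); raw 1-6 coding with ``centred=False``.
    """
    t = np.asarray(tastiness, float)
    h = np.asarray(healthiness, float)
    if centred:
        return t - t.mean(), h - h.mean()
    return t, h


def negative_log_likelihood(params: DDMParameters, tastiness_coded, healthiness_coded, rt, choice) -> float:
    """Negative log-likelihood of observed (choice, rt) pairs.

    ``choice`` is +1 accept / -1 reject (no-response trials must be removed
    by the caller).  Decision times ``rt - ndt`` are floored at 1e-4 s so
    that trials faster than the non-decision time contribute a finite
    penalty through the floored density rather than NaN.
    """
    rt = np.asarray(rt, float)
    choice = np.asarray(choice)
    if np.any(choice == 0):
        raise ValueError("no-response trials must be excluded before the likelihood")
    v = params.drift(tastiness_coded, healthiness_coded)
    td = np.maximum(rt - params.ndt, RT_EPS)
    dens = _wfpt_density_trials(td, params.threshold, params.sp_bias, np.broadcast_to(v, rt.shape), choice > 0)
    return float(-np.sum(np.log(np.maximum(dens, 1e-300))))


DEFAULT_BOUNDS = {
    "w_tastiness": (-5.0, 5.0),
    "w_healthiness": (-5.0, 5.0),
    "val_const": (-5.0, 5.0),
    "threshold": (0.1, 6.0),
    "sp_bias": (0.05, 0.95),
}


def fit_subject_condition(
    tastiness_coded,
    healthiness_coded,
    rt,
    choice,
    n_starts: int = 8,
    seed: int | None = None,
    min_trials: int = 40,
    bounds: dict | None = None,
) -> FitResult:
    """Multi-start bounded maximum-likelihood fit of the six parameters.

    No-response trials (``choice == 0``) are excluded and counted.  The ndt
    upper bound is the fastest usable RT minus a small margin.
    """
    rt = np.asarray(rt, float)
    choice = np.asarray(choice, int)
    usable = choice != 0
    excluded = int((~usable).sum())
    t_c = np.asarray(tastiness_coded, float)[usable]
    h_c = np.asarray(healthiness_coded, float)[usable]
    rt_u, ch_u = rt[usable], choice[usable]
    n = rt_u.size
    if n == 0:
        raise ValueError("no usable trials")
    if n < min_trials:
        raise ValueError(f"too few usable trials ({n} < {min_trials})")
    if np.all(ch_u == ch_u[0]) and np.std(rt_u) < 1e-6:
        return FitResult(
            params=DDMParameters(0, 0, 0, 1.0, 0.5, 0.0),
            nll=np.nan, n_trials_used=n, converged=False,
            excluded_no_response=excluded,
            message="degenerate data: identical choices with near-zero RT variance",
        )

    b = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    ndt_hi = max(float(rt_u.min()) - RT_EPS, 1e-3)
    b["ndt"] = (1e-4, ndt_hi)
    lo = np.array([b[k][0] for k in PARAM_NAMES])
    hi = np.array([b[k][1] for k in PARAM_NAMES])

    def obj(x):
        try:
            p = DDMParameters.from_array(x)
        except ValueError:
            return 1e10
        val = negative_log_likelihood(p, t_c, h_c, rt_u, ch_u)
        return val if np.isfinite(val) else 1e10

    rng = np.random.default_rng(seed)
    # heuristic centre: weights from a choice regression scale, ndt near min rt
    x0 = np.array([0.3, 0.1, 0.2, 1.0, 0.5, 0.7 * ndt_hi])
    starts = [np.clip(x0, lo + 1e-6, hi - 1e-6)]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(lo + (hi - lo) * rng.uniform(0.05, 0.95, size=6))

    best = None
    for s in starts:
        res = optimize.minimize(obj, s, method="L-BFGS-B", bounds=list(zip(lo, hi)))
        if best is None or res.fun < best.fun:
            best = res
    params = DDMParameters.from_array(best.x)
    return FitResult(
        params=params,
        nll=float(best.fun),
        n_trials_used=n,
        converged=bool(best.success) and np.isfinite(best.fun),
        excluded_no_response=excluded,
        message=str(best.message),
    )


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class DriftDiffusionModel:
    """Multi-attribute DDM for one subject x condition trial set.

    Parameters
    ----------
    tastiness, healthiness : array-like
        Integer 1-6 ratings per trial.
    rt : array-like
        Response time in seconds; NaN for no-response trials.
    choice : array-like
        +1 accept, -1 reject, 0 no response.
    centred : bool
        Mean-centre ratings before they enter the drift (default True).
    """

    def __init__(self, tastiness, healthiness, rt, choice, centred: bool = True):
        self.tastiness = np.asarray(tastiness, float)
        self.healthiness = np.asarray(healthiness, float)
        self.rt = np.asarray(rt, float)
        self.choice = np.asarray(choice, int)
        if not (self.tastiness.size == self.healthiness.size == self.rt.size == self.choice.size):
            raise ValueError("trial arrays must share length")
        self.centred = centred
        self.taste_coded, self.health_coded = code_attributes(self.tastiness, self.healthiness, centred)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, centred: bool = True) -> "DriftDiffusionModel":
        """Build from a behavioural trial table.

        Expects columns ``tastiness``, ``healthiness``, ``rt`` and
        ``choice`` (``accept`` / ``reject`` / ``none`` strings or +1/-1/0).
        """
        ch = df["choice"]
        if ch.dtype == object:
            mapping = {"accept": 1, "reject": -1, "none": 0}
            choice = ch.map(mapping)
            if choice.isna().any():
                raise ValueError("choice column must contain accept/reject/none")
            choice = choice.to_numpy(int)
        else:
            choice = ch.to_numpy(int)
        return cls(df["tastiness"], df["healthiness"], df["rt"], choice, centred=centred)

    def loglike(self, params: DDMParameters) -> float:
        m = self.choice != 0
        return -negative_log_likelihood(params, self.taste_coded[m], self.health_coded[m], self.rt[m], self.choice[m])

    def fit(self, n_starts: int = 8, seed: int | None = None, min_trials: int = 40) -> "DDMResults":
        fr = fit_subject_condition(
            self.taste_coded, self.health_coded, self.rt, self.choice,
            n_starts=n_starts, seed=seed, min_trials=min_trials,
        )
        return DDMResults(self, fr)


class DDMResults:
    """Fitted DDM: point estimates, fit diagnostics, simulation helpers."""

    def __init__(self, model: DriftDiffusionModel, fit_result: FitResult):
        self.model = model
        self.fit_result = fit_result
        self.params = fit_result.params
        self.nll = fit_result.nll
        self.converged = fit_result.converged

    def summary(self) -> pd.DataFrame:
        rows = {k: getattr(self.params, k) for k in PARAM_NAMES}
        rows.update(
            nll=self.nll,
            n_trials_used=self.fit_result.n_trials_used,
            excluded_no_response=self.fit_result.excluded_no_response,
            converged=self.converged,
        )
        return pd.DataFrame({"value": rows})

    def simulate(self, n_datasets: int = 1, rng: np.random.Generator | None = None, dt: float = 0.001):
        """Simulate (choice, rt) for every model trial, ``n_datasets`` times."""
        rng = np.random.default_rng() if rng is None else rng
        out_c, out_rt = [], []
        for _ in range(n_datasets):
            c, r = simulate_trials(self.params, self.model.taste_coded, self.model.health_coded, dt=dt, rng=rng)
            out_c.append(c)
            out_rt.append(r)
        return np.array(out_c), np.array(out_rt)

    def posterior_predictive(self, n_sim: int = 200, rng: np.random.Generator | None = None, dt: float = 0.002):
        """Correlation between observed RTs and mean simulated RTs per trial.

        NaN (missing) when the per-trial drift is constant: the expected
        simulated RT is then the same on every trial and the correlation
        is undefined.
        """
        rng = np.random.default_rng() if rng is None else rng
        drift = self.params.drift(self.model.taste_coded, self.model.health_coded)
        if np.ptp(drift) < 1e-12:
            return np.nan
        n = self.model.taste_coded.size
        _, rts = simulate_trials(
            self.params,
            np.tile(self.model.taste_coded, n_sim),
            np.tile(self.model.health_coded, n_sim),
            dt=dt, rng=rng,
        )
        mean_rt = np.nanmean(rts.reshape(n_sim, n), axis=0)
        m = (self.model.choice != 0) & np.isfinite(mean_rt)
        obs = self.model.rt[m]
        if obs.size < 3 or np.std(obs) < 1e-12 or np.std(mean_rt[m]) < 1e-12:
            return np.nan
        return float(stats.pearsonr(obs, mean_rt[m])[0])


def fit_cohort(
    trials: pd.DataFrame,
    n_starts: int = 8,
    seed: int = 0,
    min_trials: int = 40,
    centred: bool = True,
) -> pd.DataFrame:
    """Fit every subject x condition cell of a behavioural table.

    Returns one row per cell with the six parameters and diagnostics.
    """
    rows = []
    for (subj, cond), g in trials.groupby(["subject", "condition"], sort=True):
        model = DriftDiffusionModel.from_dataframe(g, centred=centred)
        sub_seed = (hash((str(subj), str(cond))) % 100000) + seed
        res = model.fit(n_starts=n_starts, seed=sub_seed, min_trials=min_trials)
        row = {"subject": subj, "condition": cond}
        row.update(res.fit_result.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def posterior_predictive_check(
    fits: pd.DataFrame,
    trials: pd.DataFrame,
    n_sim: int = 200,
    seed: int = 0,
    centred: bool = True,
) -> dict:
    """Cohort-level posterior predictive check on RTs.

    For each subject x condition, the observed RTs are correlated with the
    mean simulated RT per trial under the fitted parameters; the Fisher-z
    transformed correlations are tested against zero with a one-sample t.
    """
    rs = []
    rng = np.random.default_rng(seed)
    for _, row in fits.iterrows():
        g = trials[(trials.subject == row.subject) & (trials.condition == row.condition)]
        model = DriftDiffusionModel.from_dataframe(g, centred=centred)
        params = DDMParameters(*(row[k] for k in PARAM_NAMES))
        res = DDMResults(model, FitResult(params, np.nan, len(g), True, 0))
        r = res.posterior_predictive(n_sim=n_sim, rng=rng)
        rs.append({"subject": row.subject, "condition": row.condition, "r": r})
    df = pd.DataFrame(rs)
    valid = df.r.dropna()
    z = np.arctanh(np.clip(valid, -0.999999, 0.999999))
    t, p = stats.ttest_1samp(z, 0.0) if len(z) > 2 else (np.nan, np.nan)
    return {"per_cell": df, "mean_r": float(valid.mean()), "t": float(t), "df": len(z) - 1, "p": float(p)}


def behaviour_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-condition descriptives: mean RT and accept fraction."""
    usable = trials[trials.choice != "none"] if trials.choice.dtype == object else trials[trials.choice != 0]
    acc = usable.choice.map({"accept": 1, "reject": 0}) if usable.choice.dtype == object else (usable.choice > 0)
    usable = usable.assign(_accept=acc.astype(float))
    return usable.groupby("condition").agg(mean_rt=("rt", "mean"), accept_fraction=("_accept", "mean"), n=("rt", "size"))


# ---------------------------------------------------------------------------
# optional hierarchical sampler
# ---------------------------------------------------------------------------

class HierarchicalDDM:
    """Random-walk Metropolis hierarchical estimator (fidelity experiments).

    Subject-level parameter vectors get independent group-normal priors per
    parameter; group means have flat priors and group SDs half-normal(2)
    priors.  Subjects are updated with joint random-walk proposals, group
    hyperparameters with conjugate-style Gibbs draws for the means and
    random-walk steps for the SDs.  Default iteration counts are 11000
    samples after 1000 burn-in; scale down for quick runs.
    """

    def __init__(self, trials: pd.DataFrame, condition: str, centred: bool = True):
        self.cells = []
        sub = trials[trials.condition == condition]
        for subj, g in sub.groupby("subject"):
            m = DriftDiffusionModel.from_dataframe(g, centred=centred)
            self.cells.append((subj, m))
        if not self.cells:
            raise ValueError(f"no trials for condition {condition}")

    def sample(self, n_iter: int = 11000, burn_in: int = 1000, seed: int = 0, prop_scale: float = 0.05):
        rng = np.random.default_rng(seed)
        n_sub = len(self.cells)
        theta = np.tile(np.array([0.3, 0.1, 0.2, 1.0, 0.5, 0.3]), (n_sub, 1))
        for i, (_, m) in enumerate(self.cells):
            theta[i, 5] = 0.6 * np.nanmin(m.rt[m.choice != 0])
        mu = theta.mean(axis=0)
        sd = np.full(6, 0.5)
        lo = np.array([-5, -5, -5, 0.1, 0.05, 1e-4])
        hi = np.array([5, 5, 5, 6.0, 0.95, 4.0])

        def cell_ll(i, x):
            if np.any(x <= lo) or np.any(x >= hi):
                return -np.inf
            m = self.cells[i][1]
            try:
                return m.loglike(DDMParameters.from_array(x))
            except ValueError:
                return -np.inf

        ll = np.array([cell_ll(i, theta[i]) for i in range(n_sub)])
        keep_theta, keep_mu = [], []
        for it in range(n_iter + burn_in):
            # subject-level RW updates
            prop = theta + rng.standard_normal(theta.shape) * prop_scale
            for i in range(n_sub):
                lp_new = cell_ll(i, prop[i]) + np.sum(stats.norm.logpdf(prop[i], mu, sd))
                lp_old = ll[i] + np.sum(stats.norm.logpdf(theta[i], mu, sd))
                if np.log(rng.uniform()) < lp_new - lp_old:
                    theta[i] = prop[i]
                    ll[i] = cell_ll(i, theta[i])
            # group means: conjugate normal draw given sd
            mu = theta.mean(axis=0) + rng.standard_normal(6) * sd / np.sqrt(n_sub)
            # group sds: RW on log scale with half-normal(2) prior
            for j in range(6):
                s_new = sd[j] * np.exp(rng.standard_normal() * 0.1)
                lp = lambda s: np.sum(stats.norm.logpdf(theta[:, j], mu[j], s)) + stats.halfnorm.logpdf(s, scale=2.0) + np.log(s)
                if np.log(rng.uniform()) < lp(s_new) - lp(sd[j]):
                    sd[j] = s_new
            if it >= burn_in:
                keep_theta.append(theta.copy())
                keep_mu.append(mu.copy())
        return {
            "theta": np.array(keep_theta),
            "mu": np.array(keep_mu),
            "subjects": [s for s, _ in self.cells],
            "param_names": list(PARAM_NAMES),
        }
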