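"""Matching EEG coefficient time courses to model-predicted time courses.

An EEG coefficient time course (per channel, per band) is scaled onto its
model-predicted counterpart by linear regression, and the signed Pearson
correlation over the analysis window (``r_eeg_model``) quantifies the
match.  A channel x band detection survives the joint criterion when

1. ``|r_eeg_model| > 0.85`` and its t-based p-value is below 0.05 after
   Bonferroni correction for all channel x component comparisons, and
2. the group-level coefficient is significantly different from zero with a
   uniform sign in every bin within +/-100 ms of the model-predicted peak
   (window truncated at 1 s post-stimulus).

A looser exploratory criterion retains any channel with at least six
consecutive significant same-sign bins before 1 s.  Two model templates
competing for the same EEG series are compared with the
Meng-Rosenthal-Rubin z-test for overlapping dependent correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .regression import BetaTimecourse, BinGrid

__all__ = [
    "MatchResult",
    "match_timecourse",
    "joint_criterion_flag",
    "joint_criterion",
    "compare_dependent_correlations",
    "exploratory_criterion_flag",
    "exploratory_criterion",
]


@dataclass
class MatchResult:
    """Scaled-regression match between an EEG and a model time course."""

    r_eeg_model: float
    p: float
    scale_slope: float
    scale_intercept: float
    n_bins: int
    window: tuple

    def __post_init__(self):
        if np.isfinite(self.r_eeg_model) and not -1.0 - 1e-12 <= self.r_eeg_model <= 1.0 + 1e-12:
            raise ValueError("correlation outside [-1, 1]")


def resample_to_bins(model_times: np.ndarray, model_values: np.ndarray, grid: BinGrid) -> np.ndarray:
    """Average a dense model series within each EEG bin (NaN for empty bins)."""
    idx = grid.assign(np.asarray(model_times, float))
    out = np.full(grid.n_bins, np.nan)
    v = np.asarray(model_values, float)
    for b in range(grid.n_bins):
        m = idx == b
        if m.any():
            out[b] = v[m].mean()
    return out


def match_timecourse(eeg_beta, model_beta, times, window=(0.0, 1.0)) -> MatchResult:
    """Match two coefficient series on a common bin axis.

    ``eeg_beta`` and ``model_beta`` are aligned arrays on ``times`` (bin
    centres); only bins whose centre lies in ``window`` enter.  The signed
    Pearson correlation is reported with a two-sided t-based p (df = bins -
    2); the affine scaling (EEG ~ intercept + slope * model) is recorded.
    Constant series give NaN (missing) rather than an error.
    """
    times = np.asarray(times, float)
    e = np.asarray(eeg_beta, float)
    m = np.asarray(model_beta, float)
    sel = (times >= window[0]) & (times <= window[1]) & np.isfinite(e) & np.isfinite(m)
    n = int(sel.sum())
    if n < 3:
        raise ValueError("fewer than 3 usable bins in the window")
    e, m = e[sel], m[sel]
    if np.std(e) < 1e-300 or np.std(m) < 1e-300:
        return MatchResult(np.nan, np.nan, np.nan, np.nan, n, tuple(window))
    slope, intercept = np.polyfit(m, e, 1)
    r, p = stats.pearsonr(e, m)
    return MatchResult(float(r), float(p), float(slope), float(intercept), n, tuple(window))


def joint_criterion_flag(
    match: MatchResult,
    group_p: np.ndarray,
    group_mean: np.ndarray,
    bin_centres: np.ndarray,
    model_peak_latency: float,
    r_threshold: float = 0.85,
    alpha: float = 0.05,
    n_comparisons: int = 64 * 7,
    window_half: float = 0.100,
    cutoff: float = 1.0,
) -> bool:
    """Joint significance decision for one channel (x band) x template.

    Requires |r| above threshold with Bonferroni-corrected significance,
    plus group significance with uniform sign in every bin whose centre
    lies within ``window_half`` of the model peak (truncated at
    ``cutoff``).
    """
    if not np.isfinite(model_peak_latency):
        raise ValueError("model peak latency is missing")
    if not np.isfinite(match.r_eeg_model):
        return False
    if abs(match.r_eeg_model) <= r_threshold:
        return False
    if match.p * n_comparisons >= alpha:
        return False
    centres = np.asarray(bin_centres, float)
    lo = model_peak_latency - window_half
    hi = min(model_peak_latency + window_half, cutoff)
    sel = (centres >= lo) & (centres <= hi)
    if not sel.any():
        return False
    p = np.asarray(group_p, float)[sel]
    mu = np.asarray(group_mean, float)[sel]
    if np.any(p >= alpha):
        return False
    signs = np.sign(mu)
    return bool(np.all(signs == signs[0]) and signs[0] != 0)


def joint_criterion(entries: list, **kwargs) -> pd.DataFrame:
    """Apply the joint criterion to a list of candidate detections.

    Each entry is a dict with keys ``match`` (MatchResult), ``group_p``,
    ``group_mean``, ``bin_centres``, ``model_peak_latency`` plus free
    identifier fields (channel, band, template, condition, ...).  Returns a
    tidy frame with a boolean ``flag`` column (criterion variant 'joint').
    """
    rows = []
    for ent in entries:
        flag = joint_criterion_flag(
            ent["match"], ent["group_p"], ent["group_mean"], ent["bin_centres"], ent["model_peak_latency"], **kwargs
        )
        row = {k: v for k, v in ent.items() if k not in ("match", "group_p", "group_mean", "bin_centres", "model_peak_latency")}
        row.update(
            r_eeg_model=ent["match"].r_eeg_model,
            p_r=ent["match"].p,
            scale_slope=ent["match"].scale_slope,
            flag=flag,
            criterion="joint",
        )
        rows.append(row)
    return pd.DataFrame(rows)


def compare_dependent_correlations(r1: float, r2: float, r12: float, n: int):
    """Meng-Rosenthal-Rubin z-test for two correlations sharing one variable.

    ``r1`` and ``r2`` correlate the shared (EEG) series with each of two
    templates whose intercorrelation is ``r12``; positive z means r1 > r2.
    """
    if n <= 4:
        raise ValueError("need n > 4")
    for r in (r1, r2, r12):
        if not np.isfinite(r) or abs(r) >= 1:
            raise ValueError("correlations must be finite with |r| < 1")
    C = np.array([[1, r1, r2], [r1, 1, r12], [r2, r12, 1]])
    if np.linalg.eigvalsh(C)[0] < -1e-10:
        raise ValueError("degenerate (non-positive-definite) correlation structure")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    rbar = (r1**2 + r2**2) / 2.0
    f = min((1.0 - r12) / (2.0 * (1.0 - rbar)), 1.0)
    h = (1.0 - f * rbar) / (1.0 - rbar)
    z = (z1 - z2) * np.sqrt((n - 3.0) / (2.0 * (1.0 - r12) * h))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def exploratory_criterion_flag(
    group_p: np.ndarray,
    group_mean: np.ndarray,
    bin_centres: np.ndarray,
    min_consecutive: int = 6,
    cutoff: float = 1.0,
    alpha: float = 0.05,
) -> bool:
    """Run-length criterion: >= ``min_consecutive`` consecutive significant
    same-sign bins, all with centres at or before ``cutoff``."""
    centres = np.asarray(bin_centres, float)
    ok = (np.asarray(group_p, float) < alpha) & (centres <= cutoff)
    signs = np.sign(np.asarray(group_mean, float))
    run = 0
    prev_sign = 0
    for o, s in zip(ok, signs):
        if o and s != 0 and (run == 0 or s == prev_sign):
            run += 1
            prev_sign = s
        elif o and s != 0:
            run = 1
            prev_sign = s
        else:
            run = 0
            prev_sign = 0
        if run >= min_consecutive:
            return True
    return False


def exploratory_criterion(entries: list, **kwargs) -> pd.DataFrame:
    """Vector version of the exploratory run-length criterion."""
    rows = []
    for ent in entries:
        flag = exploratory_criterion_flag(ent["group_p"], ent["group_mean"], ent["bin_centres"], **kwargs)
        row = {k: v for k, v in ent.items() if k not in ("group_p", "group_mean", "bin_centres")}
        row.update(flag=flag, criterion="exploratory")
        rows.append(row)
    return pd.DataFrame(rows)
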