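"""Condition-level and individual-difference statistics.

One-way repeated-measures ANOVA over the three regulation conditions,
post-hoc paired t-tests, across-subject correlations of condition
differences (e.g. the change in the tastiness weight against the change in
its oscillatory correlate), and within-subject standard errors
(Cousineau-Morey) for repeated-measures error bars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

__all__ = [
    "GroupTestResult",
    "repeated_measures_anova",
    "paired_contrasts",
    "across_subject_correlation",
    "within_subject_sem",
]


@dataclass
class GroupTestResult:
    name: str
    statistic: float
    df: tuple
    p: float
    effect: str = ""

    def __post_init__(self):
        if np.isfinite(self.p) and not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


def repeated_measures_anova(values, condition_names=None, correction: str | None = None) -> GroupTestResult:
    """One-way repeated-measures ANOVA over within-subject conditions.

    ``values`` is subjects x conditions (complete cases).  F is reported
    with df (k-1, (k-1)(n-1)); no sphericity correction by default
    (``correction='gg'`` applies Greenhouse-Geisser to the df and p).
    """
    X = np.asarray(values, float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("values must be subjects x conditions with k >= 2")
    if np.any(~np.isfinite(X)):
        raise ValueError("missing cells: repeated-measures ANOVA needs complete cases")
    n, k = X.shape
    names = condition_names or [f"c{i}" for i in range(k)]
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "condition": np.tile(names, n),
        "value": X.ravel(),
    })
    if np.allclose(X - X.mean(axis=0, keepdims=True), (X - X.mean(axis=0, keepdims=True))[:, :1]):
        # no condition-by-subject variability left: F degenerates
        if np.ptp(X.mean(axis=0)) < 1e-12:
            return GroupTestResult("rm_anova", 0.0, (k - 1, (k - 1) * (n - 1)), 1.0)
    res = AnovaRM(long, depvar="value", subject="subject", within=["condition"]).fit()
    row = res.anova_table.iloc[0]
    F = float(row["F Value"])
    df1, df2 = float(row["Num DF"]), float(row["Den DF"])
    p = float(row["Pr > F"])
    if correction == "gg":
        eps = _greenhouse_geisser_epsilon(X)
        df1, df2 = df1 * eps, df2 * eps
        p = float(stats.f.sf(F, df1, df2))
    return GroupTestResult("rm_anova", F, (df1, df2), p)


def _greenhouse_geisser_epsilon(X: np.ndarray) -> float:
    k = X.shape[1]
    S = np.cov(X.T)
    H = np.eye(k) - np.ones((k, k)) / k
    S = H @ S @ H
    lam = np.linalg.eigvalsh(S)
    num = np.sum(lam) ** 2
    den = (k - 1) * np.sum(lam**2)
    return float(np.clip(num / den if den > 0 else 1.0, 1.0 / (k - 1), 1.0))


def paired_contrasts(values, pairs, condition_names=None) -> list:
    """Two-sided paired t-tests for the requested condition pairs.

    ``values`` is subjects x conditions; ``pairs`` a list of (i, j) column
    indices or name pairs.  Uncorrected by default, matching the post-hoc
    convention.  Zero-variance differences report p at the machine floor
    and are flagged in the effect field.
    """
    X = np.asarray(values, float)
    names = condition_names or [f"c{i}" for i in range(X.shape[1])]
    lut = {nm: i for i, nm in enumerate(names)}
    out = []
    for a, b in pairs:
        i = lut[a] if isinstance(a, str) else a
        j = lut[b] if isinstance(b, str) else b
        d = X[:, i] - X[:, j]
        if np.any(~np.isfinite(d)):
            raise ValueError("incomplete pairs")
        if np.ptp(d) < 1e-15:
            if abs(d.mean()) < 1e-15:
                t, p, eff = 0.0, 1.0, ""
            else:
                t = np.sign(d.mean()) * np.inf
                p, eff = np.finfo(float).tiny, "zero-variance difference"
        else:
            t, p = stats.ttest_rel(X[:, i], X[:, j])
            eff = ""
        out.append(GroupTestResult(f"paired_t[{names[i]}-{names[j]}]", float(t), (len(d) - 1,), float(p), eff))
    return out


def across_subject_correlation(delta_x, delta_y) -> GroupTestResult:
    """Pearson correlation of two per-subject condition differences."""
    x = np.asarray(delta_x, float)
    y = np.asarray(delta_y, float)
    if x.size != y.size:
        raise ValueError("mismatched subjects")
    if x.size < 5:
        raise ValueError("need at least 5 subjects")
    if np.ptp(x) < 1e-300 or np.ptp(y) < 1e-300:
        return GroupTestResult("pearson_r", np.nan, (x.size - 2,), np.nan, "constant input")
    r, p = stats.pearsonr(x, y)
    return GroupTestResult("pearson_r", float(r), (x.size - 2,), float(p))


def within_subject_sem(values) -> np.ndarray:
    """Within-subject SEM per condition (Cousineau-Morey).

    Subject means are removed (grand mean restored) before computing the
    per-condition SEM, which is then scaled by sqrt(J / (J - 1)) for J
    conditions.  Appropriate for repeated-measures error bars.
    """
    X = np.asarray(values, float)
    if X.ndim != 2:
        raise ValueError("values must be subjects x conditions")
    n, J = X.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if np.any(~np.isfinite(X)):
        raise ValueError("complete cases required")
    centred = X - X.mean(axis=1, keepdims=True) + X.mean()
    sem = centred.std(axis=0, ddof=1) / np.sqrt(n)
    return sem * np.sqrt(J / (J - 1.0))
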