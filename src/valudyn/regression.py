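"""Per-bin / per-timepoint mass-univariate OLS engine and trial splits.

A single vectorised ordinary-least-squares core serves both the simulated
signal regressions (per grid point) and the single-trial EEG feature
regressions (per ~49 ms bin): the trial-wise response at each bin is
regressed on coded tastiness, coded healthiness and RT, with an intercept.
Group-level inference is a one-sample t-test of a coefficient across
subjects per bin.  No multiple-comparison correction is applied here; the
model-EEG comparison stage owns its Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BinGrid",
    "RegressionDesign",
    "BetaTimecourse",
    "mass_ols",
    "fit_bin_regression",
    "timecourse_regression",
    "group_bin_tests",
    "split_by_rt",
]

COEF_NAMES = ("b0", "b_tastiness", "b_healthiness", "b_rt")


@dataclass(frozen=True)
class BinGrid:
    """Contiguous equal-width time bins, food-locked.

    The default spans -200 ms to +1000 ms in 25 bins of 48 ms.  With
    ``from_sampling`` the width is an integer number of samples (25 samples
    at 512 Hz gives the 48.83 ms variant).
    """

    n_bins: int = 25
    start: float = -0.200
    bin_width: float = 0.048

    def __post_init__(self):
        if self.n_bins < 1 or self.bin_width <= 0:
            raise ValueError("invalid bin grid")

    @classmethod
    def from_sampling(cls, fs: float, samples_per_bin: int = 25, n_bins: int = 25, start: float = -0.200) -> "BinGrid":
        return cls(n_bins=n_bins, start=start, bin_width=samples_per_bin / fs)

    @property
    def edges(self) -> np.ndarray:
        return self.start + self.bin_width * np.arange(self.n_bins + 1)

    @property
    def bin_centres(self) -> np.ndarray:
        return self.start + self.bin_width * (np.arange(self.n_bins) + 0.5)

    @property
    def end(self) -> float:
        return self.start + self.n_bins * self.bin_width

    def assign(self, times: np.ndarray) -> np.ndarray:
        """Bin index per sample time; -1 outside the grid.

        Samples are assigned by membership in [left, right) with the final
        right edge inclusive.
        """
        times = np.asarray(times, float)
        idx = np.floor((times - self.start) / self.bin_width).astype(int)
        idx[(times < self.start) | (times > self.end + 1e-12)] = -1
        idx[np.isclose(times, self.end)] = self.n_bins - 1
        return idx


@dataclass
class RegressionDesign:
    """Trial-level predictors: coded attributes and RT (intercept implied)."""

    tastiness_coded: np.ndarray
    healthiness_coded: np.ndarray
    rt: np.ndarray

    def __post_init__(self):
        self.tastiness_coded = np.asarray(self.tastiness_coded, float)
        self.healthiness_coded = np.asarray(self.healthiness_coded, float)
        self.rt = np.asarray(self.rt, float)
        n = self.tastiness_coded.size
        if not (self.healthiness_coded.size == n and self.rt.size == n):
            raise ValueError("design columns must share length")
        X = self.matrix
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite design values")
        if n >= 3:
            with np.errstate(invalid="ignore"):
                c = np.corrcoef(X[:, 1:].T)
            off = c[~np.eye(3, dtype=bool)]
            if np.any(np.abs(off[np.isfinite(off)]) >= 0.99):
                raise ValueError("predictors nearly collinear (|r| >= 0.99)")

    @property
    def n_trials(self) -> int:
        return self.tastiness_coded.size

    @property
    def matrix(self) -> np.ndarray:
        return np.column_stack([
            np.ones(self.n_trials),
            self.tastiness_coded,
            self.healthiness_coded,
            self.rt,
        ])


@dataclass
class BetaTimecourse:
    """Coefficient time course from a per-bin (or per-timepoint) regression."""

    times: np.ndarray
    coefs: dict  # name -> array over bins
    ses: dict  # name -> array over bins
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.times)
        for d in (self.coefs, self.ses):
            for k, v in d.items():
                if len(v) != n:
                    raise ValueError(f"length mismatch for {k}")
        for k, v in self.ses.items():
            if np.any(np.asarray(v)[np.isfinite(v)] < 0):
                raise ValueError("standard errors must be >= 0")

    def __getitem__(self, name: str) -> np.ndarray:
        return np.asarray(self.coefs[name])

    def to_frame(self) -> pd.DataFrame:
        data = {"time_centre_s": self.times}
        for k in self.coefs:
            data[k] = self.coefs[k]
        for k in self.ses:
            data[f"se_{k}"] = self.ses[k]
        df = pd.DataFrame(data)
        for k, v in self.meta.items():
            df[k] = v
        return df


def mass_ols(Y: np.ndarray, X: np.ndarray):
    """OLS of many responses on one design: ``Y`` (n x m), ``X`` (n x p).

    Returns (beta, se, t, p), each (p x m).  Two-sided p from the t
    distribution with n - p degrees of freedom.
    """
    Y = np.asarray(Y, float)
    X = np.asarray(X, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("responses and design must share the trial axis")
    if n <= p:
        raise ValueError(f"need more than {p} trials, got {n}")
    if np.linalg.matrix_rank(X) < p:
        sds = X.std(axis=0)
        bad = [COEF_NAMES[i] if p == 4 else str(i) for i in range(1, p) if sds[i] < 1e-12]
        raise ValueError(f"rank-deficient design (collinear/constant predictors: {bad or 'unknown'})")
    XtX = X.T @ X
    XtXi = np.linalg.inv(XtX)
    beta = XtXi @ (X.T @ Y)
    resid = Y - X @ beta
    dof = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    se = np.sqrt(np.outer(np.diag(XtXi), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pval = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta, se, t, pval


def fit_bin_regression(y, design: RegressionDesign):
    """OLS of one bin's trial values on the design; returns a dict of
    (coef, se, t, p) per coefficient name."""
    beta, se, t, p = mass_ols(np.asarray(y, float), design.matrix)
    return {
        name: {"coef": float(beta[i, 0]), "se": float(se[i, 0]), "t": float(t[i, 0]), "p": float(p[i, 0])}
        for i, name in enumerate(COEF_NAMES)
    }


def timecourse_regression(binned_values: np.ndarray, design: RegressionDesign, grid: BinGrid, meta: dict | None = None) -> BetaTimecourse:
    """Per-bin OLS over a (trials x bins) array."""
    binned_values = np.asarray(binned_values, float)
    if binned_values.ndim != 2:
        raise ValueError("binned_values must be trials x bins")
    if binned_values.shape[1] != grid.n_bins:
        raise ValueError("bin axis must match the grid")
    if binned_values.shape[0] != design.n_trials:
        raise ValueError("trial axis must match the design")
    beta, se, _, _ = mass_ols(binned_values, design.matrix)
    return BetaTimecourse(
        times=grid.bin_centres,
        coefs={name: beta[i] for i, name in enumerate(COEF_NAMES)},
        ses={name: se[i] for i, name in enumerate(COEF_NAMES)},
        meta=meta or {},
    )


def group_bin_tests(subject_betas, coefficient: str):
    """One-sample t-test of a coefficient across subjects, per bin.

    ``subject_betas`` is a list of BetaTimecourse on a common grid (or a
    subjects x bins array).  Returns a dict with per-bin group mean, t, df
    and two-sided p.  Degenerate zero-variance bins report p at the
    smallest positive float rather than NaN.
    """
    if isinstance(subject_betas, np.ndarray):
        mat = np.asarray(subject_betas, float)
        times = None
    else:
        if len(subject_betas) < 3:
            raise ValueError("need at least 3 subjects")
        times = np.asarray(subject_betas[0].times)
        for b in subject_betas[1:]:
            if not np.allclose(b.times, times):
                raise ValueError("subjects must share the bin grid")
        mat = np.stack([b[coefficient] for b in subject_betas])
    n = mat.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    df = n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    degen = (sd < 1e-300) & (np.abs(mean) > 0)
    t[degen] = np.sign(mean[degen]) * np.inf
    p[degen] = np.finfo(float).tiny
    p[(sd < 1e-300) & (np.abs(mean) == 0)] = 1.0
    return {"times": times, "mean": mean, "t": t, "df": df, "p": p}


def split_by_rt(rts, scheme: str = "median"):
    """RT-based trial splits for one subject (x condition).

    ``tertile`` uses the 33rd/66th percentiles -> fast / medium / slow;
    ``median`` uses the 50th -> fast / slow.  Boundary ties go to the lower
    (faster) bin.  Returns a dict of index arrays partitioning the trials.
    """
    rts = np.asarray(rts, float)
    if rts.size < 6:
        raise ValueError("need at least 6 trials to split by RT")
    if np.ptp(rts) < 1e-12:
        raise ValueError("degenerate RT distribution (all RTs equal)")
    idx = np.arange(rts.size)
    if scheme == "tertile":
        q33, q66 = np.percentile(rts, [33, 66])
        return {
            "fast": idx[rts <= q33],
            "medium": idx[(rts > q33) & (rts <= q66)],
            "slow": idx[rts > q66],
        }
    if scheme == "median":
        q50 = np.percentile(rts, 50)
        return {"fast": idx[rts <= q50], "slow": idx[rts > q50]}
    raise ValueError("scheme must be 'tertile' or 'median'")
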