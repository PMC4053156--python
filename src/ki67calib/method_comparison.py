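"""Method-comparison statistics for labelling-index measurements.

Given per-spot labelling indices from a reference procedure and one or more
candidate methods (image analysis profiles, simulated observers), this
module quantifies agreement and bias: ordinary least squares with the
reference as explanatory variable, PCA-based orthogonal regression,
confidence ellipses and the accuracy factor, Bland-Altman limits of
agreement, one-way ANOVA with Duncan multiple-range letter grouping,
inter-observer variability profiles and Pearson correlation matrices.

The *accuracy factor* is the ratio of the method-vs-reference regression
line tilt to the tilt of the reference confidence ellipse's major axis, both
in degrees; a factor of 1 means the method tracks the reference with no
proportional bias.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (AmbiguousAxisError, DegenerateFitError,
                     InsufficientDataError)

__all__ = [
    "RegressionFit", "OrthogonalFit", "ConfidenceEllipse",
    "BlandAltmanResult", "DuncanResult",
    "fit_ols", "fit_orthogonal", "confidence_ellipse", "accuracy_factor",
    "bland_altman", "anova_duncan", "variability_profile",
    "correlation_matrix",
]


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_square: float
    slope_p: float
    intercept_p: float
    standardized_slope: float
    n: int
    residual_sd: float = float("nan")
    slope_se: float = float("nan")
    intercept_se: float = float("nan")

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass(frozen=True)
class OrthogonalFit:
    slope: float
    intercept: float
    line_tilt_deg: float
    n: int


@dataclass(frozen=True)
class ConfidenceEllipse:
    centre: tuple[float, float]
    major_axis_length: float
    minor_axis_length: float
    tilt_deg: float
    degenerate: bool = False


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    differences: np.ndarray


@dataclass(frozen=True)
class DuncanResult:
    f_statistic: float
    p_value: float
    means: "pd.Series"          # sorted descending
    letters: dict               # column -> letter string, e.g. "AB"
    alpha: float = 0.05


def _as_xy(x, y, min_n=3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < min_n:
        raise InsufficientDataError(f"need at least {min_n} observations")
    return x, y


def fit_ols(x, y) -> RegressionFit:
    """OLS of method (y) on reference (x), with standardized slope.

    The standardized slope is ``slope * sd(x)/sd(y)``, which for a simple
    regression equals the Pearson correlation.
    """
    x, y = _as_xy(x, y)
    if np.ptp(x) == 0:
        raise DegenerateFitError("explanatory variable is constant")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    std_slope = model.params[1] * sx / sy if sy > 0 else float("nan")
    return RegressionFit(
        slope=float(model.params[1]), intercept=float(model.params[0]),
        r_square=float(model.rsquared), slope_p=float(model.pvalues[1]),
        intercept_p=float(model.pvalues[0]),
        standardized_slope=float(std_slope), n=len(x),
        residual_sd=float(np.sqrt(model.mse_resid)),
        slope_se=float(model.bse[1]), intercept_se=float(model.bse[0]))


def fit_orthogonal(x, y, isotropy_tol: float = 1e-9) -> OrthogonalFit:
    """Orthogonal regression: first principal axis of the centred cloud.

    The fitted line passes through the centroid along the leading eigenvector
    of the 2x2 covariance matrix; its tilt (degrees, in (-90, 90]) satisfies
    ``slope = tan(tilt)``.  An isotropic cloud (equal eigenvalues within
    ``isotropy_tol`` relative difference) has no preferred axis and raises
    :class:`AmbiguousAxisError`.
    """
    x, y = _as_xy(x, y)
    cov = np.cov(x, y)
    evals, evecs = np.linalg.eigh(cov)
    lam1, lam2 = evals[1], evals[0]          # eigh sorts ascending
    if lam1 <= 0 or (lam1 - lam2) / lam1 <= isotropy_tol:
        raise AmbiguousAxisError("principal axis is not identifiable for an "
                                 "isotropic point cloud")
    vx, vy = evecs[:, 1]
    if vx < 0:
        vx, vy = -vx, -vy
    if vx == 0:
        raise AmbiguousAxisError("principal axis is vertical; slope undefined")
    slope = vy / vx
    tilt = float(np.degrees(np.arctan2(vy, vx)))
    intercept = float(np.mean(y) - slope * np.mean(x))
    return OrthogonalFit(slope=float(slope), intercept=intercept,
                         line_tilt_deg=tilt, n=len(x))


def confidence_ellipse(points, ce_per_point=None,
                       coverage: float = 0.95) -> ConfidenceEllipse:
    """PCA-aligned coverage ellipse of a 2-D point set.

    When per-point relative errors ``ce_per_point`` are supplied, each point
    ``(x, y)`` is augmented with its four CI-extreme replicates
    ``(x*(1 +/- ce), y*(1 +/- ce))`` before fitting, so subsampling
    uncertainty widens the ellipse and can never shrink it.  Axis lengths are
    full lengths at the requested Mahalanobis coverage; tilt in [0, 180).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise InsufficientDataError("need at least three (x, y) points")
    if ce_per_point is not None:
        ce = np.asarray(ce_per_point, dtype=float)
        if ce.shape != (len(pts),):
            raise ValueError("ce_per_point must align with points")
        reps = [pts]
        for fx, fy in itertools.product((-1.0, 1.0), repeat=2):
            reps.append(np.column_stack((pts[:, 0] * (1 + fx * ce),
                                         pts[:, 1] * (1 + fy * ce))))
        pts = np.vstack(reps)
    centre = pts.mean(axis=0)
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.maximum(evals, 0.0)
    k = np.sqrt(stats.chi2.ppf(coverage, df=2))
    major = 2.0 * k * np.sqrt(evals[1])
    minor = 2.0 * k * np.sqrt(evals[0])
    vx, vy = evecs[:, 1]
    tilt = float(np.degrees(np.arctan2(vy, vx)) % 180.0)
    return ConfidenceEllipse(
        centre=(float(centre[0]), float(centre[1])),
        major_axis_length=float(major), minor_axis_length=float(minor),
        tilt_deg=tilt, degenerate=bool(evals[0] <= 1e-12 * max(evals[1], 1.0)))


def accuracy_factor(line_tilt_deg: float, ellipse_axis_tilt_deg: float) -> float:
    """Ratio of regression-line tilt to ellipse-axis tilt (degrees)."""
    if ellipse_axis_tilt_deg == 0:
        raise ZeroDivisionError("ellipse axis tilt of zero: ratio undefined")
    if not (0 < line_tilt_deg < 90 and 0 < ellipse_axis_tilt_deg < 90):
        raise ValueError("tilts must lie in (0, 90) degrees")
    return line_tilt_deg / ellipse_axis_tilt_deg


def bland_altman(x, y) -> BlandAltmanResult:
    """Differences (y - x) against means, with 95% limits of agreement."""
    x, y = _as_xy(x, y, min_n=2)
    diff = y - x
    mean_diff = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1)) if len(diff) > 1 else 0.0
    return BlandAltmanResult(
        mean_difference=mean_diff, sd_difference=sd,
        loa_low=mean_diff - 1.96 * sd, loa_high=mean_diff + 1.96 * sd,
        means=(x + y) / 2.0, differences=diff)


# ---------------------------------------------------------------------------
# one-way ANOVA with Duncan multiple-range letters
# ---------------------------------------------------------------------------

def _duncan_letters(means_sorted: np.ndarray, ranges: np.ndarray) -> list[str]:
    """Letter display for Duncan's test given sorted means and critical ranges.

    ``ranges[p]`` is the least significant range for a span of ``p`` means
    (index 2..k).  A span is non-significant when its endpoint difference is
    within its range; non-significance of a span protects all its sub-spans.
    Letters are the maximal non-significant intervals.
    """
    k = len(means_sorted)
    nonsig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        nonsig[i, i] = True
    # widest spans first so protection propagates to sub-spans
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if nonsig[i, j]:
                continue
            if means_sorted[i] - means_sorted[j] <= ranges[span]:
                for a in range(i, j + 1):
                    for b in range(a, j + 1):
                        nonsig[a, b] = True
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and nonsig[i, j + 1]:
            j += 1
        intervals.append((i, j))
    # drop intervals contained in an earlier (necessarily wider) one
    maximal = []
    for iv in intervals:
        if not any(o[0] <= iv[0] and iv[1] <= o[1] for o in maximal):
            maximal.append(iv)
    letters = [""] * k
    for idx, (i, j) in enumerate(maximal):
        ch = chr(ord("A") + idx)
        for g in range(i, j + 1):
            letters[g] += ch
    return letters


@lru_cache(maxsize=4096)
def _q_crit(alpha: float, p: int, df_err: int) -> float:
    """Studentized-range critical value at Duncan's protection level."""
    return float(stats.studentized_range.ppf((1 - alpha) ** (p - 1), p, df_err))


def anova_duncan(table: pd.DataFrame, alpha: float = 0.05) -> DuncanResult:
    """One-way ANOVA across method columns plus Duncan letter grouping.

    Expects a wide table (rows = spots, columns = methods) with equal,
    complete columns.  Duncan's multiple-range test uses studentized-range
    critical values at the stepwise protection level
    ``1 - (1 - alpha)**(p - 1)`` for a span of ``p`` ordered means; methods
    sharing a letter are statistically indistinguishable.
    """
    df = pd.DataFrame(table)
    if df.shape[1] < 2:
        raise InsufficientDataError("need at least two method columns")
    if df.isna().any().any():
        raise InsufficientDataError("unequal group sizes (missing values) "
                                    "are not supported")
    groups = [df[c].to_numpy(dtype=float) for c in df.columns]
    k = len(groups)
    n = len(groups[0])
    f_stat, p_val = stats.f_oneway(*groups)
    if not np.isfinite(f_stat):       # zero within-group variance
        f_stat, p_val = 0.0, 1.0
    grand = np.mean(np.concatenate(groups))
    df_err = k * (n - 1)
    mse = sum(np.sum((g - np.mean(g)) ** 2) for g in groups) / df_err
    means = pd.Series({c: float(np.mean(g))
                       for c, g in zip(df.columns, groups)})
    order = means.sort_values(ascending=False)
    ranges = np.zeros(k + 1)
    if mse > 0:
        se = np.sqrt(mse / n)
        for p in range(2, k + 1):
            ranges[p] = _q_crit(alpha, p, df_err) * se
    letters_sorted = _duncan_letters(order.to_numpy(), ranges)
    letters = dict(zip(order.index, letters_sorted))
    between = n * sum((np.mean(g) - grand) ** 2 for g in groups)
    if mse == 0 and between == 0:
        f_stat, p_val = 0.0, 1.0
    return DuncanResult(f_statistic=float(f_stat), p_value=float(p_val),
                        means=order, letters=letters, alpha=alpha)


def variability_profile(columns: pd.DataFrame) -> pd.DataFrame:
    """Row-wise (mean, sd) of repeated measurements, for dispersion-vs-level
    plots."""
    df = pd.DataFrame(columns)
    if df.shape[1] < 2:
        raise InsufficientDataError("need at least two measurement columns")
    return pd.DataFrame({"mean": df.mean(axis=1), "sd": df.std(axis=1, ddof=1)})


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations; constant columns yield NaN entries."""
    df = pd.DataFrame(table)
    if len(df) < 3:
        raise InsufficientDataError("need at least three rows")
    corr = df.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    for c in df.columns:                    # flag undefined entries explicitly
        if df[c].std(ddof=1) == 0:
            corr.loc[c, :] = np.nan
            corr.loc[:, c] = np.nan
            corr.loc[c, c] = np.nan
    return corr
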