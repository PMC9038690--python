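"""Statistical layer: two-phase linear regression, parametric two-sample
tests with assumption checks, and transition-to-transition stability.

The two-phase (segmented) regression fits a continuous piecewise-linear
model with the breakpoint chosen by exhaustive search over the observed
x values, minimising the total residual sum of squares.  Slope
confidence intervals are conditional on the selected breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SegmentedFit",
    "fit_two_phase",
    "TTestResult",
    "two_sample_t",
    "AssumptionChecks",
    "assumption_checks",
    "TransitionStability",
    "transition_stability",
]


class InvalidInputError(ValueError):
    pass


@dataclass
class SegmentedFit:
    """Result of a two-phase linear regression."""

    breakpoint: float
    slopes: tuple[float, float]
    intercepts: tuple[float, float]
    r_squared: float
    slope_cis: tuple[tuple[float, float], tuple[float, float]]
    residuals: np.ndarray = field(repr=False)
    rss: float = np.nan
    continuous: bool = True

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        y1 = self.intercepts[0] + self.slopes[0] * x
        y2 = self.intercepts[1] + self.slopes[1] * x
        return np.where(x <= self.breakpoint, y1, y2)

    def as_rows(self) -> list[dict]:
        return [
            {
                "phase": i + 1,
                "slope": self.slopes[i],
                "intercept": self.intercepts[i],
                "ci_low": self.slope_cis[i][0],
                "ci_high": self.slope_cis[i][1],
                "r_squared": self.r_squared,
                "breakpoint": self.breakpoint,
            }
            for i in (0, 1)
        ]


def _prepare_xy(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if y.ndim == 2:  # replicate matrix: pool observations at shared x
        if y.shape[1] != x.size:
            raise InvalidInputError("replicate matrix must have one column per x")
        x = np.tile(x, y.shape[0])
        y = y.ravel()
    if x.shape != y.shape:
        raise InvalidInputError("x and y must have the same length")
    return x, y


def fit_two_phase(
    x: np.ndarray,
    y: np.ndarray,
    min_seg: int = 3,
    continuous: bool = True,
    conf: float = 0.95,
) -> SegmentedFit:
    """Two-phase least-squares fit with exhaustively searched breakpoint.

    ``y`` may be a single series or a (replicates x len(x)) matrix, in
    which case replicates are pooled.  The breakpoint is restricted to
    observed x values leaving at least ``min_seg`` points in each phase
    (points at the breakpoint belong to phase 1).  With
    ``continuous=False`` the two segments are fitted independently.
    """
    x, y = _prepare_xy(x, y)
    ux = np.unique(x)
    if np.any(np.diff(ux) <= 0):  # unique() sorts; guard kept for clarity
        raise InvalidInputError("x must be strictly increasing")
    # min_seg counts distinct x positions so both slopes stay identifiable
    # when replicates are pooled
    candidates = [
        bp
        for bp in ux
        if (ux <= bp).sum() >= min_seg and (ux > bp).sum() >= min_seg
    ]
    if not candidates:
        raise InvalidInputError(
            f"need at least {min_seg} points on each side of a breakpoint"
        )

    best = None
    for bp in candidates:
        fit = _fit_at_breakpoint(x, y, bp, continuous, conf)
        if best is None or fit.rss < best.rss - 1e-15:
            best = fit
    return best


def _fit_at_breakpoint(x, y, bp, continuous, conf):
    n = x.size
    if continuous:
        design = np.column_stack([np.ones(n), x, np.maximum(x - bp, 0.0)])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        pred = design @ beta
        resid = y - pred
        rss = float(resid @ resid)
        dof = max(n - 3, 1)
        cov = _ols_cov(design, rss, dof)
        slope1 = float(beta[1])
        slope2 = float(beta[1] + beta[2])
        var1 = cov[1, 1]
        var2 = cov[1, 1] + cov[2, 2] + 2 * cov[1, 2]
        tcrit = sps.t.ppf(0.5 + conf / 2.0, dof)
        cis = (
            (slope1 - tcrit * np.sqrt(var1), slope1 + tcrit * np.sqrt(var1)),
            (slope2 - tcrit * np.sqrt(var2), slope2 + tcrit * np.sqrt(var2)),
        )
        intercept1 = float(beta[0])
        intercept2 = float(beta[0] - beta[2] * bp)
        slopes = (slope1, slope2)
        intercepts = (intercept1, intercept2)
    else:
        m1 = x <= bp
        slopes, intercepts, cis, resid = [], [], [], np.empty_like(y)
        rss = 0.0
        for mask in (m1, ~m1):
            xi, yi = x[mask], y[mask]
            design = np.column_stack([np.ones(xi.size), xi])
            beta, *_ = np.linalg.lstsq(design, yi, rcond=None)
            ri = yi - design @ beta
            resid[mask] = ri
            rss_i = float(ri @ ri)
            rss += rss_i
            dof = max(xi.size - 2, 1)
            cov = _ols_cov(design, rss_i, dof)
            tcrit = sps.t.ppf(0.5 + conf / 2.0, dof)
            half = tcrit * np.sqrt(cov[1, 1])
            slopes.append(float(beta[1]))
            intercepts.append(float(beta[0]))
            cis.append((beta[1] - half, beta[1] + half))
        slopes, intercepts, cis = tuple(slopes), tuple(intercepts), tuple(cis)

    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return SegmentedFit(
        breakpoint=float(bp),
        slopes=tuple(slopes),
        intercepts=tuple(intercepts),
        r_squared=r2,
        slope_cis=tuple(cis),
        residuals=resid,
        rss=rss,
        continuous=continuous,
    )


def _ols_cov(design, rss, dof):
    xtx_inv = np.linalg.pinv(design.T @ design)
    return (rss / dof) * xtx_inv


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float


def two_sample_t(
    a: np.ndarray | None = None,
    b: np.ndarray | None = None,
    *,
    stats_a: tuple[float, float, int] | None = None,
    stats_b: tuple[float, float, int] | None = None,
) -> TTestResult:
    """Pooled-variance two-sided two-sample t-test.

    Accepts either raw samples (``a``, ``b``) or (mean, sd, n) summary
    triples (``stats_a``, ``stats_b``).
    """
    if a is not None and b is not None:
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        if a.size < 2 or b.size < 2:
            raise InvalidInputError("need at least two observations per group")
        if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
            if np.mean(a) == np.mean(b):
                return TTestResult(0.0, a.size + b.size - 2, 1.0)
            raise InvalidInputError("both groups are degenerate (zero variance)")
        res = sps.ttest_ind(a, b, equal_var=True)
        return TTestResult(float(res.statistic), float(a.size + b.size - 2), float(res.pvalue))
    if stats_a is not None and stats_b is not None:
        (m1, s1, n1), (m2, s2, n2) = stats_a, stats_b
        if n1 < 2 or n2 < 2:
            raise InvalidInputError("need at least two observations per group")
        if s1 == 0 and s2 == 0 and m1 != m2:
            raise InvalidInputError("both groups are degenerate (zero variance)")
        res = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
        return TTestResult(float(res.statistic), float(n1 + n2 - 2), float(res.pvalue))
    raise InvalidInputError("provide either raw samples or summary statistics for both groups")


class AssumptionChecks(NamedTuple):
    shapiro_p: float  # minimum Shapiro-Wilk p over the samples
    bartlett_p: float  # NaN when fewer than two samples are given
    passed: bool  # all available checks above the 0.05 convention


def assumption_checks(*samples: Sequence[float], alpha: float = 0.05) -> AssumptionChecks:
    """Shapiro-Wilk normality and Bartlett homoscedasticity checks.

    Normality is tested per sample and the smallest p reported; Bartlett
    is computed across samples when two or more are given.  ``passed``
    is True when every computed p exceeds ``alpha`` (the p > 0.05
    validation convention).
    """
    if not samples:
        raise InvalidInputError("at least one sample required")
    arrays = [np.asarray(s, float) for s in samples]
    if any(a.size < 3 for a in arrays):
        raise InvalidInputError("each sample needs at least three observations")
    shapiro_p = min(float(sps.shapiro(a).pvalue) for a in arrays)
    bartlett_p = (
        float(sps.bartlett(*arrays).pvalue) if len(arrays) >= 2 else float("nan")
    )
    passed = shapiro_p > alpha and (np.isnan(bartlett_p) or bartlett_p > alpha)
    return AssumptionChecks(shapiro_p, bartlett_p, passed)


@dataclass
class TransitionStability:
    """Per-transition differences and across-replicate variance."""

    transitions: np.ndarray  # labels of the later transition of each pair
    differences: np.ndarray  # (replicates, n_transitions - 1)
    variances: np.ndarray
    stable_at: float | None  # first transition with variance <= tol


def transition_stability(
    series: np.ndarray,
    tol: float,
    transitions: np.ndarray | None = None,
) -> TransitionStability:
    """Differences between subsequent transitions and their stability point.

    ``series`` is a (replicates x transitions) matrix of a metric
    measured at every environmental transition.  For each replicate the
    difference d_t = m_t - m_(t-1) is computed; the variance of d_t
    across replicates is evaluated per transition, and the first
    transition where it drops to ``tol`` or below is reported (None if
    never).
    """
    arr = np.asarray(series, float)
    if arr.ndim != 2:
        raise InvalidInputError("series must be a 2-D replicate x transition matrix")
    n_rep, n_tr = arr.shape
    if n_rep < 2:
        raise InvalidInputError("need at least two replicates")
    if n_tr < 3:
        raise InvalidInputError("need at least three transitions")
    if transitions is None:
        transitions = np.arange(1, n_tr + 1, dtype=float)
    transitions = np.asarray(transitions, float)
    if transitions.size != n_tr:
        raise InvalidInputError("transition labels must match series length")
    diffs = np.diff(arr, axis=1)
    variances = diffs.var(axis=0, ddof=1)
    below = np.flatnonzero(variances <= tol)
    stable_at = float(transitions[1:][below[0]]) if below.size else None
    return TransitionStability(transitions[1:], diffs, variances, stable_at)


def fits_to_csv(fits: dict[str, SegmentedFit], path) -> None:
    """Write fit tables (one row per phase per series) as CSV."""
    rows = []
    for name, f in fits.items():
        for row in f.as_rows():
            rows.append({"series": name, **row})
    pd.DataFrame(rows).to_csv(path, index=False)
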