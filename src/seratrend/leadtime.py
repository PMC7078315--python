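"""Smoothed score trajectories and threshold-crossing lead time.

Per-visit model scores of cases are pooled on a common time axis (years to
diagnosis, decreasing towards zero) and smoothed with locally weighted
quadratic regression (loess: tricube weights, degree 2).  The crossing time
is the earliest time at which the smoothed curve enters — and stays above —
the model's positivity threshold through to diagnosis.  Comparing the
crossing of a candidate model against the reference cut-off model gives the
lead-time gain in months.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GRID_SIZE = 200
DEFAULT_SPAN = 0.75


@dataclass
class TrajectoryCurve:
    """Loess fit of pooled (time, score) points on a regular grid.

    ``grid`` is ordered from the earliest time (largest years-to-diagnosis)
    towards diagnosis at zero."""

    grid: np.ndarray
    fitted: np.ndarray
    se: np.ndarray
    span: float

    @property
    def band(self) -> tuple[np.ndarray, np.ndarray]:
        return self.fitted - 1.96 * self.se, self.fitted + 1.96 * self.se


@dataclass
class CrossingResult:
    """Years before diagnosis at which the curve becomes and stays positive;
    ``crossing_time`` is None when the curve never clears the threshold."""

    crossing_time: float | None
    threshold: float


def _loess_weights(t: np.ndarray, x0: float, q: int) -> np.ndarray:
    d = np.abs(t - x0)
    h = np.sort(d)[q - 1]
    if h == 0:
        h = np.max(d) if np.max(d) > 0 else 1.0
    w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
    return w


def _local_quadratic(t, y, x0, q):
    """Weighted degree-2 fit at x0; returns (value, hat-row vector l)."""
    w = _loess_weights(t, x0, q)
    active = w > 0
    B = np.column_stack([np.ones(active.sum()), t[active] - x0,
                         (t[active] - x0) ** 2])
    W = w[active]
    A = (B * W[:, None]).T @ B
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        Ainv = np.linalg.pinv(A)
    # fitted value at x0 = first row of Ainv @ B' W y  => hat row on y
    l_active = (Ainv @ (B * W[:, None]).T)[0]
    l = np.zeros(len(t))
    l[active] = l_active
    return float(l @ y), l


def fit_trajectory(points, span: float = DEFAULT_SPAN) -> TrajectoryCurve:
    """Loess smooth of pooled (time, score) points.

    ``points`` is an iterable of (years_to_diagnosis, score) pairs.  The fit
    is evaluated on a 200-point grid over the observed time range, with
    pointwise standard errors from the linear-smoother hat rows and a global
    residual variance estimate.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (time, score) pairs")
    if len(pts) < 10:
        raise ValueError("need at least 10 points to smooth")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    t, y = pts[:, 0], pts[:, 1]
    q = int(np.ceil(span * len(t)))
    if q < 4:
        raise ValueError(
            f"span {span} supports only {q} local points; increase the span")

    # residual variance from fits at the data points themselves
    resid_fit = np.array([_local_quadratic(t, y, x0, q)[0] for x0 in t])
    resid = y - resid_fit
    trace_l = 0.0
    for x0 in t:
        _, l = _local_quadratic(t, y, x0, q)
        trace_l += l[np.argmin(np.abs(t - x0))]
    dof = max(1.0, len(t) - trace_l)
    sigma2 = float(resid @ resid) / dof

    grid = np.linspace(t.max(), t.min(), GRID_SIZE)  # earliest -> diagnosis
    fitted = np.empty(GRID_SIZE)
    se = np.empty(GRID_SIZE)
    for i, x0 in enumerate(grid):
        val, l = _local_quadratic(t, y, x0, q)
        fitted[i] = val
        se[i] = np.sqrt(sigma2 * float(l @ l))
    if not np.all(np.isfinite(fitted)):
        raise ValueError("loess fit produced non-finite values")
    return TrajectoryCurve(grid=grid, fitted=fitted, se=se, span=span)


def crossing_time(curve: TrajectoryCurve, threshold: float,
                  mode: str = "sustained") -> CrossingResult:
    """Threshold crossing scanning from the earliest time towards diagnosis.

    ``sustained`` (default): the first time after which the curve stays at
    or above the threshold through to diagnosis — spurious early blips are
    ignored.  ``first_touch``: the first time the curve reaches the
    threshold at all.  Crossings are linearly interpolated between grid
    points; the result is None if the curve never qualifies.
    """
    if mode not in ("sustained", "first_touch"):
        raise ValueError(f"unknown crossing mode {mode!r}")
    g, f = curve.grid, curve.fitted  # g decreasing towards diagnosis
    above = f >= threshold
    if mode == "sustained":
        if not above[-1]:
            return CrossingResult(None, threshold)
        # walk backwards from diagnosis to find the start of the final run
        i = len(above) - 1
        while i > 0 and above[i - 1]:
            i -= 1
        if i == 0:
            return CrossingResult(float(g[0]), threshold)
    else:
        idx = np.flatnonzero(above)
        if idx.size == 0:
            return CrossingResult(None, threshold)
        i = int(idx[0])
        if i == 0:
            return CrossingResult(float(g[0]), threshold)
    # interpolate between grid[i-1] (below) and grid[i] (above)
    f0, f1 = f[i - 1], f[i]
    t0, t1 = g[i - 1], g[i]
    frac = (threshold - f0) / (f1 - f0) if f1 != f0 else 1.0
    return CrossingResult(float(t0 + frac * (t1 - t0)), threshold)


def lead_time_gain(model_curve: TrajectoryCurve, ref_curve: TrajectoryCurve,
                   model_threshold: float, ref_threshold: float,
                   mode: str = "sustained") -> float | None:
    """How many months earlier the model becomes test-positive than the
    reference; positive values favour the model.  None when either crossing
    is undefined.
    """
    mc = crossing_time(model_curve, model_threshold, mode)
    rc = crossing_time(ref_curve, ref_threshold, mode)
    if mc.crossing_time is None or rc.crossing_time is None:
        return None
    return (mc.crossing_time - rc.crossing_time) * 12.0
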