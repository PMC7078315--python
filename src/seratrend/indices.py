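"""Trend indices: scalar summaries of a serial marker trajectory.

Each subject's series of (age, log10 concentration) points for one marker is
collapsed to a single number by one of five transforms:

* Index 1 — mean derivative: the average of the gradients between
  consecutive measurement pairs.
* Index 2 — area: the average per-interval trapezoidal area under the
  series.
* Index 3 — coefficient of variation of the values; time plays no role.
* Index 4 — centre of mass: sum of age x value over the sum of ages, a
  weighted mean of the values that damps any age-concentration relationship.
* Index 5 — the final measurement (the simple cut-off comparator).

Features are named ``MARKER{i}``, e.g. ``CA125{3}`` for the CV of the serial
CA125 values.  A feature matrix assembles these per analysis unit: one row
per subject (terminal mode), or one row per subject-visit using only the
measurements available up to that visit (rolling mode, used for per-visit
score trajectories and visit-level specificity).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortSet

logger = logging.getLogger(__name__)

INDEX_NUMBERS = (1, 2, 3, 4, 5)

#: |mean| below which the CV of log10 values is numerically fragile
CV_MEAN_WARN = 0.1


@dataclass
class MarkerSeries:
    """Ordered (age in years, log10 value) trajectory of one marker for one
    subject."""

    t: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape or self.t.ndim != 1:
            raise ValueError("t and y must be 1-d arrays of equal length")
        if len(self.t) < 1:
            raise ValueError("series must contain at least one point")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("ages must be strictly increasing")

    @property
    def k(self) -> int:
        return len(self.t)


class IndexUndefined(Exception):
    """The index needs more points than the series provides; the unit's
    feature is recorded as absent, not zero."""


def index1_mean_derivative(s: MarkerSeries, variant: str = "mean") -> float:
    """Average gradient between consecutive measurement pairs.

    ``variant='mean'`` (default) is the unweighted mean of the k-1
    consecutive gradients.  ``variant='telescoping'`` weights each gradient
    by its interval length, which telescopes to the overall secant slope
    (y_k - y_1)/(t_k - t_1).
    """
    if s.k < 2:
        raise IndexUndefined("mean derivative needs at least 2 points")
    dt = np.diff(s.t)
    dy = np.diff(s.y)
    if variant == "mean":
        return float(np.mean(dy / dt))
    if variant == "telescoping":
        return float((s.y[-1] - s.y[0]) / (s.t[-1] - s.t[0]))
    raise ValueError(f"unknown index1 variant {variant!r}")


def index2_area(s: MarkerSeries, variant: str = "trapezoid") -> float:
    """Average per-interval area under the time series.

    ``variant='trapezoid'`` (default): mean over the k-1 intervals of the
    trapezoid area (t_{j+1}-t_j)(y_j+y_{j+1})/2.  ``variant='to_last'``:
    the alternative reading sum_j (t_k - t_j) y_j / k using time to the most
    recent measurement.
    """
    if s.k < 2:
        raise IndexUndefined("area needs at least 2 points")
    if variant == "trapezoid":
        areas = np.diff(s.t) * (s.y[:-1] + s.y[1:]) / 2.0
        return float(np.mean(areas))
    if variant == "to_last":
        return float(np.sum((s.t[-1] - s.t) * s.y) / s.k)
    raise ValueError(f"unknown index2 variant {variant!r}")


def index3_cv(s: MarkerSeries) -> float:
    """Coefficient of variation of the values (sample SD / mean); time is
    ignored."""
    if s.k < 2:
        raise IndexUndefined("CV needs at least 2 points")
    mean = float(np.mean(s.y))
    if mean == 0.0:
        raise ValueError("CV undefined: mean of values is zero")
    if abs(mean) < CV_MEAN_WARN:
        logger.warning(
            "index3_cv: |mean|=%.3g < %.1f, CV on log-scale values is "
            "numerically fragile", abs(mean), CV_MEAN_WARN,
        )
    return float(np.std(s.y, ddof=1) / mean)


def index4_center_of_mass(s: MarkerSeries) -> float:
    """Centre of mass: sum(t_j * y_j) / sum(t_j), an age-weighted mean."""
    if np.any(s.t <= 0):
        raise ValueError("centre of mass needs strictly positive ages")
    return float(np.sum(s.t * s.y) / np.sum(s.t))


def index5_last(s: MarkerSeries) -> float:
    """The final measurement of the series."""
    return float(s.y[-1])


def compute_index(s: MarkerSeries, number: int, *, index1_variant: str = "mean",
                  index2_variant: str = "trapezoid") -> float:
    if number == 1:
        return index1_mean_derivative(s, variant=index1_variant)
    if number == 2:
        return index2_area(s, variant=index2_variant)
    if number == 3:
        return index3_cv(s)
    if number == 4:
        return index4_center_of_mass(s)
    if number == 5:
        return index5_last(s)
    raise ValueError(f"unknown index number {number}")


def feature_name(marker: str, number: int) -> str:
    return f"{marker}{{{number}}}"


_FEATURE_RE = re.compile(r"^(?P<marker>.+)\{(?P<index>[1-5])\}$")


def parse_feature_name(name: str) -> tuple[str, int]:
    m = _FEATURE_RE.match(name)
    if m is None:
        raise ValueError(f"not a MARKER{{index}} feature name: {name!r}")
    return m.group("marker"), int(m.group("index"))


#: columns of a feature matrix that are not features
META_COLUMNS = ("subject_id", "visit_age", "label")


def feature_columns(fm: pd.DataFrame) -> list[str]:
    return [c for c in fm.columns if c not in META_COLUMNS]


def build_feature_matrix(cohort: CohortSet, indices=INDEX_NUMBERS,
                         mode: str = "terminal", *,
                         index1_variant: str = "mean",
                         index2_variant: str = "trapezoid") -> pd.DataFrame:
    """Assemble the unit x feature matrix from a log-scale, filtered cohort.

    Terminal mode produces one row per subject from its full retained series;
    rolling mode produces one row per (subject, visit) from the measurements
    at or before that visit, so a subject's last rolling row equals its
    terminal row.  Indices needing at least two points are absent (NaN) for
    single-visit units.  Returns a DataFrame indexed by unit id with the
    metadata columns ``subject_id``, ``visit_age``, ``label`` followed by the
    ``MARKER{i}`` features.
    """
    if mode not in ("terminal", "rolling"):
        raise ValueError(f"unknown mode {mode!r}")
    indices = sorted(set(indices))
    unknown = [i for i in indices if i not in INDEX_NUMBERS]
    if unknown:
        raise ValueError(f"unknown index numbers {unknown}")
    if cohort.scale != "log10":
        raise ValueError("feature matrix requires a log10-scale cohort")

    rows = []
    unit_ids = []
    n_undefined = 0
    for s in cohort.subjects:
        label = 1 if s.is_case else 0
        cut_offsets = range(1, len(s.visits) + 1) if mode == "rolling" \
            else [len(s.visits)]
        for cut in cut_offsets:
            visits = s.visits[:cut]
            row: dict[str, float] = {
                "subject_id": s.id,
                "visit_age": visits[-1].age_years,
                "label": label,
            }
            for marker in cohort.markers:
                pts = [(v.age_years, v.values[marker]) for v in visits
                       if marker in v.values]
                series = None
                if pts:
                    t, y = zip(*pts)
                    series = MarkerSeries(np.array(t), np.array(y))
                for num in indices:
                    col = feature_name(marker, num)
                    if series is None:
                        row[col] = np.nan
                        n_undefined += 1
                        continue
                    try:
                        row[col] = compute_index(
                            series, num, index1_variant=index1_variant,
                            index2_variant=index2_variant)
                    except IndexUndefined:
                        row[col] = np.nan
                        n_undefined += 1
            rows.append(row)
            unit_ids.append(s.id if mode == "terminal"
                            else f"{s.id}@{visits[-1].age_years:.4f}")
    if n_undefined:
        logger.info("build_feature_matrix: %d undefined feature cells "
                    "(series too short)", n_undefined)
    fm = pd.DataFrame(rows, index=pd.Index(unit_ids, name="unit_id"))
    if fm.index.has_duplicates:
        raise ValueError("duplicate unit ids in feature matrix")
    return fm


def complete_cases(fm: pd.DataFrame, features: list[str]) -> pd.DataFrame:
    """Units with every requested feature present; logs the dropped count."""
    sub = fm[list(META_COLUMNS) + list(features)]
    kept = sub.dropna(subset=features)
    if len(kept) < len(sub):
        logger.info("complete_cases: dropped %d/%d units with absent features",
                    len(sub) - len(kept), len(sub))
    return kept
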