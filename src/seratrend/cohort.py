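"""Cohort data model, long-format I/O, and the sample-inclusion rules.

The analysis operates on serial serum measurements from a nested case-control
screening study: each subject (a screened woman) contributes an ordered series
of visits, each visit carrying concentrations for a panel of markers.  Cases
additionally carry the time from each draw to clinical diagnosis.

Two inclusion rules define which samples enter modelling and evaluation:

* ``modelling_filter`` — keep annual screening samples only, drop case samples
  taken more than 5 years before diagnosis, and drop borderline-tumour
  subjects entirely.
* ``evaluation_subset`` — restrict cases to those whose final retained sample
  falls inside an evaluation window (within 1 year of diagnosis, or within
  1-2 years after removing the final year's samples).  Controls are never
  excluded by time rules.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

CSV_COLUMNS = [
    "subject_id",
    "group",
    "tumour_type",
    "age_years",
    "months_to_dx",
    "sample_kind",
    "marker",
    "value",
]

GROUPS = ("case", "control")
TUMOUR_TYPES = ("TypeI", "TypeII", "Borderline", "none")
SAMPLE_KINDS = ("annual_screen", "other")

#: tolerance (years) for the implied diagnosis age being constant across a
#: case's visits
DX_AGE_TOL_YEARS = 0.1


class CohortError(ValueError):
    """Raised for schema or invariant violations in cohort data."""


@dataclass
class Visit:
    """One blood draw: age at draw, timing relative to diagnosis, and the
    marker concentrations measured in that sample."""

    age_years: float
    months_to_diagnosis: float | None
    sample_kind: str
    values: dict[str, float] = field(default_factory=dict)


@dataclass
class Subject:
    id: str
    group: str
    tumour_type: str
    visits: list[Visit] = field(default_factory=list)

    @property
    def is_case(self) -> bool:
        return self.group == "case"

    @property
    def final_visit(self) -> Visit:
        return self.visits[-1]


@dataclass
class CohortSet:
    """A collection of subjects sharing one marker panel.

    ``scale`` records whether concentrations are raw assay units or base-10
    logarithms; the log transform refuses to run twice.
    """

    subjects: list[Subject]
    markers: list[str]
    provenance: str = ""
    scale: str = "raw"

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def cases(self) -> list[Subject]:
        return [s for s in self.subjects if s.is_case]

    @property
    def controls(self) -> list[Subject]:
        return [s for s in self.subjects if not s.is_case]

    def subject(self, sid: str) -> Subject:
        for s in self.subjects:
            if s.id == sid:
                return s
        raise KeyError(sid)


def validate_cohort(cohort: CohortSet) -> None:
    """Check the structural invariants; raise :class:`CohortError` on failure."""
    seen: set[str] = set()
    panel = set(cohort.markers)
    for s in cohort.subjects:
        if s.id in seen:
            raise CohortError(f"duplicate subject id {s.id!r}")
        seen.add(s.id)
        if s.group not in GROUPS:
            raise CohortError(f"subject {s.id}: unknown group {s.group!r}")
        if s.tumour_type not in TUMOUR_TYPES:
            raise CohortError(f"subject {s.id}: unknown tumour type {s.tumour_type!r}")
        if (s.tumour_type == "none") != (s.group == "control"):
            raise CohortError(
                f"subject {s.id}: tumour_type {s.tumour_type!r} inconsistent with "
                f"group {s.group!r}"
            )
        ages = [v.age_years for v in s.visits]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise CohortError(f"subject {s.id}: visit ages not strictly increasing")
        dx_ages = []
        for v in s.visits:
            if v.sample_kind not in SAMPLE_KINDS:
                raise CohortError(
                    f"subject {s.id}: unknown sample kind {v.sample_kind!r}"
                )
            if s.is_case:
                if v.months_to_diagnosis is None:
                    raise CohortError(
                        f"subject {s.id}: case visit at age {v.age_years} lacks "
                        "months_to_dx"
                    )
                if v.months_to_diagnosis < 0:
                    raise CohortError(
                        f"subject {s.id}: negative months_to_dx at age {v.age_years}"
                    )
                dx_ages.append(v.age_years + v.months_to_diagnosis / 12.0)
            elif v.months_to_diagnosis is not None:
                raise CohortError(
                    f"subject {s.id}: control visit carries months_to_dx"
                )
            for m, val in v.values.items():
                if m not in panel:
                    raise CohortError(
                        f"subject {s.id}: marker {m!r} not in panel {cohort.markers}"
                    )
                if cohort.scale == "raw" and not val > 0:
                    raise CohortError(
                        f"subject {s.id}: non-positive concentration {val} for "
                        f"{m} at age {v.age_years}"
                    )
                if not math.isfinite(val):
                    raise CohortError(
                        f"subject {s.id}: non-finite value for {m} at age {v.age_years}"
                    )
        if dx_ages and max(dx_ages) - min(dx_ages) > DX_AGE_TOL_YEARS:
            raise CohortError(
                f"subject {s.id}: implied diagnosis age varies by "
                f"{max(dx_ages) - min(dx_ages):.3f} yr across visits (tol "
                f"{DX_AGE_TOL_YEARS})"
            )


def read_cohort(path, scale: str = "raw") -> CohortSet:
    """Read a long-format cohort CSV (one row per subject-visit-marker).

    Rows for one (subject, age) are collated into a single :class:`Visit`.
    The file must carry the header ``subject_id,group,tumour_type,age_years,
    months_to_dx,sample_kind,marker,value``.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"cohort file {path} missing columns {missing}")
    if df.duplicated(subset=["subject_id", "age_years", "marker"]).any():
        dup = df[df.duplicated(subset=["subject_id", "age_years", "marker"], keep=False)]
        raise CohortError(
            "duplicate (subject, age, marker) rows, first at line "
            f"{dup.index[0] + 2}"
        )
    if scale == "raw":
        bad = df.index[~(df["value"] > 0)]
        if len(bad):
            raise CohortError(
                f"non-positive value at line {bad[0] + 2}: "
                f"{df.loc[bad[0]].to_dict()}"
            )

    markers = list(pd.unique(df["marker"].dropna()))
    subjects: list[Subject] = []
    for sid, sdf in df.groupby("subject_id", sort=False):
        group = sdf["group"].iloc[0]
        ttype = sdf["tumour_type"].iloc[0]
        visits = []
        for age, vdf in sorted(sdf.groupby("age_years"), key=lambda kv: kv[0]):
            mtd = vdf["months_to_dx"].iloc[0]
            mtd = None if pd.isna(mtd) else float(mtd)
            if group == "case" and mtd is None:
                raise CohortError(
                    f"subject {sid}: case visit at age {age} lacks months_to_dx"
                )
            visits.append(
                Visit(
                    age_years=float(age),
                    months_to_diagnosis=mtd,
                    sample_kind=str(vdf["sample_kind"].iloc[0]),
                    values={
                        str(r.marker): float(r.value) for r in vdf.itertuples()
                    },
                )
            )
        subjects.append(Subject(id=str(sid), group=str(group),
                                tumour_type=str(ttype), visits=visits))
    cohort = CohortSet(subjects=subjects, markers=markers,
                       provenance=f"read from {path}", scale=scale)
    validate_cohort(cohort)
    return cohort


def write_cohort(cohort: CohortSet, path) -> None:
    """Write the long-format CSV (comma, UTF-8, '.' decimal)."""
    rows = []
    for s in cohort.subjects:
        for v in s.visits:
            for m in cohort.markers:
                if m not in v.values:
                    continue
                rows.append(
                    (s.id, s.group, s.tumour_type, v.age_years,
                     v.months_to_diagnosis, v.sample_kind, m, v.values[m])
                )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def modelling_filter(cohort: CohortSet) -> CohortSet:
    """Apply the sample-inclusion rules for model building.

    Keeps only annual screening samples, drops case samples taken more than
    60 months before diagnosis, removes borderline subjects entirely, and
    drops subjects left without any visits.  Idempotent.
    """
    kept: list[Subject] = []
    n_visits_dropped = 0
    n_subjects_dropped = 0
    for s in cohort.subjects:
        if s.tumour_type == "Borderline":
            n_subjects_dropped += 1
            continue
        visits = [
            v
            for v in s.visits
            if v.sample_kind == "annual_screen"
            and (v.months_to_diagnosis is None or v.months_to_diagnosis <= 60.0)
        ]
        n_visits_dropped += len(s.visits) - len(visits)
        if not visits:
            n_subjects_dropped += 1
            continue
        kept.append(replace(s, visits=visits))
    logger.info(
        "modelling_filter: dropped %d visits and %d subjects (%d subjects kept)",
        n_visits_dropped, n_subjects_dropped, len(kept),
    )
    return CohortSet(subjects=kept, markers=list(cohort.markers),
                     provenance=cohort.provenance, scale=cohort.scale)


EVALUATION_WINDOWS = ("within_1yr", "yr1_to_2")


def evaluation_subset(cohort: CohortSet, window: str) -> CohortSet:
    """Restrict cases to an evaluation window relative to diagnosis.

    ``within_1yr``: keep cases whose final retained sample is at most 12
    months before diagnosis.  ``yr1_to_2``: first discard all case samples
    within 12 months of diagnosis, then keep cases whose new final sample is
    at most 24 months before diagnosis.  Controls are always retained.
    Assumes :func:`modelling_filter` has already been applied.
    """
    if window not in EVALUATION_WINDOWS:
        raise CohortError(f"unknown evaluation window {window!r}")
    kept: list[Subject] = []
    n_cases_dropped = 0
    for s in cohort.subjects:
        if not s.is_case:
            kept.append(replace(s, visits=list(s.visits)))
            continue
        visits = list(s.visits)
        if window == "yr1_to_2":
            visits = [v for v in visits if v.months_to_diagnosis > 12.0]
        limit = 12.0 if window == "within_1yr" else 24.0
        if visits and visits[-1].months_to_diagnosis <= limit:
            kept.append(replace(s, visits=visits))
        else:
            n_cases_dropped += 1
    logger.info(
        "evaluation_subset(%s): dropped %d cases (%d subjects kept)",
        window, n_cases_dropped, len(kept),
    )
    return CohortSet(subjects=kept, markers=list(cohort.markers),
                     provenance=cohort.provenance, scale=cohort.scale)


def log10_transform(cohort: CohortSet) -> CohortSet:
    """Replace every concentration by its base-10 logarithm.

    Model generation operates on the log scale throughout.  The output is
    tagged ``scale='log10'``; applying the transform twice is an error.
    """
    if cohort.scale == "log10":
        raise CohortError("cohort is already log10-scale")
    subjects = []
    for s in cohort.subjects:
        visits = []
        for v in s.visits:
            for m, val in v.values.items():
                if not val > 0:
                    raise CohortError(
                        f"subject {s.id}: non-positive value {val} for {m}"
                    )
            visits.append(
                replace(v, values={m: math.log10(val) for m, val in v.values.items()})
            )
        subjects.append(replace(s, visits=visits))
    return CohortSet(subjects=subjects, markers=list(cohort.markers),
                     provenance=cohort.provenance, scale="log10")
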