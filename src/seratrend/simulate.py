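"""Synthetic nested case-control screening cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes: each
subject has a stable subject-specific log-scale baseline for every marker,
annual screening visits with small timing jitter, and — for cases — a
change-point rise in informative markers that begins a fixed number of months
before diagnosis.  The generative model for the log10 concentration of marker
*m* at a visit is

    log10 y = b_m + s_m(type) * max(0, t_visit - t_changepoint)  + e,
    e ~ Normal(0, log10(1 + CV_m)),

where ``b_m ~ Normal(baseline_log10_mean, baseline_between_subject_sd)`` is
the subject's baseline, ``s_m(type)`` a tumour-type-specific slope in log10
units per year, and the noise SD approximates a multiplicative assay error
with coefficient of variation ``CV_m`` (exact as CV -> 0).

The default panel reproduces the study conditions of the serum set the
analysis was designed for: 31 controls and 49 cases (9 Type I, 30 Type II,
10 borderline), 3-10 annual visits each, and ten markers with assay CVs
between 4% and 22%.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .cohort import CohortSet, Subject, Visit, validate_cohort


@dataclass
class MarkerKinetics:
    """Generative parameters for one marker.

    Slopes are in log10 units per year past the change point; a marker with
    all slopes zero is uninformative.  ``changepoint_tau`` is months before
    diagnosis at which case trajectories begin to rise.
    """

    name: str
    baseline_log10_mean: float
    baseline_between_subject_sd: float = 0.15
    assay_cv: float = 0.10
    changepoint_tau: float = 24.0
    rise_slope_type1: float = 0.0
    rise_slope_type2: float = 0.0
    rise_slope_borderline: float = 0.0

    def __post_init__(self) -> None:
        if self.assay_cv < 0:
            raise ValueError(f"{self.name}: assay_cv must be >= 0")
        if self.changepoint_tau < 0:
            raise ValueError(f"{self.name}: changepoint_tau must be >= 0")

    @property
    def informative(self) -> bool:
        return any(
            s != 0.0
            for s in (self.rise_slope_type1, self.rise_slope_type2,
                      self.rise_slope_borderline)
        )

    def slope_for(self, tumour_type: str) -> float:
        return {
            "TypeI": self.rise_slope_type1,
            "TypeII": self.rise_slope_type2,
            "Borderline": self.rise_slope_borderline,
            "none": 0.0,
        }[tumour_type]

    @property
    def noise_sd(self) -> float:
        # log10(1+CV) matches a multiplicative error of relative size CV
        return math.log10(1.0 + self.assay_cv)


def default_markers() -> list[MarkerKinetics]:
    """The ten-marker screening panel with study-condition kinetics.

    Assay CVs are the intra-assay CVs of the commercial immunoassays used for
    each marker.  Baselines are plausible post-menopausal serum levels on the
    log10 scale of each assay's reporting units.  CA125 rises strongly before
    diagnosis in Type II disease; HE4, CHI3L1, PEBP4 and AGR2 rise more
    modestly; the remaining candidates are kept uninformative so the selection
    ensemble has genuine noise to reject.
    """
    return [
        MarkerKinetics("CA125", baseline_log10_mean=1.10, assay_cv=0.04,
                       baseline_between_subject_sd=0.25, changepoint_tau=24.0,
                       rise_slope_type1=0.25, rise_slope_type2=0.55,
                       rise_slope_borderline=0.15),
        MarkerKinetics("HE4", baseline_log10_mean=1.65, assay_cv=0.08,
                       baseline_between_subject_sd=0.12, changepoint_tau=20.0,
                       rise_slope_type1=0.12, rise_slope_type2=0.30,
                       rise_slope_borderline=0.05),
        MarkerKinetics("CHI3L1", baseline_log10_mean=1.60, assay_cv=0.14,
                       baseline_between_subject_sd=0.20, changepoint_tau=30.0,
                       rise_slope_type1=0.10, rise_slope_type2=0.20,
                       rise_slope_borderline=0.05),
        MarkerKinetics("PEBP4", baseline_log10_mean=1.30, assay_cv=0.20,
                       baseline_between_subject_sd=0.18, changepoint_tau=30.0,
                       rise_slope_type1=0.12, rise_slope_type2=0.15),
        MarkerKinetics("AGR2", baseline_log10_mean=0.90, assay_cv=0.18,
                       baseline_between_subject_sd=0.18, changepoint_tau=26.0,
                       rise_slope_type1=0.08, rise_slope_type2=0.15),
        MarkerKinetics("LRG1", baseline_log10_mean=1.40, assay_cv=0.16,
                       baseline_between_subject_sd=0.12),
        MarkerKinetics("FSTL1", baseline_log10_mean=1.00, assay_cv=0.11,
                       baseline_between_subject_sd=0.12),
        MarkerKinetics("SLPI", baseline_log10_mean=1.55, assay_cv=0.12,
                       baseline_between_subject_sd=0.10),
        MarkerKinetics("glycodelin", baseline_log10_mean=1.20, assay_cv=0.22,
                       baseline_between_subject_sd=0.20),
        MarkerKinetics("DNAH17", baseline_log10_mean=0.70, assay_cv=0.17,
                       baseline_between_subject_sd=0.15),
    ]


@dataclass
class SimConfig:
    """Cohort composition and visit schedule for the generator."""

    n_controls: int = 31
    n_type1: int = 9
    n_type2: int = 30
    n_borderline: int = 10
    age_at_entry_mean: float = 61.0
    age_at_entry_sd: float = 5.0
    visits_min: int = 3
    visits_max: int = 10
    visit_jitter_sd: float = 0.05
    months_to_dx_of_last_sample_max: float = 12.0
    markers: list[MarkerKinetics] = field(default_factory=default_markers)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_controls", "n_type1", "n_type2", "n_borderline"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.visits_min < 1:
            raise ValueError("visits_min must be >= 1")
        if self.visits_max < self.visits_min:
            raise ValueError("visits_max must be >= visits_min")
        if self.visit_jitter_sd < 0:
            raise ValueError("visit_jitter_sd must be >= 0")

    @property
    def n_cases(self) -> int:
        return self.n_type1 + self.n_type2 + self.n_borderline

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Generative parameters recorded for parameter-recovery tests."""

    config: SimConfig
    #: subject id -> (group, tumour_type)
    subject_groups: dict[str, tuple[str, str]]
    #: subject id -> age at diagnosis in years (cases only)
    diagnosis_age: dict[str, float]
    #: subject id -> {marker: baseline log10 value}
    baselines: dict[str, dict[str, float]]
    #: marker -> informative flag
    informative: dict[str, bool]

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config.to_dict(),
                "subject_groups": self.subject_groups,
                "diagnosis_age": self.diagnosis_age,
                "baselines": self.baselines,
                "informative": self.informative,
            },
            indent=2,
            sort_keys=True,
        )


def _visit_ages(rng: np.random.Generator, entry: float, n: int,
                jitter_sd: float) -> np.ndarray:
    """Entry age + annual grid + Normal jitter, nudged to strict ordering."""
    ages = entry + np.arange(n, dtype=float)
    if jitter_sd > 0:
        ages = ages + rng.normal(0.0, jitter_sd, size=n)
    ages = np.sort(ages)
    # enforce strict increase; jitter collisions are vanishingly rare but
    # the ordering invariant is hard
    for j in range(1, n):
        if ages[j] <= ages[j - 1]:
            ages[j] = ages[j - 1] + 1e-4
    return ages


def latent_log10(marker: MarkerKinetics, baseline: float, tumour_type: str,
                 age: float, dx_age: float | None) -> float:
    """Noise-free generative trajectory value (the analytic oracle)."""
    if dx_age is None:
        return baseline
    changepoint_age = dx_age - marker.changepoint_tau / 12.0
    years_past = max(0.0, age - changepoint_age)
    return baseline + marker.slope_for(tumour_type) * years_past


def generate_cohort(config: SimConfig) -> tuple[CohortSet, GroundTruth]:
    """Draw a cohort from the generative model; deterministic given the seed."""
    if config.n_cases + config.n_controls == 0:
        raise ValueError("empty cohort: all group sizes are zero")
    rng = np.random.default_rng(config.seed)

    roster: list[tuple[str, str, str]] = []
    for i in range(config.n_type1):
        roster.append((f"case_T1_{i:03d}", "case", "TypeI"))
    for i in range(config.n_type2):
        roster.append((f"case_T2_{i:03d}", "case", "TypeII"))
    for i in range(config.n_borderline):
        roster.append((f"case_BL_{i:03d}", "case", "Borderline"))
    for i in range(config.n_controls):
        roster.append((f"ctrl_{i:03d}", "control", "none"))

    subjects: list[Subject] = []
    subject_groups: dict[str, tuple[str, str]] = {}
    diagnosis_age: dict[str, float] = {}
    baselines: dict[str, dict[str, float]] = {}

    for sid, group, ttype in roster:
        entry = rng.normal(config.age_at_entry_mean, config.age_at_entry_sd)
        entry = float(np.clip(entry, 50.0, 74.0))  # screening-age entry window
        n_visits = int(rng.integers(config.visits_min, config.visits_max + 1))
        ages = _visit_ages(rng, entry, n_visits, config.visit_jitter_sd)

        dx_age: float | None = None
        if group == "case":
            gap_months = rng.uniform(0.0, config.months_to_dx_of_last_sample_max)
            dx_age = float(ages[-1] + gap_months / 12.0)
            diagnosis_age[sid] = dx_age

        base = {
            mk.name: float(
                rng.normal(mk.baseline_log10_mean, mk.baseline_between_subject_sd)
            )
            for mk in config.markers
        }
        baselines[sid] = base
        subject_groups[sid] = (group, ttype)

        visits = []
        for age in ages:
            mtd = None if dx_age is None else max(0.0, (dx_age - age) * 12.0)
            values = {}
            for mk in config.markers:
                mu = latent_log10(mk, base[mk.name], ttype, float(age), dx_age)
                noise = rng.normal(0.0, mk.noise_sd) if mk.noise_sd > 0 else 0.0
                values[mk.name] = 10.0 ** (mu + noise)
            visits.append(
                Visit(age_years=float(age), months_to_diagnosis=mtd,
                      sample_kind="annual_screen", values=values)
            )
        subjects.append(Subject(id=sid, group=group, tumour_type=ttype,
                                visits=visits))

    cohort = CohortSet(
        subjects=subjects,
        markers=[mk.name for mk in config.markers],
        provenance=f"simulated, seed={config.seed}",
        scale="raw",
    )
    validate_cohort(cohort)
    truth = GroundTruth(
        config=config,
        subject_groups=subject_groups,
        diagnosis_age=diagnosis_age,
        baselines=baselines,
        informative={mk.name: mk.informative for mk in config.markers},
    )
    return cohort, truth


def oracle_scores(config: SimConfig, cohort: CohortSet) -> dict[str, dict[str, float]]:
    """Noise-free latent log10 value of every marker at each subject's final visit.

    Regenerates the cohort from ``config`` (deterministic) to recover the
    subject baselines, and checks the given cohort matches.  Controls score
    exactly their baseline; a case's score grows with the rise slope and the
    time its final visit sits past the change point.
    """
    regen, truth = generate_cohort(config)
    ids = [s.id for s in cohort.subjects]
    if ids != [s.id for s in regen.subjects]:
        raise ValueError("cohort does not match config (subject roster differs)")
    for s, r in zip(cohort.subjects, regen.subjects):
        if len(s.visits) != len(r.visits) or any(
            abs(a.age_years - b.age_years) > 1e-9
            for a, b in zip(s.visits, r.visits)
        ):
            raise ValueError(
                f"cohort does not match config (visit schedule differs for {s.id})"
            )
    by_marker = {mk.name: mk for mk in config.markers}
    scores: dict[str, dict[str, float]] = {}
    for s in cohort.subjects:
        _, ttype = truth.subject_groups[s.id]
        dx = truth.diagnosis_age.get(s.id)
        final_age = s.final_visit.age_years
        scores[s.id] = {
            name: latent_log10(mk, truth.baselines[s.id][name], ttype,
                               final_age, dx)
            for name, mk in by_marker.items()
        }
    return scores


def benchmark_markers() -> list[MarkerKinetics]:
    """A 3-informative / 7-noise panel for parameter-recovery benchmarks.

    MK1 plays the role of the established marker (strong late rise); MK2 and
    MK3 are complementary candidates whose change points sit earlier, so a
    multimarker model can beat the single final-value cut-off.
    """
    informative = [
        MarkerKinetics("MK1", baseline_log10_mean=1.1, assay_cv=0.05,
                       baseline_between_subject_sd=0.20, changepoint_tau=18.0,
                       rise_slope_type1=0.35, rise_slope_type2=0.60),
        MarkerKinetics("MK2", baseline_log10_mean=1.5, assay_cv=0.10,
                       baseline_between_subject_sd=0.12, changepoint_tau=30.0,
                       rise_slope_type1=0.20, rise_slope_type2=0.35),
        MarkerKinetics("MK3", baseline_log10_mean=1.0, assay_cv=0.12,
                       baseline_between_subject_sd=0.15, changepoint_tau=36.0,
                       rise_slope_type1=0.15, rise_slope_type2=0.25),
    ]
    noise = [
        MarkerKinetics(f"NZ{i}", baseline_log10_mean=1.2, assay_cv=0.15,
                       baseline_between_subject_sd=0.15)
        for i in range(1, 8)
    ]
    return informative + noise


def benchmark_config(seed: int = 0) -> SimConfig:
    """Cohort at ~3x the scale of the reference evaluation set (28 cases,
    31 controls), with the benchmark 3-informative / 7-noise panel."""
    return SimConfig(
        n_controls=93,
        n_type1=18,
        n_type2=66,
        n_borderline=0,
        markers=benchmark_markers(),
        seed=seed,
    )
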