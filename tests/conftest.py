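import numpy as np
import pytest

from seratrend.cohort import CohortSet, Subject, Visit
from seratrend.simulate import SimConfig, generate_cohort


def make_case(sid, ages, months_to_dx_final, values_by_marker,
              tumour_type="TypeII", sample_kinds=None):
    """Build a case whose final visit is `months_to_dx_final` months before
    diagnosis, with earlier visits back-dated consistently."""
    ages = list(ages)
    dx_age = ages[-1] + months_to_dx_final / 12.0
    kinds = sample_kinds or ["annual_screen"] * len(ages)
    visits = [
        Visit(age_years=a, months_to_diagnosis=(dx_age - a) * 12.0,
              sample_kind=k,
              values={m: vals[i] for m, vals in values_by_marker.items()})
        for i, (a, k) in enumerate(zip(ages, kinds))
    ]
    return Subject(id=sid, group="case", tumour_type=tumour_type, visits=visits)


def make_control(sid, ages, values_by_marker, sample_kinds=None):
    kinds = sample_kinds or ["annual_screen"] * len(ages)
    visits = [
        Visit(age_years=a, months_to_diagnosis=None, sample_kind=k,
              values={m: vals[i] for m, vals in values_by_marker.items()})
        for i, (a, k) in enumerate(zip(ages, kinds))
    ]
    return Subject(id=sid, group="control", tumour_type="none", visits=visits)


@pytest.fixture
def tiny_cohort():
    """Two cases, one control, two markers, raw scale."""
    subjects = [
        make_case("c1", [60.0, 61.0, 62.0], 6.0,
                  {"CA125": [10.0, 20.0, 40.0], "HE4": [50.0, 50.0, 55.0]}),
        make_case("c2", [65.0, 66.0], 10.0,
                  {"CA125": [12.0, 30.0], "HE4": [60.0, 80.0]},
                  tumour_type="TypeI"),
        make_control("k1", [58.0, 59.0, 60.0],
                     {"CA125": [11.0, 12.0, 10.0], "HE4": [45.0, 44.0, 46.0]}),
    ]
    return CohortSet(subjects=subjects, markers=["CA125", "HE4"])


@pytest.fixture(scope="session")
def default_cohort():
    """The study-condition cohort from the generator (80 subjects)."""
    cohort, truth = generate_cohort(SimConfig(seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
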