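import numpy as np
import pytest

from graphsurv.records import PatientRecord


def make_record(id="P1", age=60.0, sex="male", histology="adenocarcinoma",
                lobe="LUL", stage="IA", os_time=60.0, os_event=0,
                rfs_time=55.0, rfs_event=0, split=None) -> PatientRecord:
    return PatientRecord(id, age, sex, histology, lobe, stage,
                         os_time, os_event, rfs_time, rfs_event, split)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def six_patients():
    """Hand-varied records exercising every similarity component."""
    return [
        make_record("A", 60, "male", "adenocarcinoma", "LUL", "IA", 70, 0, 65, 0),
        make_record("B", 63, "male", "adenocarcinoma", "LUL", "IA", 40, 1, 35, 1),
        make_record("C", 72, "female", "squamous", "RUL", "IIB", 20, 1, 15, 1),
        make_record("D", 58, "female", "adenocarcinoma", "LLL", "IB", 80, 0, 75, 0),
        make_record("E", 61, "male", "other", "LUL", "IA", 55, 1, 50, 1),
        make_record("F", 35, "female", "squamous", "RML", "IIA", 84, 0, 84, 0),
    ]


@pytest.fixture
def small_cohort():
    """Synthetic cohort with splits, reused by graph/model/eval tests."""
    import graphsurv as gs

    cohort = gs.generate_cohort(gs.CohortSpec(n_patients=150, seed=7))
    records = gs.assign_splits(cohort.records, seed=7)
    return records, cohort.features
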