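import datetime

import numpy as np
import pytest

from rfskit import simulate_cohort
from rfskit.cohort import Cohort, PatientBaseline
from rfskit.simulate import SimParams


def D(text: str) -> datetime.date:
    return datetime.date.fromisoformat(text)


def make_baseline(pid="P1", diagnosis="2008-01-10", surgery="2008-03-15",
                  surgery_type="mastectomy", stage="II", grade="2", er="pos",
                  pr="pos", her2="neg", age=45.0, last_contact="2013-03-15",
                  death=None, death_cause=None) -> PatientBaseline:
    return PatientBaseline(
        patient_id=pid, diagnosis_date=D(diagnosis),
        surgery_date=D(surgery) if surgery else None,
        surgery_type=surgery_type if surgery else "none",
        stage=stage, grade=grade, er=er, pr=pr, her2=her2, age_at_diagnosis=age,
        last_contact_date=D(last_contact),
        death_date=D(death) if death else None, death_cause=death_cause)


def make_cohort(baselines, events=(), labels=None) -> Cohort:
    return Cohort(baselines=list(baselines), events=list(events),
                  labels=list(labels) if labels is not None else None)


@pytest.fixture(scope="session")
def default_cohort():
    """Default study conditions, seed 1 — shared across test modules."""
    return simulate_cohort(seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SimParams(n_patients=60), seed=3)


@pytest.fixture(scope="session")
def default_matrix(default_cohort):
    from rfskit import build_indicator_matrix
    return build_indicator_matrix(default_cohort)


@pytest.fixture(scope="session")
def default_labels(default_cohort, default_matrix):
    matrix, _ = default_matrix
    gold = default_cohort.label_index()
    return np.array([gold[pid].recurred for pid in matrix.index])
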