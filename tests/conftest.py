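import numpy as np
import pytest

from ehrqa.config import default_config
from ehrqa.records import MeasurementRecord, SubjectSeries
from ehrqa.simulate import CohortSpec, ErrorModel, generate_cohort


@pytest.fixture(scope="session")
def default_cfg():
    return default_config()


@pytest.fixture(scope="session")
def labeled_cohort():
    """Default labeled synthetic cohort (200 subjects, 5% mixed errors)."""
    return generate_cohort(CohortSpec(n_subjects=200, seed=0))


@pytest.fixture(scope="session")
def clean_cohort():
    """Error-free cohort sharing the default trajectories."""
    return generate_cohort(
        CohortSpec(n_subjects=100, seed=0, error_model=ErrorModel(rate=0.0))
    )


def make_series(values, times=None, subject="S0", variable="weight"):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(len(values), dtype=float)
    return SubjectSeries(
        subject_id=subject,
        variable=variable,
        times=np.asarray(times, dtype=float),
        values=values,
        record_ids=[f"{subject}:{i}" for i in range(len(values))],
    )


def make_records(rows):
    """rows: iterable of (subject, variable, time, value) or with record_id."""
    out = []
    for i, row in enumerate(rows):
        if len(row) == 5:
            s, v, t, y, rid = row
        else:
            s, v, t, y = row
            rid = f"{s}:{i}"
        out.append(MeasurementRecord(subject_id=s, variable=v, time=t, value=y, record_id=rid))
    return out
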