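import numpy as np
import pandas as pd
import pytest

from hrasym import CohortConfig, RRRecording, analyze_cohort, generate_cohort


def make_recording(rr, ann=None, subject_id="t", age=None, sex=None) -> RRRecording:
    rr = np.asarray(rr, dtype=float)
    if ann is None:
        ann = ["N"] * rr.size
    ann = list(ann)
    return RRRecording(subject_id=subject_id, rr_ms=rr,
                       annotations=np.asarray(ann, dtype="U1"), age=age, sex=sex)


@pytest.fixture
def recording_factory():
    return make_recording


@pytest.fixture(scope="session")
def default_cohort_records() -> pd.DataFrame:
    """Per-subject record set of the shipped default synthetic cohort
    (96 subjects, master seed 42), analyzed once per test session."""
    recordings, _ = generate_cohort(CohortConfig(master_seed=42))
    return analyze_cohort(recordings)
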