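import numpy as np
import pytest

import circarhythm as cr
from circarhythm.reports import analyze_subject


@pytest.fixture(scope="session")
def control_recording():
    rec, truth = cr.generate_subject(
        cr.control_profile(), seed=1, days=7,
        subject_id="ctrl", label="control", return_truth=True)
    return rec, truth


@pytest.fixture(scope="session")
def pd_recording():
    rec, truth = cr.generate_subject(
        cr.pd_profile(), seed=2, days=7,
        subject_id="pd", label="PD", return_truth=True)
    return rec, truth


@pytest.fixture(scope="session")
def default_cohort():
    """12 PD-like + 12 control-like subjects, the documented study size."""
    return cr.generate_cohort(cr.CohortSpec(n_pd=12, n_control=12, seed=7))


@pytest.fixture(scope="session")
def cohort_analysis(default_cohort):
    """Per-subject (indices, sleep, features) for the default cohort."""
    out = []
    for rec in default_cohort:
        out.append((rec,) + analyze_subject(rec))
    return out


@pytest.fixture(scope="session")
def cohort_features(cohort_analysis):
    return [fv for _, _, _, fv in cohort_analysis]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
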