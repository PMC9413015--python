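import numpy as np
import pytest

from wristpa.core import TriaxialRecord
from wristpa.summary_measures import summarize
from wristpa.synthetic_data import generate_cohort


def make_record(x, y=None, z=None, fs=10.0, t0=0.0):
    """TriaxialRecord from plain arrays; y/z default to zero/zero."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    y = np.zeros(n) if y is None else np.asarray(y, dtype=float)
    z = np.zeros(n) if z is None else np.asarray(z, dtype=float)
    return TriaxialRecord(t0 + np.arange(n) / fs, x, y, z, fs)


@pytest.fixture(scope="session")
def random_record():
    """10,000 random samples inside the dynamic range at 10 Hz."""
    rng = np.random.default_rng(123)
    n = 10_000
    return TriaxialRecord(
        np.arange(n) / 10.0,
        rng.uniform(-7.9, 7.9, n),
        rng.uniform(-7.9, 7.9, n),
        rng.uniform(-7.9, 7.9, n),
        10.0,
    )


@pytest.fixture(scope="session")
def cohort():
    """Three labeled synthetic 24-hour days at 10 Hz (fixed seed)."""
    return generate_cohort(3, seed=11)


@pytest.fixture(scope="session")
def cohort_epochs(cohort):
    """Summarized epoch tables + labels for the session cohort."""
    return [(summarize(record), labels) for record, labels in cohort]
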