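import numpy as np
import pandas as pd
import pytest

from mdscore.datatypes import MetaboliteMatrix


def make_cohort(events, days=None, cci=None, sofa=None, horizon=30):
    """Build a schema-valid cohort table from an event vector."""
    events = np.asarray(events, dtype=int)
    n = len(events)
    if days is None:
        days = np.where(events == 1, 10, horizon)
    days = np.asarray(days)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "survival_days": days,
            "event": events,
            "mortality_label": events,
            "cci": np.full(n, 4) if cci is None else np.asarray(cci),
            "sofa": np.full(n, 8) if sofa is None else np.asarray(sofa),
        }
    )


def make_matrix(values, columns=None, panel=None):
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    columns = columns or [f"met_{j + 1:02d}" for j in range(k)]
    df = pd.DataFrame(values, columns=columns)
    df.index = pd.Index([f"P{i:04d}" for i in range(n)], name="patient_id")
    return MetaboliteMatrix(df, panel or {})


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cohort():
    return make_cohort([0, 0, 0, 1, 1, 0, 1, 0], days=[30, 30, 30, 5, 12, 30, 20, 30])
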