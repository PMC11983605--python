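import numpy as np
import pandas as pd
import pytest

from immunonet import CohortSpec, generate_cohort
from immunonet.cohort import CONTINUOUS, LABEL, PREDICTORS
from immunonet.preprocess import prepare_datasets


def make_table(n: int = 6, **overrides) -> pd.DataFrame:
    """A tiny hand-editable cohort table with sensible defaults."""
    base = {
        "age": np.linspace(25, 65, n),
        "gender": np.array(["women", "men"] * n, dtype=object)[:n],
        "family_history": np.array(["no"] * n, dtype=object),
        "symptom_count": np.arange(n, dtype=float),
        "blood_pressure": np.full(n, 120.0),
        "cholesterol": np.linspace(150, 250, n),
        "bmi": np.full(n, 25.0),
        "wbc": np.full(n, 7000.0),
        "rbc": np.full(n, 4.8e6),
        "hemoglobin": np.full(n, 14.0),
        "platelets": np.full(n, 250e3),
        "crp": np.linspace(1, 20, n),
        "esr": np.linspace(5, 40, n),
        LABEL: np.array(["RA", "SLE"] * n, dtype=object)[:n],
    }
    base.update(overrides)
    return pd.DataFrame(base)[list(PREDICTORS + (LABEL,))]


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return generate_cohort(CohortSpec(n=400, seed=0, effect_size=1.0))


@pytest.fixture(scope="session")
def prepared_small(small_cohort):
    return prepare_datasets(small_cohort, seed=0)
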