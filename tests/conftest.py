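import numpy as np
import pandas as pd
import pytest

from lrmscore.cohort import CohortTable
from lrmscore.markers import MarkerSpec, default_panel
from lrmscore.simulate import generate_cohort, paper_like_config


@pytest.fixture
def tiny_cohort() -> CohortTable:
    """Six patients, two markers, handmade values (no missing)."""
    specs = [
        MarkerSpec("albumin", "g/dl", "serology", allow_missing=True),
        MarkerSpec("cd9_cd133_2_per_ml", "particles/ml", "ev"),
    ]
    return CohortTable(
        patient_id=pd.Index([f"p{i}" for i in range(6)]),
        label=np.array([0, 0, 0, 1, 1, 1]),
        markers=pd.DataFrame(
            {
                "albumin": [4.1, 3.9, 4.4, 3.6, 3.2, 3.8],
                "cd9_cd133_2_per_ml": [1e6, 2e6, 1.5e6, 5e6, 6e6, 4e6],
            }
        ),
        specs=specs,
    )


@pytest.fixture(scope="session")
def paper_cohort() -> CohortTable:
    """One paper-like synthetic cohort (25 + 25, survival, 5% serology gaps)."""
    return generate_cohort(paper_like_config(seed=7))


@pytest.fixture(scope="session")
def clean_cohort() -> CohortTable:
    """Paper-like cohort without missingness (for modules requiring complete data)."""
    return generate_cohort(paper_like_config(seed=11, missing_rate=0.0))


def single_marker_cohort(values, labels, name="m") -> CohortTable:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    return CohortTable(
        patient_id=pd.Index([f"p{i}" for i in range(len(values))]),
        label=labels,
        markers=pd.DataFrame({name: values}),
        specs=[MarkerSpec(name, "a.u.", "serology", allow_missing=True)],
    )
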