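import numpy as np
import pandas as pd
import pytest

from ctcmet.screening import FeatureMatrix
from ctcmet.subtyping import SingleCellMatrix
from ctcmet.synthetic import CohortSimConfig, generate_ctc_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20230429)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient cohort at default generator settings, fixed seed."""
    return generate_ctc_cohort(CohortSimConfig(n_patients=60, seed=7))


@pytest.fixture
def toy_feature_matrix():
    """Tiny fully annotated feature matrix: 3 features + IS, 4 samples + QC."""
    intens = pd.DataFrame(
        {
            "s1": [10.0, 5.0, 1.0, 100.0],
            "s2": [12.0, 6.0, 1.2, 100.0],
            "s3": [40.0, 5.5, 0.9, 100.0],
            "s4": [44.0, 6.5, 1.1, 100.0],
            "qc0": [26.5, 5.75, 1.05, 100.0],
        },
        index=["m1", "m2", "m3", "IS"],
    )
    samples = pd.DataFrame(
        {
            "group": ["primary", "primary", "metastatic", "metastatic", "QC"],
            "batch": [0, 0, 0, 0, 0],
            "is_qc": [False, False, False, False, True],
            "protein_ug": [50.0, 50.0, 50.0, 50.0, 50.0],
        },
        index=intens.columns,
    )
    return FeatureMatrix(intensities=intens, samples=samples, is_feature_id="IS")


def make_cells(values: np.ndarray, columns, patients=None) -> SingleCellMatrix:
    """Wrap a raw array as a SingleCellMatrix with synthetic ids."""
    n = values.shape[0]
    idx = pd.Index([f"c{i}" for i in range(n)], name="cell_id")
    return SingleCellMatrix(
        concentrations=pd.DataFrame(values, index=idx, columns=columns),
        cells=pd.DataFrame(
            {"patient_id": patients if patients is not None else ["p0"] * n,
             "batch": 0},
            index=idx,
        ),
    )
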