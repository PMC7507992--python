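import numpy as np
import pandas as pd
import pytest

import triprot as tp


@pytest.fixture(scope="session")
def small_cohort():
    """35-patient, 400-protein complete cohort with ground truth."""
    cfg = tp.SimulationConfig(n_patients=35, n_proteins=400, seed=11)
    cohort, clinical, truth = tp.simulate_cohort(cfg)
    return cfg, cohort, clinical, truth


@pytest.fixture()
def tiny_matrix():
    """3 proteins x 4 samples log2 matrix with 2 missing cells."""
    return pd.DataFrame(
        [[0.0, 1.0, -1.0, 0.5],
         [np.nan, 0.2, 0.3, -0.2],
         [1.5, np.nan, 0.0, 0.1]],
        index=["P1", "P2", "P3"],
        columns=["S1", "S2", "S3", "S4"],
    )


def make_triplet_cohort(values: np.ndarray, n_patients: int) -> tp.Cohort:
    """Cohort from a proteins x (3 * n_patients) array laid out as triplets."""
    cols, meta = [], []
    for i in range(n_patients):
        pid = f"PT{i + 1:03d}"
        for role in ("normal", "pre", "post"):
            sid = f"{pid}_{role}"
            cols.append(sid)
            meta.append((sid, pid, role, i % 2))
    matrix = pd.DataFrame(
        values,
        index=[f"PROT{i + 1:04d}" for i in range(values.shape[0])],
        columns=cols,
    )
    sample_meta = pd.DataFrame(
        meta, columns=["sample_id", "patient_id", "role", "batch"]
    )
    return tp.Cohort(matrix, sample_meta)
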