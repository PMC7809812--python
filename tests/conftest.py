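import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from cpgrank.core_io import BetaMatrix
from cpgrank.synthetic import SimulationConfig, simulate_cohort


def random_beta_matrix(rng: np.random.Generator, n_probes=30, n_samples=8, missing_frac=0.0):
    vals = rng.uniform(0, 1, size=(n_probes, n_samples))
    if missing_frac > 0:
        mask = rng.random(vals.shape) < missing_frac
        vals[mask] = np.nan
    return BetaMatrix(
        pd.DataFrame(
            vals,
            index=[f"cg{i:05d}" for i in range(n_probes)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
    )


@pytest.fixture(scope="session")
def small_cohort():
    """2,000-probe cohort with 40 planted sites — shared across tests."""
    cfg = SimulationConfig(n_probes=2000, planted_sites=40, seed=101)
    return cfg, *simulate_cohort(cfg)


@pytest.fixture(scope="session")
def patient_control_labels(small_cohort):
    _, _, sheet, _, _ = small_cohort
    dx = sheet.table[
        (sheet.table["timepoint"] == "diagnosis")
        & (sheet.table["subject_id"] != "reference")
    ]
    return pd.Series(
        np.where(dx["disease"] == "control", "control", "patient"),
        index=dx["sample_id"].to_numpy(),
    )
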