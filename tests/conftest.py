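import numpy as np
import pandas as pd
import pytest

from ovasig.datatypes import ClinicalTable, ExpressionMatrix
from ovasig import synthdata


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_clinical(os_months, event, sample_ids=None, **covariates):
    """Minimal clinical table from arrays."""
    n = len(os_months)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    df = pd.DataFrame({"sample_id": sample_ids, "os_months": os_months, "event": event})
    for key, val in covariates.items():
        df[key] = val
    return ClinicalTable(df)


def make_matrix(values, batch=None, prefix_g="g", prefix_s="s"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        [f"{prefix_g}{i}" for i in range(values.shape[0])],
        [f"{prefix_s}{j}" for j in range(values.shape[1])],
        values,
        batch,
    )


@pytest.fixture(scope="session")
def planted_study():
    """Medium planted-signal study shared by several model tests."""
    cfg = synthdata.SimulationConfig(
        n_batches=1, samples_per_batch=240, n_genes=600, n_prognostic=20,
        beta=0.8, gamma_sd=0.0, delta_shape=0.0, seed=11,
    )
    return synthdata.simulate_integration_study(cfg)


@pytest.fixture(scope="session")
def null_study():
    """No-signal study: survival independent of expression."""
    cfg = synthdata.SimulationConfig(
        n_batches=1, samples_per_batch=120, n_genes=400, n_prognostic=1,
        beta=0.0, gamma_sd=0.0, delta_shape=0.0, seed=23,
    )
    return synthdata.simulate_integration_study(cfg)
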