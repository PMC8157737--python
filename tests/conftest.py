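import numpy as np
import pandas as pd
import pytest

from ptmdiff.io_tables import bind
from ptmdiff.normalization import log2_transform
from ptmdiff.synthetic import simulate_protein, simulate_ptm


@pytest.fixture(scope="session")
def protein_sim():
    """Small two-group proteome simulation with planted effects."""
    matrix, meta, truth = simulate_protein(
        n_features=300, n_per_group=3, frac_diff=0.1, log2fc_effect=2.0,
        d0=8.0, s0sq=0.25, seed=11,
    )
    return matrix, meta, truth


@pytest.fixture(scope="session")
def protein_log2(protein_sim):
    matrix, meta, _ = protein_sim
    return log2_transform(bind(matrix, meta)), meta


@pytest.fixture(scope="session")
def ptm_sim():
    """PTM simulation with one planted beta shift (family 0, member 1)."""
    table, meta, truth = simulate_ptm(
        families=[4, 3, 5, 2, 4], n_per_group=3,
        planted_shifts={(0, 1): 0.3}, seed=13,
    )
    return table, meta, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(99)


@pytest.fixture()
def metadata_frame():
    """A valid 6-sample, two-arm metadata table."""
    return pd.DataFrame(
        {
            "file_name": [f"Intensity.{i}" for i in range(6)],
            "sample_group": ["Nucleus Accumbens"] * 6,
            "replicate": [1, 2, 3, 1, 2, 3],
            "experimental_group": ["Treatment"] * 3 + ["Control"] * 3,
            "custom_id": ["NA_1_T", "NA_2_T", "NA_3_T", "NA_1", "NA_2", "NA_3"],
        }
    )
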