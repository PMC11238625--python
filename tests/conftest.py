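import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/naive.py importable

from coabund import (
    AbundanceMatrix,
    SampleDesign,
    SimulationConfig,
    simulate_dataset,
)


@pytest.fixture
def design4():
    """2 conditions x 2 replicates."""
    return SampleDesign(
        pd.DataFrame(
            {
                "sample_id": ["c1_r1", "c1_r2", "c2_r1", "c2_r2"],
                "condition": ["c1", "c1", "c2", "c2"],
                "replicate": [1, 2, 1, 2],
            }
        )
    )


@pytest.fixture
def matrix4(design4):
    """3 proteins x 4 samples, all positive, no missing."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [10.0, 10.0, 12.0, 8.0], [5.0, 1.0, 2.0, 9.0]],
        index=pd.Index(["P1", "P2", "P3"], name="protein_id"),
        columns=design4.sample_ids,
    )
    return AbundanceMatrix(values=values, design=design4)


def make_matrix(values, protein_ids=None, n_rep=1):
    """Build a validated AbundanceMatrix from a raw 2-D array."""
    values = np.asarray(values, dtype=float)
    n_prot, n_samp = values.shape
    if protein_ids is None:
        protein_ids = [f"P{i + 1}" for i in range(n_prot)]
    design = SampleDesign(
        pd.DataFrame(
            {
                "sample_id": [f"s{j + 1}" for j in range(n_samp)],
                "condition": [f"c{j // n_rep + 1}" for j in range(n_samp)],
                "replicate": [j % n_rep + 1 for j in range(n_samp)],
            }
        )
    )
    frame = pd.DataFrame(
        values, index=pd.Index(protein_ids, name="protein_id"), columns=design.sample_ids
    )
    return AbundanceMatrix(values=frame, design=design)


@pytest.fixture(scope="session")
def sim_small():
    """Seeded small simulated dataset (200 background) for fast end-to-end tests."""
    config = SimulationConfig(seed=7, n_background=200)
    matrix, design, truth, annotations = simulate_dataset(config)
    return config, matrix, design, truth, annotations
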