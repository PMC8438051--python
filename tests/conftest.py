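import numpy as np
import pytest

from umscape.io import CountMatrix, GeneSignatureSet
from umscape.simulate import SimulationParams, TwoClassParams, simulate_atlas, simulate_two_class


@pytest.fixture(scope="session")
def small_atlas():
    """500 tumor cells, 50 other cells, 4000 empties, 2% apoptotic."""
    params = SimulationParams(
        n_tumor_cells=500, n_other_cells=50, n_empty_droplets=4000, seed=7
    )
    return simulate_atlas(params)


@pytest.fixture(scope="session")
def two_class_data():
    """Two patients, 70/30 and 30/70 class mixtures, strong separation."""
    cm, truth = simulate_two_class(
        {"P1": 0.7, "P2": 0.3},
        separation=3.0,
        params=TwoClassParams(n_cells_per_patient=800, seed=5),
    )
    return cm, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_counts():
    return CountMatrix(
        counts=np.array([[1, 0], [2, 3]]),
        cell_ids=["c1", "c2"],
        gene_ids=["A", "MT-ND1"],
    )


@pytest.fixture
def gep_signatures():
    return GeneSignatureSet({"GEP1": ["A", "B"], "GEP2": ["C", "D"]})
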