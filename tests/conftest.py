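import numpy as np
import pytest

from activesvm import DenseStore, PlantedSpec, generate_planted


@pytest.fixture
def toy_1d():
    """Separable 1-D problem with known hard-margin solution w=1, b=0."""
    X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
    y = np.array([-1, -1, 1, 1])
    return X, y


@pytest.fixture
def small_store():
    values = np.array([[1.0, 0.0, 2.0],
                       [0.0, 3.0, 0.0]])
    return DenseStore(values, ["gA", "gB", "gC"], ["c1", "c2"])


@pytest.fixture(scope="session")
def tiny_planted():
    """Small planted dataset shared by selection/driver tests."""
    spec = PlantedSpec(n_cells=150, n_genes=120, n_classes=3,
                       markers_per_class=3, fold_change=6.0, dropout=0.2,
                       seed=7)
    store, labels, truth = generate_planted(spec)
    return store, labels, truth


@pytest.fixture(scope="session")
def binary_planted():
    spec = PlantedSpec(n_cells=60, n_genes=25, n_classes=2,
                       markers_per_class=2, fold_change=8.0, dropout=0.1,
                       seed=3)
    store, labels, truth = generate_planted(spec)
    return store, labels, truth
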