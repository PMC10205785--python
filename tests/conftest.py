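import numpy as np
import pytest

from adept import SimConfig, filter_genes, generate_layered_dataset, normalize
from adept.graph import build_knn_graph


@pytest.fixture(scope="session")
def layered():
    """Default synthetic layered dataset plus ground truth."""
    return generate_layered_dataset(SimConfig(seed=42))


@pytest.fixture(scope="session")
def layered_normalized(layered):
    d, truth = layered
    dd = filter_genes(d, 5)
    return normalize(dd), truth


@pytest.fixture(scope="session")
def small_graph():
    rng = np.random.default_rng(7)
    coords = rng.random((30, 2))
    return coords, build_knn_graph(coords, k=4)
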