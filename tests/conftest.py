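import numpy as np
import pandas as pd
import pytest

from chromomodes.hic_io import ContactMap, uniform_bins


def path3_matrix() -> np.ndarray:
    """3-bin path: contacts only between consecutive loci."""
    return np.array([[0.0, 1.0, 0.0],
                     [1.0, 0.0, 1.0],
                     [0.0, 1.0, 0.0]])


@pytest.fixture
def path3_map() -> ContactMap:
    return ContactMap(bin_size=50_000, bins=uniform_bins(3, 50_000),
                      matrix=path3_matrix(), provenance="path3")


def random_connected_map(n: int, seed: int, density: float = 0.3) -> ContactMap:
    """Random symmetric nonnegative map, guaranteed connected by a path
    backbone; used as oracle input throughout the suite."""
    rng = np.random.default_rng(seed)
    m = rng.uniform(0, 10, size=(n, n))
    m *= rng.random((n, n)) < density
    m = np.triu(m, 1)
    m = m + m.T
    for i in range(n - 1):  # backbone keeps the graph connected
        w = rng.uniform(1, 5)
        m[i, i + 1] = m[i + 1, i] = w
    return ContactMap(bin_size=50_000, bins=uniform_bins(n, 50_000), matrix=m,
                      provenance=f"random(n={n},seed={seed})")


@pytest.fixture
def random_map_factory():
    return random_connected_map
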