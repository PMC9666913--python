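import numpy as np
import pandas as pd
import pytest

from vertistrat.assemblage_grid import PresenceAbsenceMatrix, make_grid
from vertistrat.synthetic_world import WorldConfig, generate_world


@pytest.fixture(scope="session")
def default_world():
    """One seeded default synthetic world shared across tests."""
    return generate_world(WorldConfig(seed=11))


@pytest.fixture(scope="session")
def lattice_weights_20x20():
    from vertistrat.spatial_stats import build_weights

    xs, ys = np.meshgrid(np.arange(20.0), np.arange(20.0))
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    return coords, build_weights(coords, 1.0, fn="binary", style="row_standardized")


@pytest.fixture
def toy_pam():
    """4 cells × 3 species with known occupancies (2, 1, 2 cells)."""
    mat = np.array([[1, 0, 1], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=np.int8)
    return PresenceAbsenceMatrix.build(["a", "b", "c", "d"], ["s1", "s2", "s3"], mat)


def random_pam(rng, n_cells, n_species, min_richness=1, max_richness=None):
    """Random PAM with per-cell richness in [min_richness, max_richness]."""
    hi = n_species if max_richness is None else max_richness
    mat = np.zeros((n_cells, n_species), np.int8)
    for i in range(n_cells):
        k = rng.integers(min_richness, hi + 1)
        mat[i, rng.choice(n_species, k, replace=False)] = 1
    cells = [f"c{i}" for i in range(n_cells)]
    species = [f"sp_{j:03d}" for j in range(n_species)]
    return PresenceAbsenceMatrix.build(cells, species, mat)


@pytest.fixture
def grid_3x3():
    return make_grid(3, 3, 10.0)
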