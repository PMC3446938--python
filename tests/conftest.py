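import numpy as np
import pytest

from landuse_affinity import LandUseMap, SimulationConfig
from landuse_affinity.synthetic import generate_dataset


@pytest.fixture()
def uniform_urban_map():
    """50 x 50 grid of 100-m cells, all urban."""
    return LandUseMap(0.0, 0.0, 100.0, np.zeros((50, 50), dtype=np.int8))


@pytest.fixture()
def split_map():
    """Urban left half, agricultural right half; 100 x 100 grid of 100-m cells."""
    cells = np.zeros((100, 100), dtype=np.int8)
    cells[:, 50:] = 1
    return LandUseMap(0.0, 0.0, 100.0, cells)


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic scenario shared by pipeline-level tests."""
    cfg = SimulationConfig(
        seed=11, n_rows=120, n_cols=120, n_collections=250, patch_scale=800.0
    )
    return cfg, generate_dataset(cfg)


def brute_force_buffer(lmap, x, y, radius):
    """Independent oracle: explicit loop over every cell centre."""
    counts = np.zeros(4, dtype=int)
    total = 0
    for i in range(lmap.n_rows):
        cy = lmap.origin_y + (i + 0.5) * lmap.cell_size
        for j in range(lmap.n_cols):
            cx = lmap.origin_x + (j + 0.5) * lmap.cell_size
            if (cx - x) ** 2 + (cy - y) ** 2 <= radius**2:
                total += 1
                counts[lmap.cells[i, j]] += 1
    if total == 0:
        return None
    return counts[:3] / total
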