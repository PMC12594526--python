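import numpy as np
import pytest

from rodspt import CellGeometry, SimConfig, simulate_cells


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_config():
    return SimConfig(n_cells=20, spots_per_cell=100, seed=42)


@pytest.fixture
def rect_cell():
    """A lone rectangular 'cell' (simple polygon) for containment tests."""
    outline = np.array([[0, 0], [20, 0], [20, 6], [0, 6]], dtype=float)
    centerline = np.array([[0.5, 3.0], [19.5, 3.0]])
    return CellGeometry(cell_id=0, movie_id=0, outline=outline,
                        centerline=centerline, length_px=19.0, width_px=6.0)


@pytest.fixture
def straight_cells(small_config):
    return simulate_cells(small_config)
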