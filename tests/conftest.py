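import numpy as np
import pandas as pd
import pytest

from mobfit.spatial import SpatialSystem


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def random_system(n_cells: int, n_units: int, seed: int = 0,
                  extent: float = 200_000.0) -> SpatialSystem:
    """Random scattered cells with positive populations and unit labels
    guaranteeing every unit owns at least one cell."""
    r = np.random.default_rng(seed)
    x = r.uniform(0, extent, n_cells)
    y = r.uniform(0, extent, n_cells)
    pop = r.uniform(10, 10_000, n_cells)
    admin = np.concatenate([
        np.arange(1, n_units + 1),
        r.integers(1, n_units + 1, n_cells - n_units),
    ])
    r.shuffle(admin)
    return SpatialSystem(scale="test", x=x, y=y, population=pop, admin_id=admin)


@pytest.fixture
def line_system() -> SpatialSystem:
    """Four cells on a line at 0, 1, 2, 3 km with pops 10, 20, 30, 40."""
    return SpatialSystem(
        scale="test",
        x=np.array([0.0, 1000.0, 2000.0, 3000.0]),
        y=np.zeros(4),
        population=np.array([10.0, 20.0, 30.0, 40.0]),
        admin_id=np.array([1, 1, 2, 2]),
    )


@pytest.fixture
def uniform_raster() -> pd.DataFrame:
    """Fully populated 120 km x 120 km rectangle at 1 km pixels."""
    n = 120
    xs = (np.arange(n) + 0.5) * 1000.0
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    return pd.DataFrame({
        "x": X.ravel(), "y": Y.ravel(),
        "population": np.ones(n * n),
        "admin_id": np.where(X.ravel() < 60_000.0, 1, 2),
    })
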