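import numpy as np
import pytest

from ensdm.grid import GridSpec, PredictorStack, Raster
from ensdm.synth import LandscapeSpec, TruthModel, make_landscape, true_suitability


@pytest.fixture(scope="session")
def small_spec() -> LandscapeSpec:
    return LandscapeSpec(seed=11, n_rows=60, n_cols=60, autocorrelation_range_cells=8.0)


@pytest.fixture(scope="session")
def small_stack(small_spec):
    return make_landscape(small_spec)


@pytest.fixture(scope="session")
def truth() -> TruthModel:
    return TruthModel()


@pytest.fixture(scope="session")
def small_suitability(small_stack, truth):
    return true_suitability(small_stack, truth)


@pytest.fixture()
def flat_grid() -> GridSpec:
    return GridSpec(n_rows=10, n_cols=10, cell_size_km=1.0)


def make_uniform_raster(grid: GridSpec, value: float) -> Raster:
    return Raster(np.full(grid.shape, value), grid)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
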