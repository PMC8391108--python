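import numpy as np
import pytest

from coastdiff import DensityField, ModelParams, SpatialGrid


@pytest.fixture
def params() -> ModelParams:
    """The standard simulation parameterization: D=1 km^2/yr, r=0.01/yr."""
    return ModelParams(D=1.0, r=0.01, N0=1.0)


@pytest.fixture
def diffusion_only() -> ModelParams:
    return ModelParams(D=1.0, r=0.0, N0=1.0)


@pytest.fixture
def default_grid() -> SpatialGrid:
    """Default comparison grid: [0, 100] km at 0.05 km spacing."""
    return SpatialGrid.from_spacing(100.0, 0.05)


@pytest.fixture
def coarse_grid() -> SpatialGrid:
    return SpatialGrid.from_spacing(100.0, 0.1)


def make_field(values, x_max=None, time=0.0) -> DensityField:
    values = np.asarray(values, dtype=float)
    if x_max is None:
        x_max = float(len(values) - 1)
    grid = SpatialGrid(x_max=x_max, n_nodes=len(values))
    return DensityField(grid=grid, time=time, values=values)
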