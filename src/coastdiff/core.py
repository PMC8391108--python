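"""Shared parameter, grid and density-field types plus basic field reductions.

Units are fixed package-wide: kilometres for space, years for time.  The
density field itself is dimensionless, so integrated totals carry units of
km and are reported as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelParams",
    "SpatialGrid",
    "DensityField",
    "SummaryStats",
    "characteristic_length",
    "integrate_field",
    "field_moments",
    "calibrate_diffusion",
]


@dataclass(frozen=True)
class ModelParams:
    """Physical constants of a scenario.

    Parameters
    ----------
    D : float
        Diffusion coefficient, km^2/yr. Must be positive.
    r : float
        Growth rate, 1/yr. Zero for the pure-diffusion model.
    N0 : float
        Density maintained at the coastal boundary (dimensionless).
    N_inf : float
        Carrying-capacity scale for logistic growth (dimensionless).
        The working model is normalized so this defaults to 1.
    """

    D: float = 1.0
    r: float = 0.0
    N0: float = 1.0
    N_inf: float = 1.0

    def __post_init__(self) -> None:
        if not (self.D > 0):
            raise ValueError(f"diffusion coefficient D must be > 0, got {self.D}")
        if self.r < 0:
            raise ValueError(f"growth rate r must be >= 0, got {self.r}")
        if self.N0 < 0:
            raise ValueError(f"boundary density N0 must be >= 0, got {self.N0}")
        if not (self.N_inf > 0):
            raise ValueError(f"carrying capacity must be > 0, got {self.N_inf}")

    @property
    def x_G(self) -> float:
        """Characteristic length sqrt(D/r), km. Defined only for r > 0."""
        return characteristic_length(self)


def characteristic_length(params: ModelParams) -> float:
    """Return the characteristic length scale sqrt(D/r) in km.

    Raises
    ------
    ValueError
        If the growth rate is not positive (the scale is undefined).
    """
    if params.r <= 0:
        raise ValueError("characteristic length undefined for r <= 0")
    return math.sqrt(params.D / params.r)


def calibrate_diffusion(sigma: float, t: float) -> float:
    """Invert the 1D spread relation sigma^2 = 2*D*t for D (km^2/yr)."""
    if sigma < 0:
        raise ValueError("spread sigma must be >= 0")
    if t <= 0:
        raise ValueError("elapsed time must be > 0")
    return sigma**2 / (2.0 * t)


@dataclass(frozen=True)
class SpatialGrid:
    """Uniform grid on the closed interval [0, x_max]; node 0 is the coast."""

    x_max: float
    n_nodes: int

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("grid needs at least 2 nodes")
        if not (self.x_max > 0):
            raise ValueError("domain length must be > 0")

    @classmethod
    def from_spacing(cls, x_max: float, spacing: float) -> "SpatialGrid":
        """Build a grid with (approximately) the requested node spacing."""
        if spacing <= 0:
            raise ValueError("spacing must be > 0")
        n = int(round(x_max / spacing)) + 1
        return cls(x_max=x_max, n_nodes=max(n, 2))

    @property
    def spacing(self) -> float:
        return self.x_max / (self.n_nodes - 1)

    @property
    def nodes(self) -> np.ndarray:
        return np.linspace(0.0, self.x_max, self.n_nodes)


@dataclass
class DensityField:
    """A density profile N(x) on a spatial grid at one instant."""

    grid: SpatialGrid
    time: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_nodes,):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.grid.n_nodes} nodes)"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite")
        if np.any(self.values < 0):
            raise ValueError("density values must be >= 0")


@dataclass(frozen=True)
class SummaryStats:
    """Aggregate descriptors of a density profile."""

    total: float        # N*, dimensionless * km
    mean_x: float       # km
    second_moment: float  # km^2
    variance: float     # km^2


def integrate_field(field: DensityField) -> float:
    """Total population: composite trapezoid integral of the field."""
    if field.grid.n_nodes < 2:
        raise ValueError("cannot integrate a degenerate grid")
    return float(np.trapezoid(field.values, dx=field.grid.spacing))


def field_moments(field: DensityField) -> SummaryStats:
    """Normalize the field to an occupancy density and return its moments.

    The field is divided by its trapezoid total to form a probability
    density over the grid; the mean, second moment and variance of the
    location are then computed by the same quadrature rule.
    """
    total = integrate_field(field)
    if total <= 0:
        raise ValueError("field has zero total population; moments undefined")
    x = field.grid.nodes
    p = field.values / total
    dx = field.grid.spacing
    mean_x = float(np.trapezoid(x * p, dx=dx))
    second = float(np.trapezoid(x**2 * p, dx=dx))
    variance = second - mean_x**2
    return SummaryStats(total=total, mean_x=mean_x,
                        second_moment=second, variance=max(variance, 0.0))
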