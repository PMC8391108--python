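"""Steady waves in a coastal band and the entropy-maximizing band width.

The exponential growth–diffusion balance admits a time-independent
sinusoidal profile on a band 0 <= x <= L provided L does not exceed
pi * x_G. Normalizing that profile gives a stationary occupancy
distribution whose differential entropy selects a preferred band width.

Two routes to the optimal width are implemented and both are always
reported: the closed-form stationarity condition (equivalent to
L* = 2 * x_G * arctan(C)) and a direct numeric maximization of the
entropy functional. The closed form treats the constant
C = x_G * B / (A + B) as dimensionless even though x_G carries km —
a convention adopted verbatim from the source model — so the two routes
need not coincide and their discrepancy is part of the output record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "BandConfig",
    "BandSolution",
    "band_steady_density",
    "band_total",
    "band_occupancy_pdf",
    "band_entropy",
    "plane_angle",
    "optimal_band_width_closed",
    "optimal_band_width_numeric",
    "band_width_report",
]

_SIN_FLOOR = 1e-12


@dataclass(frozen=True)
class BandConfig:
    """Band geometry and edge densities.

    L : band width, km, in (0, pi*x_G] (existence window of the wave)
    A : density at the coast x = 0
    B : density at the inner edge x = L
    x_G : characteristic length sqrt(D/r), km
    """

    L: float
    A: float
    B: float
    x_G: float

    def __post_init__(self) -> None:
        if not (self.x_G > 0):
            raise ValueError("x_G must be > 0")
        if not (0 < self.L <= math.pi * self.x_G + 1e-12):
            raise ValueError(
                f"band width L={self.L} outside existence window (0, pi*x_G]"
            )
        if self.A < 0 or self.B < 0:
            raise ValueError("edge densities must be >= 0")
        if self.A + self.B == 0:
            raise ValueError("at least one edge density must be positive")

    @property
    def C(self) -> float:
        """Auxiliary constant x_G * B / (A + B); by convention C = x_G when A = 0."""
        return self.x_G * self.B / (self.A + self.B)


@dataclass(frozen=True)
class BandSolution:
    """Record of a band analysis: both optimal widths are always kept."""

    config: BandConfig
    total: float
    entropy: float
    L_star_closed: float
    L_star_numeric: float

    @property
    def width_discrepancy(self) -> float:
        return abs(self.L_star_closed - self.L_star_numeric)


def _sin_ratio(config: BandConfig) -> float:
    s = math.sin(config.L / config.x_G)
    if s < _SIN_FLOOR:
        raise ValueError(
            f"sin(L/x_G) = {s:.3e} <= 0: band profile degenerate at L={config.L}"
        )
    return s


def band_steady_density(x, config: BandConfig):
    """Steady-wave profile [B sin(x/x_G) + A sin((L-x)/x_G)] / sin(L/x_G)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > config.L + 1e-12):
        raise ValueError("x must lie in [0, L]")
    s = _sin_ratio(config)
    xg = config.x_G
    out = (config.B * np.sin(x / xg) + config.A * np.sin((config.L - x) / xg)) / s
    return float(out) if out.ndim == 0 else out


def band_total(config: BandConfig) -> float:
    """Stationary total x_G (A+B) (1 - cos(L/x_G)) / sin(L/x_G)."""
    s = _sin_ratio(config)
    u = config.L / config.x_G
    return config.x_G * (config.A + config.B) * (1.0 - math.cos(u)) / s


def band_occupancy_pdf(x, config: BandConfig):
    """Stationary occupancy density on the band (1/km)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > config.L + 1e-12):
        raise ValueError("x must lie in [0, L]")
    _sin_ratio(config)
    xg = config.x_G
    u = config.L / xg
    denom = xg * (config.A + config.B) * (1.0 - math.cos(u))
    out = (config.B * np.sin(x / xg) + config.A * np.sin((config.L - x) / xg)) / denom
    return float(out) if out.ndim == 0 else out


def band_entropy(config: BandConfig, rtol: float = 1e-10) -> float:
    """Differential entropy -int_0^L p ln p dx (natural log, km units).

    The integrand is extended by continuity with 0*ln(0) := 0 at
    endpoints where the density vanishes (e.g. the coast when A = 0).
    """
    _sin_ratio(config)

    def integrand(x):
        p = band_occupancy_pdf(x, config)
        p = np.asarray(p)
        with np.errstate(divide="ignore", invalid="ignore"):
            val = np.where(p > 0, -p * np.log(np.where(p > 0, p, 1.0)), 0.0)
        return val

    val, _ = integrate.quad(integrand, 0.0, config.L, epsrel=rtol,
                            epsabs=1e-14, limit=200)
    return float(val)


def plane_angle(x_comp: float, y_comp: float) -> float:
    """Angle between the positive x-axis and the ray to (x_comp, y_comp).

    Implemented through the sign-function formula
    sgn(x)^2 arctan(y/x) + pi (1 - sgn(x))/2 (1 + sgn(y) - sgn(y)^2),
    which agrees with atan2(y, x) away from the origin.
    """
    if x_comp == 0 and y_comp == 0:
        raise ValueError("angle undefined at the origin")
    sx = float(np.sign(x_comp))
    sy = float(np.sign(y_comp))
    first = sx**2 * math.atan(y_comp / x_comp) if x_comp != 0 else 0.0
    second = math.pi * (1.0 - sx) / 2.0 * (1.0 + sy - sy**2)
    return first + second


def optimal_band_width_closed(x_G: float, C: float) -> float:
    """Closed-form entropy-stationary band width.

    The stationarity condition p(L; L) = 1 gives tan(L/(2 x_G)) = C, i.e.
    L* = x_G * angle_to(cos, sin) with cos = (1-C^2)/(C^2+1) and
    sin = 2C/(C^2+1); equivalently L* = 2 * x_G * arctan(C) in (0, pi*x_G].
    """
    if x_G <= 0:
        raise ValueError("x_G must be > 0")
    if C <= 0:
        raise ValueError("C must be > 0")
    sin_c = 2.0 * C / (C * C + 1.0)
    cos_c = (1.0 - C * C) / (C * C + 1.0)
    return x_G * plane_angle(cos_c, sin_c)


def optimal_band_width_numeric(A: float, B: float, x_G: float,
                               n_scan: int = 1000) -> float:
    """Band width maximizing the entropy functional, by direct search.

    A dense scan over (0, pi*x_G] brackets the maximum, refined by
    bounded scalar minimization to an absolute tolerance of 1e-6 * x_G.
    Fully deterministic.
    """
    if x_G <= 0:
        raise ValueError("x_G must be > 0")
    if A < 0 or B < 0 or A + B == 0:
        raise ValueError("need A >= 0, B >= 0, A + B > 0")
    L_hi = math.pi * x_G
    eps = 1e-6 * x_G
    Ls = np.linspace(eps, L_hi - eps, n_scan)

    def H(L: float) -> float:
        return _entropy_fast(BandConfig(L=L, A=A, B=B, x_G=x_G))

    vals = np.array([H(L) for L in Ls])
    if not np.any(np.isfinite(vals)):
        raise ValueError("entropy non-finite over the whole existence window")
    k = int(np.nanargmax(vals))
    lo = Ls[max(k - 1, 0)]
    hi = Ls[min(k + 1, n_scan - 1)]
    res = optimize.minimize_scalar(
        lambda L: -H(L), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6 * x_G},
    )
    # boundary maximum: scan endpoints can beat the interior refinement
    best = float(res.x) if -res.fun >= vals[k] else float(Ls[k])
    return best


def _entropy_fast(config: BandConfig, n: int = 4001) -> float:
    """Trapezoid entropy on a dense grid; used inside the scan loop."""
    x = np.linspace(0.0, config.L, n)
    p = band_occupancy_pdf(x, config)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(p > 0, -p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    return float(np.trapezoid(f, x))


def band_width_report(A: float, B: float, x_G: float) -> BandSolution:
    """Evaluate both optimal-width routes and the solution at the closed one.

    When A = 0 the auxiliary constant follows the source convention
    C = x_G; otherwise C = x_G * B / (A + B). The closed-form and numeric
    widths are both recorded along with their discrepancy — no
    reconciliation between the two is forced.
    """
    if A == 0:
        C = x_G
    else:
        C = x_G * B / (A + B)
    L_closed = optimal_band_width_closed(x_G, C)
    L_numeric = optimal_band_width_numeric(A, B, x_G)
    config = BandConfig(L=min(L_closed, math.pi * x_G), A=A, B=B, x_G=x_G)
    return BandSolution(
        config=config,
        total=band_total(config),
        entropy=band_entropy(config),
        L_star_closed=L_closed,
        L_star_numeric=L_numeric,
    )
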