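"""Stationary fronts of the logistic growth–diffusion model.

With the carrying capacity normalized to 1, a coastal boundary density
N0 != 1 produces a stationary profile relaxing from N0 at the coast to 1
inland over the characteristic length x_G. Densities entered on a
different capacity scale are normalized on entry and rescaled on exit.

Two closed forms are provided. ``stationary_profile`` is the exact
stationary front, derived from the first integral
(N')^2 = (r/3D) (1-N)^2 (2N+1) of the steady balance, i.e.
N(x) = (3/2) tanh^2((x + x1)/(2 x_G)) - 1/2. ``stationary_profile_k0``
is a closely related tanh-squared form built from the auxiliary
constant ``k0_constant``; it matches the boundary value and the inland
limit but is *not* exactly stationary (its residual is O(r) near the
coast, vanishing as N0 -> 1), so the exact form is the default
everywhere a stationary reference is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import ModelParams, characteristic_length

__all__ = [
    "StationaryLogisticProfile",
    "logistic_reaction",
    "k0_constant",
    "front_constant",
    "stationary_profile",
    "stationary_profile_k0",
    "stationary_profile_approx",
    "stationary_residual",
    "residual_of_values",
]

#: Upper bound on admissible normalized boundary densities; beyond this
#: the auxiliary-constant construction leaves the model's regime.
N0_MAX = 7.0


def logistic_reaction(N, params: ModelParams):
    """Logistic growth rate r*N*(1 - N/N_inf), in 1/yr."""
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("density must be >= 0")
    out = params.r * N * (1.0 - N / params.N_inf)
    return float(out) if out.ndim == 0 else out


def k0_constant(N0: float) -> float:
    """Auxiliary constant (sqrt(3) - sqrt(2+N0)) / (sqrt(3) + sqrt(2+N0)).

    Positive for N0 < 1, zero at N0 = 1, negative above; stays in (-1, 1)
    throughout the admitted range 0 <= N0 < 7. Feeds the k0-variant
    profile only; the exact front uses ``front_constant``.
    """
    if N0 < 0:
        raise ValueError("N0 must be >= 0")
    if N0 >= N0_MAX:
        raise ValueError(f"N0 = {N0} outside the admitted range [0, {N0_MAX})")
    s = math.sqrt(2.0 + N0)
    return (math.sqrt(3.0) - s) / (math.sqrt(3.0) + s)


def front_constant(N0: float) -> float:
    """Decay constant (sqrt(3) - sqrt(1+2*N0)) / (sqrt(3) + sqrt(1+2*N0)).

    This is the constant of the exact front: with k = front_constant(N0),
    N(x) = (3/2) ((1 - k e^{-x/x_G})/(1 + k e^{-x/x_G}))^2 - 1/2
    satisfies D N'' + r N (1 - N) = 0 identically and equals N0 at x = 0.
    Lies in (-1, 1) for every N0 >= 0; sign(k) = sign(1 - N0).
    """
    if N0 < 0:
        raise ValueError("N0 must be >= 0")
    if N0 >= N0_MAX:
        raise ValueError(f"N0 = {N0} outside the admitted range [0, {N0_MAX})")
    s = math.sqrt(1.0 + 2.0 * N0)
    return (math.sqrt(3.0) - s) / (math.sqrt(3.0) + s)


@dataclass(frozen=True)
class StationaryLogisticProfile:
    """Stationary front fixed by the coastal density and length scale."""

    params: ModelParams

    def __post_init__(self) -> None:
        if self.params.r <= 0:
            raise ValueError("stationary logistic profile requires r > 0")
        n0 = self.params.N0 / self.params.N_inf
        if n0 >= N0_MAX:
            raise ValueError(f"normalized N0 = {n0} outside [0, {N0_MAX})")

    @property
    def K0(self) -> float:
        return k0_constant(self.params.N0 / self.params.N_inf)

    @property
    def k(self) -> float:
        return front_constant(self.params.N0 / self.params.N_inf)

    @property
    def x_G(self) -> float:
        return characteristic_length(self.params)

    def __call__(self, x):
        return stationary_profile(x, self)


def _tanh_sq_profile(x, k: float, x_G: float, amp: float, off: float):
    """amp * ((1 - k e^{-x/x_G})/(1 + k e^{-x/x_G}))^2 - off.

    The decaying-exponential representation is stable for large x where
    e^{x/x_G} would overflow; the growing-exponential form is
    algebraically identical.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    e = np.exp(-x / x_G)
    denom = 1.0 + k * e
    assert np.all(denom > 0), "denominator cannot vanish for k > -1, x >= 0"
    out = amp * ((1.0 - k * e) / denom) ** 2 - off
    return out


def stationary_profile(x, profile: StationaryLogisticProfile):
    """Exact stationary front (3/2) tanh^2((x+x1)/(2 x_G)) - 1/2.

    Returns N0 at x = 0 and tends to the carrying capacity inland;
    identically 1 when N0 equals the capacity. Valid on both sides of
    the capacity (front_constant goes negative for N0 > 1).
    """
    out = _tanh_sq_profile(x, profile.k, profile.x_G, 1.5, 0.5)
    out = out * profile.params.N_inf
    return float(out) if out.ndim == 0 else out


def stationary_profile_k0(x, profile: StationaryLogisticProfile):
    """The k0-variant 3*((1 - K0 e^{-x/x_G})/(1 + K0 e^{-x/x_G}))^2 - 2.

    Shares the endpoints of the exact front (N0 at the coast, 1 inland)
    but is not exactly stationary: its residual under the steady balance
    is -72 K0^2 r e^{2x/x_G} / (K0 + e^{x/x_G})^4, i.e. O(r) near the
    coast for moderate N0. Kept for cross-comparison; for N0 = 0.5 the
    two profiles differ by ~1.3e-2 in sup norm.
    """
    out = _tanh_sq_profile(x, profile.K0, profile.x_G, 3.0, 2.0)
    out = out * profile.params.N_inf
    return float(out) if out.ndim == 0 else out


def stationary_profile_growing_form(x, profile: StationaryLogisticProfile):
    """Exact front in the growing-exponential form, for cross-checking only."""
    x = np.asarray(x, dtype=float)
    k = profile.k
    e = np.exp(x / profile.x_G)
    out = (1.5 * ((e - k) / (e + k)) ** 2 - 0.5) * profile.params.N_inf
    return float(out) if out.ndim == 0 else out


def stationary_profile_approx(x, params: ModelParams):
    """Near-capacity approximation 1 - (1 - N0) e^{-x/x_G}.

    First-order in (1 - N0); valid for boundary densities close to the
    carrying capacity, on either side of it.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    n0 = params.N0 / params.N_inf
    xg = characteristic_length(params)
    out = (1.0 - (1.0 - n0) * np.exp(-x / xg)) * params.N_inf
    return float(out) if out.ndim == 0 else out


def stationary_residual(profile: StationaryLogisticProfile,
                        spacing: float) -> float:
    """Max |D N'' + r N (1 - N)| of the exact front by central differences.

    Checked on [spacing, 20*x_G]; for the exact profile this sits below
    1e-6 * r at spacing <= 1e-3 * x_G. A useful oracle for any claimed
    stationary field: perturbations of size 0.01 already register.
    """
    xg = profile.x_G
    if spacing > 1e-2 * xg:
        raise ValueError("spacing must be <= 1e-2 * x_G for a trustworthy residual")
    x = np.arange(spacing, 20.0 * xg + spacing / 2, spacing)
    N = stationary_profile(x, profile)
    return residual_of_values(x, N, profile.params)


def residual_of_values(x: np.ndarray, N: np.ndarray,
                       params: ModelParams) -> float:
    """Same finite-difference residual for arbitrary sampled values."""
    dx = x[1] - x[0]
    d2 = (N[:-2] - 2.0 * N[1:-1] + N[2:]) / dx**2
    res = params.D * d2 + logistic_reaction(N[1:-1], params)
    return float(np.max(np.abs(res)))
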