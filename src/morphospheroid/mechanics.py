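"""Loaded and residual Cauchy stress profiles for a kinematic state.

Radial stress is obtained by integrating the Lagrangian equilibrium
equation ``d(sigma_r)/dR = 2 mu gamma (r^6 - gamma^6 R^6) / r^7`` inward
from the boundary; hoop stress follows from the neo-Hookean identity
``sigma_theta = sigma_r + mu (alpha^2 - alpha^-4)``.  The integrand has a
removable singularity at the centre (numerator ``O(R^8)``, denominator
``O(R^7)``) and is evaluated as zero there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .kinematics import InvalidStateError, SpheroidState, elastic_stretch
from .params import Params, ParamsLike, as_dimensionless

__all__ = ["StressProfile", "radial_stress", "hoop_stress", "residual_profiles"]

Variant = Literal["loaded", "residual"]


def _mu_kappa(params: ParamsLike) -> tuple[float, float]:
    if isinstance(params, Params):
        return params.mu, params.kappa
    dp = as_dimensionless(params)
    return 1.0, dp.kappa_mu


@dataclass(frozen=True)
class StressProfile:
    """Radial and hoop Cauchy stress on the material grid."""

    sigma_r: np.ndarray
    sigma_theta: np.ndarray
    variant: Variant
    boundary_value: float

    @property
    def global_min(self) -> float:
        """Most compressive principal stress anywhere in the body."""
        return float(min(self.sigma_r.min(), self.sigma_theta.min()))


def _stress_integrand(state: SpheroidState, mu: float) -> np.ndarray:
    R = state.grid.nodes
    r = state.r
    gamma = state.gamma
    out = np.empty_like(R)
    out[0] = 0.0  # removable limit at the centre
    out[1:] = 2.0 * mu * gamma[1:] * (r[1:] ** 6 - gamma[1:] ** 6 * R[1:] ** 6) / r[1:] ** 7
    return out


def radial_stress(
    state: SpheroidState, params: ParamsLike, variant: Variant = "loaded"
) -> np.ndarray:
    """Radial Cauchy stress by inward trapezoid quadrature from the boundary.

    Boundary value is ``-kappa (b - B) / B`` for the loaded variant and
    zero for the residual (traction-free) variant.
    """
    if np.any(state.r[1:] <= 0):
        raise InvalidStateError("interior radii must be positive")
    mu, kappa = _mu_kappa(params)
    if variant == "loaded":
        boundary = -kappa * (state.b - state.grid.B) / state.grid.B
    elif variant == "residual":
        boundary = 0.0
    else:
        raise ValueError(f"unknown stress variant {variant!r}")
    f = _stress_integrand(state, mu)
    dR = np.diff(state.grid.nodes)
    increments = 0.5 * (f[:-1] + f[1:]) * dR
    # sigma_r(R) = boundary - int_R^B f dRt
    tail = np.concatenate((np.cumsum(increments[::-1])[::-1], [0.0]))
    return boundary - tail


def hoop_stress(
    state: SpheroidState, sigma_r: np.ndarray, params: ParamsLike
) -> np.ndarray:
    """Hoop stress via the algebraic neo-Hookean identity (no differentiation)."""
    mu, _ = _mu_kappa(params)
    alpha = elastic_stretch(state)
    return sigma_r + mu * (alpha**2 - alpha**-4)


def residual_profiles(
    state: SpheroidState, params: ParamsLike
) -> StressProfile:
    """Residual stress fields (zero surface traction).

    The returned profile's ``sigma_theta[-1]`` is the boundary residual
    hoop stress; it is tensile when positive.
    """
    sr = radial_stress(state, params, variant="residual")
    st = hoop_stress(state, sr, params)
    return StressProfile(
        sigma_r=sr, sigma_theta=st, variant="residual", boundary_value=0.0
    )


def loaded_profiles(state: SpheroidState, params: ParamsLike) -> StressProfile:
    """Loaded stress fields under the compressive external boundary condition."""
    sr = radial_stress(state, params, variant="loaded")
    st = hoop_stress(state, sr, params)
    return StressProfile(
        sigma_r=sr, sigma_theta=st, variant="loaded", boundary_value=float(sr[-1])
    )
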