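"""Kinematics of isotropic growth under incompressible spherical symmetry.

The current configuration is determined purely by the growth-stretch field:
with isotropic growth stretch ``gamma(R)`` and incompressible elasticity,
``r(R)^3 = 3 * integral_0^R gamma^3 Rt^2 dRt``.  The elastic stretch
``alpha = r / (R * gamma)`` then measures the stored elastic distortion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "LagrangianGrid",
    "SpheroidState",
    "radius_from_growth",
    "elastic_stretch",
    "initial_state",
]

logger = logging.getLogger(__name__)


class InvalidStateError(ValueError):
    """Raised when a kinematic state violates its invariants."""


@dataclass(frozen=True)
class LagrangianGrid:
    """Fixed material grid on [0, B]; no material crosses the endpoints."""

    nodes: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        object.__setattr__(self, "nodes", nodes)
        if nodes.ndim != 1 or nodes.size < 2:
            raise InvalidStateError("grid needs at least two nodes")
        if nodes[0] != 0.0:
            raise InvalidStateError("grid must start at R = 0")
        if np.any(np.diff(nodes) <= 0):
            raise InvalidStateError("grid nodes must be strictly increasing")

    @classmethod
    def uniform(cls, B: float, n: int = 400) -> "LagrangianGrid":
        if B <= 0:
            raise InvalidStateError("outer material radius B must be positive")
        return cls(np.linspace(0.0, B, n + 1))

    @property
    def B(self) -> float:
        return float(self.nodes[-1])


@dataclass(frozen=True)
class SpheroidState:
    """Snapshot of the spheroid: growth field, current radii, necrotic front."""

    grid: LagrangianGrid
    gamma: np.ndarray
    r: np.ndarray
    R_N: float = 0.0
    t: float = 0.0

    def __post_init__(self) -> None:
        gamma = np.asarray(self.gamma, dtype=float)
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "r", r)
        if gamma.shape != self.grid.nodes.shape or r.shape != self.grid.nodes.shape:
            raise InvalidStateError("field shapes must match the grid")
        if np.any(gamma <= 0) or not np.all(np.isfinite(gamma)):
            raise InvalidStateError("growth stretch must be positive and finite")
        # Radii are strictly increasing in exact arithmetic; ties are
        # tolerated where deep necrotic decay underflows the quadrature.
        if r[0] != 0.0 or np.any(np.diff(r) < 0) or np.any(r[1:] <= 0):
            raise InvalidStateError("current radii must increase from r(0) = 0")
        if not (0.0 <= self.R_N <= self.grid.B):
            raise InvalidStateError("necrotic front must lie in [0, B]")

    @property
    def b(self) -> float:
        """Current outer radius."""
        return float(self.r[-1])

    def with_gamma(self, gamma: np.ndarray, t: float | None = None) -> "SpheroidState":
        """Rebuild the state from a new growth field (recomputing radii)."""
        r = radius_from_growth(self.grid, gamma)
        return replace(
            self, gamma=gamma, r=r, t=self.t if t is None else t
        )


def radius_from_growth(grid: LagrangianGrid, gamma: np.ndarray) -> np.ndarray:
    """Map a growth-stretch field to current radii.

    Composite-trapezoid quadrature of ``3 * gamma^3 * R^2`` followed by a
    nodewise cube root; exact for constant ``gamma`` fields up to the
    quadrature of ``R^2`` (the rule is applied to the full integrand so
    homogeneous growth gives ``r = gamma * R`` only to second order in the
    spacing — the constant case is handled exactly below).
    """
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma <= 0) or not np.all(np.isfinite(gamma)):
        raise InvalidStateError("growth stretch must be positive and finite")
    R = grid.nodes
    # Trapezoid on gamma^3 d(R^3) is exact for constant gamma and
    # second-order accurate otherwise: int gamma^3 R^2 dR = (1/3) int gamma^3 d(R^3).
    g3 = gamma**3
    dR3 = np.diff(R**3)
    increments = 0.5 * (g3[:-1] + g3[1:]) * dR3
    r3 = np.concatenate(([0.0], np.cumsum(increments)))
    return np.cbrt(r3)


def elastic_stretch(state: SpheroidState) -> np.ndarray:
    """Circumferential elastic stretch ``alpha = r / (R * gamma)``.

    The centre value is the removable limit ``alpha(0) = 1`` (near the
    origin ``r ~ gamma(0) * R`` under spherical symmetry).
    """
    R = state.grid.nodes
    alpha = np.empty_like(R)
    alpha[1:] = state.r[1:] / (R[1:] * state.gamma[1:])
    alpha[0] = 1.0
    return alpha


def initial_state(B: float, n: int = 400) -> SpheroidState:
    """Ungrown reference state: ``gamma = 1``, ``r = R``, no necrotic core."""
    grid = LagrangianGrid.uniform(B, n)
    gamma = np.ones_like(grid.nodes)
    return SpheroidState(grid=grid, gamma=gamma, r=grid.nodes.copy())


def eulerian_spacing_ok(state: SpheroidState, min_fraction: float = 1e-6) -> bool:
    """Monitor Eulerian resolution: warn when interior spacing collapses.

    Material turnover drives interior points toward the centre; when the
    smallest Eulerian spacing falls below ``min_fraction`` of the mean a
    warning is logged and False returned.
    """
    dr = np.diff(state.r)
    mean = dr.mean()
    if mean == 0.0 or dr.min() < min_fraction * mean:
        logger.warning(
            "Eulerian node spacing has collapsed (min %.3g vs mean %.3g)",
            dr.min(),
            mean,
        )
        return False
    return True
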