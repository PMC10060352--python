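"""Growth-rate laws M1-M5, the stress-modifier function, and the necrotic front.

All laws share the form ``(1/gamma) d(gamma)/dt = k * f(stress, c)``:

* M1 — nutrient only: ``f = c - c_hat`` (necrotic tissue decays).
* M2 — local radial-stress modulation of growth; necrotic decay unaltered.
* M3 — as M2, but necrosis is permanent (front ``R_N``) and rates are
  never negative.
* M4 — stress modulation through a global measure: the most compressive
  principal stress anywhere in the body.
* M5 — both the global measure and a local radial-stress factor
  ``n(beta * sigma_r)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .kinematics import SpheroidState
from .mechanics import StressProfile
from .nutrient import necrosis_boundary_radius
from .params import InvalidParameterError, Params, ParamsLike, as_dimensionless

__all__ = [
    "GrowthLaw",
    "LAW_IDS",
    "stress_modifier",
    "growth_rate_m1",
    "growth_rate_m2",
    "growth_rate_m3",
    "growth_rate_m4",
    "growth_rate_m5",
    "global_stress_measure",
    "update_necrotic_front",
    "growth_rates",
]

LAW_IDS = ("M1", "M2", "M3", "M4", "M5")


@dataclass(frozen=True)
class GrowthLaw:
    """Selector for one of the five growth-rate laws.

    Thresholds (``c_hat``, ``sigma_hat``, ``beta``) live in the parameter
    set, which is the single source of truth for model constants; the law
    only selects which of them are active.
    """

    law_id: str

    def __post_init__(self) -> None:
        if self.law_id not in LAW_IDS:
            raise ValueError(f"unknown growth law {self.law_id!r}; expected one of {LAW_IDS}")

    @property
    def uses_stress(self) -> bool:
        return self.law_id != "M1"

    @property
    def permanent_necrosis(self) -> bool:
        return self.law_id in ("M3", "M4", "M5")

    @property
    def uses_global_measure(self) -> bool:
        return self.law_id in ("M4", "M5")


def _k_chat(params: ParamsLike) -> tuple[float, float, float, float]:
    """(k, c_hat, sigma_hat, beta) in the active unit system."""
    if isinstance(params, Params):
        return params.k, params.c_hat, params.sigma_hat, params.beta
    dp = as_dimensionless(params)
    return 1.0, dp.chat, dp.sigmahat_mu, dp.beta


def stress_modifier(s, sigma_hat: float):
    """Piecewise-linear growth modifier ``n(s)`` in [0, 1].

    Zero below the arrest threshold ``sigma_hat <= 0``, one for
    non-negative stress, linear in between; weakly increasing.  The
    degenerate case ``sigma_hat = 0`` is the pointwise limit: a step at 0.
    """
    if sigma_hat > 0:
        raise InvalidParameterError("sigma_hat must be non-positive")
    s = np.asarray(s, dtype=float)
    if sigma_hat == 0.0:
        out = np.where(s >= 0.0, 1.0, 0.0)
    else:
        out = np.clip(1.0 - s / sigma_hat, 0.0, 1.0)
    return out if out.ndim else float(out)


def growth_rate_m1(c, params: ParamsLike):
    """Nutrient-limited relative growth rate ``k (c - c_hat)``."""
    k, c_hat, _, _ = _k_chat(params)
    return k * (np.asarray(c, dtype=float) - c_hat)


def growth_rate_m2(c, sigma_r_local, params: ParamsLike):
    """Local-stress-modulated rate; necrotic decay (c < c_hat) is unaltered."""
    k, c_hat, sigma_hat, _ = _k_chat(params)
    c = np.asarray(c, dtype=float)
    n = stress_modifier(sigma_r_local, sigma_hat)
    return k * np.where(c >= c_hat, n * (c - c_hat), c - c_hat)


def _permanent_necrosis_rate(c, modifier, R, R_N, k, c_hat):
    """Common form of M3-M5: modifier * (c - c_hat), clamped >= 0, zero inside the front."""
    c = np.asarray(c, dtype=float)
    growing = np.maximum(c - c_hat, 0.0)  # clamp: preserves non-negativity at the front node
    return np.where(np.asarray(R) >= R_N, k * modifier * growing, 0.0)


def growth_rate_m3(c, sigma_r_local, R, R_N: float, params: ParamsLike):
    """Local-stress law with permanent necrosis: zero rate inside the front."""
    k, c_hat, sigma_hat, _ = _k_chat(params)
    n = stress_modifier(sigma_r_local, sigma_hat)
    return _permanent_necrosis_rate(c, n, R, R_N, k, c_hat)


def growth_rate_m4(c, global_measure: float, R, R_N: float, params: ParamsLike):
    """Non-local law: modifier evaluated on the global compressive measure."""
    k, c_hat, sigma_hat, _ = _k_chat(params)
    n = stress_modifier(global_measure, sigma_hat)
    return _permanent_necrosis_rate(c, n, R, R_N, k, c_hat)


def growth_rate_m5(
    c, global_measure: float, sigma_r_local, R, R_N: float, params: ParamsLike
):
    """Global measure combined with a local factor ``n(beta * sigma_r)``."""
    k, c_hat, sigma_hat, beta = _k_chat(params)
    n_global = stress_modifier(global_measure, sigma_hat)
    n_local = stress_modifier(beta * np.asarray(sigma_r_local, dtype=float), sigma_hat)
    return _permanent_necrosis_rate(c, n_global * n_local, R, R_N, k, c_hat)


def global_stress_measure(sigma_r: np.ndarray, sigma_theta: np.ndarray) -> float:
    """Most compressive principal stress over the whole body.

    The radial and hoop components are the eigenvalues of the diagonal
    stress tensor, so this is the largest-magnitude compressive stress
    experienced in any direction.
    """
    return float(min(np.min(sigma_r), np.min(sigma_theta)))


def update_necrotic_front(state: SpheroidState, params: ParamsLike) -> float:
    """Advance the necrotic front: the running maximum of the threshold preimage.

    The Eulerian necrosis radius (where ``c = c_hat``) is pulled back to a
    Lagrangian coordinate by monotone interpolation of ``r(R)``; the front
    never decreases, making necrosis permanent.
    """
    r_star = necrosis_boundary_radius(state.b, params)
    if r_star is None:
        return state.R_N
    R_star = float(np.interp(r_star, state.r, state.grid.nodes))
    return max(state.R_N, R_star)


def growth_rates_arrays(
    law: GrowthLaw,
    R: np.ndarray,
    R_N: float,
    c: np.ndarray,
    sigma_r: np.ndarray,
    sigma_theta: np.ndarray,
    params: ParamsLike,
) -> np.ndarray:
    """Nodewise relative growth rate ``f`` on raw field arrays."""
    if law.law_id == "M1":
        rate = growth_rate_m1(c, params)
        return rate if np.shape(rate) == R.shape else np.broadcast_to(rate, R.shape).copy()
    if law.law_id == "M2":
        return growth_rate_m2(c, sigma_r, params)
    if law.law_id == "M3":
        return growth_rate_m3(c, sigma_r, R, R_N, params)
    measure = global_stress_measure(sigma_r, sigma_theta)
    if law.law_id == "M4":
        return growth_rate_m4(c, measure, R, R_N, params)
    return growth_rate_m5(c, measure, sigma_r, R, R_N, params)


def growth_rates(
    law: Union[GrowthLaw, str],
    state: SpheroidState,
    c: np.ndarray,
    stress: StressProfile,
    params: ParamsLike,
) -> np.ndarray:
    """Nodewise relative growth rate ``f`` for the selected law."""
    if isinstance(law, str):
        law = GrowthLaw(law)
    return growth_rates_arrays(
        law, state.grid.nodes, state.R_N, c, stress.sigma_r, stress.sigma_theta, params
    )
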