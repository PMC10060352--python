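"""Quasistatic nutrient field inside the spheroid.

The nutrient obeys a reaction-diffusion balance with constant consumption;
on growth timescales diffusion is instantaneous, giving a parabolic radial
profile pinned to the surface concentration.  For outer radii beyond the
depletion radius the profile predicts negative core concentrations; the
model deliberately keeps using the parabolic form there (see
``nutrient_profile``), and the field carries a validity flag instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .params import ParamsLike, Params, as_dimensionless

__all__ = [
    "NutrientField",
    "nutrient_profile",
    "depletion_radius",
    "necrosis_boundary_radius",
]

logger = logging.getLogger(__name__)


class NutrientDomainError(ValueError):
    """Raised when radii fall outside [0, b]."""


class NutrientValidityError(ValueError):
    """Raised in strict mode when the parabolic profile is invalid (b > b_hat)."""


@dataclass(frozen=True)
class NutrientField:
    """Nutrient concentrations sampled at Eulerian radii.

    ``valid`` is False when the outer radius exceeds the depletion radius,
    i.e. when the parabolic profile predicts negative core concentrations.
    """

    r: np.ndarray
    values: np.ndarray
    b: float
    valid: bool


def _chat_scales(params: ParamsLike) -> tuple[float, float, float]:
    """Return (chat, L, c_scale): c_scale converts dimensionless c to output units."""
    dp = as_dimensionless(params)
    if isinstance(params, Params):
        return dp.chat, dp.L, params.c_inf
    return dp.chat, 1.0, 1.0


def nutrient_profile(
    r: np.ndarray,
    b: float,
    params: ParamsLike,
    *,
    strict: bool = False,
) -> NutrientField:
    """Evaluate the quasistatic nutrient profile at radii ``r``.

    In units of (L, c_inf) the profile is ``c = (r^2 - b^2)/6 + 1`` with
    ``c(b) = 1`` exactly.  Negative values are returned unmodified when
    ``b`` exceeds the depletion radius — a warning is logged and the field
    is flagged invalid; set ``strict=True`` to raise instead.
    """
    _, L, c_scale = _chat_scales(params)
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > b * (1 + 1e-12)):
        raise NutrientDomainError("radii must lie in [0, b]")
    b_hat = depletion_radius(params)
    valid = b <= b_hat * (1 + 1e-12)
    if not valid:
        msg = (
            f"outer radius b={b:.6g} exceeds the depletion radius "
            f"b_hat={b_hat:.6g}; parabolic nutrient profile predicts "
            "negative core concentrations"
        )
        if strict:
            raise NutrientValidityError(msg)
        logger.warning(msg)
    c = c_scale * ((np.square(r / L) - (b / L) ** 2) / 6.0 + 1.0)
    return NutrientField(r=r, values=c, b=float(b), valid=valid)


def depletion_radius(params: ParamsLike) -> float:
    """Outer radius at which the centre concentration reaches zero: sqrt(6)*L."""
    dp = as_dimensionless(params)
    L = dp.L if isinstance(params, Params) else 1.0
    return math.sqrt(6.0) * L


def necrosis_boundary_radius(b: float, params: ParamsLike) -> float | None:
    """Eulerian radius where the nutrient hits the necrosis threshold.

    Solves ``c(r*) = c_hat`` for the parabolic profile:
    ``r* = sqrt(b^2 - 6 L^2 (1 - chat))`` in the units of ``b``.  Returns
    ``None`` when the centre concentration already exceeds the threshold
    (fully perfused spheroid).
    """
    if b < 0:
        raise NutrientDomainError("outer radius must be non-negative")
    chat, L, _ = _chat_scales(params)
    gap = b * b - 6.0 * L * L * (1.0 - chat)
    if gap <= 0.0:
        return None
    return math.sqrt(gap)
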