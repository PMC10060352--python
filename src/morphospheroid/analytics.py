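"""Closed-form results for the nutrient-only model and robust-model bounds.

These serve both as user-facing calculators and as independent oracles for
the numerical simulator: the explicit outer-radius solution of the
nutrient-limited law, its steady states and necrotic geometry, the radius
upper bound of the globally stress-arrested laws, and the late-time
exponential rate of the boundary hoop stress.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import InvalidParameterError, Params, ParamsLike, as_dimensionless

__all__ = [
    "SteadyStateSummary",
    "closed_form_b",
    "steady_state_radius",
    "radius_upper_bound",
    "boundary_stress_asymptotic_rate",
]

#: Steady necrotic-to-outer radius ratio of the nutrient-only model;
#: parameter independent.
NECROTIC_RADIUS_RATIO = 3.0 / math.sqrt(15.0)


@dataclass(frozen=True)
class SteadyStateSummary:
    """Steady-state geometry of the nutrient-only model (law M1)."""

    b_star: float
    r_necrotic: float
    necrotic_volume_fraction: float
    stability: dict[str, str]

    def to_dict(self) -> dict:
        return {
            "b_star": self.b_star,
            "r_necrotic": self.r_necrotic,
            "necrotic_volume_fraction": self.necrotic_volume_fraction,
            "stability": dict(self.stability),
        }


def _dimless_and_scales(params: ParamsLike) -> tuple[float, float, float, float]:
    """(chat, B_over_L, L_out, T_out): output scales are 1 for dimensionless input."""
    dp = as_dimensionless(params)
    if isinstance(params, Params):
        return dp.chat, dp.B_over_L, dp.L, dp.T
    return dp.chat, dp.B_over_L, 1.0, 1.0


def closed_form_b(t, params: ParamsLike):
    """Explicit outer-radius solution of the nutrient-limited law.

    In units of (L, T):
    ``b(t) = sqrt(15 (1 - chat)) / sqrt(1 + (15 (1 - chat) / B^2 - 1) exp(-2 (1 - chat) t))``.
    Solves ``db/dt = b [ -b^2 / 15 + (1 - chat) ]`` with ``b(0) = B``.
    """
    chat, B, L, T = _dimless_and_scales(params)
    if chat >= 1:
        raise InvalidParameterError("c_hat must be below c_inf")
    t = np.asarray(t, dtype=float) / T
    bstar_sq = 15.0 * (1.0 - chat)
    b = np.sqrt(bstar_sq / (1.0 + (bstar_sq / B**2 - 1.0) * np.exp(-2.0 * (1.0 - chat) * t)))
    out = L * b
    return out if out.ndim else float(out)


def steady_state_radius(params: ParamsLike) -> SteadyStateSummary:
    """Steady outer and necrotic radii of the nutrient-only model.

    ``b* = sqrt(15 (1 - chat)) L`` and ``r_nec = 3 sqrt(1 - chat) L``; the
    ratio ``r_nec / b* = 3/sqrt(15)`` and hence the necrotic volume
    fraction ``(3/sqrt(15))^3 ~ 46%`` are parameter independent.  The
    trivial state ``b = 0`` is linearly unstable, ``b = b*`` stable.
    """
    chat, _, L, _ = _dimless_and_scales(params)
    if chat >= 1:
        raise InvalidParameterError("c_hat must be below c_inf")
    b_star = math.sqrt(15.0 * (1.0 - chat)) * L
    r_nec = 3.0 * math.sqrt(1.0 - chat) * L
    return SteadyStateSummary(
        b_star=b_star,
        r_necrotic=r_nec,
        necrotic_volume_fraction=NECROTIC_RADIUS_RATIO**3,
        stability={"b=0": "unstable", "b=b_star": "stable"},
    )


def radius_upper_bound(params: ParamsLike) -> float:
    """Upper radius bound for the globally stress-arrested laws (M4/M5).

    Growth arrests once the boundary radial stress reaches the threshold:
    ``-kappa (b - B)/B = sigma_hat`` gives ``b = B (1 - sigma_hat/kappa)``
    for ``kappa > 0``.  In free suspension (``kappa = 0``) the argument
    does not apply and ``inf`` is returned.
    """
    dp = as_dimensionless(params)
    _, B, L, _ = _dimless_and_scales(params)
    if dp.kappa_mu == 0.0:
        return math.inf
    return B * L * (1.0 - dp.sigmahat_mu / dp.kappa_mu)


def boundary_stress_asymptotic_rate(params: ParamsLike) -> float:
    """Late-time exponential rate of the boundary hoop stress under law M1.

    At the steady outer radius the boundary tissue keeps growing at rate
    ``k (c_inf - c_hat)``, so ``gamma(B, t)`` grows like
    ``exp(k (c_inf - c_hat) t)`` and the elastic stretch
    ``alpha(B, t) = b / (B gamma)`` decays at the same rate.  The hoop
    stress is dominated by the ``alpha^-4`` term of the neo-Hookean
    response, giving ``|sigma_theta(b, t)| ~ exp(4 k (c_inf - c_hat) t)``.
    Returns ``4 k (c_inf - c_hat)`` (i.e. ``4 (1 - chat)`` per unit T for
    dimensionless input).
    """
    chat, _, _, T = _dimless_and_scales(params)
    return 4.0 * (1.0 - chat) / T
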