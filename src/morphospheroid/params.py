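"""Model parameters, characteristic scales, and nondimensionalisation.

All numerical work in this package is performed in dimensionless variables:
lengths are measured in units of the diffusive lengthscale ``L``, times in
units of the growth timescale ``T``, stresses in units of the shear modulus
``mu``, and concentrations in units of the surface concentration ``c_inf``.
Dimensional quantities are converted at the boundary of the package.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Union

__all__ = [
    "Params",
    "DimensionlessParams",
    "diffusive_scales",
    "to_dimensionless",
    "from_dimensionless",
    "load_params",
    "FIGURE_PARAMS",
]


class InvalidParameterError(ValueError):
    """Raised when a parameter set violates its invariants."""


@dataclass(frozen=True)
class Params:
    """Dimensional model parameters.

    Attributes
    ----------
    k : float
        Growth-rate constant, units 1/(concentration * time).
    c_inf : float
        Nutrient concentration at the spheroid surface.
    c_hat : float
        Necrosis threshold concentration, ``0 < c_hat < c_inf``.
    lam : float
        Nutrient consumption rate, concentration/time.
    D : float
        Nutrient diffusivity, length^2/time.
    mu : float
        Shear modulus, stress units, > 0.
    kappa : float
        External-medium stiffness, stress units, >= 0.
    sigma_hat : float
        Radial-stress growth-arrest threshold, <= 0.
    beta : float
        Local stress-sensitivity multiplier (used by law M5), > 0.
    B : float
        Initial spheroid radius, length units, > 0.
    """

    k: float
    c_inf: float
    c_hat: float
    lam: float
    D: float
    mu: float
    kappa: float = 0.0
    sigma_hat: float = 0.0
    beta: float = 1.0
    B: float = 1.0

    def __post_init__(self) -> None:
        if not (self.k > 0 and self.lam > 0 and self.D > 0 and self.c_inf > 0):
            raise InvalidParameterError(
                "k, lam, D and c_inf must all be positive"
            )
        if not (0 < self.c_hat < self.c_inf):
            raise InvalidParameterError("c_hat must lie in (0, c_inf)")
        if not self.mu > 0:
            raise InvalidParameterError("mu must be positive")
        if self.kappa < 0:
            raise InvalidParameterError("kappa must be non-negative")
        if self.sigma_hat > 0:
            raise InvalidParameterError("sigma_hat must be non-positive")
        if not self.beta > 0:
            raise InvalidParameterError("beta must be positive")
        if not self.B > 0:
            raise InvalidParameterError("B must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "Params":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class DimensionlessParams:
    """Dimensionless parameter set used by the simulator internals.

    ``chat = c_hat/c_inf``, ``kappa_mu = kappa/mu``,
    ``sigmahat_mu = sigma_hat/mu``, ``B_over_L = B/L``.  ``L`` and ``T`` are
    retained so that dimensional output can be reconstructed.
    """

    chat: float
    kappa_mu: float = 0.0
    sigmahat_mu: float = 0.0
    beta: float = 1.0
    B_over_L: float = 1.0
    L: float = 1.0
    T: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.chat < 1):
            raise InvalidParameterError("chat must lie in (0, 1)")
        if self.kappa_mu < 0:
            raise InvalidParameterError("kappa_mu must be non-negative")
        if self.sigmahat_mu > 0:
            raise InvalidParameterError("sigmahat_mu must be non-positive")
        if not self.beta > 0:
            raise InvalidParameterError("beta must be positive")
        if not self.B_over_L > 0:
            raise InvalidParameterError("B_over_L must be positive")
        if not (self.L > 0 and self.T > 0):
            raise InvalidParameterError("scales L and T must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DimensionlessParams":
        return cls(**json.loads(text))


ParamsLike = Union[Params, DimensionlessParams]


def diffusive_scales(params: Params) -> tuple[float, float]:
    """Characteristic length and time scales of the nutrient problem.

    ``L = sqrt(D * c_inf / lam)`` balances nutrient supply against
    consumption; ``T = 1 / (k * c_inf)`` is the growth timescale at surface
    nutrient levels.
    """
    L = math.sqrt(params.D * params.c_inf / params.lam)
    T = 1.0 / (params.k * params.c_inf)
    return L, T


def to_dimensionless(params: Params) -> DimensionlessParams:
    """Convert a dimensional parameter set to its dimensionless form."""
    L, T = diffusive_scales(params)
    return DimensionlessParams(
        chat=params.c_hat / params.c_inf,
        kappa_mu=params.kappa / params.mu,
        sigmahat_mu=params.sigma_hat / params.mu,
        beta=params.beta,
        B_over_L=params.B / L,
        L=L,
        T=T,
    )


def from_dimensionless(
    dimless: DimensionlessParams,
    *,
    mu: float = 1.0,
    c_inf: float = 1.0,
    D: float = 1.0,
) -> Params:
    """Reconstruct dimensional parameters from a dimensionless set.

    The dimensionless form discards three independent scales; supplying
    reference values for ``mu``, ``c_inf`` and ``D`` (together with the
    stored ``L`` and ``T``) makes the inversion unique:
    ``lam = D*c_inf/L**2`` and ``k = 1/(T*c_inf)``.
    """
    lam = D * c_inf / dimless.L**2
    k = 1.0 / (dimless.T * c_inf)
    return Params(
        k=k,
        c_inf=c_inf,
        c_hat=dimless.chat * c_inf,
        lam=lam,
        D=D,
        mu=mu,
        kappa=dimless.kappa_mu * mu,
        sigma_hat=dimless.sigmahat_mu * mu,
        beta=dimless.beta,
        B=dimless.B_over_L * dimless.L,
    )


def as_dimensionless(params: ParamsLike) -> DimensionlessParams:
    """Coerce either parameter flavour to the dimensionless form."""
    if isinstance(params, DimensionlessParams):
        return params
    return to_dimensionless(params)


def load_params(path: str | Path) -> ParamsLike:
    """Read a flat key-value parameter file (YAML or JSON).

    Keys matching :class:`DimensionlessParams` fields produce a
    dimensionless set; keys matching :class:`Params` fields produce a
    dimensional one.  Mixing the two vocabularies is an error.
    """
    import yaml

    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise InvalidParameterError(f"parameter file {path} is not a mapping")
    dimless_keys = {"chat", "kappa_mu", "sigmahat_mu", "B_over_L"}
    dim_keys = {"k", "c_inf", "c_hat", "lam", "D", "mu", "kappa", "sigma_hat", "B"}
    has_dimless = bool(dimless_keys & data.keys())
    has_dim = bool(dim_keys & data.keys())
    if has_dimless and has_dim:
        raise InvalidParameterError(
            "parameter file mixes dimensional and dimensionless keys"
        )
    if has_dimless:
        return DimensionlessParams(**data)
    return Params(**data)


# Named dimensionless parameter sets used in the published illustrations.
# fig5_text and fig5_caption differ only in kappa_mu: the running text and
# the figure caption disagree on its value, so both variants are shipped.
FIGURE_PARAMS: dict[str, DimensionlessParams] = {
    "fig3": DimensionlessParams(chat=4 / 5, kappa_mu=0.0, B_over_L=1.0),
    "fig5_text": DimensionlessParams(
        chat=4 / 5, kappa_mu=100.0, sigmahat_mu=-100.0, B_over_L=1.0
    ),
    "fig5_caption": DimensionlessParams(
        chat=4 / 5, kappa_mu=316.2, sigmahat_mu=-100.0, B_over_L=1.0
    ),
    "fig6": DimensionlessParams(
        chat=9 / 10, kappa_mu=1.0, sigmahat_mu=-100.0, B_over_L=0.01
    ),
    "fig7": DimensionlessParams(
        chat=4 / 5, kappa_mu=102.4, sigmahat_mu=-100.0, B_over_L=1.0
    ),
    "fig9": DimensionlessParams(
        chat=1 / 4, kappa_mu=0.1, sigmahat_mu=-1.0, beta=6.25, B_over_L=1.0
    ),
}
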