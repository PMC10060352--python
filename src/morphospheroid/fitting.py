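"""Growth-curve fitting and synthetic multi-condition data generation.

The fitted curve is the simulated outer radius ``b(t) = L * b~((t - t0)/T)``
with dimensionless shape parameters (``chat``, ``sigmahat_mu``, ``beta``)
and scales ``L`` (length) and ``T`` (time) shared across conditions; only
the initial radius ``B`` and the external stiffness ``kappa_mu`` may vary
per dataset.  Free-suspension datasets force ``kappa_mu = 0``.

The objective is an unweighted sum of squared radius residuals by default
(volume and relative variants are available); minimisation is bounded
Nelder-Mead from Latin-hypercube multistarts, deterministic per seed.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .params import DimensionlessParams, InvalidParameterError
from .simulator import Controls, simulate

__all__ = [
    "GrowthDataset",
    "FitSpec",
    "FitResult",
    "read_growth_csv",
    "objective",
    "fit",
    "synthesize_growth_data",
]

SHARED_NAMES = ("L", "T", "chat", "sigmahat_mu", "beta")
PER_DATASET_NAMES = ("B", "kappa_mu")

#: Finite penalty returned when a proposed parameter set cannot be simulated.
PENALTY = 1e12


class ParseError(ValueError):
    """Raised on malformed growth-curve CSV input."""


class FitFailureError(RuntimeError):
    """Raised when no feasible multistart can be evaluated."""


@dataclass(frozen=True)
class GrowthDataset:
    """One observed growth curve: strictly increasing times, positive radii."""

    label: str
    times: np.ndarray
    radii: np.ndarray
    condition: str = "embedded"  # "free" (suspension) or "embedded"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        radii = np.asarray(self.radii, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "radii", radii)
        if times.size == 0:
            raise ParseError(f"dataset {self.label!r} is empty")
        if times.shape != radii.shape:
            raise ParseError("times and radii must have the same length")
        if np.any(np.diff(times) <= 0):
            raise ParseError("observation times must be strictly increasing")
        if np.any(radii <= 0):
            raise ParseError("radii must be positive")
        if self.condition not in ("free", "embedded"):
            raise ParseError("condition must be 'free' or 'embedded'")


def read_growth_csv(
    path: str | Path,
    *,
    value: str = "radius",
    time_scale: float = 1.0,
    length_scale: float = 1.0,
    label: str | None = None,
    condition: str = "embedded",
) -> GrowthDataset:
    """Read a two-column (time, size) CSV with a header row.

    ``value="diameter"`` halves the second column.  ``time_scale`` and
    ``length_scale`` multiply the raw columns to convert units.
    """
    if value not in ("radius", "diameter"):
        raise ParseError("value must be 'radius' or 'diameter'")
    path = Path(path)
    times: list[float] = []
    radii: list[float] = []
    with path.open(newline="") as handle:
        reader = csv.reader(handle)
        header = next(reader, None)
        if header is None:
            raise ParseError(f"{path}: empty file")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) < 2:
                raise ParseError(f"{path}:{lineno}: expected two columns")
            try:
                t = float(row[0]) * time_scale
                size = float(row[1]) * length_scale
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            times.append(t)
            radii.append(size / 2.0 if value == "diameter" else size)
    if not times:
        raise ParseError(f"{path}: no data rows")
    try:
        return GrowthDataset(
            label=label or path.stem,
            times=np.asarray(times),
            radii=np.asarray(radii),
            condition=condition,
        )
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from None


@dataclass(frozen=True)
class FitSpec:
    """What to fit: the law, which parameters are free, their bounds.

    ``shared_bounds`` maps shared parameter names (subset of
    ``L, T, chat, sigmahat_mu, beta``) to ``(lo, hi)`` bounds;
    ``fixed`` supplies values for every shared parameter that is not free.
    ``per_dataset_bounds`` maps names in ``{B, kappa_mu}`` to bounds;
    per-dataset parameters not listed there must appear in
    ``per_dataset_fixed`` (one mapping per dataset).
    """

    law_id: str
    shared_bounds: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    per_dataset_bounds: dict = field(default_factory=dict)
    per_dataset_fixed: tuple = ()
    objective_kind: str = "radius"  # "radius" | "volume" | "relative"
    controls: Controls = field(
        default_factory=lambda: Controls(n=80, dt=0.04, steady_tol=0.0)
    )
    n_starts: int = 16

    def __post_init__(self) -> None:
        for name in self.shared_bounds:
            if name not in SHARED_NAMES:
                raise InvalidParameterError(f"unknown shared parameter {name!r}")
        for name in self.per_dataset_bounds:
            if name not in PER_DATASET_NAMES:
                raise InvalidParameterError(f"unknown per-dataset parameter {name!r}")
        if self.objective_kind not in ("radius", "volume", "relative"):
            raise InvalidParameterError(f"unknown objective {self.objective_kind!r}")


@dataclass
class FitResult:
    """Best fit found over all starts, with a full run manifest."""

    shared: dict
    per_dataset: list[dict]
    per_dataset_rss: list[float]
    total_objective: float
    converged: bool
    manifest: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "shared": self.shared,
                "per_dataset": self.per_dataset,
                "per_dataset_rss": self.per_dataset_rss,
                "total_objective": self.total_objective,
                "converged": self.converged,
                "manifest": self.manifest,
            },
            indent=2,
        )


def _model_radii(
    shared: dict, per_ds: dict, law_id: str, times: np.ndarray, controls: Controls
) -> np.ndarray:
    """Simulated radii at observation times (model t=0 at first observation)."""
    L = shared["L"]
    T = shared["T"]
    dp = DimensionlessParams(
        chat=shared["chat"],
        kappa_mu=per_ds["kappa_mu"],
        sigmahat_mu=shared.get("sigmahat_mu", 0.0),
        beta=shared.get("beta", 1.0),
        B_over_L=per_ds["B"] / L,
    )
    t_rel = (times - times[0]) / T
    t_end = float(t_rel[-1])
    if t_end <= 0:  # single observation at t0
        return np.full(times.shape, per_ds["B"])
    traj = simulate(dp, law_id, t_end, controls)
    return L * np.interp(t_rel, traj.times, traj.b)


def _residual_ss(kind: str, model: np.ndarray, obs: np.ndarray) -> float:
    if kind == "volume":
        return float(np.sum((model**3 - obs**3) ** 2))
    if kind == "relative":
        return float(np.sum(((model - obs) / obs) ** 2))
    return float(np.sum((model - obs) ** 2))


def objective(
    fitspec: FitSpec,
    shared: dict,
    per_dataset: Sequence[dict],
    datasets: Sequence[GrowthDataset],
) -> float:
    """Sum over datasets of squared residuals; simulation failures are penalised."""
    total = 0.0
    for per_ds, ds in zip(per_dataset, datasets):
        pd_eff = dict(per_ds)
        if ds.condition == "free":
            pd_eff["kappa_mu"] = 0.0
        try:
            model = _model_radii(shared, pd_eff, fitspec.law_id, ds.times, fitspec.controls)
        except Exception:
            return PENALTY
        if not np.all(np.isfinite(model)):
            return PENALTY
        total += _residual_ss(fitspec.objective_kind, model, ds.radii)
    return total


def _free_layout(fitspec: FitSpec, datasets: Sequence[GrowthDataset]):
    """Flatten free parameters into a vector layout with bounds."""
    names: list[tuple[str, int | None]] = []  # (param name, dataset index or None)
    bounds: list[tuple[float, float]] = []
    for name in SHARED_NAMES:
        if name in fitspec.shared_bounds:
            names.append((name, None))
            bounds.append(tuple(fitspec.shared_bounds[name]))
    for i, ds in enumerate(datasets):
        for name in PER_DATASET_NAMES:
            if name in fitspec.per_dataset_bounds:
                if name == "kappa_mu" and ds.condition == "free":
                    continue  # forced to zero, never free
                names.append((name, i))
                bounds.append(tuple(fitspec.per_dataset_bounds[name]))
    return names, bounds


def _unpack(
    x: np.ndarray,
    names,
    fitspec: FitSpec,
    datasets: Sequence[GrowthDataset],
) -> tuple[dict, list[dict]]:
    shared = dict(fitspec.fixed)
    fixed_per = list(fitspec.per_dataset_fixed) or [{} for _ in datasets]
    per_dataset = [dict(f) for f in fixed_per]
    for ds, per in zip(datasets, per_dataset):
        per.setdefault("kappa_mu", 0.0)
        if ds.condition == "free":
            per["kappa_mu"] = 0.0
    for value, (name, idx) in zip(x, names):
        if idx is None:
            shared[name] = float(value)
        else:
            per_dataset[idx][name] = float(value)
    return shared, per_dataset


def fit(
    fitspec: FitSpec,
    datasets: Sequence[GrowthDataset],
    seed: int = 0,
    starts: int | None = None,
) -> FitResult:
    """Multistart bounded Nelder-Mead minimisation of :func:`objective`.

    Deterministic for a given ``seed``; all starts are logged in the
    manifest.  With no free parameters the objective is evaluated once at
    the fixed point.  When every shared parameter is fixed the objective
    decouples across datasets and each is fitted independently.
    """
    if not datasets:
        raise FitFailureError("at least one dataset is required")
    if (
        not fitspec.shared_bounds
        and fitspec.per_dataset_bounds
        and len(datasets) > 1
    ):
        return _fit_separable(fitspec, datasets, seed, starts)
    names, bounds = _free_layout(fitspec, datasets)
    n_starts = starts if starts is not None else fitspec.n_starts

    def full_objective(x: np.ndarray) -> float:
        shared, per_dataset = _unpack(x, names, fitspec, datasets)
        return objective(fitspec, shared, per_dataset, datasets)

    start_log: list[dict] = []
    if not names:
        shared, per_dataset = _unpack(np.empty(0), names, fitspec, datasets)
        total = objective(fitspec, shared, per_dataset, datasets)
        best_x = np.empty(0)
        converged = True
    else:
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        sampler = qmc.LatinHypercube(d=len(bounds), seed=seed)
        points = lo + sampler.random(n=n_starts) * (hi - lo)
        best_x, total, converged = None, math.inf, False
        for x0 in points:
            res = minimize(
                full_objective,
                x0,
                method="Nelder-Mead",
                bounds=bounds,
                options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 300 * len(bounds)},
            )
            start_log.append(
                {"x0": x0.tolist(), "x": res.x.tolist(), "fun": float(res.fun), "success": bool(res.success)}
            )
            if res.fun < total:
                best_x, total, converged = res.x, float(res.fun), bool(res.success)
        if best_x is None:
            raise FitFailureError("no feasible start could be evaluated")
        shared, per_dataset = _unpack(best_x, names, fitspec, datasets)

    rss = []
    for per_ds, ds in zip(per_dataset, datasets):
        rss.append(objective(fitspec, shared, [per_ds], [ds]))
    manifest = {
        "seed": seed,
        "n_starts": n_starts,
        "law": fitspec.law_id,
        "objective": fitspec.objective_kind,
        "free_parameters": [
            {"name": n, "dataset": i} for n, i in names
        ],
        "bounds": [list(b) for b in bounds],
        "starts": start_log,
        "controls": {"n": fitspec.controls.n, "dt": fitspec.controls.dt},
    }
    return FitResult(
        shared=shared,
        per_dataset=per_dataset,
        per_dataset_rss=rss,
        total_objective=total,
        converged=converged,
        manifest=manifest,
    )


def _fit_separable(
    fitspec: FitSpec,
    datasets: Sequence[GrowthDataset],
    seed: int,
    starts: int | None,
) -> FitResult:
    """Fit each dataset on its own when shared parameters are all fixed."""
    fixed_per = list(fitspec.per_dataset_fixed) or [{} for _ in datasets]
    per_dataset: list[dict] = []
    rss: list[float] = []
    manifests: list[dict] = []
    converged = True
    for i, ds in enumerate(datasets):
        sub = FitSpec(
            law_id=fitspec.law_id,
            shared_bounds={},
            fixed=fitspec.fixed,
            per_dataset_bounds=fitspec.per_dataset_bounds,
            per_dataset_fixed=(fixed_per[i],),
            objective_kind=fitspec.objective_kind,
            controls=fitspec.controls,
            n_starts=fitspec.n_starts,
        )
        res = fit(sub, [ds], seed=seed + i, starts=starts)
        per_dataset.append(res.per_dataset[0])
        rss.append(res.per_dataset_rss[0])
        manifests.append(res.manifest)
        converged = converged and res.converged
    return FitResult(
        shared=dict(fitspec.fixed),
        per_dataset=per_dataset,
        per_dataset_rss=rss,
        total_objective=float(sum(rss)),
        converged=converged,
        manifest={"seed": seed, "separable": True, "per_dataset_fits": manifests},
    )


def synthesize_growth_data(
    shared: dict,
    conditions: Sequence[dict],
    law_id: str,
    times: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    controls: Controls | None = None,
) -> list[GrowthDataset]:
    """Simulated multi-condition growth curves with additive Gaussian noise.

    ``shared`` carries ``L, T, chat, sigmahat_mu, beta``; each condition is
    a mapping with ``B``, ``kappa_mu``, and optional ``label`` /
    ``condition``.  With ``noise_sd = 0`` the samples lie exactly on the
    model curves; identical seeds give identical datasets.  Emulates the
    canonical experiment: one free-suspension condition and embedded
    conditions of increasing stiffness showing reduced growth.
    """
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be non-negative")
    times = np.asarray(times, dtype=float)
    controls = controls or Controls(n=200, dt=0.01, steady_tol=0.0)
    rng = np.random.default_rng(seed)
    out = []
    for i, cond in enumerate(conditions):
        per_ds = {"B": cond["B"], "kappa_mu": cond.get("kappa_mu", 0.0)}
        condition = cond.get("condition", "free" if per_ds["kappa_mu"] == 0.0 else "embedded")
        radii = _model_radii(shared, per_ds, law_id, times, controls)
        noisy = radii + rng.normal(0.0, noise_sd, size=radii.shape)
        noisy = np.maximum(noisy, 1e-12)  # keep radii positive under noise
        out.append(
            GrowthDataset(
                label=cond.get("label", f"condition_{i}"),
                times=times,
                radii=noisy,
                condition=condition,
            )
        )
    return out
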