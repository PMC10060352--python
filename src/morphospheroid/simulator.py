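"""Time integration of the coupled quasistatic growth system.

The only evolving unknowns are the growth-stretch field ``gamma(R)`` and
the necrotic front ``R_N``; radii, nutrient, and stress are quasistatic
closures recomputed from ``gamma`` at every evaluation.  Integration is
classical four-stage Runge-Kutta on ``ln gamma`` with a fixed step, which
keeps ``gamma`` positive by construction.

All computation is dimensionless: lengths in units of the diffusive
lengthscale L, times in units of T, stresses in units of mu.  Dimensional
parameter sets are converted on entry and the scales recorded on the
trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Union

import numpy as np

from .growth_laws import (
    GrowthLaw,
    global_stress_measure,
    growth_rates_arrays,
    update_necrotic_front,
)
from .kinematics import LagrangianGrid, SpheroidState, radius_from_growth
from .mechanics import loaded_profiles
from .params import DimensionlessParams, ParamsLike, as_dimensionless

__all__ = [
    "Controls",
    "Trajectory",
    "step",
    "simulate",
    "material_paths",
    "boundary_stress_history",
]

_SQRT6 = math.sqrt(6.0)

# Floor on ln(gamma): fully decayed necrotic material is held at a
# physically negligible stretch (~1e-35) so that the cubed field cannot
# underflow and break positivity of the radius quadrature.
_LN_GAMMA_FLOOR = -80.0


class IntegrationFailureError(RuntimeError):
    """Raised when the integrator encounters a non-finite rate or state."""

    def __init__(self, message: str, last_state: SpheroidState | None = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class Controls:
    """Numerical controls for :func:`simulate`.

    ``dt`` is in units of T.  ``steady_tol`` is the relative change of the
    outer radius per unit T below which the run is declared steady;
    set it to 0 to disable early termination.  ``snapshot_stride`` > 0
    stores a full state every that many steps (plus the final state).

    Material turnover drives interior points towards the centre, squeezing
    the proliferating rim into an exponentially thin Lagrangian layer that
    a fixed grid cannot resolve; when ``remesh`` is on, interior nodes are
    redistributed uniformly in the current Eulerian radius (interpolating
    ``ln gamma``) whenever spacing degrades by ``remesh_factor``.
    """

    n: int = 400
    dt: float = 1.0 / 200.0
    steady_tol: float = 1e-8
    steady_window: float = 1.0
    gamma_max: float = 1e12
    snapshot_stride: int = 0
    remesh: bool = True
    remesh_factor: float = 2.0


@dataclass
class Trajectory:
    """Recorded time series of a simulation run."""

    times: np.ndarray
    b: np.ndarray
    center_sigma_r: np.ndarray
    r_necrotic: np.ndarray
    global_measure: np.ndarray
    snapshots: list[SpheroidState]
    status: str
    law_id: str
    params: DimensionlessParams
    controls: Controls
    nutrient_valid: bool

    @property
    def final_state(self) -> SpheroidState:
        if not self.snapshots:
            raise ValueError("no snapshots stored; rerun with snapshot_stride > 0")
        return self.snapshots[-1]

    def manifest(self) -> dict:
        """JSON-serialisable run summary."""
        return {
            "law": self.law_id,
            "status": self.status,
            "t_final": float(self.times[-1]),
            "b_final": float(self.b[-1]),
            "n": self.controls.n,
            "dt": self.controls.dt,
            "steady_tol": self.controls.steady_tol,
            "gamma_max": self.controls.gamma_max,
            "nutrient_valid": self.nutrient_valid,
            "params": {
                "chat": self.params.chat,
                "kappa_mu": self.params.kappa_mu,
                "sigmahat_mu": self.params.sigmahat_mu,
                "beta": self.params.beta,
                "B_over_L": self.params.B_over_L,
            },
        }


class _Workspace:
    """Precomputed grid quantities for the raw-array RK4 loop."""

    __slots__ = ("grid", "R", "R6", "dR", "dR3", "B", "kappa")

    def __init__(self, grid: LagrangianGrid, params: DimensionlessParams):
        self.grid = grid
        self.R = grid.nodes
        self.R6 = self.R**6
        self.dR = np.diff(self.R)
        self.dR3 = np.diff(self.R**3)
        self.B = grid.B
        self.kappa = params.kappa_mu


def _closure(ws: _Workspace, y: np.ndarray):
    """Quasistatic fields from ln(gamma): (gamma, r, b, c, sigma_r, sigma_theta).

    Mirrors kinematics.radius_from_growth, the dimensionless nutrient
    profile, and mechanics.radial_stress/hoop_stress on raw arrays; the
    unit-test suite asserts the two routes agree.
    """
    gamma = np.exp(np.maximum(y, _LN_GAMMA_FLOOR))
    g3 = gamma**3
    r3 = np.empty_like(y)
    r3[0] = 0.0
    np.cumsum(0.5 * (g3[:-1] + g3[1:]) * ws.dR3, out=r3[1:])
    r = np.cbrt(r3)
    b = r[-1]
    c = (r * r - b * b) / 6.0 + 1.0
    # radial stress: inward trapezoid of 2*gamma*(r^6 - gamma^6 R^6)/r^7
    f = np.empty_like(y)
    f[0] = 0.0  # removable limit at the centre
    r6 = r3[1:] ** 2
    f[1:] = 2.0 * gamma[1:] * (r6 - g3[1:] ** 2 * ws.R6[1:]) / (r6 * r[1:])
    increments = 0.5 * (f[:-1] + f[1:]) * ws.dR
    boundary = -ws.kappa * (b - ws.B) / ws.B
    sigma_r = np.empty_like(y)
    sigma_r[-1] = boundary
    sigma_r[:-1] = boundary - np.cumsum(increments[::-1])[::-1]
    alpha_sq = np.empty_like(y)
    alpha_sq[0] = 1.0
    alpha_sq[1:] = (r[1:] / (ws.R[1:] * gamma[1:])) ** 2
    sigma_theta = sigma_r + (alpha_sq - alpha_sq**-2)
    return gamma, r, b, c, sigma_r, sigma_theta


def _rk4_raw(
    ws: _Workspace,
    y: np.ndarray,
    R_N: float,
    law: GrowthLaw,
    params: DimensionlessParams,
    dt: float,
    first_closure=None,
) -> np.ndarray:
    """One RK4 update of ln(gamma); quasistatic closure at every stage."""
    if first_closure is None:
        first_closure = _closure(ws, y)
    _, _, _, c1, sr1, st1 = first_closure
    k1 = growth_rates_arrays(law, ws.R, R_N, c1, sr1, st1, params)

    _, _, _, c2, sr2, st2 = _closure(ws, y + 0.5 * dt * k1)
    k2 = growth_rates_arrays(law, ws.R, R_N, c2, sr2, st2, params)

    _, _, _, c3, sr3, st3 = _closure(ws, y + 0.5 * dt * k2)
    k3 = growth_rates_arrays(law, ws.R, R_N, c3, sr3, st3, params)

    _, _, _, c4, sr4, st4 = _closure(ws, y + dt * k3)
    k4 = growth_rates_arrays(law, ws.R, R_N, c4, sr4, st4, params)

    y_new = np.maximum(y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4), _LN_GAMMA_FLOOR)
    if not np.all(np.isfinite(y_new)):
        raise IntegrationFailureError("non-finite integrator update")
    return y_new


def _state_from_y(
    grid: LagrangianGrid, y: np.ndarray, R_N: float, t: float
) -> SpheroidState:
    gamma = np.exp(np.maximum(y, _LN_GAMMA_FLOOR))
    return SpheroidState(
        grid=grid, gamma=gamma, r=radius_from_growth(grid, gamma), R_N=R_N, t=t
    )


def step(
    state: SpheroidState,
    law: Union[GrowthLaw, str],
    params: ParamsLike,
    dt: float,
) -> SpheroidState:
    """Advance one RK4 step of size ``dt`` (in units of T).

    The necrotic front is held fixed over the step and updated afterwards
    for the permanent-necrosis laws.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    law = GrowthLaw(law) if isinstance(law, str) else law
    dp = as_dimensionless(params)
    ws = _Workspace(state.grid, dp)
    try:
        y_new = _rk4_raw(ws, np.log(state.gamma), state.R_N, law, dp, dt)
    except IntegrationFailureError as exc:
        raise IntegrationFailureError(str(exc), last_state=state) from None
    new_state = _state_from_y(state.grid, y_new, state.R_N, state.t + dt)
    if law.permanent_necrosis:
        new_state = replace(new_state, R_N=update_necrotic_front(new_state, dp))
    return new_state


def _remesh(state: SpheroidState, y: np.ndarray) -> tuple[SpheroidState, np.ndarray]:
    """Redistribute interior nodes uniformly in the current Eulerian radius.

    The material endpoints (0 and B) are preserved; ``ln gamma`` is
    interpolated linearly onto the new node positions and radii are rebuilt
    from the interpolated field so the state stays self-consistent.
    """
    R_old = state.grid.nodes
    n = R_old.size - 1
    r_target = np.linspace(0.0, state.b, n + 1)
    R_new = np.interp(r_target, state.r, R_old)
    R_new[0], R_new[-1] = 0.0, state.grid.B
    # enforce strict monotonicity where the collapsed core maps many
    # material nodes to indistinguishable radii
    eps = state.grid.B * 1e-13
    np.maximum.accumulate(R_new, out=R_new)
    for i in range(1, n + 1):
        if R_new[i] <= R_new[i - 1]:
            R_new[i] = R_new[i - 1] + eps
    if R_new[-1] > state.grid.B:  # pushed past the endpoint by the epsilon fix
        R_new = np.minimum(R_new, state.grid.B - eps * (n - np.arange(n + 1)))
        R_new[0], R_new[-1] = 0.0, state.grid.B
    y_new = np.interp(R_new, R_old, y)
    grid = LagrangianGrid(R_new)
    gamma = np.exp(np.maximum(y_new, _LN_GAMMA_FLOOR))
    r = radius_from_growth(grid, gamma)
    return (
        SpheroidState(grid=grid, gamma=gamma, r=r, R_N=state.R_N, t=state.t),
        y_new,
    )


def _needs_remesh(state: SpheroidState, factor: float) -> bool:
    dr = np.diff(state.r)
    target = state.b / dr.size
    return bool(dr.max() > factor * target)


def simulate(
    params: ParamsLike,
    law: Union[GrowthLaw, str],
    t_end: float,
    controls: Controls | None = None,
) -> Trajectory:
    """Run the model to ``t_end`` (units of T) and record the trajectory.

    Terminates early with status ``"steady_state"`` when the relative
    change of the outer radius per unit T drops below ``steady_tol``, or
    with ``"unbounded_growth_stretch"`` when any nodal growth stretch
    exceeds ``gamma_max`` (the unbounded-growth regime of the
    nutrient-only laws); otherwise the status is ``"completed"``.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    law = GrowthLaw(law) if isinstance(law, str) else law
    dp = as_dimensionless(params)
    controls = controls or Controls()

    grid = LagrangianGrid.uniform(dp.B_over_L, controls.n)
    ws = _Workspace(grid, dp)
    y = np.zeros_like(grid.nodes)
    R_N = 0.0
    t = 0.0

    n_steps = max(1, int(round(t_end / controls.dt)))
    dt = t_end / n_steps
    window_steps = max(1, int(round(controls.steady_window / dt)))
    nec_gap = 6.0 * (1.0 - dp.chat)  # b^2 - r*^2 at the necrosis threshold

    times = [0.0]
    bs: list[float] = []
    center_sr: list[float] = []
    r_nec: list[float] = []
    gmeasure: list[float] = []
    snapshots: list[SpheroidState] = []
    status = "completed"

    cl = _closure(ws, y)
    nutrient_valid = cl[2] <= _SQRT6 * (1 + 1e-12)

    def record(closure) -> None:
        _, r, b, _, sigma_r, sigma_theta = closure
        bs.append(float(b))
        center_sr.append(float(sigma_r[0]))
        gmeasure.append(global_stress_measure(sigma_r, sigma_theta))
        if law.permanent_necrosis:
            r_nec.append(float(np.interp(R_N, ws.R, r)))
        else:
            gap = b * b - nec_gap
            r_nec.append(math.sqrt(gap) if gap > 0 else 0.0)

    record(cl)
    if controls.snapshot_stride > 0:
        snapshots.append(_state_from_y(grid, y, R_N, 0.0))

    for j in range(1, n_steps + 1):
        y = _rk4_raw(ws, y, R_N, law, dp, dt, first_closure=cl)
        t = j * dt
        cl = _closure(ws, y)
        gamma, r, b = cl[0], cl[1], cl[2]

        if law.permanent_necrosis:
            gap = b * b - nec_gap
            if gap > 0:
                R_N = max(R_N, float(np.interp(math.sqrt(gap), r, ws.R)))

        if controls.remesh and float(np.max(np.diff(r))) > controls.remesh_factor * b / controls.n:
            state = SpheroidState(grid=grid, gamma=gamma, r=r, R_N=R_N, t=t)
            state, y = _remesh(state, y)
            grid = state.grid
            ws = _Workspace(grid, dp)
            cl = _closure(ws, y)
            gamma, r, b = cl[0], cl[1], cl[2]

        times.append(t)
        record(cl)
        if b > _SQRT6 * (1 + 1e-12):
            nutrient_valid = False
        if controls.snapshot_stride > 0 and j % controls.snapshot_stride == 0:
            snapshots.append(_state_from_y(grid, y, R_N, t))

        if float(np.max(gamma)) > controls.gamma_max:
            status = "unbounded_growth_stretch"
            break
        if controls.steady_tol > 0 and j >= window_steps:
            b_then = bs[j - window_steps]
            elapsed = times[j] - times[j - window_steps]
            if abs(bs[j] - b_then) / bs[j] < controls.steady_tol * elapsed:
                status = "steady_state"
                break

    if controls.snapshot_stride > 0 and snapshots[-1].t != t:
        snapshots.append(_state_from_y(grid, y, R_N, t))

    return Trajectory(
        times=np.asarray(times),
        b=np.asarray(bs),
        center_sigma_r=np.asarray(center_sr),
        r_necrotic=np.asarray(r_nec),
        global_measure=np.asarray(gmeasure),
        snapshots=snapshots,
        status=status,
        law_id=law.law_id,
        params=dp,
        controls=controls,
        nutrient_valid=bool(nutrient_valid),
    )


def material_paths(trajectory: Trajectory, R_values) -> np.ndarray:
    """Eulerian paths ``r(R, t_j)`` of Lagrangian points, from stored snapshots.

    Returns an array of shape ``(len(R_values), n_snapshots)``; the row for
    ``R = B`` is the outer-radius curve, and ``R = 0`` stays at zero.
    """
    if not trajectory.snapshots:
        raise ValueError("no snapshots stored; rerun with snapshot_stride > 0")
    R_values = np.atleast_1d(np.asarray(R_values, dtype=float))
    B = trajectory.snapshots[0].grid.B
    if np.any(R_values < 0) or np.any(R_values > B * (1 + 1e-12)):
        raise ValueError("requested material points must lie in [0, B]")
    out = np.empty((R_values.size, len(trajectory.snapshots)))
    for j, st in enumerate(trajectory.snapshots):
        out[:, j] = np.interp(R_values, st.grid.nodes, st.r)
    return out


def boundary_stress_history(
    trajectory: Trajectory, params: ParamsLike | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Hoop stress at the outer boundary for each stored snapshot.

    Returns ``(times, sigma_theta_boundary)``.
    """
    if not trajectory.snapshots:
        raise ValueError("no snapshots stored; rerun with snapshot_stride > 0")
    dp = trajectory.params if params is None else as_dimensionless(params)
    ts = np.array([st.t for st in trajectory.snapshots])
    vals = np.array(
        [loaded_profiles(st, dp).sigma_theta[-1] for st in trajectory.snapshots]
    )
    return ts, vals
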