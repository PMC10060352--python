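import numpy as np
import pytest

from morphospheroid import Controls, DimensionlessParams, Params, simulate
from morphospheroid.kinematics import LagrangianGrid, SpheroidState, radius_from_growth


@pytest.fixture
def unit_params() -> Params:
    """Dimensional parameters with unit scales (L = T = mu = c_inf = 1)."""
    return Params(
        k=1.0, c_inf=1.0, c_hat=0.5, lam=1.0, D=1.0, mu=1.0,
        kappa=0.0, sigma_hat=0.0, beta=1.0, B=1.0,
    )


@pytest.fixture
def fig3() -> DimensionlessParams:
    return DimensionlessParams(chat=4 / 5, B_over_L=1.0)


def make_state(gamma_fn, B: float = 1.0, n: int = 400, R_N: float = 0.0) -> SpheroidState:
    """Build a self-consistent state from a growth-stretch profile gamma(R)."""
    grid = LagrangianGrid.uniform(B, n)
    gamma = np.asarray(gamma_fn(grid.nodes), dtype=float)
    if gamma.ndim == 0:
        gamma = np.full_like(grid.nodes, float(gamma))
    r = radius_from_growth(grid, gamma)
    return SpheroidState(grid=grid, gamma=gamma, r=r, R_N=R_N)


@pytest.fixture(scope="session")
def fig3_run():
    """Long nutrient-only run at the canonical parameter set, with snapshots."""
    params = DimensionlessParams(chat=4 / 5, B_over_L=1.0)
    return simulate(
        params,
        "M1",
        30.0,
        Controls(steady_tol=0.0, snapshot_stride=100),
    )


@pytest.fixture(scope="session")
def fig6_run():
    """Robust-model run (M4) at the persistent-necrosis fixture, to steady state."""
    params = DimensionlessParams(chat=9 / 10, kappa_mu=1.0, sigmahat_mu=-100.0, B_over_L=0.01)
    return simulate(
        params,
        "M4",
        2000.0,
        Controls(steady_tol=1e-8, snapshot_stride=4000),
    )


@pytest.fixture(scope="session")
def fig9_run():
    """Local+global stress law (M5) at the residual-stress fixture, to steady state."""
    params = DimensionlessParams(
        chat=1 / 4, kappa_mu=0.1, sigmahat_mu=-1.0, beta=6.25, B_over_L=1.0
    )
    return simulate(
        params,
        "M5",
        2000.0,
        Controls(dt=1 / 100, steady_tol=1e-8, snapshot_stride=200),
    )
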