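"""CSV export of states, stress profiles, and growth curves."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import SpheroidState, elastic_stretch
from .mechanics import StressProfile
from .simulator import Trajectory

__all__ = ["state_frame", "stress_frame", "growth_curve_frame", "write_csv"]


def state_frame(state: SpheroidState) -> pd.DataFrame:
    """Snapshot as columns (R, gamma, r, alpha)."""
    return pd.DataFrame(
        {
            "R": state.grid.nodes,
            "gamma": state.gamma,
            "r": state.r,
            "alpha": elastic_stretch(state),
        }
    )


def stress_frame(state: SpheroidState, profile: StressProfile) -> pd.DataFrame:
    """Stress profile as columns (R, r, sigma_r, sigma_theta), in units of mu."""
    return pd.DataFrame(
        {
            "R": state.grid.nodes,
            "r": state.r,
            "sigma_r": profile.sigma_r,
            "sigma_theta": profile.sigma_theta,
        }
    )


def growth_curve_frame(trajectory: Trajectory) -> pd.DataFrame:
    """Growth curve and diagnostics as columns (t, b, ...) in units of (T, L, mu)."""
    return pd.DataFrame(
        {
            "t": trajectory.times,
            "b": trajectory.b,
            "center_sigma_r": trajectory.center_sigma_r,
            "r_necrotic": trajectory.r_necrotic,
            "global_stress_measure": trajectory.global_measure,
        }
    )


def write_csv(frame: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
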