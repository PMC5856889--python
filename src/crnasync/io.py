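"""Trajectory CSV writers/readers.

Column 1 is ``time``; one column per species (counts) in species
declaration order.  LNA trajectories add ``sd:<species>`` columns.  Floats
are written at full precision so the round trip is lossless.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .semantics import DeterministicTrajectory, GaussianTrajectory, StochasticPath

__all__ = ["trajectory_frame", "write_trajectory_csv", "read_trajectory_csv"]


def trajectory_frame(traj, grid: np.ndarray | None = None) -> pd.DataFrame:
    """DataFrame view of any trajectory type (SSA paths sample their jump path)."""
    if isinstance(traj, DeterministicTrajectory):
        data = {"time": traj.times}
        for i, s in enumerate(traj.species):
            data[s] = traj.values[i]
    elif isinstance(traj, GaussianTrajectory):
        data = {"time": traj.times}
        for i, s in enumerate(traj.species):
            data[s] = traj.mean[i]
        for s in traj.species:
            data[f"sd:{s}"] = traj.sd_series(s)
    elif isinstance(traj, StochasticPath):
        if grid is not None:
            vals = traj.on_grid(np.asarray(grid, dtype=float))
            data = {"time": np.asarray(grid, dtype=float)}
        else:
            vals = traj.states.T
            data = {"time": traj.jump_times}
        for i, s in enumerate(traj.species):
            data[s] = vals[i]
    else:
        raise TypeError(f"unknown trajectory type {type(traj)!r}")
    return pd.DataFrame(data)


def write_trajectory_csv(traj, path, grid: np.ndarray | None = None) -> None:
    trajectory_frame(traj, grid).to_csv(path, index=False, float_format="%.17g")


def read_trajectory_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
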