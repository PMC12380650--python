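"""CSV dialects for trajectories and marker recordings.

Two fixed-column formats, both UTF-8 with a header row, ``.`` decimal and SI
units:

* trajectory: ``t, x, y, theta1, theta2, theta3, tau1, tau2, tau3``
  (torque columns written as empty fields when absent);
* markers:    ``t, sx, sy, ex, ey, wx, wy, fx, fy``
  (shoulder, elbow, wrist, fingertip x/y in metres).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .arm_model import ArmTrajectory
from .exceptions import InvalidArgumentError
from .measurement import MarkerRecording

__all__ = [
    "TRAJECTORY_COLUMNS",
    "MARKER_COLUMNS",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_marker_csv",
    "read_marker_csv",
]

TRAJECTORY_COLUMNS = ["t", "x", "y", "theta1", "theta2", "theta3",
                      "tau1", "tau2", "tau3"]
MARKER_COLUMNS = ["t", "sx", "sy", "ex", "ey", "wx", "wy", "fx", "fy"]


def write_trajectory_csv(path, traj: ArmTrajectory, fingertip) -> None:
    fingertip = np.asarray(fingertip, dtype=float)
    data = {
        "t": traj.t, "x": fingertip[:, 0], "y": fingertip[:, 1],
        "theta1": traj.theta[:, 0], "theta2": traj.theta[:, 1],
        "theta3": traj.theta[:, 2],
    }
    for j in range(3):
        data[f"tau{j + 1}"] = traj.tau[:, j] if traj.tau is not None else np.nan
    pd.DataFrame(data, columns=TRAJECTORY_COLUMNS).to_csv(path, index=False)


def read_trajectory_csv(path):
    """Read the trajectory dialect; returns ``(ArmTrajectory, fingertip)``."""
    df = pd.read_csv(path)
    if list(df.columns) != TRAJECTORY_COLUMNS:
        raise InvalidArgumentError(
            f"trajectory CSV must have columns {TRAJECTORY_COLUMNS}, "
            f"got {list(df.columns)}")
    theta = df[["theta1", "theta2", "theta3"]].to_numpy()
    traj = ArmTrajectory.from_theta(df["t"].to_numpy(), theta)
    tau = df[["tau1", "tau2", "tau3"]].to_numpy()
    if not np.any(np.isnan(tau)):
        traj.tau = tau
    return traj, df[["x", "y"]].to_numpy()


def write_marker_csv(path, rec: MarkerRecording) -> None:
    m = rec.markers
    df = pd.DataFrame({
        "t": rec.t,
        "sx": m[:, 0, 0], "sy": m[:, 0, 1],
        "ex": m[:, 1, 0], "ey": m[:, 1, 1],
        "wx": m[:, 2, 0], "wy": m[:, 2, 1],
        "fx": m[:, 3, 0], "fy": m[:, 3, 1],
    }, columns=MARKER_COLUMNS)
    df.to_csv(path, index=False)


def read_marker_csv(path) -> MarkerRecording:
    """Read the marker dialect, validating the sampling rate from ``t``."""
    df = pd.read_csv(path)
    if list(df.columns) != MARKER_COLUMNS:
        raise InvalidArgumentError(
            f"marker CSV must have columns {MARKER_COLUMNS}, got {list(df.columns)}")
    t = df["t"].to_numpy()
    steps = np.diff(t)
    if t.size < 2 or steps[0] <= 0 or np.any(np.abs(steps - steps[0]) > 1e-9):
        raise InvalidArgumentError("marker CSV time column must be uniform")
    fs = 1.0 / steps[0]
    markers = df[MARKER_COLUMNS[1:]].to_numpy().reshape(-1, 4, 2)
    return MarkerRecording(fs=fs, markers=markers)
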