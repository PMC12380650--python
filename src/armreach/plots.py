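"""Simple path and joint-angle figures (matplotlib)."""

from __future__ import annotations

import numpy as np


def plot_fingertip_path(built, ax=None, label=None, **kwargs):
    """Fingertip path in the workspace, start marked with a dot."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xy = built.fingertip
    ax.plot(xy[:, 0], xy[:, 1], label=label, **kwargs)
    ax.plot(xy[0, 0], xy[0, 1], "o", color=ax.lines[-1].get_color(), ms=4)
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.set_aspect("equal")
    if label:
        ax.legend()
    return ax


def plot_joint_angles(traj, ax=None, labels=("shoulder", "elbow", "wrist")):
    """Joint angles over time (degrees)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for j, name in enumerate(labels):
        ax.plot(traj.t, np.degrees(traj.theta[:, j]), label=name)
    ax.set_xlabel("t (s)")
    ax.set_ylabel("joint angle (deg)")
    ax.legend()
    return ax
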