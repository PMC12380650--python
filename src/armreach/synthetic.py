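"""Synthetic "measured" reaching movements for end-to-end testing.

Generates marker recordings that emulate point-to-point horizontal reaches
at the five packaged start/target pairs: a straight (optionally gently
curved) fingertip path with a minimum-jerk speed profile, an optional
smooth wrist rotation, rest tails on both sides, marker placement by the
package's own forward kinematics and i.i.d. Gaussian marker noise.  The
generator is a kinematic phantom — it does not simulate human-like control —
but it exercises every stage of the measurement pipeline with exact ground
truth attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import arm_model as am
from .exceptions import InvalidArgumentError
from .measurement import MarkerRecording
from .trajectory import MovementTask

__all__ = [
    "TASK_POINTS",
    "TASK_NAMES",
    "MOVEMENT_TIMES",
    "make_task",
    "SynthConfig",
    "SynthGroundTruth",
    "synth_measurement",
]

# Numbered workspace points (m), shoulder at the origin.
TASK_POINTS = {
    1: np.array([0.0, 0.3]),
    2: np.array([-0.21, 0.37]),
    3: np.array([-0.15, 0.56]),
    4: np.array([0.15, 0.56]),
    5: np.array([0.21, 0.37]),
}

TASK_NAMES = ("T24", "T25", "T31", "T41", "T53")

# Mean measured movement times (s) per direction, keyed by the instructed
# initial wrist angle in degrees.
MOVEMENT_TIMES = {
    0: {"T24": 0.672, "T25": 0.663, "T31": 0.550, "T41": 0.537, "T53": 0.686},
    30: {"T24": 0.658, "T25": 0.640, "T31": 0.551, "T41": 0.530, "T53": 0.654},
}


def make_task(name: str, initial_wrist_deg: float = 0.0,
              tf: float | None = None) -> MovementTask:
    """Named movement direction ``Tab`` = reach from point ``a`` to point ``b``.

    The default movement time is the mean measured duration for that
    direction at the nearest instructed initial wrist angle (0° or 30°);
    pass ``tf`` to override.
    """
    if name not in TASK_NAMES:
        raise InvalidArgumentError(
            f"unknown task {name!r}; valid names: {list(TASK_NAMES)}")
    a, b = int(name[1]), int(name[2])
    if tf is None:
        row = 30 if abs(initial_wrist_deg - 30.0) < abs(initial_wrist_deg) else 0
        tf = MOVEMENT_TIMES[row][name]
    return MovementTask(
        start=TASK_POINTS[a], target=TASK_POINTS[b], tf=tf,
        initial_wrist=np.deg2rad(initial_wrist_deg), name=name)


@dataclass(frozen=True)
class SynthConfig:
    """Settings of the synthetic-movement generator.

    ``wrist_delta`` is the total smooth wrist rotation over the movement
    (rad); ``path_bump`` a lateral bow amplitude (m, positive bows to the
    left of the chord) used to emulate gently curved measured paths;
    ``noise_sigma`` the i.i.d. Gaussian noise per marker coordinate (m,
    OPTOTRAK-like sub-millimetre default); ``rest_duration`` the stationary
    tail kept on each side (s).
    """

    task: MovementTask
    wrist_delta: float = 0.0
    path_bump: float = 0.0
    noise_sigma: float = 0.0003
    rest_duration: float = 0.4
    fs: float = 200.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise InvalidArgumentError("noise_sigma must be >= 0")
        if self.rest_duration < 0:
            raise InvalidArgumentError("rest_duration must be >= 0")
        if self.fs <= 0:
            raise InvalidArgumentError("fs must be > 0")


@dataclass
class SynthGroundTruth:
    """Exact movement attached to a synthetic recording (noise-free)."""

    onset_index: int
    offset_index: int
    onset_time: float
    offset_time: float
    theta: np.ndarray          # (N, 3) true joint angles, full recording
    fingertip: np.ndarray      # (N, 2) true fingertip path, full recording
    task: MovementTask = field(default=None)  # type: ignore[assignment]

    @property
    def movement_time(self) -> float:
        return self.offset_time - self.onset_time


def _minimum_jerk_progress(u: np.ndarray) -> np.ndarray:
    return 10.0 * u**3 - 15.0 * u**4 + 6.0 * u**5


def synth_measurement(cfg: SynthConfig, arm: am.ArmParameters,
                      branch: str = "elbow-cw"):
    """Generate one synthetic marker recording with ground truth.

    The fingertip follows the task chord (plus the optional lateral bump)
    with minimum-jerk progress; the wrist angle rises smoothly by
    ``wrist_delta`` along the same profile, so the movement starts and ends
    at rest.  Joint angles come from the package's inverse kinematics and
    markers from its forward kinematics — a single source of kinematic
    truth.  Returns ``(MarkerRecording, SynthGroundTruth)``; the same seed
    reproduces the recording bit for bit.
    """
    task = cfg.task
    n_move = int(round(task.tf * cfg.fs)) + 1
    n_rest = int(round(cfg.rest_duration * cfg.fs))

    u = np.arange(n_move) / (n_move - 1)
    s = _minimum_jerk_progress(u)
    chord = task.target - task.start
    normal = np.array([-chord[1], chord[0]])
    norm_len = np.linalg.norm(normal)
    if norm_len > 0:
        normal = normal / norm_len
    xy = task.start + s[:, None] * chord + (cfg.path_bump * np.sin(np.pi * s))[:, None] * normal
    theta3 = task.initial_wrist + cfg.wrist_delta * s

    xy = np.concatenate([np.repeat(xy[:1], n_rest, axis=0), xy,
                         np.repeat(xy[-1:], n_rest, axis=0)])
    theta3 = np.concatenate([np.full(n_rest, theta3[0]), theta3,
                             np.full(n_rest, theta3[-1])])

    theta = am.inverse_kinematics(xy, theta3, arm, branch=branch)
    elbow, wrist, fingertip = am.forward_kinematics(theta, arm)
    n = theta.shape[0]
    markers = np.stack([np.zeros((n, 2)), elbow, wrist, fingertip], axis=1)

    rng = np.random.default_rng(cfg.seed)
    noisy = markers + rng.normal(0.0, cfg.noise_sigma, size=markers.shape)

    truth = SynthGroundTruth(
        onset_index=n_rest,
        offset_index=n_rest + n_move - 1,
        onset_time=n_rest / cfg.fs,
        offset_time=(n_rest + n_move - 1) / cfg.fs,
        theta=theta,
        fingertip=fingertip,
        task=task,
    )
    return MarkerRecording(fs=cfg.fs, markers=noisy), truth
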