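"""Measurement-side processing of marker recordings.

Mirrors the treatment of optical motion-capture data: four markers
(shoulder, elbow, wrist, fingertip) sampled at 200 Hz, zero-phase low-pass
filtering, movement onset/offset detection from the two-dimensional path
curvature, conversion of marker positions to joint angles, and RMS
comparison between a model-optimal movement and a measured one on
normalized time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .arm_model import ArmTrajectory
from .exceptions import InvalidArgumentError, OnsetDetectionError
from .trajectory import MovementTask

__all__ = [
    "MARKER_ORDER",
    "MarkerRecording",
    "MeasuredMovement",
    "lowpass_filter",
    "detect_onset_offset",
    "markers_to_angles",
    "process_recording",
    "rms_errors",
]

MARKER_ORDER = ("shoulder", "elbow", "wrist", "fingertip")


@dataclass
class MarkerRecording:
    """Planar positions of the four arm markers over time.

    ``markers`` has shape (N, 4, 2) in metres, marker order shoulder →
    elbow → wrist → fingertip; ``fs`` is the sampling rate in Hz.
    """

    fs: float
    markers: np.ndarray

    def __post_init__(self):
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise InvalidArgumentError("sampling rate fs must be positive")
        markers = np.asarray(self.markers, dtype=float)
        if markers.ndim != 3 or markers.shape[1] < 4 or markers.shape[2] != 2:
            raise InvalidArgumentError(
                "markers must have shape (N, >=4, 2): shoulder, elbow, wrist, fingertip")
        if not np.all(np.isfinite(markers)):
            raise InvalidArgumentError("markers contain non-finite values")
        self.markers = markers

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.markers.shape[0]) / self.fs

    @property
    def fingertip(self) -> np.ndarray:
        return self.markers[:, 3, :]


@dataclass
class MeasuredMovement:
    """A recording cropped to the detected movement interval."""

    traj: ArmTrajectory
    fingertip: np.ndarray
    movement_time: float
    task: MovementTask | None = None
    onset_index: int = 0
    offset_index: int = 0

    def __post_init__(self):
        if self.movement_time <= 0 or self.onset_index >= self.offset_index:
            raise InvalidArgumentError("onset must precede offset")


def lowpass_filter(series, fs: float, order: int = 4, cutoff: float = 10.0) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter along the time axis.

    Filters forward and backward (``filtfilt``), so the passband gain is the
    squared one-pass magnitude and the phase lag is zero — a symmetric pulse
    stays centred.  Requires ``fs > 2 * cutoff`` and a series longer than
    the filter warm-up length.
    """
    if fs <= 2.0 * cutoff:
        raise InvalidArgumentError(f"fs={fs} must exceed twice the cutoff {cutoff}")
    series = np.asarray(series, dtype=float)
    b, a = butter(order, cutoff, fs=fs, btype="low")
    padlen = 3 * (max(len(a), len(b)) - 1)
    if series.shape[0] <= padlen:
        raise InvalidArgumentError(
            f"series too short for the filter warm-up ({series.shape[0]} <= {padlen})")
    return filtfilt(b, a, series, axis=0)


def _path_curvature_per_mm(xy_m: np.ndarray, fs: float) -> np.ndarray:
    """Signed-magnitude curvature |x'y'' − y'x''| / speed³ in 1/mm."""
    xy = 1000.0 * np.asarray(xy_m, dtype=float)  # mm
    dt = 1.0 / fs
    v = np.gradient(xy, dt, axis=0, edge_order=2)
    a = np.gradient(v, dt, axis=0, edge_order=2)
    num = np.abs(v[:, 0] * a[:, 1] - v[:, 1] * a[:, 0])
    speed3 = (v[:, 0] ** 2 + v[:, 1] ** 2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = num / speed3
    kappa[~np.isfinite(kappa)] = np.inf  # zero speed: treat as resting
    return kappa


def detect_onset_offset(fingertip_m, fs: float, threshold: float = 0.3):
    """Movement onset/offset from path curvature (threshold in 1/mm).

    Path curvature is tiny while the fingertip travels at speed and blows up
    in the noise-dominated rest phases, so: starting from the movement
    midpoint — taken as the peak-tangential-speed sample — search backward
    for the first sample whose curvature exceeds the threshold (onset), and
    forward likewise (offset).

    Returns ``(onset_index, offset_index)``.  Raises
    :class:`OnsetDetectionError` naming the side if no crossing exists.
    """
    fingertip_m = np.asarray(fingertip_m, dtype=float)
    if fingertip_m.ndim != 2 or fingertip_m.shape[1] != 2:
        raise InvalidArgumentError("fingertip series must have shape (N, 2)")
    kappa = _path_curvature_per_mm(fingertip_m, fs)
    v = np.gradient(1000.0 * fingertip_m, 1.0 / fs, axis=0, edge_order=2)
    mid = int(np.argmax(np.hypot(v[:, 0], v[:, 1])))

    above = kappa > threshold
    back = np.flatnonzero(above[: mid + 1])
    if back.size == 0:
        raise OnsetDetectionError("onset")
    onset = int(back[-1])
    fwd = np.flatnonzero(above[mid:])
    if fwd.size == 0:
        raise OnsetDetectionError("offset")
    offset = int(mid + fwd[0])
    return onset, offset


def markers_to_angles(rec: MarkerRecording) -> np.ndarray:
    """Joint angles (N, 3) from marker positions.

    ``theta1`` is the upper-arm direction from the +x axis; ``theta2`` and
    ``theta3`` are the relative elbow and wrist angles, each wrapped to
    (−π, π].  A global rotation of all markers therefore shifts only
    ``theta1``.
    """
    m = rec.markers
    seg = np.diff(m[:, :4, :], axis=1)  # upper arm, forearm, hand vectors
    norms = np.linalg.norm(seg, axis=2)
    if np.any(norms < 1e-12):
        raise InvalidArgumentError("coincident consecutive markers: degenerate geometry")
    ang = np.arctan2(seg[..., 1], seg[..., 0])  # absolute link angles
    theta = np.empty_like(ang)
    theta[:, 0] = ang[:, 0]
    theta[:, 1:] = np.diff(ang, axis=1)
    return -np.mod(-theta + np.pi, 2.0 * np.pi) + np.pi  # wrap to (-pi, pi]


def process_recording(
    rec: MarkerRecording,
    task: MovementTask | None = None,
    cutoff: float = 10.0,
    order: int = 4,
    threshold: float = 0.3,
) -> MeasuredMovement:
    """Filter → detect onset/offset → crop to the movement interval."""
    filtered = lowpass_filter(rec.markers.reshape(rec.markers.shape[0], -1), rec.fs,
                              order=order, cutoff=cutoff)
    filtered = filtered.reshape(rec.markers.shape)
    smooth = MarkerRecording(fs=rec.fs, markers=filtered)
    onset, offset = detect_onset_offset(smooth.fingertip, rec.fs, threshold=threshold)
    theta = markers_to_angles(smooth)[onset: offset + 1]
    n = offset - onset + 1
    t = np.arange(n) / rec.fs
    traj = ArmTrajectory.from_theta(t, theta)
    return MeasuredMovement(
        traj=traj,
        fingertip=smooth.fingertip[onset: offset + 1],
        movement_time=(offset - onset) / rec.fs,
        task=task,
        onset_index=onset,
        offset_index=offset,
    )


def _resample_normalized(t, series, n: int) -> np.ndarray:
    s = (np.asarray(t, dtype=float) - t[0]) / (t[-1] - t[0])
    s_new = np.linspace(0.0, 1.0, n)
    series = np.asarray(series, dtype=float)
    return np.stack([np.interp(s_new, s, series[:, j])
                     for j in range(series.shape[1])], axis=1)


def rms_errors(
    t_a, fingertip_a, theta_a,
    t_b, fingertip_b, theta_b,
    n: int = 101,
    per_joint: bool = False,
):
    """RMS discrepancy between two movements on normalized time.

    Both movements are resampled onto ``n`` equally spaced points of
    ``t / tf`` (so the comparison is invariant to the raw sampling rates).
    Returns ``(fingertip_rms, joint_rms)``: the fingertip value is the RMS
    Euclidean distance (m); the joint value pools the squared angle errors
    of all three joints (rad), or is reported per joint with
    ``per_joint=True``.  Symmetric in its two arguments.
    """
    fa = _resample_normalized(t_a, fingertip_a, n)
    fb = _resample_normalized(t_b, fingertip_b, n)
    tha = _resample_normalized(t_a, theta_a, n)
    thb = _resample_normalized(t_b, theta_b, n)
    fingertip_rms = float(np.sqrt(np.mean(np.sum((fa - fb) ** 2, axis=1))))
    if per_joint:
        joint_rms = np.sqrt(np.mean((tha - thb) ** 2, axis=0))
    else:
        joint_rms = float(np.sqrt(np.mean((tha - thb) ** 2)))
    return fingertip_rms, joint_rms


def rms_errors_movements(optimal, measured, n: int = 101, per_joint: bool = False):
    """Convenience wrapper comparing a built optimum with a measured movement.

    ``optimal`` is a :class:`~armreach.trajectory.BuiltTrajectory`;
    ``measured`` a :class:`MeasuredMovement`.  Raises when the two carry
    different named tasks.
    """
    task_a = getattr(optimal, "task", None)
    if (task_a is not None and measured.task is not None
            and task_a.name is not None and measured.task.name is not None
            and task_a.name != measured.task.name):
        raise InvalidArgumentError(
            f"task mismatch: {task_a.name!r} vs {measured.task.name!r}")
    return rms_errors(
        optimal.traj.t, optimal.fingertip, optimal.traj.theta,
        measured.traj.t, measured.fingertip, measured.traj.theta,
        n=n, per_joint=per_joint)
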