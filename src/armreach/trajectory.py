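"""Candidate-movement representation: 7-knot quintic splines and arm trajectories.

A candidate movement (an :class:`Individual`) is three 7-dimensional knot
vectors — fingertip x, fingertip y and wrist angle — at equally spaced times
``t_k = k tf / 6``.  Knots are interpolated by a quintic spline with clamped
rest-to-rest ends (first and second derivatives zero at ``t = 0`` and
``t = tf``; a natural-end variant is available to probe sensitivity to this
assumption).  Sampling the splines, solving the wrist-resolved inverse
kinematics per sample and attaching inverse-dynamics torques yields a full
:class:`~armreach.arm_model.ArmTrajectory`.

Spline interpolation at fixed knot times is linear in the knot values, so
per-grid design matrices (value and first three derivatives) are precomputed
and cached; converting an individual to time series is then four small
matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.interpolate import make_interp_spline

from . import arm_model as am
from .exceptions import InvalidArgumentError, UnreachableTargetError

__all__ = [
    "N_KNOTS",
    "MovementTask",
    "Individual",
    "BuiltTrajectory",
    "spline_through_knots",
    "knot_basis",
    "seed_individual",
    "individual_to_arm_trajectory",
]

N_KNOTS = 7

_BC = {
    # rest-to-rest: zero velocity and acceleration at both ends
    "clamped": ([(1, 0.0), (2, 0.0)], [(1, 0.0), (2, 0.0)]),
    # natural ends for a quintic: zero 3rd and 4th derivatives
    "natural": ([(3, 0.0), (4, 0.0)], [(3, 0.0), (4, 0.0)]),
}


@dataclass(frozen=True)
class MovementTask:
    """Point-to-point reach: start/target fingertip positions and duration."""

    start: np.ndarray
    target: np.ndarray
    tf: float
    initial_wrist: float = 0.0
    name: str | None = None

    def __post_init__(self):
        start = np.asarray(self.start, dtype=float)
        target = np.asarray(self.target, dtype=float)
        if start.shape != (2,) or target.shape != (2,):
            raise InvalidArgumentError("start and target must be 2-vectors (m)")
        if not (np.isfinite(self.tf) and self.tf > 0):
            raise InvalidArgumentError("movement time tf must be positive")
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "target", target)

    @property
    def distance(self) -> float:
        return float(np.linalg.norm(self.target - self.start))


@dataclass(frozen=True)
class Individual:
    """One candidate movement: fingertip x/y and wrist-angle knot vectors.

    The first and last x/y knots are the task's start and target and the
    first wrist knot is the initial wrist angle; the final wrist knot is free
    (final posture is part of the optimization).
    """

    x_knots: np.ndarray
    y_knots: np.ndarray
    wrist_knots: np.ndarray

    def __post_init__(self):
        for name in ("x_knots", "y_knots", "wrist_knots"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_KNOTS,):
                raise InvalidArgumentError(f"{name} must have {N_KNOTS} entries")
            if not np.all(np.isfinite(arr)):
                raise InvalidArgumentError(f"{name} contains non-finite values")
            object.__setattr__(self, name, arr)

    def matches_task(self, task: MovementTask, tol: float = 1e-12) -> bool:
        return (abs(self.x_knots[0] - task.start[0]) <= tol
                and abs(self.y_knots[0] - task.start[1]) <= tol
                and abs(self.x_knots[-1] - task.target[0]) <= tol
                and abs(self.y_knots[-1] - task.target[1]) <= tol
                and abs(self.wrist_knots[0] - task.initial_wrist) <= tol)


def spline_through_knots(knots, tf: float, ends: str = "clamped"):
    """Quintic spline through 7 equally spaced knots on ``[0, tf]``.

    Returns a ``scipy.interpolate.BSpline``; derivatives through order 3 (and
    beyond) are available via ``.derivative(nu)``.  With clamped ends the
    representable space contains every rest-to-rest quintic polynomial, in
    particular the minimum-jerk profile.
    """
    knots = np.asarray(knots, dtype=float)
    if knots.shape != (N_KNOTS,):
        raise InvalidArgumentError(f"expected {N_KNOTS} knots, got shape {knots.shape}")
    if not np.all(np.isfinite(knots)):
        raise InvalidArgumentError("knots contain non-finite values")
    if ends not in _BC:
        raise InvalidArgumentError(f"unknown end condition {ends!r}; use {sorted(_BC)}")
    t_k = np.linspace(0.0, tf, N_KNOTS)
    return make_interp_spline(t_k, knots, k=5, bc_type=_BC[ends])


@lru_cache(maxsize=32)
def knot_basis(tf: float, n_samples: int, ends: str = "clamped"):
    """Design matrices mapping 7 knots to sampled values and derivatives.

    Returns ``(t, B)`` where ``t`` is the uniform grid with ``n_samples``
    points on ``[0, tf]`` and ``B[d]`` (d = 0..3) is the ``(n_samples, 7)``
    matrix of the d-th spline derivative of the unit-knot interpolants.
    """
    t = np.linspace(0.0, tf, n_samples)
    B = [np.empty((n_samples, N_KNOTS)) for _ in range(4)]
    for j in range(N_KNOTS):
        unit = np.zeros(N_KNOTS)
        unit[j] = 1.0
        sp = spline_through_knots(unit, tf, ends)
        for d in range(4):
            B[d][:, j] = sp(t, nu=d)
    t.setflags(write=False)
    for b in B:
        b.setflags(write=False)
    return t, tuple(B)


def seed_individual(task: MovementTask, wrist_delta: float = 0.0) -> Individual:
    """Straight-line, constant-speed knot placement with a (near-)constant wrist.

    This is the unbiased starting shape for the optimizer: knots evenly
    spaced along the chord, wrist angle ramping linearly by ``wrist_delta``
    (zero by default).
    """
    s = np.linspace(0.0, 1.0, N_KNOTS)
    return Individual(
        x_knots=task.start[0] + s * (task.target[0] - task.start[0]),
        y_knots=task.start[1] + s * (task.target[1] - task.start[1]),
        wrist_knots=task.initial_wrist + s * wrist_delta,
    )


@dataclass
class BuiltTrajectory:
    """An individual converted to dense time series.

    ``violation`` is the reachability excess (mean metres outside the
    annulus over the grid, zero when feasible) accumulated while clamping
    infeasible samples in penalty mode.
    """

    traj: am.ArmTrajectory
    fingertip: np.ndarray              # (n, 2) positions
    fingertip_jerk: np.ndarray         # (n, 2) third derivatives
    wrist_angle: np.ndarray            # (n,) theta3 samples
    violation: float = 0.0
    first_infeasible_time: float | None = None
    D: np.ndarray | None = None
    mean_abs_torque: np.ndarray | None = None
    fingertip_speed: np.ndarray = field(default=None)  # type: ignore[assignment]


def individual_to_arm_trajectory(
    ind: Individual,
    task: MovementTask,
    arm: am.ArmParameters,
    dt: float | None = None,
    cond: am.ViscosityCondition | None = None,
    branch: str = "elbow-cw",
    ends: str = "clamped",
    penalty_mode: bool = False,
) -> BuiltTrajectory:
    """Sample an individual's splines and lift them to a joint-space trajectory.

    The default grid step is ``tf / 200``.  Joint
    velocities and accelerations come from central differences on the dense
    angle grid.  When ``cond`` is given, the joint-viscosity fixed point is
    resolved and inverse-dynamics torques are attached to the result.

    Unreachable samples raise :class:`UnreachableTargetError` carrying the
    first offending time — unless ``penalty_mode`` is set, in which case the
    fingertip is clamped radially to the reachable annulus and the excess is
    reported in ``violation`` for the optimizer to penalize.
    """
    if dt is None:
        dt = task.tf / 200.0
    n = int(round(task.tf / dt)) + 1
    t, B = knot_basis(task.tf, n, ends)

    xy = np.stack([B[0] @ ind.x_knots, B[0] @ ind.y_knots], axis=1)
    jerk = np.stack([B[3] @ ind.x_knots, B[3] @ ind.y_knots], axis=1)
    speed = np.hypot(B[1] @ ind.x_knots, B[1] @ ind.y_knots)
    theta3 = B[0] @ ind.wrist_knots

    lower, upper, _, _ = am.reachable_bounds(theta3, arm)
    dist = np.hypot(xy[:, 0], xy[:, 1])
    excess = np.maximum(dist - upper, 0.0) + np.maximum(lower - dist, 0.0)
    violation = float(np.mean(excess))
    first_bad = None
    if violation > 0.0:
        bad = np.flatnonzero(excess > 0.0)
        first_bad = float(t[bad[0]])
        if not penalty_mode:
            raise UnreachableTargetError(
                dist[bad[0]], lower[bad[0]], upper[bad[0]], time=first_bad)
        # radial clamp keeps the sample solvable while the penalty steers
        # the optimizer back inside the annulus
        margin = 1e-9
        target_d = np.clip(dist, lower + margin, upper - margin)
        safe = np.where(dist > 0, dist, 1.0)
        xy = xy * (target_d / safe)[:, None]

    theta = am.inverse_kinematics(xy, theta3, arm, branch=branch)
    traj = am.ArmTrajectory.from_theta(t, theta)

    built = BuiltTrajectory(
        traj=traj, fingertip=xy, fingertip_jerk=jerk, wrist_angle=theta3,
        violation=violation, first_infeasible_time=first_bad,
        fingertip_speed=speed,
    )
    if cond is not None:
        D, tbar, tau = am.resolve_viscosity(traj, arm, cond, return_torques=True)
        traj.tau = tau
        built.D = D
        built.mean_abs_torque = tbar
    return built
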