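"""Smoothness cost functionals evaluated on candidate arm trajectories.

All five costs share the form ``C = 1/2 ∫ Σ_i (d q_i / dt)^2 dt`` for some
per-channel signal ``q``:

* HJ  — hand jerk: ``q`` = fingertip velocity's second derivative (so the
  integrand is squared third derivatives of position);
* AJ  — angular jerk: third derivatives of the three joint angles;
* TC  — torque change: first derivatives of the three joint torques;
* MSC — muscle-stress change: first derivatives of the eight muscle
  stresses, with tensions from the per-instant stress-minimizing QP;
* MCC — motor-command change: first derivatives of eight per-muscle command
  signals.  When tension is modelled as ``T_i = k·alpha_i·PCSA_i`` the
  stress equals ``k·alpha_i``, so ``C_MSC = k² · C_MCC`` exactly.

Time derivatives are central differences on the uniform grid (second-order,
one-sided at the ends) and integration is trapezoidal, matching the
differencing order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .arm_model import ArmTrajectory
from .exceptions import InvalidArgumentError
from .muscle_model import MuscleSelection, distribute_tension_series

__all__ = [
    "MODELS",
    "CostBreakdown",
    "cost_aj",
    "cost_tc",
    "cost_hj",
    "cost_msc",
    "cost_mcc",
    "stress_series",
]

MODELS = ("HJ", "AJ", "TC", "MSC", "MCC")

_MIN_SAMPLES = 7


@dataclass
class CostBreakdown:
    """A model's cost for one candidate, split into per-channel contributions."""

    model: str
    value: float
    per_channel: np.ndarray
    feasible: bool = True
    penalty: float = 0.0
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.model not in MODELS:
            raise InvalidArgumentError(f"unknown model {self.model!r}; use {MODELS}")


def _diff(arr: np.ndarray, dt: float, order: int = 1) -> np.ndarray:
    for _ in range(order):
        arr = np.gradient(arr, dt, axis=0, edge_order=2)
    return arr


def _fd_weights(offsets, order: int) -> np.ndarray:
    """Finite-difference weights for a derivative at offset 0 (Taylor match)."""
    offsets = np.asarray(offsets, dtype=float)
    n = offsets.size
    powers = np.arange(n)[:, None]
    A = offsets[None, :] ** powers / np.array(
        [math.factorial(k) for k in range(n)])[:, None]
    b = np.zeros(n)
    b[order] = 1.0
    return np.linalg.solve(A, b)


# third derivative: 5-point central stencil in the interior (second order),
# 6-point one-sided stencils at the edges (third order) — the integrand of a
# jerk cost is largest right at the boundaries, where repeated np.gradient
# passes would lose an order of accuracy
_JERK_CENTRAL = _fd_weights([-2, -1, 0, 1, 2], 3)
_JERK_EDGE = [_fd_weights(np.arange(6) - shift, 3) for shift in range(2)]


def _diff3(arr: np.ndarray, dt: float) -> np.ndarray:
    """Third time derivative along axis 0, uniformly second-order accurate."""
    n = arr.shape[0]
    out = np.empty_like(arr)
    for k, w in enumerate(_JERK_CENTRAL):
        sl = arr[k:n - 4 + k]
        if k == 0:
            acc = w * sl
        else:
            acc = acc + w * sl
    out[2:n - 2] = acc
    for i, w in enumerate(_JERK_EDGE):
        out[i] = np.tensordot(w, arr[:6], axes=(0, 0))
        out[n - 1 - i] = -np.tensordot(w, arr[n - 6:][::-1], axes=(0, 0))
    return out / dt**3


def _check_grid(arr, what):
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise InvalidArgumentError(f"{what} must be a 2-D (time x channel) array")
    if arr.shape[0] < _MIN_SAMPLES:
        raise InvalidArgumentError(
            f"{what} needs at least {_MIN_SAMPLES} samples, got {arr.shape[0]}")
    return arr


def _half_integral_sq(rates: np.ndarray, dt: float):
    per_channel = 0.5 * np.trapezoid(rates**2, dx=dt, axis=0)
    return float(per_channel.sum()), per_channel


def cost_aj(traj: ArmTrajectory):
    """Angular-jerk cost: ``1/2 ∫ Σ (d³θ_i/dt³)² dt`` over the three joints."""
    theta = _check_grid(traj.theta, "joint-angle series")
    return _half_integral_sq(_diff3(theta, traj.dt), traj.dt)


def cost_tc(traj: ArmTrajectory):
    """Torque-change cost: ``1/2 ∫ Σ (dτ_i/dt)² dt`` over the three joints."""
    if traj.tau is None:
        raise InvalidArgumentError("trajectory has no torques attached")
    tau = _check_grid(traj.tau, "torque series")
    return _half_integral_sq(_diff(tau, traj.dt), traj.dt)


def cost_hj(fingertip, dt: float, jerk=None):
    """Hand-jerk cost: ``1/2 ∫ (x⃛² + y⃛²) dt`` of the fingertip path.

    If the exact spline third derivative is available pass it as ``jerk``;
    otherwise it is formed by repeated central differences of ``fingertip``.
    """
    if jerk is None:
        fingertip = _check_grid(fingertip, "fingertip series")
        jerk = _diff3(fingertip, dt)
    else:
        jerk = _check_grid(jerk, "fingertip jerk series")
    return _half_integral_sq(jerk, dt)


def cost_mcc(alpha, dt: float):
    """Motor-command-change cost: ``1/2 ∫ Σ (dα_i/dt)² dt`` over 8 commands."""
    alpha = _check_grid(alpha, "motor-command series")
    return _half_integral_sq(_diff(alpha, dt), dt)


def stress_series(traj: ArmTrajectory, sel: MuscleSelection) -> np.ndarray:
    """Per-sample stress vectors of the QP tension distribution, shape (N, 8)."""
    if traj.tau is None:
        raise InvalidArgumentError("trajectory has no torques attached")
    tensions = distribute_tension_series(traj.tau, sel)
    return tensions / sel.pcsa


def cost_msc(traj: ArmTrajectory, sel: MuscleSelection, return_tensions: bool = False):
    """Muscle-stress-change cost.

    Per sample, the inner stress-minimizing QP distributes the joint torque
    over the eight muscles; the cost is ``1/2 ∫ Σ (dS_i/dt)² dt`` of the
    resulting stress trajectories.  Stress derivatives are central
    differences across the QP solutions; an occasional kink where the QP
    active set changes is tolerated (the dense grid keeps its contribution
    small, verified by grid-halving tests).
    """
    if traj.tau is None:
        raise InvalidArgumentError("trajectory has no torques attached")
    tau = _check_grid(traj.tau, "torque series")
    tensions = distribute_tension_series(tau, sel)
    stresses = tensions / sel.pcsa
    value, per_channel = _half_integral_sq(_diff(stresses, traj.dt), traj.dt)
    if return_tensions:
        return value, per_channel, tensions
    return value, per_channel
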