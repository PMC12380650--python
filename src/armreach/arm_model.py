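"""Kinematics, rigid-body dynamics and joint viscosity of a planar three-joint arm.

The arm moves in the horizontal plane (no gravity term), with the shoulder
fixed at the origin.  Joint angles follow the convention

* ``theta1`` — shoulder angle, measured counter-clockwise from the +x axis;
* ``theta2`` — elbow flexion relative to the upper arm (CCW positive);
* ``theta3`` — wrist flexion relative to the forearm (CCW positive);

so ``theta = (0, 0, 0)`` is the fully extended arm along +x.  All quantities
are SI (m, kg, N·m, rad).

The equation of motion is

    M(theta) ddtheta + H(theta, dtheta) + D dtheta = tau

with ``M`` the 3×3 configuration-dependent inertia matrix, ``H`` the
Coriolis/centrifugal vector and ``D`` a constant joint-viscosity matrix whose
entries are linear in the scale factors ``alpha_A``/``alpha_B`` and in the
mean absolute joint torques of the movement being evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .exceptions import (
    ConvergenceError,
    IntegrationDivergenceError,
    InvalidArgumentError,
    UnreachableTargetError,
)

__all__ = [
    "ArmParameters",
    "ArmTrajectory",
    "ViscosityCondition",
    "VISCOSITY_CONDITIONS",
    "forward_kinematics",
    "inverse_kinematics",
    "reachable_bounds",
    "inertia_matrix",
    "coriolis_vector",
    "inverse_dynamics",
    "forward_dynamics",
    "viscosity_matrix",
    "resolve_viscosity",
]

# phi = _LOWER @ theta maps relative joint angles to absolute link angles
_LOWER = np.array([[1.0, 0.0, 0.0], [1.0, 1.0, 0.0], [1.0, 1.0, 1.0]])


@dataclass(frozen=True)
class ArmParameters:
    """Segment parameters of the upper arm (1), forearm (2) and hand (3).

    ``I1..I3`` are moments of inertia of each link about its *proximal* joint
    axis.  The values shipped in the ``table2_mean`` profile are empirical
    estimates, so ``I_i >= m_i * Lg_i**2`` is not asserted; positivity is.
    """

    L1: float
    L2: float
    L3: float
    Lg1: float
    Lg2: float
    Lg3: float
    m1: float
    m2: float
    m3: float
    I1: float
    I2: float
    I3: float

    def __post_init__(self):
        for name in ("L1", "L2", "L3", "Lg1", "Lg2", "Lg3",
                     "m1", "m2", "m3", "I1", "I2", "I3"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0.0:
                raise InvalidArgumentError(f"{name} must be finite and > 0, got {value!r}")
        for i in (1, 2, 3):
            if getattr(self, f"Lg{i}") >= getattr(self, f"L{i}"):
                raise InvalidArgumentError(
                    f"Lg{i} must be smaller than L{i} (COM lies inside the link)"
                )

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.L1, self.L2, self.L3])

    @classmethod
    def from_mapping(cls, mapping) -> "ArmParameters":
        expected = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(mapping) - expected
        if unknown:
            raise InvalidArgumentError(f"unknown arm parameter keys: {sorted(unknown)}")
        missing = expected - set(mapping)
        if missing:
            raise InvalidArgumentError(f"missing arm parameter keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    @classmethod
    def from_profile(cls, name_or_path: str = "table2_mean") -> "ArmParameters":
        """Load a named packaged profile or a key-value parameter file."""
        path = Path(str(name_or_path))
        if path.suffix == ".params" or path.exists():
            text = path.read_text()
        else:
            ref = resources.files("armreach.data") / f"{name_or_path}.params"
            try:
                text = ref.read_text()
            except FileNotFoundError:
                raise InvalidArgumentError(
                    f"unknown arm profile {name_or_path!r} (packaged: 'table2_mean')"
                ) from None
        return cls.from_mapping(parse_params(text))

    def to_params(self) -> str:
        return "".join(
            f"{name} = {getattr(self, name)!r}\n"
            for name in self.__dataclass_fields__  # type: ignore[attr-defined]
        )


def parse_params(text: str) -> dict:
    """Parse the simple ``key = value`` fixture dialect (``#`` comments)."""
    out = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise InvalidArgumentError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = float(value)
    return out


@dataclass
class ArmTrajectory:
    """Uniformly sampled joint-space time series, optionally with torques."""

    t: np.ndarray
    theta: np.ndarray
    omega: np.ndarray
    alpha: np.ndarray
    tau: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        n = self.t.shape[0]
        if n < 2:
            raise InvalidArgumentError("trajectory needs at least 2 samples")
        for name in ("theta", "omega", "alpha"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, 3):
                raise InvalidArgumentError(
                    f"{name} must have shape ({n}, 3), got {arr.shape}"
                )
            setattr(self, name, arr)
        if self.tau is not None:
            self.tau = np.asarray(self.tau, dtype=float)
            if self.tau.shape != (n, 3):
                raise InvalidArgumentError(f"tau must have shape ({n}, 3)")
        steps = np.diff(self.t)
        if steps[0] <= 0 or np.any(np.abs(steps - steps[0]) > 1e-12):
            raise InvalidArgumentError("time grid must be uniform and increasing")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def tf(self) -> float:
        return float(self.t[-1])

    @classmethod
    def from_theta(cls, t, theta) -> "ArmTrajectory":
        """Build a trajectory from angles alone, differentiating numerically.

        Velocities and accelerations are second-order central differences on
        the uniform grid (one-sided at the ends).
        """
        t = np.asarray(t, dtype=float)
        theta = np.asarray(theta, dtype=float)
        dt = t[1] - t[0]
        omega = np.gradient(theta, dt, axis=0, edge_order=2)
        alpha = np.gradient(omega, dt, axis=0, edge_order=2)
        return cls(t=t, theta=theta, omega=omega, alpha=alpha)


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

def _unit(phi):
    return np.stack([np.cos(phi), np.sin(phi)], axis=-1)


def forward_kinematics(theta, arm: ArmParameters):
    """Positions of the elbow, wrist and fingertip (shoulder at the origin).

    Parameters
    ----------
    theta : array_like, shape (..., 3)
        Joint angles in radians.

    Returns
    -------
    elbow, wrist, fingertip : ndarray, shape (..., 2)
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape[-1] != 3:
        raise InvalidArgumentError("theta must have 3 components")
    if not np.all(np.isfinite(theta)):
        raise InvalidArgumentError("theta contains non-finite values")
    phi1 = theta[..., 0]
    phi2 = phi1 + theta[..., 1]
    phi3 = phi2 + theta[..., 2]
    elbow = arm.L1 * _unit(phi1)
    wrist = elbow + arm.L2 * _unit(phi2)
    fingertip = wrist + arm.L3 * _unit(phi3)
    return elbow, wrist, fingertip


def reachable_bounds(theta3, arm: ArmParameters):
    """Reachable shoulder-to-fingertip distance bounds for a given wrist angle.

    Folding the forearm and hand into one effective link of length
    ``r = sqrt(L2² + L3² + 2 L2 L3 cos(theta3))`` (offset angle ``delta``),
    the fingertip is reachable iff ``|L1 - r| <= |p| <= L1 + r``.

    Returns ``(lower, upper, r, delta)``, broadcasting over ``theta3``.
    """
    theta3 = np.asarray(theta3, dtype=float)
    c3, s3 = np.cos(theta3), np.sin(theta3)
    r = np.sqrt(arm.L2**2 + arm.L3**2 + 2.0 * arm.L2 * arm.L3 * c3)
    delta = np.arctan2(arm.L3 * s3, arm.L2 + arm.L3 * c3)
    return np.abs(arm.L1 - r), arm.L1 + r, r, delta


def inverse_kinematics(p, theta3, arm: ArmParameters, branch: str = "elbow-cw"):
    """Closed-form inverse kinematics for a given wrist angle.

    The wrist angle ``theta3`` removes the redundancy: forearm plus hand act
    as a single effective link ``r(theta3)`` and the problem reduces to
    planar two-link inverse kinematics for links ``(L1, r)``.

    ``branch`` selects the elbow solution: ``"elbow-cw"`` (default) places
    the elbow clockwise of the shoulder→fingertip chord, i.e. positive elbow
    flexion — the posture of a right arm reaching forward in the horizontal
    plane; ``"elbow-ccw"`` is the mirror solution.

    Raises
    ------
    UnreachableTargetError
        If ``|p|`` lies outside the annulus ``[|L1 - r|, L1 + r]``.
    """
    if branch not in ("elbow-cw", "elbow-ccw"):
        raise InvalidArgumentError(f"unknown branch {branch!r}")
    p = np.asarray(p, dtype=float)
    theta3 = np.asarray(theta3, dtype=float)
    if p.shape[-1] != 2:
        raise InvalidArgumentError("p must have 2 components (x, y)")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(theta3))):
        raise InvalidArgumentError("non-finite inverse-kinematics input")

    lower, upper, r, delta = reachable_bounds(theta3, arm)
    x, y = p[..., 0], p[..., 1]
    d = np.hypot(x, y)
    # tolerate roundoff at the annulus boundary
    tol = 1e-12 + 1e-9 * upper
    bad_hi = d > upper + tol
    bad_lo = d < lower - tol
    if np.any(bad_hi) or np.any(bad_lo):
        idx = np.argmax(bad_hi | bad_lo)
        d_flat = np.broadcast_to(d, np.broadcast_shapes(d.shape, lower.shape)).ravel()
        lo_flat = np.broadcast_to(lower, d_flat.shape)
        up_flat = np.broadcast_to(upper, d_flat.shape)
        raise UnreachableTargetError(d_flat[idx], lo_flat[idx], up_flat[idx])

    cos_q2 = np.clip((d**2 - arm.L1**2 - r**2) / (2.0 * arm.L1 * r), -1.0, 1.0)
    q2 = np.arccos(cos_q2)
    if branch == "elbow-ccw":
        q2 = -q2
    theta1 = np.arctan2(y, x) - np.arctan2(r * np.sin(q2), arm.L1 + r * np.cos(q2))
    theta2 = q2 - delta
    theta1 = np.mod(theta1 + np.pi, 2.0 * np.pi) - np.pi
    return np.stack(np.broadcast_arrays(theta1, theta2, theta3), axis=-1)


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

def _inertia_constants(arm: ArmParameters):
    # Own-link terms use I_i about the proximal joint directly (fixture
    # convention); coupling terms depend on masses and COM offsets only.
    a11 = arm.I1 + (arm.m2 + arm.m3) * arm.L1**2
    a22 = arm.I2 + arm.m3 * arm.L2**2
    a33 = arm.I3
    k12 = (arm.m2 * arm.Lg2 + arm.m3 * arm.L2) * arm.L1
    k13 = arm.m3 * arm.L1 * arm.Lg3
    k23 = arm.m3 * arm.L2 * arm.Lg3
    return a11, a22, a33, k12, k13, k23


def _abs_inertia(theta, arm: ArmParameters):
    """Inertia matrix in absolute link angles, plus its theta2/theta3 gradients."""
    theta = np.asarray(theta, dtype=float)
    a11, a22, a33, k12, k13, k23 = _inertia_constants(arm)
    th2 = theta[..., 1]
    th23 = theta[..., 1] + theta[..., 2]
    th3 = theta[..., 2]
    shape = theta.shape[:-1]
    A = np.zeros(shape + (3, 3))
    A[..., 0, 0] = a11
    A[..., 1, 1] = a22
    A[..., 2, 2] = a33
    A[..., 0, 1] = A[..., 1, 0] = k12 * np.cos(th2)
    A[..., 0, 2] = A[..., 2, 0] = k13 * np.cos(th23)
    A[..., 1, 2] = A[..., 2, 1] = k23 * np.cos(th3)

    dA = np.zeros(shape + (3, 3, 2))  # d/dtheta2, d/dtheta3
    s2, s23, s3 = np.sin(th2), np.sin(th23), np.sin(th3)
    dA[..., 0, 1, 0] = dA[..., 1, 0, 0] = -k12 * s2
    dA[..., 0, 2, 0] = dA[..., 2, 0, 0] = -k13 * s23
    dA[..., 0, 2, 1] = dA[..., 2, 0, 1] = -k13 * s23
    dA[..., 1, 2, 1] = dA[..., 2, 1, 1] = -k23 * s3
    return A, dA


def inertia_matrix(theta, arm: ArmParameters) -> np.ndarray:
    """Symmetric positive-definite inertia matrix ``M(theta)``, shape (..., 3, 3).

    Assembled from the kinetic energy in absolute link angles ``phi = L theta``
    (``L`` unit lower-triangular), so ``M = Lᵀ M_abs L``.
    """
    A, _ = _abs_inertia(theta, arm)
    return np.einsum("ji,...jk,kl->...il", _LOWER, A, _LOWER)


def coriolis_vector(theta, omega, arm: ArmParameters) -> np.ndarray:
    """Coriolis/centrifugal torque vector ``H(theta, omega)``, shape (..., 3).

    Built from Christoffel symbols of ``M(theta)``, which guarantees the
    skew-symmetry property ``omegaᵀ (dM/dt − 2C) omega = 0`` and hence exact
    energy balance of the rigid-body part.
    """
    omega = np.asarray(omega, dtype=float)
    _, dA = _abs_inertia(theta, arm)
    # dM[..., i, j, k] = dM_rel_ij / dtheta_k  (k = 0 term vanishes)
    dM23 = np.einsum("ji,...jkm,kl->...ilm", _LOWER, dA, _LOWER)
    dM = np.concatenate([np.zeros(dM23.shape[:-1] + (1,)), dM23], axis=-1)
    gamma = 0.5 * (dM + np.swapaxes(dM, -2, -1) - np.moveaxis(dM, -1, -3))
    return np.einsum("...ijk,...j,...k->...i", gamma, omega, omega)


def _rigid_torque(theta, omega, alpha, arm: ArmParameters) -> np.ndarray:
    """Rigid-body torque ``M(theta) alpha + H(theta, omega)`` without viscosity.

    Evaluated in absolute link angles ``phi = L theta``, where the kinetic
    energy is ``1/2 sum_ij k_ij cos(phi_i - phi_j) dphi_i dphi_j`` and the
    Euler–Lagrange equations collapse to

        tau_abs_i = sum_j k_ij [cos(phi_i - phi_j) ddphi_j
                                + sin(phi_i - phi_j) dphi_j**2],

    mapped back by ``tau = Lᵀ tau_abs``.  Algebraically identical to the
    ``M``/``H`` route of :func:`inertia_matrix`/:func:`coriolis_vector`
    (tested against it), but a few times faster on long sample batches.
    """
    a11, a22, a33, k12, k13, k23 = _inertia_constants(arm)
    phi = np.cumsum(theta, axis=-1)
    dphi = np.cumsum(omega, axis=-1)
    ddphi = np.cumsum(alpha, axis=-1)
    K = np.array([[a11, k12, k13], [k12, a22, k23], [k13, k23, a33]])
    diff = phi[..., :, None] - phi[..., None, :]
    cosd = np.cos(diff)
    sind = np.sin(diff)
    tau_abs = (K * cosd) @ ddphi[..., None] + (K * sind) @ (dphi[..., None] ** 2)
    tau_abs = tau_abs[..., 0]
    # tau_rel_i = sum_{j >= i} tau_abs_j  (Lᵀ applied)
    return np.flip(np.cumsum(np.flip(tau_abs, axis=-1), axis=-1), axis=-1)


def inverse_dynamics(traj_or_theta, arm: ArmParameters, D, omega=None, alpha=None):
    """Joint torques ``tau = M(theta) alpha + H(theta, omega) + D omega``.

    Accepts either an :class:`ArmTrajectory` (returns a per-sample torque
    series) or explicit ``theta, omega, alpha`` arrays of shape (..., 3).
    """
    if isinstance(traj_or_theta, ArmTrajectory):
        theta, omega, alpha = traj_or_theta.theta, traj_or_theta.omega, traj_or_theta.alpha
    else:
        theta = np.asarray(traj_or_theta, dtype=float)
        if omega is None or alpha is None:
            raise InvalidArgumentError("omega and alpha required with raw angle input")
    theta, omega, alpha = (np.asarray(a, dtype=float) for a in (theta, omega, alpha))
    if not theta.shape == omega.shape == alpha.shape:
        raise InvalidArgumentError("theta, omega, alpha shapes differ")
    D = np.asarray(D, dtype=float)
    return _rigid_torque(theta, omega, alpha, arm) + omega @ D.T


def _acceleration(theta, omega, tau, arm, D):
    M = inertia_matrix(theta, arm)
    H = coriolis_vector(theta, omega, arm)
    rhs = np.asarray(tau) - H - omega @ D.T
    return np.linalg.solve(M, rhs[..., None])[..., 0]


def forward_dynamics(tau, theta0, omega0, arm: ArmParameters, D, dt: float) -> ArmTrajectory:
    """Integrate the equation of motion under a sampled torque input.

    ``tau`` has shape (N, 3) with samples at ``t_k = k dt``; the torque is
    treated as piecewise linear between samples.  Integration is classical
    fixed-step Runge–Kutta 4 — the dynamics are smooth and non-stiff at
    desk scale, so no step control is needed.
    """
    tau = np.asarray(tau, dtype=float)
    if tau.ndim != 2 or tau.shape[1] != 3:
        raise InvalidArgumentError("tau must have shape (N, 3)")
    n = tau.shape[0]
    D = np.asarray(D, dtype=float)
    theta = np.empty((n, 3))
    omega = np.empty((n, 3))
    theta[0] = np.asarray(theta0, dtype=float)
    omega[0] = np.asarray(omega0, dtype=float)

    for k in range(n - 1):
        tau0, tau1 = tau[k], tau[k + 1]
        tau_half = 0.5 * (tau0 + tau1)
        th, om = theta[k], omega[k]

        k1_th = om
        k1_om = _acceleration(th, om, tau0, arm, D)
        k2_th = om + 0.5 * dt * k1_om
        k2_om = _acceleration(th + 0.5 * dt * k1_th, k2_th, tau_half, arm, D)
        k3_th = om + 0.5 * dt * k2_om
        k3_om = _acceleration(th + 0.5 * dt * k2_th, k3_th, tau_half, arm, D)
        k4_th = om + dt * k3_om
        k4_om = _acceleration(th + dt * k3_th, k4_th, tau1, arm, D)

        theta[k + 1] = th + dt / 6.0 * (k1_th + 2 * k2_th + 2 * k3_th + k4_th)
        omega[k + 1] = om + dt / 6.0 * (k1_om + 2 * k2_om + 2 * k3_om + k4_om)
        if not (np.all(np.isfinite(theta[k + 1])) and np.all(np.isfinite(omega[k + 1]))):
            raise IntegrationDivergenceError(f"non-finite state at step {k + 1}")

    alpha = _acceleration(theta, omega, tau, arm, D)
    return ArmTrajectory(t=np.arange(n) * dt, theta=theta, omega=omega, alpha=alpha, tau=tau)


# ---------------------------------------------------------------------------
# Joint viscosity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ViscosityCondition:
    """Scale factors and mean-torque terms defining the viscosity matrix.

    ``alpha_a`` scales the viscosity of all joints; ``alpha_b`` additionally
    scales only the wrist entry.  ``mean_abs_torque`` holds the mean absolute
    joint torques of the movement under evaluation (N·m); since the torques
    themselves depend on ``D``, use :func:`resolve_viscosity` to obtain a
    self-consistent pair.
    """

    name: str
    alpha_a: float
    alpha_b: float
    mean_abs_torque: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        if self.alpha_a < 0 or self.alpha_b < 0:
            raise InvalidArgumentError("viscosity scale factors must be >= 0")
        tbar = np.asarray(self.mean_abs_torque, dtype=float)
        if tbar.shape != (3,) or np.any(tbar < 0) or not np.all(np.isfinite(tbar)):
            raise InvalidArgumentError("mean_abs_torque must be a nonnegative 3-vector")
        object.__setattr__(self, "mean_abs_torque", tbar)

    def with_torques(self, tbar) -> "ViscosityCondition":
        return replace(self, mean_abs_torque=np.asarray(tbar, dtype=float))

    @classmethod
    def named(cls, name: str) -> "ViscosityCondition":
        try:
            alpha_a, alpha_b = _NAMED_SCALES[name]
        except KeyError:
            raise InvalidArgumentError(
                f"unknown viscosity condition {name!r}; valid names: "
                f"{sorted(_NAMED_SCALES)}"
            ) from None
        return cls(name=name, alpha_a=alpha_a, alpha_b=alpha_b)


# name -> (alpha_A, alpha_B); BxxAyy: xx = 10*alpha_B, yy = 10*alpha_A
_NAMED_SCALES = {
    "B05A10": (1.0, 0.5),
    "B10A10": (1.0, 1.0),
    "B20A10": (1.0, 2.0),
    "B10A05": (0.5, 1.0),
    "B10A20": (2.0, 1.0),
}

VISCOSITY_CONDITIONS = {name: ViscosityCondition.named(name) for name in _NAMED_SCALES}


def viscosity_matrix(cond: ViscosityCondition) -> np.ndarray:
    """Joint-viscosity matrix ``D`` (N·m·s/rad) for one condition.

    Shoulder/elbow entries follow perturbation estimates during reaching;
    the wrist entry is referenced to the average of the shoulder and elbow
    values.  Each entry grows linearly with the mean absolute torque of the
    corresponding joint during the movement.
    """
    return _viscosity_entries(cond.alpha_a, cond.alpha_b, cond.mean_abs_torque)


def _viscosity_entries(aA: float, aB: float, tbar) -> np.ndarray:
    t1, t2, t3 = tbar
    D = np.zeros((3, 3))
    D[0, 0] = 0.63 * aA + 0.095 * t1
    D[0, 1] = D[1, 0] = 0.175 * aA + 0.0375 * t2
    D[1, 1] = 0.76 * aA + 0.185 * t2
    D[2, 2] = 0.695 * aA * aB + 0.140 * t3
    return D


def resolve_viscosity(traj: ArmTrajectory, arm: ArmParameters, cond: ViscosityCondition,
                      tol: float = 1e-6, max_iter: int = 50, return_torques: bool = False):
    """Self-consistent viscosity matrix and mean absolute torques.

    The viscosity entries depend on the mean absolute joint torques over the
    movement, which themselves depend on the viscous torque ``D omega`` —
    a fixed point resolved by iteration from ``tau_bar = 0`` until the
    largest entry change of ``D`` falls below ``tol``.

    Returns ``(D, tau_bar)``, or ``(D, tau_bar, tau)`` with the converged
    torque series when ``return_torques`` is set.
    """
    # tau = tau_rigid + D omega, and only the viscous term depends on D:
    # precompute the rigid-body part once and iterate on D alone.
    tau_rigid = inverse_dynamics(traj, arm, np.zeros((3, 3)))
    omega = traj.omega
    aA, aB = cond.alpha_a, cond.alpha_b
    D = _viscosity_entries(aA, aB, np.zeros(3))
    for _ in range(max_iter):
        tau = tau_rigid + omega @ D.T
        tbar = np.mean(np.abs(tau), axis=0)
        D_new = _viscosity_entries(aA, aB, tbar)
        delta = np.max(np.abs(D_new - D))
        D = D_new
        if delta < tol:
            if return_torques:
                return D, tbar, tau_rigid + omega @ D.T
            return D, tbar
    raise ConvergenceError(
        f"viscosity fixed point did not converge in {max_iter} iterations "
        f"(last max |dD| = {delta:.3e})", residual=delta)
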