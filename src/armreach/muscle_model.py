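"""Eight-muscle model: moment arms, PCSAs and stress-minimizing tension distribution.

The arm is actuated by eight muscle groups in fixed order

    SF, SE — monoarticular shoulder flexor / extensor
    EF, EE — monoarticular elbow flexor / extensor
    DF, DE — biarticular (shoulder+elbow) flexor / extensor
    WF, WE — monoarticular wrist flexor / extensor

Joint torque is ``tau = A T`` with ``T >= 0`` the muscle tensions (muscles
only pull) and ``A`` the 3×8 moment-arm matrix whose sparsity encodes which
joints each group spans.  Eight published PCSA/moment-arm combinations
(S11..S42) are packaged; they differ in which anatomical muscles were summed
into each group.

Because tensions are redundant (8 unknowns, 3 torque constraints), a unique
tension is selected per time instant by minimizing the sum of squared muscle
stresses ``sum (T_i / PCSA_i)^2`` — a strictly convex quadratic program
solved here by a primal active-set method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidArgumentError, TensionSolverError

__all__ = [
    "MUSCLE_NAMES",
    "SELECTION_NAMES",
    "MuscleSelection",
    "MuscleState",
    "build_selection",
    "distribute_tension",
    "distribute_tension_series",
    "compute_stress",
    "stress_to_kpa",
    "max_tension_summary",
]

MUSCLE_NAMES = ("SF", "SE", "EF", "EE", "DF", "DE", "WF", "WE")

# PCSA in cm^2, shared within each S_x1/S_x2 pair (muscle sets differ only
# in moment arms between the two members of a pair).
_PCSA = {
    "S1": (10.97, 3.87, 13.40, 9.74, 3.23, 3.87, 6.1, 6.8),
    "S2": (10.97, 16.77, 14.69, 9.74, 3.23, 3.87, 6.1, 6.8),
    "S3": (24.52, 25.80, 9.03, 7.74, 3.23, 3.87, 6.1, 6.8),
    "S4": (24.52, 44.52, 14.69, 9.74, 3.23, 3.87, 6.1, 6.8),
}

# Moment arms a1..a10 in cm (flexors positive, extensors negative):
# a1,a2 = SF,SE at shoulder; a5,a6 = EF,EE at elbow; a3,a4 / a7,a8 = DF,DE
# at shoulder / elbow; a9,a10 = WF,WE at wrist.
_MOMENT_ARMS = {
    "S11": (4.06, -7.87, 2.92, -2.54, 1.98, -1.68, 4.32, -2.29, 1.70, -1.07),
    "S12": (2.84, -2.46, 2.92, -2.54, 1.98, -1.68, 4.32, -2.29, 1.70, -1.07),
    "S21": (4.06, -5.97, 2.92, -2.54, 2.42, -1.68, 4.32, -2.29, 1.70, -1.07),
    "S22": (2.84, -1.40, 2.92, -2.54, 2.42, -1.68, 4.32, -2.29, 1.70, -1.07),
    "S31": (4.57, -3.12, 2.92, -2.54, 2.67, -2.03, 4.32, -2.29, 1.70, -1.07),
    "S32": (2.88, -1.57, 2.92, -2.54, 2.67, -2.03, 4.32, -2.29, 1.70, -1.07),
    "S41": (4.57, -3.53, 2.92, -2.54, 2.42, -1.68, 4.32, -2.29, 1.70, -1.07),
    "S42": (2.88, -1.16, 2.92, -2.54, 2.42, -1.68, 4.32, -2.29, 1.70, -1.07),
}

SELECTION_NAMES = tuple(sorted(_MOMENT_ARMS))


def _moment_arm_matrix(a_cm) -> np.ndarray:
    """3×8 moment-arm matrix in metres from the a1..a10 vector in cm."""
    a = np.asarray(a_cm, dtype=float) / 100.0
    A = np.zeros((3, 8))
    A[0, 0], A[0, 1] = a[0], a[1]          # SF, SE at shoulder
    A[0, 4], A[0, 5] = a[2], a[3]          # DF, DE at shoulder
    A[1, 2], A[1, 3] = a[4], a[5]          # EF, EE at elbow
    A[1, 4], A[1, 5] = a[6], a[7]          # DF, DE at elbow
    A[2, 6], A[2, 7] = a[8], a[9]          # WF, WE at wrist
    return A


@dataclass(frozen=True)
class MuscleSelection:
    """One PCSA/moment-arm combination.

    ``pcsa`` is kept in cm² (so stresses are N/cm²); ``moment_arm_cm`` holds
    the published a1..a10 values and ``A`` the derived 3×8 matrix in metres.
    """

    name: str
    pcsa: np.ndarray
    moment_arm_cm: np.ndarray
    A: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        pcsa = np.asarray(self.pcsa, dtype=float)
        arms = np.asarray(self.moment_arm_cm, dtype=float)
        if pcsa.shape != (8,) or np.any(pcsa <= 0):
            raise InvalidArgumentError("pcsa must be 8 positive values (cm^2)")
        if arms.shape != (10,):
            raise InvalidArgumentError("moment_arm_cm must have 10 entries")
        if np.any(arms[0::2] <= 0) or np.any(arms[1::2] >= 0):
            raise InvalidArgumentError(
                "flexor moment arms (odd a_i) must be > 0 and extensor arms "
                "(even a_i) < 0")
        object.__setattr__(self, "pcsa", pcsa)
        object.__setattr__(self, "moment_arm_cm", arms)
        object.__setattr__(self, "A", _moment_arm_matrix(arms))

    def to_params(self) -> str:
        lines = [f"pcsa_{n} = {float(v)!r}" for n, v in zip(MUSCLE_NAMES, self.pcsa)]
        lines += [f"a{i + 1} = {float(v)!r}" for i, v in enumerate(self.moment_arm_cm)]
        return "".join(line + "\n" for line in lines)

    @classmethod
    def from_mapping(cls, name, mapping) -> "MuscleSelection":
        pcsa = [mapping[f"pcsa_{n}"] for n in MUSCLE_NAMES]
        arms = [mapping[f"a{i + 1}"] for i in range(10)]
        return cls(name=name, pcsa=np.array(pcsa), moment_arm_cm=np.array(arms))


@dataclass(frozen=True)
class MuscleState:
    """Tensions (N) and stresses (N/cm²) of the eight muscles at one instant."""

    tension: np.ndarray
    stress: np.ndarray


def build_selection(name: str) -> MuscleSelection:
    """Packaged muscle selection by name (S11, S12, ..., S42)."""
    if name not in _MOMENT_ARMS:
        raise InvalidArgumentError(
            f"unknown muscle selection {name!r}; valid names: {list(SELECTION_NAMES)}")
    return MuscleSelection(
        name=name,
        pcsa=np.array(_PCSA[name[:2]]),
        moment_arm_cm=np.array(_MOMENT_ARMS[name]),
    )


def compute_stress(tension, sel: MuscleSelection) -> np.ndarray:
    """Muscle stress ``S_i = T_i / PCSA_i`` (N/cm²), elementwise over (..., 8)."""
    tension = np.asarray(tension, dtype=float)
    if tension.shape[-1] != 8:
        raise InvalidArgumentError("tension must have 8 components")
    if np.any(tension < -1e-9):
        raise InvalidArgumentError("tension must be nonnegative")
    return tension / sel.pcsa


def stress_to_kpa(stress) -> np.ndarray:
    """Convert stress from the internal N/cm² to kPa (1 N/cm² = 10 kPa)."""
    return 10.0 * np.asarray(stress, dtype=float)


# ---------------------------------------------------------------------------
# Tension distribution QP
# ---------------------------------------------------------------------------
#
#   minimize   sum_i (T_i / PCSA_i)^2
#   subject to A T = tau,  T >= 0
#
# With W = diag(PCSA^2), the minimizer restricted to a support F satisfies
# T_F = W_F A_Fᵀ y with (A_F W_F A_Fᵀ) y = tau; KKT optimality additionally
# requires (Aᵀ y)_i <= 0 for every muscle held at zero.  The primal active-set
# loop below moves between such supports along feasible directions and
# terminates because the objective is strictly convex.

_FLEXOR_COL = (0, 2, 6)     # per-joint monoarticular flexor column
_EXTENSOR_COL = (1, 3, 7)


def _feasible_start(tau, A):
    """A feasible tension using one monoarticular muscle per joint.

    Works for the full 3-joint/8-muscle problem and for the shoulder–elbow
    2-joint/6-muscle subproblem (the column layout is shared).
    """
    T = np.zeros(A.shape[1])
    for j in range(A.shape[0]):
        col = _FLEXOR_COL[j] if tau[j] >= 0 else _EXTENSOR_COL[j]
        T[col] = tau[j] / A[j, col]
    return T


def _solve_small(G, b):
    """Solve the tiny SPD system ``G y = b`` (1x1 .. 3x3) in closed form.

    Falls back to least squares when ``G`` is (numerically) singular, which
    yields a consistent minimum-norm multiplier in the degenerate case of a
    support that spans fewer joints than constraints carry torque.
    """
    n = G.shape[0]
    if n == 1:
        if abs(G[0, 0]) > 1e-300:
            return b / G[0, 0]
    elif n == 2:
        det = G[0, 0] * G[1, 1] - G[0, 1] * G[1, 0]
        if abs(det) > 1e-14 * (abs(G[0, 0]) + abs(G[1, 1])) ** 2:
            return np.array([(G[1, 1] * b[0] - G[0, 1] * b[1]) / det,
                             (G[0, 0] * b[1] - G[1, 0] * b[0]) / det])
    elif n == 3:
        c0 = G[1, 1] * G[2, 2] - G[1, 2] * G[2, 1]
        c1 = G[1, 2] * G[2, 0] - G[1, 0] * G[2, 2]
        c2 = G[1, 0] * G[2, 1] - G[1, 1] * G[2, 0]
        det = G[0, 0] * c0 + G[0, 1] * c1 + G[0, 2] * c2
        if abs(det) > 1e-14 * max(abs(G).max(), 1e-30) ** 3:
            adj = np.array([
                [c0, G[0, 2] * G[2, 1] - G[0, 1] * G[2, 2],
                 G[0, 1] * G[1, 2] - G[0, 2] * G[1, 1]],
                [c1, G[0, 0] * G[2, 2] - G[0, 2] * G[2, 0],
                 G[0, 2] * G[1, 0] - G[0, 0] * G[1, 2]],
                [c2, G[0, 1] * G[2, 0] - G[0, 0] * G[2, 1],
                 G[0, 0] * G[1, 1] - G[0, 1] * G[1, 0]],
            ])
            return (adj @ b) / det
    return np.linalg.lstsq(G, b, rcond=None)[0]


def _eqp(free, A, w2, tau):
    """Equality-constrained minimizer on a support; returns (T_free, y)."""
    Af = A[:, free]
    G = (Af * w2[free]) @ Af.T
    y = _solve_small(G, tau)
    return w2[free] * (Af.T @ y), y


def _solve_qp(tau, A, w2, free=None, tol=1e-11, max_iter=100):
    """Active-set solve; returns (T, free_mask).  ``free`` warm-starts the support."""
    x = _feasible_start(tau, A)
    if free is None:
        free = np.ones(A.shape[1], dtype=bool)
    else:
        free = free.copy()
        # the warm support must be able to carry the feasible start
        free |= x > 0
    scale = 1.0 + np.max(np.abs(tau))
    for _ in range(max_iter):
        T_f, y = _eqp(free, A, w2, tau)
        if T_f.min() >= -tol * scale:
            x = np.zeros(A.shape[1])
            x[free] = np.maximum(T_f, 0.0)
            # KKT check for muscles held at zero
            lam = A.T @ y
            fixed = ~free
            if not np.any(fixed) or np.all(lam[fixed] <= tol * (1.0 + np.abs(lam).max())):
                return x, free
            release = np.flatnonzero(fixed)[np.argmax(lam[fixed])]
            free[release] = True
        else:
            # partial step from the current feasible point, block at zero
            xf = x[free]
            d = T_f - xf
            neg = d < -tol * scale
            with np.errstate(divide="ignore", invalid="ignore"):
                steps = np.where(neg, xf / -d, np.inf)
            j = int(np.argmin(steps))
            alpha = min(1.0, steps[j])
            xf = np.maximum(xf + alpha * d, 0.0)
            x[free] = xf
            block = np.flatnonzero(free)[j]
            x[block] = 0.0
            free[block] = False
    raise TensionSolverError(
        f"active-set QP did not terminate for tau={np.array2string(np.asarray(tau))}")


def distribute_tension(tau, sel: MuscleSelection) -> MuscleState:
    """Stress-minimizing tension distribution for one joint-torque vector.

    Solves the strictly convex QP above; the minimizer is unique, the torque
    constraint holds to solver precision (~1e-12 relative) and antagonists of
    an unopposed torque stay exactly at zero.
    """
    tau = np.asarray(tau, dtype=float)
    if tau.shape != (3,):
        raise InvalidArgumentError("tau must be a 3-vector")
    if not np.all(np.isfinite(tau)):
        raise InvalidArgumentError("tau contains non-finite values")
    w2 = sel.pcsa**2
    T, _ = _solve_qp(tau, sel.A, w2)
    return MuscleState(tension=T, stress=T / sel.pcsa)


def distribute_tension_series(taus, sel: MuscleSelection, tol: float = 1e-11) -> np.ndarray:
    """Tension distribution along a torque series, shape (N, 3) -> (N, 8).

    Along a smooth trajectory the optimal support (set of active muscles)
    changes only at isolated instants, so the series is solved in runs: under
    a tentative support the equality-constrained minimizer is a single linear
    map applied to all remaining torques at once, and samples are accepted
    while they stay feasible (``T >= 0``) and dual-feasible (KKT multipliers
    of the zeroed muscles nonnegative).  At the first sample that violates
    either condition the support is re-derived by the active-set solver and
    the run restarts.  Results are identical to solving each sample alone.
    """
    taus = np.asarray(taus, dtype=float)
    if taus.ndim != 2 or taus.shape[1] != 3:
        raise InvalidArgumentError("taus must have shape (N, 3)")
    if not np.all(np.isfinite(taus)):
        raise InvalidArgumentError("torque series contains non-finite values")
    n = taus.shape[0]
    w2 = sel.pcsa**2
    out = np.zeros((n, 8))

    # The wrist decouples exactly: its two muscles act on no other joint and
    # no other muscle acts on it, and the objective is separable.  For a
    # single-joint flexor/extensor pair the minimizer uses the agonist alone.
    tau3 = taus[:, 2]
    a9, a10 = sel.A[2, 6], sel.A[2, 7]
    out[:, 6] = np.where(tau3 >= 0, tau3 / a9, 0.0)
    out[:, 7] = np.where(tau3 < 0, tau3 / a10, 0.0)

    # shoulder-elbow subproblem: 6 muscles, 2 torque constraints
    out[:, :6] = _series_runs(taus[:, :2], sel.A[:2, :6], w2[:6], tol)
    return out


def _series_runs(taus, A, w2, tol):
    """Run-based series solve of the subproblem QP (see caller docstring)."""
    n = taus.shape[0]
    ncols = A.shape[1]
    out = np.zeros((n, ncols))
    scale = 1.0 + np.max(np.abs(taus), axis=1)
    out[0], free = _solve_qp(taus[0], A, w2)
    k = 1
    window = 64  # bounded lookahead: support changes cost O(window), not O(n)
    while k < n:
        end = min(k + window, n)
        Af = A[:, free]
        G = (Af * w2[free]) @ Af.T
        try:
            Y = np.linalg.solve(G, taus[k:end].T)       # (njoints, m)
        except np.linalg.LinAlgError:
            out[k], free = _solve_qp(taus[k], A, w2, free=free)
            k += 1
            continue
        Tf = w2[free, None] * (Af.T @ Y)                # (nfree, m)
        lam = A.T @ Y                                   # (ncols, m)
        ok = np.all(Tf >= -tol * scale[k:end], axis=0)
        fixed = ~free
        if np.any(fixed):
            lam_scale = tol * (1.0 + np.abs(lam).max(axis=0))
            ok &= np.all(lam[fixed] <= lam_scale, axis=0)
        m = ok.size
        m_ok = int(np.argmin(ok)) if not ok.all() else m
        if m_ok > 0:
            block = np.zeros((m_ok, ncols))
            block[:, free] = np.maximum(Tf[:, :m_ok].T, 0.0)
            out[k:k + m_ok] = block
            k += m_ok
        if m_ok < m and k < n:  # genuine violation: re-derive the support
            out[k], free = _solve_qp(taus[k], A, w2, free=free)
            k += 1
    return out


def max_tension_summary(tensions, sel: MuscleSelection):
    """Per-muscle maximum tension over a movement, paired with PCSA.

    Returns a list of ``(muscle name, max tension N, PCSA cm²)`` tuples in
    muscle order — the raw material for inspecting whether thicker muscles
    take larger peak loads.
    """
    tensions = np.asarray(tensions, dtype=float)
    if tensions.size == 0:
        raise InvalidArgumentError("empty tension series")
    if tensions.ndim == 1:
        tensions = tensions[None, :]
    if tensions.shape[-1] != 8:
        raise InvalidArgumentError("tension series must have 8 columns")
    peak = tensions.max(axis=0)
    return [(name, float(peak[i]), float(sel.pcsa[i]))
            for i, name in enumerate(MUSCLE_NAMES)]
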