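"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: the tension
oracle enumerates all 2^8 support sets instead of iterating an active set,
and the kinetic-energy oracle is built from link geometry instead of the
assembled inertia matrix.
"""

import numpy as np


def brute_force_tension(tau, sel, feas_tol=1e-8):
    """Globally optimal stress-minimizing tension by support enumeration.

    For every subset F of muscles, the equality-constrained stationary point
    restricted to F is ``T_F = W_F A_Fᵀ (A_F W_F A_Fᵀ)⁺ tau`` with
    ``W = diag(PCSA²)``; the optimum of the inequality-constrained problem
    is the best enumerated candidate that is feasible (``T >= 0`` and
    ``A T = tau``).
    """
    A = sel.A
    w2 = sel.pcsa ** 2
    best, best_obj = None, np.inf
    for mask in range(1, 2 ** 8):
        free = np.array([(mask >> i) & 1 for i in range(8)], dtype=bool)
        Af = A[:, free]
        G = (Af * w2[free]) @ Af.T
        y = np.linalg.pinv(G) @ tau
        T = np.zeros(8)
        T[free] = w2[free] * (Af.T @ y)
        if T.min() < -feas_tol:
            continue
        if np.abs(A @ T - tau).max() > feas_tol:
            continue
        obj = np.sum((T / sel.pcsa) ** 2)
        if obj < best_obj:
            best_obj, best = obj, np.maximum(T, 0.0)
    return best


def brute_force_tension_batch(taus, sel, feas_tol=1e-8):
    """Vectorized support enumeration over a batch of torque vectors."""
    A = sel.A
    w2 = sel.pcsa ** 2
    taus = np.asarray(taus, dtype=float)
    n = taus.shape[0]
    best_obj = np.full(n, np.inf)
    best = np.zeros((n, 8))
    for mask in range(1, 2 ** 8):
        free = np.array([(mask >> i) & 1 for i in range(8)], dtype=bool)
        Af = A[:, free]
        G = (Af * w2[free]) @ Af.T
        P = w2[free, None] * (Af.T @ np.linalg.pinv(G))   # (nf, 3)
        Tf = taus @ P.T                                   # (n, nf)
        T = np.zeros((n, 8))
        T[:, free] = Tf
        ok = (Tf.min(axis=1, initial=0.0) >= -feas_tol) & \
             (np.abs(T @ A.T - taus).max(axis=1) <= feas_tol)
        obj = np.sum((T / sel.pcsa) ** 2, axis=1)
        better = ok & (obj < best_obj)
        best_obj[better] = obj[better]
        best[better] = np.maximum(T[better], 0.0)
    return best


def minimum_jerk(amplitude, T, t):
    """The rest-to-rest quintic profile and its exact cost ingredients."""
    s = np.asarray(t) / T
    return amplitude * (10 * s ** 3 - 15 * s ** 4 + 6 * s ** 5)


def minimum_jerk_cost(amplitude, T):
    """Closed form of ``1/2 ∫ (d³x/dt³)² dt`` for the quintic profile."""
    return 360.0 * amplitude ** 2 / T ** 5


def kinetic_energy_from_links(theta, omega, arm):
    """Kinetic energy per sample from link COM velocities and spins.

    Uses only the geometric chain (COM positions differentiated by hand),
    never the assembled inertia matrix, so it is an independent check of the
    dynamics.  ``Ic_i = I_i - m_i Lg_i²`` converts the fixture's
    about-proximal-joint inertias to COM inertias.
    """
    theta = np.asarray(theta, dtype=float)
    omega = np.asarray(omega, dtype=float)
    phi = np.cumsum(theta, axis=1)
    dphi = np.cumsum(omega, axis=1)

    def dunit(phi_i, dphi_i):
        return np.stack([-np.sin(phi_i) * dphi_i, np.cos(phi_i) * dphi_i], axis=1)

    v1 = arm.Lg1 * dunit(phi[:, 0], dphi[:, 0])
    v2 = arm.L1 * dunit(phi[:, 0], dphi[:, 0]) + arm.Lg2 * dunit(phi[:, 1], dphi[:, 1])
    v3 = (arm.L1 * dunit(phi[:, 0], dphi[:, 0])
          + arm.L2 * dunit(phi[:, 1], dphi[:, 1])
          + arm.Lg3 * dunit(phi[:, 2], dphi[:, 2]))
    ic = [arm.I1 - arm.m1 * arm.Lg1 ** 2,
          arm.I2 - arm.m2 * arm.Lg2 ** 2,
          arm.I3 - arm.m3 * arm.Lg3 ** 2]
    ke = 0.5 * (arm.m1 * np.sum(v1 ** 2, axis=1)
                + arm.m2 * np.sum(v2 ** 2, axis=1)
                + arm.m3 * np.sum(v3 ** 2, axis=1)
                + ic[0] * dphi[:, 0] ** 2
                + ic[1] * dphi[:, 1] ** 2
                + ic[2] * dphi[:, 2] ** 2)
    return ke
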