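import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import cumulative_simpson

from armreach import arm_model as am
from armreach.exceptions import (
    ConvergenceError,
    InvalidArgumentError,
    UnreachableTargetError,
)

from oracles import kinetic_energy_from_links


def random_reachable_angles(rng, n):
    """Joint angles well inside the workspace (elbow flexed, wrist modest)."""
    return rng.uniform([-np.pi / 2, 0.1, -1.2], [np.pi, 2.7, 1.2], size=(n, 3))


class TestForwardKinematics:
    def test_fully_extended_is_collinear(self, arm):
        elbow, wrist, tip = am.forward_kinematics([0.0, 0.0, 0.0], arm)
        total = arm.L1 + arm.L2 + arm.L3
        np.testing.assert_allclose(tip, [total, 0.0], atol=1e-15)
        np.testing.assert_allclose(elbow[1], 0.0, atol=1e-15)
        np.testing.assert_allclose(wrist[1], 0.0, atol=1e-15)

    def test_rigid_rotation(self, arm):
        _, _, tip = am.forward_kinematics([np.pi / 2, 0.0, 0.0], arm)
        np.testing.assert_allclose(tip, [0.0, arm.L1 + arm.L2 + arm.L3], atol=1e-15)

    def test_segment_length_preserved(self, arm, rng):
        theta = rng.uniform(-np.pi, np.pi, size=(1000, 3))
        _, wrist, tip = am.forward_kinematics(theta, arm)
        np.testing.assert_allclose(
            np.linalg.norm(tip - wrist, axis=1), arm.L3, atol=1e-12)

    def test_nonfinite_rejected(self, arm):
        with pytest.raises(InvalidArgumentError):
            am.forward_kinematics([np.nan, 0.0, 0.0], arm)


class TestInverseKinematics:
    def test_fully_extended_pose(self, arm):
        theta = am.inverse_kinematics(
            [arm.L1 + arm.L2 + arm.L3, 0.0], 0.0, arm)
        np.testing.assert_allclose(theta, 0.0, atol=1e-9)

    def test_effective_link_length(self, arm):
        # folding forearm+hand at a right angle shortens the distal link to
        # the hypotenuse sqrt(L2^2 + L3^2)
        _, upper, r, _ = am.reachable_bounds(np.pi / 2, arm)
        np.testing.assert_allclose(r, np.hypot(arm.L2, arm.L3), rtol=1e-12)
        np.testing.assert_allclose(upper, arm.L1 + r, rtol=1e-12)

    def test_roundtrip_on_random_postures(self, arm, rng):
        theta = random_reachable_angles(rng, 1000)
        _, _, p = am.forward_kinematics(theta, arm)
        rec = am.inverse_kinematics(p, theta[:, 2], arm)
        _, _, p2 = am.forward_kinematics(rec, arm)
        assert np.abs(p2 - p).max() < 1e-9

    def test_branches_mirror(self, arm):
        p = [0.3, 0.3]
        cw = am.inverse_kinematics(p, 0.2, arm, branch="elbow-cw")
        ccw = am.inverse_kinematics(p, 0.2, arm, branch="elbow-ccw")
        for theta in (cw, ccw):
            _, _, tip = am.forward_kinematics(theta, arm)
            np.testing.assert_allclose(tip, p, atol=1e-9)
        assert not np.allclose(cw, ccw)

    def test_unreachable_reports_bounds(self, arm):
        with pytest.raises(UnreachableTargetError) as exc:
            am.inverse_kinematics([1.0, 0.0], 0.0, arm)
        assert exc.value.distance == pytest.approx(1.0)
        assert exc.value.upper == pytest.approx(arm.L1 + arm.L2 + arm.L3)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(-1.2, 2.7), st.floats(-1.0, 1.0), st.floats(0.3, 2.6))
    def test_roundtrip_property(self, arm, th1, th3, th2):
        theta = np.array([th1, th2, th3])
        _, _, p = am.forward_kinematics(theta, arm)
        rec = am.inverse_kinematics(p, th3, arm)
        _, _, p2 = am.forward_kinematics(rec, arm)
        assert np.abs(p2 - p).max() < 1e-9


class TestDynamics:
    def test_inertia_positive_definite(self, arm, rng):
        theta = rng.uniform(-np.pi, np.pi, size=(300, 3))
        M = am.inertia_matrix(theta, arm)
        np.linalg.cholesky(M)  # raises if any sample is not SPD
        np.testing.assert_allclose(M, np.swapaxes(M, 1, 2), atol=1e-14)

    def test_statics_zero_torque(self, arm, b10a10, rng):
        theta = rng.uniform(-1, 1, size=(50, 3))
        zero = np.zeros_like(theta)
        tau = am.inverse_dynamics(theta, arm, am.viscosity_matrix(b10a10),
                                  omega=zero, alpha=zero)
        np.testing.assert_allclose(tau, 0.0, atol=1e-14)

    def test_locked_proximal_joints_single_joint_form(self, arm):
        # shoulder and elbow locked, wrist oscillating: the wrist equation
        # reduces to I3 * ddtheta3 + D33 * dtheta3
        t = np.linspace(0.0, 1.0, 501)
        w = 2 * np.pi * 1.5
        theta = np.stack([np.full_like(t, 0.4), np.full_like(t, 1.1),
                          0.3 * np.sin(w * t)], axis=1)
        omega = np.stack([np.zeros_like(t), np.zeros_like(t),
                          0.3 * w * np.cos(w * t)], axis=1)
        alpha = np.stack([np.zeros_like(t), np.zeros_like(t),
                          -0.3 * w * w * np.sin(w * t)], axis=1)
        D = np.diag([0.5, 0.4, 0.3])
        tau = am.inverse_dynamics(theta, arm, D, omega=omega, alpha=alpha)
        expected = arm.I3 * alpha[:, 2] + 0.3 * omega[:, 2]
        np.testing.assert_allclose(tau[:, 2], expected, rtol=1e-12, atol=1e-12)

    def test_rigid_torque_matches_lagrangian_assembly(self, arm, rng):
        # dual route: fast absolute-angle formulation vs M/H Christoffel route
        theta = rng.normal(0, 1, (200, 3))
        omega = rng.normal(0, 3, (200, 3))
        alpha = rng.normal(0, 10, (200, 3))
        M = am.inertia_matrix(theta, arm)
        H = am.coriolis_vector(theta, omega, arm)
        slow = np.einsum("nij,nj->ni", M, alpha) + H
        fast = am.inverse_dynamics(theta, arm, np.zeros((3, 3)),
                                   omega=omega, alpha=alpha)
        np.testing.assert_allclose(fast, slow, rtol=1e-10, atol=1e-10)

    def test_energy_balance_without_viscosity(self, arm):
        # independent oracle: KE from link geometry; applied power from the
        # inverse-dynamics torques; Simpson-accumulated power must track KE
        t = np.linspace(0.0, 1.0, 8001)
        w = 2 * np.pi
        theta = np.stack([0.4 * np.sin(w * t), 1.2 + 0.3 * np.cos(w * t),
                          0.3 * np.sin(0.7 * w * t)], axis=1)
        omega = np.stack([0.4 * w * np.cos(w * t), -0.3 * w * np.sin(w * t),
                          0.21 * w * np.cos(0.7 * w * t)], axis=1)
        alpha = np.stack([-0.4 * w ** 2 * np.sin(w * t),
                          -0.3 * w ** 2 * np.cos(w * t),
                          -0.147 * w ** 2 * np.sin(0.7 * w * t)], axis=1)
        tau = am.inverse_dynamics(theta, arm, np.zeros((3, 3)),
                                  omega=omega, alpha=alpha)
        ke = kinetic_energy_from_links(theta, omega, arm)
        power = np.einsum("ni,ni->n", omega, tau)
        work = cumulative_simpson(power, x=t, initial=0.0)
        residual = np.abs(ke - ke[0] - work).max()
        assert residual < 1e-6 * ke.max()

    def test_forward_inverse_roundtrip(self, arm, b10a10):
        tf = 1.0
        t = np.linspace(0.0, tf, 2001)
        theta = np.stack([0.3 * np.sin(2 * np.pi * t),
                          1.0 + 0.4 * np.sin(2 * np.pi * t + 1.0),
                          0.2 * np.cos(3.0 * t)], axis=1)
        traj = am.ArmTrajectory.from_theta(t, theta)
        D = am.viscosity_matrix(b10a10)
        tau = am.inverse_dynamics(traj, arm, D)
        sim = am.forward_dynamics(tau, theta[0], traj.omega[0], arm, D,
                                  tf / 2000)
        rms = np.sqrt(np.mean((sim.theta - theta) ** 2))
        assert rms < 1e-4

    def test_equilibrium_stays_put(self, arm):
        tau = np.zeros((100, 3))
        theta0 = np.array([0.3, 1.2, 0.1])
        sim = am.forward_dynamics(tau, theta0, np.zeros(3), arm,
                                  np.zeros((3, 3)), 0.005)
        np.testing.assert_allclose(sim.theta, np.tile(theta0, (100, 1)), atol=1e-12)

    def test_viscous_damping_dissipates(self, arm, b10a10):
        D = am.viscosity_matrix(b10a10)
        theta0 = np.array([0.3, 1.2, 0.1])
        omega0 = np.array([1.0, -2.0, 3.0])
        sim = am.forward_dynamics(np.zeros((400, 3)), theta0, omega0, arm, D,
                                  0.0025)
        M = am.inertia_matrix(sim.theta, arm)
        ke = 0.5 * np.einsum("ni,nij,nj->n", sim.omega, M, sim.omega)
        assert np.all(np.diff(ke) <= 1e-10)


class TestViscosity:
    def test_reference_condition_matrix(self):
        cond = am.ViscosityCondition.named("B10A10")
        D = am.viscosity_matrix(cond)
        np.testing.assert_allclose(
            D, [[0.63, 0.175, 0.0], [0.175, 0.76, 0.0], [0.0, 0.0, 0.695]])

    def test_named_scale_factors(self):
        expected = {"B05A10": (1.0, 0.5), "B10A10": (1.0, 1.0),
                    "B20A10": (1.0, 2.0), "B10A05": (0.5, 1.0),
                    "B10A20": (2.0, 1.0)}
        for name, (a, b) in expected.items():
            cond = am.ViscosityCondition.named(name)
            assert (cond.alpha_a, cond.alpha_b) == (a, b)

    def test_doubled_wrist_scale_rounds_to_printed_value(self):
        D = am.viscosity_matrix(am.ViscosityCondition.named("B20A10"))
        assert D[2, 2] == pytest.approx(1.39)
        assert f"{D[2, 2]:.1f}" == "1.4"

    def test_zero_alpha_a_zeroes_everything(self):
        cond = am.ViscosityCondition(name="custom", alpha_a=0.0, alpha_b=1.0)
        np.testing.assert_array_equal(am.viscosity_matrix(cond), 0.0)

    def test_torque_terms_enter_linearly(self):
        cond = am.ViscosityCondition(
            name="custom", alpha_a=1.0, alpha_b=1.0,
            mean_abs_torque=np.array([2.0, 3.0, 4.0]))
        D = am.viscosity_matrix(cond)
        assert D[0, 0] == pytest.approx(0.63 + 0.095 * 2)
        assert D[0, 1] == D[1, 0] == pytest.approx(0.175 + 0.0375 * 3)
        assert D[1, 1] == pytest.approx(0.76 + 0.185 * 3)
        assert D[2, 2] == pytest.approx(0.695 + 0.140 * 4)

    def test_negative_scale_rejected(self):
        with pytest.raises(InvalidArgumentError):
            am.ViscosityCondition(name="bad", alpha_a=-1.0, alpha_b=1.0)

    def test_unknown_name_lists_valid(self):
        with pytest.raises(InvalidArgumentError, match="B10A10"):
            am.ViscosityCondition.named("B99A99")

    def test_resolve_zero_motion(self, arm, b10a10):
        t = np.linspace(0, 1, 201)
        theta = np.tile([0.3, 1.2, 0.1], (201, 1))
        traj = am.ArmTrajectory(t=t, theta=theta, omega=np.zeros((201, 3)),
                                alpha=np.zeros((201, 3)))
        D, tbar = am.resolve_viscosity(traj, arm, b10a10)
        np.testing.assert_allclose(tbar, 0.0, atol=1e-15)
        np.testing.assert_allclose(D, am.viscosity_matrix(b10a10))

    def test_resolved_pair_is_self_consistent(self, arm, b10a10, t41):
        from armreach.trajectory import individual_to_arm_trajectory, seed_individual
        built = individual_to_arm_trajectory(seed_individual(t41), t41, arm)
        D, tbar, tau = am.resolve_viscosity(built.traj, arm, b10a10,
                                            return_torques=True)
        np.testing.assert_allclose(
            D, am.viscosity_matrix(b10a10.with_torques(tbar)), atol=1e-6)
        np.testing.assert_allclose(tbar, np.mean(np.abs(tau), axis=0), atol=1e-6)

    def test_resolve_nonconvergence_raises(self, arm, b10a10, t41):
        from armreach.trajectory import individual_to_arm_trajectory, seed_individual
        built = individual_to_arm_trajectory(seed_individual(t41), t41, arm)
        with pytest.raises(ConvergenceError):
            am.resolve_viscosity(built.traj, arm, b10a10, max_iter=1, tol=1e-12)


class TestArmParameters:
    def test_profile_values_are_loaded(self, arm):
        assert arm.L1 == 0.283 and arm.L2 == 0.240 and arm.L3 == 0.195
        assert arm.I3 == 0.00438

    def test_com_inside_link_enforced(self):
        good = ArmParametersKwargs()
        good["Lg2"] = good["L2"] + 0.01
        with pytest.raises(InvalidArgumentError, match="Lg2"):
            am.ArmParameters(**good)

    def test_positivity_enforced(self):
        bad = ArmParametersKwargs()
        bad["m1"] = -1.0
        with pytest.raises(InvalidArgumentError, match="m1"):
            am.ArmParameters(**bad)

    def test_unknown_profile(self):
        with pytest.raises(InvalidArgumentError, match="table2_mean"):
            am.ArmParameters.from_profile("nonexistent_profile")

    def test_roundtrip_through_params_text(self, arm, tmp_path):
        path = tmp_path / "custom.params"
        path.write_text(arm.to_params())
        again = am.ArmParameters.from_profile(str(path))
        assert again == arm


def ArmParametersKwargs():
    return dict(L1=0.283, L2=0.240, L3=0.195, Lg1=0.110, Lg2=0.0928,
                Lg3=0.0674, m1=1.617, m2=0.878, m3=0.512, I1=0.0363,
                I2=0.0128, I3=0.00438)


class TestArmTrajectory:
    def test_uniform_grid_required(self):
        t = np.array([0.0, 0.1, 0.25])
        with pytest.raises(InvalidArgumentError):
            am.ArmTrajectory(t=t, theta=np.zeros((3, 3)),
                             omega=np.zeros((3, 3)), alpha=np.zeros((3, 3)))

    def test_finite_difference_consistency(self):
        t = np.linspace(0, 1, 401)
        theta = np.stack([np.sin(t), np.cos(t), t ** 2], axis=1)
        traj = am.ArmTrajectory.from_theta(t, theta)
        dt = traj.dt
        interior = slice(1, -1)
        expected = (theta[2:] - theta[:-2]) / (2 * dt)
        np.testing.assert_allclose(traj.omega[interior], expected, atol=1e-12)
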