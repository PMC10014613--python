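"""Skeletal model: prosthesis operator, contact, passive joints, dynamics."""

import numpy as np
import pytest

from cpgwalk.body import (BodyModel, MechState, default_body,
                          apply_prosthesis, contact_force,
                          joint_passive_moment, equations_of_motion,
                          integrate_step, contact_point_positions,
                          save_body, load_body, pack_body, pack_chains)
from cpgwalk import _kernels as K


class TestProsthesis:
    def test_scaling_and_stiffness(self, body):
        out = apply_prosthesis(body, "right")
        assert out.segments["shank_r"].mass == pytest.approx(
            body.segments["shank_r"].mass * 0.65)
        assert out.segments["foot_r"].mass == pytest.approx(
            body.segments["foot_r"].mass * 0.65)
        assert out.segments["shank_r"].inertia == pytest.approx(
            body.segments["shank_r"].inertia * 0.40)
        assert out.segments["foot_r"].inertia == pytest.approx(
            body.segments["foot_r"].inertia * 0.40)
        assert out.prosthesis.ankle_stiffness == 400.0
        assert out.prosthesis.side == "right"

    def test_hand_arithmetic_examples(self, body):
        out = apply_prosthesis(body, "left")
        assert out.segments["shank_l"].mass == pytest.approx(3.0 * 0.65)
        assert out.segments["shank_l"].inertia == pytest.approx(0.05 * 0.40)

    def test_other_side_unchanged(self, body):
        out = apply_prosthesis(body, "right")
        for name in ("hat", "thigh_l", "shank_l", "foot_l", "thigh_r"):
            assert out.segments[name].mass == body.segments[name].mass
        assert out.joint_viscosity == body.joint_viscosity
        assert body.prosthesis is None  # original untouched

    def test_unknown_side(self, body):
        with pytest.raises(ValueError):
            apply_prosthesis(body, "middle")


class TestContactForce:
    COEFFS = {"k_h": 5.0e3, "c_h": 1.0e3, "k_v": 2.5e4, "c_v": 5.0e2}

    def test_above_ground_no_force(self):
        f = contact_force((0.0, 0.01), (0.0, 0.0), self.COEFFS, anchor_x=0.0)
        assert np.all(f == 0.0)

    def test_vertical_spring_arithmetic(self):
        f = contact_force((0.0, -0.01), (0.0, 0.0), self.COEFFS)
        assert f[1] == pytest.approx(250.0)

    def test_horizontal_spring_arithmetic(self):
        f = contact_force((0.0, -0.001), (0.0, 0.0), self.COEFFS,
                          anchor_x=0.002)
        assert f[0] == pytest.approx(10.0)

    def test_no_adhesion(self):
        # fast upward motion would make the damper pull down; clamp at 0
        f = contact_force((0.0, -0.001), (0.0, 1.0), self.COEFFS)
        assert f[1] == 0.0


class TestPassiveJoints:
    def test_no_motion_no_moment(self, body):
        for joint in ("hip", "knee", "ankle"):
            assert joint_passive_moment(joint, "left", 0.1, 0.0, body) == 0.0

    def test_hip_viscous_moment(self, body):
        m = joint_passive_moment("hip", "right", 0.0, 1.0, body)
        assert m == pytest.approx(-1.09)

    @pytest.mark.parametrize("joint,visc", [("hip", 1.09), ("knee", 3.17),
                                            ("ankle", 0.943)])
    def test_default_viscosities(self, body, joint, visc):
        assert body.joint_viscosity[joint] == visc
        m = joint_passive_moment(joint, "left", 0.0, 2.0, body)
        assert m == pytest.approx(-2.0 * visc)

    def test_lock_restores_toward_range(self, body):
        lo, hi = body.joint_limits["knee"]
        assert joint_passive_moment("knee", "left", lo - 0.05, 0.0, body) > 0
        assert joint_passive_moment("knee", "left", hi + 0.05, 0.0, body) < 0

    def test_prosthetic_ankle_spring(self, body):
        utta = apply_prosthesis(body, "right")
        m = joint_passive_moment("ankle", "right", 0.1, 0.0, utta)
        assert m == pytest.approx(-400.0 * 0.1)
        assert joint_passive_moment("ankle", "left", 0.1, 0.0, utta) == 0.0

    def test_unknown_joint(self, body):
        with pytest.raises(ValueError):
            joint_passive_moment("elbow", "left", 0.0, 0.0, body)


def airborne_state(y=5.0):
    return MechState(q=np.array([0.0, y, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]),
                     qd=np.zeros(9))


class TestDynamics:
    def test_free_fall(self, body):
        qdd = equations_of_motion(airborne_state(), np.zeros(6),
                                  np.zeros((4, 2)), body)
        assert qdd[1] == pytest.approx(-9.81, abs=1e-9)
        assert np.allclose(np.delete(qdd, 1), 0.0, atol=1e-9)

    def test_static_standing_equilibrium(self, body):
        """A consistent static solution exists: least-squares contact forces
        (vertical at heel/toe) that null all accelerations carry the body
        weight and leave residual accelerations ~0."""
        st = MechState(q=np.array([0.0, body.standing_hip_height,
                                   0, 0, 0, 0, 0, 0, 0]), qd=np.zeros(9))
        # accelerations are affine in the applied vertical contact forces
        base = equations_of_motion(st, np.zeros(6), np.zeros((4, 2)), body)
        cols = []
        for p in range(4):
            fc = np.zeros((4, 2))
            fc[p, 1] = 1.0
            cols.append(equations_of_motion(st, np.zeros(6), fc, body) - base)
        A = np.array(cols).T
        f, *_ = np.linalg.lstsq(A, -base, rcond=None)
        fc = np.zeros((4, 2))
        fc[:, 1] = f
        qdd = equations_of_motion(st, np.zeros(6), fc, body)
        assert np.all(f > 0.0)
        assert f.sum() == pytest.approx(body.total_mass * 9.81, rel=1e-6)
        assert np.allclose(qdd, 0.0, atol=1e-6)

    def test_mass_scaling_linearity(self, body):
        st = MechState(q=np.array([0, 5.0, .1, .2, .3, .1, -.2, -.1, .05]),
                       qd=np.array([.1, .2, .3, -.1, 0, .2, -.3, .1, 0]))
        tau = np.array([1.0, 2.0, -1.0, 0.5, -2.0, 1.0])
        fc = np.array([[10.0, 50.0], [5.0, 20.0], [0.0, 30.0], [2.0, 10.0]])
        a1 = equations_of_motion(st, tau, fc, body)
        heavy = body.copy()
        for seg in heavy.segments.values():
            seg.mass *= 2.0
            seg.inertia *= 2.0
        a2 = equations_of_motion(st, 2 * tau, 2 * fc, heavy)
        assert np.allclose(a1, a2, atol=1e-10)

    def test_energy_conserved_without_damping(self, body):
        """Airborne, zero viscosity, no contact: total mechanical energy is
        conserved to RK4 accuracy — a strong consistency check of the mass
        matrix and velocity-product terms."""
        b = body.copy()
        b.joint_viscosity = {k: 0.0 for k in b.joint_viscosity}
        q = np.array([0, 5.0, 0.05, 0.3, 0.1, 0.1, -0.2, -0.3, -0.1])
        qd = np.array([0.1, 0, 0.2, -0.3, 0.1, 0.3, 0.2, -0.1, 0.4])

        pb = pack_body(b)
        ci, off, _, _ = pack_chains(b)

        def energy(q, qd):
            E = 0.0
            for i in range(7):
                m = pb[K.PB_MASS + i]
                I = pb[K.PB_INERTIA + i]
                px, py, vx, vy = q[0], q[1], qd[0], qd[1]
                for k in range(3):
                    a = ci[i, k]
                    if a < 0:
                        break
                    c, s = np.cos(q[a]), np.sin(q[a])
                    ox, oy = off[i, k]
                    wx, wy = ox * c - oy * s, ox * s + oy * c
                    px += wx
                    py += wy
                    vx += -wy * qd[a]
                    vy += wx * qd[a]
                E += (0.5 * m * (vx * vx + vy * vy)
                      + 0.5 * I * qd[2 + i] ** 2 + m * 9.81 * py)
            return E

        def deriv(s):
            stx = MechState(q=s[:9], qd=s[9:])
            return np.concatenate([
                s[9:], equations_of_motion(stx, np.zeros(6),
                                           np.zeros((4, 2)), b)])

        s = np.concatenate([q, qd])
        E0 = energy(s[:9], s[9:])
        for _ in range(1000):
            s = integrate_step(s, deriv, 1e-4)
        assert energy(s[:9], s[9:]) == pytest.approx(E0, rel=1e-10)

    def test_energy_decays_with_viscosity_only(self, body):
        """Airborne with viscous joints and zero activation: the internal
        mechanical energy (kinetic energy in the COM frame) decreases
        monotonically — uniform gravity does no work on relative motion."""
        body = body.copy()
        body.lock_stiffness = 0.0  # the limit springs are conservative
        q = np.array([0, 50.0, 0.0, 0.3, 0.0, 0.0, -0.3, 0.0, 0.0])
        qd = np.array([0, 0, 0.0, 1.0, -0.5, 0.0, -1.0, 0.5, 0.0])
        pb = pack_body(body)
        ci, off, _, _ = pack_chains(body)

        def internal_energy(q, qd):
            vels = []
            masses = []
            E_rot = 0.0
            for i in range(7):
                m = pb[K.PB_MASS + i]
                vx, vy = qd[0], qd[1]
                for k in range(3):
                    a = ci[i, k]
                    if a < 0:
                        break
                    c, s = np.cos(q[a]), np.sin(q[a])
                    ox, oy = off[i, k]
                    wx, wy = ox * c - oy * s, ox * s + oy * c
                    vx += -wy * qd[a]
                    vy += wx * qd[a]
                vels.append((vx, vy))
                masses.append(m)
                E_rot += 0.5 * pb[K.PB_INERTIA + i] * qd[2 + i] ** 2
            vels = np.array(vels)
            masses = np.array(masses)
            v_com = (masses[:, None] * vels).sum(0) / masses.sum()
            rel = vels - v_com
            return E_rot + 0.5 * float(masses @ (rel ** 2).sum(1))

        def deriv(s):
            stx = MechState(q=s[:9], qd=s[9:])
            th = stx.joint_angles()
            thd = stx.joint_velocities()
            tau6 = np.zeros(6)
            K.joint_passive_kernel(th, thd, pb, tau6)
            return np.concatenate([
                s[9:], equations_of_motion(stx, tau6, np.zeros((4, 2)), body)])

        s = np.concatenate([q, qd])
        prev = np.inf
        for i in range(500):
            s = integrate_step(s, deriv, 1e-4)
            if i % 50 == 0:
                cur = internal_energy(s[:9], s[9:])
                assert cur <= prev + 1e-9
                prev = cur

    def test_left_right_mirror_symmetry(self, body):
        """Mirroring the state (x -> -x, angles negated, legs swapped) with
        mirrored torques/forces mirrors the accelerations.  A full spatial
        mirror also reflects the foot fore-aft, so the check uses a body
        with fore-aft-symmetric feet (heel and toe swap roles)."""
        b = body.copy()
        b.heel = (-0.1, -0.06)
        b.toe = (0.1, -0.06)
        b.foot_com = (0.0, -0.04)
        q = np.array([0.3, 0.9, 0.1, 0.25, 0.05, -0.1, -0.2, -0.15, 0.08])
        qd = np.array([0.5, -0.1, 0.2, 0.4, -0.3, 0.1, -0.2, 0.3, -0.1])
        tau = np.array([5.0, -3.0, 2.0, 1.0, 4.0, -2.0])
        fc = np.array([[10.0, 300.0], [5.0, 100.0], [-3.0, 150.0],
                       [2.0, 50.0]])

        def mirror_q(v):
            return np.array([-v[0], v[1], -v[2], -v[6], -v[7], -v[8],
                             -v[3], -v[4], -v[5]])

        a = equations_of_motion(MechState(q=q, qd=qd), tau, fc, b)
        tau_m = -np.concatenate([tau[3:], tau[:3]])
        # legs swap AND heel<->toe swap within each foot; fx flips
        fc_m = np.vstack([fc[3], fc[2], fc[1], fc[0]]) * np.array([-1.0, 1.0])
        a_m = equations_of_motion(MechState(q=mirror_q(q), qd=mirror_q(qd)),
                                  tau_m, fc_m, b)
        assert np.allclose(a_m, mirror_q(a), atol=1e-9)

    def test_singular_inertia_raises(self, body):
        bad = body.copy()
        bad.segments["hat"].inertia = 0.0
        bad.segments["hat"].mass = 0.0
        st = airborne_state()
        with pytest.raises(ValueError):
            equations_of_motion(st, np.zeros(6), np.zeros((4, 2)), bad)


class TestIntegrator:
    def test_zero_dt_identity(self):
        s = np.array([1.0, 2.0])
        out = integrate_step(s, lambda x: -x, 0.0)
        assert np.array_equal(out, s)

    def test_exponential_order(self):
        lam, dt = -2.0, 0.01
        out = integrate_step(np.array([1.0]), lambda x: lam * x, dt)
        assert abs(out[0] - np.exp(lam * dt)) < abs(lam * dt) ** 5

    def test_harmonic_oscillator_fourth_order_convergence(self):
        # global error over one period shrinks ~16x when dt halves
        def deriv(s):
            return np.array([s[1], -s[0]])

        def global_error(n):
            dt = 2 * np.pi / n  # land exactly on one period
            s = np.array([1.0, 0.0])
            for _ in range(n):
                s = integrate_step(s, deriv, dt)
            return np.hypot(s[0] - 1.0, s[1])

        e1 = global_error(300)
        e2 = global_error(600)
        assert e1 / e2 == pytest.approx(16.0, rel=0.2)

    def test_non_finite_derivative_raises(self):
        with pytest.raises(FloatingPointError):
            integrate_step(np.array([1.0]),
                           lambda x: np.array([np.inf]), 0.1)

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            integrate_step(np.array([1.0]), lambda x: -x, -0.1)


class TestStateAndIO:
    def test_state_shape_and_finiteness_checked(self):
        with pytest.raises(ValueError):
            MechState(q=np.zeros(5), qd=np.zeros(9))
        with pytest.raises(ValueError):
            MechState(q=np.full(9, np.nan), qd=np.zeros(9))

    def test_total_mass(self, body):
        assert body.total_mass == pytest.approx(
            sum(s.mass for s in body.segments.values()))
        assert body.total_mass == pytest.approx(70.0)

    def test_segment_validation(self):
        with pytest.raises(ValueError):
            from cpgwalk.body import Segment
            Segment(mass=-1.0, length=0.4, inertia=0.1, com=0.2)

    def test_yaml_round_trip(self, body, tmp_path):
        utta = apply_prosthesis(body, "left")
        path = tmp_path / "body.yaml"
        save_body(utta, path)
        back = load_body(path)
        assert back.total_mass == pytest.approx(utta.total_mass)
        assert back.prosthesis.side == "left"
        assert back.joint_viscosity == utta.joint_viscosity
        assert back.contact == utta.contact

    def test_contact_points_at_ground_when_standing(self, body):
        st = MechState(q=np.array([0.0, body.standing_hip_height,
                                   0, 0, 0, 0, 0, 0, 0]), qd=np.zeros(9))
        pos, vel = contact_point_positions(st, body)
        assert np.allclose(pos[:, 1], 0.0, atol=1e-12)
        assert np.allclose(vel, 0.0)
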