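"""Planar 7-segment skeletal model and rigid-body dynamics.

The skeleton is HAT (head-arms-trunk lumped), two thighs, two shanks and two
feet, connected by pin joints at the hips, knees and ankles, each with a
linear viscous element.  Knee and ankle range-of-motion "locks" are stiff
one-sided torsional spring-dampers engaged beyond the limits.  Ground
contact at the heel and toe of each foot is a linear spring-damper, vertical
force floored at zero (no adhesion), horizontal spring anchored to the
touchdown point.

Generalized coordinates are minimal: pelvis/hip position (x, y) plus the 7
absolute segment angles (9 DOF).  All angles are zero in the neutral
standing posture, CCW positive, +x forward.

Default segment parameters are reconstructed from standard anthropometric
tables for a ~70 kg, ~1.7 m adult and are fully editable through the YAML
body configuration.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import _kernels as K

SEGMENT_NAMES = ("hat", "thigh_l", "shank_l", "foot_l", "thigh_r", "shank_r", "foot_r")
JOINT_NAMES = ("hip", "knee", "ankle")
SIDES = ("left", "right")

GRAVITY = 9.81


@dataclass
class Segment:
    """One rigid segment: mass (kg), length (m), inertia about COM (kg m^2),
    COM offset from the proximal joint along the segment (m)."""

    mass: float
    length: float
    inertia: float
    com: float

    def __post_init__(self):
        if self.mass <= 0 or self.length <= 0 or self.inertia <= 0:
            raise ValueError("segment mass, length and inertia must be positive")


@dataclass
class Prosthesis:
    """Transtibial prosthesis descriptor: which shank+foot complex is
    replaced, inertial scaling applied to it, and the passive rotational
    stiffness of the prosthetic ankle (Nm/rad)."""

    side: str
    mass_scale: float = 0.65
    inertia_scale: float = 0.40
    ankle_stiffness: float = 400.0

    def __post_init__(self):
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}; expected one of {SIDES}")


@dataclass
class BodyModel:
    """Full skeletal configuration: segments, joints, contact, prosthesis."""

    segments: dict[str, Segment]
    joint_viscosity: dict[str, float]
    joint_limits: dict[str, tuple[float, float]]
    contact: dict[str, float]          # k_h, c_h, k_v, c_v
    foot_com: tuple[float, float]      # COM offset in the foot frame
    heel: tuple[float, float]          # heel contact point in the foot frame
    toe: tuple[float, float]           # toe contact point in the foot frame
    lock_stiffness: float = 1000.0
    lock_damping: float = 50.0
    prosthesis: Prosthesis | None = None
    gravity: float = GRAVITY
    pitch_ref: float = -0.10           # posture-control HAT pitch target (rad)
    fall_fraction: float = 0.60        # fall when HAT COM < fraction * standing
    hip_min_height: float = 0.45       # fall when the hip drops below this (m)

    @property
    def total_mass(self) -> float:
        return sum(s.mass for s in self.segments.values())

    @property
    def standing_hip_height(self) -> float:
        """Hip height in the neutral standing posture (sole on the ground)."""
        return (self.segments["thigh_l"].length + self.segments["shank_l"].length
                - self.heel[1])

    @property
    def standing_hat_com_height(self) -> float:
        return self.standing_hip_height + self.segments["hat"].com

    def copy(self) -> "BodyModel":
        return copy.deepcopy(self)


def default_body() -> BodyModel:
    """Reconstructed default anthropometrics (70 kg total)."""
    segments = {
        "hat": Segment(mass=48.0, length=0.80, inertia=3.0, com=0.35),
        "thigh_l": Segment(mass=7.0, length=0.41, inertia=0.12, com=0.18),
        "shank_l": Segment(mass=3.0, length=0.42, inertia=0.05, com=0.18),
        "foot_l": Segment(mass=1.0, length=0.25, inertia=0.005, com=0.05),
        "thigh_r": Segment(mass=7.0, length=0.41, inertia=0.12, com=0.18),
        "shank_r": Segment(mass=3.0, length=0.42, inertia=0.05, com=0.18),
        "foot_r": Segment(mass=1.0, length=0.25, inertia=0.005, com=0.05),
    }
    return BodyModel(
        segments=segments,
        joint_viscosity={"hip": 1.09, "knee": 3.17, "ankle": 0.943},
        joint_limits={
            "hip": (-0.70, 1.80),
            "knee": (-0.05, 2.40),
            "ankle": (-0.90, 0.70),
        },
        contact={"k_h": 5.0e3, "c_h": 1.0e3, "k_v": 2.5e4, "c_v": 5.0e2},
        foot_com=(0.04, -0.04),
        heel=(-0.07, -0.06),
        toe=(0.18, -0.06),
    )


def apply_prosthesis(body: BodyModel, side: str) -> BodyModel:
    """Return a copy of ``body`` with a transtibial prosthesis on ``side``.

    The shank+foot complex mass is scaled to 65 %, its moments of inertia to
    40 %, and the ankle passive rotational stiffness is set to 400 Nm/rad.
    The prosthesis descriptor also marks TA, SO and GC on that side for
    removal (enforced by the muscle module).
    """
    if side not in SIDES:
        raise ValueError(f"unknown side {side!r}; expected one of {SIDES}")
    out = body.copy()
    pros = Prosthesis(side=side)
    suffix = "_l" if side == "left" else "_r"
    for name in (f"shank{suffix}", f"foot{suffix}"):
        seg = out.segments[name]
        seg.mass *= pros.mass_scale
        seg.inertia *= pros.inertia_scale
    out.prosthesis = pros
    return out


def removed_muscles(body: BodyModel) -> set[tuple[str, str]]:
    """(name, side) pairs of muscles absent from this body (prosthesis)."""
    if body.prosthesis is None:
        return set()
    return {(m, body.prosthesis.side) for m in ("TA", "SO", "GC")}


# ---------------------------------------------------------------------------
# packing for the numba kernels

def pack_body(body: BodyModel) -> np.ndarray:
    pb = np.zeros(K.PB_LEN)
    for i, name in enumerate(SEGMENT_NAMES):
        pb[K.PB_MASS + i] = body.segments[name].mass
        pb[K.PB_INERTIA + i] = body.segments[name].inertia
    pb[K.PB_C_HAT] = body.segments["hat"].com
    pb[K.PB_L_TH] = body.segments["thigh_l"].length
    pb[K.PB_C_TH] = body.segments["thigh_l"].com
    pb[K.PB_L_SH] = body.segments["shank_l"].length
    pb[K.PB_C_SH] = body.segments["shank_l"].com
    pb[K.PB_FCX], pb[K.PB_FCY] = body.foot_com
    pb[K.PB_HEELX], pb[K.PB_HEELY] = body.heel
    pb[K.PB_TOEX], pb[K.PB_TOEY] = body.toe
    pb[K.PB_G] = body.gravity
    pb[K.PB_KH] = body.contact["k_h"]
    pb[K.PB_CH] = body.contact["c_h"]
    pb[K.PB_KV] = body.contact["k_v"]
    pb[K.PB_CV] = body.contact["c_v"]
    for j, name in enumerate(JOINT_NAMES):
        pb[K.PB_VISC + j] = body.joint_viscosity[name]
        pb[K.PB_LIM + 2 * j] = body.joint_limits[name][0]
        pb[K.PB_LIM + 2 * j + 1] = body.joint_limits[name][1]
    pb[K.PB_LOCK_K] = body.lock_stiffness
    pb[K.PB_LOCK_C] = body.lock_damping
    if body.prosthesis is None:
        pb[K.PB_PROS_SIDE] = -1.0
        pb[K.PB_PROS_K] = 0.0
    else:
        pb[K.PB_PROS_SIDE] = 0.0 if body.prosthesis.side == "left" else 1.0
        pb[K.PB_PROS_K] = body.prosthesis.ankle_stiffness
    pb[K.PB_MTOT] = body.total_mass
    pb[K.PB_HATCOM_Y0] = body.standing_hat_com_height
    pb[K.PB_FALL_FRAC] = body.fall_fraction
    pb[K.PB_HIP_MIN] = body.hip_min_height
    pb[K.PB_PITCH_REF] = body.pitch_ref
    return pb


def pack_chains(body: BodyModel):
    """COM and contact-point kinematic chains for the dynamics kernel.

    Each point is hip + sum_k R(q[ci_k]) off_k; ci entries are q-indices
    (2..8) padded with -1.
    """
    L_th = body.segments["thigh_l"].length
    c_th = body.segments["thigh_l"].com
    L_sh = body.segments["shank_l"].length
    c_sh = body.segments["shank_l"].com
    c_hat = body.segments["hat"].com
    fcx, fcy = body.foot_com

    seg_ci = -np.ones((7, 3), np.int64)
    seg_off = np.zeros((7, 3, 2))
    # hat
    seg_ci[0, 0] = 2; seg_off[0, 0] = (0.0, c_hat)
    for side in range(2):
        th, sh, ft = 3 + 3 * side, 4 + 3 * side, 5 + 3 * side
        i_th, i_sh, i_ft = 1 + 3 * side, 2 + 3 * side, 3 + 3 * side
        seg_ci[i_th, 0] = th; seg_off[i_th, 0] = (0.0, -c_th)
        seg_ci[i_sh, 0] = th; seg_off[i_sh, 0] = (0.0, -L_th)
        seg_ci[i_sh, 1] = sh; seg_off[i_sh, 1] = (0.0, -c_sh)
        seg_ci[i_ft, 0] = th; seg_off[i_ft, 0] = (0.0, -L_th)
        seg_ci[i_ft, 1] = sh; seg_off[i_ft, 1] = (0.0, -L_sh)
        seg_ci[i_ft, 2] = ft; seg_off[i_ft, 2] = (fcx, fcy)

    cp_ci = -np.ones((4, 3), np.int64)
    cp_off = np.zeros((4, 3, 2))
    for side in range(2):
        th, sh, ft = 3 + 3 * side, 4 + 3 * side, 5 + 3 * side
        for p, off in enumerate((body.heel, body.toe)):
            i = 2 * side + p
            cp_ci[i, 0] = th; cp_off[i, 0] = (0.0, -L_th)
            cp_ci[i, 1] = sh; cp_off[i, 1] = (0.0, -L_sh)
            cp_ci[i, 2] = ft; cp_off[i, 2] = off
    return seg_ci, seg_off, cp_ci, cp_off


# ---------------------------------------------------------------------------
# module-surface operations

@dataclass
class MechState:
    """Mechanical state: generalized coordinates, velocities and time."""

    q: np.ndarray
    qd: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.q = np.asarray(self.q, float)
        self.qd = np.asarray(self.qd, float)
        if self.q.shape != (9,) or self.qd.shape != (9,):
            raise ValueError("q and qd must have shape (9,)")
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.qd))):
            raise ValueError("state must be finite")

    def joint_angles(self) -> np.ndarray:
        th = np.empty(6)
        thd = np.empty(6)
        K.joint_angles_kernel(self.q, self.qd, th, thd)
        return th

    def joint_velocities(self) -> np.ndarray:
        th = np.empty(6)
        thd = np.empty(6)
        K.joint_angles_kernel(self.q, self.qd, th, thd)
        return thd


def contact_force(position, velocity, coeffs, anchor_x=None) -> np.ndarray:
    """Ground contact force at one point.

    position, velocity: world (x, y) / (vx, vy) of the contact point;
    coeffs: dict with k_h, c_h, k_v, c_v; anchor_x: horizontal touchdown
    anchor (None = horizontal spring inactive).  Above ground the force is
    zero; while penetrating the vertical force k_v*depth + c_v*(-vy) is
    floored at 0 and the horizontal spring-damper acts about the anchor.
    """
    px, py = float(position[0]), float(position[1])
    vx, vy = float(velocity[0]), float(velocity[1])
    active = anchor_x is not None
    fx, fy = K.contact_force_kernel(
        py, vy, px, vx, anchor_x if active else 0.0, active,
        coeffs["k_h"], coeffs["c_h"], coeffs["k_v"], coeffs["c_v"])
    return np.array([fx, fy])


def joint_passive_moment(joint: str, side: str, theta: float, theta_dot: float,
                         body: BodyModel) -> float:
    """Passive joint moment: viscous damping, range-of-motion lock beyond the
    limits, and (prosthetic ankle) the 400 Nm/rad passive spring."""
    if joint not in JOINT_NAMES:
        raise ValueError(f"unknown joint {joint!r}")
    if side not in SIDES:
        raise ValueError(f"unknown side {side!r}")
    th = np.zeros(6)
    thd = np.zeros(6)
    i = 3 * SIDES.index(side) + JOINT_NAMES.index(joint)
    th[i] = theta
    thd[i] = theta_dot
    tau6 = np.zeros(6)
    K.joint_passive_kernel(th, thd, pack_body(body), tau6)
    return float(tau6[i])


def contact_point_positions(state: MechState, body: BodyModel):
    """World positions/velocities of [heel_L, toe_L, heel_R, toe_R]."""
    pos = np.empty((4, 2))
    vel = np.empty((4, 2))
    K.contact_points_kernel(state.q, state.qd, pack_body(body), pos, vel)
    return pos, vel


def equations_of_motion(state: MechState, joint_torques, contact_forces,
                        body: BodyModel) -> np.ndarray:
    """Generalized accelerations under gravity, relative joint torques
    (hip_L, knee_L, ankle_L, hip_R, knee_R, ankle_R) and world contact
    forces (4, 2) applied at heel/toe points."""
    tau6 = np.asarray(joint_torques, float)
    fc = np.asarray(contact_forces, float).reshape(4, 2)
    if tau6.shape != (6,):
        raise ValueError("joint_torques must have 6 entries")
    pb = pack_body(body)
    seg_ci, seg_off, cp_ci, cp_off = pack_chains(body)
    M = np.empty((9, 9))
    Q = np.empty(9)
    qdd = np.empty(9)
    ok = K.eom_kernel(state.q, state.qd, pb, seg_ci, seg_off, cp_ci, cp_off,
                      tau6, fc, M, Q, qdd)
    if not ok:
        raise ValueError("singular mass matrix: invalid inertia configuration")
    return qdd


def integrate_step(state: np.ndarray, deriv, dt: float) -> np.ndarray:
    """One classical RK4 step of an arbitrary first-order system.

    ``deriv(s) -> ds``.  Raises on non-finite derivatives (numerical
    blow-up; a trial hitting this is treated as a fall by the trial runner).
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    s = np.asarray(state, float)
    if dt == 0:
        return s.copy()
    k1 = np.asarray(deriv(s), float)
    k2 = np.asarray(deriv(s + 0.5 * dt * k1), float)
    k3 = np.asarray(deriv(s + 0.5 * dt * k2), float)
    k4 = np.asarray(deriv(s + dt * k3), float)
    if not np.all(np.isfinite(k4)):
        raise FloatingPointError("non-finite derivative")
    return s + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


# ---------------------------------------------------------------------------
# YAML configuration I/O

def body_to_dict(body: BodyModel) -> dict:
    d = {
        "segments": {n: asdict(s) for n, s in body.segments.items()},
        "joint_viscosity": dict(body.joint_viscosity),
        "joint_limits": {k: list(v) for k, v in body.joint_limits.items()},
        "contact": dict(body.contact),
        "foot_com": list(body.foot_com),
        "heel": list(body.heel),
        "toe": list(body.toe),
        "lock_stiffness": body.lock_stiffness,
        "lock_damping": body.lock_damping,
        "gravity": body.gravity,
        "pitch_ref": body.pitch_ref,
        "fall_fraction": body.fall_fraction,
        "hip_min_height": body.hip_min_height,
        "prosthesis": None if body.prosthesis is None else asdict(body.prosthesis),
    }
    return d


def body_from_dict(d: dict) -> BodyModel:
    pros = d.get("prosthesis")
    return BodyModel(
        segments={n: Segment(**s) for n, s in d["segments"].items()},
        joint_viscosity=dict(d["joint_viscosity"]),
        joint_limits={k: tuple(v) for k, v in d["joint_limits"].items()},
        contact=dict(d["contact"]),
        foot_com=tuple(d["foot_com"]),
        heel=tuple(d["heel"]),
        toe=tuple(d["toe"]),
        lock_stiffness=d.get("lock_stiffness", 1000.0),
        lock_damping=d.get("lock_damping", 50.0),
        prosthesis=None if pros is None else Prosthesis(**pros),
        gravity=d.get("gravity", GRAVITY),
        pitch_ref=d.get("pitch_ref", -0.10),
        fall_fraction=d.get("fall_fraction", 0.60),
        hip_min_height=d.get("hip_min_height", 0.45),
    )


def save_body(body: BodyModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(body_to_dict(body), fh, sort_keys=False)


def load_body(path) -> BodyModel:
    with open(path) as fh:
        return body_from_dict(yaml.safe_load(fh))
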