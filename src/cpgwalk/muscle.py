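"""Hill-type muscle mechanics for the 9 muscles of each leg.

Each muscle is a contractile element (CE) scaled by activation and by
force-length and force-velocity gains, in parallel with a passive damping
element (PD) and a passive elastic element (PE, engaged in stretch only):

    F = F_ce_max * k(xi) * h(eta) * alpha + c_pd * Ldot + F_pe(L)
    k(xi)  = 0.32 + 0.71 exp(-1.112 (xi - 1)) sin(3.722 (xi - 0.656))
    h(eta) = 1 + tanh(3 eta)
    F_pe   = k_pe (exp(15 (L - L_opt)) - 1), floored at 0 for L < L_opt

with xi = L / L_opt and eta = Ldot / V_max.  By default eta > 0 on
lengthening, which makes h the usual eccentric-enhancement / concentric-
deficit curve; the sign convention is exposed as ``fv_sign`` because the
sign of "contraction velocity" is a modelling convention.

Muscle paths use constant moment arms calibrated so that L = L_opt in the
neutral standing posture: L = L_opt + sum_j rho_j * theta_j over the
spanned joints, with hip flexion, knee flexion and ankle dorsiflexion
positive.  rho_j > 0 means the muscle lengthens as theta_j grows, and a
tension F produces the joint torque -rho_j * F.

Default parameters are reconstructed from the planar walking-model
literature and editable via the CSV muscle table.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .body import BodyModel, removed_muscles

MUSCLE_NAMES = ("GM", "IL", "BFL", "RF", "BFS", "VA", "GC", "SO", "TA")
BIARTICULAR = {"BFL", "RF", "GC"}
SIDES = ("left", "right")


@dataclass
class MuscleSpec:
    """Constant parameters of one muscle.

    moment_arms maps joint name -> signed lengthening coefficient rho
    (m/rad); see the module docstring for the sign convention.
    """

    name: str
    side: str
    f_ce_max: float      # maximum CE tension (N)
    l_opt: float         # optimum length (m)
    v_max: float         # maximum contraction velocity (m/s)
    c_pd: float          # PD viscosity (Ns/m)
    k_pe: float          # PE coefficient (N)
    moment_arms: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in MUSCLE_NAMES:
            raise ValueError(f"unknown muscle {self.name!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")
        if self.f_ce_max <= 0 or self.l_opt <= 0 or self.v_max <= 0:
            raise ValueError("f_ce_max, l_opt and v_max must be positive")
        want_two = self.name in BIARTICULAR
        if self.moment_arms and (len(self.moment_arms) == 2) != want_two:
            raise ValueError(f"{self.name} must span "
                             f"{'two joints' if want_two else 'one joint'}")


@dataclass
class MuscleState:
    """Instantaneous muscle state."""

    L: float
    Ld: float
    alpha: float
    F: float = 0.0

    def normalized(self, spec: MuscleSpec) -> tuple[float, float]:
        return self.L / spec.l_opt, self.Ld / spec.v_max


# (f_ce_max, l_opt, v_max, c_pd, k_pe, {joint: rho})  — reconstructed defaults
_DEFAULTS = {
    "GM": (1200.0, 0.14, 0.56, 40.0, 10.0, {"hip": 0.062}),
    "IL": (1200.0, 0.13, 0.52, 40.0, 10.0, {"hip": -0.050}),
    "BFL": (1000.0, 0.35, 1.40, 40.0, 10.0, {"hip": 0.054, "knee": -0.035}),
    "RF": (1200.0, 0.34, 1.36, 40.0, 10.0, {"hip": -0.049, "knee": 0.042}),
    "BFS": (800.0, 0.12, 0.48, 30.0, 8.0, {"knee": -0.035}),
    "VA": (2500.0, 0.10, 0.40, 60.0, 15.0, {"knee": 0.042}),
    "GC": (1500.0, 0.40, 1.60, 45.0, 12.0, {"knee": -0.020, "ankle": 0.050}),
    "SO": (3000.0, 0.06, 0.24, 70.0, 20.0, {"ankle": 0.050}),
    "TA": (1000.0, 0.08, 0.32, 35.0, 8.0, {"ankle": -0.037}),
}


def default_muscles(body: BodyModel | None = None) -> list[MuscleSpec]:
    """The 18 default muscles, excluding any removed by a prosthesis."""
    removed = removed_muscles(body) if body is not None else set()
    out = []
    for side in SIDES:
        for name in MUSCLE_NAMES:
            if (name, side) in removed:
                continue
            f, lo, vm, cpd, kpe, arms = _DEFAULTS[name]
            out.append(MuscleSpec(name, side, f, lo, vm, cpd, kpe, dict(arms)))
    return out


def force_length(xi: float) -> float:
    """Active force-length gain k(xi), clamped at 0."""
    if xi <= 0:
        raise ValueError("normalized length must be positive")
    return K.force_length(float(xi))


def force_velocity(eta: float) -> float:
    """Force-velocity gain h(eta) = 1 + tanh(3 eta)."""
    return K.force_velocity(float(eta))


def muscle_tension(spec: MuscleSpec, st: MuscleState, fv_sign: float = 1.0) -> float:
    """Total tension of one muscle (N); may be negative through the PD term."""
    if not 0.0 <= st.alpha <= 1.0:
        raise ValueError("activation must lie in [0, 1]")
    F, _ = K.muscle_tension_kernel(
        spec.f_ce_max, spec.l_opt, spec.v_max, spec.c_pd, spec.k_pe,
        st.L, st.Ld, st.alpha, fv_sign)
    return float(F)


def muscle_kinematics(joint_angles: dict[str, float],
                      joint_velocities: dict[str, float],
                      spec: MuscleSpec,
                      tension: float = 0.0):
    """Muscle length, velocity and joint torque contributions.

    joint_angles/velocities are for the muscle's own leg, keyed by joint
    name.  Returns (L, Ld, {joint: torque}).
    """
    L = spec.l_opt
    Ld = 0.0
    torques = {}
    for joint, rho in spec.moment_arms.items():
        if joint not in joint_angles:
            raise KeyError(f"{spec.name} spans {joint!r}, absent from skeleton")
        L += rho * joint_angles[joint]
        Ld += rho * joint_velocities.get(joint, 0.0)
        torques[joint] = -rho * tension
    return L, Ld, torques


def pack_muscles(specs: list[MuscleSpec] | None = None,
                 body: BodyModel | None = None) -> np.ndarray:
    """(18, 10) parameter matrix for the kernels.

    Rows follow the canonical order (left GM..TA then right GM..TA);
    muscles absent from ``specs`` or removed by the body's prosthesis get
    removed=1 and contribute nothing.
    """
    if specs is None:
        specs = default_muscles()
    removed = removed_muscles(body) if body is not None else set()
    by_key = {(s.name, s.side): s for s in specs}
    pm = np.zeros((18, 10))
    for si, side in enumerate(SIDES):
        for ti, name in enumerate(MUSCLE_NAMES):
            m = ti + 9 * si
            pm[m, 8] = si
            spec = by_key.get((name, side))
            if spec is None or (name, side) in removed:
                pm[m, 9] = 1.0
                # keep positive placeholders so the kernel never divides by 0
                f, lo, vm, cpd, kpe, _ = _DEFAULTS[name]
                pm[m, 0:5] = (f, lo, vm, cpd, kpe)
                continue
            pm[m, 0] = spec.f_ce_max
            pm[m, 1] = spec.l_opt
            pm[m, 2] = spec.v_max
            pm[m, 3] = spec.c_pd
            pm[m, 4] = spec.k_pe
            pm[m, 5] = spec.moment_arms.get("hip", 0.0)
            pm[m, 6] = spec.moment_arms.get("knee", 0.0)
            pm[m, 7] = spec.moment_arms.get("ankle", 0.0)
    return pm


# ---------------------------------------------------------------------------
# CSV muscle table I/O

_CSV_FIELDS = ("name", "side", "f_ce_max", "l_opt", "v_max", "c_pd", "k_pe",
               "rho_hip", "rho_knee", "rho_ankle")


def save_muscles(specs: list[MuscleSpec], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        w.writeheader()
        for s in specs:
            w.writerow({
                "name": s.name, "side": s.side,
                "f_ce_max": s.f_ce_max, "l_opt": s.l_opt, "v_max": s.v_max,
                "c_pd": s.c_pd, "k_pe": s.k_pe,
                "rho_hip": s.moment_arms.get("hip", ""),
                "rho_knee": s.moment_arms.get("knee", ""),
                "rho_ankle": s.moment_arms.get("ankle", ""),
            })


def load_muscles(path) -> list[MuscleSpec]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            arms = {}
            for joint in ("hip", "knee", "ankle"):
                v = row.get(f"rho_{joint}", "")
                if v not in ("", None):
                    arms[joint] = float(v)
            out.append(MuscleSpec(
                row["name"], row["side"], float(row["f_ce_max"]),
                float(row["l_opt"]), float(row["v_max"]), float(row["c_pd"]),
                float(row["k_pe"]), arms))
    return out
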