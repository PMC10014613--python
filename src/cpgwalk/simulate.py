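"""Forward-dynamics walking trials.

A trial integrates the monolithic 42-dimensional state (9 generalized
coordinates + velocities, 12 CPG membrane states, 12 adaptation states)
with classical RK4 at a 0.1 ms step, from a standing posture with a small
forward push.  Contact touchdown anchors are event states updated once per
full step.  A trial ends at the requested duration or at a fall (HAT COM
below 60 % of its standing height, hip too low, or numerical blow-up).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as K
from .body import BodyModel, default_body, pack_body, pack_chains
from .controller import (ControllerWeights, FEED_SLOT_UNIT, FEED_SLOT_SENSOR,
                         POS_ROW_MUSCLE, POS_ROW_SENSOR, N_UNITS,
                         build_cpg_matrix, motoneuron_map)
from .muscle import MuscleSpec, pack_muscles, MUSCLE_NAMES

DT_DEFAULT = 1e-4        # integration step (s)
LOG_DT_DEFAULT = 1e-3    # logging interval (s)

# energetics coefficients (documented in docs/methods.md)
C_ACT_DEFAULT = 0.15
C_SHORT_DEFAULT = 0.25
FV_SIGN_DEFAULT = 1.0    # eta > 0 on lengthening


@dataclass
class TrialResult:
    """Logged time series and summary scalars of one trial."""

    t: np.ndarray                 # (n,)
    q: np.ndarray                 # (n, 9)
    qd: np.ndarray                # (n, 9)
    grf: np.ndarray               # (n, 2) vertical GRF left, right
    foot_x: np.ndarray            # (n, 4) heel_l, toe_l, heel_r, toe_r x
    alpha: np.ndarray             # (n, 18) muscle activations
    edot: np.ndarray              # (n, 18) muscle metabolic rates (W)
    distance: float               # hip forward displacement (m)
    fell: bool
    t_end: float                  # walked duration (s)
    energy: float                 # integral of total metabolic rate (J)
    body_mass: float

    @property
    def speed(self) -> float:
        """Mean forward speed D / T (m/s)."""
        return self.distance / self.t_end if self.t_end > 0 else 0.0

    @property
    def cost_of_transport(self) -> float:
        """Gross metabolic cost over the whole trial,
        E / (T M V) = E / (M D) (J/kg/m)."""
        if self.distance <= 0:
            return np.inf
        return self.energy / (self.body_mass * self.distance)

    def to_frame(self) -> pd.DataFrame:
        cols = {"t": self.t}
        for i in range(9):
            cols[f"q{i}"] = self.q[:, i]
        for i in range(9):
            cols[f"qd{i}"] = self.qd[:, i]
        cols["grf_l"] = self.grf[:, 0]
        cols["grf_r"] = self.grf[:, 1]
        for i, name in enumerate(("heel_lx", "toe_lx", "heel_rx", "toe_rx")):
            cols[name] = self.foot_x[:, i]
        for side in ("l", "r"):
            for j, name in enumerate(MUSCLE_NAMES):
                m = j + (9 if side == "r" else 0)
                cols[f"alpha_{name}_{side}"] = self.alpha[:, m]
                cols[f"edot_{name}_{side}"] = self.edot[:, m]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.attrs = {}
        with open(path, "w") as fh:
            fh.write(f"# distance={float(self.distance)!r} "
                     f"fell={int(self.fell)} t_end={float(self.t_end)!r} "
                     f"energy={float(self.energy)!r} "
                     f"body_mass={float(self.body_mass)!r}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialResult":
        with open(path) as fh:
            header = fh.readline()
            df = pd.read_csv(fh)
        meta = {}
        for tok in header.lstrip("#").split():
            k, v = tok.split("=")
            meta[k] = float(v)
        n = len(df)
        alpha = np.empty((n, 18))
        edot = np.empty((n, 18))
        for side_i, side in enumerate(("l", "r")):
            for j, name in enumerate(MUSCLE_NAMES):
                alpha[:, j + 9 * side_i] = df[f"alpha_{name}_{side}"]
                edot[:, j + 9 * side_i] = df[f"edot_{name}_{side}"]
        return cls(
            t=df["t"].to_numpy(),
            q=df[[f"q{i}" for i in range(9)]].to_numpy(),
            qd=df[[f"qd{i}" for i in range(9)]].to_numpy(),
            grf=df[["grf_l", "grf_r"]].to_numpy(),
            foot_x=df[["heel_lx", "toe_lx", "heel_rx", "toe_rx"]].to_numpy(),
            alpha=alpha, edot=edot,
            distance=meta["distance"], fell=bool(meta["fell"]),
            t_end=meta["t_end"], energy=meta["energy"],
            body_mass=meta["body_mass"])


def standing_state(body: BodyModel, lean: float = -0.10, split: float = 0.15,
                   push: float = 0.35) -> np.ndarray:
    """Initial 42-state: standing with a slight forward trunk lean, a small
    fore-aft leg split (left leg forward) and a forward push (m/s).

    The hip height is chosen so the lowest contact point just touches the
    ground; CPG states get a small fixed left/right-antisymmetric kick so
    the oscillators start in antiphase.
    """
    s = np.zeros(42)
    s[2] = lean
    s[3] = split          # left leg forward
    s[4] = split
    s[6] = -split         # right leg back
    s[7] = -split
    # drop the hip so that min foot point height = 0
    s[1] = 1.5
    pos = np.empty((4, 2))
    vel = np.empty((4, 2))
    K.contact_points_kernel(s[0:9], s[9:18], pack_body(body), pos, vel)
    s[1] = 1.5 - pos[:, 1].min() - 1e-4
    s[9] = push
    # antisymmetric CPG kick: left flexors / right extensors
    for unit in (0, 2, 4):
        s[18 + unit] = 0.1
    for unit in (1, 3, 5):
        s[18 + 6 + unit] = 0.1
    return s


def run_trial(body: BodyModel | None = None,
              muscles: list[MuscleSpec] | None = None,
              weights: ControllerWeights | None = None,
              duration: float = 10.0,
              dt: float = DT_DEFAULT,
              log_dt: float = LOG_DT_DEFAULT,
              initial_state: np.ndarray | None = None,
              fv_sign: float = FV_SIGN_DEFAULT,
              c_act: float = C_ACT_DEFAULT,
              c_short: float = C_SHORT_DEFAULT) -> TrialResult:
    """Run one forward-dynamics trial; deterministic for identical inputs."""
    if body is None:
        body = default_body()
    if weights is None:
        weights = ControllerWeights()
    if dt <= 0:
        raise ValueError("dt must be positive")
    pb = pack_body(body)
    seg_ci, seg_off, cp_ci, cp_off = pack_chains(body)
    pm = pack_muscles(muscles, body)
    s0 = standing_state(body) if initial_state is None else np.asarray(
        initial_state, float).copy()

    log_dec = max(1, int(round(log_dt / dt)))
    nmax = int(round(duration / dt)) // log_dec + 2
    log_t = np.zeros(nmax)
    log_q = np.zeros((nmax, 9))
    log_qd = np.zeros((nmax, 9))
    log_grf = np.zeros((nmax, 2))
    log_footx = np.zeros((nmax, 4))
    log_alpha = np.zeros((nmax, 18))
    log_edot = np.zeros((nmax, 18))

    tau = np.full(N_UNITS, weights.tau)
    taup = np.full(N_UNITS, weights.taup)
    W = build_cpg_matrix(weights.w_cpg)
    walpha = motoneuron_map()

    nlog, fell, t_end, distance, e_int = K.run_trial_kernel(
        s0, pb, seg_ci, seg_off, cp_ci, cp_off,
        pm, fv_sign, c_act, c_short,
        tau, taup, weights.beta, W, weights.u0, weights.w_feed,
        FEED_SLOT_UNIT, FEED_SLOT_SENSOR,
        weights.w_pos, POS_ROW_MUSCLE, POS_ROW_SENSOR, walpha,
        duration, dt, log_dec,
        log_t, log_q, log_qd, log_grf, log_footx, log_alpha, log_edot)

    return TrialResult(
        t=log_t[:nlog].copy(), q=log_q[:nlog].copy(), qd=log_qd[:nlog].copy(),
        grf=log_grf[:nlog].copy(), foot_x=log_footx[:nlog].copy(),
        alpha=log_alpha[:nlog].copy(), edot=log_edot[:nlog].copy(),
        distance=float(distance), fell=bool(fell), t_end=float(t_end),
        energy=float(e_int), body_mass=body.total_mass)
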