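"""Spinal controller: Matsuoka CPG, sensory feedback, motoneurons, posture.

The rhythm generator is a 12-unit Matsuoka network — a flexor/extensor
oscillator for the hip, knee and ankle of each leg:

    tau_i  du_i/dt = -u_i + sum_j W_ij y_j - beta v_i + u0 + Feed_i
    tau'_i dv_i/dt = -v_i + y_i,        y_i = max(0, u_i)

where u is the membrane-like internal state, v the self-inhibition
(adaptation) state, u0 a tonic external drive and Feed_i linear sensory
feedback.  Feedback draws on segment-angle deviations from vertical and on
contact-gated vertical GRFs (normalized by body weight) through a
16-slot-per-leg wiring table with searchable signed coefficients w_feed
(32 total; the symmetric-control scenario ties the two legs together).

Motoneuron output per muscle is a saturating sigmoid of the CPG drive plus
a posture-control correction P_m:

    alpha_m = clamp(2 / (1 + exp(-0.25 (sum_i walpha_mi y_i + P_m))) - 1, 0, 1)

P_m consists of PD terms on HAT pitch and stance-leg joint angles, gated by
ipsilateral foot contact and mixed by the 23-coefficient w_pos table.  The
18x12 motoneuron map walpha is fixed structure (each muscle is driven by
the flexor or extensor unit of its joint's oscillator, biarticular muscles
by both joints); it is not part of the searched parameter set.

The CPG connection matrix is built from 11 shared connection strengths
(within-pair mutual inhibition per joint, contralateral hip-hip coupling,
and ipsilateral hip->knee->ankle couplings), so the full searchable set is
u0 + 32 w_feed (16 per leg) + 11 w_cpg + 23 w_pos.

The wiring tables and default time constants are reconstructed defaults
(documented in docs/methods.md) and are serialized with the weight file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from . import _kernels as K

N_UNITS = 12
N_MUSCLES = 18
N_FEED = 16          # per-leg feedback slots
N_CPG_PARAMS = 11
N_POS = 23

UNIT_NAMES = ("hipF", "hipE", "kneeF", "kneeE", "ankF", "ankE")

# feedback wiring: slot -> (target local unit, sensor kind)
# sensor kinds: 0 HAT pitch, 1 ipsi thigh, 2 contra thigh, 3 ipsi shank,
# 4 ipsi foot, 5 ipsi GRF, 6 contra GRF
FEED_TABLE = (
    (0, 0), (1, 0),          # HAT pitch -> hip F/E
    (0, 1), (1, 1),          # ipsi thigh angle -> hip F/E
    (0, 2), (1, 2),          # contra thigh angle -> hip F/E
    (2, 3), (3, 3),          # ipsi shank angle -> knee F/E
    (4, 4), (5, 4),          # ipsi foot angle -> ankle F/E
    (1, 5), (3, 5), (5, 5),  # ipsi GRF -> hip/knee/ankle E
    (0, 6), (2, 6), (4, 6),  # contra GRF -> hip/knee/ankle F
)

# posture wiring: row -> (muscle type, sensor kind)
# sensor kinds: 0/1 HAT pitch err/rate, 2/3 hip, 4/5 knee, 6/7 ankle
# angle/velocity, 8 normalized GRF
POS_TABLE = (
    (K.M_GM, 0), (K.M_GM, 1), (K.M_BFL, 0), (K.M_BFL, 1),
    (K.M_IL, 0), (K.M_IL, 1), (K.M_RF, 0), (K.M_RF, 1),
    (K.M_GM, 2), (K.M_GM, 3), (K.M_IL, 2), (K.M_IL, 3),
    (K.M_VA, 4), (K.M_VA, 5), (K.M_BFS, 4), (K.M_BFS, 5),
    (K.M_SO, 6), (K.M_SO, 7), (K.M_TA, 6), (K.M_TA, 7),
    (K.M_VA, 8), (K.M_SO, 8), (K.M_GM, 8),
)

FEED_SLOT_UNIT = np.array([u for u, _ in FEED_TABLE], np.int64)
FEED_SLOT_SENSOR = np.array([s for _, s in FEED_TABLE], np.int64)
POS_ROW_MUSCLE = np.array([m for m, _ in POS_TABLE], np.int64)
POS_ROW_SENSOR = np.array([s for _, s in POS_TABLE], np.int64)

assert len(FEED_TABLE) == N_FEED
assert len(POS_TABLE) == N_POS


def motoneuron_map() -> np.ndarray:
    """Fixed 18x12 map from CPG outputs to muscle drives."""
    w = np.zeros((N_MUSCLES, N_UNITS))
    # (muscle type, local unit, gain)
    wiring = (
        (K.M_GM, 1, 1.0),
        (K.M_IL, 0, 1.0),
        (K.M_BFL, 1, 0.5), (K.M_BFL, 2, 0.5),
        (K.M_RF, 0, 0.5), (K.M_RF, 3, 0.5),
        (K.M_BFS, 2, 1.0),
        (K.M_VA, 3, 1.0),
        (K.M_GC, 5, 0.5), (K.M_GC, 2, 0.25),
        (K.M_SO, 5, 1.0),
        (K.M_TA, 4, 1.0),
    )
    for side in range(2):
        for mtype, unit, gain in wiring:
            w[mtype + 9 * side, unit + 6 * side] = gain
    return w


def build_cpg_matrix(params) -> np.ndarray:
    """12x12 connection matrix from the 11 shared connection strengths.

    Order: [hip pair, knee pair, ankle pair mutual coupling;
    contralateral hipF-hipF, hipE-hipE; ipsi hipF->kneeF, hipE->kneeE,
    kneeF->ankF, kneeE->ankE, hipF->ankF, hipE->ankE].
    """
    p = np.asarray(params, float)
    if p.shape != (N_CPG_PARAMS,):
        raise ValueError(f"expected {N_CPG_PARAMS} CPG connection parameters")
    W = np.zeros((N_UNITS, N_UNITS))
    for side in range(2):
        o = 6 * side
        c = 6 * (1 - side)
        W[o + 0, o + 1] = W[o + 1, o + 0] = p[0]   # hip F<->E
        W[o + 2, o + 3] = W[o + 3, o + 2] = p[1]   # knee F<->E
        W[o + 4, o + 5] = W[o + 5, o + 4] = p[2]   # ankle F<->E
        W[o + 0, c + 0] = p[3]                     # contralateral hipF
        W[o + 1, c + 1] = p[4]                     # contralateral hipE
        W[o + 2, o + 0] = p[5]                     # hipF -> kneeF
        W[o + 3, o + 1] = p[6]                     # hipE -> kneeE
        W[o + 4, o + 2] = p[7]                     # kneeF -> ankF
        W[o + 5, o + 3] = p[8]                     # kneeE -> ankE
        W[o + 4, o + 0] = p[9]                     # hipF -> ankF
        W[o + 5, o + 1] = p[10]                    # hipE -> ankE
    return W


DEFAULT_CPG_PARAMS = np.array(
    [-2.0, -2.0, -2.0, -1.0, -1.0, 0.5, 0.5, 0.5, 0.5, 0.0, 0.0])
DEFAULT_TAU = 0.05
DEFAULT_TAUP = 0.60
DEFAULT_BETA = 2.5


@dataclass
class CPGNetwork:
    """State and parameters of the 12-unit Matsuoka network."""

    u: np.ndarray = field(default_factory=lambda: np.zeros(N_UNITS))
    v: np.ndarray = field(default_factory=lambda: np.zeros(N_UNITS))
    tau: np.ndarray = field(default_factory=lambda: np.full(N_UNITS, DEFAULT_TAU))
    taup: np.ndarray = field(default_factory=lambda: np.full(N_UNITS, DEFAULT_TAUP))
    beta: float = DEFAULT_BETA
    W: np.ndarray = field(
        default_factory=lambda: build_cpg_matrix(DEFAULT_CPG_PARAMS))
    u0: float = 1.0

    def __post_init__(self):
        for name in ("u", "v", "tau", "taup"):
            setattr(self, name, np.asarray(getattr(self, name), float))
        self.W = np.asarray(self.W, float)
        if np.any(self.tau <= 0) or np.any(self.taup <= 0):
            raise ValueError("time constants must be positive")

    @property
    def y(self) -> np.ndarray:
        return np.maximum(0.0, self.u)


@dataclass
class FeedbackWeights:
    """Searchable feedback / posture coefficient blocks."""

    w_feed: np.ndarray = field(default_factory=lambda: np.zeros((2, N_FEED)))
    w_pos: np.ndarray = field(default_factory=lambda: np.zeros(N_POS))
    w_alpha: np.ndarray = field(default_factory=motoneuron_map)

    def __post_init__(self):
        self.w_feed = np.asarray(self.w_feed, float).reshape(2, N_FEED)
        self.w_pos = np.asarray(self.w_pos, float)
        self.w_alpha = np.asarray(self.w_alpha, float)

    @property
    def symmetric(self) -> bool:
        return bool(np.array_equal(self.w_feed[0], self.w_feed[1]))


@dataclass
class SensorSnapshot:
    """Proprioceptive/load snapshot consumed by the controller.

    Segment angles follow the q ordering (hat, thigh_l, shank_l, foot_l,
    thigh_r, shank_r, foot_r); GRFs are vertical, per limb, in N.
    """

    seg_angles: np.ndarray
    seg_velocities: np.ndarray
    joint_angles: np.ndarray          # 6: hip/knee/ankle L then R
    joint_velocities: np.ndarray
    grf: np.ndarray                   # (2,) left, right
    body_weight: float
    contact: np.ndarray | None = None  # (2,) booleans; default grf > 0

    def __post_init__(self):
        self.seg_angles = np.asarray(self.seg_angles, float)
        self.seg_velocities = np.asarray(self.seg_velocities, float)
        self.joint_angles = np.asarray(self.joint_angles, float)
        self.joint_velocities = np.asarray(self.joint_velocities, float)
        self.grf = np.asarray(self.grf, float)
        if np.any(self.grf < 0):
            raise ValueError("vertical GRF must be non-negative")
        if self.contact is None:
            self.contact = self.grf > 0.0
        self.contact = np.asarray(self.contact, bool)

    def _q_like(self) -> np.ndarray:
        q = np.zeros(9)
        q[2:9] = self.seg_angles
        return q


def cpg_derivatives(net: CPGNetwork, feed) -> tuple[np.ndarray, np.ndarray]:
    """(du/dt, dv/dt) of the Matsuoka network for a 12-long feedback vector."""
    feed = np.asarray(feed, float)
    if feed.shape != (N_UNITS,):
        raise ValueError("feed must have 12 entries (zero-padded)")
    if not (np.all(np.isfinite(net.u)) and np.all(np.isfinite(feed))):
        raise ValueError("non-finite CPG inputs")
    du = np.empty(N_UNITS)
    dv = np.empty(N_UNITS)
    K.cpg_deriv_kernel(net.u, net.v, feed, net.tau, net.taup, net.beta,
                       net.W, net.u0, du, dv)
    return du, dv


def compute_feedback(sensors: SensorSnapshot, w: FeedbackWeights) -> np.ndarray:
    """Feedback vector Feed_i (12,) through the per-leg wiring table."""
    bw = sensors.body_weight
    grfn = sensors.grf / bw
    grfn = np.where(sensors.contact, grfn, 0.0)
    feed = np.empty(N_UNITS)
    K.feedback_kernel(sensors._q_like(), grfn[0], grfn[1], w.w_feed,
                      FEED_SLOT_UNIT, FEED_SLOT_SENSOR, feed)
    return feed


def posture_control(sensors: SensorSnapshot, w_pos, pitch_ref: float = -0.10
                    ) -> np.ndarray:
    """Posture correction P_m (18,), gated by ipsilateral foot contact."""
    w_pos = np.asarray(w_pos, float)
    grfn = sensors.grf / sensors.body_weight
    q = sensors._q_like()
    qd = np.zeros(9)
    qd[2:9] = sensors.seg_velocities
    P = np.empty(N_MUSCLES)
    K.posture_kernel(q, qd, sensors.joint_angles, sensors.joint_velocities,
                     grfn[0], grfn[1], bool(sensors.contact[0]),
                     bool(sensors.contact[1]), pitch_ref, w_pos,
                     POS_ROW_MUSCLE, POS_ROW_SENSOR, P)
    return P


def motoneuron_output(y, P, w_alpha=None, removed=None) -> np.ndarray:
    """Muscle activations alpha (18,) in [0, 1].

    Prosthetic-side (removed) muscles are forced to 0.
    """
    y = np.asarray(y, float)
    if np.any(y < 0):
        raise ValueError("CPG outputs must be non-negative")
    P = np.asarray(P, float)
    if w_alpha is None:
        w_alpha = motoneuron_map()
    if removed is None:
        removed = np.zeros(N_MUSCLES)
    removed = np.asarray(removed, float)
    alpha = np.empty(N_MUSCLES)
    K.motoneuron_kernel(y, P, np.asarray(w_alpha, float), removed, alpha)
    return alpha


# ---------------------------------------------------------------------------
# full controller weight bundle + file I/O

@dataclass
class ControllerWeights:
    """Everything the GA searches plus the fixed structural pieces."""

    u0: float = 1.0
    w_feed: np.ndarray = field(default_factory=lambda: np.zeros((2, N_FEED)))
    w_cpg: np.ndarray = field(default_factory=lambda: DEFAULT_CPG_PARAMS.copy())
    w_pos: np.ndarray = field(default_factory=lambda: np.zeros(N_POS))
    tau: float = DEFAULT_TAU
    taup: float = DEFAULT_TAUP
    beta: float = DEFAULT_BETA

    def __post_init__(self):
        self.w_feed = np.asarray(self.w_feed, float).reshape(2, N_FEED)
        self.w_cpg = np.asarray(self.w_cpg, float)
        self.w_pos = np.asarray(self.w_pos, float)

    def network(self) -> CPGNetwork:
        return CPGNetwork(tau=np.full(N_UNITS, self.tau),
                          taup=np.full(N_UNITS, self.taup),
                          beta=self.beta,
                          W=build_cpg_matrix(self.w_cpg),
                          u0=self.u0)

    def feedback(self) -> FeedbackWeights:
        return FeedbackWeights(w_feed=self.w_feed.copy(),
                               w_pos=self.w_pos.copy())


def save_weights(w: ControllerWeights, path) -> None:
    d = {
        "schema": "cpgwalk-weights-1",
        "cpg": {"tau": float(w.tau), "taup": float(w.taup),
                "beta": float(w.beta), "u0": float(w.u0),
                "w": [float(x) for x in w.w_cpg]},
        "feedback": {"w_left": [float(x) for x in w.w_feed[0]],
                     "w_right": [float(x) for x in w.w_feed[1]]},
        "posture": {"w": [float(x) for x in w.w_pos]},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_weights(path) -> ControllerWeights:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if d.get("schema") != "cpgwalk-weights-1":
        raise ValueError("unrecognized weight file schema")
    return ControllerWeights(
        u0=d["cpg"]["u0"],
        w_feed=np.array([d["feedback"]["w_left"], d["feedback"]["w_right"]]),
        w_cpg=np.array(d["cpg"]["w"]),
        w_pos=np.array(d["posture"]["w"]),
        tau=d["cpg"]["tau"], taup=d["cpg"]["taup"], beta=d["cpg"]["beta"])
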