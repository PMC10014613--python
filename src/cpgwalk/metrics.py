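"""Gait metrics: events, spatiotemporal parameters, energetics, symmetry.

Foot-strike and toe-off are threshold crossings of the vertical GRF with a
minimum-duration debounce to reject contact-model chatter.  Stance time is
off - strike; step length is the anterior distance between the feet at each
strike (leading foot minus trailing foot).  The gross metabolic cost of
transport is

    C = 1 / (T M V) * integral_0^T sum_m Edot_m dt        [J/kg/m]

(trapezoid rule on the logged grid) and the symmetry index of a right/left
spatiotemporal pair is

    SI = 2 (R - L) / (R + L) * 100                        [%]

reported as the absolute symmetry index |SI| alongside the signed value.
Summary windows follow the stride convention: strides 3-8 of the reference
limb (five full steps once the gait has settled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .muscle import MuscleSpec, MuscleState

GRF_THRESHOLD = 10.0      # N
DEBOUNCE = 0.020          # s
STRIDE_WINDOW = (3, 8)    # 1-based, inclusive


class NoStepsError(ValueError):
    """Raised when a GRF trace contains no threshold crossings."""


@dataclass
class GaitEvents:
    """Per-limb strike/off times and derived quantities."""

    strikes: dict[str, np.ndarray]
    offs: dict[str, np.ndarray]

    def stance_times(self, side: str) -> np.ndarray:
        """off - strike for every completed stance of one limb."""
        st = self.strikes[side]
        off = self.offs[side]
        out = []
        j = 0
        for t0 in st:
            while j < len(off) and off[j] <= t0:
                j += 1
            if j < len(off):
                out.append(off[j] - t0)
        return np.array(out)


@dataclass
class EnergyTrace:
    """Total metabolic rate trace plus the scalars entering the CoT."""

    t: np.ndarray              # (n,)
    edot: np.ndarray           # (n,) or (n, m) per-muscle rates (W)
    body_mass: float
    speed: float               # mean speed V (m/s)
    duration: float | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.edot = np.asarray(self.edot, float)
        if self.duration is None:
            self.duration = float(self.t[-1] - self.t[0])

    def total_rate(self) -> np.ndarray:
        return self.edot if self.edot.ndim == 1 else self.edot.sum(axis=1)


def _crossings(t, grf, threshold, debounce):
    """Debounced upward (strike) and downward (off) crossing times.

    The trace is split into above/below segments; interior segments shorter
    than the debounce window are merged into their neighbours (a 1-sample
    chatter spike creates no events).  The trailing segment is never merged
    (trials truncate mid-phase).
    """
    above = grf >= threshold
    change = np.flatnonzero(above[1:] != above[:-1]) + 1
    seg_start = [t[0]] + [t[i] for i in change]
    seg_state = [bool(above[0])] + [bool(above[i]) for i in change]
    end_time = t[-1]
    k = 1
    while k < len(seg_start):
        seg_end = seg_start[k + 1] if k + 1 < len(seg_start) else end_time
        if seg_end - seg_start[k] < debounce and k + 1 < len(seg_start):
            del seg_start[k:k + 2]
            del seg_state[k:k + 2]
            k = max(1, k - 1)
        else:
            k += 1
    strikes = np.array([seg_start[k] for k in range(1, len(seg_start))
                        if seg_state[k]])
    offs = np.array([seg_start[k] for k in range(1, len(seg_start))
                     if not seg_state[k]])
    return strikes, offs


def detect_gait_events(t, grf_left, grf_right,
                       threshold: float = GRF_THRESHOLD,
                       debounce: float = DEBOUNCE) -> GaitEvents:
    """Strike/off events per limb from uniformly sampled vertical GRFs."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    t = np.asarray(t, float)
    strikes, offs = {}, {}
    for side, grf in (("left", grf_left), ("right", grf_right)):
        s, o = _crossings(t, np.asarray(grf, float), threshold, debounce)
        strikes[side] = s
        offs[side] = o
    if all(len(s) == 0 for s in strikes.values()):
        raise NoStepsError("no GRF threshold crossings: not a walking trial")
    return GaitEvents(strikes=strikes, offs=offs)


def step_lengths(events: GaitEvents, t, foot_x_left, foot_x_right) -> dict:
    """Step length per limb: at each strike of a limb, the anterior distance
    from the contralateral foot to the striking foot."""
    t = np.asarray(t, float)
    fx = {"left": np.asarray(foot_x_left, float),
          "right": np.asarray(foot_x_right, float)}
    out = {}
    for side, other in (("left", "right"), ("right", "left")):
        vals = []
        for ts in events.strikes[side]:
            i = int(np.searchsorted(t, ts))
            i = min(i, len(t) - 1)
            vals.append(fx[side][i] - fx[other][i])
        out[side] = np.array(vals)
    return out


def metabolic_rate(spec: MuscleSpec, st: MuscleState,
                   c_act: float = 0.15, c_short: float = 0.25,
                   fv_sign: float = 1.0) -> float:
    """Metabolic rate (W) of one muscle.

    Activation/maintenance heat c_act*alpha^2*F_ce_max*V_max, shortening
    heat c_short*alpha*F_ce_max*max(0, -Ldot), plus positive CE mechanical
    work; no basal term.  Always >= 0; removed muscles simply contribute no
    state.
    """
    _, F_ce = K.muscle_tension_kernel(
        spec.f_ce_max, spec.l_opt, spec.v_max, spec.c_pd, spec.k_pe,
        st.L, st.Ld, st.alpha, fv_sign)
    return float(K.metabolic_rate_kernel(
        st.alpha, st.Ld, F_ce, spec.f_ce_max, spec.v_max, c_act, c_short))


def cost_of_transport(trace: EnergyTrace) -> float:
    """Gross metabolic cost of transport C (J/kg/m), trapezoid rule."""
    if trace.duration <= 0 or trace.body_mass <= 0 or trace.speed <= 0:
        raise ValueError("duration, mass and speed must be positive")
    total = np.trapezoid(trace.total_rate(), trace.t)
    return float(total / (trace.duration * trace.body_mass * trace.speed))


def asi(R: float, L: float) -> float:
    """Signed symmetry index 2 (R - L) / (R + L) * 100 (%).

    Callers wanting the absolute symmetry index take abs().
    """
    if R < 0 or L < 0:
        raise ValueError("R and L must be non-negative")
    if R + L == 0:
        raise ValueError("R + L must be positive")
    return float(2.0 * (R - L) / (R + L) * 100.0)


def _window(values: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    """1-based inclusive stride-window selection."""
    lo, hi = window
    return values[lo - 1:hi]


def summarize_trial(trial, stride_window: tuple[int, int] = STRIDE_WINDOW,
                    threshold: float = GRF_THRESHOLD,
                    debounce: float = DEBOUNCE) -> dict:
    """Spatiotemporal and energetic summary of a trial over a stride window.

    ``trial`` is a TrialResult.  Returns means/SDs of stance time and step
    length per side, signed and absolute symmetry indices of both, the cost
    of transport over the window, and the mean speed.  Raises if the trial
    holds fewer strides than the window needs.
    """
    ev = detect_gait_events(trial.t, trial.grf[:, 0], trial.grf[:, 1],
                            threshold, debounce)
    sl = step_lengths(ev, trial.t, trial.foot_x[:, 0], trial.foot_x[:, 2])
    lo, hi = stride_window
    need = hi
    for side in ("left", "right"):
        if len(ev.stance_times(side)) < need or len(sl[side]) < need:
            raise ValueError(
                f"trial holds fewer than {need} strides on the {side} side; "
                f"shorten the stride window")

    out = {"stride_window": list(stride_window), "speed": trial.speed,
           "distance": trial.distance, "fell": bool(trial.fell)}
    means = {}
    for side in ("left", "right"):
        stw = _window(ev.stance_times(side), stride_window)
        slw = _window(sl[side], stride_window)
        means[side] = (stw.mean(), slw.mean())
        out[f"stance_time_{side}_mean"] = float(stw.mean())
        out[f"stance_time_{side}_sd"] = float(stw.std(ddof=1))
        out[f"step_length_{side}_mean"] = float(slw.mean())
        out[f"step_length_{side}_sd"] = float(slw.std(ddof=1))
    st_asi = asi(means["right"][0], means["left"][0])
    sl_asi = asi(means["right"][1], means["left"][1])
    out["stance_time_asi_signed"] = st_asi
    out["stance_time_asi_abs"] = abs(st_asi)
    out["step_length_asi_signed"] = sl_asi
    out["step_length_asi_abs"] = abs(sl_asi)

    # CoT over the window: from the first in-window left strike to the last
    t0 = min(ev.strikes[side][lo - 1] for side in ("left", "right"))
    t1 = max(ev.strikes[side][hi - 1] for side in ("left", "right"))
    mask = (trial.t >= t0) & (trial.t <= t1)
    i0 = int(np.flatnonzero(mask)[0])
    i1 = int(np.flatnonzero(mask)[-1])
    dx = trial.q[i1, 0] - trial.q[i0, 0]
    dur = trial.t[i1] - trial.t[i0]
    if dur > 0 and dx > 0:
        trace = EnergyTrace(t=trial.t[mask], edot=trial.edot[mask],
                            body_mass=trial.body_mass, speed=dx / dur)
        out["cost_of_transport"] = cost_of_transport(trace)
    else:
        out["cost_of_transport"] = float("nan")
    return out
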