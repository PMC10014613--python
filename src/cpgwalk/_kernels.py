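"""Numba-compiled numerical kernels.

Everything that runs inside the 0.1 ms RK4 loop lives here: planar 9-DOF
rigid-body dynamics of the 7-segment biped, Hill-type muscle mechanics,
Matsuoka CPG derivatives, motoneuron/posture output, ground contact, muscle
energetics, and the monolithic trial integrator.  The public modules
(``body``, ``muscle``, ``controller``, ``metrics``) wrap these kernels, so
there is a single implementation of every formula.

Array conventions
-----------------
Generalized coordinates ``q`` (9,):
    ``[x, y, th_hat, th_thigh_L, th_shank_L, th_foot_L, th_thigh_R,
    th_shank_R, th_foot_R]`` — pelvis/hip point position plus absolute
    segment angles, CCW positive, 0 = neutral standing, +x = forward.
Full state ``s`` (42,): ``[q, qdot, u (12 CPG), v (12 CPG)]``.
Joint angles (6,): ``[hip_L, knee_L, ankle_L, hip_R, knee_R, ankle_R]``
    with hip flexion, knee flexion and ankle dorsiflexion positive, all 0 at
    neutral standing.
Muscles (18,): types ``[GM, IL, BFL, RF, BFS, VA, GC, SO, TA]``, left leg
    first (m = type + 9*side).
CPG units (12,): per leg ``[hipF, hipE, kneeF, kneeE, ankF, ankE]``, left
    leg units 0-5, right leg 6-11.

Body parameter vector ``pb`` layout: see ``PB_*`` index constants below.
Muscle parameter matrix ``pm`` (18, 10):
    ``[F_ce_max, L_opt, V_max, c_pd, k_pe, rho_hip, rho_knee, rho_ankle,
    side, removed]``.
"""

import math

import numpy as np
from numba import njit

# -- body parameter vector indices -------------------------------------------
PB_MASS = 0          # 7 segment masses (hat, thL, shL, ftL, thR, shR, ftR)
PB_INERTIA = 7       # 7 segment inertias about COM
PB_C_HAT = 14        # HAT COM height above hip
PB_L_TH = 15         # thigh length (hip->knee)
PB_C_TH = 16         # thigh COM below hip
PB_L_SH = 17         # shank length (knee->ankle)
PB_C_SH = 18         # shank COM below knee
PB_FCX = 19          # foot COM offset in foot frame
PB_FCY = 20
PB_HEELX = 21        # heel contact point in foot frame
PB_HEELY = 22
PB_TOEX = 23         # toe contact point in foot frame
PB_TOEY = 24
PB_G = 25
PB_KH = 26           # contact: horizontal spring
PB_CH = 27           # contact: horizontal damper
PB_KV = 28           # contact: vertical spring
PB_CV = 29           # contact: vertical damper
PB_VISC = 30         # 3 joint viscosities (hip, knee, ankle)
PB_LIM = 33          # 6 limits (hip lo, hi, knee lo, hi, ankle lo, hi)
PB_LOCK_K = 39       # joint-lock stiffness
PB_LOCK_C = 40       # joint-lock damping
PB_PROS_SIDE = 41    # -1 none, 0 left, 1 right
PB_PROS_K = 42       # prosthetic ankle passive stiffness
PB_MTOT = 43         # total body mass
PB_HATCOM_Y0 = 44    # standing HAT COM height (fall reference)
PB_FALL_FRAC = 45    # fall when HAT COM drops below this fraction of standing
PB_HIP_MIN = 46      # fall when hip drops below this height
PB_PITCH_REF = 47    # posture-control HAT pitch target
PB_LEN = 48

NQ = 9
NS = 42
NMUSCLE = 18
NUNIT = 12

# muscle type ids
M_GM, M_IL, M_BFL, M_RF, M_BFS, M_VA, M_GC, M_SO, M_TA = range(9)


@njit(cache=True)
def force_length(xi):
    """Active force-length gain k(xi), clamped at zero.

    k(xi) = 0.32 + 0.71 exp(-1.112 (xi-1)) sin(3.722 (xi-0.656)).
    """
    k = 0.32 + 0.71 * math.exp(-1.112 * (xi - 1.0)) * math.sin(3.722 * (xi - 0.656))
    if k < 0.0:
        return 0.0
    return k


@njit(cache=True)
def force_velocity(eta):
    """Force-velocity gain h(eta) = 1 + tanh(3 eta), bounded in (0, 2)."""
    return 1.0 + math.tanh(3.0 * eta)


@njit(cache=True)
def passive_elastic(L, L_opt, k_pe):
    """PE force k_pe*(exp(15(L-L_opt))-1), active in stretch only."""
    if L <= L_opt:
        return 0.0
    return k_pe * (math.exp(15.0 * (L - L_opt)) - 1.0)


@njit(cache=True)
def muscle_tension_kernel(F_ce_max, L_opt, V_max, c_pd, k_pe, L, Ld, alpha, fv_sign):
    """Total muscle tension: CE (force-length x force-velocity x activation)
    plus passive damping and passive elastic elements.

    Returns (F_total, F_ce). fv_sign flips the velocity convention fed to
    h(eta); +1 means eta > 0 on lengthening (default).
    """
    xi = L / L_opt
    eta = fv_sign * Ld / V_max
    F_ce = F_ce_max * force_length(xi) * force_velocity(eta) * alpha
    F = F_ce + c_pd * Ld + passive_elastic(L, L_opt, k_pe)
    return F, F_ce


@njit(cache=True)
def metabolic_rate_kernel(alpha, Ld, F_ce, F_ce_max, V_max, c_act, c_short):
    """Instantaneous metabolic rate (W) of one muscle.

    Activation/maintenance heat (c_act * alpha^2 * F_ce_max * V_max),
    shortening heat (c_short * alpha * F_ce_max * max(0, -Ld)) and positive
    CE mechanical work (CE power while shortening).  Non-negative; zero for
    an inactive, isometric muscle.
    """
    e = c_act * alpha * alpha * F_ce_max * V_max
    if Ld < 0.0:
        e += c_short * alpha * F_ce_max * (-Ld)
        w = F_ce * (-Ld)
        if w > 0.0:
            e += w
    return e


@njit(cache=True)
def joint_angles_kernel(q, qd, th, thd):
    """Relative joint angles/velocities from segment angles.

    Fills th, thd (6,): [hip_L, knee_L, ankle_L, hip_R, knee_R, ankle_R].
    """
    th[0] = q[3] - q[2]
    th[1] = q[3] - q[4]
    th[2] = q[5] - q[4]
    th[3] = q[6] - q[2]
    th[4] = q[6] - q[7]
    th[5] = q[8] - q[7]
    thd[0] = qd[3] - qd[2]
    thd[1] = qd[3] - qd[4]
    thd[2] = qd[5] - qd[4]
    thd[3] = qd[6] - qd[2]
    thd[4] = qd[6] - qd[7]
    thd[5] = qd[8] - qd[7]


@njit(cache=True)
def contact_points_kernel(q, qd, pb, pos, vel):
    """World positions/velocities of the 4 contact points.

    Order: [heel_L, toe_L, heel_R, toe_R]; pos, vel are (4, 2) outputs.
    """
    for side in range(2):
        ith = 3 + 3 * side
        ish = 4 + 3 * side
        ift = 5 + 3 * side
        sth = math.sin(q[ith]); cth = math.cos(q[ith])
        ssh = math.sin(q[ish]); csh = math.cos(q[ish])
        sft = math.sin(q[ift]); cft = math.cos(q[ift])
        # knee = hip + L_th * (sin, -cos); ankle = knee + L_sh * (sin, -cos)
        ax = q[0] + pb[PB_L_TH] * sth + pb[PB_L_SH] * ssh
        ay = q[1] - pb[PB_L_TH] * cth - pb[PB_L_SH] * csh
        avx = qd[0] + pb[PB_L_TH] * cth * qd[ith] + pb[PB_L_SH] * csh * qd[ish]
        avy = qd[1] + pb[PB_L_TH] * sth * qd[ith] + pb[PB_L_SH] * ssh * qd[ish]
        for p in range(2):
            if p == 0:
                ox = pb[PB_HEELX]; oy = pb[PB_HEELY]
            else:
                ox = pb[PB_TOEX]; oy = pb[PB_TOEY]
            wx = ox * cft - oy * sft
            wy = ox * sft + oy * cft
            i = 2 * side + p
            pos[i, 0] = ax + wx
            pos[i, 1] = ay + wy
            vel[i, 0] = avx - wy * qd[ift]
            vel[i, 1] = avy + wx * qd[ift]


@njit(cache=True)
def contact_force_kernel(py, vy, px, vx, anchor_x, active, kh, ch, kv, cv):
    """Spring-damper ground contact force (fx, fy) at one point.

    Vertical: kv*depth + cv*(-vy), floored at 0 (no adhesion), only while
    penetrating.  Horizontal: spring to the touchdown anchor plus damper,
    only while the contact is active and penetrating.
    """
    fx = 0.0
    fy = 0.0
    if py < 0.0:
        fy = kv * (-py) + cv * (-vy)
        if fy < 0.0:
            fy = 0.0
        if active:
            fx = kh * (anchor_x - px) - ch * vx
    return fx, fy


@njit(cache=True)
def chol_solve(A, b, x):
    """Solve A x = b for symmetric positive-definite A (in-place Cholesky).

    Returns False if A is not positive definite (degenerate inertia).
    """
    n = A.shape[0]
    for j in range(n):
        d = A[j, j]
        for k in range(j):
            d -= A[j, k] * A[j, k]
        if d <= 0.0 or not math.isfinite(d):
            return False
        d = math.sqrt(d)
        A[j, j] = d
        for i in range(j + 1, n):
            s = A[i, j]
            for k in range(j):
                s -= A[i, k] * A[j, k]
            A[i, j] = s / d
    for i in range(n):
        s = b[i]
        for k in range(i):
            s -= A[i, k] * x[k]
        x[i] = s / A[i, i]
    for i in range(n - 1, -1, -1):
        s = x[i]
        for k in range(i + 1, n):
            s -= A[k, i] * x[k]
        x[i] = s / A[i, i]
    return True


@njit(cache=True)
def eom_kernel(q, qd, pb, seg_ci, seg_off, cp_ci, cp_off, tau6, fc, M, Q, qdd):
    """Generalized accelerations of the 9-DOF chain (Newton-Euler).

    seg_ci/seg_off describe each segment COM as hip + sum_k R(q[ci_k]) off_k;
    cp_ci/cp_off likewise for the 4 contact points.  tau6 are relative joint
    torques, fc (4,2) world contact forces.  M, Q, qdd are work arrays; qdd
    receives the result.  Returns False on a singular mass matrix.
    """
    g = pb[PB_G]
    for i in range(NQ):
        Q[i] = 0.0
        for j in range(NQ):
            M[i, j] = 0.0

    jidx = np.empty(5, np.int64)
    jvx = np.empty(5)
    jvy = np.empty(5)

    for seg in range(7):
        m = pb[PB_MASS + seg]
        jidx[0] = 0; jvx[0] = 1.0; jvy[0] = 0.0
        jidx[1] = 1; jvx[1] = 0.0; jvy[1] = 1.0
        bx = 0.0
        by = 0.0
        n = 2
        for k in range(3):
            a = seg_ci[seg, k]
            if a < 0:
                break
            c = math.cos(q[a]); s = math.sin(q[a])
            ox = seg_off[seg, k, 0]; oy = seg_off[seg, k, 1]
            wx = ox * c - oy * s
            wy = ox * s + oy * c
            jidx[n] = a
            jvx[n] = -wy
            jvy[n] = wx
            td = qd[a]
            bx -= wx * td * td
            by -= wy * td * td
            n += 1
        for a_ in range(n):
            ia = jidx[a_]
            Q[ia] += m * (-g * jvy[a_] - (jvx[a_] * bx + jvy[a_] * by))
            for b_ in range(n):
                M[ia, jidx[b_]] += m * (jvx[a_] * jvx[b_] + jvy[a_] * jvy[b_])
        M[2 + seg, 2 + seg] += pb[PB_INERTIA + seg]

    # contact forces through the point Jacobians
    for p in range(4):
        fx = fc[p, 0]
        fy = fc[p, 1]
        if fx == 0.0 and fy == 0.0:
            continue
        Q[0] += fx
        Q[1] += fy
        for k in range(3):
            a = cp_ci[p, k]
            if a < 0:
                break
            c = math.cos(q[a]); s = math.sin(q[a])
            ox = cp_off[p, k, 0]; oy = cp_off[p, k, 1]
            wx = ox * c - oy * s
            wy = ox * s + oy * c
            Q[a] += -wy * fx + wx * fy
    # relative joint torques -> generalized forces
    # hip_L (thigh - hat), knee_L (thigh - shank), ankle_L (foot - shank)
    Q[3] += tau6[0]; Q[2] -= tau6[0]
    Q[3] += tau6[1]; Q[4] -= tau6[1]
    Q[5] += tau6[2]; Q[4] -= tau6[2]
    Q[6] += tau6[3]; Q[2] -= tau6[3]
    Q[6] += tau6[4]; Q[7] -= tau6[4]
    Q[8] += tau6[5]; Q[7] -= tau6[5]
    return chol_solve(M, Q, qdd)


@njit(cache=True)
def joint_passive_kernel(th, thd, pb, tau6):
    """Adds viscous, range-of-motion lock and prosthetic-ankle moments."""
    lock_k = pb[PB_LOCK_K]
    lock_c = pb[PB_LOCK_C]
    for side in range(2):
        for j in range(3):
            i = 3 * side + j
            m = -pb[PB_VISC + j] * thd[i]
            lo = pb[PB_LIM + 2 * j]
            hi = pb[PB_LIM + 2 * j + 1]
            if th[i] < lo:
                m += -lock_k * (th[i] - lo) - lock_c * thd[i]
            elif th[i] > hi:
                m += -lock_k * (th[i] - hi) - lock_c * thd[i]
            if j == 2 and pb[PB_PROS_SIDE] == side:
                m += -pb[PB_PROS_K] * th[i]
            tau6[i] += m


@njit(cache=True)
def cpg_deriv_kernel(u, v, feed, tau, taup, beta, W, u0, du, dv):
    """Matsuoka network derivatives.

    tau_i du_i = -u_i + sum_j W_ij y_j - beta v_i + u0 + feed_i
    tau'_i dv_i = -v_i + y_i,   y_i = max(0, u_i).
    """
    for i in range(NUNIT):
        s = -u[i] - beta * v[i] + u0 + feed[i]
        for j in range(NUNIT):
            yj = u[j]
            if yj < 0.0:
                yj = 0.0
            s += W[i, j] * yj
        du[i] = s / tau[i]
        yi = u[i]
        if yi < 0.0:
            yi = 0.0
        dv[i] = (-v[i] + yi) / taup[i]


@njit(cache=True)
def feedback_kernel(q, grfn_l, grfn_r, wfeed, feed_unit, feed_sensor, feed):
    """Sensory feedback Feed_i: linear combination of segment angles and
    contact-gated normalized vertical GRFs through the 16-slot-per-leg wiring.

    Sensor kinds: 0 HAT pitch, 1 ipsi thigh, 2 contra thigh, 3 ipsi shank,
    4 ipsi foot, 5 ipsi GRF, 6 contra GRF (GRF in body weights).
    """
    for i in range(NUNIT):
        feed[i] = 0.0
    for side in range(2):
        for slot in range(feed_unit.shape[0]):
            kind = feed_sensor[slot]
            if kind == 0:
                val = q[2]
            elif kind == 1:
                val = q[3 + 3 * side]
            elif kind == 2:
                val = q[3 + 3 * (1 - side)]
            elif kind == 3:
                val = q[4 + 3 * side]
            elif kind == 4:
                val = q[5 + 3 * side]
            elif kind == 5:
                val = grfn_l if side == 0 else grfn_r
            else:
                val = grfn_r if side == 0 else grfn_l
            feed[feed_unit[slot] + 6 * side] += wfeed[side, slot] * val


@njit(cache=True)
def posture_kernel(q, qd, th, thd, grfn_l, grfn_r, contact_l, contact_r,
                   pitch_ref, wpos, pos_muscle, pos_sensor, P):
    """Posture-control corrections P_m (18,): PD terms on HAT pitch and
    stance-leg joint angles, gated by ipsilateral foot contact, mixed into
    per-muscle corrections by the 23-coefficient table.

    Sensor kinds: 0/1 HAT pitch err/rate, 2/3 hip ang/vel, 4/5 knee,
    6/7 ankle, 8 normalized GRF.
    """
    for m in range(NMUSCLE):
        P[m] = 0.0
    for side in range(2):
        if side == 0:
            if not contact_l:
                continue
            grfn = grfn_l
        else:
            if not contact_r:
                continue
            grfn = grfn_r
        for row in range(pos_muscle.shape[0]):
            kind = pos_sensor[row]
            if kind == 0:
                val = q[2] - pitch_ref
            elif kind == 1:
                val = qd[2]
            elif kind == 2:
                val = th[3 * side]
            elif kind == 3:
                val = thd[3 * side]
            elif kind == 4:
                val = th[3 * side + 1]
            elif kind == 5:
                val = thd[3 * side + 1]
            elif kind == 6:
                val = th[3 * side + 2]
            elif kind == 7:
                val = thd[3 * side + 2]
            else:
                val = grfn
            P[pos_muscle[row] + 9 * side] += wpos[row] * val


@njit(cache=True)
def motoneuron_kernel(u, P, walpha, removed, alpha):
    """Motoneuron output per muscle (Eq.-style saturating sigmoid).

    alpha_m = clamp(2/(1+exp(-0.25 (sum_i walpha_mi y_i + P_m))) - 1, 0, 1);
    removed (prosthetic-side) muscles get 0.
    """
    for m in range(NMUSCLE):
        if removed[m]:
            alpha[m] = 0.0
            continue
        drive = P[m]
        for i in range(NUNIT):
            yi = u[i]
            if yi < 0.0:
                yi = 0.0
            drive += walpha[m, i] * yi
        a = 2.0 / (1.0 + math.exp(-0.25 * drive)) - 1.0
        if a < 0.0:
            a = 0.0
        elif a > 1.0:
            a = 1.0
        alpha[m] = a


@njit(cache=True)
def muscle_torque_kernel(th, thd, pm, alpha, fv_sign, c_act, c_short,
                         tau6, F_out, Edot_out):
    """Muscle tensions -> relative joint torques and metabolic rates.

    Muscle length L = L_opt + rho_hip*hip + rho_knee*knee + rho_ankle*ankle
    on the muscle's own leg (angles 0 at neutral standing); torque at joint
    j is -rho_j * F.
    """
    for i in range(6):
        tau6[i] = 0.0
    for m in range(NMUSCLE):
        if pm[m, 9] != 0.0:  # removed
            F_out[m] = 0.0
            Edot_out[m] = 0.0
            continue
        side = int(pm[m, 8])
        o = 3 * side
        rh = pm[m, 5]; rk = pm[m, 6]; ra = pm[m, 7]
        L = pm[m, 1] + rh * th[o] + rk * th[o + 1] + ra * th[o + 2]
        Ld = rh * thd[o] + rk * thd[o + 1] + ra * thd[o + 2]
        F, F_ce = muscle_tension_kernel(
            pm[m, 0], pm[m, 1], pm[m, 2], pm[m, 3], pm[m, 4],
            L, Ld, alpha[m], fv_sign)
        F_out[m] = F
        Edot_out[m] = metabolic_rate_kernel(
            alpha[m], Ld, F_ce, pm[m, 0], pm[m, 2], c_act, c_short)
        tau6[o] += -rh * F
        tau6[o + 1] += -rk * F
        tau6[o + 2] += -ra * F


@njit(cache=True)
def full_deriv(s, anchors, active, pb, seg_ci, seg_off, cp_ci, cp_off,
               pm, fv_sign, c_act, c_short,
               tau, taup, beta, W, u0, wfeed, feed_unit, feed_sensor,
               wpos, pos_muscle, pos_sensor, walpha,
               ds, aux, wM, wQ, wqdd, wth, wthd, wtau6, wfc, wpos4, wvel4,
               wfeedv, wP, walpha_out, wF, wEdot, wdu, wdv):
    """Time derivative of the full 42-state (mechanics + CPG) system.

    aux (3,) receives [grf_L, grf_R, sum Edot]; walpha_out the 18 muscle
    activations.  Returns False if the mass matrix factorization fails.
    """
    q = s[0:9]
    qd = s[9:18]
    u = s[18:30]
    v = s[30:42]

    contact_points_kernel(q, qd, pb, wpos4, wvel4)
    for p in range(4):
        fx, fy = contact_force_kernel(
            wpos4[p, 1], wvel4[p, 1], wpos4[p, 0], wvel4[p, 0],
            anchors[p], active[p] != 0, pb[PB_KH], pb[PB_CH], pb[PB_KV], pb[PB_CV])
        wfc[p, 0] = fx
        wfc[p, 1] = fy
    grf_l = wfc[0, 1] + wfc[1, 1]
    grf_r = wfc[2, 1] + wfc[3, 1]
    mg = pb[PB_MTOT] * pb[PB_G]
    grfn_l = grf_l / mg
    grfn_r = grf_r / mg
    contact_l = grf_l > 0.0
    contact_r = grf_r > 0.0

    joint_angles_kernel(q, qd, wth, wthd)
    posture_kernel(q, qd, wth, wthd, grfn_l, grfn_r, contact_l, contact_r,
                   pb[PB_PITCH_REF], wpos, pos_muscle, pos_sensor, wP)
    removed = pm[:, 9]
    motoneuron_kernel(u, wP, walpha, removed, walpha_out)
    muscle_torque_kernel(wth, wthd, pm, walpha_out, fv_sign, c_act, c_short,
                         wtau6, wF, wEdot)
    joint_passive_kernel(wth, wthd, pb, wtau6)
    ok = eom_kernel(q, qd, pb, seg_ci, seg_off, cp_ci, cp_off, wtau6, wfc,
                    wM, wQ, wqdd)
    if not ok:
        return False

    feedback_kernel(q, grfn_l, grfn_r, wfeed, feed_unit, feed_sensor, wfeedv)
    cpg_deriv_kernel(u, v, wfeedv, tau, taup, beta, W, u0, wdu, wdv)

    for i in range(9):
        ds[i] = qd[i]
        ds[9 + i] = wqdd[i]
    for i in range(NUNIT):
        ds[18 + i] = wdu[i]
        ds[30 + i] = wdv[i]
    esum = 0.0
    for m in range(NMUSCLE):
        esum += wEdot[m]
    aux[0] = grf_l
    aux[1] = grf_r
    aux[2] = esum
    return True


@njit(cache=True)
def hat_com_y(q, pb):
    return q[1] + pb[PB_C_HAT] * math.cos(q[2])


@njit(cache=True)
def run_trial_kernel(s0, pb, seg_ci, seg_off, cp_ci, cp_off,
                     pm, fv_sign, c_act, c_short,
                     tau, taup, beta, W, u0, wfeed, feed_unit, feed_sensor,
                     wpos, pos_muscle, pos_sensor, walpha,
                     duration, dt, log_dec,
                     log_t, log_q, log_qd, log_grf, log_footx, log_alpha,
                     log_edot):
    """Integrate one walking trial with classical RK4 at step dt.

    Contact anchors/activity are event states updated once per full step.
    Logs every log_dec-th step into the preallocated arrays.  Aborts on a
    fall (HAT COM below the fall fraction of its standing height, hip below
    PB_HIP_MIN) or on numerical blow-up (treated as a fall).

    Returns (n_logged, fell, t_end, distance, energy_integral).
    """
    s = s0.copy()
    ds1 = np.empty(NS); ds2 = np.empty(NS); ds3 = np.empty(NS); ds4 = np.empty(NS)
    st = np.empty(NS)
    aux = np.empty(3)
    wM = np.empty((NQ, NQ)); wQ = np.empty(NQ); wqdd = np.empty(NQ)
    wth = np.empty(6); wthd = np.empty(6); wtau6 = np.empty(6)
    wfc = np.empty((4, 2)); wp4 = np.empty((4, 2)); wv4 = np.empty((4, 2))
    wfeedv = np.empty(NUNIT); wP = np.empty(NMUSCLE)
    wal = np.empty(NMUSCLE); wF = np.empty(NMUSCLE); wEdot = np.empty(NMUSCLE)
    wdu = np.empty(NUNIT); wdv = np.empty(NUNIT)

    anchors = np.zeros(4)
    active = np.zeros(4, np.int64)
    contact_points_kernel(s[0:9], s[9:18], pb, wp4, wv4)
    for p in range(4):
        if wp4[p, 1] < 0.0:
            active[p] = 1
            anchors[p] = wp4[p, 0]

    x0 = s[0]
    fall_y = pb[PB_FALL_FRAC] * pb[PB_HATCOM_Y0]
    nstep = int(round(duration / dt))
    nlog = 0
    fell = 0
    e_int = 0.0
    t = 0.0
    t_end = duration

    for step in range(nstep + 1):
        ok = full_deriv(s, anchors, active, pb, seg_ci, seg_off, cp_ci, cp_off,
                        pm, fv_sign, c_act, c_short,
                        tau, taup, beta, W, u0, wfeed, feed_unit, feed_sensor,
                        wpos, pos_muscle, pos_sensor, walpha,
                        ds1, aux, wM, wQ, wqdd, wth, wthd, wtau6, wfc, wp4, wv4,
                        wfeedv, wP, wal, wF, wEdot, wdu, wdv)
        if not ok:
            fell = 1
            t_end = t
            break

        if step % log_dec == 0:
            log_t[nlog] = t
            for i in range(NQ):
                log_q[nlog, i] = s[i]
                log_qd[nlog, i] = s[9 + i]
            log_grf[nlog, 0] = aux[0]
            log_grf[nlog, 1] = aux[1]
            contact_points_kernel(s[0:9], s[9:18], pb, wp4, wv4)
            log_footx[nlog, 0] = wp4[0, 0]
            log_footx[nlog, 1] = wp4[1, 0]
            log_footx[nlog, 2] = wp4[2, 0]
            log_footx[nlog, 3] = wp4[3, 0]
            for m in range(NMUSCLE):
                log_alpha[nlog, m] = wal[m]
                log_edot[nlog, m] = wEdot[m]
            nlog += 1

        if step == nstep:
            t_end = t
            break

        e_int += aux[2] * dt

        # RK4 substeps
        for i in range(NS):
            st[i] = s[i] + 0.5 * dt * ds1[i]
        ok = full_deriv(st, anchors, active, pb, seg_ci, seg_off, cp_ci, cp_off,
                        pm, fv_sign, c_act, c_short,
                        tau, taup, beta, W, u0, wfeed, feed_unit, feed_sensor,
                        wpos, pos_muscle, pos_sensor, walpha,
                        ds2, aux, wM, wQ, wqdd, wth, wthd, wtau6, wfc, wp4, wv4,
                        wfeedv, wP, wal, wF, wEdot, wdu, wdv)
        if not ok:
            fell = 1; t_end = t; break
        for i in range(NS):
            st[i] = s[i] + 0.5 * dt * ds2[i]
        ok = full_deriv(st, anchors, active, pb, seg_ci, seg_off, cp_ci, cp_off,
                        pm, fv_sign, c_act, c_short,
                        tau, taup, beta, W, u0, wfeed, feed_unit, feed_sensor,
                        wpos, pos_muscle, pos_sensor, walpha,
                        ds3, aux, wM, wQ, wqdd, wth, wthd, wtau6, wfc, wp4, wv4,
                        wfeedv, wP, wal, wF, wEdot, wdu, wdv)
        if not ok:
            fell = 1; t_end = t; break
        for i in range(NS):
            st[i] = s[i] + dt * ds3[i]
        ok = full_deriv(st, anchors, active, pb, seg_ci, seg_off, cp_ci, cp_off,
                        pm, fv_sign, c_act, c_short,
                        tau, taup, beta, W, u0, wfeed, feed_unit, feed_sensor,
                        wpos, pos_muscle, pos_sensor, walpha,
                        ds4, aux, wM, wQ, wqdd, wth, wthd, wtau6, wfc, wp4, wv4,
                        wfeedv, wP, wal, wF, wEdot, wdu, wdv)
        if not ok:
            fell = 1; t_end = t; break

        finite = True
        for i in range(NS):
            s[i] = s[i] + (dt / 6.0) * (ds1[i] + 2.0 * ds2[i] + 2.0 * ds3[i] + ds4[i])
            if not math.isfinite(s[i]):
                finite = False
        t = (step + 1) * dt
        if not finite:
            fell = 1
            t_end = t
            break

        # contact anchor events
        contact_points_kernel(s[0:9], s[9:18], pb, wp4, wv4)
        for p in range(4):
            if wp4[p, 1] < 0.0:
                if active[p] == 0:
                    active[p] = 1
                    anchors[p] = wp4[p, 0]
            else:
                active[p] = 0

        if hat_com_y(s[0:9], pb) < fall_y or s[1] < pb[PB_HIP_MIN]:
            fell = 1
            t_end = t
            break

    distance = s[0] - x0
    return nlog, fell, t_end, distance, e_int
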