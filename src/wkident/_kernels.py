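"""Compiled numerical kernels (numba) for the simulator and identifier.

Two hot loops live here:

* ``euler_predict`` — the forward-Euler predictor of the five-element
  arterial model over one buffered cardiac cycle, with optional forward
  sensitivities of the output with respect to the five parameters
  (used as the analytic Jacobian of the identification residuals).
* ``cardio_run`` — fixed-step RK4 integration of the closed-loop
  cardiovascular model (four time-varying-elastance chambers, four
  diode valves with resistance and inertance, systemic and pulmonary
  five-element arterial blocks, two RC venous beds).

Everything here is plain float/array code; the user-facing API with
dataclasses, validation and units lives in the sibling modules.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Euler predictor of the arterial model (identification inner loop)
# ---------------------------------------------------------------------------


@njit(cache=True)
def euler_predict(theta, U, Y, h, x0, S0, want_jac):
    """Residuals (and Jacobian) of the Euler-discretised arterial model.

    Residual definition: r_k = sqrt(h) * (C X_k - Y_k), so that
    sum(r**2) equals the integral-style cost  sum_k h (Y_k - Yhat_k)^2.

    State recursion: X_{k+1} = X_k + h (A X_k + B U_k); the Jacobian is
    propagated by differentiating this recursion w.r.t. each parameter,
    seeded with ``S0 = dX_1/dTheta`` (non-zero when the initial-state
    policy itself depends on the parameters).

    Returns (resid, jac, diverged_at); diverged_at is -1 on success or
    the 0-based sample index at which the state left the finite range.
    Residuals past a divergence are left at 0 — the caller decides how
    to treat them.
    """
    R0, R, C1, C2, L = theta[0], theta[1], theta[2], theta[3], theta[4]
    m = U.shape[0]
    resid = np.zeros(m)
    jac = np.zeros((m, 5))
    sh = np.sqrt(h)

    A = np.empty((3, 3))
    A[0, 0] = -R0 / L
    A[0, 1] = R0 / L
    A[0, 2] = 1.0 / C1
    A[1, 0] = 0.0
    A[1, 1] = -1.0 / (R * C2)
    A[1, 2] = -1.0 / C2
    A[2, 0] = -1.0 / L
    A[2, 1] = 1.0 / L
    A[2, 2] = 0.0
    B = np.zeros((3, 3))
    B[0, 1] = R0
    B[1, 0] = 1.0 / C2
    B[1, 2] = 1.0 / (R * C2)
    B[2, 1] = 1.0

    # partial derivatives of A and B w.r.t. (Rsa0, Rsa, Csa1, Csa2, Lsa)
    dA = np.zeros((5, 3, 3))
    dB = np.zeros((5, 3, 3))
    dA[0, 0, 0] = -1.0 / L
    dA[0, 0, 1] = 1.0 / L
    dB[0, 0, 1] = 1.0
    dA[1, 1, 1] = 1.0 / (R * R * C2)
    dB[1, 1, 2] = -1.0 / (R * R * C2)
    dA[2, 0, 2] = -1.0 / (C1 * C1)
    dA[3, 1, 1] = 1.0 / (R * C2 * C2)
    dA[3, 1, 2] = 1.0 / (C2 * C2)
    dB[3, 1, 0] = -1.0 / (C2 * C2)
    dB[3, 1, 2] = -1.0 / (R * C2 * C2)
    dA[4, 0, 0] = R0 / (L * L)
    dA[4, 0, 1] = -R0 / (L * L)
    dA[4, 2, 0] = 1.0 / (L * L)
    dA[4, 2, 1] = -1.0 / (L * L)

    x = x0.copy()
    S = S0.copy()  # dX/dTheta_i in columns
    for k in range(m):
        ok = True
        for j in range(3):
            if not np.isfinite(x[j]) or np.abs(x[j]) > 1e12:
                ok = False
        if not ok:
            return resid, jac, k
        resid[k] = sh * (x[0] - Y[k])
        if want_jac:
            for i in range(5):
                jac[k, i] = sh * S[0, i]
        # advance sensitivities first (they use the current x)
        if want_jac:
            Sn = np.empty((3, 5))
            for i in range(5):
                for r in range(3):
                    acc = 0.0
                    for c in range(3):
                        acc += A[r, c] * S[c, i] + dA[i, r, c] * x[c] + dB[i, r, c] * U[k, c]
                    Sn[r, i] = S[r, i] + h * acc
            S = Sn
        xn = np.empty(3)
        for r in range(3):
            acc = 0.0
            for c in range(3):
                acc += A[r, c] * x[c] + B[r, c] * U[k, c]
            xn[r] = x[r] + h * acc
        x = xn
    return resid, jac, -1


# ---------------------------------------------------------------------------
# Closed-loop cardiovascular model
# ---------------------------------------------------------------------------
#
# State vector layout (16 floats):
#   0 V_lv   1 V_la   2 V_rv   3 V_ra          chamber volumes [mL]
#   4 Q_mi   5 Q_ao   6 Q_ti   7 Q_po          valve flows [mL/s]
#   8 p_ao   9 p_sa  10 Q_Csa1                 systemic arterial states
#  11 p_pa  12 p_ps  13 Q_Cpa1                 pulmonary arterial states
#  14 V_sv  15 V_pv                            venous stressed volumes [mL]
#
# chambers: (4, 9) rows LV, LA, RV, RA:
#   [Emax, Emin, V0, tau1, tau2, n1, n2, onset, norm]
# valves: (4, 2) rows mitral, aortic, tricuspid, pulmonic: [R, L]
# sa, pa: (5,) Windkessel parameter vectors (Rsa0, Rsa, Csa1, Csa2, Lsa)
# ven: (4,) [R_sv, C_sv, R_pv, C_pv]
# ramp segments: (n, 4) rows [t_start, t_end, v_start, v_end]; empty -> off


@njit(cache=True)
def _ramp_val(t, segs, baseline):
    """Piecewise-linear schedule: linear interpolation inside a segment,
    baseline everywhere outside; hold windows need explicit segments."""
    for i in range(segs.shape[0]):
        t0, t1, v0, v1 = segs[i, 0], segs[i, 1], segs[i, 2], segs[i, 3]
        if t0 <= t <= t1:
            if t1 > t0:
                return v0 + (v1 - v0) * (t - t0) / (t1 - t0)
            return v1
    return baseline


@njit(cache=True)
def _activation(t, T, tau1, tau2, n1, n2, onset, norm):
    """Normalised double-Hill activation, periodic with period T."""
    tloc = (t / T - onset) % 1.0 * T
    a = (tloc / tau1) ** n1
    g1 = a / (1.0 + a)
    g2 = 1.0 / (1.0 + (tloc / tau2) ** n2)
    return g1 * g2 / norm


@njit(cache=True)
def _cardio_rhs(t, y, dy, chambers, valves, sa, pa, ven, T, rsa_segs, csa1_segs):
    # chamber pressures
    p_ch = np.empty(4)
    for i in range(4):
        Emax, Emin, V0 = chambers[i, 0], chambers[i, 1], chambers[i, 2]
        act = _activation(
            t, T, chambers[i, 3], chambers[i, 4], chambers[i, 5], chambers[i, 6],
            chambers[i, 7], chambers[i, 8],
        )
        E = Emin + (Emax - Emin) * act
        p_ch[i] = E * (y[i] - V0)
    plv, pla, prv, pra = p_ch[0], p_ch[1], p_ch[2], p_ch[3]

    psv = y[14] / ven[1]
    ppv = y[15] / ven[3]

    rsa_t = _ramp_val(t, rsa_segs, sa[1])
    csa1_t = _ramp_val(t, csa1_segs, sa[2])

    # valves: ideal diode + R + L; flow state clamped >= 0 by the stepper
    dp_mi = pla - plv
    dp_ao = plv - y[8]
    dp_ti = pra - prv
    dp_po = prv - y[11]
    q = y[4:8]
    dps = (dp_mi, dp_ao, dp_ti, dp_po)
    dq = np.zeros(4)
    for i in range(4):
        if q[i] > 0.0 or dps[i] > 0.0:
            dq[i] = (dps[i] - valves[i, 0] * q[i]) / valves[i, 1]
    dQmi, dQao, dQti, dQpo = dq[0], dq[1], dq[2], dq[3]

    # systemic arterial block: exactly the five-element state space,
    # inputs [Q_ao, dQ_ao/dt, p_sv]
    R0, R, C1, C2, L = sa[0], rsa_t, csa1_t, sa[3], sa[4]
    pao, psa, qc1 = y[8], y[9], y[10]
    dy[8] = -R0 / L * pao + R0 / L * psa + qc1 / C1 + R0 * dQao
    dy[9] = (y[5] - qc1) / C2 - (psa - psv) / (R * C2)
    dy[10] = (psa - pao) / L + dQao

    # pulmonary arterial block, inputs [Q_po, dQ_po/dt, p_pv]
    R0p, Rp, C1p, C2p, Lp = pa[0], pa[1], pa[2], pa[3], pa[4]
    ppa, pps, qpc1 = y[11], y[12], y[13]
    dy[11] = -R0p / Lp * ppa + R0p / Lp * pps + qpc1 / C1p + R0p * dQpo
    dy[12] = (y[7] - qpc1) / C2p - (pps - ppv) / (Rp * C2p)
    dy[13] = (pps - ppa) / Lp + dQpo

    # venous beds and chamber volumes
    q_out_sa = (psa - psv) / rsa_t
    q_svr = (psv - pra) / ven[0]
    q_out_pa = (pps - ppv) / Rp
    q_pvr = (ppv - pla) / ven[2]
    dy[14] = q_out_sa - q_svr
    dy[15] = q_out_pa - q_pvr
    dy[0] = y[4] - y[5]
    dy[1] = q_pvr - y[4]
    dy[2] = y[6] - y[7]
    dy[3] = q_svr - y[6]
    dy[4] = dQmi
    dy[5] = dQao
    dy[6] = dQti
    dy[7] = dQpo
    return 0


@njit(cache=True)
def rk4_step(t, y, dt, chambers, valves, sa, pa, ven, T, rsa_segs, csa1_segs):
    """One classical RK4 step; valve flows clamped non-negative after it."""
    k1 = np.zeros(16)
    k2 = np.zeros(16)
    k3 = np.zeros(16)
    k4 = np.zeros(16)
    _cardio_rhs(t, y, k1, chambers, valves, sa, pa, ven, T, rsa_segs, csa1_segs)
    _cardio_rhs(t + 0.5 * dt, y + 0.5 * dt * k1, k2, chambers, valves, sa, pa, ven, T, rsa_segs, csa1_segs)
    _cardio_rhs(t + 0.5 * dt, y + 0.5 * dt * k2, k3, chambers, valves, sa, pa, ven, T, rsa_segs, csa1_segs)
    _cardio_rhs(t + dt, y + dt * k3, k4, chambers, valves, sa, pa, ven, T, rsa_segs, csa1_segs)
    yn = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    for i in range(4, 8):
        if yn[i] < 0.0:
            yn[i] = 0.0
    return yn


@njit(cache=True)
def cardio_run(y0, t0, n_out, out_dt, n_sub, chambers, valves, sa, pa, ven, T,
               rsa_segs, csa1_segs, out):
    """Integrate the closed loop, recording ``n_out`` samples ``out_dt`` apart.

    Recorded channels per sample:
    [p_ao, Q_ao, p_sv, p_lv, V_lv, V_total_stressed].
    Returns (status, y_final): status -1 on success, else the output-sample
    index at which a non-finite state or negative chamber volume appeared.
    """
    dt = out_dt / n_sub
    y = y0.copy()
    dy = np.zeros(16)
    for k in range(n_out):
        t = t0 + k * out_dt
        # record
        _cardio_rhs(t, y, dy, chambers, valves, sa, pa, ven, T, rsa_segs, csa1_segs)
        Emax, Emin, V0 = chambers[0, 0], chambers[0, 1], chambers[0, 2]
        act = _activation(t, T, chambers[0, 3], chambers[0, 4], chambers[0, 5],
                          chambers[0, 6], chambers[0, 7], chambers[0, 8])
        out[k, 0] = y[8]
        out[k, 1] = y[5]
        out[k, 2] = y[14] / ven[1]
        out[k, 3] = (Emin + (Emax - Emin) * act) * (y[0] - V0)
        out[k, 4] = y[0]
        csa1_t = _ramp_val(t, csa1_segs, sa[2])
        v_sa = csa1_t * (y[8] - sa[0] * y[10]) + sa[3] * y[9]
        v_pa = pa[2] * (y[11] - pa[0] * y[13]) + pa[3] * y[12]
        out[k, 5] = y[0] + y[1] + y[2] + y[3] + v_sa + v_pa + y[14] + y[15]
        for i in range(16):
            if not np.isfinite(y[i]):
                return k, y
        for i in range(4):
            if y[i] < 0.0:
                return k, y
        for s in range(n_sub):
            y = rk4_step(t + s * dt, y, dt, chambers, valves, sa, pa, ven, T,
                         rsa_segs, csa1_segs)
    return -1, y
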