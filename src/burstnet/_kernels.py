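"""Numba-jitted fixed-step integration kernels for the two network models.

These loops are the hot paths of the package (parameter sweeps integrate
tens of millions of steps); they implement exactly the same Heun/Euler
rules as :func:`burstnet.core_numerics.integrate_fixed_step`, specialised
to the two vector fields. Agreement between a kernel step and the generic
integrator is asserted in the test suite.

Biophysical parameter vectors use the fixed layout in ``PVEC_FIELDS``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Layout of the parameter vector handed to the biophysical kernels.
PVEC_FIELDS = (
    "V_K", "V_l", "V_Ca", "g_K", "g_l", "g_Ca", "g_kCa", "g_sCa",
    "c", "v1", "v2", "v3", "v4", "v5", "v6", "phi", "tau_n",
    "eps", "mu", "Ca0", "tau_w_form",
)
TAU_W_ML_CANONICAL = 0.0  # tau_w = 1/cosh((V - v3)/(2 v4))
TAU_W_PAPER_LITERAL = 1.0  # tau_w = 0.5 (1 + tanh((V - v3)/(2 v2)))


@njit(cache=False)
def _biophys_derivs(V, w, Ca, ng, s, drives, p, K, beta, v_th,
                    coupling_sign, synapse_ode, dV, dw, dCa, dn, ds):
    """Derivatives of the coupled burster population; returns the mean
    synaptic action S actually used in the coupling."""
    N = V.shape[0]
    V_K = p[0]; V_l = p[1]; V_Ca = p[2]
    g_K = p[3]; g_l = p[4]; g_Ca = p[5]; g_kCa = p[6]; g_sCa = p[7]
    c = p[8]; v1 = p[9]; v2 = p[10]; v3 = p[11]; v4 = p[12]
    v5 = p[13]; v6 = p[14]; phi = p[15]; tau_n = p[16]
    eps = p[17]; mu = p[18]; Ca0 = p[19]; tau_w_form = p[20]

    # mean synaptic action
    S = 0.0
    if K != 0.0 or synapse_ode:
        if synapse_ode:
            for i in range(N):
                S += s[i]
        else:
            for i in range(N):
                S += beta / (1.0 + beta + np.exp(-V[i] / 2.0))
        S /= N

    for i in range(N):
        Vi = V[i]
        m_inf = 0.5 * (1.0 + np.tanh((Vi - v1) / v2))
        w_inf = 0.5 * (1.0 + np.tanh((Vi - v3) / v4))
        n_inf = 0.5 * (1.0 + np.tanh((Vi - v5) / v6))
        if tau_w_form == TAU_W_PAPER_LITERAL:
            tau_w = 0.5 * (1.0 + np.tanh((Vi - v3) / (2.0 * v2)))
        else:
            tau_w = 1.0 / np.cosh((Vi - v3) / (2.0 * v4))
        I_Ca = (g_Ca * m_inf + g_sCa * ng[i]) * (Vi - V_Ca)
        z = Ca[i] / (Ca[i] + Ca0)
        coup = coupling_sign * K * S * (Vi - v_th)
        dV[i] = (drives[i] - I_Ca - (g_K * w[i] + g_kCa * z) * (Vi - V_K)
                 - g_l * (Vi - V_l) + coup) / c
        dw[i] = phi * (w_inf - w[i]) / tau_w
        dCa[i] = eps * (-mu * I_Ca - Ca[i])
        dn[i] = eps * (n_inf - ng[i]) / tau_n
        if synapse_ode:
            a = 1.0 / (1.0 + np.exp(-Vi / 2.0))
            ds[i] = a * (1.0 - s[i]) - s[i] / beta
    return S


@njit(cache=False)
def biophys_net_integrate(V0, w0, Ca0_, n0, s0, drives, p, K, beta, v_th,
                          coupling_sign, synapse_ode, dt, n_steps,
                          record_every, use_heun, record_all):
    """Integrate the all-to-all burster network with mean-field coupling.

    Returns thinned recordings ``(V_rec, S_rec, w_rec, Ca_rec, n_rec,
    s_rec, blowup_step)``; ``blowup_step >= 0`` flags the first step at
    which a non-finite membrane potential appeared (recording truncated).
    When ``record_all`` is false the gating/calcium/synapse recordings are
    1x1 placeholders.
    """
    N = V0.shape[0]
    n_rec = n_steps // record_every + 1
    V_rec = np.empty((n_rec, N))
    S_rec = np.empty(n_rec)
    if record_all:
        w_rec = np.empty((n_rec, N))
        Ca_rec = np.empty((n_rec, N))
        ng_rec = np.empty((n_rec, N))
        s_rec = np.empty((n_rec, N)) if synapse_ode else np.empty((1, 1))
    else:
        w_rec = np.empty((1, 1))
        Ca_rec = np.empty((1, 1))
        ng_rec = np.empty((1, 1))
        s_rec = np.empty((1, 1))

    V = V0.copy(); w = w0.copy(); Ca = Ca0_.copy(); ng = n0.copy(); s = s0.copy()
    dV1 = np.empty(N); dw1 = np.empty(N); dCa1 = np.empty(N); dn1 = np.empty(N); ds1 = np.empty(N)
    dV2 = np.empty(N); dw2 = np.empty(N); dCa2 = np.empty(N); dn2 = np.empty(N); ds2 = np.empty(N)
    Vp = np.empty(N); wp = np.empty(N); Cap = np.empty(N); ngp = np.empty(N); sp = np.empty(N)

    S = _biophys_derivs(V, w, Ca, ng, s, drives, p, K, beta, v_th,
                        coupling_sign, synapse_ode, dV1, dw1, dCa1, dn1, ds1)
    if not synapse_ode:
        S = 0.0
        for i in range(N):
            S += beta / (1.0 + beta + np.exp(-V[i] / 2.0))
        S /= N
    V_rec[0] = V; S_rec[0] = S
    if record_all:
        w_rec[0] = w; Ca_rec[0] = Ca; ng_rec[0] = ng
        if synapse_ode:
            s_rec[0] = s
    r = 1
    blowup = -1
    for step in range(1, n_steps + 1):
        _biophys_derivs(V, w, Ca, ng, s, drives, p, K, beta, v_th,
                        coupling_sign, synapse_ode, dV1, dw1, dCa1, dn1, ds1)
        if use_heun:
            for i in range(N):
                Vp[i] = V[i] + dt * dV1[i]
                wp[i] = w[i] + dt * dw1[i]
                Cap[i] = Ca[i] + dt * dCa1[i]
                ngp[i] = ng[i] + dt * dn1[i]
                if synapse_ode:
                    sp[i] = s[i] + dt * ds1[i]
            _biophys_derivs(Vp, wp, Cap, ngp, sp, drives, p, K, beta, v_th,
                            coupling_sign, synapse_ode, dV2, dw2, dCa2, dn2, ds2)
            for i in range(N):
                V[i] += 0.5 * dt * (dV1[i] + dV2[i])
                w[i] += 0.5 * dt * (dw1[i] + dw2[i])
                Ca[i] += 0.5 * dt * (dCa1[i] + dCa2[i])
                ng[i] += 0.5 * dt * (dn1[i] + dn2[i])
                if synapse_ode:
                    s[i] += 0.5 * dt * (ds1[i] + ds2[i])
        else:
            for i in range(N):
                V[i] += dt * dV1[i]
                w[i] += dt * dw1[i]
                Ca[i] += dt * dCa1[i]
                ng[i] += dt * dn1[i]
                if synapse_ode:
                    s[i] += dt * ds1[i]
        # gating variables live in [0,1], calcium is non-negative
        for i in range(N):
            if w[i] < 0.0:
                w[i] = 0.0
            elif w[i] > 1.0:
                w[i] = 1.0
            if ng[i] < 0.0:
                ng[i] = 0.0
            elif ng[i] > 1.0:
                ng[i] = 1.0
            if Ca[i] < 0.0:
                Ca[i] = 0.0
            if synapse_ode:
                if s[i] < 0.0:
                    s[i] = 0.0
                elif s[i] > 1.0:
                    s[i] = 1.0
        ok = True
        for i in range(N):
            if not np.isfinite(V[i]):
                ok = False
        if not ok:
            blowup = step
            break
        if step % record_every == 0:
            S = 0.0
            if synapse_ode:
                for i in range(N):
                    S += s[i]
            else:
                for i in range(N):
                    S += beta / (1.0 + beta + np.exp(-V[i] / 2.0))
            S /= N
            V_rec[r] = V
            S_rec[r] = S
            if record_all:
                w_rec[r] = w; Ca_rec[r] = Ca; ng_rec[r] = ng
                if synapse_ode:
                    s_rec[r] = s
            r += 1
    return V_rec[:r], S_rec[:r], w_rec[:min(r, w_rec.shape[0])], \
        Ca_rec[:min(r, Ca_rec.shape[0])], ng_rec[:min(r, ng_rec.shape[0])], \
        s_rec[:min(r, s_rec.shape[0])], blowup


@njit(cache=False)
def _phase_derivs(theta, drives, n_sub, K, beta, v_th, exclude_self,
                  gamma_sign, out):
    """Drift of the mean-field coupled phase-burster network.

    Per neuron: F(theta_i) - Gamma_i sin(theta_i)(cos(theta_i) - v_th) with
    F(theta) = I_i - cos(theta) - cos(theta/n) and Gamma_i the mean synaptic
    field (optionally excluding the neuron's own term). Returns the
    full-sum Gamma for recording.
    """
    N = theta.shape[0]
    trans = np.empty(N)
    tot = 0.0
    for i in range(N):
        cth = np.cos(theta[i])
        tr = beta / (1.0 + beta + np.exp(-gamma_sign * cth / 2.0))
        trans[i] = tr
        tot += tr
    for i in range(N):
        th = theta[i]
        if exclude_self and N > 1:
            g = K * (tot - trans[i]) / N
        else:
            g = K * tot / N
        out[i] = (drives[i] - np.cos(th) - np.cos(th / n_sub)
                  - g * np.sin(th) * (np.cos(th) - v_th))
    return K * tot / N


@njit(cache=False)
def phase_net_integrate(theta0, drives, n_sub, K, beta, v_th, exclude_self,
                        gamma_sign, dt, n_steps, record_every, use_heun):
    """Integrate the phase-burster network; phases evolve unwrapped.

    Returns ``(theta_rec, gamma_rec)`` thinned by ``record_every``. The
    flow is bounded (|dtheta/dt| <= |I| + 2 + K beta/(1+beta)), so no
    blow-up monitoring is needed.
    """
    N = theta0.shape[0]
    n_rec = n_steps // record_every + 1
    th_rec = np.empty((n_rec, N))
    gam_rec = np.empty(n_rec)
    theta = theta0.copy()
    d1 = np.empty(N)
    d2 = np.empty(N)
    tmp = np.empty(N)
    gam_rec[0] = _phase_derivs(theta, drives, n_sub, K, beta, v_th,
                               exclude_self, gamma_sign, d1)
    th_rec[0] = theta
    r = 1
    for step in range(1, n_steps + 1):
        gam = _phase_derivs(theta, drives, n_sub, K, beta, v_th,
                            exclude_self, gamma_sign, d1)
        if use_heun:
            for i in range(N):
                tmp[i] = theta[i] + dt * d1[i]
            _phase_derivs(tmp, drives, n_sub, K, beta, v_th,
                          exclude_self, gamma_sign, d2)
            for i in range(N):
                theta[i] += 0.5 * dt * (d1[i] + d2[i])
        else:
            for i in range(N):
                theta[i] += dt * d1[i]
        if step % record_every == 0:
            th_rec[r] = theta
            # Gamma at the recorded state
            gam_rec[r] = _phase_derivs(theta, drives, n_sub, K, beta, v_th,
                                       exclude_self, gamma_sign, d2)
            r += 1
    return th_rec[:r], gam_rec[:r]
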