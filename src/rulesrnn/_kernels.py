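"""Compiled inner loops for simulation and backpropagation through time.

The per-step updates here mirror :func:`rulesrnn.network.srnn_step` exactly
(same operation order, float64 throughout); they exist only to remove the
per-step interpreter overhead of rolling a 400-step trial. The backward
kernel implements the reverse-mode adjoint recursion of the discrete
dynamics with the SuperSpike fast-sigmoid pseudo-derivative standing in for
the threshold derivative, treating the reset and refractory gates as
constants of the forward trajectory.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def forward_hard(
    inp,            # (5, T, B) input spikes
    W_eff,          # (N, N) signed recurrent matrix
    W_in,           # (N, 5)
    W_out,          # (n_out, n_exc)
    n_exc,
    alpha_m, alpha_s, phi_a, r_eff, v_rest, v_th, psi, beta,
    sfa,            # (N,) 0/1 adaptation assignment
    n_ref,
    a_dm, a_ds, r_dec,
    V0,             # (N, B) initial membrane potentials
    Ib0,            # (N, B) baseline currents
    sd_m, sd_b,     # per-step noise SDs (mV, nA)
    noise_m,        # (T, N, B) float32 standard normals, (1,1,1) when disabled
    noise_b,
    use_noise,
    record_currents,
):
    T = inp.shape[1]
    B = inp.shape[2]
    N = W_eff.shape[0]
    n_out = W_out.shape[0]

    dt_ = inp.dtype
    V = V0.copy()
    I = np.zeros((N, B), dtype=dt_)
    A = np.zeros((N, B), dtype=dt_)
    refrac = np.zeros((N, B), dtype=np.int64)
    I_base = Ib0.copy()
    S_prev = np.zeros((N, B), dtype=dt_)
    Id = np.zeros((n_out, B), dtype=dt_)
    Vd = np.zeros((n_out, B), dtype=dt_)

    S = np.empty((T, N, B), dtype=dt_)
    sg = np.empty((T, N, B), dtype=dt_)
    carry = np.empty((T, N, B), dtype=dt_)
    elig = np.empty((T, N, B), dtype=dt_)
    dec_V = np.empty((T, n_out, B), dtype=dt_)
    Id_tr = np.empty((T, n_out, B), dtype=dt_)
    cur = (np.empty((T, N, B), dtype=dt_) if record_currents
           else np.empty((1, 1, 1), dtype=dt_))

    one_m_am = 1.0 - alpha_m
    for t in range(T):
        rec_in = W_eff @ S_prev
        ext_in = W_in @ np.ascontiguousarray(inp[:, t, :])
        for i in range(N):
            a_s = alpha_s[i]
            psi_i = psi * sfa[i]
            for b in range(B):
                I[i, b] = a_s * I[i, b] + rec_in[i, b] + ext_in[i, b] + I_base[i, b]
                if use_noise:
                    I_base[i, b] += sd_b * noise_b[t, i, b]
                ok = refrac[i, b] == 0
                if ok:
                    v_pre = v_rest + alpha_m * (V[i, b] - v_rest) \
                        + one_m_am * r_eff * I[i, b]
                    if use_noise:
                        v_pre += sd_m * noise_m[t, i, b]
                else:
                    v_pre = v_rest
                A[i, b] = phi_a * A[i, b] + (1.0 - phi_a) * S_prev[i, b]
                v_thr = v_th + psi_i * A[i, b]
                fired = ok and (v_pre >= v_thr)
                s = 1.0 if fired else 0.0
                S[t, i, b] = s
                dv = v_pre - v_thr
                if dv < 0.0:
                    dv = -dv
                g = 1.0 / (1.0 + beta * dv * 1e-3)
                sg[t, i, b] = g * g if ok else 0.0
                carry[t, i, b] = (1.0 - s) if ok else 0.0
                elig[t, i, b] = 1.0 if ok else 0.0
                if fired:
                    V[i, b] = v_rest
                    refrac[i, b] = n_ref
                else:
                    V[i, b] = v_pre
                    if refrac[i, b] > 0:
                        refrac[i, b] -= 1
                if record_currents:
                    cur[t, i, b] = I[i, b]
        dec_in = W_out @ np.ascontiguousarray(S[t, :n_exc, :])
        for o in range(n_out):
            for b in range(B):
                Id[o, b] = a_ds * Id[o, b] + dec_in[o, b]
                Vd[o, b] = a_dm * Vd[o, b] + (1.0 - a_dm) * r_dec * Id[o, b]
                dec_V[t, o, b] = Vd[o, b]
                Id_tr[t, o, b] = Id[o, b]
        S_prev = np.ascontiguousarray(S[t])
    return S, sg, carry, elig, dec_V, Id_tr, cur


@njit(cache=True)
def backward_core(
    S, sg, carry, elig,      # (T, N, B) forward traces
    inp,                     # (5, T, B)
    dec_V,                   # (T, n_out, B)
    y,                       # (n_out, B) targets
    W_eff_T,                 # (N, N)
    W_out, W_out_T,
    n_exc,
    alpha_m, alpha_s, phi_a, r_eff, psi_sfa,    # psi_sfa: (N,) psi * mask
    a_dm, a_ds, r_dec,
    scored,
    g_reg_bin,               # (n_bin,) dL/dS per spike, from the rate penalty
    nb_steps,
    sg_gain,                 # dampening of the pseudo-derivative (1 = exact)
):
    T, N, B = S.shape
    n_out = W_out.shape[0]
    dt_ = S.dtype

    # decoder adjoint sweep
    gId_steps = np.empty((T, n_out, B), dtype=dt_)
    gW_out = np.zeros_like(W_out)
    gVd = np.zeros((n_out, B), dtype=dt_)
    gId = np.zeros((n_out, B), dtype=dt_)
    denom = float(scored * B)
    for t in range(T - 1, -1, -1):
        for o in range(n_out):
            for b in range(B):
                gv = a_dm * gVd[o, b]
                if t >= T - scored:
                    gv += (dec_V[t, o, b] - y[o, b]) / denom
                gVd[o, b] = gv
                gId[o, b] = (1.0 - a_dm) * r_dec * gv + a_ds * gId[o, b]
                gId_steps[t, o, b] = gId[o, b]
        gW_out += np.ascontiguousarray(gId) @ np.ascontiguousarray(S[t, :n_exc, :]).T

    # recurrent adjoint sweep
    gM_eff = np.zeros((N, N), dtype=dt_)
    gW_in = np.zeros((N, 5), dtype=dt_)
    gVpre_next = np.zeros((N, B), dtype=dt_)
    elig_next = np.ones((N, B), dtype=dt_)
    gI_next = np.zeros((N, B), dtype=dt_)
    gA_next = np.zeros((N, B), dtype=dt_)
    one_m_am = 1.0 - alpha_m
    for t in range(T - 1, -1, -1):
        gS = W_eff_T @ gI_next
        dec_part = W_out_T @ np.ascontiguousarray(gId_steps[t])
        reg = g_reg_bin[t // nb_steps]
        gI = np.empty((N, B), dtype=dt_)
        for i in range(N):
            a_s = alpha_s[i]
            ps = psi_sfa[i]
            for b in range(B):
                gs = gS[i, b] + (1.0 - phi_a) * gA_next[i, b] + reg
                if i < n_exc:
                    gs += dec_part[i, b]
                sg_d = sg_gain * sg[t, i, b]
                gvp = sg_d * gs \
                    + alpha_m * gVpre_next[i, b] * elig_next[i, b] * carry[t, i, b]
                gA_next[i, b] = -ps * sg_d * gs + phi_a * gA_next[i, b]
                gI[i, b] = one_m_am * r_eff * gvp + a_s * gI_next[i, b]
                gVpre_next[i, b] = gvp
        if t > 0:
            gM_eff += gI @ np.ascontiguousarray(S[t - 1]).T
        gW_in += gI @ np.ascontiguousarray(inp[:, t, :]).T
        gI_next = gI
        elig_next = np.ascontiguousarray(elig[t])
    return gM_eff, gW_in, gW_out
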