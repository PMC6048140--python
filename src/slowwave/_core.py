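"""Compiled inner loop of the network integrator.

Numerically identical (up to float op ordering) to the pure-numpy engine in
``simulator.py``; one step comprises spike delivery, the gating RK2, two
float32 matrix products that supply the synaptic drive for both RK stages
of every neuron, the membrane RK2, and threshold/reset handling.  The
first call compiles; subsequent calls in the same process are fast.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["integrate"]


@njit(cache=True)
def integrate(
    J_exc,            # (N, NE) float32
    J_inh,            # (N, NI) float32
    g_exc,            # (nge, n_exc_r) group conductance weights
    g_inh,            # (ngi, n_inh_r)
    VR_exc,           # (nge,)
    VR_inh,           # (ngi,)
    itup_E, itdn_E,   # (n_exc_r,)
    itup_I, itdn_I,   # (n_inh_r,)
    Jin_scaled,       # (NE,) gamma_input * gain * J_input
    ev_step,          # (n_ev,) sorted afferent event steps
    ev_nid,           # (n_ev,) afferent event neuron ids
    n_steps, dt, delay_steps, NE, NI,
    C, gL, VL, DT, VT, Vreset, Vpeak, tau_u, a_u, b_u, t_ref,
    gammaE, gammaI, tin_up, tin_dn,
    noise_sd_step, noise_seed,
    rec_every, rec_ids, traces,
):
    N = NE + NI
    nge = g_exc.shape[0]
    ngi = g_inh.shape[0]
    n_exc_r = g_exc.shape[1]
    n_inh_r = g_inh.shape[1]

    V = np.full(N, VL)
    u = np.zeros(N)
    t_last = np.full(N, -1e12)
    xE = np.zeros((n_exc_r, NE)); sE = np.zeros((n_exc_r, NE))
    xI = np.zeros((n_inh_r, NI)); sI = np.zeros((n_inh_r, NI))
    xin = np.zeros(NE); sin = np.zeros(NE); sin0 = np.zeros(NE)

    ring = np.zeros((delay_steps, N), np.uint8)
    D_exc = np.zeros((NE, 2 * nge), np.float32)
    D_inh = np.zeros((NI, 2 * ngi), np.float32)

    cap = 1 << 16
    sp_ids = np.empty(cap, np.int32)
    sp_ts = np.empty(cap, np.float64)
    n_sp = 0

    if noise_sd_step > 0.0:
        np.random.seed(noise_seed)

    ev_ptr = 0
    n_ev = ev_step.shape[0]
    blow_up_t = -1.0

    for i in range(n_steps):
        t = i * dt
        slot = i % delay_steps
        # recurrent spike delivery (emitted delay_steps ago)
        for j in range(N):
            if ring[slot, j]:
                if j < NE:
                    for r in range(n_exc_r):
                        xE[r, j] += itup_E[r]
                else:
                    for r in range(n_inh_r):
                        xI[r, j - NE] += itup_I[r]
                ring[slot, j] = 0
        # afferent delivery
        while ev_ptr < n_ev and ev_step[ev_ptr] == i:
            xin[ev_nid[ev_ptr]] += 1.0 / tin_up
            ev_ptr += 1

        # stage-1 drive columns (start-of-step gating)
        for c in range(nge):
            for j in range(NE):
                acc = 0.0
                for r in range(n_exc_r):
                    acc += g_exc[c, r] * sE[r, j]
                D_exc[j, c] = acc
        for c in range(ngi):
            for j in range(NI):
                acc = 0.0
                for r in range(n_inh_r):
                    acc += g_inh[c, r] * sI[r, j]
                D_inh[j, c] = acc

        # gating RK2 (decay + saturating rise; impulses already applied)
        for r in range(n_exc_r):
            for j in range(NE):
                x0 = xE[r, j]; s0 = sE[r, j]
                dx1 = -x0 * itup_E[r]
                ds1 = x0 * (1.0 - s0) - s0 * itdn_E[r]
                x1 = x0 + dt * dx1
                s1 = s0 + dt * ds1
                dx2 = -x1 * itup_E[r]
                ds2 = x1 * (1.0 - s1) - s1 * itdn_E[r]
                xE[r, j] = x0 + 0.5 * dt * (dx1 + dx2)
                sE[r, j] = s0 + 0.5 * dt * (ds1 + ds2)
        for r in range(n_inh_r):
            for j in range(NI):
                x0 = xI[r, j]; s0 = sI[r, j]
                dx1 = -x0 * itup_I[r]
                ds1 = x0 * (1.0 - s0) - s0 * itdn_I[r]
                x1 = x0 + dt * dx1
                s1 = s0 + dt * ds1
                dx2 = -x1 * itup_I[r]
                ds2 = x1 * (1.0 - s1) - s1 * itdn_I[r]
                xI[r, j] = x0 + 0.5 * dt * (dx1 + dx2)
                sI[r, j] = s0 + 0.5 * dt * (ds1 + ds2)
        for j in range(NE):
            x0 = xin[j]; s0 = sin[j]
            sin0[j] = s0
            dx1 = -x0 / tin_up
            ds1 = x0 * (1.0 - s0) - s0 / tin_dn
            x1 = x0 + dt * dx1
            s1 = s0 + dt * ds1
            dx2 = -x1 / tin_up
            ds2 = x1 * (1.0 - s1) - s1 / tin_dn
            xin[j] = x0 + 0.5 * dt * (dx1 + dx2)
            sin[j] = s0 + 0.5 * dt * (ds1 + ds2)

        # stage-2 drive columns (end-of-step gating)
        for c in range(nge):
            for j in range(NE):
                acc = 0.0
                for r in range(n_exc_r):
                    acc += g_exc[c, r] * sE[r, j]
                D_exc[j, nge + c] = acc
        for c in range(ngi):
            for j in range(NI):
                acc = 0.0
                for r in range(n_inh_r):
                    acc += g_inh[c, r] * sI[r, j]
                D_inh[j, ngi + c] = acc

        P = np.dot(J_exc, D_exc)  # (N, 2*nge) float32
        Q = np.dot(J_inh, D_inh)  # (N, 2*ngi)

        # membrane RK2 per neuron
        for j in range(N):
            Iin1 = Jin_scaled[j] * sin0[j] if j < NE else 0.0
            Iin2 = Jin_scaled[j] * sin[j] if j < NE else 0.0
            if noise_sd_step > 0.0:
                eta = np.random.normal(0.0, noise_sd_step)
                Iin1 += eta
                Iin2 += eta
            V0 = V[j]; u0 = u[j]
            # stage 1
            Vc = V0 if V0 < Vpeak else Vpeak
            z = (t - t_last[j]) / t_ref
            if z > 6.0:
                z = 6.0
            ref = -np.expm1(-(z**20))
            ex = gL * DT * np.exp((Vc - VT) / DT) * ref
            Isyn = 0.0
            for c in range(nge):
                Isyn += gammaE * P[j, c] * (VR_exc[c] - Vc)
            for c in range(ngi):
                Isyn += gammaI * Q[j, c] * (VR_inh[c] - Vc)
            k1V = (-gL * (Vc - VL) + ex - u0 + Isyn + Iin1) / C
            k1u = (-u0 + a_u * (Vc - VL)) / tau_u
            V1 = V0 + dt * k1V
            u1 = u0 + dt * k1u
            # stage 2
            Vc = V1 if V1 < Vpeak else Vpeak
            z = (t + dt - t_last[j]) / t_ref
            if z > 6.0:
                z = 6.0
            ref = -np.expm1(-(z**20))
            ex = gL * DT * np.exp((Vc - VT) / DT) * ref
            Isyn = 0.0
            for c in range(nge):
                Isyn += gammaE * P[j, nge + c] * (VR_exc[c] - Vc)
            for c in range(ngi):
                Isyn += gammaI * Q[j, ngi + c] * (VR_inh[c] - Vc)
            k2V = (-gL * (Vc - VL) + ex - u1 + Isyn + Iin2) / C
            k2u = (-u1 + a_u * (Vc - VL)) / tau_u
            Vn = V0 + 0.5 * dt * (k1V + k2V)
            un = u0 + 0.5 * dt * (k1u + k2u)

            if Vn >= Vpeak:
                denom = Vn - V0
                frac = (Vpeak - V0) / denom if denom > 0 else 1.0
                if frac < 0.0:
                    frac = 0.0
                elif frac > 1.0:
                    frac = 1.0
                ts = t + dt * frac
                if ts - t_last[j] >= t_ref:
                    if n_sp >= cap:
                        cap *= 2
                        tmp_i = np.empty(cap, np.int32)
                        tmp_t = np.empty(cap, np.float64)
                        tmp_i[:n_sp] = sp_ids[:n_sp]
                        tmp_t[:n_sp] = sp_ts[:n_sp]
                        sp_ids = tmp_i
                        sp_ts = tmp_t
                    sp_ids[n_sp] = j
                    sp_ts[n_sp] = ts
                    n_sp += 1
                    t_last[j] = ts
                    Vn = Vreset
                    un = un + b_u
                    ring[(i + delay_steps) % delay_steps, j] = 1
                else:
                    Vn = Vpeak  # refractory: hold at ceiling, spike later
            if not np.isfinite(Vn):
                blow_up_t = t + dt
            V[j] = Vn
            u[j] = un

        if blow_up_t >= 0.0:
            break
        if rec_ids.shape[0] > 0 and (i + 1) % rec_every == 0:
            row = (i + 1) // rec_every - 1
            if row < traces.shape[0]:
                for k in range(rec_ids.shape[0]):
                    traces[row, k] = V[rec_ids[k]]

    return sp_ids[:n_sp], sp_ts[:n_sp], blow_up_t
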