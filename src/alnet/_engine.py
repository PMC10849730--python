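"""Numba inner loop: fixed-step RK4 integration of the coupled neuron and
synapse system with event handling.

Within each step the full coupled vector field (voltages, gating variables,
calcium, synaptic O/R/G) is advanced by one classical RK4 step; spike events
are then detected on the updated voltages (upward 0 mV crossing, 1 ms
lockout), cholinergic transmitter pulses start, valence-gated facilitation
updates are applied through the pre/post adjacency, and facilitation decays
by one step's exponential factor.  The ordering means a facilitation update
sees each same-step spike exactly once.

Two exact algebraic reductions keep the loop fast: (i) receptor/effector
states (O, R, G) follow identical ODEs for every connection sharing a
presynaptic neuron and are therefore integrated once per presynaptic neuron,
while the per-connection conductance g*F scales the current; (ii) gating
steady states and relaxation times are read from a dense voltage-grid lookup
table (0.05 mV spacing, linear interpolation) built from the exact kinetics
functions, with interpolation error far below the integration error at
dt = 0.04 ms.
"""

import math

import numpy as np
from numba import njit

from .kinetics import a_h, a_m, h_m, k_m, na_h, na_m, t_h, t_m

# calcium dynamics
CA_INF = 2.4e-4
A_CA = 5.2e-5
TAU_CA = 5.0
# reversals (mV)
ENA, EKREV, ECA, EH = 50.0, -95.0, 140.0, -43.0
EL, EKL = -70.0, -95.0
EGABA, EACH, EKS = -70.0, 0.0, -95.0
# fast synapse rates (1/ms)
AL_GABA, BE_GABA = 10.0, 0.2
AL_ACH, BE_ACH = 1.0, 0.2
ACH_AMP, ACH_TMAX = 0.5, 0.3
V0_GABA, SIG_GABA = -20.0, 1.5
# slow synapse cascade
R1, R2, R3, R4, KSLOW = 0.5, 0.0013, 0.1, 0.033, 100.0
# spike detection
THRESHOLD, REFRACTORY = 0.0, 1.0

# kinetics lookup table: columns (inf, tau) per gate in the order
# Na_m, Na_h, K_m, A_m, A_h, T_m, T_h, h_m
VMIN, VMAX, DV = -150.0, 100.0, 0.05
_GATE_FNS = (na_m, na_h, k_m, a_m, a_h, t_m, t_h, h_m)


def _build_table():
    v = np.arange(VMIN, VMAX + DV / 2, DV)
    tab = np.empty((v.size, 16))
    for c, fn in enumerate(_GATE_FNS):
        for i, vi in enumerate(v):
            inf, tau = fn(vi)
            tab[i, 2 * c] = inf
            tab[i, 2 * c + 1] = tau
    return tab


KINETICS_TABLE = _build_table()
_INV_DV = 1.0 / DV
_NROW = KINETICS_TABLE.shape[0]


@njit(cache=True, fastmath=True)
def _envelope(trel, tau_r, tau_d, dur):
    if trel < 0.0:
        return 0.0
    norm = 1.0 - math.exp(-dur / tau_r)
    if trel < dur:
        return (1.0 - math.exp(-trel / tau_r)) / norm
    return math.exp(-(trel - dur) / tau_d)


@njit(cache=True, fastmath=True)
def _derivs(t, env_amp, V, gate, ca, Og, Oa, Rs, Gs,
            is_pn, cm, gl, gkl, gch, area,
            pre, post, g, F, n_gaba, n_ach, last_spike, profile, noise,
            tab, dV, dgate, dca, dOg, dOa, dRs, dGs, Isyn, sfac):
    n = V.shape[0]
    m = pre.shape[0]
    slow0 = n_gaba + n_ach
    # per-presynaptic-neuron transmitter and receptor dynamics
    for i in range(n):
        Isyn[i] = 0.0
        Tg = 1.0 / (1.0 + math.exp(-(V[i] - V0_GABA) / SIG_GABA))
        dOg[i] = AL_GABA * (1.0 - Og[i]) * Tg - BE_GABA * Og[i]
        dtsp = t - last_spike[i]
        Ta = ACH_AMP if (dtsp >= 0.0 and dtsp <= ACH_TMAX) else 0.0
        dOa[i] = AL_ACH * (1.0 - Oa[i]) * Ta - BE_ACH * Oa[i]
        dRs[i] = R1 * (1.0 - Rs[i]) * Tg - R2 * Rs[i]
        dGs[i] = R3 * Rs[i] - R4 * Gs[i]
        g4 = Gs[i] * Gs[i] * Gs[i] * Gs[i]
        sfac[i] = g4 / (g4 + KSLOW)
    # per-connection currents
    for s in range(n_gaba):                       # fast GABA_A
        q = post[s]
        Isyn[q] += g[s] * F[s] * Og[pre[s]] * (V[q] - EGABA)
    for s in range(n_gaba, slow0):                # nACh
        q = post[s]
        Isyn[q] += g[s] * Oa[pre[s]] * (V[q] - EACH)
    for s in range(slow0, m):                     # slow inhibition
        q = post[s]
        Isyn[q] += g[s] * F[s] * sfac[pre[s]] * (V[q] - EKS)
    # neuron dynamics
    for i in range(n):
        v = V[i]
        u = (v - VMIN) * _INV_DV
        if u < 0.0:
            u = 0.0
        elif u > _NROW - 2:
            u = float(_NROW - 2)
        r0 = int(u)
        w = u - r0
        ina_m = tab[r0, 0] + w * (tab[r0 + 1, 0] - tab[r0, 0])
        tna_m = tab[r0, 1] + w * (tab[r0 + 1, 1] - tab[r0, 1])
        ina_h = tab[r0, 2] + w * (tab[r0 + 1, 2] - tab[r0, 2])
        tna_h = tab[r0, 3] + w * (tab[r0 + 1, 3] - tab[r0, 3])
        ik_m = tab[r0, 4] + w * (tab[r0 + 1, 4] - tab[r0, 4])
        tk_m = tab[r0, 5] + w * (tab[r0 + 1, 5] - tab[r0, 5])
        it_m = tab[r0, 10] + w * (tab[r0 + 1, 10] - tab[r0, 10])
        tt_m = tab[r0, 11] + w * (tab[r0 + 1, 11] - tab[r0, 11])
        it_h = tab[r0, 12] + w * (tab[r0 + 1, 12] - tab[r0, 12])
        tt_h = tab[r0, 13] + w * (tab[r0 + 1, 13] - tab[r0, 13])
        dgate[i, 0] = (ina_m - gate[i, 0]) / tna_m
        dgate[i, 1] = (ina_h - gate[i, 1]) / tna_h
        dgate[i, 2] = (ik_m - gate[i, 2]) / tk_m
        dgate[i, 5] = (it_m - gate[i, 5]) / tt_m
        dgate[i, 6] = (it_h - gate[i, 6]) / tt_h
        m3 = gate[i, 0] * gate[i, 0] * gate[i, 0]
        n2 = gate[i, 2] * gate[i, 2]
        n4 = n2 * n2
        tm2 = gate[i, 5] * gate[i, 5]
        ina = gch[i, 0] * m3 * gate[i, 1] * (v - ENA)
        ik = gch[i, 1] * n4 * (v - EKREV)
        it = gch[i, 3] * tm2 * gate[i, 6] * (v - ECA)
        iint = ina + ik + it
        if is_pn[i]:
            ia_m = tab[r0, 6] + w * (tab[r0 + 1, 6] - tab[r0, 6])
            ta_m = tab[r0, 7] + w * (tab[r0 + 1, 7] - tab[r0, 7])
            ia_h = tab[r0, 8] + w * (tab[r0 + 1, 8] - tab[r0, 8])
            ta_h = tab[r0, 9] + w * (tab[r0 + 1, 9] - tab[r0, 9])
            ih_m = tab[r0, 14] + w * (tab[r0 + 1, 14] - tab[r0, 14])
            th_m = tab[r0, 15] + w * (tab[r0 + 1, 15] - tab[r0, 15])
            dgate[i, 3] = (ia_m - gate[i, 3]) / ta_m
            dgate[i, 4] = (ia_h - gate[i, 4]) / ta_h
            dgate[i, 7] = (ih_m - gate[i, 7]) / th_m
            a2 = gate[i, 3] * gate[i, 3]
            iint += gch[i, 2] * a2 * a2 * gate[i, 4] * (v - EKREV)
            iint += gch[i, 4] * gate[i, 7] * (v - EH)
        else:
            dgate[i, 3] = 0.0
            dgate[i, 4] = 0.0
            dgate[i, 7] = 0.0
        dca[i] = -A_CA * (it / area[i]) - (ca[i] - CA_INF) / TAU_CA
        istim = profile[i] * env_amp + noise[i]
        dV[i] = (-(gl[i] * (v - EL) + gkl[i] * (v - EKL) + iint + Isyn[i])
                 + istim) / cm[i]


@njit(cache=True, fastmath=True)
def _axpy(out, x, a, d):
    for i in range(x.shape[0]):
        out[i] = x[i] + a * d[i]


@njit(cache=True, fastmath=True)
def _axpy2(out, x, a, d):
    for i in range(x.shape[0]):
        for j in range(8):
            out[i, j] = x[i, j] + a * d[i, j]


@njit(cache=True, fastmath=True)
def run_window(V, gate, ca, Og, Oa, Rs, Gs, last_spike, above,
               is_pn, n_pn, cm, gl, gkl, gch, area,
               pre, post, g, F, plastic, env_reinforced,
               n_gaba, n_ach,
               pre_ptr, pre_idx, post_ptr, post_idx,
               profile, onset, pdur, tau_r, tau_d, pulse_amp,
               noise_sd, noise_seed, t0, n_steps, dt,
               plast_on, valence, dFpre, dFpost,
               decay_fast, decay_slow, forgetting_on,
               tab, spike_neuron, spike_time,
               lfp, lfp_every,
               rec_ids, v_rec):
    """Advance the network by ``n_steps`` RK4 steps from global time ``t0``.

    Mutates all state arrays in place; returns the number of recorded
    spikes (negative on integration failure: -1 - neuron index).
    ``valence``: +1 rewarded, -1 habituated, 0 neutral.
    """
    n = V.shape[0]
    m = pre.shape[0]
    nb = 12 * n
    # one flat buffer block per RK stage: V, ca, Og, Oa, Rs, Gs + gate(8n)
    dV1 = np.empty(n); dV2 = np.empty(n); dV3 = np.empty(n); dV4 = np.empty(n)
    dg1 = np.empty((n, 8)); dg2 = np.empty((n, 8))
    dg3 = np.empty((n, 8)); dg4 = np.empty((n, 8))
    dc1 = np.empty(n); dc2 = np.empty(n); dc3 = np.empty(n); dc4 = np.empty(n)
    dOg1 = np.empty(n); dOg2 = np.empty(n); dOg3 = np.empty(n); dOg4 = np.empty(n)
    dOa1 = np.empty(n); dOa2 = np.empty(n); dOa3 = np.empty(n); dOa4 = np.empty(n)
    dRs1 = np.empty(n); dRs2 = np.empty(n); dRs3 = np.empty(n); dRs4 = np.empty(n)
    dGs1 = np.empty(n); dGs2 = np.empty(n); dGs3 = np.empty(n); dGs4 = np.empty(n)
    tV = np.empty(n); tg = np.empty((n, 8)); tc = np.empty(n)
    tOg = np.empty(n); tOa = np.empty(n); tRs = np.empty(n); tGs = np.empty(n)
    Isyn = np.empty(n)
    sfac = np.empty(n)
    noise = np.zeros(n)

    noise_every = max(1, int(round(1.0 / dt)))
    np.random.seed(noise_seed)
    cap = spike_neuron.shape[0]
    n_spk = 0
    n_rec = rec_ids.shape[0]

    if lfp.shape[0] > 0:
        ssum = 0.0
        for i in range(n_pn):
            ssum += V[i]
        lfp[0] = ssum / n_pn
    for ri in range(n_rec):
        v_rec[ri, 0] = V[rec_ids[ri]]

    for step in range(n_steps):
        t = t0 + step * dt
        if step % noise_every == 0:
            for i in range(n):
                noise[i] = np.random.standard_normal() * noise_sd[i]
        e1 = _envelope(t - onset, tau_r, tau_d, pdur) * pulse_amp
        eh = _envelope(t + 0.5 * dt - onset, tau_r, tau_d, pdur) * pulse_amp
        e2 = _envelope(t + dt - onset, tau_r, tau_d, pdur) * pulse_amp
        h = 0.5 * dt

        _derivs(t, e1, V, gate, ca, Og, Oa, Rs, Gs, is_pn, cm, gl, gkl, gch,
                area, pre, post, g, F, n_gaba, n_ach, last_spike, profile,
                noise, tab, dV1, dg1, dc1, dOg1, dOa1, dRs1, dGs1, Isyn, sfac)
        _axpy(tV, V, h, dV1); _axpy2(tg, gate, h, dg1); _axpy(tc, ca, h, dc1)
        _axpy(tOg, Og, h, dOg1); _axpy(tOa, Oa, h, dOa1)
        _axpy(tRs, Rs, h, dRs1); _axpy(tGs, Gs, h, dGs1)
        _derivs(t + h, eh, tV, tg, tc, tOg, tOa, tRs, tGs, is_pn, cm, gl,
                gkl, gch, area, pre, post, g, F, n_gaba, n_ach, last_spike,
                profile, noise, tab, dV2, dg2, dc2, dOg2, dOa2, dRs2, dGs2,
                Isyn, sfac)
        _axpy(tV, V, h, dV2); _axpy2(tg, gate, h, dg2); _axpy(tc, ca, h, dc2)
        _axpy(tOg, Og, h, dOg2); _axpy(tOa, Oa, h, dOa2)
        _axpy(tRs, Rs, h, dRs2); _axpy(tGs, Gs, h, dGs2)
        _derivs(t + h, eh, tV, tg, tc, tOg, tOa, tRs, tGs, is_pn, cm, gl,
                gkl, gch, area, pre, post, g, F, n_gaba, n_ach, last_spike,
                profile, noise, tab, dV3, dg3, dc3, dOg3, dOa3, dRs3, dGs3,
                Isyn, sfac)
        _axpy(tV, V, dt, dV3); _axpy2(tg, gate, dt, dg3); _axpy(tc, ca, dt, dc3)
        _axpy(tOg, Og, dt, dOg3); _axpy(tOa, Oa, dt, dOa3)
        _axpy(tRs, Rs, dt, dRs3); _axpy(tGs, Gs, dt, dGs3)
        _derivs(t + dt, e2, tV, tg, tc, tOg, tOa, tRs, tGs, is_pn, cm, gl,
                gkl, gch, area, pre, post, g, F, n_gaba, n_ach, last_spike,
                profile, noise, tab, dV4, dg4, dc4, dOg4, dOa4, dRs4, dGs4,
                Isyn, sfac)

        sixth = dt / 6.0
        for i in range(n):
            V[i] += sixth * (dV1[i] + 2.0 * dV2[i] + 2.0 * dV3[i] + dV4[i])
            if not np.isfinite(V[i]):
                return -1 - i
            for j in range(8):
                x = gate[i, j] + sixth * (dg1[i, j] + 2.0 * dg2[i, j]
                                          + 2.0 * dg3[i, j] + dg4[i, j])
                gate[i, j] = min(1.0, max(0.0, x))
            c = ca[i] + sixth * (dc1[i] + 2.0 * dc2[i] + 2.0 * dc3[i] + dc4[i])
            ca[i] = c if c > 0.0 else 0.0
            x = Og[i] + sixth * (dOg1[i] + 2.0 * dOg2[i] + 2.0 * dOg3[i] + dOg4[i])
            Og[i] = min(1.0, max(0.0, x))
            x = Oa[i] + sixth * (dOa1[i] + 2.0 * dOa2[i] + 2.0 * dOa3[i] + dOa4[i])
            Oa[i] = min(1.0, max(0.0, x))
            x = Rs[i] + sixth * (dRs1[i] + 2.0 * dRs2[i] + 2.0 * dRs3[i] + dRs4[i])
            Rs[i] = min(1.0, max(0.0, x))
            x = Gs[i] + sixth * (dGs1[i] + 2.0 * dGs2[i] + 2.0 * dGs3[i] + dGs4[i])
            Gs[i] = x if x > 0.0 else 0.0

        tnew = t + dt
        for i in range(n):
            if V[i] >= THRESHOLD:
                if not above[i]:
                    above[i] = True
                    if tnew - last_spike[i] >= REFRACTORY:
                        last_spike[i] = tnew
                        if n_spk < cap:
                            spike_neuron[n_spk] = i
                            spike_time[n_spk] = tnew
                            n_spk += 1
                        if plast_on:
                            if valence == 1 and dFpre > 0.0:
                                for a_ in range(pre_ptr[i], pre_ptr[i + 1]):
                                    s = pre_idx[a_]
                                    if plastic[s]:
                                        F[s] += dFpre
                                        env_reinforced[s] = True
                            if valence == -1 and dFpost > 0.0:
                                for a_ in range(post_ptr[i], post_ptr[i + 1]):
                                    s = post_idx[a_]
                                    if plastic[s]:
                                        F[s] += dFpost
                                        env_reinforced[s] = True
            else:
                above[i] = False

        if plast_on:
            for s in range(m):
                if plastic[s]:
                    mult = decay_fast
                    if forgetting_on and not env_reinforced[s]:
                        mult = decay_slow
                    F[s] = 1.0 + (F[s] - 1.0) * mult

        if lfp.shape[0] > 0 and (step + 1) % lfp_every == 0:
            ssum = 0.0
            for i in range(n_pn):
                ssum += V[i]
            lfp[(step + 1) // lfp_every] = ssum / n_pn
        for ri in range(n_rec):
            v_rec[ri, step + 1] = V[rec_ids[ri]]

    return n_spk
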