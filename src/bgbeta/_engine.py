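"""Fixed-step RK4 network integration kernel (numba).

The kernel advances every neuron with classical 4th-order Runge-Kutta at a
fixed step h, delivers spikes through per-connection delay ring buffers,
and draws external Poisson input arrival-by-arrival from exponential gaps
(equivalent to per-step Poisson counts, but with one random draw per event
rather than per step).

Conventions
-----------
* All delta-function increments (synaptic jumps, Poisson arrivals) are
  applied at step boundaries: everything scheduled to arrive during
  [t, t+h) is added to the conductances at time t, before the RK4 step.
* A step whose endpoint reaches V_peak is accepted; the spike is
  timestamped at the end of the step, V is reset, w += b, and deliveries
  are scheduled at (end of step) + connection delay.
* Inside the RK4 right-hand side the voltage is clamped at V_peak (and
  the aeif exponential argument capped): the stage values of a blow-up
  step are formally divergent and must not contaminate the adaptation
  current; the accepted endpoint still crosses V_peak and triggers the
  reset.

Each step runs three passes per population block: (0) a scalar pass
consuming due ring-buffer slots and Poisson arrivals (both sparse),
(1) a branch-free integration pass specialized per neuron-model variant
(auto-vectorizable; populations with a refractory period fall back to a
scalar variant that freezes V between spike and release), and (2) a
scalar spike-detection/reset/delivery pass.

Parameter-matrix column layout (one row per population) is defined by
`PAR_COLS`; conductance stage coefficients (columns c2e..cni) are the
exact RK4 propagation factors of the linear decay dg/dt = -g/tau,
precomputed for the chosen h.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

PAR_COLS = (
    "variant",      # 0 aeif, 1 aqif, 2 aqif2
    "C_inv", "E_L", "E_ex", "E_in", "V_th", "I_e", "a", "inv_tau_w",
    "g_L", "Delta_T", "inv_Delta_T", "k", "V_b",
    "V_reset", "V_peak", "b", "t_ref",
    "c2e", "c3e", "c4e", "cne",
    "c2i", "c3i", "c4i", "cni",
)
COL = {name: i for i, name in enumerate(PAR_COLS)}

V_FLOOR = -150.0
EXP_ARG_CAP = 20.0


def stage_coefficients(tau: float, h: float) -> tuple[float, float, float, float]:
    """RK4 stage/update factors for dg/dt = -g/tau over one step h.

    Returns (c2, c3, c4, cn): the stage-2/3/4 conductance multipliers and
    the end-of-step multiplier (the 4th-order Taylor polynomial of
    exp(-h/tau)).
    """
    r = h / tau
    c2 = 1.0 - 0.5 * r
    c3 = 1.0 - 0.5 * r * c2
    c4 = 1.0 - r * c3
    cn = 1.0 - (r / 6.0) * (1.0 + 2.0 * c2 + 2.0 * c3 + c4)
    return c2, c3, c4, cn


@njit(inline="always")
def _dVw(var, V, w, ge, gi, C_inv, E_L, E_ex, E_in, V_th, I_e, a,
         inv_tau_w, g_L, Delta_T, inv_DT, kq, V_b, V_peak):
    # stage voltage clamped at V_peak: keeps the adaptation current and
    # the exponential finite on the (accepted) blow-up step
    if V > V_peak:
        V = V_peak
    I_syn = -ge * (V - E_ex) - gi * (V - E_in)
    if var == 0:
        arg = (V - V_th) * inv_DT
        if arg > EXP_ARG_CAP:
            arg = EXP_ARG_CAP
        I_spk = -g_L * (V - E_L) + g_L * Delta_T * math.exp(arg)
        dw = (-w + a * (V - E_L)) * inv_tau_w
    elif var == 1:
        I_spk = kq * (V - E_L) * (V - V_th)
        dw = (-w + a * (V - E_L)) * inv_tau_w
    else:
        I_spk = kq * (V - E_L) * (V - V_th)
        if V < V_b:
            d = V - V_b
            dw = (-w + a * d * d * d) * inv_tau_w
        else:
            dw = -w * inv_tau_w
    dV = (I_spk + I_syn - w + I_e) * C_inv
    return dV, dw


@njit(cache=True, fastmath=True)
def run_kernel(
    pop_start,        # (P+1,) int64 population block boundaries
    par,              # (P, len(PAR_COLS)) float64
    ext_rate,         # (N,) float64, expected external events per step
    ext_w,            # (N,) float64, external synaptic weight nS
    V, w, g_ex, g_in,           # (N,) float64 state, modified in place
    out_indptr, out_tgt, out_conn,   # global out-edge CSR
    conn_delay,       # (C,) int64 delay in steps
    conn_weight,      # (C,) float64 nS
    conn_is_ex,       # (C,) int8
    ring_len,         # int, > max delay steps + 1
    n_steps,          # int
    h,                # float, ms
    seed,             # int, seeds the kernel RNG
    spike_step,       # (cap,) int32 output
    spike_id,         # (cap,) int32 output
    rec_ids,          # (n_rec,) int64 neurons to trace (may be empty)
    rec_V, rec_ge, rec_gi, rec_w,    # (n_rec, n_steps) float32 traces
):
    """Integrate the network; returns (n_spikes, status).

    status: 0 ok, 1 spike-buffer overflow (partial result),
    2 non-finite state encountered (neuron id in spike_id[0]).
    """
    np.random.seed(seed)
    N = V.shape[0]
    P = pop_start.shape[0] - 1
    cap = spike_step.shape[0]
    n_rec = rec_ids.shape[0]

    # (slot, neuron) layout: the per-step consumption row is contiguous
    buf_ex = np.zeros((ring_len, N))
    buf_in = np.zeros((ring_len, N))
    refr_until = np.full(N, -1.0)
    inv_rate = np.empty(N)
    next_ext = np.empty(N)
    for i in range(N):
        if ext_rate[i] > 0.0:
            inv_rate[i] = 1.0 / ext_rate[i]
            next_ext[i] = np.random.exponential() * inv_rate[i]
        else:
            inv_rate[i] = 0.0
            next_ext[i] = 1.0e18

    nspk = 0
    half = 0.5 * h
    sixth = h / 6.0

    for s in range(n_steps):
        slot = s % ring_len
        s1 = s + 1.0
        t_end = (s + 1) * h
        row_ex = buf_ex[slot]
        row_in = buf_in[slot]

        # pass 0: due synaptic deliveries and Poisson arrivals (sparse)
        for i in range(N):
            bx = row_ex[i]
            if bx != 0.0:
                g_ex[i] += bx
                row_ex[i] = 0.0
            bi = row_in[i]
            if bi != 0.0:
                g_in[i] += bi
                row_in[i] = 0.0
            if next_ext[i] < s1:
                acc = 0.0
                while next_ext[i] < s1:
                    acc += 1.0
                    next_ext[i] += np.random.exponential() * inv_rate[i]
                g_ex[i] += acc * ext_w[i]

        for p in range(P):
            lo = pop_start[p]
            hi = pop_start[p + 1]
            var = int(par[p, 0])
            C_inv = par[p, 1]; E_L = par[p, 2]; E_ex = par[p, 3]
            E_in = par[p, 4]; V_th = par[p, 5]; I_e = par[p, 6]
            a = par[p, 7]; inv_tw = par[p, 8]; g_L = par[p, 9]
            DT = par[p, 10]; inv_DT = par[p, 11]; kq = par[p, 12]
            V_b = par[p, 13]; V_reset = par[p, 14]; V_peak = par[p, 15]
            b = par[p, 16]; t_ref = par[p, 17]
            c2e = par[p, 18]; c3e = par[p, 19]; c4e = par[p, 20]
            cne = par[p, 21]
            c2i = par[p, 22]; c3i = par[p, 23]; c4i = par[p, 24]
            cni = par[p, 25]

            # pass 1: RK4 integration, specialized per variant
            if t_ref > 0.0:
                # general path honouring the refractory freeze of V
                for i in range(lo, hi):
                    ge = g_ex[i]; gi = g_in[i]
                    Vi = V[i]; wi = w[i]
                    frozen = s * h < refr_until[i]
                    d1V, d1w = _dVw(var, Vi, wi, ge, gi, C_inv, E_L, E_ex,
                                    E_in, V_th, I_e, a, inv_tw, g_L, DT,
                                    inv_DT, kq, V_b, V_peak)
                    if frozen:
                        d1V = 0.0
                    d2V, d2w = _dVw(var, Vi + half * d1V, wi + half * d1w,
                                    ge * c2e, gi * c2i, C_inv, E_L, E_ex,
                                    E_in, V_th, I_e, a, inv_tw, g_L, DT,
                                    inv_DT, kq, V_b, V_peak)
                    if frozen:
                        d2V = 0.0
                    d3V, d3w = _dVw(var, Vi + half * d2V, wi + half * d2w,
                                    ge * c3e, gi * c3i, C_inv, E_L, E_ex,
                                    E_in, V_th, I_e, a, inv_tw, g_L, DT,
                                    inv_DT, kq, V_b, V_peak)
                    if frozen:
                        d3V = 0.0
                    d4V, d4w = _dVw(var, Vi + h * d3V, wi + h * d3w,
                                    ge * c4e, gi * c4i, C_inv, E_L, E_ex,
                                    E_in, V_th, I_e, a, inv_tw, g_L, DT,
                                    inv_DT, kq, V_b, V_peak)
                    if frozen:
                        d4V = 0.0
                    V[i] = Vi + sixth * (d1V + 2.0 * d2V + 2.0 * d3V + d4V)
                    w[i] = wi + sixth * (d1w + 2.0 * d2w + 2.0 * d3w + d4w)
                    g_ex[i] = ge * cne
                    g_in[i] = gi * cni
            elif var == 0:      # aeif
                for i in range(lo, hi):
                    ge = g_ex[i]; gi = g_in[i]
                    Vi = V[i]; wi = w[i]

                    Vc = min(Vi, V_peak)
                    ar = min((Vc - V_th) * inv_DT, EXP_ARG_CAP)
                    Is = -g_L * (Vc - E_L) + g_L * DT * math.exp(ar)
                    d1V = (Is - ge * (Vc - E_ex) - gi * (Vc - E_in)
                           - wi + I_e) * C_inv
                    d1w = (-wi + a * (Vc - E_L)) * inv_tw

                    V2 = Vi + half * d1V; w2 = wi + half * d1w
                    Vc = min(V2, V_peak)
                    ar = min((Vc - V_th) * inv_DT, EXP_ARG_CAP)
                    Is = -g_L * (Vc - E_L) + g_L * DT * math.exp(ar)
                    d2V = (Is - ge * c2e * (Vc - E_ex) - gi * c2i * (Vc - E_in)
                           - w2 + I_e) * C_inv
                    d2w = (-w2 + a * (Vc - E_L)) * inv_tw

                    V3 = Vi + half * d2V; w3 = wi + half * d2w
                    Vc = min(V3, V_peak)
                    ar = min((Vc - V_th) * inv_DT, EXP_ARG_CAP)
                    Is = -g_L * (Vc - E_L) + g_L * DT * math.exp(ar)
                    d3V = (Is - ge * c3e * (Vc - E_ex) - gi * c3i * (Vc - E_in)
                           - w3 + I_e) * C_inv
                    d3w = (-w3 + a * (Vc - E_L)) * inv_tw

                    V4 = Vi + h * d3V; w4 = wi + h * d3w
                    Vc = min(V4, V_peak)
                    ar = min((Vc - V_th) * inv_DT, EXP_ARG_CAP)
                    Is = -g_L * (Vc - E_L) + g_L * DT * math.exp(ar)
                    d4V = (Is - ge * c4e * (Vc - E_ex) - gi * c4i * (Vc - E_in)
                           - w4 + I_e) * C_inv
                    d4w = (-w4 + a * (Vc - E_L)) * inv_tw

                    V[i] = Vi + sixth * (d1V + 2.0 * d2V + 2.0 * d3V + d4V)
                    w[i] = wi + sixth * (d1w + 2.0 * d2w + 2.0 * d3w + d4w)
                    g_ex[i] = ge * cne
                    g_in[i] = gi * cni
            elif var == 1:      # aqif
                for i in range(lo, hi):
                    ge = g_ex[i]; gi = g_in[i]
                    Vi = V[i]; wi = w[i]

                    Vc = min(Vi, V_peak)
                    d1V = (kq * (Vc - E_L) * (Vc - V_th)
                           - ge * (Vc - E_ex) - gi * (Vc - E_in)
                           - wi + I_e) * C_inv
                    d1w = (-wi + a * (Vc - E_L)) * inv_tw

                    V2 = Vi + half * d1V; w2 = wi + half * d1w
                    Vc = min(V2, V_peak)
                    d2V = (kq * (Vc - E_L) * (Vc - V_th)
                           - ge * c2e * (Vc - E_ex) - gi * c2i * (Vc - E_in)
                           - w2 + I_e) * C_inv
                    d2w = (-w2 + a * (Vc - E_L)) * inv_tw

                    V3 = Vi + half * d2V; w3 = wi + half * d2w
                    Vc = min(V3, V_peak)
                    d3V = (kq * (Vc - E_L) * (Vc - V_th)
                           - ge * c3e * (Vc - E_ex) - gi * c3i * (Vc - E_in)
                           - w3 + I_e) * C_inv
                    d3w = (-w3 + a * (Vc - E_L)) * inv_tw

                    V4 = Vi + h * d3V; w4 = wi + h * d3w
                    Vc = min(V4, V_peak)
                    d4V = (kq * (Vc - E_L) * (Vc - V_th)
                           - ge * c4e * (Vc - E_ex) - gi * c4i * (Vc - E_in)
                           - w4 + I_e) * C_inv
                    d4w = (-w4 + a * (Vc - E_L)) * inv_tw

                    V[i] = Vi + sixth * (d1V + 2.0 * d2V + 2.0 * d3V + d4V)
                    w[i] = wi + sixth * (d1w + 2.0 * d2w + 2.0 * d3w + d4w)
                    g_ex[i] = ge * cne
                    g_in[i] = gi * cni
            else:               # aqif2: cubic adaptation below the pivot
                for i in range(lo, hi):
                    ge = g_ex[i]; gi = g_in[i]
                    Vi = V[i]; wi = w[i]

                    Vc = min(Vi, V_peak)
                    dd = min(Vc - V_b, 0.0)
                    d1V = (kq * (Vc - E_L) * (Vc - V_th)
                           - ge * (Vc - E_ex) - gi * (Vc - E_in)
                           - wi + I_e) * C_inv
                    d1w = (-wi + a * dd * dd * dd) * inv_tw

                    V2 = Vi + half * d1V; w2 = wi + half * d1w
                    Vc = min(V2, V_peak)
                    dd = min(Vc - V_b, 0.0)
                    d2V = (kq * (Vc - E_L) * (Vc - V_th)
                           - ge * c2e * (Vc - E_ex) - gi * c2i * (Vc - E_in)
                           - w2 + I_e) * C_inv
                    d2w = (-w2 + a * dd * dd * dd) * inv_tw

                    V3 = Vi + half * d2V; w3 = wi + half * d2w
                    Vc = min(V3, V_peak)
                    dd = min(Vc - V_b, 0.0)
                    d3V = (kq * (Vc - E_L) * (Vc - V_th)
                           - ge * c3e * (Vc - E_ex) - gi * c3i * (Vc - E_in)
                           - w3 + I_e) * C_inv
                    d3w = (-w3 + a * dd * dd * dd) * inv_tw

                    V4 = Vi + h * d3V; w4 = wi + h * d3w
                    Vc = min(V4, V_peak)
                    dd = min(Vc - V_b, 0.0)
                    d4V = (kq * (Vc - E_L) * (Vc - V_th)
                           - ge * c4e * (Vc - E_ex) - gi * c4i * (Vc - E_in)
                           - w4 + I_e) * C_inv
                    d4w = (-w4 + a * dd * dd * dd) * inv_tw

                    V[i] = Vi + sixth * (d1V + 2.0 * d2V + 2.0 * d3V + d4V)
                    w[i] = wi + sixth * (d1w + 2.0 * d2w + 2.0 * d3w + d4w)
                    g_ex[i] = ge * cne
                    g_in[i] = gi * cni

            # pass 2: spike detection, reset, delayed delivery
            for i in range(lo, hi):
                Vi = V[i]
                if Vi >= V_peak:
                    if nspk >= cap:
                        return nspk, 1
                    spike_step[nspk] = s + 1
                    spike_id[nspk] = i
                    nspk += 1
                    V[i] = V_reset
                    w[i] += b
                    if t_ref > 0.0:
                        refr_until[i] = t_end + t_ref
                    for e in range(out_indptr[i], out_indptr[i + 1]):
                        c = out_conn[e]
                        tgt = out_tgt[e]
                        dslot = (s + 1 + conn_delay[c]) % ring_len
                        if conn_is_ex[c] == 1:
                            buf_ex[dslot, tgt] += conn_weight[c]
                        else:
                            buf_in[dslot, tgt] += conn_weight[c]
                elif Vi < V_FLOOR:
                    V[i] = V_FLOOR
                elif Vi != Vi or w[i] != w[i]:
                    spike_id[0] = i
                    spike_step[0] = s
                    return nspk, 2

        for r in range(n_rec):
            i = rec_ids[r]
            rec_V[r, s] = V[i]
            rec_ge[r, s] = g_ex[i]
            rec_gi[r, s] = g_in[i]
            rec_w[r, s] = w[i]

    return nspk, 0


@njit(cache=True)
def sample_subsets(ks, n_avail, seed):
    """Concatenated uniform k-subsets of range(n_avail), one per entry
    of ks: a lazily reset partial Fisher-Yates shuffle, O(total edges).

    Used to realize random connectivity (distinct targets per source
    neuron); deterministic given the seed.
    """
    np.random.seed(seed)
    total = 0
    for k in ks:
        total += k
    out = np.empty(total, np.int32)
    vals = np.empty(n_avail, np.int64)
    stamp = np.full(n_avail, -1, np.int64)
    pos = 0
    for si in range(ks.shape[0]):
        k = ks[si]
        for j in range(k):
            r = j + np.random.randint(0, n_avail - j)
            vj = vals[j] if stamp[j] == si else j
            vr = vals[r] if stamp[r] == si else r
            out[pos] = vr
            vals[r] = vj
            stamp[r] = si
            pos += 1
    return out
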