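"""Numba-compiled fixed-step integrators for the HH model populations.

Both kernels use the exponential-Euler scheme: gating variables relax
exactly toward their voltage-dependent steady states with precomputed
per-step decay factors (looked up and linearly interpolated from voltage
tables), and the membrane potential relaxes toward the instantaneous
equilibrium V_inf = (sum g_x E_x + I_inj) / sum g_x with rate g_tot / C_m.
Synaptic conductances are linear filters advanced by exact per-step decay
with impulse increments: a single-time-constant alpha cascade for
excitation and a peak-normalized bi-exponential for inhibition.

Spikes are upward threshold crossings with an absolute lockout.  All
arithmetic is deterministic for fixed inputs.
"""

import numba
import numpy as np
from numba import njit

NB_FLAGS = dict(cache=True, fastmath=False)


@njit(inline="always")
def _interp(lut, row, pos, i0, frac):
    a = lut[row, i0]
    return a + (lut[row, i0 + 1] - a) * frac


@njit(**NB_FLAGS)
def mso_kernel(dt, n_steps, lut, v_min, inv_dv,
               v, m, h, w, r, z_const,
               c_m, g_na, g_klt, g_h, g_leak,
               e_na, e_k, e_h, e_leak, e_e, e_i,
               exc_imp, inh_imp, i_inj,
               tau_e, inh_e1, inh_e2, inh_norm,
               spike_thresh, lockout_steps,
               spike_steps, spike_counts, v_out, record_v):
    n = v.shape[0]
    max_spk = spike_steps.shape[1]
    n_lut = lut.shape[1]
    # alpha cascade states: es (input stage), eg (conductance)
    es = np.zeros(n)
    eg = np.zeros(n)
    ia = np.zeros(n)
    ib = np.zeros(n)
    last_spike = np.full(n, -lockout_steps - 1)
    alpha_c = dt * np.e / tau_e
    exc_decay = np.exp(-dt / tau_e)
    for t in range(n_steps):
        inj = i_inj[t]
        for j in range(n):
            vj = v[j]
            pos = (vj - v_min) * inv_dv
            if pos < 0.0:
                pos = 0.0
            elif pos > n_lut - 2:
                pos = float(n_lut - 2)
            i0 = int(pos)
            frac = pos - i0

            g_e = eg[j]
            g_i = inh_norm * (ia[j] - ib[j])
            m3h = m[j] * m[j] * m[j] * h[j]
            w4 = w[j] * w[j]
            w4 = w4 * w4
            gna = g_na * m3h
            gklt = g_klt * w4 * z_const
            gh = g_h * r[j]
            g_tot = gna + gklt + gh + g_leak + g_e + g_i
            v_inf = (gna * e_na + gklt * e_k + gh * e_h + g_leak * e_leak
                     + g_e * e_e + g_i * e_i + inj) / g_tot
            v_new = v_inf + (vj - v_inf) * np.exp(-dt * g_tot / c_m)

            # gate updates at the pre-step voltage
            m[j] = _interp(lut, 0, pos, i0, frac) + \
                (m[j] - _interp(lut, 0, pos, i0, frac)) * _interp(lut, 1, pos, i0, frac)
            h[j] = _interp(lut, 2, pos, i0, frac) + \
                (h[j] - _interp(lut, 2, pos, i0, frac)) * _interp(lut, 3, pos, i0, frac)
            w[j] = _interp(lut, 4, pos, i0, frac) + \
                (w[j] - _interp(lut, 4, pos, i0, frac)) * _interp(lut, 5, pos, i0, frac)
            r[j] = _interp(lut, 6, pos, i0, frac) + \
                (r[j] - _interp(lut, 6, pos, i0, frac)) * _interp(lut, 7, pos, i0, frac)

            if (v_new >= spike_thresh and vj < spike_thresh
                    and t - last_spike[j] > lockout_steps):
                c = spike_counts[j]
                if c < max_spk:
                    spike_steps[j, c] = t
                    spike_counts[j] = c + 1
                last_spike[j] = t

            v[j] = v_new
            if record_v:
                v_out[t, j] = v_new

            # advance synaptic filters, then add this step's impulses
            eg[j] = exc_decay * (eg[j] + alpha_c * es[j])
            es[j] = exc_decay * es[j] + exc_imp[t, j]
            ia[j] = inh_e2 * ia[j] + inh_imp[t, j]
            ib[j] = inh_e1 * ib[j] + inh_imp[t, j]
    return 0


@njit(**NB_FLAGS)
def gbc_kernel(dt, n_steps, lut, v_min, inv_dv,
               v, m, h, ng, p, w, z, r,
               c_m, g_na, g_kht, g_klt, g_h, g_leak,
               e_na, e_k, e_h, e_leak, e_e,
               exc_imp, i_inj, tau_e,
               spike_thresh, lockout_steps,
               spike_steps, spike_counts, v_out, record_v):
    n = v.shape[0]
    max_spk = spike_steps.shape[1]
    n_lut = lut.shape[1]
    es = np.zeros(n)
    eg = np.zeros(n)
    last_spike = np.full(n, -lockout_steps - 1)
    alpha_c = dt * np.e / tau_e
    exc_decay = np.exp(-dt / tau_e)
    for t in range(n_steps):
        inj = i_inj[t]
        for j in range(n):
            vj = v[j]
            pos = (vj - v_min) * inv_dv
            if pos < 0.0:
                pos = 0.0
            elif pos > n_lut - 2:
                pos = float(n_lut - 2)
            i0 = int(pos)
            frac = pos - i0

            g_e = eg[j]
            m3h = m[j] * m[j] * m[j] * h[j]
            n2 = ng[j] * ng[j]
            w4 = w[j] * w[j]
            w4 = w4 * w4
            gna = g_na * m3h
            gkht = g_kht * (0.85 * n2 + 0.15 * p[j])
            gklt = g_klt * w4 * z[j]
            gh = g_h * r[j]
            g_tot = gna + gkht + gklt + gh + g_leak + g_e
            v_inf = (gna * e_na + (gkht + gklt) * e_k + gh * e_h
                     + g_leak * e_leak + g_e * e_e + inj) / g_tot
            v_new = v_inf + (vj - v_inf) * np.exp(-dt * g_tot / c_m)

            for gi in range(7):
                row = 2 * gi
                x_inf = _interp(lut, row, pos, i0, frac)
                dec = _interp(lut, row + 1, pos, i0, frac)
                if gi == 0:
                    m[j] = x_inf + (m[j] - x_inf) * dec
                elif gi == 1:
                    h[j] = x_inf + (h[j] - x_inf) * dec
                elif gi == 2:
                    ng[j] = x_inf + (ng[j] - x_inf) * dec
                elif gi == 3:
                    p[j] = x_inf + (p[j] - x_inf) * dec
                elif gi == 4:
                    w[j] = x_inf + (w[j] - x_inf) * dec
                elif gi == 5:
                    z[j] = x_inf + (z[j] - x_inf) * dec
                else:
                    r[j] = x_inf + (r[j] - x_inf) * dec

            if (v_new >= spike_thresh and vj < spike_thresh
                    and t - last_spike[j] > lockout_steps):
                c = spike_counts[j]
                if c < max_spk:
                    spike_steps[j, c] = t
                    spike_counts[j] = c + 1
                last_spike[j] = t

            v[j] = v_new
            if record_v:
                v_out[t, j] = v_new

            eg[j] = exc_decay * (eg[j] + alpha_c * es[j])
            es[j] = exc_decay * es[j] + exc_imp[t, j]
    return 0


@njit(**NB_FLAGS)
def enforce_dead_time(times, dead):
    """Keep spikes separated by at least `dead` (same units as times)."""
    out = np.empty_like(times)
    k = 0
    last = -1e30
    for i in range(times.shape[0]):
        t = times[i]
        if t - last >= dead:
            out[k] = t
            k = k + 1
            last = t
    return out[:k]
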