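"""Numba kernel for conductance-based LIF integration.

Fixed-step exponential-Euler update: the membrane equation is solved
exactly over dt with frozen conductances. Excitatory (NMDA) synapses carry
saturating gating variables s in [0, 1] (jump alpha*(1-s) per presynaptic
spike, exponential decay), so recurrent excitation is bounded by the
synaptic maximum conductance; GABA synapses are jump-and-decay. External
drives (injected currents and two Poisson channels, each a saturating
NMDA-like gate per neuron) are piecewise constant over blocks of steps.

Units: time ms, voltage mV, capacitance nF, conductance uS, current nA.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_lif"]

ERR_NONE = 0
ERR_NONFINITE = 1
ERR_OVERFLOW = 2


@njit(cache=True)
def run_lif(
    seed,
    n_steps,
    dt,
    steps_per_block,
    # uniform LIF parameters
    tau_m,
    v_rest,
    v_thr,
    v_reset,
    ref_steps,
    cap,
    # excitatory synapses (CSR over sources) with gating saturation
    exc_ptr,
    exc_tgt,
    exc_g,  # max conductance per synapse (uS)
    # inhibitory synapses (CSR over sources), jump-and-decay
    inh_ptr,
    inh_tgt,
    inh_g,
    # receptor kinetics
    tau_e,
    tau_i,
    e_rev_e,
    e_rev_i,
    alpha,  # NMDA gating jump factor
    adapt_inc,  # (n,) adaptation conductance jump per own spike
    adapt_decay,  # (n,) per-step decay factor of the adaptation conductance
    # drives: (n_blocks, n) injected current and Poisson rates (Hz)
    i_ext,
    rate_a,
    amp_a,  # (n,) conductance jump of the fast background channel
    tau_a,  # decay of the background channel (ms)
    rate_b,
    amp_b,  # (n,) max conductance of the saturating input channel
    cap_spikes,
):
    np.random.seed(seed)
    n = i_ext.shape[1]
    n_blocks = i_ext.shape[0]
    n_exc = exc_tgt.shape[0]
    v = np.full(n, v_rest)
    s_exc = np.zeros(n_exc)
    g_i = np.zeros(n)
    pend_i = np.zeros(n)
    s_a = np.zeros(n)
    s_b = np.zeros(n)
    refr = np.zeros(n, dtype=np.int64)
    spk_t = np.empty(cap_spikes)
    spk_id = np.empty(cap_spikes, dtype=np.int32)
    count = 0
    de = np.exp(-dt / tau_e)
    di = np.exp(-dt / tau_i)
    da = np.exp(-dt / tau_a)
    g_ad = np.zeros(n)
    g_leak = cap / tau_m
    p_scale = dt * 1e-3  # Hz -> probability per step
    err = ERR_NONE
    err_t = -1.0
    err_n = -1
    g_e = np.zeros(n)
    for step in range(n_steps):
        block = step // steps_per_block
        if block >= n_blocks:
            block = n_blocks - 1
        t_now = step * dt
        # decay gates and rebuild per-target excitatory conductance
        for i in range(n):
            g_e[i] = 0.0
        for k in range(n_exc):
            s_exc[k] *= de
            g_e[exc_tgt[k]] += exc_g[k] * s_exc[k]
        for i in range(n):
            s_a[i] *= da  # fast non-saturating background conductance
            s_b[i] *= de  # saturating NMDA-like input gate
            ra = rate_a[block, i]
            if ra > 0.0 and np.random.random() < ra * p_scale:
                s_a[i] += amp_a[i]
            rb = rate_b[block, i]
            if rb > 0.0 and np.random.random() < rb * p_scale:
                s_b[i] += alpha * (1.0 - s_b[i])
            g_e[i] += s_a[i] + amp_b[i] * s_b[i]
            g_i[i] = g_i[i] * di + pend_i[i]
            pend_i[i] = 0.0
            g_ad[i] *= adapt_decay[i]
            if refr[i] > 0:
                refr[i] -= 1
                v[i] = v_reset
                continue
            ge = g_e[i]
            gi = g_i[i] + g_ad[i]
            g_tot = g_leak + ge + gi
            v_inf = (g_leak * v_rest + ge * e_rev_e + gi * e_rev_i + i_ext[block, i]) / g_tot
            vi = v_inf + (v[i] - v_inf) * np.exp(-dt * g_tot / cap)
            if not np.isfinite(vi):
                err = ERR_NONFINITE
                err_t = t_now
                err_n = i
                break
            if vi >= v_thr:
                if count >= cap_spikes:
                    err = ERR_OVERFLOW
                    err_t = t_now
                    err_n = i
                    break
                spk_t[count] = t_now
                spk_id[count] = i
                count += 1
                vi = v_reset
                refr[i] = ref_steps - 1 if ref_steps > 0 else 0
                g_ad[i] += adapt_inc[i]
                for k in range(exc_ptr[i], exc_ptr[i + 1]):
                    s_exc[k] += alpha * (1.0 - s_exc[k])
                for k in range(inh_ptr[i], inh_ptr[i + 1]):
                    pend_i[inh_tgt[k]] += inh_g[k]
            v[i] = vi
        if err != ERR_NONE:
            break
    return spk_t[:count], spk_id[:count], err, err_t, err_n, v
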