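"""Numba kernels for the fiber-population simulation.

The stimulation waveform is piecewise constant (biphasic pulse phases and
gaps), so each fiber is integrated segment by segment with an
exponential-Euler step that is exact for the membrane equation while the
drive is constant; threshold-crossing times are solved analytically inside a
step, giving sub-microsecond spike timing without a dense 1 MHz grid.

The Ornstein-Uhlenbeck noise current is refreshed on its own clock (about
its correlation time, ``noise_update_us``), with draws taken from
pre-generated per-fiber standard-normal streams so the hot loop stays free
of RNG calls.

Parameter vector layout (``NeuronParams.pack`` in :mod:`cisim.anf`):

==  =============================================
0   C cathodic-excitatory circuit (F)
1   C anodic-excitatory circuit (F)
2   membrane time constant (us)
3   threshold voltage (V)
4   inhibitory compression beta
5   absolute refractory period (us)
6   subthreshold adaptation conductance a_sub (S)
7   subthreshold adaptation time constant (us)
8   suprathreshold adaptation increment b (A)
9   suprathreshold adaptation time constant (us)
10  noise current s.d. (A)
11  noise time constant (us)
12  noise refresh interval (us)
==  =============================================
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def simulate_piecewise(seg_i_a, seg_dur_us, params, noise_c, noise_a, spikes_out):
    """Integrate one fiber over piecewise-constant induced current.

    ``seg_i_a`` is the induced current (A) in each segment, ``seg_dur_us``
    the segment durations; ``noise_c``/``noise_a`` are standard-normal draw
    streams for the two circuits.  Spike times (s) are written to
    ``spikes_out``; returns the spike count.  With zero noise amplitude the
    result is deterministic.
    """
    (c_cath, c_anod, tau_m_us, v_th, beta, arp_us, a_sub, tau_sub_us,
     b_supra, tau_supra_us, sigma, tau_nz_us, noise_update_us) = (
        params[0], params[1], params[2], params[3], params[4], params[5],
        params[6], params[7], params[8], params[9], params[10], params[11],
        params[12])
    tau_m_s = tau_m_us * 1e-6
    r_cath = tau_m_s / c_cath
    r_anod = tau_m_s / c_anod
    use_noise = sigma > 0.0 and noise_c.shape[0] > 0

    v_c = 0.0
    v_a = 0.0
    isub_c = 0.0
    isub_a = 0.0
    isupra = 0.0
    nz_c = 0.0
    nz_a = 0.0
    t_us = 0.0
    t_ready_us = 0.0
    n_spikes = 0
    max_spikes = spikes_out.shape[0]
    draw = 0
    n_draws = noise_c.shape[0]
    since_draw = noise_update_us  # force a draw at t = 0

    prev_dt = -1.0
    dec_sub = 0.0
    dec_sup = 0.0
    dec_m = 0.0
    prev_nz_dt = -1.0
    dec_nz = 0.0
    nz_kick = 0.0

    for s in range(seg_i_a.shape[0]):
        i_stim = seg_i_a[s]
        dur = seg_dur_us[s]
        if dur <= 0.0:
            continue
        i_pos = i_stim if i_stim > 0.0 else 0.0
        i_neg = i_stim if i_stim < 0.0 else 0.0
        drive_c = -(i_neg + beta * i_pos)
        drive_a = i_pos + beta * i_neg
        nsub = int(np.ceil(dur / noise_update_us))
        dt = dur / nsub
        if dt != prev_dt:
            # segment durations repeat heavily; reuse the decay factors
            dec_sub = np.exp(-dt / tau_sub_us)
            dec_sup = np.exp(-dt / tau_supra_us)
            dec_m = np.exp(-dt / tau_m_us)
            prev_dt = dt
        for _ in range(nsub):
            if use_noise:
                since_draw += dt
                if since_draw >= noise_update_us and draw < n_draws:
                    if since_draw != prev_nz_dt:
                        dec_nz = np.exp(-since_draw / tau_nz_us)
                        nz_kick = sigma * np.sqrt(1.0 - dec_nz * dec_nz)
                        prev_nz_dt = since_draw
                    nz_c = nz_c * dec_nz + nz_kick * noise_c[draw]
                    nz_a = nz_a * dec_nz + nz_kick * noise_a[draw]
                    draw += 1
                    since_draw = 0.0
            remaining = dt
            if t_us < t_ready_us:
                hold = t_ready_us - t_us
                if hold >= remaining:
                    hold = remaining
                if hold == dt:
                    isub_c *= dec_sub
                    isub_a *= dec_sub
                    isupra *= dec_sup
                else:
                    e_sub = np.exp(-hold / tau_sub_us)
                    isub_c *= e_sub
                    isub_a *= e_sub
                    isupra *= np.exp(-hold / tau_supra_us)
                t_us += hold
                remaining -= hold
                v_c = 0.0
                v_a = 0.0
            if remaining <= 0.0:
                continue
            em = dec_m if remaining == dt else np.exp(-remaining / tau_m_us)
            itot_c = drive_c + nz_c - isub_c - isupra
            itot_a = drive_a + nz_a - isub_a - isupra
            vinf_c = r_cath * itot_c
            vinf_a = r_anod * itot_a
            v0_c = v_c
            v0_a = v_a
            vn_c = vinf_c + (v_c - vinf_c) * em
            vn_a = vinf_a + (v_a - vinf_a) * em
            # analytic first-crossing time inside the step, either circuit
            tc = 1e18
            if vn_c >= v_th and vinf_c > v_th and v0_c < v_th:
                tc = tau_m_us * np.log((vinf_c - v0_c) / (vinf_c - v_th))
            if vn_a >= v_th and vinf_a > v_th and v0_a < v_th:
                ta = tau_m_us * np.log((vinf_a - v0_a) / (vinf_a - v_th))
                if ta < tc:
                    tc = ta
            if tc <= remaining:
                t_spike = t_us + tc
                if n_spikes < max_spikes:
                    spikes_out[n_spikes] = t_spike * 1e-6
                    n_spikes += 1
                isupra = isupra * np.exp(-remaining / tau_supra_us) + b_supra
                isub_c = isub_c * np.exp(-remaining / tau_sub_us)
                isub_a = isub_a * np.exp(-remaining / tau_sub_us)
                v_c = 0.0
                v_a = 0.0
                t_ready_us = t_spike + arp_us
                t_us += remaining
            else:
                isub_c = isub_c + (1.0 - dec_sub) * (a_sub * v0_c - isub_c)
                isub_a = isub_a + (1.0 - dec_sub) * (a_sub * v0_a - isub_a)
                isupra *= dec_sup
                v_c = vn_c
                v_a = vn_a
                t_us += remaining
    return n_spikes


@njit(cache=True)
def slot_values(patterns_t, single_vals, amps_ua, steer_idx, group_of_slot):
    """Induced-current coefficient per (cycle, slot, fiber).

    ``patterns_t`` is the fiber-contiguous transpose (15, 8, nodes, F) of the
    channel activation patterns.  For single-channel slots the argmax node is
    amplitude-independent and ``single_vals`` (15, 8, F) is used directly;
    for simultaneous slots the combined per-node activation is accumulated
    with the fiber axis innermost (vectorizable) and the node of largest
    absolute combined activation selected per fiber.
    """
    n_channels, n_steer, NN, F = patterns_t.shape
    n_cycles = amps_ua.shape[0]
    n_slots = group_of_slot.shape[0]
    vals = np.zeros((n_cycles, n_slots, F))
    cur = np.empty(F)
    best = np.empty(F)
    for k in range(n_cycles):
        for sl in range(n_slots):
            if group_of_slot[sl, 1] < 0:
                ch = group_of_slot[sl, 0]
                amp = amps_ua[k, ch] * 1e-6
                sv = single_vals[ch, steer_idx[k, ch]]
                for f in range(F):
                    vals[k, sl, f] = amp * sv[f]
            else:
                for f in range(F):
                    best[f] = 0.0
                # terminal nodes (0 and NN-1) carry no activation
                for a in range(1, NN - 1):
                    for f in range(F):
                        cur[f] = 0.0
                    for m in range(group_of_slot.shape[1]):
                        ch = group_of_slot[sl, m]
                        if ch < 0:
                            continue
                        amp = amps_ua[k, ch] * 1e-6
                        row = patterns_t[ch, steer_idx[k, ch], a]
                        for f in range(F):
                            cur[f] += amp * row[f]
                    for f in range(F):
                        v = cur[f] if cur[f] >= 0.0 else -cur[f]
                        if v > best[f]:
                            best[f] = v
                            vals[k, sl, f] = cur[f]
    return vals


@njit(cache=True)
def run_population(vals, m_c, seg_slot, seg_phase, seg_dur_us, lead_us,
                   tail_us, params, noise_c, noise_a, spikes_out, counts_out):
    """Spike generation for a fiber population from per-slot coefficients.

    ``vals``          (n_cycles, n_slots, F) from :func:`slot_values`.
    ``seg_slot/phase/dur`` describe one stimulation cycle: slot index (-1 for
    gap), phase sign (-1 cathodic, +1 anodic, 0 gap) and duration.
    ``noise_c/noise_a`` are (F, n_draws) standard-normal streams.

    The induced current of fiber ``f`` during a pulse phase is
    ``phase_sign * M_C * vals[cycle, slot, f]``; spike times (s) land in
    ``spikes_out``.
    """
    n_cycles, n_slots, F = vals.shape
    n_tpl = seg_slot.shape[0]
    n_seg_total = n_cycles * n_tpl + 2
    for f in range(F):
        seg_i = np.zeros(n_seg_total)
        seg_d = np.empty(n_seg_total)
        pos = 0
        seg_d[pos] = lead_us
        pos += 1
        for k in range(n_cycles):
            for j in range(n_tpl):
                sl = seg_slot[j]
                ph = seg_phase[j]
                seg_d[pos] = seg_dur_us[j]
                if sl >= 0 and ph != 0:
                    seg_i[pos] = ph * m_c * vals[k, sl, f]
                pos += 1
        seg_d[pos] = tail_us
        pos += 1
        counts_out[f] = simulate_piecewise(seg_i[:pos], seg_d[:pos], params,
                                           noise_c[f], noise_a[f],
                                           spikes_out[f])
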