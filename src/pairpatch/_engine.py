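"""Fixed-step integrator for the two-cell model.

The subthreshold system is

    C_i dV_i/dt = -g_leak,i (V_i - E_i) + gj (V_j - V_i)
                  + sum_syn g_syn(t) (E_rev - V_i) + I_inj,i + I_noise,i

integrated with Heun's method at a fixed 0.1 ms step (the 10 kHz sampling
grid).  Action potentials are stereotyped waveforms pasted at threshold
crossings: while a cell is "in" an AP its displayed voltage follows the
waveform (and drives the gap junction), its free membrane state is parked
at the reset potential, and integration resumes after the waveform plus an
absolute refractory period.  Voltage clamp is ideal (zero series
resistance): the clamped cell sits exactly at the holding potential and
the recorded channel is the amplifier current required to hold it there.

Chemical release is evaluated at each presynaptic AP peak from a
pre-drawn uniform stream, so a sweep's random outcome is fully determined
by the arrays passed in.
"""

import numpy as np
from numba import njit

MODE_CC = 0
MODE_VC = 1

MAX_EVENTS = 512


@njit(cache=True)
def run_sweep(dt, i_cmd, noise, mode, vhold, v0,
              cap, gl, el, theta, vreset, refr_steps,
              ap_n, wave, peak_off,
              gj,
              syn_pre, syn_post, syn_p, syn_delay_steps,
              dec_r, dec_d, syn_gnorm, syn_erev,
              syn_u,
              rec, spk, rel):
    """Integrate one sweep in place.

    rec : (2, n) output traces (mV in CC, pA amplifier current in VC)
    spk : (2, max_spk) output AP peak times (ms); returns counts
    rel : (n_syn, max_spk) int8 release outcome per presynaptic spike
    """
    n = i_cmd.shape[1]
    n_syn = syn_pre.shape[0]

    V = v0.copy()
    vd = np.zeros(2)
    ap_start = np.full(2, -1, np.int64)
    ap_end = np.zeros(2, np.int64)
    refr_until = np.zeros(2, np.int64)
    nsp = np.zeros(2, np.int64)

    a = np.zeros(n_syn)
    b = np.zeros(n_syn)
    evq = np.zeros((n_syn, MAX_EVENTS), np.int64)
    ev_cnt = np.zeros(n_syn, np.int64)
    ev_head = np.zeros(n_syn, np.int64)

    k1 = np.zeros(2)
    vp = np.zeros(2)
    gsyn = np.zeros(2)

    for k in range(n):
        # synaptic conductance state at time k
        for s in range(n_syn):
            a[s] *= dec_d[s]
            b[s] *= dec_r[s]
            while ev_head[s] < ev_cnt[s] and evq[s, ev_head[s]] == k:
                a[s] += 1.0
                b[s] += 1.0
                ev_head[s] += 1
        gsyn[0] = 0.0
        gsyn[1] = 0.0
        for s in range(n_syn):
            g = syn_gnorm[s] * (a[s] - b[s])
            if g < 0.0:
                g = 0.0
            gsyn[syn_post[s]] += g

        # displayed voltages at time k
        for i in range(2):
            if mode[i] == MODE_VC:
                vd[i] = vhold[i]
            elif ap_start[i] >= 0 and k < ap_end[i]:
                vd[i] = wave[i, k - ap_start[i]]
            else:
                vd[i] = V[i]

        # record sample k
        for i in range(2):
            j = 1 - i
            if mode[i] == MODE_VC:
                isyn = 0.0
                for s in range(n_syn):
                    if syn_post[s] == i:
                        g = syn_gnorm[s] * (a[s] - b[s])
                        if g > 0.0:
                            isyn += g * (syn_erev[s] - vhold[i])
                rec[i, k] = (gl[i] * (vhold[i] - el[i])
                             - gj * (vd[j] - vhold[i])
                             - isyn - noise[i, k])
            else:
                rec[i, k] = vd[i]

        # Heun step for free CC cells
        for i in range(2):
            j = 1 - i
            if mode[i] == MODE_CC and not (ap_start[i] >= 0 and k < ap_end[i]):
                isyn = 0.0
                for s in range(n_syn):
                    if syn_post[s] == i:
                        g = syn_gnorm[s] * (a[s] - b[s])
                        if g > 0.0:
                            isyn += g * (syn_erev[s] - V[i])
                k1[i] = (-gl[i] * (V[i] - el[i]) + gj * (vd[j] - V[i])
                         + isyn + i_cmd[i, k] + noise[i, k]) / cap[i]
                vp[i] = V[i] + dt * k1[i]
            else:
                k1[i] = 0.0
                vp[i] = vd[i]
        for i in range(2):
            j = 1 - i
            if mode[i] == MODE_CC and not (ap_start[i] >= 0 and k < ap_end[i]):
                isyn = 0.0
                for s in range(n_syn):
                    if syn_post[s] == i:
                        g = syn_gnorm[s] * (a[s] - b[s])
                        if g > 0.0:
                            isyn += g * (syn_erev[s] - vp[i])
                k2 = (-gl[i] * (vp[i] - el[i]) + gj * (vp[j] - vp[i])
                      + isyn + i_cmd[i, k] + noise[i, k]) / cap[i]
                V[i] = V[i] + 0.5 * dt * (k1[i] + k2)

        # AP bookkeeping and threshold crossing for the next step
        for i in range(2):
            if ap_start[i] >= 0 and k + 1 >= ap_end[i]:
                ap_start[i] = -1
            if (mode[i] == MODE_CC and ap_start[i] < 0
                    and k + 1 >= refr_until[i] and V[i] >= theta[i]):
                ap_start[i] = k + 1
                ap_end[i] = k + 1 + ap_n[i]
                refr_until[i] = ap_end[i] + refr_steps[i]
                peak_step = k + 1 + peak_off[i]
                sidx = nsp[i]
                if sidx < spk.shape[1]:
                    spk[i, sidx] = peak_step * dt
                nsp[i] = sidx + 1
                for s in range(n_syn):
                    if syn_pre[s] == i and sidx < syn_u.shape[1]:
                        if syn_u[s, sidx] < syn_p[s]:
                            rel[s, sidx] = 1
                            if ev_cnt[s] < MAX_EVENTS:
                                est = peak_step + syn_delay_steps[s]
                                evq[s, ev_cnt[s]] = est
                                ev_cnt[s] += 1
                V[i] = vreset[i]

    return nsp[0], nsp[1]
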