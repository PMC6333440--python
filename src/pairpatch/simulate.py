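"""Synthetic paired recordings and fictive-locomotion ventral-root signals.

``simulate_pair`` runs the two-cell model of :mod:`pairpatch._engine`
under the three stimulation protocols (suprathreshold pulse trains,
hyper/depolarising step families, subthreshold sinusoids) and returns a
:class:`~pairpatch.model.SweepBundle` with the ground truth embedded.
``simulate_ventral_roots`` produces rectified-EMG-like multi-channel
signals whose burst envelope follows a given cycle frequency, duty cycle
and per-channel phase, optionally with a frequency switch mid-recording
(emulating drug wash-in).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np

from . import _engine
from .model import (
    CURRENT_CLAMP,
    VOLTAGE_CLAMP,
    PairMeta,
    PairModelSpec,
    ProtocolSpec,
    PulseTrainProtocol,
    SinusoidProtocol,
    StepFamilyProtocol,
    SweepBundle,
)

# Refuse protocols whose total simulated time exceeds this cap (seconds of
# biological time); guards against accidental runaway configurations.
MAX_TOTAL_SIMULATED_S = 3600.0

_PROTO_CODE = {"pulse_train": 1, "step_family": 2, "sinusoid": 3}
_MAX_SPIKES = 512


def _sweep_commands(protocol: ProtocolSpec, dt: float) -> Iterator[tuple[float, np.ndarray]]:
    """Yield (label, injected-current array in pA) per sweep."""
    if isinstance(protocol, PulseTrainProtocol):
        n = int(round(protocol.sweep_duration_ms / dt))
        cmd = np.zeros(n)
        for onset in protocol.pulse_onsets_ms:
            i0 = int(round(onset / dt))
            i1 = int(round((onset + protocol.pulse_width_ms) / dt))
            cmd[i0:i1] = protocol.pulse_amplitude_pa
        for sweep in range(protocol.n_sweeps):
            yield float(sweep), cmd
    elif isinstance(protocol, StepFamilyProtocol):
        n = int(round(protocol.sweep_duration_ms / dt))
        i0 = int(round(protocol.pre_ms / dt))
        i1 = int(round((protocol.pre_ms + protocol.step_ms) / dt))
        for _rep in range(protocol.n_repeats):
            for amp in protocol.amplitudes_pa:
                cmd = np.zeros(n)
                cmd[i0:i1] = amp
                yield float(amp), cmd
    elif isinstance(protocol, SinusoidProtocol):
        for f in protocol.frequencies_hz:
            dur = protocol.sweep_duration_ms(f)
            n = int(round(dur / dt))
            t = np.arange(n) * dt
            cmd = np.zeros(n)
            on = t >= protocol.pad_ms
            cmd[on] = protocol.amplitude_pa * np.sin(
                2.0 * math.pi * f * (t[on] - protocol.pad_ms) / 1000.0
            )
            for _sweep in range(protocol.n_sweeps):
                yield float(f), cmd
    else:  # pragma: no cover - exhaustive over the protocol union
        raise TypeError(f"unknown protocol {protocol!r}")


def _total_duration_s(protocol: ProtocolSpec) -> float:
    if isinstance(protocol, PulseTrainProtocol):
        return protocol.sweep_duration_ms * protocol.n_sweeps / 1000.0
    if isinstance(protocol, StepFamilyProtocol):
        return (protocol.sweep_duration_ms * protocol.n_repeats
                * len(protocol.amplitudes_pa) / 1000.0)
    return sum(protocol.sweep_duration_ms(f) for f in protocol.frequencies_hz) \
        * protocol.n_sweeps / 1000.0


def _ap_waveform(theta: float, amp: float, width_ms: float, dt: float):
    """Half-cosine-squared AP bump starting and ending at threshold."""
    m = int(round(width_ms / dt))
    if m % 2 == 0:
        m += 1  # odd length so the peak sample is hit exactly
    s = (np.arange(m) + 0.5) / m
    wave = theta + amp * np.sin(math.pi * s) ** 2
    return wave, int(np.argmax(wave))


def _noise_current_sd(spec: PairModelSpec, cell: int) -> float:
    """Per-sample current-noise SD (pA) yielding the target baseline voltage SD.

    For white current noise filtered by an RC membrane the stationary
    voltage variance is (sigma_c/C)^2 * tau/2 where sigma_c is the
    continuous-time noise scale; discretised at step dt the per-sample SD
    is sigma_c/sqrt(dt).
    """
    npar = spec.neuron(cell)
    sigma_c = spec.noise_sd_mv * npar.capacitance_pf * math.sqrt(2.0 / npar.tau_ms)
    return sigma_c


def simulate_pair(spec: PairModelSpec, protocol: ProtocolSpec,
                  meta: Optional[PairMeta] = None,
                  pair_id: str = "pair") -> SweepBundle:
    """Simulate one paired-recording protocol block.

    The injected cell is always in current clamp; the non-injected cell
    follows ``protocol.post_mode``.  Identical (spec, protocol) inputs
    give bit-identical output: noise and release randomness derive from
    ``spec.seed`` combined with a protocol tag and the sweep index.
    """
    total_s = _total_duration_s(protocol)
    if total_s > MAX_TOTAL_SIMULATED_S:
        raise ValueError(
            f"protocol simulates {total_s:.0f} s > cap {MAX_TOTAL_SIMULATED_S:.0f} s")

    dt = 1000.0 / protocol.sampling_rate_hz
    inj = protocol.injected_cell
    post = 2 if inj == 1 else 1
    post_mode = getattr(protocol, "post_mode", CURRENT_CLAMP)

    mode = np.zeros(2, np.int64)
    vhold = np.zeros(2)
    if post_mode == VOLTAGE_CLAMP:
        mode[post - 1] = _engine.MODE_VC
        vhold[post - 1] = protocol.vc_hold_mv

    cells = [spec.neuron_1, spec.neuron_2]
    cap = np.array([c.capacitance_pf for c in cells])
    gl = np.array([c.leak_conductance_ns for c in cells])
    el = np.array([c.leak_reversal_mv for c in cells])
    theta = np.array([c.spike_threshold_mv for c in cells])
    vreset = np.array([c.spike_reset_mv for c in cells])
    refr_steps = np.array([int(round(c.refractory_ms / dt)) for c in cells],
                          np.int64)
    waves, peak_offs, ap_ns = [], [], []
    for c in cells:
        w, p = _ap_waveform(c.spike_threshold_mv, c.ap_amplitude_mv,
                            c.ap_width_ms, dt)
        waves.append(w)
        peak_offs.append(p)
        ap_ns.append(len(w))
    max_ap = max(ap_ns)
    wave = np.zeros((2, max_ap))
    for i, w in enumerate(waves):
        wave[i, :len(w)] = w
    ap_n = np.array(ap_ns, np.int64)
    peak_off = np.array(peak_offs, np.int64)

    syns = spec.chem_synapses
    n_syn = len(syns)
    syn_pre = np.array([s.pre_cell - 1 for s in syns], np.int64).reshape(n_syn)
    syn_post = np.array([s.post_cell - 1 for s in syns], np.int64).reshape(n_syn)
    syn_p = np.array([s.release_probability for s in syns]).reshape(n_syn)
    syn_delay_steps = np.array([int(round(s.delay_ms / dt)) for s in syns],
                               np.int64).reshape(n_syn)
    dec_r = np.array([math.exp(-dt / s.tau_rise_ms) for s in syns]).reshape(n_syn)
    dec_d = np.array([math.exp(-dt / s.tau_decay_ms) for s in syns]).reshape(n_syn)
    syn_gnorm = np.empty(n_syn)
    for j, s in enumerate(syns):
        tp = s.time_to_peak_ms
        peak = math.exp(-tp / s.tau_decay_ms) - math.exp(-tp / s.tau_rise_ms)
        syn_gnorm[j] = s.peak_conductance_ns / peak
    syn_erev = np.array([s.reversal_mv for s in syns]).reshape(n_syn)

    noise_sd = np.array([_noise_current_sd(spec, 1), _noise_current_sd(spec, 2)])
    sqrt_dt = math.sqrt(dt)

    v0 = el.copy()
    for i in range(2):
        if mode[i] == _engine.MODE_VC:
            v0[i] = vhold[i]

    base = np.random.SeedSequence(
        (int(spec.seed) & 0x7FFFFFFF, _PROTO_CODE[protocol.kind], inj,
         1 if post_mode == VOLTAGE_CLAMP else 0))
    plan = list(_sweep_commands(protocol, dt))
    children = base.spawn(len(plan))

    sweeps, labels, spike_log, release_log = [], [], [], []
    for (label, cmd), child in zip(plan, children):
        n = cmd.shape[0]
        rng = np.random.default_rng(child)
        noise = rng.standard_normal((2, n)) * (noise_sd[:, None] / sqrt_dt)
        syn_u = rng.random((max(n_syn, 1), _MAX_SPIKES))
        i_cmd = np.zeros((2, n))
        i_cmd[inj - 1] = cmd

        rec = np.empty((2, n))
        spk = np.zeros((2, _MAX_SPIKES))
        rel = np.zeros((max(n_syn, 1), _MAX_SPIKES), np.int8)
        ns1, ns2 = _engine.run_sweep(
            dt, i_cmd, noise, mode, vhold, v0,
            cap, gl, el, theta, vreset, refr_steps,
            ap_n, wave, peak_off,
            spec.gap.gj_ns,
            syn_pre, syn_post, syn_p, syn_delay_steps,
            dec_r, dec_d, syn_gnorm, syn_erev,
            syn_u, rec, spk, rel)
        ns1 = min(int(ns1), _MAX_SPIKES)
        ns2 = min(int(ns2), _MAX_SPIKES)
        sweeps.append(np.vstack([cmd[None, :], rec]))
        labels.append(label)
        spike_log.append((spk[0, :ns1].copy(), spk[1, :ns2].copy()))
        n_pre = [ns1, ns2]
        release_log.append(
            [rel[j, :n_pre[syn_pre[j]]].copy() for j in range(n_syn)])

    modes = [CURRENT_CLAMP, CURRENT_CLAMP]
    modes[post - 1] = post_mode
    return SweepBundle(
        pair_id=pair_id, protocol=protocol, sweeps=sweeps, sweep_labels=labels,
        modes=(modes[0], modes[1]), sampling_rate_hz=protocol.sampling_rate_hz,
        meta=meta or PairMeta(), ground_truth=spec,
        spike_log=spike_log, release_log=release_log)


# --------------------------------------------------------------------------
# Pharmacology emulation
# --------------------------------------------------------------------------

def glutamatergic_block(spec: PairModelSpec) -> PairModelSpec:
    """Emulate AMPA/NMDA receptor blockade: chemical synapses removed."""
    from dataclasses import replace
    return replace(spec, chem_synapses=())


def gap_junction_block(spec: PairModelSpec,
                       fraction_remaining: float = 0.2) -> PairModelSpec:
    """Emulate a gap-junction blocker as a graded reduction of gj.

    Carbenoxolone does not fully close junctions; the default leaves 20%
    of the conductance in place.
    """
    from dataclasses import replace
    from .model import GapJunctionParams
    if not 0.0 <= fraction_remaining <= 1.0:
        raise ValueError("fraction_remaining must be in [0, 1]")
    return replace(spec, gap=GapJunctionParams(
        spec.gap.gj_ns * fraction_remaining))


# --------------------------------------------------------------------------
# Ventral-root-like fictive locomotion
# --------------------------------------------------------------------------

@dataclass
class VentralRootRecording:
    """Multi-channel rectified-EMG-like signal set with generator truth."""

    time_s: np.ndarray
    channels: np.ndarray          # (n_channels, n_samples)
    sampling_rate_hz: float
    channel_names: tuple[str, ...]
    frequency_hz: float
    phase_map: tuple[float, ...]
    burst_duty: float
    epoch_change: Optional[tuple[float, float]] = None

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]


def simulate_ventral_roots(frequency_hz: float,
                           phase_map: Sequence[float],
                           duration_s: float,
                           burst_duty: float = 0.4,
                           noise_sd: float = 0.2,
                           seed: int = 0,
                           epoch_change: Optional[tuple[float, float]] = None,
                           sampling_rate_hz: float = 1000.0,
                           burst_amplitude: float = 1.0,
                           edge_smooth_s: float = 0.05,
                           channel_names: Optional[Sequence[str]] = None,
                           ) -> VentralRootRecording:
    """Generate alternating-burst ventral-root-like channels.

    Each channel is white carrier noise amplitude-modulated by a periodic
    burst envelope: channel ``c`` bursts while the cycle fraction
    ``(phi(t) - phase_map[c]) mod 1`` is below ``burst_duty``, where
    ``phi`` integrates the instantaneous cycle frequency (switching to a
    new frequency at ``epoch_change = (time_s, new_frequency_hz)`` if
    given).  Additive sensor noise of SD ``noise_sd`` is superimposed.
    """
    if not phase_map:
        raise ValueError("phase_map must name at least one channel")
    if not 0.0 < burst_duty < 1.0:
        raise ValueError("burst duty must be in (0, 1)")
    if not 0.0 < frequency_hz < sampling_rate_hz / 2.0:
        raise ValueError("frequency must be in (0, sampling_rate/2)")
    phases = tuple(float(p) for p in phase_map)
    if any(not 0.0 <= p < 1.0 for p in phases):
        raise ValueError("phases must lie in [0, 1)")
    if epoch_change is not None:
        t_change, f2 = epoch_change
        if not 0.0 < f2 < sampling_rate_hz / 2.0:
            raise ValueError("post-change frequency out of range")
        if not 0.0 <= t_change <= duration_s:
            raise ValueError("epoch change time outside the recording")

    n = int(round(duration_s * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz
    phi = frequency_hz * t
    if epoch_change is not None:
        t_change, f2 = epoch_change
        late = t >= t_change
        phi[late] = frequency_hz * t_change + f2 * (t[late] - t_change)

    rng = np.random.default_rng(
        np.random.SeedSequence((int(seed) & 0x7FFFFFFF, 0x5652)))
    n_ch = len(phases)
    channels = np.empty((n_ch, n))
    smooth = max(1, int(round(edge_smooth_s * sampling_rate_hz)))
    kernel = np.hanning(2 * smooth + 1)
    kernel /= kernel.sum()
    for c, ph in enumerate(phases):
        frac = np.mod(phi - ph, 1.0)
        env = (frac < burst_duty).astype(float)
        env = np.convolve(env, kernel, mode="same")
        carrier = rng.standard_normal(n)
        sensor = rng.standard_normal(n) * noise_sd
        channels[c] = env * carrier * burst_amplitude + sensor

    names = tuple(channel_names) if channel_names else tuple(
        f"ch{c + 1}" for c in range(n_ch))
    if len(names) != n_ch:
        raise ValueError("channel_names length must match phase_map")
    return VentralRootRecording(
        time_s=t, channels=channels, sampling_rate_hz=sampling_rate_hz,
        channel_names=names, frequency_hz=frequency_hz, phase_map=phases,
        burst_duty=burst_duty, epoch_change=epoch_change)
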