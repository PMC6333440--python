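"""Sweep processing: spike detection, QC, averaging, event measurement."""

import math

import numpy as np
import pytest
from scipy import stats as sps

import pairpatch as pp
from pairpatch.sweeps import _presyn_peaks, baseline_window_ms, detect_spikes

FS = 10_000.0


# --------------------------------------------------------------------------
# Spike detection
# --------------------------------------------------------------------------

def test_flat_trace_has_no_spikes():
    st = detect_spikes(np.full(5000, -65.0), FS)
    assert st.n_spikes == 0


def test_train_yields_five_peaks_at_twenty_ms_gaps(electrical_pulse):
    tr = electrical_pulse.cell_trace(1, 0)
    st = detect_spikes(tr, FS)
    assert st.n_spikes == 5
    proto = electrical_pulse.protocol
    gaps = np.diff(st.peak_times_ms)
    assert np.allclose(gaps, proto.pulse_width_ms + proto.isi_ms, atol=2.0)


def test_detected_peaks_match_simulator_log(electrical_pulse):
    for i in range(0, electrical_pulse.n_sweeps, 10):
        st = detect_spikes(electrical_pulse.cell_trace(1, i), FS)
        logged = electrical_pulse.spike_log[i][0]
        assert len(st.peak_times_ms) == len(logged)
        assert np.max(np.abs(st.peak_times_ms - logged)) <= 0.2


# --------------------------------------------------------------------------
# QC
# --------------------------------------------------------------------------

def test_qc_keeps_fully_spiking_sweeps(electrical_pulse):
    included = pp.qc_sweeps(electrical_pulse)
    assert included == list(range(electrical_pulse.n_sweeps))


def test_qc_matches_brute_force_recount():
    """Near-threshold pulses: kept set equals an explicit 5/5-spike recount."""
    spec = pp.PairModelSpec(seed=44)
    proto = pp.PulseTrainProtocol(injected_cell=1, pulse_amplitude_pa=207.0,
                                  n_sweeps=30)
    b = pp.simulate_pair(spec, proto)
    with np.errstate(all="ignore"):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            included = pp.qc_sweeps(b)
    onsets = proto.pulse_onsets_ms
    expected = []
    for i in range(b.n_sweeps):
        st = detect_spikes(b.cell_trace(1, i), FS)
        ok = all(np.any((st.peak_times_ms > o)
                        & (st.peak_times_ms <= o + proto.pulse_width_ms + 5.0))
                 for o in onsets) and st.n_spikes == 5
        if ok:
            expected.append(i)
    assert included == expected
    assert 0 < len(included) < b.n_sweeps  # amplitude really is marginal


def test_qc_requires_pulse_train(electrical_steps):
    with pytest.raises(ValueError):
        pp.qc_sweeps(electrical_steps)


# --------------------------------------------------------------------------
# Averaging
# --------------------------------------------------------------------------

def test_average_of_identical_sweeps_is_the_sweep(chem_clean_pulse):
    b = chem_clean_pulse
    avg = pp.average_sweeps(b, [0])
    post = b.cell_trace(2, 0)
    base = post[:int(100 / b.dt_ms)][int(50 / b.dt_ms):].mean()
    assert np.allclose(avg.post, post - base, atol=1e-12)
    assert np.allclose(avg.injected, b.cell_trace(1, 0))


def test_responding_only_average_rescales_by_release_probability():
    """All-sweep average ~ p x single event; conditional average ~ the event."""
    p = 0.3
    spec = pp.PairModelSpec(
        chem_synapses=(pp.ChemSynParams(pre_cell=1, release_probability=p),),
        seed=12)
    b = pp.simulate_pair(spec, pp.PulseTrainProtocol(injected_cell=1))
    inc = pp.qc_sweeps(b)
    fp = pp.failure_profile(b, inc)
    avg_all = pp.average_sweeps(b, inc)
    avg_resp = pp.average_sweeps(b, inc, "responding_only", fp)
    presyn = detect_spikes(avg_all.injected, FS)
    first = lambda avg: pp.measure_response(
        avg.post, FS, presyn, "EPSP", avg.baseline_window_ms,
        noise_criterion=0.0)[0].amplitude
    a_all, a_resp = first(avg_all), first(avg_resp)
    p_hat = fp.response_rate
    assert a_all == pytest.approx(p_hat * a_resp, rel=0.15)
    assert a_resp > 2.5 * a_all  # p well below one


def test_averaging_reduces_noise_like_sqrt_n(unconnected_pulse):
    b = unconnected_pulse
    inc = list(range(b.n_sweeps))
    avg = pp.average_sweeps(b, inc)
    dt = b.dt_ms
    single_sd = np.mean([b.cell_trace(2, i)[:int(100 / dt)].std()
                         for i in inc])
    avg_sd = avg.post[:int(100 / dt)].std()
    assert avg_sd == pytest.approx(single_sd / math.sqrt(len(inc)), rel=0.5)


def test_average_rejects_mismatched_lengths(electrical_pulse):
    b = electrical_pulse
    clipped = pp.SweepBundle(
        pair_id=b.pair_id, protocol=b.protocol,
        sweeps=[b.sweeps[0], b.sweeps[1][:, :100]],
        sweep_labels=[0.0, 1.0], modes=b.modes,
        sampling_rate_hz=b.sampling_rate_hz)
    with pytest.raises(ValueError):
        pp.average_sweeps(clipped, [0, 1])


# --------------------------------------------------------------------------
# Event measurement
# --------------------------------------------------------------------------

def test_zero_trace_reports_no_events():
    post = np.zeros(4000)
    peaks = np.array([110.0, 140.0, 170.0, 200.0, 230.0])
    ev = pp.measure_response(post, FS, peaks, "EPSC", (50.0, 100.0),
                             min_amplitude=1.0)
    assert ev == [None] * 5


def test_constructed_epsc_amplitude_and_latency():
    """A synthetic EPSC of -10.6 pA peaking 5.0 ms after the AP peak."""
    dt = 1000.0 / FS
    t = np.arange(4000) * dt
    ap_peak = 110.0
    tr, td = 1.0, 8.0
    tpeak = math.log(td / tr) * td * tr / (td - tr)
    onset = ap_peak + 5.0 - tpeak
    shape = np.where(t >= onset,
                     np.exp(-(t - onset) / td) - np.exp(-(t - onset) / tr),
                     0.0)
    peak_val = math.exp(-tpeak / td) - math.exp(-tpeak / tr)
    post = -10.6 * shape / peak_val
    ev = pp.measure_response(post, FS, np.array([ap_peak]), "EPSC",
                             (50.0, 100.0))
    assert ev[0] is not None
    assert ev[0].amplitude == pytest.approx(-10.6, abs=0.2)
    assert ev[0].latency_ms == pytest.approx(5.0, abs=0.2)


def test_epsp_onset_latency_equals_synaptic_delay(chem_clean_pulse):
    """Noise-free chemical pair: onset latency ~ delay, EPSC latency ~ delay+rise."""
    b = chem_clean_pulse
    avg = pp.average_sweeps(b, [0])
    presyn = detect_spikes(avg.injected, FS)
    ev = pp.measure_response(avg.post, FS, presyn, "EPSP",
                             avg.baseline_window_ms)
    syn = b.ground_truth.chem_synapses[0]
    assert ev[0].latency_ms == pytest.approx(syn.delay_ms, abs=0.3)

    vc = pp.simulate_pair(b.ground_truth,
                          pp.PulseTrainProtocol(injected_cell=1, n_sweeps=1,
                                                post_mode="voltage_clamp"))
    vavg = pp.average_sweeps(vc, [0])
    vev = pp.measure_response(vavg.post, FS, detect_spikes(vavg.injected, FS),
                              "EPSC", vavg.baseline_window_ms)
    assert vev[0].amplitude < 0  # inward at -60 mV
    expected = syn.delay_ms + syn.time_to_peak_ms
    assert vev[0].latency_ms == pytest.approx(expected, abs=0.2)


def test_electrical_pair_onset_precedes_ap_peak(electrical_pulse):
    b = electrical_pulse
    inc = pp.qc_sweeps(b)
    avg = pp.average_sweeps(b, inc)
    presyn = detect_spikes(avg.injected, FS)
    ev = pp.measure_response(avg.post, FS, presyn, "EPSP",
                             avg.baseline_window_ms)
    assert ev[0] is not None
    assert ev[0].latency_ms < -3.0


# --------------------------------------------------------------------------
# Failure profiles
# --------------------------------------------------------------------------

def test_reliable_synapse_never_fails():
    spec = pp.PairModelSpec(
        chem_synapses=(pp.ChemSynParams(pre_cell=1, release_probability=1.0),),
        seed=3)
    b = pp.simulate_pair(spec, pp.PulseTrainProtocol(injected_cell=1,
                                                     n_sweeps=20))
    fp = pp.failure_profile(b, pp.qc_sweeps(b, warn_below=0))
    assert fp.failure_rate == 0.0


def test_electrical_pair_responds_on_every_sweep(electrical_pulse):
    fp = pp.failure_profile(electrical_pulse, pp.qc_sweeps(electrical_pulse))
    assert fp.failure_rate == 0.0


def test_stochastic_failure_rate_within_binomial_interval(chemical_pulse):
    b = chemical_pulse
    inc = pp.qc_sweeps(b)
    fp = pp.failure_profile(b, inc)
    n = len(inc)
    lo = sps.binom.ppf(0.005, n, 0.3) / n
    hi = sps.binom.ppf(0.995, n, 0.3) / n
    assert lo <= fp.response_rate <= hi
    # detected responding sweeps coincide with the simulator's release log
    truth = np.array([int(b.release_log[i][0][0]) for i in inc], bool)
    agree = (fp.responding == truth).mean()
    assert agree >= 0.95


def test_failure_profile_needs_long_baseline(chemical_pulse):
    short = pp.PulseTrainProtocol(injected_cell=1, pre_ms=10.0, n_sweeps=2)
    b = pp.simulate_pair(pp.PairModelSpec(seed=5), short)
    with pytest.raises(ValueError):
        pp.failure_profile(b, [0, 1])


# --------------------------------------------------------------------------
# Spikelets
# --------------------------------------------------------------------------

def _supra_step_bundle(gj_ns, seed=15):
    # 150 pA: just suprathreshold, so presynaptic APs stay well separated
    # and each spikelet decays back toward the step plateau before the next
    spec = pp.PairModelSpec(gap=pp.GapJunctionParams(gj_ns), seed=seed)
    proto = pp.StepFamilyProtocol(injected_cell=1, amplitudes_pa=(150.0,),
                                  n_repeats=2)
    return pp.simulate_pair(spec, proto)


def test_no_spikelets_without_gap_junction():
    res = pp.detect_spikelets(_supra_step_bundle(0.0))
    assert res.spikelets == []


def test_one_spikelet_per_presynaptic_spike():
    b = _supra_step_bundle(1.0)
    res = pp.detect_spikelets(b)
    assert res.n_presyn_spikes > 10
    assert len(res.spikelets) == res.n_presyn_spikes
    assert res.n_postsyn_spikes == 0
    # spikelets are time-locked within 5 ms of their presynaptic APs
    for s in res.spikelets:
        assert -1.0 <= s.time_ms - s.presyn_peak_ms <= 5.0
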