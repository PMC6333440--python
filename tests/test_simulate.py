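"""Simulator contracts: determinism, passive-circuit oracles, release stats."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.integrate import solve_ivp

import pairpatch as pp


def _steady_deflection(bundle, sweep, cell, proto):
    dt = bundle.dt_ms
    w0, w1 = proto.step_window_ms
    tr = bundle.cell_trace(cell, sweep)
    s = tr[int((w1 - 200.0) / dt):int(w1 / dt)].mean()
    b = tr[:int(w0 / dt)].mean()
    return s - b


def test_identical_spec_and_seed_is_bit_identical():
    spec = pp.PairModelSpec(gap=pp.GapJunctionParams(1.0),
                            chem_synapses=(pp.ChemSynParams(pre_cell=1),),
                            seed=99)
    proto = pp.PulseTrainProtocol(injected_cell=1, n_sweeps=3)
    a = pp.simulate_pair(spec, proto)
    b = pp.simulate_pair(spec, proto)
    for sa, sb in zip(a.sweeps, b.sweeps):
        assert np.array_equal(sa, sb)
    for la, lb in zip(a.spike_log, b.spike_log):
        assert np.array_equal(la[0], lb[0]) and np.array_equal(la[1], lb[1])


def test_unconnected_pair_transfers_nothing():
    """With gj = 0 and no synapse, the non-injected cell only carries noise."""
    spec = pp.PairModelSpec(seed=4)
    proto = pp.StepFamilyProtocol(injected_cell=1, amplitudes_pa=(80.0,),
                                  n_repeats=1)
    b = pp.simulate_pair(spec, proto)
    dv1 = _steady_deflection(b, 0, 1, proto)
    dv2 = _steady_deflection(b, 0, 2, proto)
    assert dv1 > 5.0
    assert abs(dv2) < 0.1  # ~3 x SD of a 200 ms window mean


def test_dc_coupling_matches_closed_form():
    """Steady-state dV2/dV1 = gj / (g_leak2 + gj) for a passive pair."""
    spec = pp.PairModelSpec(
        neuron_2=pp.NeuronParams(leak_conductance_ns=9.0),
        gap=pp.GapJunctionParams(1.0), noise_sd_mv=0.0, seed=1)
    proto = pp.StepFamilyProtocol(injected_cell=1, amplitudes_pa=(70.0,),
                                  n_repeats=1)
    b = pp.simulate_pair(spec, proto)
    k = _steady_deflection(b, 0, 2, proto) / _steady_deflection(b, 0, 1, proto)
    assert k == pytest.approx(0.100, rel=0.02)


def test_engine_matches_independent_ode_solver():
    """Sub-threshold traces agree with scipy.solve_ivp on the same circuit."""
    gl1, gl2, gj, cap = 10.0, 9.0, 1.0, 100.0
    spec = pp.PairModelSpec(
        neuron_2=pp.NeuronParams(leak_conductance_ns=gl2),
        gap=pp.GapJunctionParams(gj), noise_sd_mv=0.0, seed=1)
    proto = pp.StepFamilyProtocol(injected_cell=1, amplitudes_pa=(70.0,),
                                  n_repeats=1)
    b = pp.simulate_pair(spec, proto)

    def rhs(t, y):
        v1, v2 = y
        i = 70.0 if 200.0 <= t < 1200.0 else 0.0
        return [(-gl1 * (v1 + 65) + gj * (v2 - v1) + i) / cap,
                (-gl2 * (v2 + 65) + gj * (v1 - v2)) / cap]

    t_eval = [500.0, 900.0, 1195.0]
    sol = solve_ivp(rhs, [0, 1200], [-65.0, -65.0], t_eval=t_eval,
                    rtol=1e-10, atol=1e-12)
    for j, t in enumerate(t_eval):
        idx = int(t / b.dt_ms)
        assert b.cell_trace(1, 0)[idx] == pytest.approx(sol.y[0, j], abs=1e-3)
        assert b.cell_trace(2, 0)[idx] == pytest.approx(sol.y[1, j], abs=1e-3)


def test_suprathreshold_train_evokes_one_spike_per_pulse():
    spec = pp.PairModelSpec(noise_sd_mv=0.0, seed=2)
    b = pp.simulate_pair(spec, pp.PulseTrainProtocol(injected_cell=1,
                                                     n_sweeps=1))
    spikes = b.spike_log[0][0]
    assert len(spikes) == 5
    assert np.allclose(np.diff(spikes), 30.0, atol=1.0)  # onset-to-onset


def test_deterministic_synapse_releases_once_per_spike(chem_clean_pulse):
    """p = 1: exactly 5 EPSPs per sweep, each starting delay after the AP."""
    b = chem_clean_pulse
    rel = b.release_log[0][0]
    assert rel.tolist() == [1, 1, 1, 1, 1]
    spikes = b.spike_log[0][0]
    post = b.cell_trace(2, 0)
    dt = b.dt_ms
    for t_ap in spikes:
        i0 = int(round((t_ap + 2.0) / dt))  # conductance onset = peak + delay
        before = post[i0 - 1] - post[0]
        after = post[i0 + 10] - post[0]
        assert after - before > 0.05  # depolarisation begins at the delay


def test_release_fraction_within_exact_binomial_interval():
    """First-pulse release fraction obeys Binomial(n_sweeps, p)."""
    p, n = 0.3, 50
    spec = pp.PairModelSpec(
        chem_synapses=(pp.ChemSynParams(pre_cell=1, release_probability=p),),
        seed=8)
    b = pp.simulate_pair(spec, pp.PulseTrainProtocol(injected_cell=1,
                                                     n_sweeps=n))
    count = sum(int(sw[0][0]) for sw in b.release_log)
    lo = sps.binom.ppf(0.005, n, p)
    hi = sps.binom.ppf(0.995, n, p)
    assert lo <= count <= hi


def test_baseline_noise_sd_matches_target():
    spec = pp.PairModelSpec(seed=4)
    proto = pp.StepFamilyProtocol(injected_cell=1, amplitudes_pa=(0.0,),
                                  n_repeats=3)
    b = pp.simulate_pair(spec, proto)
    sds = [b.cell_trace(c, i).std() for c in (1, 2) for i in range(3)]
    assert np.mean(sds) == pytest.approx(0.1, rel=0.15)


def test_parameter_validation():
    with pytest.raises(ValueError):
        pp.NeuronParams(capacitance_pf=-1.0)
    with pytest.raises(ValueError):
        pp.NeuronParams(spike_threshold_mv=-70.0)  # below leak reversal
    with pytest.raises(ValueError):
        pp.ChemSynParams(tau_rise_ms=5.0, tau_decay_ms=1.0)
    with pytest.raises(ValueError):
        pp.GapJunctionParams(gj_ns=-0.1)
    with pytest.raises(ValueError):
        pp.PairModelSpec(chem_synapses=(pp.ChemSynParams(pre_cell=1),
                                        pp.ChemSynParams(pre_cell=1)))
    with pytest.raises(ValueError):
        pp.PulseTrainProtocol(pulse_amplitude_pa=500.0)
    with pytest.raises(ValueError):
        pp.StepFamilyProtocol(amplitudes_pa=(50.0, 40.0))
    with pytest.raises(ValueError):
        pp.SinusoidProtocol(frequencies_hz=(-1.0,))


def test_runaway_protocol_rejected():
    proto = pp.PulseTrainProtocol(injected_cell=1, n_sweeps=50,
                                  tail_ms=500_000.0)
    with pytest.raises(ValueError, match="cap"):
        pp.simulate_pair(pp.PairModelSpec(seed=1), proto)


# --------------------------------------------------------------------------
# Ventral-root generator
# --------------------------------------------------------------------------

def test_ventral_root_phases_by_construction():
    rec = pp.simulate_ventral_roots(0.4, (0.0, 0.5, 0.5, 0.0),
                                    duration_s=60.0, seed=5)
    # channels 1 and 4 share the envelope phase; 1 and 2 are antiphase
    env = [np.abs(ch) for ch in rec.channels]
    sos_corr = np.corrcoef(env[0], env[3])[0, 1]
    anti_corr = np.corrcoef(env[0], env[1])[0, 1]
    assert sos_corr > anti_corr


def test_epoch_change_doubles_interburst_interval():
    rec = pp.simulate_ventral_roots(0.4, (0.0,), duration_s=300.0, seed=6,
                                    epoch_change=(150.0, 0.2))
    b = pp.detect_bursts(rec.channels[0], rec.sampling_rate_hz)
    early = b.onsets_s[(b.onsets_s > 5) & (b.onsets_s < 145)]
    late = b.onsets_s[(b.onsets_s > 155) & (b.onsets_s < 295)]
    assert np.diff(late).mean() == pytest.approx(2 * np.diff(early).mean(),
                                                 rel=0.1)


def test_burst_count_tracks_frequency():
    rec = pp.simulate_ventral_roots(0.39, (0.0,), duration_s=300.0,
                                    burst_duty=0.4, seed=7)
    b = pp.detect_bursts(rec.channels[0], rec.sampling_rate_hz)
    assert abs(b.n_bursts - 0.39 * 300.0) <= 2


def test_ventral_root_validation():
    with pytest.raises(ValueError):
        pp.simulate_ventral_roots(0.4, (), duration_s=10.0)
    with pytest.raises(ValueError):
        pp.simulate_ventral_roots(0.4, (0.0,), duration_s=10.0,
                                  burst_duty=1.2)
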