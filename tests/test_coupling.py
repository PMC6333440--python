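"""Coupling quantification: rheobase, DC coefficient, transfer, drugs."""

import math

import numpy as np
import pytest

import pairpatch as pp
from pairpatch.coupling import expected_transfer


def test_rheobase_matches_analytic_lif_value():
    """Noise-free isolated cell: first spiking step just above g(theta-E)."""
    cell = pp.NeuronParams(spike_threshold_mv=-52.5)  # analytic 125 pA
    spec = pp.PairModelSpec(neuron_1=cell, neuron_2=cell, noise_sd_mv=0.0,
                            seed=1)
    fam = pp.depolarizing_step_family(1, 100.0, 150.0, n_repeats=1)
    b = pp.simulate_pair(spec, fam)
    assert pp.compute_rheobase(b) == 130.0  # next 5 pA step above analytic


def test_rheobase_requires_a_spiking_step():
    spec = pp.PairModelSpec(noise_sd_mv=0.0, seed=1)
    fam = pp.depolarizing_step_family(1, 5.0, 50.0, n_repeats=1)
    b = pp.simulate_pair(spec, fam)
    with pytest.raises(ValueError, match="no spiking step"):
        pp.compute_rheobase(b)


def test_coupling_coefficient_recovers_conductance_ratio():
    spec = pp.PairModelSpec(
        neuron_2=pp.NeuronParams(leak_conductance_ns=9.0),
        gap=pp.GapJunctionParams(1.0), seed=21)
    b12 = pp.simulate_pair(spec, pp.depolarizing_step_family(1, 100.0, 150.0))
    b21 = pp.simulate_pair(spec, pp.depolarizing_step_family(2, 100.0, 150.0))
    cm = pp.coupling_coefficient(b12, b21)
    assert cm.k_12 == pytest.approx(1.0 / (9.0 + 1.0), abs=0.005)
    assert cm.k_21 == pytest.approx(1.0 / (10.0 + 1.0), abs=0.005)
    assert cm.coupled


def test_identical_cells_give_symmetric_coupling():
    spec = pp.PairModelSpec(gap=pp.GapJunctionParams(1.5), seed=22)
    b12 = pp.simulate_pair(spec, pp.depolarizing_step_family(1, 100.0, 150.0))
    b21 = pp.simulate_pair(spec, pp.depolarizing_step_family(2, 100.0, 150.0))
    cm = pp.coupling_coefficient(b12, b21)
    assert cm.k_12 == pytest.approx(cm.k_21, rel=0.05)
    assert cm.k_mean == pytest.approx(1.5 / 11.5, rel=0.05)


def test_uncoupled_pair_reports_zero_with_flag():
    spec = pp.PairModelSpec(seed=23)
    b12 = pp.simulate_pair(spec, pp.depolarizing_step_family(1, 100.0, 150.0))
    b21 = pp.simulate_pair(spec, pp.depolarizing_step_family(2, 100.0, 150.0))
    cm = pp.coupling_coefficient(b12, b21)
    assert cm.k_12 == 0.0 and cm.k_21 == 0.0
    assert not cm.coupled


def test_conductance_recovered_by_inverting_the_coupling_formula():
    """gj_hat = k g_leak2 / (1 - k) recovers the simulated conductance.

    Low recording noise isolates the estimator identity: at gj = 0.2 nS
    the transferred deflection is ~0.25 mV, so default noise alone spans
    several percent of k.
    """
    for gj in (0.2, 0.3, 2.0):
        spec = pp.PairModelSpec(gap=pp.GapJunctionParams(gj),
                                noise_sd_mv=0.02, seed=24)
        b12 = pp.simulate_pair(spec,
                               pp.depolarizing_step_family(1, 100.0, 165.0))
        b21 = pp.simulate_pair(spec,
                               pp.depolarizing_step_family(2, 100.0, 165.0))
        k = pp.coupling_coefficient(b12, b21).k_12
        gj_hat = k * 10.0 / (1.0 - k)
        assert gj_hat == pytest.approx(gj, rel=0.05)


# --------------------------------------------------------------------------
# Frequency response
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def sinus_bundle():
    spec = pp.PairModelSpec(gap=pp.GapJunctionParams(1.0), seed=7)
    proto = pp.SinusoidProtocol(injected_cell=1,
                                frequencies_hz=(2.0, 10.0, 20.0))
    return pp.simulate_pair(spec, proto)


def test_transfer_matches_rc_filter_theory(sinus_bundle):
    fr = pp.frequency_response(sinus_bundle)
    for p in fr.points:
        k_exp, lag_exp = expected_transfer(1.0, 10.0, 100.0, p.frequency_hz)
        assert p.coupling == pytest.approx(k_exp, rel=0.03)
        assert p.phase_lag_deg == pytest.approx(lag_exp, abs=2.0)
    # ~49 degrees of lag at 20 Hz for tau = 10 ms
    assert fr.points[-1].phase_lag_deg == pytest.approx(48.8, abs=2.0)


def test_normalisation_is_exact_at_two_hz(sinus_bundle):
    fr = pp.frequency_response(sinus_bundle)
    assert fr.normalized_coupling[0] == 1.0
    assert np.all(np.diff(fr.normalized_coupling) < 0)


def test_injected_cell_fit_residual_is_noise_level(sinus_bundle):
    fr = pp.frequency_response(sinus_bundle)
    for p in fr.points:
        assert p.fit_residual_mv < 0.05  # well under the 0.1 mV noise SD


def test_frequency_response_needs_two_cycles(sinus_bundle):
    b = sinus_bundle
    short = pp.SweepBundle(
        pair_id=b.pair_id, protocol=b.protocol,
        sweeps=[s[:, :4000] for s in b.sweeps],
        sweep_labels=list(b.sweep_labels), modes=b.modes,
        sampling_rate_hz=b.sampling_rate_hz)
    with pytest.raises(ValueError, match="cycles"):
        pp.frequency_response(short)


# --------------------------------------------------------------------------
# Pharmacology emulation
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def electrical_train():
    spec = pp.PairModelSpec(gap=pp.GapJunctionParams(1.0), seed=9)
    return spec, pp.simulate_pair(spec, pp.PulseTrainProtocol(injected_cell=1))


def test_identical_bundles_give_hundred_percent(electrical_train):
    _, pre = electrical_train
    dc = pp.drug_comparison(pre, pre, "gap_block")
    assert dc.percent_of_control == 100.0
    assert dc.latency_shift_ms == 0.0


def test_gap_block_scales_epsp_with_conductance(electrical_train):
    spec, pre = electrical_train
    blocked = pp.gap_junction_block(spec, fraction_remaining=0.2)
    post = pp.simulate_pair(blocked, pre.protocol)
    dc = pp.drug_comparison(pre, post, "gap_block")
    assert dc.percent_of_control == pytest.approx(20.0, abs=3.0)
    assert abs(dc.latency_shift_ms) < 0.5


def test_glutamatergic_block_spares_electrical_epsps(electrical_train):
    spec, pre = electrical_train
    post = pp.simulate_pair(pp.glutamatergic_block(spec), pre.protocol)
    dc = pp.drug_comparison(pre, post, "glutamatergic_block")
    assert dc.percent_of_control == pytest.approx(100.0, abs=5.0)


def test_drug_comparison_rejects_mismatched_protocols(electrical_train):
    spec, pre = electrical_train
    other = pp.simulate_pair(spec, pp.PulseTrainProtocol(
        injected_cell=1, pulse_amplitude_pa=200.0, n_sweeps=5))
    with pytest.raises(ValueError, match="do not match"):
        pp.drug_comparison(pre, other, "gap_block")


def test_epsp_amplitude_scales_linearly_with_small_gj():
    """Doubling gj (gj << g_leak) doubles the transferred EPSP."""
    amps = {}
    for gj in (0.25, 0.5):
        spec = pp.PairModelSpec(gap=pp.GapJunctionParams(gj), seed=26)
        b = pp.simulate_pair(spec, pp.PulseTrainProtocol(injected_cell=1,
                                                         n_sweeps=20))
        from pairpatch.classify import evaluate_direction
        amps[gj] = evaluate_direction(b).amplitude_mv
    assert amps[0.5] == pytest.approx(2.0 * amps[0.25], rel=0.08)
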