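"""Shared fixtures: representative simulated pairs reused across tests."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pairpatch as pp

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


ELEC_SPEC = pp.PairModelSpec(gap=pp.GapJunctionParams(1.0), seed=11)
CHEM_SPEC = pp.PairModelSpec(
    chem_synapses=(pp.ChemSynParams(pre_cell=1, release_probability=0.3),),
    seed=12)
UNCONN_SPEC = pp.PairModelSpec(seed=13)

# deterministic (noise-free) variants for convention checks
CHEM_CLEAN_SPEC = pp.PairModelSpec(
    chem_synapses=(pp.ChemSynParams(pre_cell=1, release_probability=1.0),),
    noise_sd_mv=0.0, seed=1)

STEP_AMPS = (-60.0, -30.0, 30.0, 60.0)


@pytest.fixture(scope="session")
def electrical_pulse():
    return pp.simulate_pair(ELEC_SPEC, pp.PulseTrainProtocol(injected_cell=1))


@pytest.fixture(scope="session")
def electrical_pulse_rev():
    return pp.simulate_pair(ELEC_SPEC, pp.PulseTrainProtocol(injected_cell=2))


@pytest.fixture(scope="session")
def electrical_steps():
    return pp.simulate_pair(
        ELEC_SPEC, pp.StepFamilyProtocol(injected_cell=1,
                                         amplitudes_pa=STEP_AMPS,
                                         n_repeats=2))


@pytest.fixture(scope="session")
def electrical_steps_rev():
    return pp.simulate_pair(
        ELEC_SPEC, pp.StepFamilyProtocol(injected_cell=2,
                                         amplitudes_pa=STEP_AMPS,
                                         n_repeats=2))


@pytest.fixture(scope="session")
def chemical_pulse():
    return pp.simulate_pair(CHEM_SPEC, pp.PulseTrainProtocol(injected_cell=1))


@pytest.fixture(scope="session")
def chemical_pulse_rev():
    return pp.simulate_pair(CHEM_SPEC, pp.PulseTrainProtocol(injected_cell=2))


@pytest.fixture(scope="session")
def chemical_steps():
    return pp.simulate_pair(
        CHEM_SPEC, pp.StepFamilyProtocol(injected_cell=1,
                                         amplitudes_pa=STEP_AMPS,
                                         n_repeats=2))


@pytest.fixture(scope="session")
def chemical_steps_rev():
    return pp.simulate_pair(
        CHEM_SPEC, pp.StepFamilyProtocol(injected_cell=2,
                                         amplitudes_pa=STEP_AMPS,
                                         n_repeats=2))


@pytest.fixture(scope="session")
def unconnected_pulse():
    return pp.simulate_pair(UNCONN_SPEC,
                            pp.PulseTrainProtocol(injected_cell=1))


@pytest.fixture(scope="session")
def chem_clean_pulse():
    """Noise-free p=1 chemical pair, single sweep: latency conventions."""
    return pp.simulate_pair(CHEM_CLEAN_SPEC,
                            pp.PulseTrainProtocol(injected_cell=1, n_sweeps=1))
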