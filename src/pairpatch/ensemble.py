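"""Labelled synthetic ensembles for classifier validation.

``make_ensemble`` draws pairs from three ground-truth classes —
bidirectionally gap-junction-coupled (gj uniform in 0.5-3 nS), one-way
chemically connected (release probability uniform in 0.2-0.9, random
direction), and unconnected — with mild cell-to-cell variability in
passive properties.  ``run_ensemble`` pushes every pair through the full
measurement chain (pulse trains both directions, sub-threshold step
families both directions, classification) and tabulates the verdicts
against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import (
    BIDIRECTIONAL_ELECTRICAL,
    NOT_CONNECTED,
    UNIDIRECTIONAL_CHEMICAL,
    ConnectionCall,
    classify_pair_from_bundles,
)
from .model import (
    ChemSynParams,
    GapJunctionParams,
    NeuronParams,
    PairModelSpec,
    PulseTrainProtocol,
    StepFamilyProtocol,
)
from .simulate import simulate_pair

#: ground-truth parameter ranges of the validation ensemble
GJ_RANGE_NS = (0.5, 3.0)
RELEASE_P_RANGE = (0.2, 0.9)

#: sub-rheobase steps used for the ensemble transfer test; two repeats keep
#: the steady-state SEM well below the weakest expected transfer
ENSEMBLE_STEP_AMPS = (-60.0, -30.0, 30.0, 60.0)
ENSEMBLE_STEP_REPEATS = 2


@dataclass(frozen=True)
class LabelledPair:
    pair_id: str
    spec: PairModelSpec
    true_label: str
    true_direction: Optional[tuple[int, int]]


def _jittered_neuron(rng: np.random.Generator) -> NeuronParams:
    return NeuronParams(
        capacitance_pf=float(rng.uniform(90.0, 110.0)),
        leak_conductance_ns=float(rng.uniform(9.0, 11.0)),
    )


def make_ensemble(n_electrical: int = 20, n_chemical: int = 20,
                  n_unconnected: int = 20, seed: int = 0,
                  gj_range_ns: tuple[float, float] = GJ_RANGE_NS,
                  p_range: tuple[float, float] = RELEASE_P_RANGE,
                  ) -> list[LabelledPair]:
    """Draw a labelled ensemble; ``seed`` fixes every pair completely."""
    ss = np.random.SeedSequence((int(seed) & 0x7FFFFFFF, 0xE5))
    rng = np.random.default_rng(ss)
    pairs: list[LabelledPair] = []

    def _pair_seed() -> int:
        return int(rng.integers(0, 2 ** 31 - 1))

    for i in range(n_electrical):
        spec = PairModelSpec(
            neuron_1=_jittered_neuron(rng), neuron_2=_jittered_neuron(rng),
            gap=GapJunctionParams(float(rng.uniform(*gj_range_ns))),
            noise_sd_mv=0.1, seed=_pair_seed())
        pairs.append(LabelledPair(f"elec_{i:03d}", spec,
                                  BIDIRECTIONAL_ELECTRICAL, None))
    for i in range(n_chemical):
        pre = int(rng.integers(1, 3))
        syn = ChemSynParams(pre_cell=pre,
                            release_probability=float(rng.uniform(*p_range)))
        spec = PairModelSpec(
            neuron_1=_jittered_neuron(rng), neuron_2=_jittered_neuron(rng),
            gap=GapJunctionParams(0.0), chem_synapses=(syn,),
            noise_sd_mv=0.1, seed=_pair_seed())
        pairs.append(LabelledPair(f"chem_{i:03d}", spec,
                                  UNIDIRECTIONAL_CHEMICAL, syn.direction))
    for i in range(n_unconnected):
        spec = PairModelSpec(
            neuron_1=_jittered_neuron(rng), neuron_2=_jittered_neuron(rng),
            gap=GapJunctionParams(0.0), noise_sd_mv=0.1, seed=_pair_seed())
        pairs.append(LabelledPair(f"none_{i:03d}", spec, NOT_CONNECTED, None))
    return pairs


def analyze_labelled_pair(pair: LabelledPair,
                          n_pulse_sweeps: int = 50) -> ConnectionCall:
    """Run the full two-direction protocol battery and classify one pair."""
    calls = {}
    for inj in (1, 2):
        pulse = simulate_pair(pair.spec,
                              PulseTrainProtocol(injected_cell=inj,
                                                 n_sweeps=n_pulse_sweeps),
                              pair_id=pair.pair_id)
        step = simulate_pair(pair.spec,
                             StepFamilyProtocol(
                                 injected_cell=inj,
                                 amplitudes_pa=ENSEMBLE_STEP_AMPS,
                                 n_repeats=ENSEMBLE_STEP_REPEATS),
                             pair_id=pair.pair_id)
        calls[inj] = (pulse, step)
    return classify_pair_from_bundles(calls[1][0], calls[2][0],
                                      calls[1][1], calls[2][1])


@dataclass(frozen=True)
class EnsembleResult:
    table: pd.DataFrame            # per-pair truth vs verdict
    confusion: pd.DataFrame        # truth rows x verdict columns

    @property
    def accuracy(self) -> float:
        t = self.table
        correct = (t["true_label"] == t["called_label"])
        direction_ok = (t["true_label"] != UNIDIRECTIONAL_CHEMICAL) | \
            (t["true_direction"] == t["called_direction"])
        return float((correct & direction_ok).mean())

    def confusions(self, truth: str, called: str) -> int:
        try:
            return int(self.confusion.loc[truth, called])
        except KeyError:
            return 0


LABELS = (BIDIRECTIONAL_ELECTRICAL, UNIDIRECTIONAL_CHEMICAL, NOT_CONNECTED)


def run_ensemble(pairs: Sequence[LabelledPair],
                 n_pulse_sweeps: int = 50) -> EnsembleResult:
    rows = []
    for pair in pairs:
        call = analyze_labelled_pair(pair, n_pulse_sweeps=n_pulse_sweeps)
        rows.append({
            "pair_id": pair.pair_id,
            "true_label": pair.true_label,
            "called_label": call.label,
            "true_direction": str(pair.true_direction),
            "called_direction": str(call.direction),
            "onset_latency_12_ms": call.evidence_12.onset_latency_ms,
            "onset_latency_21_ms": call.evidence_21.onset_latency_ms,
            "failure_rate_12": call.evidence_12.failure_rate,
            "failure_rate_21": call.evidence_21.failure_rate,
            "amplitude_12_mv": call.evidence_12.amplitude_mv,
            "amplitude_21_mv": call.evidence_21.amplitude_mv,
            "transfer_ratio_12": (call.step_12.transfer_ratio
                                  if call.step_12 else np.nan),
            "transfer_ratio_21": (call.step_21.transfer_ratio
                                  if call.step_21 else np.nan),
            "notes": ";".join(call.notes),
        })
    table = pd.DataFrame(rows)
    confusion = pd.crosstab(table["true_label"], table["called_label"]) \
        .reindex(index=LABELS, columns=LABELS, fill_value=0)
    return EnsembleResult(table=table, confusion=confusion)
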