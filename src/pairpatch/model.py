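"""Domain types for paired-recording simulation and analysis.

Unit conventions used throughout the package: time in ms, voltage in mV,
current in pA, conductance in nS, capacitance in pF.  With this system
``C dV/dt`` is in pA and ``g * V`` in pA, so the two-neuron membrane
equation requires no conversion factors.  Sampling rates are quoted in Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional, Sequence, Union

import numpy as np

AGE_GROUPS = ("P0-5", "P13-17", "P23-35", "adult")
SUBTYPES = ("nonV2a", "V2a", "unlabeled")
PREPARATIONS = ("slice", "dorsal_horn_removed")

CURRENT_CLAMP = "current_clamp"
VOLTAGE_CLAMP = "voltage_clamp"


def _require_finite(obj) -> None:
    for f in fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, (int, float)) and not math.isfinite(v):
            raise ValueError(f"{type(obj).__name__}.{f.name} must be finite, got {v!r}")


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire cell with a stereotyped action-potential waveform.

    The subthreshold membrane is a single RC compartment
    ``C dV/dt = -g_leak (V - E_leak) + I``; when V crosses
    ``spike_threshold_mv`` a fixed half-cosine AP waveform of height
    ``ap_amplitude_mv`` and duration ``ap_width_ms`` is pasted onto the
    trace, after which V restarts from ``spike_reset_mv``.

    Defaults describe a generic ventral interneuron resting near -65 mV
    with a 10 ms membrane time constant; they are deliberately exposed in
    config because measured passive properties for these cells are not
    available.
    """

    capacitance_pf: float = 100.0
    leak_conductance_ns: float = 10.0
    leak_reversal_mv: float = -65.0
    spike_threshold_mv: float = -52.0
    spike_reset_mv: float = -57.0
    refractory_ms: float = 5.0
    ap_amplitude_mv: float = 80.0
    ap_width_ms: float = 2.0

    def __post_init__(self):
        _require_finite(self)
        if self.capacitance_pf <= 0:
            raise ValueError("capacitance must be > 0")
        if self.leak_conductance_ns <= 0:
            raise ValueError("leak conductance must be > 0")
        if self.ap_width_ms <= 0:
            raise ValueError("ap_width must be > 0")
        if self.spike_threshold_mv <= self.leak_reversal_mv:
            raise ValueError("spike threshold must be above the leak reversal")

    @property
    def tau_ms(self) -> float:
        """Membrane time constant C/g_leak in ms."""
        return self.capacitance_pf / self.leak_conductance_ns

    @property
    def rheobase_pa(self) -> float:
        """Analytic rheobase of the isolated cell, g_leak * (theta - E_leak)."""
        return self.leak_conductance_ns * (
            self.spike_threshold_mv - self.leak_reversal_mv
        )


@dataclass(frozen=True)
class GapJunctionParams:
    """Ohmic, non-rectifying junctional conductance; 0 means unconnected."""

    gj_ns: float = 0.0

    def __post_init__(self):
        _require_finite(self)
        if self.gj_ns < 0:
            raise ValueError("gap-junction conductance must be >= 0")


@dataclass(frozen=True)
class ChemSynParams:
    """Stochastic chemical synapse from ``pre_cell`` onto the other cell.

    Release is drawn independently per presynaptic spike with
    ``release_probability``; a successful release opens a difference-of-
    exponentials conductance (normalised to ``peak_conductance_ns``)
    ``delay_ms`` after the presynaptic AP peak.
    """

    pre_cell: int = 1
    release_probability: float = 0.3
    delay_ms: float = 2.0
    tau_rise_ms: float = 0.5
    tau_decay_ms: float = 5.0
    peak_conductance_ns: float = 0.6
    reversal_mv: float = 0.0

    def __post_init__(self):
        _require_finite(self)
        if self.pre_cell not in (1, 2):
            raise ValueError("pre_cell must be 1 or 2")
        if not 0.0 <= self.release_probability <= 1.0:
            raise ValueError("release_probability must be in [0, 1]")
        if self.delay_ms < 0:
            raise ValueError("delay must be >= 0")
        if not self.tau_decay_ms > self.tau_rise_ms > 0:
            raise ValueError("need tau_decay > tau_rise > 0")
        if self.peak_conductance_ns < 0:
            raise ValueError("peak conductance must be >= 0")

    @property
    def post_cell(self) -> int:
        return 2 if self.pre_cell == 1 else 1

    @property
    def direction(self) -> tuple[int, int]:
        return (self.pre_cell, self.post_cell)

    @property
    def time_to_peak_ms(self) -> float:
        """Rise time of the conductance transient (peak relative to onset)."""
        tr, td = self.tau_rise_ms, self.tau_decay_ms
        return math.log(td / tr) * td * tr / (td - tr)


@dataclass(frozen=True)
class PairModelSpec:
    """Ground truth for one simulated pair.

    ``noise_sd_mv`` is the target standard deviation of the baseline
    membrane-potential noise of each isolated cell; internally it is
    realised as white current noise low-pass filtered by the membrane.
    ``seed`` fully determines all stochastic output.
    """

    neuron_1: NeuronParams = NeuronParams()
    neuron_2: NeuronParams = NeuronParams()
    gap: GapJunctionParams = GapJunctionParams()
    chem_synapses: tuple[ChemSynParams, ...] = ()
    noise_sd_mv: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not math.isfinite(self.noise_sd_mv) or self.noise_sd_mv < 0:
            raise ValueError("noise_sd_mv must be finite and >= 0")
        syns = tuple(self.chem_synapses)
        object.__setattr__(self, "chem_synapses", syns)
        if len(syns) > 2:
            raise ValueError("at most two chemical synapses (one per direction)")
        dirs = [s.direction for s in syns]
        if len(set(dirs)) != len(dirs):
            raise ValueError("at most one chemical synapse per direction")

    def neuron(self, cell: int) -> NeuronParams:
        return self.neuron_1 if cell == 1 else self.neuron_2

    def synapse(self, pre_cell: int) -> Optional[ChemSynParams]:
        for s in self.chem_synapses:
            if s.pre_cell == pre_cell:
                return s
        return None


# --------------------------------------------------------------------------
# Stimulation protocols
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseTrainProtocol:
    """Suprathreshold pulse train: 5 x 10 ms pulses, 20 ms gaps, 50 sweeps.

    The injected cell is driven with strong (100-300 pA) pulses so every
    pulse evokes one AP; the other cell is recorded in current clamp
    (biased near rest) or in ideal voltage clamp at ``vc_hold_mv``.
    ``start_to_start_s`` is inter-sweep bookkeeping only: sweeps carry
    independent noise so the quiet gap between them is not simulated.
    """

    injected_cell: int = 1
    pulse_amplitude_pa: float = 250.0
    n_pulses: int = 5
    pulse_width_ms: float = 10.0
    isi_ms: float = 20.0
    n_sweeps: int = 50
    start_to_start_s: float = 2.0
    pre_ms: float = 100.0
    tail_ms: float = 150.0
    post_mode: str = CURRENT_CLAMP
    vc_hold_mv: float = -60.0
    sampling_rate_hz: float = 10_000.0

    kind = "pulse_train"

    def __post_init__(self):
        if self.injected_cell not in (1, 2):
            raise ValueError("injected_cell must be 1 or 2")
        if not 100.0 <= self.pulse_amplitude_pa <= 300.0:
            raise ValueError("pulse amplitude must be within 100-300 pA")
        if self.post_mode not in (CURRENT_CLAMP, VOLTAGE_CLAMP):
            raise ValueError(f"unknown post_mode {self.post_mode!r}")
        if self.n_sweeps < 1 or self.n_pulses < 1:
            raise ValueError("need at least one sweep and one pulse")

    @property
    def pulse_onsets_ms(self) -> np.ndarray:
        step = self.pulse_width_ms + self.isi_ms
        return self.pre_ms + step * np.arange(self.n_pulses)

    @property
    def sweep_duration_ms(self) -> float:
        return float(self.pulse_onsets_ms[-1] + self.pulse_width_ms + self.tail_ms)


@dataclass(frozen=True)
class StepFamilyProtocol:
    """Family of 1 s current steps in 5 pA increments.

    Used for rheobase, DC coupling coefficients and the sub-threshold
    transfer test.  Each amplitude is repeated ``n_repeats`` times and the
    repeats averaged downstream: a single 1 s step with the default noise
    level leaves the steady-state window mean too uncertain for a percent-
    level coupling coefficient.
    """

    injected_cell: int = 1
    amplitudes_pa: tuple[float, ...] = ()
    step_ms: float = 1000.0
    pre_ms: float = 200.0
    post_ms: float = 300.0
    n_repeats: int = 5
    increment_pa: float = 5.0
    sampling_rate_hz: float = 10_000.0
    post_mode: str = CURRENT_CLAMP

    kind = "step_family"

    def __post_init__(self):
        if self.injected_cell not in (1, 2):
            raise ValueError("injected_cell must be 1 or 2")
        amps = tuple(float(a) for a in self.amplitudes_pa)
        object.__setattr__(self, "amplitudes_pa", amps)
        if not amps:
            raise ValueError("step family needs at least one amplitude")
        if any(b <= a for a, b in zip(amps, amps[1:])):
            raise ValueError("step amplitudes must be strictly increasing")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.post_mode != CURRENT_CLAMP:
            raise ValueError("step transfer is a current-clamp protocol")

    @property
    def sweep_duration_ms(self) -> float:
        return self.pre_ms + self.step_ms + self.post_ms

    @property
    def step_window_ms(self) -> tuple[float, float]:
        return (self.pre_ms, self.pre_ms + self.step_ms)


def depolarizing_step_family(injected_cell: int = 1,
                             start_pa: float = 100.0,
                             stop_pa: float = 150.0,
                             increment_pa: float = 5.0,
                             **kw) -> StepFamilyProtocol:
    """Convenience family spanning the rheobase region in 5 pA increments."""
    amps = tuple(np.arange(start_pa, stop_pa + 0.5 * increment_pa, increment_pa))
    return StepFamilyProtocol(injected_cell=injected_cell, amplitudes_pa=amps,
                              increment_pa=increment_pa, **kw)


ALLOWED_SINUSOID_HZ = (0.2, 1.0, 2.0, 5.0, 10.0, 20.0)


@dataclass(frozen=True)
class SinusoidProtocol:
    """Subthreshold +/-20 pA sinusoidal injection at fixed frequencies.

    Sweep duration is an integer number of cycles covering at least
    ``min_fit_s`` (plus 1.5 s per Hz at high frequency) after a short
    settling pad, so the least-squares sinusoid fit on the 10-sweep
    average resolves the transferred amplitude to ~1%.
    """

    injected_cell: int = 1
    frequencies_hz: tuple[float, ...] = ALLOWED_SINUSOID_HZ
    amplitude_pa: float = 20.0
    n_sweeps: int = 10
    pad_ms: float = 200.0
    min_fit_s: float = 25.0
    sampling_rate_hz: float = 10_000.0
    post_mode: str = CURRENT_CLAMP

    kind = "sinusoid"

    def __post_init__(self):
        if self.injected_cell not in (1, 2):
            raise ValueError("injected_cell must be 1 or 2")
        freqs = tuple(float(f) for f in self.frequencies_hz)
        object.__setattr__(self, "frequencies_hz", freqs)
        if not freqs:
            raise ValueError("need at least one frequency")
        if any(f <= 0 for f in freqs):
            raise ValueError("all frequencies must be positive")
        if self.sampling_rate_hz <= 2 * max(freqs):
            raise ValueError("sampling rate must exceed twice the highest frequency")
        if self.post_mode != CURRENT_CLAMP:
            raise ValueError("sinusoid transfer is a current-clamp protocol")

    def n_cycles(self, f_hz: float) -> int:
        target_s = max(self.min_fit_s, 1.5 * f_hz)
        return max(2, int(math.ceil(target_s * f_hz)))

    def sweep_duration_ms(self, f_hz: float) -> float:
        return self.pad_ms + 1000.0 * self.n_cycles(f_hz) / f_hz


ProtocolSpec = Union[PulseTrainProtocol, StepFamilyProtocol, SinusoidProtocol]


# --------------------------------------------------------------------------
# Recorded data containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PairMeta:
    """Cell/recording metadata carried alongside each bundle."""

    subtype: str = "unlabeled"
    age_group: str = "P0-5"
    preparation: str = "slice"
    distance_um: float = float("nan")

    def __post_init__(self):
        if self.subtype not in SUBTYPES:
            raise ValueError(f"subtype must be one of {SUBTYPES}")
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"age_group must be one of {AGE_GROUPS}")
        if self.preparation not in PREPARATIONS:
            raise ValueError(f"preparation must be one of {PREPARATIONS}")


@dataclass
class SweepBundle:
    """One paired-recording session: aligned sweeps plus protocol metadata.

    Each sweep is a ``(3, n)`` float64 array with rows
    ``(i_inj_pA, cell1, cell2)``.  A cell channel holds membrane potential
    (mV) in current clamp or clamp current (pA) in voltage clamp, per
    ``modes``.  ``sweep_labels`` annotates each sweep with the step
    amplitude (pA), the sinusoid frequency (Hz), or the sweep index.
    ``spike_log``/``release_log`` are simulator ground truth: per-sweep AP
    peak times for each cell, and per-synapse release outcomes per
    presynaptic spike.
    """

    pair_id: str
    protocol: ProtocolSpec
    sweeps: list[np.ndarray]
    sweep_labels: list[float]
    modes: tuple[str, str]
    sampling_rate_hz: float
    meta: PairMeta = field(default_factory=PairMeta)
    ground_truth: Optional[PairModelSpec] = None
    spike_log: Optional[list[tuple[np.ndarray, np.ndarray]]] = None
    # per sweep: list of per-synapse int8 arrays, one entry per presynaptic spike
    release_log: Optional[list[list[np.ndarray]]] = None

    def __post_init__(self):
        if len(self.sweeps) != len(self.sweep_labels):
            raise ValueError("one label per sweep required")
        for sw in self.sweeps:
            if sw.ndim != 2 or sw.shape[0] != 3:
                raise ValueError("each sweep must be a (3, n) array")

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    @property
    def injected_cell(self) -> int:
        return self.protocol.injected_cell

    @property
    def post_cell(self) -> int:
        return 2 if self.injected_cell == 1 else 1

    def time_ms(self, sweep: int = 0) -> np.ndarray:
        return np.arange(self.sweeps[sweep].shape[1]) * self.dt_ms

    def cell_trace(self, cell: int, sweep: int) -> np.ndarray:
        return self.sweeps[sweep][cell]

    def command(self, sweep: int) -> np.ndarray:
        return self.sweeps[sweep][0]

    def sweeps_with_label(self, label: float, atol: float = 1e-9) -> list[int]:
        return [i for i, l in enumerate(self.sweep_labels)
                if abs(l - label) <= atol]

    def mode_of(self, cell: int) -> str:
        return self.modes[cell - 1]
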