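# Methods

This note documents the models, estimators and numerical choices behind
`pairpatch`, in the spirit of a methods section: what is assumed, what
the defaults mean, and what the synthetic test bed does and does not
establish about real recordings.

## The two-cell model

Each cell is a leaky integrate-and-fire compartment

    C_i dV_i/dt = -g_leak,i (V_i - E_i) + g_j (V_j - V_i)
                  + Σ_syn g_syn(t) (E_rev - V_i) + I_inj,i + I_noise,i

with a **stereotyped action potential** pasted at threshold crossings: a
half-cosine bump of height `ap_amplitude_mv` and width `ap_width_ms`
replaces the displayed voltage, after which integration restarts from
`spike_reset_mv` following an absolute refractory period. The pasted
waveform drives the gap junction, so spikelets in the coupled cell have
realistic shapes and the sub-threshold dynamics retain exact closed-form
solutions — the property all the oracles in the test suite rely on.

The **gap junction** is ohmic, non-rectifying and voltage-independent
(no rectification is assumed). The **chemical synapse** is a
difference-of-exponentials conductance (τ_rise < τ_decay, normalised so
its peak equals `peak_conductance_ns`), gated per presynaptic spike by
an independent Bernoulli draw with `release_probability`, and delayed by
`delay_ms` relative to the presynaptic AP peak.

**Voltage clamp is ideal** (zero series resistance): the clamped cell
sits exactly at the holding potential and the recorded channel is the
amplifier current. An EPSC at −60 mV with a 0 mV-reversal synapse is
therefore inward (negative), `g_syn·(E_rev − V_hold)` sign-flipped into
amplifier convention.

### Default parameters

| parameter | default | rationale |
|---|---|---|
| C | 100 pF | passive properties of these interneurons are not published; τ = C/g = 10 ms is a generic interneuron value, exposed in config |
| g_leak | 10 nS | as above (input resistance 100 MΩ) |
| E_leak | −65 mV | cells rest/are biased near −65 mV |
| spike threshold | −52 mV | gives a 130 pA rheobase and guarantees one AP per 10 ms pulse at the 100–300 pA protocol amplitudes |
| AP height / width | 80 mV / 2 ms | peak near +28 mV, realistic spikelet drive |
| refractory | 5 ms | prevents double firing within one 10 ms pulse |
| g_j | 0–3 nS | yields coupling coefficients ~2–23%, the experimentally observed range |
| synapse g_peak | 0.6 nS, τ 0.5/5 ms, delay 2 ms | unitary EPSP ≈ 1.4 mV and onset ≈ 2 ms after the AP peak, the scale reported for these connections |
| noise | 0.1 mV baseline SD | realised as white current noise scaled by `σ_c = SD·C·√(2/τ)` so the membrane-filtered voltage noise hits the target; makes detection thresholds meaningful |

Integration is Heun's method (second order) at a fixed 0.1 ms step, the
10 kHz sampling grid of the emulated rig; against `scipy.solve_ivp` at
`rtol=1e-10` the sub-threshold traces agree to <1 µV. Randomness derives
from one master seed: each (protocol, injected cell, sweep) gets its own
`SeedSequence` child, so identical inputs are bit-identical and sweeps
are statistically independent.

## Event measurement conventions

All event measurements run on traces smoothed with a zero-lag Gaussian
(−3 dB at 1 kHz). Latencies are referenced to the presynaptic AP peak:
**EPSC latency** is peak-to-peak; **EPSP latency** is peak-to-onset and
is negative when the depolarisation leads the AP peak, as it does
through a gap junction.

**Onset** is the point where the trace first exceeds
`baseline + 3·SD` (with a 5 %-of-peak floor so noiseless traces remain
well posed), taking the criterion crossing contiguous with the response
peak and backtracking to the preceding local minimum, stopping at the
baseline-noise floor. Several alternatives (first crossing anywhere in
the window; unbounded backtracking) were found to chase detached noise
bumps or flat-baseline ties and were rejected.

**Baseline SD estimation.** A single 50 ms window of membrane-filtered
noise (τ = 10 ms) contains only a handful of independent samples and
underestimates the SD by up to a factor of two. All detection criteria
therefore use an SD **pooled across sweeps** (per-sweep demeaned),
divided by √n for n-sweep averages.

**Per-sweep response criterion = 5 SD.** The extremum of
membrane-filtered noise over the 15 ms detection window exceeds 3 SD on
~7 % of sweeps — an intrinsic excursion property of the noise, hardly
reduced by smoothing — which would contaminate failure-conditional
averages with false "responses". At 5 SD the false-positive rate is
negligible while unitary EPSPs (>10 SD) are never missed. Averaged-trace
measurements keep the conventional 3 SD criterion, plus an absolute
0.1 mV floor for *declaring a connection*, because extremum statistics
of the residual averaged noise would otherwise fabricate responses on
unconnected pairs.

## Classification rule

A pair is **bidirectional_electrical** when both directions respond,
onset latencies are below +0.5 ms, and the sub-threshold step-transfer
test (steady-state deflection of the non-injected cell > 3× its SEM with
matching sign, both polarities, both directions) passes — step transfer
is the decisive criterion. A pair is **unidirectional_chemical** when
exactly one direction responds, no step transfer exists, and the onset
latency is clearly positive *or* the failure rate is ≥ 0.2 while the
onset is not unambiguously electrical (≤ −3 ms); the failure fallback
exists because onset estimation on a ~10-sweep responding-only average
occasionally slides below +0.5 ms, while electrical transfer never
fails. Everything else is **not_connected**, with ambiguous evidence
recorded in the call's notes. The step-transfer SEM uses a deterministic
noise-based estimator (window-mean variance `2σ²τ_int/T` with the
integrated autocorrelation time estimated from pooled baselines); an
empirical across-repeat SEM from 2–5 repeats is a noisy ratio that
produced ~20 % false transfers in development.

Latency conventions the rule relies on (onset ≈ synapse delay for
chemical pairs; onset several ms negative for electrical pairs; EPSC
peak latency ≈ delay + conductance rise time) are asserted against
noise-free simulations in the test suite.

## Protocol sizing

* **Step families** repeat each amplitude (default 5×) and average
  repeats: the steady-state window mean of one 1 s step has ~0.032 mV
  SE under default noise, too coarse for a ±0.005 coupling-coefficient
  band; five repeats bring the k SE to ~0.0016.
* **Sinusoid sweeps** last `max(25 s, 1.5·f s)` per frequency (integer
  cycles after a 200 ms settling pad, 10 sweeps averaged). This comes
  from an a-priori power analysis: the LSQ amplitude-fit variance is
  `2·S(f)/T` with `S` the averaged-noise spectral density, and these
  durations keep the fit SE near 1 % of the transferred signal so the
  3 % transfer oracle is meaningful. Between 0.2 and 2 Hz the true
  transfer varies by <1 %, so monotonicity of normalized coupling in
  that flat region is only assessed to within 1 %.
* **Coupling step families** for the DC oracle span 100–150 pA in 5 pA
  increments, bracketing the ~140 pA rheobase of the default cell.

## Ventral-root generator and rhythm analysis

Channels are white carrier noise amplitude-modulated by a periodic burst
envelope (duty default 0.4, 50 ms cosine edges, additive sensor noise),
with per-channel phases in cycle fractions and an optional mid-recording
frequency switch emulating drug wash-in. Default sampling is 1 kHz —
sufficient for envelope analysis, not a model of motor-unit spectra.

Burst detection: rectify → 4 Hz low-pass envelope → threshold at
mean + 0.5 SD → merge gaps < 250 ms → drop bursts < 250 ms, all five
constants exposed. A modulation-depth guard (envelope CV < 0.3 → "no
rhythm") rejects unmodulated noise, whose flat envelope would otherwise
produce spurious threshold crossings. Cycle frequency is the reciprocal
mean onset-to-onset interval (≥5 cycles required); alternation is a
circular mean phase in [0.4, 0.6] with resultant ≥ 0.7.

## Statistics

Standard tests delegate to scipy/statsmodels (Mann-Whitney, paired t,
Kruskal-Wallis, Pearson chi-square without continuity correction,
type-II two-way ANOVA). Dunn's post-hoc is computed from its textbook
rank-z definition with tie correction and Bonferroni adjustment, since
no installed package provides it; it is verified against an independent
re-derivation in the tests. Because pairing a two-way ANOVA with
Mann-Whitney post-hocs is unusual, the ANOVA result and the pairwise
Mann-Whitney table are exposed side by side without asserting either as
canonical. For age-group incidence the chi-square is computed both over
all four age groups and over the three older groups; the four-group
variant reproduces the conventional result for these counts
(p ≈ 0.008). A paired t on zero-variance differences reports p = 1
(identical) or NaN (constant shift) with a note instead of failing.

## What the synthetic tests do and do not show

The generator reproduces the *structure* of the experiments: protocol
timing, sampling, sweep counts, realistic coupling strengths, high
failure rates, spikelet shapes, and alternating burst trains with a
frequency drop after wash-in. It does **not** model active dendrites,
HH channel kinetics, series-resistance artifacts, electrode drift,
synaptic depression/facilitation within the 5-pulse train, or real drug
pharmacodynamics (blockers are emulated as parameter changes: chemical
synapses removed, or g_j scaled to a residual fraction — carbenoxolone
does not fully close junctions, hence the 20 % default residual).
Passing tests therefore establish that the *analysis chain* is correct
and well calibrated under the stated noise model, not that it is robust
to every artifact of real rigs; the detection constants are exposed so
they can be re-tuned against real data.

## Known limitations

* The LIF cells have a single time constant; coupling-coefficient and
  transfer oracles assume passivity below threshold, which the model
  enforces exactly but real neurons only approximate.
* Classification assumes the study's protocol battery (both directions
  pulsed, step families available); with steps missing, electrical
  coupling is deliberately left unconfirmed rather than guessed.
* The ensemble used for classifier validation draws cell parameters
  within ±10 % of defaults; performance on strongly heterogeneous
  populations is untested.
* Mixed electrical+chemical pairs are flagged
  (`possible_chemical_component`) rather than decomposed.
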