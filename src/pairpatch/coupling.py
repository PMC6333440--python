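"""Electrical-coupling quantification.

Rheobase and the DC coupling coefficient follow the standard paired-
recording definitions: rheobase is the lowest 5 pA step that evokes an
AP, and the coupling coefficient k is the steady-state voltage deflection
of the non-injected cell divided by that of the injected cell at the
depolarising step just below rheobase.  For a passive pair the expected
value is k = gj / (g_leak,post + gj), and under sinusoidal drive the
transfer is gj / |(g_leak,post + gj) + i 2 pi f C_post|, i.e. the
electrical synapse behaves as a first-order low-pass filter with phase
lag arctan(2 pi f C_post / (g_leak,post + gj)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import (
    CURRENT_CLAMP,
    PulseTrainProtocol,
    SinusoidProtocol,
    StepFamilyProtocol,
    SweepBundle,
)
from .sweeps import (
    average_sweeps,
    detect_spikes,
    measure_response,
    pooled_baseline_sd,
    qc_sweeps,
)

STEADY_MS = 200.0   # steady-state window: last 200 ms of the 1 s step


# --------------------------------------------------------------------------
# Rheobase and DC coupling
# --------------------------------------------------------------------------

def _step_spike_count(bundle: SweepBundle, sweep: int) -> int:
    proto = bundle.protocol
    w0, w1 = proto.step_window_ms
    tr = bundle.cell_trace(bundle.injected_cell, sweep)
    st = detect_spikes(tr, bundle.sampling_rate_hz)
    return int(np.sum((st.peak_times_ms >= w0) & (st.peak_times_ms <= w1)))


def compute_rheobase(bundle: SweepBundle) -> float:
    """Lowest step amplitude (pA) evoking at least one AP in any repeat."""
    if not isinstance(bundle.protocol, StepFamilyProtocol):
        raise ValueError("rheobase needs a step-family bundle")
    for amp in bundle.protocol.amplitudes_pa:
        for i in bundle.sweeps_with_label(amp):
            if _step_spike_count(bundle, i) > 0:
                return float(amp)
    raise ValueError("no spiking step in the family")


def _step_deflections(bundle: SweepBundle, amplitude: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-repeat steady-state deflections (injected, non-injected) in mV."""
    proto = bundle.protocol
    dt = bundle.dt_ms
    w0, w1 = proto.step_window_ms
    s0 = int(round((w1 - STEADY_MS) / dt))
    s1 = int(round(w1 / dt))
    b0 = int(round(max(0.0, w0 - STEADY_MS) / dt))
    b1 = int(round(w0 / dt))
    idx = bundle.sweeps_with_label(amplitude)
    if not idx:
        raise ValueError(f"no sweep at {amplitude} pA")
    inj, post = bundle.injected_cell, bundle.post_cell
    dv_inj, dv_post = [], []
    for i in idx:
        vi = bundle.cell_trace(inj, i)
        vp = bundle.cell_trace(post, i)
        dv_inj.append(vi[s0:s1].mean() - vi[b0:b1].mean())
        dv_post.append(vp[s0:s1].mean() - vp[b0:b1].mean())
    return np.array(dv_inj), np.array(dv_post)


def _deflection_sem(bundle: SweepBundle, amplitude: float,
                    cell: Optional[int] = None) -> float:
    """Noise-based SEM of the repeat-averaged steady-state deflection.

    The deflection is the difference of two window means (steady minus
    baseline, ``STEADY_MS`` each) averaged over repeats.  The variance of
    a window mean of correlated noise is 2 sigma^2 tau_int / T, with the
    integrated autocorrelation time tau_int estimated from the pooled
    pre-stimulus baselines.  This deterministic estimator stays stable
    even with very few repeats, where an empirical across-repeat SEM
    would be a noisy ratio.
    """
    idx = bundle.sweeps_with_label(amplitude)
    dt = bundle.dt_ms
    w0 = bundle.protocol.step_window_ms[0]
    nb = int(round(w0 / dt))
    cell = bundle.post_cell if cell is None else cell
    segs = [bundle.cell_trace(cell, i)[:nb] for i in idx]
    pooled = np.concatenate([s - s.mean() for s in segs])
    var = float(pooled.var())
    if var == 0.0:
        return 0.0
    # integrated autocorrelation time up to 50 ms lags
    kmax = min(int(round(50.0 / dt)), nb - 2)
    acf_sum = 0.0
    for k in range(1, kmax + 1):
        c = 0.0
        n_tot = 0
        for s in segs:
            x = s - s.mean()
            c += float(np.dot(x[:-k], x[k:]))
            n_tot += len(x) - k
        rho = c / (n_tot * var)
        if rho <= 0.0:
            break
        acf_sum += rho
    tau_int = dt * (0.5 + acf_sum)
    sd_window_mean = math.sqrt(2.0 * var * tau_int / STEADY_MS)
    return float(sd_window_mean * math.sqrt(2.0 / len(idx)))


@dataclass(frozen=True)
class CouplingMeasure:
    """DC coupling coefficients of one pair (both directions)."""

    k_12: float
    k_21: float
    rheobase_1_pa: float
    rheobase_2_pa: float
    coupled_12: bool
    coupled_21: bool

    @property
    def k_mean(self) -> float:
        return 0.5 * (self.k_12 + self.k_21)

    @property
    def coupled(self) -> bool:
        return self.coupled_12 and self.coupled_21


def _directional_k(bundle: SweepBundle) -> tuple[float, float, bool]:
    proto = bundle.protocol
    rheo = compute_rheobase(bundle)
    prior = rheo - proto.increment_pa
    if not bundle.sweeps_with_label(prior):
        raise ValueError(f"pre-rheobase step {prior} pA missing from family")
    for i in bundle.sweeps_with_label(prior):
        if _step_spike_count(bundle, i) > 0:
            raise ValueError("pre-rheobase step evoked a spike (QC failure)")
    dv_inj, dv_post = _step_deflections(bundle, prior)
    sem = _deflection_sem(bundle, prior)
    mpost, minj = dv_post.mean(), dv_inj.mean()
    coupled = abs(mpost) > 3.0 * sem
    k = float(mpost / minj) if coupled else 0.0
    return k, rheo, coupled


def coupling_coefficient(bundle_12: SweepBundle,
                         bundle_21: SweepBundle) -> CouplingMeasure:
    """DC coupling coefficients from step families run in both directions.

    ``bundle_12`` injects cell 1 (k_12 = deflection in cell 2 / cell 1);
    ``bundle_21`` the reverse.  A direction whose non-injected deflection
    stays below 3 x its SEM is reported as k = 0 with the coupled flag
    cleared.
    """
    if bundle_12.injected_cell != 1 or bundle_21.injected_cell != 2:
        raise ValueError("bundle_12 must inject cell 1 and bundle_21 cell 2")
    k12, rheo1, c12 = _directional_k(bundle_12)
    k21, rheo2, c21 = _directional_k(bundle_21)
    return CouplingMeasure(k_12=k12, k_21=k21, rheobase_1_pa=rheo1,
                           rheobase_2_pa=rheo2, coupled_12=c12,
                           coupled_21=c21)


# --------------------------------------------------------------------------
# Frequency-dependent transfer
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FrequencyPoint:
    frequency_hz: float
    coupling: float          # amplitude ratio non-injected / injected
    phase_lag_deg: float     # positive = non-injected lags
    injected_amplitude_mv: float
    fit_residual_mv: float


@dataclass(frozen=True)
class FrequencyResponse:
    points: tuple[FrequencyPoint, ...]

    @property
    def frequencies_hz(self) -> np.ndarray:
        return np.array([p.frequency_hz for p in self.points])

    @property
    def coupling(self) -> np.ndarray:
        return np.array([p.coupling for p in self.points])

    @property
    def phase_lag_deg(self) -> np.ndarray:
        return np.array([p.phase_lag_deg for p in self.points])

    @property
    def normalized_coupling(self) -> np.ndarray:
        """Coupling divided by the value at 2 Hz (exactly 1 there)."""
        ref = [p.coupling for p in self.points
               if abs(p.frequency_hz - 2.0) < 1e-9]
        if not ref:
            raise ValueError("normalisation requires a 2 Hz measurement")
        return self.coupling / ref[0]


def _fit_sinusoid(trace: np.ndarray, dt_ms: float, f_hz: float,
                  i0: int, i1: int) -> tuple[float, float, float]:
    """LSQ fit R sin(wt + phi) + c over [i0, i1); returns (R, phi_rad, rms)."""
    t = np.arange(i0, i1) * dt_ms / 1000.0
    w = 2.0 * math.pi * f_hz
    X = np.column_stack([np.cos(w * t), np.sin(w * t), np.ones(len(t))])
    coef, *_ = np.linalg.lstsq(X, trace[i0:i1], rcond=None)
    c, s = coef[0], coef[1]
    resid = trace[i0:i1] - X @ coef
    return math.hypot(c, s), math.atan2(c, s), float(resid.std())


def frequency_response(bundle: SweepBundle,
                       settle_ms: float = 200.0) -> FrequencyResponse:
    """Coupling and phase lag per injection frequency from 10-sweep averages.

    For each frequency the sweeps are averaged, the first
    ``pad + settle_ms`` discarded, and a sinusoid at the injection
    frequency fitted to both cells over an integer number of cycles; the
    coupling is the amplitude ratio and the phase lag the fitted phase
    difference.
    """
    proto = bundle.protocol
    if not isinstance(proto, SinusoidProtocol):
        raise ValueError("frequency_response needs a sinusoid bundle")
    dt = bundle.dt_ms
    points = []
    for f in proto.frequencies_hz:
        idx = bundle.sweeps_with_label(f)
        avg = np.mean([bundle.sweeps[i] for i in idx], axis=0)
        n = avg.shape[1]
        i0 = int(round((proto.pad_ms + settle_ms) / dt))
        cycle = 1000.0 / f / dt
        n_cyc = int((n - i0) // cycle)
        if n_cyc < 2:
            raise ValueError(
                f"fewer than 2 full cycles at {f} Hz; lengthen the sweep")
        i1 = i0 + int(round(n_cyc * cycle))
        inj, post = bundle.injected_cell, bundle.post_cell
        r1, p1, _ = _fit_sinusoid(avg[inj], dt, f, i0, i1)
        r2, p2, rms = _fit_sinusoid(avg[post], dt, f, i0, i1)
        lag = math.degrees(p1 - p2)
        lag = (lag + 180.0) % 360.0 - 180.0
        points.append(FrequencyPoint(
            frequency_hz=f, coupling=r2 / r1, phase_lag_deg=lag,
            injected_amplitude_mv=r1, fit_residual_mv=rms))
    return FrequencyResponse(points=tuple(points))


def expected_transfer(gj_ns: float, g_leak_post_ns: float, c_post_pf: float,
                      f_hz: float) -> tuple[float, float]:
    """Closed-form passive transfer (coupling, phase-lag degrees)."""
    w = 2.0 * math.pi * f_hz / 1000.0          # rad/ms; w*C in nS
    denom = complex(g_leak_post_ns + gj_ns, w * c_post_pf)
    return gj_ns / abs(denom), math.degrees(math.atan2(w * c_post_pf,
                                                       g_leak_post_ns + gj_ns))


@dataclass(frozen=True)
class CouplingProfile:
    """Full electrical characterisation of one pair."""

    dc: CouplingMeasure
    freq: Optional[FrequencyResponse] = None


def build_coupling_profile(step_12: SweepBundle, step_21: SweepBundle,
                           sinus: Optional[SweepBundle] = None
                           ) -> CouplingProfile:
    dc = coupling_coefficient(step_12, step_21)
    freq = frequency_response(sinus) if sinus is not None else None
    return CouplingProfile(dc=dc, freq=freq)


# --------------------------------------------------------------------------
# Pharmacology-emulation comparisons
# --------------------------------------------------------------------------

DRUG_MODES = ("glutamatergic_block", "gap_block")


@dataclass(frozen=True)
class DrugComparison:
    """First/fifth EPSP amplitudes before and after a drug emulation."""

    mode: str
    epsp1_pre_mv: float
    epsp1_post_mv: float
    epsp5_pre_mv: float
    epsp5_post_mv: float
    latency_shift_ms: float      # shift of the first-EPSP peak latency

    @property
    def percent_of_control(self) -> float:
        return 100.0 * self.epsp1_post_mv / self.epsp1_pre_mv

    @property
    def percent_of_control_epsp5(self) -> float:
        return 100.0 * self.epsp5_post_mv / self.epsp5_pre_mv


def _train_epsps(bundle: SweepBundle) -> list:
    included = qc_sweeps(bundle, warn_below=0)
    sd = pooled_baseline_sd(bundle, included) / math.sqrt(len(included))
    avg = average_sweeps(bundle, included)
    presyn = detect_spikes(avg.injected, bundle.sampling_rate_hz)
    events = measure_response(avg.post, bundle.sampling_rate_hz, presyn,
                              kind="EPSP",
                              baseline_window_ms=avg.baseline_window_ms,
                              noise_criterion=0.0,
                              n_sweeps_averaged=avg.n_averaged,
                              baseline_sd=sd)
    return events


def drug_comparison(pre: SweepBundle, post: SweepBundle,
                    mode: str) -> DrugComparison:
    """Compare first/fifth averaged EPSPs before vs after a drug emulation.

    The latency shift is measured on the first-EPSP *peak* latency (AP
    peak to response peak), which is invariant under pure amplitude
    scaling of the transfer and therefore the meaningful pre/post
    quantity; amplitudes are measured without a detection criterion so a
    strongly reduced response still yields a number.
    """
    if mode not in DRUG_MODES:
        raise ValueError(f"mode must be one of {DRUG_MODES}")
    pp, qp = pre.protocol, post.protocol
    if not (isinstance(pp, PulseTrainProtocol)
            and isinstance(qp, PulseTrainProtocol)):
        raise ValueError("drug comparison needs pulse-train bundles")
    if (pp.injected_cell, pp.n_pulses, pp.pulse_amplitude_pa) != \
       (qp.injected_cell, qp.n_pulses, qp.pulse_amplitude_pa):
        raise ValueError("pre/post protocols do not match")
    if pre.mode_of(pre.post_cell) != CURRENT_CLAMP:
        raise ValueError("EPSP comparison needs a current-clamp post cell")
    ev_pre = _train_epsps(pre)
    ev_post = _train_epsps(post)
    last = pp.n_pulses - 1
    if ev_pre[0] is None or ev_post[0] is None:
        raise ValueError("no measurable first EPSP")
    return DrugComparison(
        mode=mode,
        epsp1_pre_mv=ev_pre[0].amplitude,
        epsp1_post_mv=ev_post[0].amplitude,
        epsp5_pre_mv=ev_pre[last].amplitude if ev_pre[last] else math.nan,
        epsp5_post_mv=ev_post[last].amplitude if ev_post[last] else math.nan,
        latency_shift_ms=ev_post[0].peak_latency_ms - ev_pre[0].peak_latency_ms)
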