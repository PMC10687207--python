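"""Current-clamp trace analysis: input resistance, sag, spike metrics,
alpha-EPSP decay and summation.

The conventions mirror standard whole-cell analysis of stellate neurons:

* baseline = mean voltage over the 500 ms before step onset;
* steady state = mean over the last 25 ms of the step;
* R_N = (steady state - baseline) / injected current;
* initial peak dV = extremum (matching the step sign) minus baseline within
  an early window of the step;
* sag = |initial peak - steady state|;
* spike threshold from the phase-plane plot (first sample with dV/dt above a
  deflection criterion), amplitude from threshold to peak, half-width at
  half amplitude, AHP from threshold to the post-spike minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .cable import Trace

__all__ = [
    "MetricsConfig",
    "StepMetrics",
    "APMetrics",
    "AlphaMetrics",
    "measure_step",
    "count_spikes",
    "ap_metrics",
    "fit_alpha_decay",
    "summation_and_coupling",
    "SpikesPresentError",
]


@dataclass(frozen=True)
class MetricsConfig:
    """Analysis windows and criteria (all configurable, defaults declared)."""

    baseline_window: float = 500.0  # ms before step onset
    steady_window: float = 25.0  # ms at end of step
    peak_window: float = 500.0  # ms after onset for the initial peak / sag
    spike_threshold: float = -20.0  # mV upward crossing
    refractory: float = 2.0  # ms
    dvdt_criterion: float = 15.0  # mV/ms phase-plane deflection criterion


class SpikesPresentError(ValueError):
    """Raised when subthreshold metrics are requested on a spiking trace."""


@dataclass(frozen=True)
class StepMetrics:
    initial_peak_dv: float  # mV
    sag_amplitude: float  # mV
    r_n: float  # MOhm
    spike_count: int
    latency_first_spike: float  # ms, nan if no spike
    baseline: float  # mV
    steady_state: float  # mV


@dataclass(frozen=True)
class APMetrics:
    threshold: float  # mV
    amplitude: float  # mV
    half_width: float  # ms
    ahp_amplitude: float  # mV


@dataclass(frozen=True)
class AlphaMetrics:
    peaks: tuple[float, ...]  # mV from pre-train baseline
    decay_tau: float  # ms (single EPSP) or nan
    summation_ratio: float  # peak_n / peak_1
    coupling_first_amp: float  # mV, nan when no spike in the sweep


# ---------------------------------------------------------------------------


def count_spikes(trace: Trace, cfg: MetricsConfig | None = None
                 ) -> tuple[int, np.ndarray]:
    """Count upward crossings of the detection threshold with a refractory
    guard; returns (count, spike times in ms)."""
    cfg = cfg or MetricsConfig()
    v = trace.samples
    above = v >= cfg.spike_threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times = []
    last = -np.inf
    for i in crossings:
        t = i * trace.dt
        if t - last >= cfg.refractory:
            times.append(t)
            last = t
    return len(times), np.array(times)


def measure_step(trace: Trace, i_step: float | None = None,
                 cfg: MetricsConfig | None = None,
                 allow_spikes: bool = False) -> StepMetrics:
    """Analyse a square-step voltage response.

    Step timing is read from the trace's stimulus metadata.  Subthreshold
    metrics (R_N, sag, initial peak) refuse spiking traces unless
    ``allow_spikes`` is set, in which case they are reported as nan.
    """
    cfg = cfg or MetricsConfig()
    meta = trace.stimulus
    if i_step is None:
        i_step = meta.get("amplitude_pA")
    if not i_step:
        raise ValueError("step current must be nonzero")
    t_on = meta["step_onset_ms"]
    t_off = meta["step_offset_ms"]

    baseline = float(np.mean(trace.window(max(0.0, t_on - cfg.baseline_window), t_on)))
    steady = float(np.mean(trace.window(t_off - cfg.steady_window, t_off)))
    n_spikes, times = count_spikes(trace, cfg)
    step_spikes = times[(times >= t_on) & (times < t_off)] if n_spikes else times
    latency = float(step_spikes[0] - t_on) if len(step_spikes) else float("nan")

    if len(step_spikes):
        if not allow_spikes:
            raise SpikesPresentError(
                "trace contains spikes; subthreshold metrics unavailable "
                "(pass allow_spikes=True to get spike counts only)")
        return StepMetrics(float("nan"), float("nan"), float("nan"),
                           len(step_spikes), latency, baseline, steady)

    early = trace.window(t_on, t_on + cfg.peak_window)
    peak = float(early.max()) if i_step > 0 else float(early.min())
    r_n = (steady - baseline) / i_step * 1e3  # mV/pA -> MOhm
    sag = abs(peak - steady)
    return StepMetrics(peak - baseline, sag, r_n, 0, latency, baseline, steady)


def ap_metrics(trace: Trace, cfg: MetricsConfig | None = None) -> APMetrics:
    """Single-spike characterisation from the phase-plane plot.

    ``trace`` must contain exactly one spike.  Threshold is the voltage at
    the first sample where dV/dt exceeds the deflection criterion before the
    peak; half-width is measured at half the threshold-to-peak amplitude
    with linear interpolation of the crossings.
    """
    cfg = cfg or MetricsConfig()
    n, times = count_spikes(trace, cfg)
    if n != 1:
        raise ValueError(f"expected exactly one spike in window, found {n}")
    v = trace.samples
    dvdt = np.gradient(v, trace.dt)
    i_peak = int(np.argmax(v))
    pre = np.flatnonzero(dvdt[:i_peak + 1] >= cfg.dvdt_criterion)
    if pre.size == 0:
        raise ValueError("no phase-plane deflection above criterion before peak")
    i_thr = int(pre[0])
    threshold = float(v[i_thr])
    amplitude = float(v[i_peak] - threshold)
    half = threshold + amplitude / 2.0

    # interpolated half-amplitude crossings around the peak
    up = np.flatnonzero((v[:i_peak] < half) & (v[1:i_peak + 1] >= half))
    dn = np.flatnonzero((v[i_peak:-1] >= half) & (v[i_peak + 1:] < half)) + i_peak
    if up.size == 0 or dn.size == 0:
        raise ValueError("cannot locate half-amplitude crossings")
    iu, idn = up[-1], dn[0]
    tu = (iu + (half - v[iu]) / (v[iu + 1] - v[iu])) * trace.dt
    td = (idn + (v[idn] - half) / (v[idn] - v[idn + 1])) * trace.dt
    half_width = float(td - tu)

    ahp_min = float(v[i_peak:].min())
    return APMetrics(threshold, amplitude, half_width, threshold - ahp_min)


def _exp_decay(t, a, tau):
    return a * np.exp(-t / tau)


def fit_alpha_decay(trace: Trace, fit_window: tuple[float, float] | None = None,
                    baseline_end: float | None = None) -> float:
    """Decay time constant of a single alpha-EPSP.

    Fits V(t) - baseline = A*exp(-t/tau) over the decay phase.  By default
    the window runs from the EPSP peak to the end of the trace; pass
    ``fit_window`` (ms) to restrict it.
    """
    meta = trace.stimulus
    onsets = meta.get("onsets_ms", [0.0])
    t0 = onsets[0]
    base_end = baseline_end if baseline_end is not None else t0
    base = float(np.mean(trace.window(0.0, base_end))) if base_end > 0 else 0.0
    y = trace.samples - base
    i_pk = int(np.argmax(y))
    if fit_window is None:
        seg = y[i_pk:]
        t = np.arange(seg.size) * trace.dt
    else:
        i0 = int(round(fit_window[0] / trace.dt))
        i1 = int(round(fit_window[1] / trace.dt))
        seg = y[i0:i1]
        t = np.arange(seg.size) * trace.dt
    popt, _ = curve_fit(_exp_decay, t, seg, p0=[max(seg[0], 1e-9), 20.0],
                        maxfev=20000)
    return float(popt[1])


def summation_and_coupling(trace: Trace, n: int | None = None,
                           cfg: MetricsConfig | None = None) -> AlphaMetrics:
    """Per-event peaks, summation ratio and EPSP-spike coupling of a train.

    Peaks are measured from the pre-train baseline.  The summation ratio is
    peak_n/peak_1.  If the sweep contains a spike, the first-EPSP amplitude
    of that sweep is recorded as the coupling readout (and peaks after the
    spike are not interpreted).
    """
    cfg = cfg or MetricsConfig()
    meta = trace.stimulus
    onsets = list(meta["onsets_ms"])
    if n is not None:
        onsets = onsets[:n]
    if len(onsets) < 1:
        raise ValueError("no alpha-EPSP onsets in stimulus metadata")
    interval = (onsets[1] - onsets[0]) if len(onsets) > 1 else \
        (trace.samples.size * trace.dt - onsets[0])
    base = float(np.mean(trace.window(0.0, onsets[0])))
    peaks = []
    for t0 in onsets:
        seg = trace.window(t0, t0 + interval)
        peaks.append(float(seg.max() - base))
    n_spk, _ = count_spikes(trace, cfg)
    coupling = peaks[0] if n_spk > 0 else float("nan")
    ratio = peaks[-1] / peaks[0]
    decay = float("nan")
    if len(onsets) == 1:
        decay = fit_alpha_decay(trace)
    return AlphaMetrics(tuple(peaks), decay, ratio, coupling)
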