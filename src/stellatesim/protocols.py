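"""Declarative stimulation protocols: current steps, alpha-EPSP trains and
voltage-clamp families.

All builders are pure functions returning sampled waveforms (numpy arrays at
the requested dt) plus per-sweep metadata dictionaries describing onsets and
levels, so analysis code never has to guess window boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "StepProtocol",
    "AlphaTrainProtocol",
    "VCProtocol",
    "step_waveform",
    "build_step_family",
    "alpha_waveform",
    "build_alpha_train",
    "calibrate_alpha_amplitude",
    "build_vc_family",
]


@dataclass(frozen=True)
class StepProtocol:
    """Long square current steps (5 s by default, as in the slice protocol)."""

    amplitudes: tuple[float, ...]  # pA
    step_duration: float = 5000.0  # ms
    baseline_pre: float = 500.0  # ms
    baseline_post: float = 500.0  # ms
    hold_mode: str = "fixed"  # "fixed" (-70 mV) | "rmp"
    hold_voltage: float = -70.0

    def __post_init__(self) -> None:
        if min(self.step_duration, self.baseline_pre, self.baseline_post) <= 0:
            raise ValueError("durations must be positive")
        if self.hold_mode not in ("fixed", "rmp"):
            raise ValueError("hold_mode must be 'fixed' or 'rmp'")


@dataclass(frozen=True)
class AlphaTrainProtocol:
    """Train of alpha-function current injections (artificial EPSPs)."""

    tau_rise: float = 1.0  # ms
    count: int = 5
    frequency: float = 50.0  # Hz
    current_amplitude: float | None = None  # pA; None -> calibrate
    target_peak_range: tuple[float, float] = (1.0, 5.0)  # mV
    onset: float = 100.0  # ms
    tail: float = 400.0  # ms after last onset

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.frequency <= 0 or self.tau_rise <= 0:
            raise ValueError("frequency and tau_rise must be positive")


@dataclass(frozen=True)
class VCProtocol:
    """Voltage-clamp family for T-current activation or inactivation.

    Activation: 1 s prepulse to ``prepulse_level`` (-100 mV) then 1 s test
    steps over ``test_levels`` (-90..-45 mV).  Inactivation: 1 s prepulses
    over ``test_levels`` (-100..-55 mV) then a fixed 1 s test step to -50 mV.
    The paired leak sweep steps to -100 then -110 mV.
    """

    mode: str  # "activation" | "inactivation"
    hold: float = -70.0
    prepulse_level: float = -100.0
    prepulse_duration: float = 1000.0
    test_levels: tuple[float, ...] = ()
    test_level_fixed: float = -50.0
    test_duration: float = 1000.0
    leak_levels: tuple[float, float] = (-100.0, -110.0)
    pre_hold: float = 100.0
    post_hold: float = 100.0

    def __post_init__(self) -> None:
        if self.mode not in ("activation", "inactivation"):
            raise ValueError("mode must be 'activation' or 'inactivation'")
        if min(self.prepulse_duration, self.test_duration) <= 0:
            raise ValueError("durations must be positive")
        if not all(math.isfinite(v) for v in self.levels):
            raise ValueError("levels must be finite")

    @property
    def levels(self) -> tuple[float, ...]:
        """Voltage axis of the family (5 mV increments by default)."""
        if self.test_levels:
            return self.test_levels
        if self.mode == "activation":
            return tuple(np.arange(-90.0, -44.9, 5.0))
        return tuple(np.arange(-100.0, -54.9, 5.0))


# ---------------------------------------------------------------------------
# Current-clamp waveforms


def step_waveform(amplitude: float, proto: StepProtocol, dt: float
                  ) -> tuple[np.ndarray, dict]:
    """One square step; metadata carries onset/offset in ms."""
    n_pre = int(round(proto.baseline_pre / dt))
    n_step = int(round(proto.step_duration / dt))
    n_post = int(round(proto.baseline_post / dt))
    wave = np.zeros(n_pre + n_step + n_post)
    wave[n_pre:n_pre + n_step] = amplitude
    meta = {"kind": "step", "amplitude_pA": float(amplitude),
            "step_onset_ms": n_pre * dt, "step_offset_ms": (n_pre + n_step) * dt}
    return wave, meta


def build_step_family(proto: StepProtocol, dt: float
                      ) -> list[tuple[np.ndarray, dict]]:
    return [step_waveform(a, proto, dt) for a in proto.amplitudes]


def alpha_waveform(amplitude: float, tau: float, onset: float,
                   duration: float, dt: float) -> np.ndarray:
    """Alpha-function current I(t) = A*((t-onset)/tau)*exp(1-(t-onset)/tau).

    Zero before onset; the peak equals exactly A at t = onset + tau.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.arange(int(round(duration / dt))) * dt
    s = (t - onset) / tau
    return np.where(s > 0, amplitude * s * np.exp(1.0 - s), 0.0)


def build_alpha_train(proto: AlphaTrainProtocol, dt: float,
                      amplitude: float | None = None
                      ) -> tuple[np.ndarray, dict]:
    """Superpose ``count`` alpha waveforms at the train frequency."""
    interval = 1000.0 / proto.frequency
    if interval < dt:
        raise ValueError("inter-pulse interval shorter than dt")
    amp = amplitude if amplitude is not None else proto.current_amplitude
    if amp is None:
        raise ValueError("amplitude not set; run calibrate_alpha_amplitude")
    duration = proto.onset + interval * (proto.count - 1) + proto.tail
    onsets = [proto.onset + k * interval for k in range(proto.count)]
    wave = np.zeros(int(round(duration / dt)))
    for t0 in onsets:
        wave += alpha_waveform(amp, proto.tau_rise, t0, duration, dt)
    meta = {"kind": "alpha_train", "amplitude_pA": float(amp),
            "tau_rise_ms": proto.tau_rise, "onsets_ms": onsets,
            "frequency_hz": proto.frequency}
    return wave, meta


def calibrate_alpha_amplitude(cell, proto: AlphaTrainProtocol, cfg,
                              target_peak: tuple[float, float] | None = None,
                              hold_voltage: float = -70.0,
                              bounds: tuple[float, float] = (1.0, 5000.0),
                              max_iter: int = 40) -> tuple[float, float]:
    """Bisect the injected amplitude until the first alpha-EPSP peak falls in
    the target somatic depolarization range (1-5 mV by default).

    Returns (amplitude_pA, achieved_peak_mV).  Raises if the range cannot be
    reached within ``bounds`` or the response is not monotone in amplitude.
    """
    from .cable import run_current_clamp  # deferred to avoid import cycle

    lo_t, hi_t = target_peak if target_peak else proto.target_peak_range
    target = 0.5 * (lo_t + hi_t)
    single = AlphaTrainProtocol(tau_rise=proto.tau_rise, count=1,
                                frequency=proto.frequency, onset=proto.onset,
                                tail=5.0 * proto.tau_rise + 50.0)

    def first_peak(amp: float) -> float:
        wave, meta = build_alpha_train(single, cfg.dt, amplitude=amp)
        tr = run_current_clamp(cell, wave, cfg, hold_voltage=hold_voltage,
                               stimulus_meta=meta)
        base = np.mean(tr.window(0.0, proto.onset))
        return float(tr.window(proto.onset, tr.samples.size * tr.dt).max() - base)

    lo, hi = bounds
    p_lo, p_hi = first_peak(lo), first_peak(hi)
    if not p_hi > p_lo:
        raise RuntimeError("alpha-EPSP peak is not monotone in amplitude")
    if not (p_lo <= hi_t and p_hi >= lo_t):
        raise RuntimeError(
            f"target {lo_t}-{hi_t} mV unreachable within amplitude bounds "
            f"(peaks {p_lo:.3f}-{p_hi:.3f} mV)")
    amp, peak = hi, p_hi
    for _ in range(max_iter):
        amp = 0.5 * (lo + hi)
        peak = first_peak(amp)
        if lo_t <= peak <= hi_t and abs(peak - target) < 0.1 * (hi_t - lo_t):
            break
        if peak < target:
            lo = amp
        else:
            hi = amp
    if not lo_t <= peak <= hi_t:
        raise RuntimeError(f"bisection failed to reach {lo_t}-{hi_t} mV")
    return float(amp), float(peak)


# ---------------------------------------------------------------------------
# Voltage-clamp families


def _vc_command(levels_and_durations: Sequence[tuple[float, float]],
                dt: float) -> np.ndarray:
    return np.concatenate([np.full(int(round(dur / dt)), level)
                           for level, dur in levels_and_durations])


def build_vc_family(proto: VCProtocol, dt: float
                    ) -> tuple[list[tuple[np.ndarray, dict]],
                               tuple[np.ndarray, dict]]:
    """Build (test sweeps, leak sweep) command waveforms with metadata.

    Each sweep's metadata records the voltage-axis value for the gating
    curve (test level for activation, prepulse level for inactivation) and
    the test-window boundaries.
    """
    sweeps = []
    for level in proto.levels:
        if proto.mode == "activation":
            segs = [(proto.hold, proto.pre_hold),
                    (proto.prepulse_level, proto.prepulse_duration),
                    (level, proto.test_duration),
                    (proto.hold, proto.post_hold)]
            test_level = level
        else:
            segs = [(proto.hold, proto.pre_hold),
                    (level, proto.prepulse_duration),
                    (proto.test_level_fixed, proto.test_duration),
                    (proto.hold, proto.post_hold)]
            test_level = proto.test_level_fixed
        cmd = _vc_command(segs, dt)
        t_test0 = proto.pre_hold + proto.prepulse_duration
        meta = {"mode": proto.mode, "curve_voltage": float(level),
                "test_level_mV": float(test_level),
                "prepulse_level_mV": float(segs[1][0]),
                "prepulse_onset_ms": proto.pre_hold,
                "hold_mV": proto.hold,
                "test_onset_ms": t_test0,
                "test_offset_ms": t_test0 + proto.test_duration}
        sweeps.append((cmd, meta))
    l1, l2 = proto.leak_levels
    leak_cmd = _vc_command([(proto.hold, proto.pre_hold),
                            (l1, proto.prepulse_duration),
                            (l2, proto.test_duration),
                            (proto.hold, proto.post_hold)], dt)
    leak_meta = {"mode": "leak", "hold_mV": proto.hold,
                 "level1_mV": float(l1), "level2_mV": float(l2),
                 "step1_onset_ms": proto.pre_hold,
                 "step2_onset_ms": proto.pre_hold + proto.prepulse_duration,
                 "step2_offset_ms": (proto.pre_hold + proto.prepulse_duration
                                     + proto.test_duration)}
    return sweeps, (leak_cmd, leak_meta)
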