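"""Voltage-gated channel kinetics for the stellate-cell model.

Every conductance is described by Hodgkin-Huxley style gating variables with
Boltzmann steady states and voltage-dependent (polynomial) time constants.
The module also defines the intracellular Ca2+ pool used by the
Ca2+-dependent K+ conductance.

Units follow the electrophysiology convention used throughout the package:
voltages in mV, times in ms, conductance densities in S/cm2, current
densities in mA/cm2 (outward positive), concentrations in mM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "BoltzmannParams",
    "TauPolynomial",
    "GateSpec",
    "ChannelSpec",
    "CalciumPoolSpec",
    "KCaParams",
    "boltzmann_eval",
    "tau_eval",
    "gate_step",
    "kca_activation",
    "channel_current",
    "ca_pool_step",
    "t_type",
    "persistent_na",
    "transient_na",
    "delayed_rectifier_k",
    "hcn",
    "kca_channel",
    "leak_reference",
    "channel_to_dict",
    "channel_from_dict",
]

FARADAY = 96485.332  # C/mol


@dataclass(frozen=True)
class BoltzmannParams:
    """Sigmoidal steady-state curve with half-maximal voltage and slope.

    ``direction`` fixes the monotone sense: ``activation`` rises with
    depolarization, ``inactivation`` falls.  ``slope`` is positive in both
    cases, matching how V1/2 and k are conventionally reported.
    """

    v_half: float  # mV
    slope: float  # mV, > 0
    direction: str = "activation"
    low_asymptote: float = 0.0
    high_asymptote: float = 1.0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("slope must be positive")
        if not 0.0 <= self.low_asymptote <= self.high_asymptote <= 1.0:
            raise ValueError("asymptotes must satisfy 0 <= low <= high <= 1")
        if self.direction not in ("activation", "inactivation"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class TauPolynomial:
    """Quadratic voltage dependence of a gating time constant.

    tau(V) = max(floor, offset + linear_coeff*V + quad_coeff*V^2).
    A constant time constant is the special case linear_coeff=quad_coeff=0.
    """

    offset: float  # ms
    linear_coeff: float = 0.0  # ms/mV
    quad_coeff: float = 0.0  # ms/mV^2
    floor: float = 1.0  # ms

    def __post_init__(self) -> None:
        if not self.floor > 0:
            raise ValueError("tau floor must be positive")


@dataclass(frozen=True)
class GateSpec:
    """One Hodgkin-Huxley gating variable: steady state, kinetics, exponent."""

    steady_state: BoltzmannParams
    tau: TauPolynomial
    exponent: int = 1

    def __post_init__(self) -> None:
        if self.exponent < 1:
            raise ValueError("gate exponent must be >= 1")


@dataclass(frozen=True)
class KCaParams:
    """Hill-type Ca2+ dependence of the Ca2+-activated K+ conductance."""

    half_activation_ca: float = 1e-3  # mM (1 uM)
    hill_coeff: float = 2.0
    tau: float = 10.0  # ms

    def __post_init__(self) -> None:
        if not self.hill_coeff > 0:
            raise ValueError("hill coefficient must be positive")


@dataclass(frozen=True)
class ChannelSpec:
    """A membrane conductance: density, gating variables and reversal."""

    name: str
    gbar: float  # S/cm2
    gates: tuple[GateSpec, ...] = ()
    reversal: float = 0.0  # mV
    is_calcium: bool = False  # current feeds the intracellular Ca2+ pool
    ca_gated: bool = False
    kca: KCaParams | None = None

    def __post_init__(self) -> None:
        if self.gbar < 0:
            raise ValueError("gbar must be >= 0")
        if self.ca_gated and self.kca is None:
            raise ValueError("ca_gated channel requires KCaParams")

    def with_gbar(self, gbar: float) -> "ChannelSpec":
        return ChannelSpec(self.name, gbar, self.gates, self.reversal,
                           self.is_calcium, self.ca_gated, self.kca)


@dataclass(frozen=True)
class CalciumPoolSpec:
    """Submembrane Ca2+ shell with first-order extrusion.

    Inward Ca2+ current raises the shell concentration; extrusion relaxes it
    back to ``ca_rest`` with time constant ``tau_removal`` (500 ms in the
    stellate model).  ``influx_scale`` is a dimensionless factor standing in
    for fast endogenous buffering (1 = unbuffered shell).
    """

    tau_removal: float = 500.0  # ms
    shell_depth: float = 1.0  # um
    ca_rest: float = 5e-5  # mM (50 nM)
    influx_scale: float = 0.05

    def __post_init__(self) -> None:
        if not self.tau_removal > 0:
            raise ValueError("tau_removal must be positive")
        if not self.ca_rest > 0:
            raise ValueError("ca_rest must be positive")

    @property
    def influx_factor(self) -> float:
        """mM per ms per (mA/cm2) of inward Ca2+ current density."""
        depth_cm = self.shell_depth * 1e-4
        return self.influx_scale / (2.0 * FARADAY * depth_cm)


# ---------------------------------------------------------------------------
# Elementary operations


def boltzmann_eval(params: BoltzmannParams, v):
    """Steady-state open fraction at voltage ``v`` (scalar or array).

    Activation: y = lo + (hi-lo)/(1+exp(-(v-v_half)/k)); inactivation flips
    the sign of the exponent so the curve falls with depolarization.  This is
    algebraically the Boltzmann fit form y = A2 + (A1-A2)/(1+exp((x-x0)/k))
    with (A1, A2) the asymptotes at hyper-/depolarized limits.
    """
    varr = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(varr)):
        raise ValueError("voltage must be finite")
    s = -1.0 if params.direction == "activation" else 1.0
    lo, hi = params.low_asymptote, params.high_asymptote
    y = lo + (hi - lo) / (1.0 + np.exp(s * (varr - params.v_half) / params.slope))
    return y if varr.ndim else float(y)


def tau_eval(tau: TauPolynomial, v):
    """Evaluate tau(V) = max(floor, A + B*V + C*V^2) in ms."""
    varr = np.asarray(v, dtype=float)
    val = tau.offset + tau.linear_coeff * varr + tau.quad_coeff * varr ** 2
    out = np.maximum(val, tau.floor)
    return out if varr.ndim else float(out)


def gate_step(x, v, gate: GateSpec, dt: float):
    """Exact exponential relaxation of a gate over one time step.

    Solves dx/dt = (x_inf(v) - x)/tau(v) with v frozen over ``dt``:
    x' = x_inf + (x - x_inf)*exp(-dt/tau).  Result stays in [0, 1].
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    xinf = boltzmann_eval(gate.steady_state, v)
    tau = tau_eval(gate.tau, v)
    return xinf + (x - xinf) * np.exp(-dt / tau)


def kca_activation(ca, params: KCaParams):
    """Hill steady-state activation of the KCa conductance by shell [Ca2+]."""
    caa = np.maximum(np.asarray(ca, dtype=float), 0.0)
    cn = caa ** params.hill_coeff
    return cn / (cn + params.half_activation_ca ** params.hill_coeff)


def channel_current(spec: ChannelSpec, gate_states: Sequence[float], v,
                    ca=None):
    """Ohmic current density i = gbar * prod(x^p) * (v - E), outward positive.

    ``gate_states`` supplies one value (scalar or array) per voltage gate in
    ``spec.gates``; a Ca2+-gated channel additionally requires ``ca``.
    """
    if len(gate_states) != len(spec.gates):
        raise ValueError(
            f"channel {spec.name!r} expects {len(spec.gates)} gate states, "
            f"got {len(gate_states)}")
    open_frac = 1.0
    for x, gate in zip(gate_states, spec.gates):
        open_frac = open_frac * np.asarray(x, dtype=float) ** gate.exponent
    if spec.ca_gated:
        if ca is None:
            raise ValueError(f"channel {spec.name!r} is Ca2+-gated; ca required")
        open_frac = open_frac * kca_activation(ca, spec.kca)
    return spec.gbar * open_frac * (np.asarray(v, dtype=float) - spec.reversal)


def ca_pool_step(ca, i_ca, pool: CalciumPoolSpec, dt: float):
    """Advance the shell [Ca2+] one step (exact exponential update).

    d[Ca]/dt = ([Ca]_rest - [Ca])/tau_removal + phi * max(0, -i_ca)
    with phi = influx_scale/(2*F*depth); only inward Ca2+ current loads the
    shell.  The influx is frozen over the step, giving the closed-form
    update toward the instantaneous fixed point ca_rest + tau*phi*influx.
    """
    drive = np.maximum(-np.asarray(i_ca, dtype=float), 0.0)
    ca_inf = pool.ca_rest + pool.tau_removal * pool.influx_factor * drive
    out = ca_inf + (np.asarray(ca, dtype=float) - ca_inf) * math.exp(
        -dt / pool.tau_removal)
    return np.maximum(out, 0.0)


# ---------------------------------------------------------------------------
# Channel library
#
# The T-type parameters are the measured ventral stellate-cell values
# (activation V1/2 -53.9 mV, k 7.9; inactivation V1/2 -79.7 mV, k 7.5; rise
# tau 11.9 ms and decay tau 77.5 ms at -45 mV).  The spike currents (NaT,
# KDR), HCN and NaP use canonical kinetics; only their densities are tuned
# by the calibration module.


def t_type(gbar: float = 2e-4,
           act_v_half: float = -53.9, act_slope: float = 7.9,
           inact_v_half: float = -79.7, inact_slope: float = 7.5,
           tau_m_at_m45: float = 11.9, tau_m_slope: float = -0.4,
           tau_h: float = 77.5, e_ca: float = 120.0) -> ChannelSpec:
    """Low-voltage-activated T-type Ca2+ conductance (CaV3.2-like), m*h.

    tau_m is linear in V, anchored at the measured 11.9 ms rise at -45 mV and
    slowing with hyperpolarization; tau_h is the measured 77.5 ms decay,
    taken voltage-independent (only the -45 mV value is constrained by data).
    """
    m = GateSpec(
        BoltzmannParams(act_v_half, act_slope, "activation"),
        TauPolynomial(offset=tau_m_at_m45 + tau_m_slope * 45.0,
                      linear_coeff=tau_m_slope, floor=1.0))
    h = GateSpec(
        BoltzmannParams(inact_v_half, inact_slope, "inactivation"),
        TauPolynomial(offset=tau_h, floor=1.0))
    return ChannelSpec("t_type", gbar, (m, h), reversal=e_ca, is_calcium=True)


def persistent_na(gbar: float = 5e-5, v_half: float = -49.0,
                  slope: float = 5.0, tau: float = 5.0,
                  e_na: float = 55.0) -> ChannelSpec:
    """Non-inactivating persistent Na+ conductance, single activation gate.

    Activation sits just above the voltage reached by subthreshold steps
    from -70 mV, so the current engages strongly only once the T-type
    window current has pulled the membrane toward -60 mV.
    """
    m = GateSpec(BoltzmannParams(v_half, slope, "activation"),
                 TauPolynomial(offset=tau, floor=0.1))
    return ChannelSpec("nap", gbar, (m,), reversal=e_na)


def transient_na(gbar: float = 0.05, e_na: float = 55.0) -> ChannelSpec:
    """Spike-generating transient Na+ conductance, m3h."""
    m = GateSpec(BoltzmannParams(-38.0, 6.0, "activation"),
                 TauPolynomial(offset=0.15, floor=0.05), exponent=3)
    h = GateSpec(BoltzmannParams(-55.0, 7.0, "inactivation"),
                 TauPolynomial(offset=20.0, linear_coeff=0.25, floor=1.0))
    return ChannelSpec("nat", gbar, (m, h), reversal=e_na)


def delayed_rectifier_k(gbar: float = 0.02, e_k: float = -90.0,
                        v_half: float = -30.0, slope: float = 9.0,
                        tau: float = 4.0) -> ChannelSpec:
    """Delayed-rectifier K+ conductance, n4.

    The axonal instance of the model uses a lower activation midpoint,
    representing the lower-threshold K+ channels of the axon initial
    segment that cap its persistent-Na+ plateau.
    """
    n = GateSpec(BoltzmannParams(v_half, slope, "activation"),
                 TauPolynomial(offset=tau, floor=1.0), exponent=4)
    return ChannelSpec("kdr", gbar, (n,), reversal=e_k)


def hcn(gbar: float = 1e-4, v_half: float = -80.0, slope: float = 4.0,
        tau: float = 200.0, e_h: float = -20.0) -> ChannelSpec:
    """HCN (Ih) conductance: opens with hyperpolarization, slow kinetics."""
    q = GateSpec(BoltzmannParams(v_half, slope, "inactivation"),
                 TauPolynomial(offset=tau, floor=5.0))
    return ChannelSpec("hcn", gbar, (q,), reversal=e_h)


def kca_channel(gbar: float = 1e-4, e_k: float = -90.0,
                params: KCaParams | None = None) -> ChannelSpec:
    """Ca2+-dependent K+ conductance gated by the shell [Ca2+] (Hill form)."""
    return ChannelSpec("kca", gbar, (), reversal=e_k, ca_gated=True,
                       kca=params or KCaParams())


def leak_reference(gbar: float, e_rev: float = -70.0) -> ChannelSpec:
    """Ungated ohmic conductance (used as an explicit leak in test cells)."""
    return ChannelSpec("leak", gbar, (), reversal=e_rev)


# ---------------------------------------------------------------------------
# Serialization: ChannelSpec round-trips losslessly through plain dicts
# (and hence YAML/JSON).


def channel_to_dict(spec: ChannelSpec) -> dict:
    d = asdict(spec)
    d["gates"] = [asdict(g) for g in spec.gates]
    return d


def channel_from_dict(d: dict) -> ChannelSpec:
    gates = tuple(
        GateSpec(steady_state=BoltzmannParams(**g["steady_state"]),
                 tau=TauPolynomial(**g["tau"]),
                 exponent=g.get("exponent", 1))
        for g in d.get("gates", ()))
    kca = KCaParams(**d["kca"]) if d.get("kca") else None
    return ChannelSpec(name=d["name"], gbar=d["gbar"], gates=gates,
                       reversal=d["reversal"],
                       is_calcium=d.get("is_calcium", False),
                       ca_gated=d.get("ca_gated", False), kca=kca)
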