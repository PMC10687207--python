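"""Compartmental cable model of a stellate neuron and its integrator.

The neuron is a tree of cylindrical sections (soma, dendrites, axon), each
split into one or more compartments.  Voltage is advanced with an implicit
(backward-Euler) update on the branched cable: gating variables are relaxed
analytically with voltage frozen over the step, membrane conductances are
then frozen and the resulting linear tree system is solved exactly with a
Hines-ordered elimination.  The scheme is unconditionally stable, which
matters for the stiff spike currents.

Unit conventions: um for geometry, mV, ms, pA at the pipette, S/cm2 for
densities.  Internally the solver works with absolute quantities (mF, S,
mA) so that compartments of different size combine correctly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

from .channels import (
    BoltzmannParams,
    CalciumPoolSpec,
    ChannelSpec,
    GateSpec,
    TauPolynomial,
    boltzmann_eval,
    kca_activation,
    tau_eval,
)

__all__ = [
    "Section",
    "Morphology",
    "PassiveParams",
    "CellModel",
    "SimConfig",
    "Trace",
    "DiscretisedCell",
    "build_cell",
    "run_current_clamp",
    "run_voltage_clamp",
    "holding_current",
    "apply_pharmacology",
    "BLOCKERS",
    "read_swc",
    "write_swc",
]

REGIONS = ("soma", "dendrite", "axon")
_SWC_TYPE = {"soma": 1, "axon": 2, "dendrite": 3}
_SWC_REGION = {1: "soma", 2: "axon", 3: "dendrite", 4: "dendrite"}


@dataclass(frozen=True)
class Section:
    """A cylindrical piece of neurite."""

    id: int
    parent_id: int | None
    region: str
    length: float  # um
    diameter: float  # um
    n_segments: int = 1

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError(f"section {self.id}: non-positive geometry")
        if self.n_segments < 1:
            raise ValueError(f"section {self.id}: n_segments must be >= 1")


@dataclass(frozen=True)
class Morphology:
    """Rooted tree of sections; exactly one root (parent_id None)."""

    sections: tuple[Section, ...]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sections]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate section ids")
        roots = [s for s in self.sections if s.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"morphology must have exactly one root, got {len(roots)}")
        by_id = {s.id: s for s in self.sections}
        for s in self.sections:
            if s.parent_id is not None and s.parent_id not in by_id:
                raise ValueError(f"section {s.id}: orphan parent {s.parent_id}")
        # cycle check via iterative parent walk
        for s in self.sections:
            seen, cur = set(), s
            while cur.parent_id is not None:
                if cur.id in seen:
                    raise ValueError("morphology contains a cycle")
                seen.add(cur.id)
                cur = by_id[cur.parent_id]

    @property
    def root(self) -> Section:
        return next(s for s in self.sections if s.parent_id is None)

    def total_area(self) -> float:
        """Total membrane area in um2 (lateral cylinder areas)."""
        return float(sum(math.pi * s.diameter * s.length for s in self.sections))


@dataclass(frozen=True)
class PassiveParams:
    """Uniform passive membrane: Cm 1 uF/cm2, Rm 50 kOhm*cm2, Ra 150 Ohm*cm."""

    cm: float = 1.0  # uF/cm2
    rm: float = 50.0  # kOhm*cm2
    ra: float = 150.0  # Ohm*cm
    e_leak: float = -70.0  # mV

    def __post_init__(self) -> None:
        if min(self.cm, self.rm, self.ra) <= 0:
            raise ValueError("passive parameters must be positive")


@dataclass(frozen=True)
class CellModel:
    morphology: Morphology
    passive: PassiveParams = PassiveParams()
    distributions: dict[str, tuple[ChannelSpec, ...]] = field(default_factory=dict)
    ca_pool: CalciumPoolSpec = CalciumPoolSpec()
    temperature: float = 34.0  # degC; kinetics are taken as already at 34 C

    def __post_init__(self) -> None:
        regions = {s.region for s in self.morphology.sections}
        for region in self.distributions:
            if region not in regions:
                raise ValueError(f"distribution region {region!r} not in morphology")

    def channel_names(self) -> set[str]:
        return {c.name for chans in self.distributions.values() for c in chans}


@dataclass(frozen=True)
class SimConfig:
    dt: float = 0.025  # ms
    v_init: float = -70.0  # mV
    settle_time: float = 500.0  # ms
    integrator: str = "implicit_first_order"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.settle_time < 0:
            raise ValueError("settle_time must be >= 0")


@dataclass
class Trace:
    """Uniformly sampled voltage or current time series."""

    dt: float  # ms
    samples: np.ndarray
    kind: str  # "voltage" | "current"
    stimulus: dict = field(default_factory=dict)
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("empty trace")
        if self.kind not in ("voltage", "current"):
            raise ValueError(f"unknown trace kind {self.kind!r}")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Samples with t0 <= t < t1 (ms from trace start)."""
        i0 = max(0, int(round(t0 / self.dt)))
        i1 = min(self.samples.size, int(round(t1 / self.dt)))
        return self.samples[i0:i1]


# ---------------------------------------------------------------------------
# Discretisation


class _ChannelInstance:
    """A ChannelSpec instantiated on a set of compartments."""

    __slots__ = ("spec", "idx", "g_abs", "states", "kca_state")

    def __init__(self, spec: ChannelSpec, idx: np.ndarray, area_cm2: np.ndarray):
        self.spec = spec
        self.idx = idx
        self.g_abs = spec.gbar * area_cm2[idx]  # S
        self.states = [np.zeros(idx.size) for _ in spec.gates]
        self.kca_state = np.zeros(idx.size) if spec.ca_gated else None

    def init_steady(self, v: np.ndarray, ca: np.ndarray) -> None:
        vloc = v[self.idx]
        for k, gate in enumerate(self.spec.gates):
            self.states[k][:] = boltzmann_eval(gate.steady_state, vloc)
        if self.kca_state is not None:
            self.kca_state[:] = kca_activation(ca[self.idx], self.spec.kca)

    def advance_gates(self, v: np.ndarray, ca: np.ndarray, dt: float) -> None:
        vloc = v[self.idx]
        for k, gate in enumerate(self.spec.gates):
            ss = gate.steady_state
            s = -1.0 if ss.direction == "activation" else 1.0
            xinf = ss.low_asymptote + (ss.high_asymptote - ss.low_asymptote) / (
                1.0 + np.exp((s / ss.slope) * (vloc - ss.v_half)))
            tp = gate.tau
            tau = tp.offset + tp.linear_coeff * vloc + tp.quad_coeff * vloc * vloc
            tau = np.maximum(tau, tp.floor)
            x = self.states[k]
            x[:] = xinf + (x - xinf) * np.exp(-dt / tau)
        if self.kca_state is not None:
            ainf = kca_activation(ca[self.idx], self.spec.kca)
            tau = self.spec.kca.tau
            self.kca_state[:] = ainf + (self.kca_state - ainf) * math.exp(-dt / tau)

    def open_fraction(self) -> np.ndarray:
        open_frac = np.ones(self.idx.size)
        for x, gate in zip(self.states, self.spec.gates):
            if gate.exponent == 1:
                open_frac = open_frac * x
            else:
                open_frac = open_frac * x ** gate.exponent
        if self.kca_state is not None:
            open_frac = open_frac * self.kca_state
        return open_frac


class DiscretisedCell:
    """Compartment arrays plus channel instances, ready for integration."""

    def __init__(self, model: CellModel):
        self.model = model
        morph, passive = model.morphology, model.passive
        by_id = {s.id: s for s in morph.sections}

        # order sections parent-before-child
        ordered: list[Section] = []
        placed: set[int] = set()
        pending = list(morph.sections)
        while pending:
            progressed = False
            for s in list(pending):
                if s.parent_id is None or s.parent_id in placed:
                    ordered.append(s)
                    placed.add(s.id)
                    pending.remove(s)
                    progressed = True
            if not progressed:  # unreachable for a valid tree
                raise ValueError("sections do not form a connected tree")

        areas, parents, g_ax, regions = [], [], [], []
        sec_last_comp: dict[int, int] = {}
        half_r: list[float] = []  # axial half-resistance of each compartment (Ohm)
        for s in ordered:
            seg_len_cm = (s.length / s.n_segments) * 1e-4
            cross_cm2 = math.pi * (s.diameter * 1e-4 / 2.0) ** 2
            r_half = passive.ra * (seg_len_cm / 2.0) / cross_cm2
            area = math.pi * (s.diameter * 1e-4) * seg_len_cm  # cm2
            for k in range(s.n_segments):
                i = len(areas)
                areas.append(area)
                regions.append(s.region)
                half_r.append(r_half)
                if k == 0:
                    if s.parent_id is None:
                        parents.append(-1)
                        g_ax.append(0.0)
                    else:
                        p = sec_last_comp[s.parent_id]
                        parents.append(p)
                        g_ax.append(1.0 / (r_half + half_r[p]))
                else:
                    parents.append(i - 1)
                    g_ax.append(1.0 / (2.0 * r_half))
            sec_last_comp[s.id] = len(areas) - 1

        self.n = len(areas)
        self.area_cm2 = np.array(areas)
        self.parent = np.array(parents, dtype=int)
        self.g_ax = np.array(g_ax)  # S, coupling of compartment i to parent
        self.region = np.array(regions)
        self.c_abs = passive.cm * self.area_cm2 * 1e-3  # mF
        self.g_pass = self.area_cm2 / (passive.rm * 1e3)  # S
        self.e_leak = passive.e_leak
        self.channels: list[_ChannelInstance] = []
        for region, specs in model.distributions.items():
            idx = np.flatnonzero(self.region == region)
            if idx.size == 0:
                continue
            for spec in specs:
                self.channels.append(_ChannelInstance(spec, idx, self.area_cm2))

        self.v = np.full(self.n, passive.e_leak)
        self.ca = np.full(self.n, model.ca_pool.ca_rest)
        # coupling contributions to the system diagonal (symmetric tree laplacian)
        self._diag_extra = np.zeros(self.n)
        for i in range(1, self.n):
            self._diag_extra[i] += self.g_ax[i]
            self._diag_extra[self.parent[i]] += self.g_ax[i]
        self._root_children = np.flatnonzero(self.parent == 0)
        self._flat = None  # lazily built arrays for the compiled kernel

    # -- reporting ---------------------------------------------------------
    @property
    def total_area_um2(self) -> float:
        return float(self.area_cm2.sum() * 1e8)

    def passive_input_resistance(self) -> float:
        """Steady somatic input resistance of the passive tree, in MOhm.

        Solves the dense steady-state linear system directly (no time
        stepping); used as the analytic oracle for the integrator.
        """
        G = np.diag(self.g_pass.astype(float))
        for i in range(1, self.n):
            p = self.parent[i]
            G[i, i] += self.g_ax[i]
            G[p, p] += self.g_ax[i]
            G[i, p] -= self.g_ax[i]
            G[p, i] -= self.g_ax[i]
        rhs = np.zeros(self.n)
        rhs[0] = 1e-9  # 1 pA in mA
        dv = np.linalg.solve(G, rhs)  # mV
        return float(dv[0] / 1e-9 * 1e-6)  # mV/mA -> MOhm

    # -- state -------------------------------------------------------------
    def init_state(self, v0: float | np.ndarray) -> None:
        self.v[:] = v0
        self.ca[:] = self.model.ca_pool.ca_rest
        for _ in range(8):  # self-consistent resting [Ca2+]
            for ch in self.channels:
                ch.init_steady(self.v, self.ca)
            self._update_ca(np.inf)  # relax to instantaneous fixed point
        for ch in self.channels:
            ch.init_steady(self.v, self.ca)

    def _update_ca(self, dt: float) -> None:
        pool = self.model.ca_pool
        influx = np.zeros(self.n)
        for ch in self.channels:
            if ch.spec.is_calcium:
                i_density = ch.spec.gbar * ch.open_fraction() * (
                    self.v[ch.idx] - ch.spec.reversal)
                influx[ch.idx] += np.maximum(-i_density, 0.0)
        ca_inf = pool.ca_rest + pool.tau_removal * pool.influx_factor * influx
        if np.isinf(dt):
            self.ca[:] = ca_inf
        else:
            decay = math.exp(-dt / pool.tau_removal)
            self.ca[:] = ca_inf + (self.ca - ca_inf) * decay
        np.maximum(self.ca, 0.0, out=self.ca)

    # -- single implicit step ---------------------------------------------
    def step(self, dt: float, i_inj_mA: float = 0.0, inj_comp: int = 0,
             clamp_v: float | None = None) -> float:
        """Advance one time step; returns clamp current in mA if clamped."""
        v, ca = self.v, self.ca
        G = self.g_pass.copy()
        GE = self.g_pass * self.e_leak
        for ch in self.channels:
            ch.advance_gates(v, ca, dt)
            g_eff = ch.g_abs * ch.open_fraction()
            G[ch.idx] += g_eff
            GE[ch.idx] += g_eff * ch.spec.reversal

        dw = self.c_abs / dt + G + self._diag_extra
        rhs = (self.c_abs / dt) * v + GE
        if i_inj_mA != 0.0:
            rhs[inj_comp] += i_inj_mA

        parent, a = self.parent, self.g_ax
        n = self.n
        # Hines elimination leaves -> root (children are indexed after parents)
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = a[i] / dw[i]
            dw[p] -= f * a[i]
            rhs[p] += f * rhs[i]
        v_new = np.empty(n)
        v_new[0] = rhs[0] / dw[0] if clamp_v is None else clamp_v
        for i in range(1, n):
            v_new[i] = (rhs[i] + a[i] * v_new[parent[i]]) / dw[i]

        i_clamp = 0.0
        if clamp_v is not None:
            # amplifier current = capacitive + ionic + axial out of the root
            i_clamp = (self.c_abs[0] * (clamp_v - v[0]) / dt
                       + G[0] * clamp_v - GE[0] - i_inj_mA)
            for i in self._root_children:
                i_clamp += a[i] * (clamp_v - v_new[i])
        self.v = v_new
        self._update_ca(dt)
        return i_clamp


    # -- compiled whole-sweep runner ---------------------------------------
    def _flatten(self) -> dict:
        """Flat (gate x compartment) arrays for the compiled kernel."""
        gate_comp, gate_ce, gate_vh, gate_k, gate_sgn = [], [], [], [], []
        gate_lo, gate_hi, gate_tA, gate_tB, gate_tC, gate_tF, gate_exp = \
            [], [], [], [], [], [], []
        kca_ce, kca_comp, kca_half, kca_hill, kca_tau = [], [], [], [], []
        ce_comp, ce_gabs, ce_erev, ce_isca = [], [], [], []
        ce_offset = 0
        for ch in self.channels:
            m = ch.idx.size
            for j in range(m):
                ce_comp.append(ch.idx[j])
                ce_gabs.append(ch.g_abs[j])
                ce_erev.append(ch.spec.reversal)
                ce_isca.append(ch.spec.is_calcium)
            for gate in ch.spec.gates:
                ss, tp = gate.steady_state, gate.tau
                sgn = -1.0 if ss.direction == "activation" else 1.0
                for j in range(m):
                    gate_comp.append(ch.idx[j])
                    gate_ce.append(ce_offset + j)
                    gate_vh.append(ss.v_half)
                    gate_k.append(ss.slope)
                    gate_sgn.append(sgn)
                    gate_lo.append(ss.low_asymptote)
                    gate_hi.append(ss.high_asymptote)
                    gate_tA.append(tp.offset)
                    gate_tB.append(tp.linear_coeff)
                    gate_tC.append(tp.quad_coeff)
                    gate_tF.append(tp.floor)
                    gate_exp.append(gate.exponent)
            if ch.spec.ca_gated:
                for j in range(m):
                    kca_ce.append(ce_offset + j)
                    kca_comp.append(ch.idx[j])
                    kca_half.append(ch.spec.kca.half_activation_ca)
                    kca_hill.append(ch.spec.kca.hill_coeff)
                    kca_tau.append(ch.spec.kca.tau)
            ce_offset += m
        pool = self.model.ca_pool
        return {
            "gate_comp": np.array(gate_comp, dtype=np.int64),
            "gate_ce": np.array(gate_ce, dtype=np.int64),
            "gate_vh": np.array(gate_vh), "gate_k": np.array(gate_k),
            "gate_sgn": np.array(gate_sgn), "gate_lo": np.array(gate_lo),
            "gate_hi": np.array(gate_hi), "gate_tA": np.array(gate_tA),
            "gate_tB": np.array(gate_tB), "gate_tC": np.array(gate_tC),
            "gate_tF": np.array(gate_tF),
            "gate_exp": np.array(gate_exp, dtype=np.int64),
            "kca_ce": np.array(kca_ce, dtype=np.int64),
            "kca_comp": np.array(kca_comp, dtype=np.int64),
            "kca_half": np.array(kca_half), "kca_hill": np.array(kca_hill),
            "kca_tau": np.array(kca_tau),
            "ce_comp": np.array(ce_comp, dtype=np.int64),
            "ce_gabs": np.array(ce_gabs), "ce_erev": np.array(ce_erev),
            "ce_isca": np.array(ce_isca, dtype=np.bool_),
            "ca_phi": pool.influx_factor / self.area_cm2,
            "e_leak_arr": np.full(self.n, self.e_leak),
        }

    def _gather_states(self, flat: dict) -> tuple[np.ndarray, np.ndarray]:
        gate_state, kca_state = [], []
        for ch in self.channels:
            for k in range(len(ch.spec.gates)):
                gate_state.append(ch.states[k])
            if ch.kca_state is not None:
                kca_state.append(ch.kca_state)
        g = np.concatenate(gate_state) if gate_state else np.empty(0)
        kc = np.concatenate(kca_state) if kca_state else np.empty(0)
        return g, kc

    def _scatter_states(self, gate_state: np.ndarray,
                        kca_state: np.ndarray) -> None:
        gi = ki = 0
        for ch in self.channels:
            m = ch.idx.size
            for k in range(len(ch.spec.gates)):
                ch.states[k][:] = gate_state[gi:gi + m]
                gi += m
            if ch.kca_state is not None:
                ch.kca_state[:] = kca_state[ki:ki + m]
                ki += m

    def run_wave(self, wave: np.ndarray, dt: float, clamp: bool = False,
                 inj_comp: int = 0) -> np.ndarray:
        """Advance the cell through a full stimulus waveform.

        ``wave`` is the injected current (pA) in current clamp or the
        command voltage (mV) under ideal somatic clamp; returns the somatic
        voltage (mV) or the amplifier current (pA) per sample.  Uses the
        compiled kernel when numba is available; otherwise falls back to
        the per-step reference integrator (identical arithmetic).
        """
        from ._kernel import HAVE_NUMBA, _run

        wave = np.ascontiguousarray(wave, dtype=float)
        out = np.empty(wave.size)
        if HAVE_NUMBA:
            if self._flat is None:
                self._flat = self._flatten()
            flat = self._flat
            gate_state, kca_state = self._gather_states(flat)
            pool = self.model.ca_pool
            _run(wave, dt, inj_comp, 1 if clamp else 0,
                 self.v, self.ca, out,
                 self.parent, self.g_ax, self._diag_extra, self.c_abs,
                 self.g_pass, flat["e_leak_arr"],
                 flat["gate_comp"], flat["gate_ce"], flat["gate_vh"],
                 flat["gate_k"], flat["gate_sgn"], flat["gate_lo"],
                 flat["gate_hi"], flat["gate_tA"], flat["gate_tB"],
                 flat["gate_tC"], flat["gate_tF"], flat["gate_exp"],
                 gate_state,
                 flat["kca_ce"], flat["kca_comp"], flat["kca_half"],
                 flat["kca_hill"], flat["kca_tau"], kca_state,
                 flat["ce_comp"], flat["ce_gabs"], flat["ce_erev"],
                 flat["ce_isca"],
                 pool.ca_rest, pool.tau_removal, flat["ca_phi"],
                 self._root_children.astype(np.int64))
            self._scatter_states(gate_state, kca_state)
        else:
            for k in range(wave.size):
                if clamp:
                    out[k] = self.step(dt, clamp_v=wave[k]) * 1e9
                else:
                    self.step(dt, wave[k] * 1e-9, inj_comp)
                    out[k] = self.v[0]
        return out


def build_cell(morph: Morphology, passive: PassiveParams | None = None,
               distributions: dict[str, Sequence[ChannelSpec]] | None = None,
               pool: CalciumPoolSpec | None = None,
               temperature: float = 34.0) -> CellModel:
    """Assemble a CellModel; raises on invalid geometry or unknown regions."""
    dist = {r: tuple(chs) for r, chs in (distributions or {}).items()}
    return CellModel(morph, passive or PassiveParams(), dist,
                     pool or CalciumPoolSpec(), temperature)


# ---------------------------------------------------------------------------
# Virtual pharmacology

#: blocker name -> {channel name: gbar scale factor}
BLOCKERS: dict[str, dict[str, float]] = {
    "tta-p2": {"t_type": 0.0},
    "riluzole": {"nap": 0.0},
    "ttx": {"nat": 0.0, "nap": 0.0},
}


def apply_pharmacology(cell: CellModel, blocks: dict[str, float]) -> CellModel:
    """Return a copy of ``cell`` with named channel densities scaled.

    ``blocks`` maps channel names (or a blocker name from BLOCKERS) to a
    scale factor; the original model is unchanged.
    """
    scales: dict[str, float] = {}
    for key, scale in blocks.items():
        if key.lower() in BLOCKERS:
            for name in BLOCKERS[key.lower()]:
                scales[name] = BLOCKERS[key.lower()][name]
        else:
            scales[key] = scale
    known = cell.channel_names()
    unknown = set(scales) - known
    if unknown:
        raise KeyError(f"unknown channel(s) {sorted(unknown)}; model has {sorted(known)}")
    new_dist = {
        region: tuple(c.with_gbar(c.gbar * scales.get(c.name, 1.0)) for c in chans)
        for region, chans in cell.distributions.items()
    }
    return replace(cell, distributions=new_dist)


# ---------------------------------------------------------------------------
# Simulation drivers


def holding_current(cell: CellModel | DiscretisedCell, v_hold: float) -> float:
    """Constant somatic current (pA) holding the isopotential cell at v_hold.

    Exact when the steady state at v_hold is isopotential (uniform leak
    reversal); otherwise a good starting bias that the settle period refines.
    """
    disc = cell if isinstance(cell, DiscretisedCell) else DiscretisedCell(cell)
    disc.init_state(v_hold)
    i_total = float(np.sum(disc.g_pass * (v_hold - disc.e_leak)))  # mA
    for ch in disc.channels:
        i_total += float(np.sum(ch.g_abs * ch.open_fraction()
                                * (v_hold - ch.spec.reversal)))
    return i_total * 1e9  # pA


def _settle(disc: DiscretisedCell, cfg: SimConfig, bias_pA: float) -> None:
    disc.init_state(cfg.v_init)
    n_settle = int(round(cfg.settle_time / cfg.dt))
    if n_settle:
        disc.run_wave(np.full(n_settle, bias_pA), cfg.dt)


def run_current_clamp(cell: CellModel, waveform: np.ndarray, cfg: SimConfig,
                      hold_voltage: float | None = None,
                      stimulus_meta: dict | None = None) -> Trace:
    """Somatic voltage response to an injected current waveform (pA at cfg.dt).

    If ``hold_voltage`` is given, a constant bias current holds the cell
    near that potential (the waveform rides on top of the bias); otherwise
    the cell rests freely from cfg.v_init.  The cell settles for
    cfg.settle_time before the waveform starts.
    """
    disc = DiscretisedCell(cell)
    bias = holding_current(disc, hold_voltage) if hold_voltage is not None else 0.0
    cfg_eff = cfg if hold_voltage is None else replace(cfg, v_init=hold_voltage)
    _settle(disc, cfg_eff, bias)
    wave = np.asarray(waveform, dtype=float)
    out = disc.run_wave(wave + bias, cfg.dt)
    bad = np.flatnonzero(~np.isfinite(out))
    if bad.size:
        raise RuntimeError(
            f"current-clamp simulation diverged at t = {bad[0] * cfg.dt:.3f} ms")
    return Trace(cfg.dt, out, "voltage", stimulus=dict(stimulus_meta or {}),
                 annotations={"hold_voltage": hold_voltage, "bias_pA": bias})


def run_voltage_clamp(cell: CellModel, command: np.ndarray, cfg: SimConfig,
                      stimulus_meta: dict | None = None) -> Trace:
    """Total amplifier current (pA) under ideal somatic voltage clamp.

    The somatic voltage follows the command exactly (no series resistance).
    The cell is first settled while clamped at the first command value.
    """
    disc = DiscretisedCell(cell)
    cmd = np.asarray(command, dtype=float)
    disc.init_state(cmd[0])
    n_settle = int(round(cfg.settle_time / cfg.dt))
    if n_settle:
        disc.run_wave(np.full(n_settle, cmd[0]), cfg.dt, clamp=True)
    out = disc.run_wave(cmd, cfg.dt, clamp=True)
    bad = np.flatnonzero(~np.isfinite(out))
    if bad.size:
        raise RuntimeError(
            f"voltage-clamp simulation diverged at t = {bad[0] * cfg.dt:.3f} ms")
    return Trace(cfg.dt, out, "current", stimulus=dict(stimulus_meta or {}),
                 annotations={"command_hold": float(cmd[0])})


# ---------------------------------------------------------------------------
# SWC input/output (standard 7-column format)


def read_swc(path) -> Morphology:
    """Read an SWC file: one section per sample point (frustum to parent).

    The root soma sample (radius r) becomes an L = d = 2r cylinder, the
    conventional equal-area stand-in for a spherical soma.
    """
    points: dict[int, tuple[int, float, float, float, float, int]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"{path}: malformed SWC line {lineno}: {raw!r}")
            try:
                pid = int(parts[0]); typ = int(parts[1])
                x, y, z, r = map(float, parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed SWC line {lineno}: {raw!r}") from exc
            points[pid] = (typ, x, y, z, r, parent)
    sections = []
    for pid, (typ, x, y, z, r, parent) in sorted(points.items()):
        region = _SWC_REGION.get(typ, "dendrite")
        if parent == -1:
            sections.append(Section(pid, None, region, 2 * r, 2 * r))
        else:
            if parent not in points:
                raise ValueError(f"{path}: point {pid} references missing parent {parent}")
            px, py, pz = points[parent][1:4]
            length = math.dist((x, y, z), (px, py, pz))
            if length <= 0:
                raise ValueError(f"{path}: zero-length segment at point {pid}")
            sections.append(Section(pid, parent, region, length, 2 * r))
    return Morphology(tuple(sections))


def write_swc(morph: Morphology, path) -> None:
    """Write the morphology as SWC, laying branches out radially in the plane.

    Coordinates are synthesised deterministically (the tree carries only
    topology and dimensions); lengths and diameters are preserved exactly.
    """
    by_id = {s.id: s for s in morph.sections}
    children: dict[int | None, list[Section]] = {}
    for s in morph.sections:
        children.setdefault(s.parent_id, []).append(s)
    coords: dict[int, tuple[float, float]] = {}
    angles: dict[int, float] = {}
    root = morph.root
    coords[root.id] = (0.0, 0.0)
    angles[root.id] = 0.0
    lines = [f"{root.id} {_SWC_TYPE[root.region]} 0.0 0.0 0.0 "
             f"{root.length / 2.0:.4f} -1"]
    stack = [root.id]
    while stack:
        pid = stack.pop()
        kids = sorted(children.get(pid, []), key=lambda s: s.id)
        n_kids = len(kids)
        for j, s in enumerate(kids):
            ang = angles[pid] if n_kids == 1 else 2.0 * math.pi * j / n_kids
            x0, y0 = coords[pid]
            x1 = x0 + s.length * math.cos(ang)
            y1 = y0 + s.length * math.sin(ang)
            coords[s.id] = (x1, y1)
            angles[s.id] = ang
            lines.append(f"{s.id} {_SWC_TYPE[s.region]} {x1:.4f} {y1:.4f} 0.0 "
                         f"{s.diameter / 2.0:.4f} {pid}")
            stack.append(s.id)
    with open(path, "w") as fh:
        fh.write("# SWC written by stellatesim\n")
        fh.write("\n".join(lines) + "\n")
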