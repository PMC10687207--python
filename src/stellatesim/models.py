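"""Reference stellate-cell models and virtual experiments.

``ventral_cell`` assembles the ventral stellate model: a surrogate
morphology with uniform passive properties (Cm 1 uF/cm2, Rm 50 kOhm*cm2,
Ra 150 Ohm*cm, 34 C), spike currents (NaT, KDR) plus HCN, a Ca2+-dependent
K+ conductance fed by the T-type Ca2+ current through the 500-ms extrusion
pool, a somatic T-type conductance with the measured ventral kinetics, and
a persistent Na+ conductance in soma and axon.  The default densities were
set with the package's calibration routine against the in-silico R_N table
(60/100 MOhm with the full channel set at +50/+100 pA; 45/55 MOhm without
the T conductance; 40/45 MOhm without NaP).

The module also provides the virtual experiments used throughout the
package: the four-arm R_N table, firing curves, and the voltage-clamp
T-current measurement pipeline (leak subtraction, blocker-difference
isolation, Boltzmann/exponential fits).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import channels as chan
from .cable import (
    CellModel,
    Morphology,
    PassiveParams,
    Section,
    SimConfig,
    Trace,
    apply_pharmacology,
    build_cell,
    run_current_clamp,
    run_voltage_clamp,
)
from .metrics import count_spikes, measure_step
from .protocols import StepProtocol, VCProtocol, build_vc_family, step_waveform
from .vclamp import (
    SweepSet,
    build_gating_curves,
    fit_boltzmann,
    fit_decay_tau,
    isolate_t_current,
    leak_subtract,
)

__all__ = [
    "DEFAULT_GBAR",
    "MODEL_ARMS",
    "surrogate_morphology",
    "soma_only_morphology",
    "ventral_cell",
    "tcurrent_cell",
    "rn_table",
    "firing_curve",
    "record_vc_family",
    "measure_t_kinetics",
]

#: Peak conductance densities (S/cm2) of the ventral model, calibrated
#: against the in-silico R_N table (see module docstring).
DEFAULT_GBAR: dict[str, float] = {
    "nat": 0.04,
    "kdr": 0.05,
    "kca": 2.74e-5,
    "hcn": 1.77e-4,
    "t_type": 6.87e-4,
    "nap": 1.37e-4,
    "kdr_axon": 0.0385,
}

#: The four model arms of the in-silico R_N experiment.
MODEL_ARMS: dict[str, dict[str, float]] = {
    "full": {},
    "no_t": {"t_type": 0.0},
    "no_nap": {"nap": 0.0},
    "no_nap_no_t": {"nap": 0.0, "t_type": 0.0},
}


def surrogate_morphology(n_dendrites: int = 10, dend_length: float = 450.0,
                         dend_diam: float = 4.0, soma_size: float = 20.0,
                         axon_length: float = 250.0, axon_diam: float = 1.0,
                         nseg_dend: int = 5) -> Morphology:
    """Stellate-like surrogate: soma cylinder, radiating dendrites, axon stub.

    The thin axon is electrotonically semi-isolated: the persistent Na+
    conductance it carries can depolarize it locally ahead of the soma,
    which is what lets subthreshold somatic depolarizations recruit a
    sustained inward current.
    """
    secs = [Section(1, None, "soma", soma_size, soma_size)]
    for k in range(n_dendrites):
        secs.append(Section(2 + k, 1, "dendrite", dend_length, dend_diam,
                            nseg_dend))
    secs.append(Section(2 + n_dendrites, 1, "axon", axon_length, axon_diam, 5))
    return Morphology(tuple(secs))


def soma_only_morphology(size: float = 20.0) -> Morphology:
    return Morphology((Section(1, None, "soma", size, size),))


def ventral_cell(gbar: dict[str, float] | None = None,
                 morphology: Morphology | None = None) -> CellModel:
    """The full ventral stellate model (all six active conductances)."""
    g = dict(DEFAULT_GBAR, **(gbar or {}))
    morph = morphology or surrogate_morphology()
    soma = (
        chan.transient_na(g["nat"]),
        chan.delayed_rectifier_k(g["kdr"]),
        chan.kca_channel(g["kca"]),
        chan.hcn(g["hcn"]),
        chan.t_type(g["t_type"]),
        chan.persistent_na(g.get("nap_soma", g["nap"] * 0.05)),
    )
    # The persistent Na+ conductance is concentrated in the axon: its local
    # regenerative depolarization, braked by the axonal delayed rectifier,
    # is what sustains the somatic plateau once the T current has pushed
    # the soma across the axonal recruitment threshold.  The spike current
    # stays somatic so subthreshold recruitment does not fire the axon.
    axon = (
        chan.delayed_rectifier_k(g.get("kdr_axon", g["kdr"]), v_half=-40.0,
                                 slope=7.0),
        chan.persistent_na(g["nap"]),
    )
    dend = (chan.hcn(g["hcn"]),)  # HCN is dendritic as well as somatic
    return build_cell(morph, PassiveParams(),
                      {"soma": soma, "axon": axon, "dendrite": dend})


def tcurrent_cell(gbar_t: float = 2e-4,
                  morphology: Morphology | None = None) -> CellModel:
    """Minimal voltage-clamp preparation: passive soma plus the T conductance.

    The pharmacological cocktail used for T-current recordings silences all
    other voltage-gated currents, so the model cell carries only the leak
    and the T-type conductance.
    """
    morph = morphology or soma_only_morphology()
    return build_cell(morph, PassiveParams(),
                      {"soma": (chan.t_type(gbar_t),)})


# ---------------------------------------------------------------------------
# Current-clamp experiments


def rn_table(cell: CellModel | None = None,
             amplitudes: tuple[float, ...] = (50.0, 100.0),
             arms: dict[str, dict[str, float]] | None = None,
             dt: float = 0.05, step_duration: float = 5000.0,
             hold: float | None = None, method: str = "simulate") -> pd.DataFrame:
    """R_N of each model arm at each step amplitude (the four-arm table).

    Steps are applied from the free resting potential by default
    (``hold=None``); pass a voltage to bias-hold instead.
    ``method='simulate'`` runs full 5-s current-clamp sweeps and measures
    R_N from the last 25 ms; ``method='steady'`` uses the settled
    steady-state solver (equivalent for subthreshold steps, used by the
    calibration search).  Returns a tidy DataFrame with columns
    arm/amplitude_pA/r_n_mohm/sag_mv/peak_dv_mv.
    """
    cell = cell or ventral_cell()
    arms = MODEL_ARMS if arms is None else arms
    rows = []
    for arm_name, blocks in arms.items():
        arm_cell = apply_pharmacology(cell, blocks) if blocks else cell
        for amp in amplitudes:
            if method == "steady":
                from .calibrate import settled_rn

                rn, _ = settled_rn(arm_cell, amp, hold)
                rows.append({"arm": arm_name, "amplitude_pA": amp,
                             "r_n_mohm": rn, "sag_mv": np.nan,
                             "peak_dv_mv": np.nan})
                continue
            proto = StepProtocol((amp,), step_duration=step_duration,
                                 hold_mode="rmp" if hold is None else "fixed")
            wave, meta = step_waveform(amp, proto, dt)
            tr = run_current_clamp(cell=arm_cell, waveform=wave,
                                   cfg=SimConfig(dt=dt,
                                                 v_init=hold if hold is not None
                                                 else -65.0,
                                                 settle_time=2500.0),
                                   hold_voltage=hold, stimulus_meta=meta)
            m = measure_step(tr)
            rows.append({"arm": arm_name, "amplitude_pA": amp,
                         "r_n_mohm": m.r_n, "sag_mv": m.sag_amplitude,
                         "peak_dv_mv": m.initial_peak_dv})
    return pd.DataFrame(rows)


def firing_curve(cell: CellModel, amplitudes: tuple[float, ...],
                 dt: float = 0.025, step_duration: float = 2000.0,
                 hold: float | None = None) -> pd.DataFrame:
    """Spike count per depolarizing step amplitude (steps from rest)."""
    rows = []
    for amp in amplitudes:
        proto = StepProtocol((amp,), step_duration=step_duration,
                             hold_mode="rmp" if hold is None else "fixed")
        wave, meta = step_waveform(amp, proto, dt)
        tr = run_current_clamp(cell, wave,
                               SimConfig(dt=dt,
                                         v_init=hold if hold is not None
                                         else -65.0,
                                         settle_time=1000.0),
                               hold_voltage=hold, stimulus_meta=meta)
        n, times = count_spikes(tr)
        rows.append({"amplitude_pA": amp, "spike_count": n,
                     "latency_ms": (times[0] - meta["step_onset_ms"])
                     if n else np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Voltage-clamp pipeline


def record_vc_family(cell: CellModel, proto: VCProtocol, dt: float = 0.05,
                     condition: str = "control", repeats: int = 1,
                     settle_time: float = 200.0,
                     noise_sigma: float = 0.0, seed: int = 0) -> SweepSet:
    """Simulate a voltage-clamp family (plus its leak sweep) on one cell.

    ``repeats`` sweeps are averaged per level, mirroring the experimental
    at-least-three repetitions; optional Gaussian current noise (pA) is
    drawn per repeat from ``seed``.
    """
    cfg = SimConfig(dt=dt, v_init=proto.hold, settle_time=settle_time)
    rng = np.random.default_rng(seed)
    sweeps, (leak_cmd, leak_meta) = build_vc_family(proto, dt)

    def record(cmd, meta):
        tr = run_voltage_clamp(cell, cmd, cfg, stimulus_meta=meta)
        if repeats == 1 and noise_sigma == 0.0:
            return tr
        acc = np.zeros_like(tr.samples)
        for _ in range(repeats):
            rep = tr.samples.copy()
            if noise_sigma > 0:
                rep = rep + rng.normal(0.0, noise_sigma, rep.size)
            acc += rep
        return Trace(tr.dt, acc / repeats, "current", stimulus=dict(meta),
                     annotations=dict(tr.annotations))

    fam = {meta["curve_voltage"]: record(cmd, meta) for cmd, meta in sweeps}
    leak = record(leak_cmd, leak_meta)
    return SweepSet(fam, leak=leak, condition=condition, mode=proto.mode)


def _isolated_family(cell: CellModel, proto: VCProtocol, dt: float,
                     repeats: int, noise_sigma: float, seed: int) -> SweepSet:
    blocked_cell = apply_pharmacology(cell, {"tta-p2": 0.0})
    control = record_vc_family(cell, proto, dt, "control", repeats,
                               noise_sigma=noise_sigma, seed=seed)
    blocked = record_vc_family(blocked_cell, proto, dt, "blocker", repeats,
                               noise_sigma=noise_sigma, seed=seed + 1)
    sub_c = SweepSet({lvl: leak_subtract(tr, control.leak)
                      for lvl, tr in control.sweeps.items()},
                     leak=control.leak, condition="control", mode=proto.mode)
    sub_b = SweepSet({lvl: leak_subtract(tr, blocked.leak)
                      for lvl, tr in blocked.sweeps.items()},
                     leak=blocked.leak, condition="blocker", mode=proto.mode)
    return isolate_t_current(sub_c, sub_b)


def measure_t_kinetics(cell: CellModel | None = None, dt: float = 0.05,
                       repeats: int = 1, noise_sigma: float = 0.0,
                       seed: int = 0) -> dict:
    """Full T-current round trip on one cell: both protocol families,
    leak subtraction, TTA-P2-difference isolation, I/Imax curves, fits.

    Returns a dict with the activation/inactivation BoltzmannFits, the
    isolated sweep sets, the gating curves and the decay tau at -45 mV.
    """
    cell = cell or tcurrent_cell()
    act = _isolated_family(cell, VCProtocol("activation"), dt, repeats,
                           noise_sigma, seed)
    inact = _isolated_family(cell, VCProtocol("inactivation"), dt, repeats,
                             noise_sigma, seed + 100)
    v_a, y_a = build_gating_curves(act)
    v_i, y_i = build_gating_curves(inact)
    act_fit = fit_boltzmann(v_a, y_a)
    inact_fit = fit_boltzmann(v_i, y_i)
    decay_tau = fit_decay_tau(act.sweeps[-45.0])
    return {
        "activation_fit": act_fit,
        "inactivation_fit": inact_fit,
        "activation_curve": (v_a, y_a),
        "inactivation_curve": (v_i, y_i),
        "decay_tau_ms": decay_tau,
        "isolated_activation": act,
        "isolated_inactivation": inact,
    }
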