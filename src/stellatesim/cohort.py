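"""Synthetic dorsoventral cohort generation.

Everything the analysis pipeline consumes can be generated here without
external data: surrogate stellate morphologies, a cohort of model cells
whose channel densities follow dorsoventral gradients (peak T-type current
three times larger at the ventral border, HCN and K+ densities higher
dorsally), noisy virtual recordings, Sholl profiles and synthetic qPCR Ct
tables with a configurable expression fold.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cable import CellModel, Morphology, Section, SimConfig, Trace, run_current_clamp

__all__ = [
    "MorphSpec",
    "CohortSpec",
    "CohortCell",
    "make_surrogate_morphology",
    "sholl_profile",
    "classify_location",
    "sample_cohort",
    "synth_recording",
    "synth_qpcr",
    "cohort_t_peak_gradient",
]


@dataclass(frozen=True)
class MorphSpec:
    """Surrogate stellate morphology: ovoid soma, radiating dendrites, axon."""

    soma_length: float = 20.0  # um
    soma_diameter: float = 20.0
    n_primary_dendrites: int = 10
    dendrite_length: float = 450.0
    dendrite_diameter: float = 4.0
    dendrite_length_jitter: float = 0.1  # fractional, seeded
    dendrite_nseg: int = 5
    axon_length: float = 250.0
    axon_diameter: float = 1.0

    def __post_init__(self) -> None:
        if min(self.soma_length, self.soma_diameter) <= 0:
            raise ValueError("soma geometry must be positive")
        if self.n_primary_dendrites < 0 or self.n_primary_dendrites > 20:
            raise ValueError("dendrite count outside the plausible range 0-20")


@dataclass(frozen=True)
class CohortSpec:
    """A dorsoventral cohort of model stellate cells.

    ``gradients`` maps channel names to (dorsal, ventral) peak densities in
    S/cm2, interpolated in the cell's normalized location (0 = dorsal
    border, 1 = ventral border).  Defaults anchor the T-type density ratio
    at 3 (ventral:dorsal) and make HCN and delayed-rectifier K+ densities
    twice as high dorsally; NaP is uniform.
    """

    n_cells: int = 12
    gradients: dict[str, tuple[float, float]] = field(default_factory=dict)
    interpolation: str = "linear"
    voltage_noise_mv: float = 0.1
    current_noise_pa: float = 2.0
    seed: int = 0
    morph: MorphSpec = MorphSpec()

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.voltage_noise_mv < 0 or self.current_noise_pa < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.interpolation not in ("linear", "geometric"):
            raise ValueError("interpolation must be linear or geometric")
        if not self.gradients:
            # ventral anchors = the calibrated ventral model; T-type density
            # 3x larger ventrally, HCN and K+ densities 2x larger dorsally
            object.__setattr__(self, "gradients", {
                "t_type": (6.87e-4 / 3.0, 6.87e-4),
                "hcn": (3.54e-4, 1.77e-4),
                "kdr": (0.10, 0.05),
            })


@dataclass(frozen=True)
class CohortCell:
    location: float  # 0 = dorsal border, 1 = ventral border
    tag: str | None  # "dorsal" | "ventral" | None
    gbar: dict[str, float]
    cell: CellModel


# ---------------------------------------------------------------------------
# Morphology


def make_surrogate_morphology(spec: MorphSpec | None = None,
                              seed: int = 0) -> Morphology:
    """Deterministic surrogate morphology; dendrite lengths are jittered
    around the spec value by the seeded fraction."""
    spec = spec or MorphSpec()
    rng = np.random.default_rng(seed)
    secs = [Section(1, None, "soma", spec.soma_length, spec.soma_diameter)]
    for k in range(spec.n_primary_dendrites):
        jit = 1.0 + spec.dendrite_length_jitter * (2.0 * rng.random() - 1.0)
        secs.append(Section(2 + k, 1, "dendrite", spec.dendrite_length * jit,
                            spec.dendrite_diameter, spec.dendrite_nseg))
    if spec.axon_length > 0:
        secs.append(Section(2 + spec.n_primary_dendrites, 1, "axon",
                            spec.axon_length, spec.axon_diameter, 4))
    return Morphology(tuple(secs))


def sholl_profile(morph: Morphology, ring_spacing: float = 10.0
                  ) -> pd.DataFrame:
    """Dendritic crossings of concentric rings around the soma centroid.

    Ring radii are multiples of ``ring_spacing`` (10 um in the standard
    protocol).  Distances are measured along the path from the soma
    surface; for the radial surrogate morphologies path distance equals
    euclidean distance.
    """
    by_id = {s.id: s for s in morph.sections}
    root = morph.root

    def path_start(sec: Section) -> float:
        d = 0.0
        cur = sec
        while cur.parent_id is not None:
            parent = by_id[cur.parent_id]
            if parent.region == "dendrite":
                d += parent.length
            cur = parent
        return d

    spans = [(path_start(s), path_start(s) + s.length)
             for s in morph.sections if s.region == "dendrite"]
    max_r = max((b for _, b in spans), default=0.0)
    radii = np.arange(ring_spacing, max_r + ring_spacing, ring_spacing)
    radii = radii[radii <= max_r]
    counts = [sum(1 for a, b in spans if a < r <= b) for r in radii]
    return pd.DataFrame({"radius_um": radii, "crossings": counts})


# ---------------------------------------------------------------------------
# Cohort


def classify_location(location: float, border_fraction: float = 0.30
                      ) -> str | None:
    """Dorsal/ventral tag by the 30%-of-border rule, else untagged."""
    if not 0.0 <= location <= 1.0:
        raise ValueError("location must lie in [0, 1]")
    if location <= border_fraction:
        return "dorsal"
    if location >= 1.0 - border_fraction:
        return "ventral"
    return None


def _interp(dorsal: float, ventral: float, x: float, how: str) -> float:
    if how == "geometric":
        return dorsal * (ventral / dorsal) ** x
    return dorsal + (ventral - dorsal) * x


def sample_cohort(spec: CohortSpec | None = None) -> list[CohortCell]:
    """Build the cohort: evenly spaced locations spanning [0, 1] (a single
    cell sits at the dorsal border), per-cell densities interpolated along
    the gradients, one shared morphology per cohort."""
    from .models import DEFAULT_GBAR, ventral_cell

    spec = spec or CohortSpec()
    morph = make_surrogate_morphology(spec.morph, spec.seed)
    locations = (np.linspace(0.0, 1.0, spec.n_cells)
                 if spec.n_cells > 1 else np.array([0.0]))
    out = []
    for loc in locations:
        g = dict(DEFAULT_GBAR)
        for name, (d_val, v_val) in spec.gradients.items():
            g[name] = _interp(d_val, v_val, float(loc), spec.interpolation)
        out.append(CohortCell(float(loc), classify_location(float(loc)),
                              g, ventral_cell(g, morph)))
    return out


def synth_recording(cell: CellModel, waveform: np.ndarray, cfg: SimConfig,
                    noise_sigma: float = 0.0, seed: int = 0,
                    hold_voltage: float | None = -70.0,
                    stimulus_meta: dict | None = None) -> Trace:
    """Simulated current-clamp recording with additive Gaussian noise.

    ``noise_sigma`` = 0 returns the deterministic simulation unchanged.
    """
    tr = run_current_clamp(cell, waveform, cfg, hold_voltage=hold_voltage,
                           stimulus_meta=stimulus_meta)
    if noise_sigma <= 0:
        return tr
    rng = np.random.default_rng(seed)
    noisy = tr.samples + rng.normal(0.0, noise_sigma, tr.samples.size)
    return Trace(tr.dt, noisy, tr.kind, stimulus=dict(tr.stimulus),
                 annotations={**tr.annotations, "noise_sigma": noise_sigma,
                              "noise_seed": seed})


# ---------------------------------------------------------------------------
# qPCR


def synth_qpcr(fold: float = 1.82, ct_reference_mean: float = 20.0,
               ct_sigma: float = 0.0, replicates: int = 3,
               n_samples: int = 1, target_offset: float = 5.0,
               seed: int = 0) -> pd.DataFrame:
    """Triplicate Ct table whose expected ddCt equals -log2(fold).

    The reference gene has the same mean Ct in both regions; the target
    gene sits ``target_offset`` cycles above it dorsally and
    ``target_offset - log2(fold)`` ventrally (higher expression = lower Ct).
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    means = {
        ("dorsal", "reference"): ct_reference_mean,
        ("ventral", "reference"): ct_reference_mean,
        ("dorsal", "target"): ct_reference_mean + target_offset,
        ("ventral", "target"): ct_reference_mean + target_offset
        - math.log2(fold),
    }
    for s in range(n_samples):
        for (region, gene), mu in means.items():
            for rep in range(replicates):
                ct = mu + (rng.normal(0.0, ct_sigma) if ct_sigma > 0 else 0.0)
                rows.append({"sample": f"animal{s + 1}", "region": region,
                             "gene": gene, "replicate": rep + 1, "ct": ct})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end gradient measurement


def cohort_t_peak_gradient(spec: CohortSpec | None = None, dt: float = 0.1,
                           noise_sigma: float = 0.0) -> dict:
    """Measure each cohort cell's peak T current at the near-maximal -45 mV
    test potential with the full voltage-clamp pipeline, regress the peaks
    on location, and report the ventral:dorsal amplitude ratio predicted at
    the two borders.

    Returns {"table": DataFrame, "regression": RegressionFit,
    "ratio_ventral_dorsal": float}.
    """
    from .models import measure_t_kinetics, record_vc_family
    from .protocols import VCProtocol
    from .vclamp import (gradient_regression, isolate_t_current,
                         leak_subtract, peak_current, SweepSet)
    from .cable import apply_pharmacology

    spec = spec or CohortSpec()
    proto = VCProtocol("activation", test_levels=(-45.0,))
    rows = []
    for k, cc in enumerate(sample_cohort(spec)):
        control = record_vc_family(cc.cell, proto, dt, "control",
                                   noise_sigma=noise_sigma,
                                   seed=spec.seed + 17 * k)
        blocked = record_vc_family(apply_pharmacology(cc.cell, {"tta-p2": 0.0}),
                                   proto, dt, "blocker",
                                   noise_sigma=noise_sigma,
                                   seed=spec.seed + 17 * k + 1)
        sub_c = SweepSet({lvl: leak_subtract(tr, control.leak)
                          for lvl, tr in control.sweeps.items()},
                         leak=control.leak, mode="activation")
        sub_b = SweepSet({lvl: leak_subtract(tr, blocked.leak)
                          for lvl, tr in blocked.sweeps.items()},
                         leak=blocked.leak, mode="activation",
                         condition="blocker")
        iso = isolate_t_current(sub_c, sub_b)
        peak = peak_current(iso.sweeps[-45.0])
        rows.append({"location": cc.location, "tag": cc.tag,
                     "gbar_t": cc.gbar["t_type"], "peak_pA": peak})
    table = pd.DataFrame(rows)
    # regress peak magnitude on location; border-predicted amplitude ratio
    reg = gradient_regression(np.abs(table["peak_pA"]), table["location"])
    ratio = float(reg.predict(1.0) / reg.predict(0.0))
    return {"table": table, "regression": reg, "ratio_ventral_dorsal": ratio}
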