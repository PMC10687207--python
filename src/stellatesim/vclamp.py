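"""Voltage-clamp current isolation and curve fitting.

Pipeline for the T-type Ca2+ current: linear leak subtraction using the
-100/-110 mV leak sweep, blocker-difference isolation (control minus
full T-block, inward-negative), peak-based activation/inactivation curves
normalized to the family maximum (I/Imax), Boltzmann and exponential fits,
quadratic tau-V fits, dorsoventral gradient regression and ddCt fold-change
arithmetic for the qPCR comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .cable import Trace
from .channels import TauPolynomial

__all__ = [
    "SweepSet",
    "BoltzmannFit",
    "RegressionFit",
    "leak_subtract",
    "isolate_t_current",
    "peak_current",
    "build_gating_curves",
    "fit_boltzmann",
    "fit_exponential",
    "fit_tau_polynomial",
    "gradient_regression",
    "ddct_fold",
    "read_ct_table",
]


@dataclass
class SweepSet:
    """A family of current sweeps keyed by curve voltage, plus the leak sweep."""

    sweeps: dict[float, Trace]
    leak: Trace | None = None
    condition: str = "control"  # "control" | "blocker"
    mode: str = "activation"

    def __post_init__(self) -> None:
        dts = {tr.dt for tr in self.sweeps.values()}
        sizes = {tr.samples.size for tr in self.sweeps.values()}
        if len(dts) > 1 or len(sizes) > 1:
            raise ValueError("sweeps must share dt and duration")

    @property
    def dt(self) -> float:
        return next(iter(self.sweeps.values())).dt

    def levels(self) -> list[float]:
        return sorted(self.sweeps)


@dataclass(frozen=True)
class BoltzmannFit:
    """y = a2 + (a1 - a2)/(1 + exp((v - v_half)/slope)), slope > 0."""

    v_half: float
    slope: float
    a1: float
    a2: float
    rss: float

    def __call__(self, v):
        return _boltzmann(np.asarray(v, dtype=float),
                          self.a1, self.a2, self.v_half, self.slope)


@dataclass(frozen=True)
class RegressionFit:
    intercept: float
    slope: float
    pearson_r: float
    degenerate: bool = False

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


# ---------------------------------------------------------------------------
# Leak subtraction and isolation


def _leak_line(leak: Trace, steady_fraction: float = 0.25
               ) -> tuple[float, float]:
    """Linear leak (g in nS, reversal in mV) from the -100/-110 leak sweep.

    Uses the steady tail (last ``steady_fraction``) of each of the two step
    windows recorded in the sweep metadata.
    """
    m = leak.stimulus
    v1, v2 = m["level1_mV"], m["level2_mV"]
    t1a, t1b = m["step1_onset_ms"], m["step2_onset_ms"]
    t2a, t2b = m["step2_onset_ms"], m["step2_offset_ms"]
    i1 = float(np.mean(leak.window(t1b - steady_fraction * (t1b - t1a), t1b)))
    i2 = float(np.mean(leak.window(t2b - steady_fraction * (t2b - t2a), t2b)))
    g = (i2 - i1) / (v2 - v1)  # pA/mV = nS
    if abs(g) < 1e-12:
        return 0.0, 0.0
    e_rev = v1 - i1 / g
    return g, e_rev


def command_waveform(trace: Trace) -> np.ndarray:
    """Reconstruct the command voltage waveform from sweep metadata."""
    m = trace.stimulus
    n = trace.samples.size
    v = np.full(n, m.get("hold_mV", trace.annotations.get("command_hold", -70.0)))
    if m.get("mode") == "leak":
        seg = [(m["step1_onset_ms"], m["step2_onset_ms"], m["level1_mV"]),
               (m["step2_onset_ms"], m["step2_offset_ms"], m["level2_mV"])]
    else:
        seg = [(m.get("prepulse_onset_ms", m["test_onset_ms"] - 1000.0),
                m["test_onset_ms"], m["prepulse_level_mV"]),
               (m["test_onset_ms"], m["test_offset_ms"], m["test_level_mV"])]
    for t0, t1, level in seg:
        i0, i1 = int(round(t0 / trace.dt)), int(round(t1 / trace.dt))
        v[max(i0, 0):min(i1, n)] = level
    return v


def leak_subtract(sweep: Trace, leak: Trace) -> Trace:
    """Remove the linear leak from a voltage-clamp sweep.

    The leak conductance and reversal are estimated from the steady windows
    of the -100/-110 mV leak pair and the current g*(Vcmd(t) - E) is
    subtracted sample-wise; for a -10 mV pair this reduces to scaling the
    pair difference by (command dV / -10 mV).
    """
    if abs(sweep.dt - leak.dt) > 1e-12:
        raise ValueError("sweep and leak pair have mismatched dt")
    g, e_rev = _leak_line(leak)
    vcmd = command_waveform(sweep)
    out = sweep.samples - g * (vcmd - e_rev)
    return Trace(sweep.dt, out, "current", stimulus=dict(sweep.stimulus),
                 annotations={**sweep.annotations, "leak_subtracted": True,
                              "leak_g_nS": g, "leak_e_mV": e_rev})


def _subtract_sets(a: SweepSet, b: SweepSet, condition: str) -> SweepSet:
    if sorted(a.sweeps) != sorted(b.sweeps):
        raise ValueError("sweep sets have mismatched test levels")
    diff = {}
    for lvl, tr in a.sweeps.items():
        other = b.sweeps[lvl]
        if abs(tr.dt - other.dt) > 1e-12 or tr.samples.size != other.samples.size:
            raise ValueError("sweeps have mismatched sampling")
        diff[lvl] = Trace(tr.dt, tr.samples - other.samples, "current",
                          stimulus=dict(tr.stimulus),
                          annotations={"difference": condition})
    return SweepSet(diff, leak=a.leak, condition=condition, mode=a.mode)


def isolate_t_current(control: SweepSet, blocked: SweepSet) -> SweepSet:
    """Blocker-difference isolation: T current = control - blocked.

    With a full T-type block in the ``blocked`` condition the difference is
    the isolated T current, inward-negative.
    """
    return _subtract_sets(control, blocked, "isolated_t")


def peak_current(trace: Trace, blank: float = 2.0) -> float:
    """Peak (most negative) current within the test step, skipping an
    initial blanking window that guards against the capacitive artefact."""
    m = trace.stimulus
    seg = trace.window(m["test_onset_ms"] + blank, m["test_offset_ms"])
    return float(seg.min())


# ---------------------------------------------------------------------------
# Curves and fits


def build_gating_curves(tset: SweepSet, blank: float = 2.0
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Normalized peak-current curve (V, I/Imax) from isolated sweeps.

    The voltage axis is the test level for activation families and the
    prepulse level for inactivation families (stored per sweep as
    ``curve_voltage``); peaks are expressed as a fraction of the maximal
    peak magnitude of the family.
    """
    vs, peaks = [], []
    for lvl in tset.levels():
        tr = tset.sweeps[lvl]
        vs.append(tr.stimulus.get("curve_voltage", lvl))
        peaks.append(peak_current(tr, blank))
    vs = np.array(vs)
    mags = np.abs(np.array(peaks))
    if mags.max() <= 0:
        raise ValueError("no inward current in family; cannot normalize")
    return vs, mags / mags.max()


def _boltzmann(v, a1, a2, x0, k):
    return a2 + (a1 - a2) / (1.0 + np.exp((v - x0) / k))


def fit_boltzmann(v, y, n_starts: int = 5) -> BoltzmannFit:
    """Bounded multi-start least-squares Boltzmann fit (slope > 0).

    Starts are spread over the voltage span of the data; the lowest-residual
    convergent fit wins.  Raises on unidentifiable (flat) curves.
    """
    v = np.asarray(v, dtype=float)
    y = np.asarray(y, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 points to fit a Boltzmann")
    if np.ptp(y) < 1e-6:
        raise ValueError("flat curve: Boltzmann parameters unidentifiable")
    span = np.ptp(v)
    lo = [-2.0, -2.0, v.min() - span, 0.01]
    hi = [2.0, 2.0, v.max() + span, 5.0 * span]
    best = None
    for x0 in np.linspace(v.min(), v.max(), n_starts):
        p0 = [y[0], y[-1], x0, max(span / 10.0, 1.0)]
        try:
            popt, _ = curve_fit(_boltzmann, v, y, p0=p0,
                                bounds=(lo, hi), maxfev=20000)
        except RuntimeError:
            continue
        rss = float(np.sum((_boltzmann(v, *popt) - y) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise RuntimeError("Boltzmann fit failed to converge from any start")
    (a1, a2, x0, k), rss = best
    return BoltzmannFit(v_half=float(x0), slope=float(k), a1=float(a1),
                        a2=float(a2), rss=rss)


def fit_exponential(t, y) -> tuple[float, float]:
    """Single-exponential least squares y = A*exp(-t/tau); returns (tau, A)."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    a0 = y[0] if abs(y[0]) > 0 else (np.max(np.abs(y)) + 1e-12)
    tau0 = max((t[-1] - t[0]) / 3.0, 1e-3)
    popt, _ = curve_fit(lambda tt, a, tau: a * np.exp(-tt / tau), t, y,
                        p0=[a0, tau0], maxfev=20000)
    return float(popt[1]), float(popt[0])


def fit_decay_tau(trace: Trace, blank: float = 2.0,
                  window_after_peak: float | None = None) -> float:
    """Decay time constant of an isolated inward current at one test level.

    Fits |I|(t) = A*exp(-t/tau) from the peak to the end of the test step
    (or ``window_after_peak`` ms past the peak).
    """
    m = trace.stimulus
    i0 = int(round((m["test_onset_ms"] + blank) / trace.dt))
    i1 = int(round(m["test_offset_ms"] / trace.dt))
    seg = -trace.samples[i0:i1]
    ipk = int(np.argmax(seg))
    iend = seg.size if window_after_peak is None else \
        min(seg.size, ipk + int(round(window_after_peak / trace.dt)))
    t = (np.arange(iend - ipk)) * trace.dt
    tau, _ = fit_exponential(t, seg[ipk:iend])
    return tau


def fit_tau_polynomial(vs, taus, floor: float = 1.0) -> TauPolynomial:
    """Quadratic tau-V fit: tau(V) = A + B*V + C*V^2 (exact through 3 points)."""
    c, b, a = np.polyfit(np.asarray(vs, dtype=float),
                         np.asarray(taus, dtype=float), 2)
    return TauPolynomial(offset=float(a), linear_coeff=float(b),
                         quad_coeff=float(c), floor=floor)


def gradient_regression(values, positions) -> RegressionFit:
    """Ordinary least squares of a measurement against dorsoventral location
    (0 = dorsal border, 1 = ventral border), with Pearson's r.

    A constant input is degenerate: slope 0, r reported as 0 with a flag.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for the gradient regression")
    if np.ptp(y) < 1e-15 or np.ptp(x) < 1e-15:
        return RegressionFit(float(np.mean(y)), 0.0, 0.0, degenerate=True)
    res = stats.linregress(x, y)
    return RegressionFit(float(res.intercept), float(res.slope),
                         float(res.rvalue))


# ---------------------------------------------------------------------------
# qPCR ddCt


def read_ct_table(path) -> pd.DataFrame:
    """Read a Ct table CSV with columns sample, region, gene, replicate, ct."""
    df = pd.read_csv(path)
    required = {"sample", "region", "gene", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    return df


def ddct_fold(ct: pd.DataFrame, target: str = "target",
              reference: str = "reference") -> float:
    """Fold change ventral/dorsal by the ddCt method.

    dCt = mean Ct(target) - mean Ct(reference) per region (replicate means);
    ddCt = dCt_ventral - dCt_dorsal; fold = 2**(-ddCt).  When several
    samples (animals) are present the fold is the geometric-mean equivalent:
    2**(-mean of per-sample ddCt).
    """
    if not np.isfinite(ct["ct"]).all():
        raise ValueError("Ct values must be finite")
    need = {("dorsal", target), ("dorsal", reference),
            ("ventral", target), ("ventral", reference)}
    have = set(map(tuple, ct[["region", "gene"]].drop_duplicates().values))
    if not need <= have:
        raise ValueError(f"Ct table incomplete; missing {sorted(need - have)}")
    ddcts = []
    for _, sub in ct.groupby("sample"):
        means = sub.groupby(["region", "gene"])["ct"].mean()
        dct_v = means[("ventral", target)] - means[("ventral", reference)]
        dct_d = means[("dorsal", target)] - means[("dorsal", reference)]
        ddcts.append(dct_v - dct_d)
    return float(2.0 ** (-np.mean(ddcts)))
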