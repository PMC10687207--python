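# stellatesim

Conductance-based modelling and analysis of medial entorhinal cortex (mEC)
layer II stellate-cell electrophysiology, built around one question: how do
low-voltage-activated T-type Ca²⁺ currents (Ca_V3.2-like) and persistent
Na⁺ currents together raise the excitability of ventral stellate neurons?

The package is aimed at cellular electrophysiologists and modellers. It
provides, as a plain Python library:

* **A compartmental Hodgkin–Huxley simulator** (`stellatesim.cable`): a
  branched tree of cylindrical sections with uniform passive properties
  (C_m = 1 µF/cm², R_m = 50 kΩ·cm², R_a = 150 Ω·cm, 34 °C), integrated
  with an unconditionally stable backward-Euler scheme (numba-accelerated
  when available, with a bit-identical reference path).
* **The channel repertoire** (`stellatesim.channels`): transient and
  persistent Na⁺, delayed-rectifier and Ca²⁺-dependent K⁺, HCN, and a
  T-type Ca²⁺ conductance parameterized by the measured ventral values —
  activation V₁/₂ = −53.9 mV (k = 7.9), inactivation V₁/₂ = −79.7 mV
  (k = 7.5), rise τ 11.9 ms and decay τ 77.5 ms at −45 mV — plus a
  submembrane Ca²⁺ pool with a 500-ms extrusion time constant.
* **Virtual electrophysiology** (`stellatesim.protocols`, `.metrics`,
  `.vclamp`): 5-s current steps with R_N (steady state over the last
  25 ms), sag and initial-peak analysis; spike counting, phase-plane
  threshold, half-width and AHP; α-function EPSP trains
  (A·(t/τ)·e^{1−t/τ}, τ = 1 ms) with summation ratios; voltage-clamp
  activation/inactivation families with −100/−110 mV leak subtraction,
  blocker-difference current isolation, I/I_max gating curves and
  Boltzmann y = A₂ + (A₁−A₂)/(1+e^{(V−V₁/₂)/k}) fitting; dorsoventral
  gradient regression and qPCR ΔΔC_T fold changes (fold = 2^−ΔΔCt).
* **A calibrated ventral stellate model** (`stellatesim.models`) with
  virtual pharmacology (TTA-P2 = full T block, riluzole = persistent-Na⁺
  block, TTX = all Na⁺), and a deterministic density-calibration search
  (`stellatesim.calibrate`).
* **A synthetic dorsoventral cohort generator** (`stellatesim.cohort`):
  surrogate morphologies (SWC round trip, Sholl profiles), cells with a
  3:1 ventral:dorsal T-type density gradient and opposing HCN/K⁺
  gradients, noisy virtual recordings, and synthetic Ct tables.

A thin CLI (`stellatesim simulate|calibrate|cohort|analyze|rn-table|fit-tcurrent`)
wraps the same functions; the `examples/` scripts are the best place to
start.

## Worked example

```sh
python examples/t_current_round_trip.py
```

```
activation   V1/2 =  -52.59 mV   k =  8.03 mV
inactivation V1/2 =  -79.64 mV   k =  7.54 mV
decay tau at -45 mV =  75.24 ms
```

The simulated voltage-clamp families were generated from a channel with
activation midpoint −53.9 mV, slope 7.9 mV and decay τ 77.5 ms; the
analysis pipeline recovers them to within their experimental
uncertainties. The residual offsets are introduced by the measurement
procedure itself — peak currents normalized as I/I_max retain the ohmic
driving-force variation across test potentials and the partial
inactivation that accrues before the peak — exactly as they are in the
slice experiment this pipeline mirrors.

`python examples/input_resistance_table.py` runs the four-arm 5-s-step
experiment on the calibrated ventral model (full model; T deleted;
persistent Na⁺ deleted; both deleted) and prints the R_N/sag table, and
`python examples/dorsoventral_cohort.py` measures the cohort's T-current
gradient end to end (border-predicted ventral:dorsal peak ratio ≈ 3) and
the synthetic qPCR fold change (1.82).

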