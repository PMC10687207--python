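# Methods

## The model

The ventral stellate cell is a compartmental conductance-based model on a
surrogate morphology: an ovoid soma (20 × 20 µm cylinder), ten radiating
dendrites (450 µm long, 4 µm diameter, five segments each) and a thin
axon stub (250 µm, 1 µm, five segments). Passive properties are uniform
(C_m = 1 µF/cm², R_m = 50 kΩ·cm², R_a = 150 Ω·cm, leak reversal −70 mV)
and the temperature is 34 °C; all kinetics are taken as already at that
temperature (no Q10 machinery).

Membrane currents are Hodgkin–Huxley style, each gate having a Boltzmann
steady state (positive slope factor; a direction flag, not the sign of k,
selects activation vs inactivation) and a time constant that is either
constant or quadratic in voltage with a floor:

| conductance | gates | V₁/₂, k (mV) | τ (ms) | E (mV) | location |
|---|---|---|---|---|---|
| transient Na⁺ (NaT) | m³h | −38, 6 / −55, 7 | 0.15 / 20 + 0.25·V | +55 | soma |
| delayed-rectifier K⁺ (KDR) | n⁴ | −30, 9 | 4 | −90 | soma |
| axonal K⁺ (KDR, axon instance) | n⁴ | −40, 7 | 4 | −90 | axon |
| HCN | q | −80, 4 (inact. sense) | 200 | −20 | soma + dendrites |
| persistent Na⁺ (NaP) | m | −49, 5 | 5 | +55 | axon (95 %) + soma (5 %) |
| T-type Ca²⁺ | m·h | −53.9, 7.9 / −79.7, 7.5 | 11.9 at −45 mV, −0.4 ms/mV / 77.5 | +120 (ohmic) | soma |
| KCa | Hill(Ca) | — (half 1 µM, Hill 2) | 10 | −90 | soma |

The T-type parameters are the measured ventral stellate values; its decay
time constant is taken voltage-independent because only the −45 mV value
is experimentally constrained, and its rise time constant slows linearly
with hyperpolarization from the measured 11.9 ms anchor. The Ca²⁺ shell
(1 µm, resting 50 nM) is loaded by the inward T current with a
dimensionless buffering factor of 0.05 and relaxes with the 500-ms
extrusion time constant. The ohmic +120 mV Ca²⁺ driving force keeps the
leak-subtraction and I–V analyses linear; a GHK treatment would be the
natural extension.

The remaining kinetics are declared surrogates, not measured facts. Two
deliberate choices matter for the subthreshold phenomenology. First, NaP
activation is placed at −49 mV (k = 5) so that it is nearly silent at the
voltages reached by small steps from rest (−68…−64 mV) and engages
steeply above −62 mV; a steeper gate is not an option because the slope of
its negative conductance would exceed the membrane's total positive slope
and the depolarized operating point would lose stability. Second, NaP is
concentrated in the axon with a low-threshold axonal K⁺ rectifier
(V₁/₂ −40 mV) capping it: the semi-isolated axon can depolarize locally
ahead of the soma, which is how a subthreshold somatic depolarization
recruits a sustained inward current, and the axonal rectifier sets the
level at which that local plateau saturates.

## Numerical scheme

Voltage is advanced by backward Euler on the branched cable (default
dt = 0.025 ms; the 5-s R_N protocols use 0.05 ms and the cohort screens
0.1 ms, both verified against the dt-halving convergence test). Each step
relaxes every gate analytically with voltage frozen, freezes the resulting
conductances, and solves the linear tree system exactly with a
Hines-ordered elimination; the Ca²⁺ shell then takes its exact exponential
update toward the instantaneous fixed point. Ideal somatic voltage clamp
pins the root compartment to the command (no series resistance, matching
the ≥70 %-compensated recordings the protocols come from). The integrator
exists twice: a per-step numpy reference and a numba-compiled whole-sweep
kernel; they are the same arithmetic and the test suite asserts their
trajectories agree to rounding. Sweeps are independent — the 10-s
inter-sweep intervals of the bench protocol are modelled as full recovery,
with every sweep starting from a settled state.

Steady-state analyses (calibration, R_N screens) exploit the separation of
time scales: every gate relaxes within a few hundred ms, far inside the
5-s steps, so the settled response solves the algebraic cable equation.
Because the NaP feedback can make that equation bistable, the solver first
simulates the step briefly (the trajectory performs the branch selection a
real step would) and then polishes the fixed point by Newton iteration,
rejecting solutions inconsistent with the trajectory.

## Protocols and analysis conventions

Current-clamp steps are 5 s with 500-ms baselines, applied from the free
resting potential by default (a bias-held −70 mV mode exists). Baseline is
the mean over the 500 ms before onset, steady state the mean over the last
25 ms of the step, R_N their difference over the injected current, the
initial peak the extremum (matching the step sign) within the first
500 ms, and sag the distance from that peak to steady state. Subthreshold
metrics refuse spiking traces rather than excising spikes. Spikes are
upward crossings of −20 mV with a 2-ms refractory guard; the phase-plane
threshold is the first sample with dV/dt ≥ 15 mV/ms (configurable
10–20 mV/ms — a literal "greater than zero" criterion is met by any
noise), amplitude is threshold to peak, half-width is interpolated at half
amplitude, and the AHP is threshold minus the post-spike minimum.

α-EPSPs are injected currents A·(t/τ)·e^{1−t/τ} with τ = 1 ms, calibrated
by bisection so the first EPSP peaks between 1 and 5 mV, and delivered in
trains of five at 50 or 20 Hz from a −70 mV hold (the bench convention;
switchable). The summation ratio is the fifth peak over the first, both
measured from the pre-train baseline.

Voltage-clamp families follow the bench protocol: hold −70 mV; activation
= 1-s prepulse to −100 mV then 1-s tests −90…−45 mV; inactivation = 1-s
prepulses −100…−55 mV then a 1-s test at −50 mV; 5-mV increments (the
printed ranges imply ten sweeps; the increment itself is a configurable
choice); a −100/−110 mV leak sweep per family. Leak subtraction estimates
the linear leak (conductance and reversal) from the two steady windows of
the leak sweep and removes g·(V_cmd(t) − E) sample-wise — for steady
currents this is exactly the "scale the −10 mV pair by ΔV/−10" rule, and
it nulls a passive cell at every level. The isolated T current is control
minus full-block, inward-negative. Peaks are extrema within the test step
after a 2-ms blank (capacitive guard), normalized to the family maximum
(I/I_max), and fitted with a bounded multi-start Boltzmann (five starts
across the voltage span, lowest residual wins). Decay fits use the stated
single exponential A·e^{−t/τ} from the peak to the end of the test step.

Two honest imperfections of this pipeline are worth knowing. The I/I_max
activation curve retains the ohmic driving-force variation across test
potentials and the inactivation that accrues before the peak, so the
fitted activation midpoint sits ≈1.3 mV right of the underlying gate
midpoint and the slope reads ≈0.1 mV high; the same is true of the real
measurement. And the leak-pair potentials carry a small T-current tail
(the activation curve's exponential skirt), which biases the estimated
leak line when the T conductance is large relative to the leak; tests
quantify both effects.

## Calibration and what the model does (and does not) reproduce

Only peak conductance densities are calibrated; gating shapes stay fixed.
The generic search (`stellatesim.calibrate.calibrate`) is a deterministic
coordinate descent on log-spaced density grids — one global pass over the
bounds, then halving refinement spans — scoring candidates by weighted
squared relative deviation of settled R_N values from their targets plus
penalties for leaving the subthreshold band or a physiological resting
potential. The shipped ventral densities were set with this machinery
against the in-silico four-arm R_N table (targets 60/100 MΩ full,
45/55 MΩ without T, 40/45 MΩ without NaP, at +50/+100 pA).

The calibrated model reproduces five of those six values within 15 %
(58.4/63.1, 46.7/62.0, 41.2/46.6 MΩ as printed by
`examples/input_resistance_table.py`), together with the qualitative
signatures: T-type deletion lowers R_N measured with depolarizing but not
hyperpolarizing steps, removing NaP after T has a smaller effect than the
full spread, and T deletion reduces spike output at ≥ +150 pA. The
full-model +100 pA value saturates near 63 MΩ instead of 100 MΩ. This is
a structural limit of the surrogate, not a tuning failure: the T window
conductance implied by the printed Boltzmann parameters is nearly flat
between −70 and −60 mV, and any response measured relative to the arm's
own equilibrium cancels a flat perturbation exactly, so the T current can
only act through its transient; meanwhile the NaP steepness needed to
double R_N at −60 mV exceeds what fixed-point stability allows, given the
baseline slope pinned by the no-NaP/no-T pair. Reaching all six values
simultaneously evidently requires kinetics the source text does not print
(the published model's supplementary parameter set). The model also fires
sparse single spikes near threshold rather than tonic trains — the NaP
plateau holds the membrane in a depolarization-blocked state after a
spike — so spike-count contrasts are sign-correct but small.

## The synthetic cohort

The cohort emulates the study conditions, not any particular animal:
cells at evenly spaced normalized locations (0 = dorsal border), tagged
dorsal/ventral by the within-30 %-of-border rule; per-cell densities
interpolated between a dorsal and a ventral anchor — T-type 3× larger
ventrally (ventral anchor = the calibrated model), HCN and delayed
rectifier 2× larger dorsally (magnitudes taken from prior literature on
these gradients, not measured here); one shared morphology so that
excitability differences are attributable to conductances; NaP uniform.
Recording noise is additive white Gaussian (defaults 0.1 mV / 2 pA,
seeded); no 1/f or line components, so passing tests show estimator
correctness under idealized noise, not robustness to structured artefacts.
The qPCR generator emits triplicate Ct tables whose expected ΔΔC_T is
−log₂(fold), fold 1.82 by default, with the reference gene equal across
regions. The measured cohort gradient is summarized by regressing peak
T currents (at the near-maximal −45 mV test potential) on location and
reporting the border-predicted ventral:dorsal ratio, which is robust to
how locations are sampled. Flattening the T gradient weakens the
location–R_N slope but does not abolish it, because the HCN/K⁺ gradients
also shape R_N in this model; the knockout-like contrast therefore holds
at the level of sign, not magnitude.

## Degenerate inputs and tie-breaks

Flat gating curves raise rather than return arbitrary Boltzmann
parameters; constant gradient data report slope 0 with an explicit
degeneracy flag; zero-amplitude steps are rejected; morphologies must be
single-rooted acyclic trees with positive geometry; τ polynomials are
floored (1 ms default) so fitted quadratics cannot produce non-physical
time constants; Ca²⁺ never goes negative. Multi-start fits break ties by
lowest residual. All generators and searches are pure functions of their
inputs and seeds.
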