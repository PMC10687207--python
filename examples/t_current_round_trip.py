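"""T-type Ca2+ current kinetics measured with the virtual patch clamp.

Builds a soma-only preparation carrying the ventral T-type conductance,
simulates the activation family (1-s prepulse to -100 mV, 1-s test steps
-90..-45 mV), the inactivation family (1-s prepulses -100..-55 mV, test
step to -50 mV) and the -100/-110 mV leak pairs, with and without a full
T-type block, then runs the analysis pipeline: leak subtraction,
blocker-difference isolation, I/Imax curve construction, Boltzmann fits and
a single-exponential fit of the decay at -45 mV.
"""

from stellatesim.models import measure_t_kinetics

res = measure_t_kinetics(dt=0.05)
act, inact = res["activation_fit"], res["inactivation_fit"]
print(f"activation   V1/2 = {act.v_half:7.2f} mV   k = {act.slope:5.2f} mV")
print(f"inactivation V1/2 = {inact.v_half:7.2f} mV   k = {inact.slope:5.2f} mV")
print(f"decay tau at -45 mV = {res['decay_tau_ms']:6.2f} ms")
print(
    "\nThe channel model is parameterized with the measured ventral values"
    "\n(-53.9/7.9 activation, -79.7/7.5 inactivation, 77.5 ms decay); the"
    "\nsmall systematic offsets are what the peak-current I/Imax procedure"
    "\nitself introduces (ohmic driving force, inactivation before the peak)."
)
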