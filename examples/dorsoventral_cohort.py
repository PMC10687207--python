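"""Dorsoventral cohort: T-current gradient and Ca_V3.2 expression fold.

Generates the default synthetic cohort (cells spanning the dorsoventral
axis with a 3:1 ventral:dorsal T-type density gradient and opposing HCN/K+
gradients), measures each cell's peak T current at the near-maximal -45 mV
test potential with the full voltage-clamp pipeline, regresses the peaks on
location, and computes the qPCR ddCt fold change from the default synthetic
Ct table.
"""

from stellatesim.cohort import CohortSpec, cohort_t_peak_gradient, synth_qpcr
from stellatesim.vclamp import ddct_fold

res = cohort_t_peak_gradient(CohortSpec(n_cells=8), dt=0.1)
print(res["table"].to_string(index=False, float_format=lambda x: f"{x:9.4g}"))
reg = res["regression"]
print(f"\nlocation regression: r = {reg.pearson_r:.3f}, "
      f"border-predicted ventral:dorsal peak ratio = "
      f"{res['ratio_ventral_dorsal']:.2f}")
print(f"qPCR ddCt fold change (ventral/dorsal) = "
      f"{ddct_fold(synth_qpcr()):.2f}")
print(
    "\nThe measured peak ratio reproduces the configured 3:1 density"
    "\ngradient end to end; the fold change reproduces the 1.82 expression"
    "\nratio built into the synthetic Ct table."
)
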