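"""Temporal summation of artificial EPSP trains.

Calibrates the alpha-function current amplitude so a single alpha-EPSP
depolarizes the ventral model soma by 1-5 mV, then injects trains of five
alpha-EPSPs at 50 and 20 Hz and reports the summation ratio (fifth peak
over first peak, both from the pre-train baseline).
"""

import numpy as np

from stellatesim.cable import SimConfig, run_current_clamp
from stellatesim.metrics import summation_and_coupling
from stellatesim.models import ventral_cell
from stellatesim.protocols import (AlphaTrainProtocol, build_alpha_train,
                                   calibrate_alpha_amplitude)

cell = ventral_cell()
cfg = SimConfig(dt=0.05, v_init=-70.0, settle_time=500.0)
amp, peak = calibrate_alpha_amplitude(cell, AlphaTrainProtocol(), cfg)
print(f"calibrated alpha amplitude: {amp:.0f} pA "
      f"(single-EPSP peak {peak:.2f} mV)")
for freq in (50.0, 20.0):
    wave, meta = build_alpha_train(AlphaTrainProtocol(frequency=freq),
                                   cfg.dt, amplitude=amp)
    tr = run_current_clamp(cell, wave, cfg, hold_voltage=-70.0,
                           stimulus_meta=meta)
    m = summation_and_coupling(tr)
    print(f"{freq:4.0f} Hz: peaks {np.round(m.peaks, 2)} mV, "
          f"summation ratio {m.summation_ratio:.2f}")
print(
    "\nThe 50-Hz train summates (ratio > 1) while at 20 Hz the inter-pulse"
    "\ninterval lets each EPSP decay, so the ratio is smaller - the"
    "\nfrequency dependence expected of temporal integration."
)
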