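"""Fit every beat of a synthetic recording and flag repolarisation spread.

Generates a 40-beat single-lead record whose cathodic repolarisation spread
(sigmaTn) ramps up mid-record, runs detection + per-beat bulk fits, and
applies the fixed case-derived thresholds (elongation at sigmaTn >= 80 ms).
"""

import numpy as np

from tensorcardiography import synth
from tensorcardiography.fitting import FitConfig
from tensorcardiography.pipeline import fit_record
from tensorcardiography.tensor import (ThresholdRule, extract_series,
                                       flag_thresholds)

cfg = synth.GeneratorConfig(n_beats=40, scenario="ischemia", seed=8,
                            noise_sd=0.02, ramp_start=15, ramp_len=10,
                            st_shift_start=30, rri_sd=10.0)
record, truth = synth.synthesize_record(cfg)
tensor = fit_record(record, mode="bulk",
                    cfg=FitConfig(mode="bulk", restarts=1))

print(f"tensor shape: {tensor.values.shape}  "
      f"(beat x lead x component x metric)")
print(f"converged beats: {int(tensor.mask.sum())}/{tensor.n_beats}")

sigma_tn = extract_series(tensor, "II", "sigmaTn")
labels = flag_thresholds(sigma_tn, ThresholdRule("sigmaTn", 80.0, 70.0))
first_high = int(np.argmax(labels == "high"))
print(f"sigmaTn: {np.nanmean(sigma_tn[:15]):.1f} ms before the ramp, "
      f"{np.nanmean(sigma_tn[-10:]):.1f} ms after")
print(f"first 'high' (elongation) flag at beat {first_high} "
      f"(ramp starts at beat 15)")
print("the flag fires once the fitted spread crosses the 80 ms rule — "
      "a per-beat, single-parameter abnormality readout.")
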