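"""Decompose a single heartbeat into its four Gaussian-CDF components.

Builds the population-mean lead-II beat from the published RT-separate
parameters, samples it at 1 kHz with mild noise, and fits it back.  The
printed intervals are the collective action-potential durations: muRTp for
the anodic (endocardial-side) group, muRTn for the cathodic
(epicardial-side) group.
"""

import numpy as np

from tensorcardiography import presets, synth
from tensorcardiography.fitting import BeatFiducials, fit_rt_separate

model = presets.beat_model_from_intervals(presets.SEPARATE_ALL_AVE,
                                          mode="separate")
rng = np.random.default_rng(0)
samples, truth = synth.synthesize_beat(model, fs=1000.0, noise_sd=0.02,
                                       rng=rng)
t = np.arange(len(samples)).astype(float)  # ms at 1 kHz

result = fit_rt_separate(t, samples, BeatFiducials.from_truth(truth))

print(f"fit quality: r2(QRS) = {result.r2_qrs:.4f}, "
      f"r2(T) = {result.r2_t:.4f}")
print(f"anodic AP duration   muRTp = {result.metrics.muRTp:7.2f} ms "
      f"(generated {model.muTp - model.muRp:.2f})")
print(f"cathodic AP duration muRTn = {result.metrics.muRTn:7.2f} ms "
      f"(generated {model.muTn - model.muRn:.2f})")
print(f"repolarisation spreads: sigmaTp = {result.model.sigmaTp:.2f} ms, "
      f"sigmaTn = {result.model.sigmaTn:.2f} ms")
print("sigmaTn >> sigmaTp: epicardial-side repolarisation timing is far "
      "more dispersed than endocardial-side, as in the healthy population.")
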