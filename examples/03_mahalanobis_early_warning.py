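"""Multivariate monitoring: spread parameters beat conventional indices.

Emulates an ischaemia onset: the cathodic repolarisation spread drifts for
~50 beats before any ST-level or QT change appears.  Both parameter pairs
are scored by Mahalanobis distance against the same quiet reference window;
the repolarisation-spread score crosses its alarm line first.
"""

import numpy as np

from tensorcardiography import synth
from tensorcardiography.anomaly import fit_reference, md_series
from tensorcardiography.fitting import FitConfig
from tensorcardiography.pipeline import fit_record
from tensorcardiography.tensor import extract_series

cfg = synth.GeneratorConfig(n_beats=160, scenario="ischemia", seed=11,
                            noise_sd=0.02, ramp_start=60, ramp_len=50,
                            st_shift_start=120, rri_sd=10.0)
record, _ = synth.synthesize_record(cfg)
tensor = fit_record(record, mode="bulk",
                    cfg=FitConfig(mode="bulk", restarts=1))

N_REF = 60


def alarm_beat(names):
    X = np.column_stack([extract_series(tensor, "II", p) for p in names])
    ref = fit_reference(X, (0, N_REF), list(names))
    md = md_series(X, ref)
    thr = np.nanquantile(md[:N_REF], 0.99)
    for i in np.nonzero(md > thr)[0]:
        if i >= N_REF and np.all(md[i:i + 3] > thr):
            return i, md
    return None, md


i_tcg, md_tcg = alarm_beat(("sigmaTn", "sigmaTp"))
i_conv, md_conv = alarm_beat(("STlevel", "QT"))
print(f"spread drift starts at beat 60; ST/QT shift at beat 120")
print(f"MD(sigmaTn, sigmaTp) sustained alarm at beat {i_tcg}")
print(f"MD(ST level, QT)     sustained alarm at beat {i_conv}")
print(f"-> the decomposition flags the repolarisation abnormality "
      f"{i_conv - i_tcg} beats before the conventional indices.")
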