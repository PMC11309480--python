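"""End-to-end analysis: record → beats → per-beat fits → parameter tensor."""

from __future__ import annotations

import logging

import numpy as np

from .fitting import (BeatFiducials, FitConfig, fit_extended, fit_rt_bulk,
                      fit_rt_separate)
from .segmentation import (ECGRecord, FiducialPoints, conventional_indices,
                           detect_r_peaks, locate_fiducials)
from .tensor import ParameterTensor, assemble_tensor

log = logging.getLogger(__name__)

__all__ = ["fit_record"]

_FITTERS = {"separate": fit_rt_separate, "bulk": fit_rt_bulk,
            "extended": fit_extended}


def fit_record(record: ECGRecord, mode: str = "bulk",
               cfg: FitConfig | None = None,
               leads: list[str] | None = None,
               fiducials: dict[str, FiducialPoints] | None = None,
               invert_negative: bool = True) -> ParameterTensor:
    """Run the full decomposition of a record and assemble the tensor.

    Beats are detected independently per lead; a lead whose QRS is
    net-negative is fitted after sign inversion (flagged in the tensor's
    companion data via the fit warnings, since the canonical model assumes a
    positive main deflection).  Beats whose fiducials are unusable, or whose
    fit does not converge, are masked in the output, never dropped.

    ``fiducials`` may supply pre-computed landmarks per lead (e.g. from an
    external delineator); otherwise the built-in detector runs.
    """
    if mode not in _FITTERS:
        raise ValueError(f"mode must be one of {sorted(_FITTERS)}")
    cfg = cfg or FitConfig(mode=mode)
    fitter = _FITTERS[mode]
    leads = leads or record.lead_names

    per_lead = {}
    n_beats_per_lead = {}
    for lead in leads:
        x = record.lead(lead)
        # polarity: fit net-negative-QRS leads on the inverted signal
        flip = False
        if invert_negative:
            lo, hi = np.percentile(x, [0.5, 99.5])
            med = np.median(x)
            if (med - lo) > (hi - med):
                x = -x
                flip = True
                log.info("lead %s: net-negative QRS, fitting inverted", lead)
        fid_all = (fiducials or {}).get(lead)
        if fid_all is None:
            r = detect_r_peaks(x, record.fs)
            fid_all = locate_fiducials(x, record.fs, r)
        st, qt, rri = conventional_indices(x, fid_all)
        results = []
        ms = 1000.0 / record.fs
        t_axis = np.arange(record.n_samples) * ms
        for b in range(fid_all.n_beats):
            if not fid_all.usable[b]:
                results.append(None)
                continue
            fid = BeatFiducials(
                qrs_onset=fid_all.qrs_onset[b] * ms,
                r_peak=fid_all.r_peak[b] * ms,
                j_point=fid_all.j_point[b] * ms,
                t_onset=fid_all.t_onset[b] * ms,
                t_peak=fid_all.t_peak[b] * ms,
                t_end=fid_all.t_end[b] * ms)
            try:
                fr = fitter(t_axis, x, fid, cfg)
            except ValueError as e:
                log.warning("lead %s beat %d: fit skipped (%s)", lead, b, e)
                results.append(None)
                continue
            if flip:
                fr.warnings.append("lead inverted before fitting")
            results.append(fr)
        per_lead[lead] = {
            "fits": results,
            "conventional": np.column_stack([st, qt, rri]),
            "timestamps": fid_all.r_peak * ms,
        }
        n_beats_per_lead[lead] = fid_all.n_beats

    n = min(n_beats_per_lead.values()) if n_beats_per_lead else 0
    fits = [{lead: per_lead[lead]["fits"][b] for lead in leads}
            for b in range(n)]
    conv = np.stack([np.stack([per_lead[lead]["conventional"][b]
                               for lead in leads]) for b in range(n)]) \
        if n else np.zeros((0, len(leads), 3))
    ts = per_lead[leads[0]]["timestamps"][:n] if n else np.zeros(0)
    return assemble_tensor(fits, lead_names=list(leads), timestamps=ts,
                           conventional=conv)
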