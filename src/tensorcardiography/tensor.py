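"""Assembly of per-beat fits into the 4th-order parameter tensor.

The tensor is a plain multi-way container (beat × lead × component × metric),
not an object of tensor algebra: axis 2 runs over the four canonical
components (Rp, Rn, Tp, Tn) and axis 3 over their metrics (μ, σ, k).  Levels
β, derived intervals, fit quality and conventional indices live in companion
arrays, and non-converged or implausible beats are masked — never dropped or
interpolated, so beat indices stay aligned with the recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import COMPONENT_NAMES

__all__ = ["ParameterTensor", "ThresholdRule", "assemble_tensor",
           "extract_series", "flag_thresholds", "PARAM_COLUMNS"]

METRICS = ("mu", "sigma", "k")

#: fixed column order of the tabular (CSV) representation.
PARAM_COLUMNS = [
    "muRp", "muRn", "muTn", "muTp",
    "sigmaRp", "sigmaRn", "sigmaTp", "sigmaTn",
    "kRp", "kRn", "kTp", "kTn",
    "betaR", "betaT",
    "muRTp", "muRTn", "muRpn", "muTpn",
    "r2QRS", "r2T", "STlevel", "QT", "RRI",
]

_INTERVALS = ("muRTp", "muRTn", "muRpn", "muTpn")


@dataclass
class ThresholdRule:
    """Fixed high/low flagging rule for one parameter series.

    Labels follow the clinical reading: values ≥ ``high`` are flagged
    ``"high"`` (elongation / elevation), ≤ ``low`` are ``"low"``
    (shortening / depression), in between ``"normal"``; missing stays
    ``"missing"``.
    """

    parameter: str
    high: float
    low: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"low ({self.low}) must be < high ({self.high})")


@dataclass
class ParameterTensor:
    """4th-order parameter container with companion per-beat arrays.

    ``values`` has shape (n_beats, n_leads, 4, 3); entries of masked
    (non-converged) beat×lead cells are NaN and ``mask`` is False there.
    """

    values: np.ndarray
    mask: np.ndarray
    betas: np.ndarray        # (n_beats, n_leads, 2): betaR, betaT (bulk: β, β)
    intervals: np.ndarray    # (n_beats, n_leads, 4): muRTp, muRTn, muRpn, muTpn
    r2: np.ndarray           # (n_beats, n_leads, 2): r2QRS, r2T
    conventional: np.ndarray  # (n_beats, n_leads, 3): ST, QT, RRI
    timestamps: np.ndarray   # (n_beats,) beat time in ms
    lead_names: list[str]

    def __post_init__(self) -> None:
        n, l = self.values.shape[:2]
        if self.values.shape != (n, l, 4, 3):
            raise ValueError(f"values must be (n, leads, 4, 3), got "
                             f"{self.values.shape}")

    @property
    def n_beats(self) -> int:
        return self.values.shape[0]

    @property
    def n_leads(self) -> int:
        return self.values.shape[1]

    # -- tabular round trip --------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """One row per beat × lead, fixed column contract (masked → NaN)."""
        rows = []
        for b in range(self.n_beats):
            for l, lead in enumerate(self.lead_names):
                row = {"beat": b, "lead": lead,
                       "time_ms": float(self.timestamps[b]),
                       "converged": bool(self.mask[b, l])}
                for ci, comp in enumerate(COMPONENT_NAMES):
                    for mi, met in enumerate(METRICS):
                        row[f"{met}{comp}"] = self.values[b, l, ci, mi]
                row["betaR"], row["betaT"] = self.betas[b, l]
                for k, name in enumerate(_INTERVALS):
                    row[name] = self.intervals[b, l, k]
                row["r2QRS"], row["r2T"] = self.r2[b, l]
                row["STlevel"], row["QT"], row["RRI"] = self.conventional[b, l]
                rows.append(row)
        cols = ["beat", "lead", "time_ms", "converged"] + PARAM_COLUMNS
        return pd.DataFrame(rows, columns=cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ParameterTensor":
        leads = list(dict.fromkeys(df["lead"]))
        beats = sorted(df["beat"].unique())
        n, nl = len(beats), len(leads)
        t = cls(values=np.full((n, nl, 4, 3), np.nan),
                mask=np.zeros((n, nl), dtype=bool),
                betas=np.full((n, nl, 2), np.nan),
                intervals=np.full((n, nl, 4), np.nan),
                r2=np.full((n, nl, 2), np.nan),
                conventional=np.full((n, nl, 3), np.nan),
                timestamps=np.zeros(n), lead_names=[str(x) for x in leads])
        for _, row in df.iterrows():
            b = beats.index(row["beat"])
            l = leads.index(row["lead"])
            t.timestamps[b] = row["time_ms"]
            t.mask[b, l] = bool(row["converged"])
            for ci, comp in enumerate(COMPONENT_NAMES):
                for mi, met in enumerate(METRICS):
                    t.values[b, l, ci, mi] = row[f"{met}{comp}"]
            t.betas[b, l] = (row["betaR"], row["betaT"])
            t.intervals[b, l] = [row[k] for k in _INTERVALS]
            t.r2[b, l] = (row["r2QRS"], row["r2T"])
            t.conventional[b, l] = (row["STlevel"], row["QT"], row["RRI"])
        return t


def assemble_tensor(fits, lead_names=None, timestamps=None,
                    conventional=None) -> ParameterTensor:
    """Build a :class:`ParameterTensor` from per-beat, per-lead fit results.

    Parameters
    ----------
    fits :
        Sequence over beats; each element is a mapping ``lead name →
        FitResult`` (or None for a beat the fitter skipped).  All beats must
        carry the same lead set.
    lead_names :
        Order of the lead axis; defaults to the keys of the first beat.
    timestamps :
        Beat times in ms (default: beat index).
    conventional :
        Optional (n_beats, n_leads, 3) array of (ST, QT, RRI) per beat.
    """
    fits = list(fits)
    n = len(fits)
    first = next((f for f in fits if f), None)
    if lead_names is None:
        lead_names = list(first.keys()) if first else []
    lead_set = set(lead_names)
    bad = [i for i, f in enumerate(fits) if f and set(f.keys()) != lead_set]
    if bad:
        raise ValueError(f"inconsistent lead sets at beats {bad}; "
                         f"expected {sorted(lead_set)}")
    nl = len(lead_names)
    tens = ParameterTensor(
        values=np.full((n, nl, 4, 3), np.nan),
        mask=np.zeros((n, nl), dtype=bool),
        betas=np.full((n, nl, 2), np.nan),
        intervals=np.full((n, nl, 4), np.nan),
        r2=np.full((n, nl, 2), np.nan),
        conventional=(np.asarray(conventional, dtype=float)
                      if conventional is not None
                      else np.full((n, nl, 3), np.nan)),
        timestamps=(np.asarray(timestamps, dtype=float)
                    if timestamps is not None else np.arange(n, dtype=float)),
        lead_names=list(lead_names),
    )
    for b, beat in enumerate(fits):
        if not beat:
            continue
        for l, lead in enumerate(lead_names):
            fr = beat[lead]
            if fr is None:
                continue
            m = fr.model
            for ci, comp in enumerate(COMPONENT_NAMES):
                c = m.components[comp]
                tens.values[b, l, ci, :] = (c.mu, c.sigma, c.k)
            if m.mode == "bulk":
                tens.betas[b, l] = (m.beta, m.beta)
            else:
                tens.betas[b, l] = (m.beta_r, m.beta_t)
            met = fr.metrics
            tens.intervals[b, l] = (met.muRTp, met.muRTn, met.muRpn,
                                    met.muTpn)
            tens.r2[b, l] = (fr.r2_qrs, fr.r2_t)
            tens.mask[b, l] = bool(fr.converged and
                                   "implausible fit: r2 < 0.5"
                                   not in fr.warnings)
    # blank out the parameter entries of masked cells
    tens.values[~tens.mask] = np.nan
    tens.intervals[~tens.mask] = np.nan
    tens.betas[~tens.mask] = np.nan
    return tens


def extract_series(tensor: ParameterTensor, lead, parameter: str) -> np.ndarray:
    """Beat-ordered series of one raw or derived parameter for one lead.

    Valid names are the μ/σ/k of each component (``muRp`` … ``kTn``), the
    levels ``betaR``/``betaT``, the intervals ``muRTp``/``muRTn``/``muRpn``/
    ``muTpn``, the fit stats ``r2QRS``/``r2T`` and the conventional indices
    ``STlevel``/``QT``/``RRI``.  Masked beats propagate as NaN.
    """
    l = tensor.lead_names.index(lead) if isinstance(lead, str) else int(lead)
    for ci, comp in enumerate(COMPONENT_NAMES):
        for mi, met in enumerate(METRICS):
            if parameter == f"{met}{comp}":
                return tensor.values[:, l, ci, mi].copy()
    if parameter in _INTERVALS:
        return tensor.intervals[:, l, _INTERVALS.index(parameter)].copy()
    if parameter in ("betaR", "betaT"):
        return tensor.betas[:, l, ("betaR", "betaT").index(parameter)].copy()
    if parameter in ("r2QRS", "r2T"):
        return tensor.r2[:, l, ("r2QRS", "r2T").index(parameter)].copy()
    if parameter in ("STlevel", "QT", "RRI"):
        return tensor.conventional[
            :, l, ("STlevel", "QT", "RRI").index(parameter)].copy()
    raise KeyError(f"unknown parameter {parameter!r}; valid names: "
                   + ", ".join(PARAM_COLUMNS))


def flag_thresholds(series, rule: ThresholdRule) -> np.ndarray:
    """Label each beat ``high`` / ``low`` / ``normal`` / ``missing``."""
    x = np.asarray(series, dtype=float)
    out = np.full(x.shape, "normal", dtype=object)
    out[np.isnan(x)] = "missing"
    with np.errstate(invalid="ignore"):
        out[x >= rule.high] = "high"
        out[x <= rule.low] = "low"
    return out
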