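"""Published parameter presets used as generator inputs and reference points.

Three sources of parameters ship with the package:

* population means of the RT-separate and RT-bulk decompositions over 699
  healthy adults (lead II), as interval metrics plus σ/k per component;
* the six time-point parameter sets recorded during a coronary-intervention
  (PCI) ischaemia case, used to exercise threshold flagging;
* forty consecutive 10-beat-average parameter rows around a ventricular-
  fibrillation episode in an early-repolarisation-syndrome (ERS) patient,
  used by the alternans generator scenario.

Rows are stored as interval metrics (muRTp, muRTn, muRpn, muTpn); absolute μ
values are reconstructed with :func:`beat_model_from_intervals` once a μRp
reference is chosen (tables only determine differences).
"""

from __future__ import annotations

from .model import BeatModel

__all__ = [
    "SEPARATE_ALL_AVE",
    "SEPARATE_ALL_SD",
    "BULK_ALL_AVE",
    "BULK_ALL_SD",
    "PCI_TIMEPOINTS",
    "ERS_BEAT_BLOCKS",
    "DEFAULT_THRESHOLDS",
    "beat_model_from_intervals",
]

#: Population mean, RT-separate decomposition (healthy adults, lead II).
SEPARATE_ALL_AVE = {
    "kRp": 1.99, "kRn": 2.01, "kTp": 0.80, "kTn": 0.80,
    "sigmaRp": 6.71, "sigmaRn": 5.83, "sigmaTp": 23.56, "sigmaTn": 54.29,
    "muRTp": 307.35, "muRTn": 231.70, "muRpn": 22.18, "muTpn": 53.48,
}

#: Population SD matching :data:`SEPARATE_ALL_AVE`.
SEPARATE_ALL_SD = {
    "kRp": 0.66, "kRn": 0.62, "kTp": 0.32, "kTn": 0.32,
    "sigmaRp": 1.05, "sigmaRn": 1.50, "sigmaTp": 2.68, "sigmaTn": 9.48,
    "muRTp": 23.67, "muRTn": 26.89, "muRpn": 3.26, "muTpn": 10.0,
}

#: Population mean, RT-bulk decomposition.
BULK_ALL_AVE = {
    "kRp": 1.97, "kRn": 1.88, "kTp": 1.94, "kTn": 1.91,
    "sigmaRp": 6.56, "sigmaRn": 5.51, "sigmaTp": 35.73, "sigmaTn": 50.07,
    "muRTp": 299.98, "muRTn": 256.13, "muRpn": 20.99, "muTpn": 22.86,
}

#: Population SD matching :data:`BULK_ALL_AVE`.
BULK_ALL_SD = {
    "kRp": 0.61, "kRn": 0.58, "kTp": 0.60, "kTn": 0.59,
    "sigmaRp": 1.01, "sigmaRn": 1.66, "sigmaTp": 5.24, "sigmaTn": 7.30,
    "muRTp": 24.62, "muRTn": 23.72, "muRpn": 3.28, "muTpn": 9.55,
}

#: T-wave parameters at the six annotated PCI time points (bulk fits):
#: 1 pre-PCI rest, 2 coronary angiography, 3/4 first and second balloon
#: inflation, 5 third inflation (QT prolongation), 6 post-PCI.
PCI_TIMEPOINTS = {
    1: {"kTp": 1.58, "kTn": 1.59, "sigmaTp": 37.48, "sigmaTn": 60.39,
        "muRpn": 23.77, "muTpn": 23.62, "muRTp": 336.25, "muRTn": 288.85},
    2: {"kTp": 2.16, "kTn": 2.38, "sigmaTp": 56.72, "sigmaTn": 86.59,
        "muRpn": 26.70, "muTpn": 7.77, "muRTp": 360.74, "muRTn": 326.27},
    3: {"kTp": 1.78, "kTn": 1.58, "sigmaTp": 32.35, "sigmaTn": 57.59,
        "muRpn": 23.25, "muTpn": 67.43, "muRTp": 341.00, "muRTn": 250.32},
    4: {"kTp": 1.59, "kTn": 1.47, "sigmaTp": 31.63, "sigmaTn": 66.97,
        "muRpn": 23.91, "muTpn": 52.34, "muRTp": 350.72, "muRTn": 274.47},
    5: {"kTp": 1.36, "kTn": 1.54, "sigmaTp": 54.18, "sigmaTn": 104.01,
        "muRpn": 25.59, "muTpn": 14.32, "muRTp": 408.53, "muRTn": 368.62},
    6: {"kTp": 1.69, "kTn": 1.69, "sigmaTp": 31.81, "sigmaTn": 87.27,
        "muRpn": 23.05, "muTpn": 30.60, "muRTp": 368.83, "muRTn": 315.18},
}

# ERS case, bulk fits averaged over consecutive 10-beat blocks: sections
# A (50 sinus beats pre-VF), B (20 beats immediately pre-VF), C (20 beats
# post-VF) and D (45 beats later).  Columns: sigmaRp sigmaRn sigmaTp sigmaTn
# muRTp muRTn muRpn muTpn kRp kRn kTp kTn beta RRI QT.
_ERS_COLS = ("sigmaRp", "sigmaRn", "sigmaTp", "sigmaTn", "muRTp", "muRTn",
             "muRpn", "muTpn", "kRp", "kRn", "kTp", "kTn", "beta",
             "RRI", "QT")
_ERS_ROWS = {
    "A1": (6.90, 3.76, 28.29, 89.01, 325.80, 266.65, 22.15, 36.99, 1.38, 1.36, 1.37, 1.36, -0.08, 820, 384),
    "A2": (6.70, 3.80, 29.87, 86.61, 324.23, 271.72, 21.83, 30.68, 1.54, 1.53, 1.53, 1.53, -0.06, 822, 381),
    "A3": (6.67, 3.83, 30.24, 86.67, 324.51, 273.64, 21.71, 29.16, 1.60, 1.59, 1.59, 1.59, -0.05, 819, 379),
    "A4": (6.70, 3.75, 30.31, 85.65, 324.46, 272.25, 21.72, 30.49, 1.61, 1.59, 1.59, 1.60, -0.06, 822, 379),
    "A5": (6.73, 3.82, 30.68, 85.22, 324.54, 274.92, 21.65, 27.97, 1.63, 1.62, 1.62, 1.62, -0.06, 820, 377),
    "A6": (6.72, 3.71, 29.69, 87.10, 325.22, 270.72, 21.86, 32.64, 1.50, 1.48, 1.49, 1.48, -0.06, 820, 382),
    "A7": (6.95, 3.82, 29.01, 88.76, 325.57, 266.83, 22.12, 36.62, 1.40, 1.37, 1.39, 1.37, -0.08, 816, 384),
    "A8": (6.64, 3.76, 29.80, 86.35, 324.06, 268.54, 21.90, 33.62, 1.52, 1.50, 1.51, 1.51, -0.06, 818, 386),
    "A9": (6.79, 3.83, 30.45, 85.48, 324.22, 272.67, 21.79, 29.76, 1.60, 1.59, 1.59, 1.59, -0.06, 819, 385),
    "A10": (6.74, 3.80, 30.64, 85.96, 324.26, 272.48, 21.72, 30.06, 1.61, 1.60, 1.60, 1.61, -0.06, 819, 383),
    "B1": (6.86, 3.91, 32.58, 87.23, 345.58, 297.54, 21.84, 26.21, 1.55, 1.54, 1.54, 1.54, 0.01, 804, 424),
    "B2": (6.67, 3.76, 31.11, 89.16, 327.44, 276.39, 21.78, 29.27, 1.41, 1.39, 1.40, 1.40, -0.06, 806, 391),
    "B3": (6.71, 3.78, 30.14, 87.97, 326.81, 273.13, 21.88, 31.80, 1.44, 1.42, 1.43, 1.42, -0.07, 809, 386),
    "B4": (6.72, 3.84, 31.29, 85.70, 325.52, 276.36, 21.64, 27.51, 1.58, 1.56, 1.57, 1.57, -0.05, 811, 384),
    "B5": (6.71, 3.84, 31.47, 85.49, 325.44, 276.35, 21.57, 27.52, 1.61, 1.59, 1.60, 1.60, -0.06, 815, 390),
    "B6": (6.71, 3.77, 31.08, 85.57, 325.28, 276.18, 21.62, 27.48, 1.61, 1.59, 1.59, 1.59, -0.05, 819, 384),
    "B7": (6.71, 3.74, 30.84, 83.99, 325.21, 274.56, 21.59, 29.07, 1.59, 1.56, 1.58, 1.57, -0.07, 824, 383),
    "B8": (6.75, 3.72, 29.90, 88.56, 326.20, 272.98, 21.83, 31.39, 1.46, 1.44, 1.45, 1.44, -0.05, 829, 381),
    "B9": (6.91, 3.78, 29.08, 87.60, 326.00, 270.41, 21.89, 33.70, 1.44, 1.42, 1.43, 1.42, -0.08, 829, 382),
    "B10": (6.79, 3.79, 30.34, 85.11, 325.15, 274.40, 21.70, 29.04, 1.58, 1.56, 1.57, 1.57, -0.06, 834, 383),
    "C1": (7.63, 4.10, 31.25, 82.52, 324.41, 265.72, 21.92, 36.77, 1.57, 1.53, 1.56, 1.53, -0.07, 741, 453),
    "C2": (7.08, 3.90, 29.51, 78.84, 310.85, 249.05, 21.90, 39.91, 1.58, 1.54, 1.58, 1.54, -0.14, 736, 390),
    "C3": (7.06, 3.90, 30.49, 78.34, 309.73, 251.28, 21.73, 36.72, 1.67, 1.64, 1.67, 1.64, -0.16, 734, 387),
    "C4": (6.34, 3.58, 31.06, 92.84, 312.94, 254.30, 21.78, 36.86, 1.59, 1.56, 1.58, 1.57, -0.10, 733, 441),
    "C5": (6.87, 3.88, 30.72, 78.57, 309.09, 250.75, 21.63, 36.71, 1.69, 1.67, 1.68, 1.67, -0.15, 731, 377),
    "C6": (6.69, 3.91, 30.71, 74.94, 307.97, 246.32, 21.58, 40.08, 1.69, 1.68, 1.68, 1.68, -0.13, 731, 374),
    "C7": (6.96, 3.85, 30.34, 78.60, 309.60, 250.31, 21.82, 37.47, 1.60, 1.58, 1.59, 1.58, -0.11, 734, 383),
    "C8": (7.19, 3.89, 30.19, 79.96, 310.64, 251.11, 21.97, 37.55, 1.53, 1.49, 1.52, 1.49, -0.14, 735, 434),
    "C9": (7.09, 3.96, 30.63, 76.96, 309.11, 250.91, 21.86, 36.34, 1.61, 1.58, 1.61, 1.57, -0.17, 736, 387),
    "C10": (6.98, 3.92, 31.26, 78.00, 309.12, 253.30, 21.73, 34.10, 1.68, 1.65, 1.67, 1.65, -0.15, 738, 376),
    "D1": (6.87, 3.92, 31.72, 77.88, 309.79, 256.19, 21.76, 31.84, 1.66, 1.65, 1.66, 1.65, -0.11, 750, 372),
    "D2": (6.83, 3.92, 31.61, 77.84, 309.98, 256.91, 21.67, 31.40, 1.68, 1.67, 1.67, 1.67, -0.09, 749, 383),
    "D3": (6.92, 3.89, 31.77, 76.30, 309.57, 256.69, 21.59, 31.29, 1.70, 1.68, 1.69, 1.68, -0.11, 751, 372),
    "D4": (6.92, 3.86, 31.27, 78.71, 310.48, 256.68, 21.73, 32.06, 1.61, 1.59, 1.60, 1.59, -0.10, 753, 372),
    "D5": (7.08, 3.89, 30.86, 80.64, 311.25, 255.86, 21.94, 33.45, 1.51, 1.50, 1.51, 1.49, -0.10, 757, 386),
    "D6": (6.95, 3.90, 30.90, 79.59, 311.03, 255.56, 21.86, 33.61, 1.56, 1.55, 1.55, 1.55, -0.12, 757, 374),
    "D7": (6.93, 3.93, 31.74, 76.74, 310.06, 258.64, 21.71, 29.72, 1.66, 1.65, 1.66, 1.65, -0.11, 758, 371),
    "D8": (6.86, 3.94, 31.84, 77.62, 310.25, 258.02, 21.58, 30.65, 1.67, 1.66, 1.67, 1.66, -0.08, 759, 373),
    "D9": (6.84, 3.90, 31.83, 78.38, 310.69, 259.24, 21.60, 29.85, 1.69, 1.68, 1.68, 1.68, -0.07, 760, 370),
    "D10": (6.96, 3.91, 32.06, 77.66, 310.64, 259.88, 21.54, 29.21, 1.70, 1.67, 1.69, 1.67, -0.09, 763, 369),
}

#: ERS case 10-beat-block parameters, keyed "A1".."D10".
ERS_BEAT_BLOCKS = {k: dict(zip(_ERS_COLS, v)) for k, v in _ERS_ROWS.items()}

#: Case-derived repolarisation-spread flagging rules (ms): elongation when
#: σTp ≥ 45 / σTn ≥ 80, shortening when σTp ≤ 35 / σTn ≤ 70.  These were set
#: on a single ischaemia case, not calibrated on a population.
DEFAULT_THRESHOLDS = {
    "sigmaTp": {"high": 45.0, "low": 35.0},
    "sigmaTn": {"high": 80.0, "low": 70.0},
}


def beat_model_from_intervals(
    row: dict, mode: str = "separate", mu_rp: float = 100.0
) -> BeatModel:
    """Build an absolute-time :class:`BeatModel` from an interval-style row.

    Published tables carry only μ *differences*; absolute means are fixed by
    choosing the μRp reference (default 100 ms into the beat frame):
    ``μRn = μRp + muRpn``, ``μTn = μRn + muRTn``, ``μTp = μTn + muTpn``.

    ``row`` must contain the four k's, four σ's and the interval metrics
    ``muRpn``/``muRTn``/``muTpn``; ``beta`` (bulk) or ``betaR``/``betaT``
    (separate) default to 0.  σRp/σRn default to the population means when a
    row (e.g. a PCI time point) prints only T-wave parameters.
    """
    muRn = mu_rp + row["muRpn"]
    muTn = muRn + row["muRTn"]
    muTp = muTn + row["muTpn"]
    kw = dict(
        muRp=mu_rp, muRn=muRn, muTn=muTn, muTp=muTp,
        sigmaRp=row.get("sigmaRp", SEPARATE_ALL_AVE["sigmaRp"]),
        sigmaRn=row.get("sigmaRn", SEPARATE_ALL_AVE["sigmaRn"]),
        sigmaTp=row["sigmaTp"], sigmaTn=row["sigmaTn"],
        kRp=row.get("kRp", row.get("kTp")), kRn=row.get("kRn", row.get("kTn")),
        kTp=row["kTp"], kTn=row["kTn"],
    )
    if mode == "bulk":
        kw["beta"] = row.get("beta", 0.0)
    else:
        kw["beta_r"] = row.get("betaR", 0.0)
        kw["beta_t"] = row.get("betaT", 0.0)
    return BeatModel.from_params(mode, **kw)
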