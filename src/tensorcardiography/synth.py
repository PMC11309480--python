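"""Forward-model ECG synthesis: single beats, records, and case scenarios.

Every beat is produced by the package's own CDF-difference model, so the
generating parameters and model-implied fiducial times are known exactly and
serve as ground truth for segmentation and fitting tests.

Model-implied fiducials use Gaussian envelope rules: QRS onset at
``μRp − 3 σRp``, J point at ``μRn + 3 σRn``, T onset at ``μTn − 3 σTn``
(clamped past the J point), and T end at ``μTp + (√(2π)/2) σTp`` — the point
where the tangent at the steepest descent of the anodic repolarisation curve
meets its asymptote, i.e. the model-side analogue of the clinical
tangent-method T end (the full Gaussian tail has no finite endpoint).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import presets
from .model import BeatModel, forward_bulk, forward_separate

__all__ = [
    "BeatTruth",
    "GeneratorConfig",
    "forward_full",
    "model_fiducials",
    "synthesize_beat",
    "synthesize_record",
]


def forward_full(m: BeatModel, t_grid) -> np.ndarray:
    """Evaluate a model over a whole beat (QRS through T).

    Bulk models evaluate directly.  Separate-mode models sum the R and T
    segment equations (both baselines included); because the rising R pair
    does not close, a small residual level ``kRp − kRn`` persists after the
    QRS, as in the separate decomposition itself.
    """
    if m.mode == "bulk":
        return forward_bulk(m, t_grid)
    return (forward_separate(m, t_grid, "R")
            + forward_separate(m, t_grid, "T"))


@dataclass(frozen=True)
class BeatTruth:
    """Generating parameters and model-implied fiducials of one beat (ms,
    relative to the beat's own time origin)."""

    model: BeatModel
    qrs_onset: float
    r_peak: float
    j_point: float
    t_onset: float
    t_peak: float
    t_end: float

    @property
    def qt(self) -> float:
        return self.t_end - self.qrs_onset


def model_fiducials(m: BeatModel) -> dict[str, float]:
    """Model-implied fiducial times (ms) from the Gaussian envelope rules."""
    onset = m.muRp - 3.0 * m.sigmaRp
    j = m.muRn + 3.0 * m.sigmaRn
    t_on = max(m.muTn - 3.0 * m.sigmaTn, j + 10.0)
    t_end = m.muTp + np.sqrt(2.0 * np.pi) / 2.0 * m.sigmaTp
    # R and T apex from dense evaluation of the noiseless model
    tg = np.arange(onset, t_end, 0.5)
    y = forward_full(m, tg)
    qrs = (tg >= onset) & (tg <= j)
    twin = (tg >= t_on) & (tg <= t_end)
    r_peak = float(tg[qrs][np.argmax(y[qrs])])
    t_peak = float(tg[twin][np.argmax(y[twin])])
    return {"qrs_onset": onset, "r_peak": r_peak, "j_point": j,
            "t_onset": t_on, "t_peak": t_peak, "t_end": t_end}


def synthesize_beat(
    m: BeatModel,
    fs: float = 1000.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    duration_ms: float | None = None,
) -> tuple[np.ndarray, BeatTruth]:
    """Sample one beat on a uniform grid, optionally with additive noise.

    Returns ``(samples, truth)``; the grid spans ``[0, duration_ms)`` with
    the model's own time frame (μRp typically ~100 ms into the beat).
    """
    import warnings
    if fs < 250:
        warnings.warn("fs < 250 Hz poorly resolves the T end")
    fid = model_fiducials(m)
    if duration_ms is None:
        duration_ms = fid["t_end"] + 100.0
    t = np.arange(0.0, duration_ms, 1000.0 / fs)
    y = forward_full(m, t)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise requires an explicit rng (seeded)")
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return y, BeatTruth(model=m, **fid)


@dataclass
class GeneratorConfig:
    """Configuration of a synthetic multi-beat record.

    Defaults reproduce a healthy lead-II recording: fixed population-mean
    parameters, 1000 Hz, RR interval 820 ± 20 ms, no noise or drift.  Setting
    ``param_sd`` draws each beat's parameters from independent normals with
    the given SDs (population-table SDs are a natural choice).  ``scenario``
    selects a case emulation instead of the plain parameter scheme:

    * ``"normal"`` — stationary beats from ``params``/``param_sd``;
    * ``"ischemia"`` — the cathodic repolarisation spread σTn ramps
      60 → 104 ms over ``ramp_len`` beats starting at ``ramp_start`` (σTp
      held at 30 ms); from ``st_shift_start`` onward the cathodic weight kRn
      rises by 0.1 mV and the transmural repolarisation delay grows,
      producing an ST depression with QT prolongation.  The spread drift
      precedes the conventional-index changes, as observed during coronary
      occlusion;
    * ``"ers"`` — beat parameters follow the ERS case's published 10-beat
      blocks (sections A–D) with beat-to-beat σTn alternans of amplitude
      ``alternans_ms`` superimposed in sections B and C.
    """

    n_beats: int = 10
    fs: float = 1000.0
    mode: str = "separate"
    params: dict | None = None
    param_sd: dict | None = None
    scenario: str = "normal"
    rri_mean: float = 820.0
    rri_sd: float = 20.0
    noise_sd: float = 0.0
    drift_amplitude: float = 0.0
    drift_freq_hz: float = 0.3
    seed: int | None = None
    mu_rp: float = 100.0
    lead_name: str = "II"
    # ischemia scenario timing (beat indices)
    ramp_start: int = 60
    ramp_len: int = 50
    st_shift_start: int = 120
    # ers scenario
    beats_per_block: int = 10
    alternans_ms: float = 6.0

    def __post_init__(self) -> None:
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        stochastic = (self.noise_sd > 0 or self.param_sd is not None
                      or self.rri_sd > 0 or self.scenario == "ers")
        if stochastic and self.seed is None:
            raise ValueError("a seed is mandatory for stochastic generation")


def _normal_row(cfg: GeneratorConfig, rng: np.random.Generator, i: int) -> dict:
    base = dict(cfg.params if cfg.params is not None else
                (presets.BULK_ALL_AVE if cfg.mode == "bulk"
                 else presets.SEPARATE_ALL_AVE))
    if cfg.param_sd:
        for key, sd in cfg.param_sd.items():
            base[key] = rng.normal(base[key], sd)
        # keep parameters physical
        for key in list(base):
            if key.startswith(("sigma", "k")):
                base[key] = max(base[key], 0.5)
    return base


#: within-subject beat-to-beat jitter of the ischemia scenario, sized from
#: the row-to-row spread of the published 10-beat case blocks (σTn ~±1.3 ms,
#: interval metrics ~±3 ms, weights ~±0.015 mV).  The weight jitter gives the
#: ST level its physiologic ~0.02 mV beat-to-beat wander.
ISCHEMIA_JITTER = {"sigmaTn": 1.3, "sigmaTp": 1.0, "muRTn": 3.0,
                   "muTpn": 3.0, "kRp": 0.015, "kRn": 0.015}


def _ischemia_row(cfg: GeneratorConfig, rng: np.random.Generator, i: int) -> dict:
    row = dict(cfg.params) if cfg.params is not None else dict(presets.BULK_ALL_AVE)
    row.setdefault("beta", 0.0)
    frac = np.clip((i - cfg.ramp_start) / max(cfg.ramp_len, 1), 0.0, 1.0)
    row["sigmaTn"] = 60.0 + frac * (104.0 - 60.0)
    row["sigmaTp"] = 30.0
    if i >= cfg.st_shift_start:
        row["kRn"] = row.get("kRn", row["kTn"]) + 0.10  # ST depression
        row["muTpn"] = row["muTpn"] + 15.0              # mild QT prolongation
    jitter = cfg.param_sd if cfg.param_sd is not None else ISCHEMIA_JITTER
    for key, sd in jitter.items():
        row[key] = max(rng.normal(row[key], sd), 0.5)
    return row


def _ers_row(cfg: GeneratorConfig, rng: np.random.Generator, i: int) -> dict:
    blocks = list(presets.ERS_BEAT_BLOCKS)
    b = min(i // cfg.beats_per_block, len(blocks) - 1)
    name = blocks[b]
    row = dict(presets.ERS_BEAT_BLOCKS[name])
    row["section"] = name[0]
    row["rri"] = row.pop("RRI")
    row.pop("QT")
    if name[0] in ("B", "C"):
        row["sigmaTn"] += cfg.alternans_ms * (1 if i % 2 == 0 else -1)
    return row


def synthesize_record(cfg: GeneratorConfig):
    """Generate a multi-beat single-lead record plus its truth table.

    Returns ``(record, truth)`` where ``record`` is a
    :class:`~tensorcardiography.segmentation.ECGRecord` and ``truth`` a
    DataFrame with one row per beat: beat start (ms and samples), every
    generating parameter, and the model-implied fiducials in record samples.

    Raises if any drawn RR interval is too short to contain its beat
    (``RRI < QT + 100 ms``), which would overlap consecutive beats.
    """
    from .segmentation import ECGRecord

    rng = np.random.default_rng(cfg.seed if cfg.seed is not None else 0)
    row_fn = {"normal": _normal_row, "ischemia": _ischemia_row,
              "ers": _ers_row}.get(cfg.scenario)
    if row_fn is None:
        raise ValueError(f"unknown scenario {cfg.scenario!r}")
    mode = "bulk" if cfg.scenario in ("ischemia", "ers") else cfg.mode

    rows, models, rris = [], [], []
    for i in range(cfg.n_beats):
        row = row_fn(cfg, rng, i)
        rri = row.pop("rri", None)
        if rri is None:
            rri = rng.normal(cfg.rri_mean, cfg.rri_sd) if cfg.rri_sd > 0 \
                else cfg.rri_mean
        m = presets.beat_model_from_intervals(
            {k: v for k, v in row.items() if k != "section"},
            mode=mode, mu_rp=cfg.mu_rp)
        fid = model_fiducials(m)
        if rri < fid["t_end"] - fid["qrs_onset"] + 100.0:
            raise ValueError(
                f"beat {i}: RRI {rri:.0f} ms < QT + 100 ms — beats overlap")
        rows.append(row)
        models.append(m)
        rris.append(float(rri))

    n_per_beat = [int(round(r * cfg.fs / 1000.0)) for r in rris]
    starts = np.concatenate([[0], np.cumsum(n_per_beat[:-1])]).astype(int)
    total = int(starts[-1] + n_per_beat[-1])
    sig = np.zeros(total)
    dt = 1000.0 / cfg.fs
    records = []
    for i, (m, s0, npts) in enumerate(zip(models, starts, n_per_beat)):
        t_local = np.arange(npts) * dt
        sig[s0:s0 + npts] = forward_full(m, t_local)
        fid = model_fiducials(m)
        rec = {"beat": i, "start_sample": int(s0),
               "start_ms": s0 * dt, "rri_ms": rris[i]}
        rec.update({k: v for k, v in rows[i].items()})
        met_cols = ("muRp", "muRn", "muTn", "muTp")
        rec.update({c: getattr(m, c) for c in met_cols})
        rec.update({f"{k}_sample": int(round((s0 * dt + v) / dt))
                    for k, v in fid.items()})
        rec["qt_true_ms"] = fid["t_end"] - fid["qrs_onset"]
        records.append(rec)

    if cfg.noise_sd > 0:
        sig = sig + rng.normal(0.0, cfg.noise_sd, size=sig.shape)
    if cfg.drift_amplitude > 0:
        t_all = np.arange(total) / cfg.fs
        phase = rng.uniform(0, 2 * np.pi) if cfg.seed is not None else 0.0
        sig = sig + cfg.drift_amplitude * np.sin(
            2 * np.pi * cfg.drift_freq_hz * t_all + phase)

    record = ECGRecord(signals=sig[:, None], fs=cfg.fs,
                       lead_names=[cfg.lead_name])
    truth = pd.DataFrame(records)
    return record, truth
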