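"""Beat detection, fiducial delineation and conventional ECG indices.

A transparent rule-based delineator: R peaks from a smoothed amplitude
threshold with a 200 ms refractory period, QRS onset/J point from derivative
threshold crossings, T end by the tangent method on the descending T limb.
Fiducials only set fit windows and initial values for the decomposition, so
modest landmark error is tolerated downstream; an external delineator can be
substituted by constructing :class:`FiducialPoints` directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "ECGRecord",
    "FiducialPoints",
    "detect_r_peaks",
    "locate_fiducials",
    "conventional_indices",
]


@dataclass
class ECGRecord:
    """A multi-lead ECG: ``signals`` is (n_samples, n_leads) in mV."""

    signals: np.ndarray
    fs: float
    lead_names: list[str]
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.signals.shape[0] < self.signals.shape[1]:
            # accept (n_leads, n_samples) input
            self.signals = self.signals.T
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if len(self.lead_names) != self.signals.shape[1]:
            raise ValueError("lead_names length must match signal columns")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[0]

    def lead(self, name: str) -> np.ndarray:
        return self.signals[:, self.lead_names.index(name)]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class FiducialPoints:
    """Per-beat landmark sample indices; one entry per detected beat.

    ``usable`` marks beats whose landmarks were all found in physiologic
    order; unusable beats keep placeholder indices and must be skipped.
    """

    qrs_onset: np.ndarray
    r_peak: np.ndarray
    j_point: np.ndarray
    t_onset: np.ndarray
    t_peak: np.ndarray
    t_end: np.ndarray
    usable: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        for i in np.nonzero(self.usable)[0]:
            seq = (self.qrs_onset[i], self.r_peak[i], self.j_point[i],
                   self.t_onset[i], self.t_peak[i], self.t_end[i])
            if not all(a < b for a, b in zip(seq, seq[1:])):
                raise ValueError(
                    f"beat {i}: fiducials not strictly increasing: {seq}")

    @property
    def n_beats(self) -> int:
        return len(self.r_peak)

    def qt_ms(self) -> np.ndarray:
        """QT interval per beat: T end − QRS onset, ms (NaN if unusable)."""
        qt = (self.t_end - self.qrs_onset) * 1000.0 / self.fs
        return np.where(self.usable, qt, np.nan)

    def rri_ms(self) -> np.ndarray:
        """RR interval per beat (ΔR-peak to the previous beat; first is NaN)."""
        out = np.full(self.n_beats, np.nan)
        if self.n_beats > 1:
            out[1:] = np.diff(self.r_peak) * 1000.0 / self.fs
        return out


def detect_r_peaks(signal: np.ndarray, fs: float) -> np.ndarray:
    """Locate one R peak per beat with a 200 ms refractory period.

    The signal is smoothed with a 20 ms moving average (which nulls 50 Hz
    mains interference), then a slope-energy feature (squared derivative
    integrated over 30 ms) isolates the QRS — its slopes are several times
    steeper than the T wave's, so tall T waves are rejected.  Feature peaks
    above 25% of the maximum, at least 200 ms apart, are refined to the local
    maximum of the raw signal within ±50 ms.
    """
    x = np.asarray(signal, dtype=float)
    if fs < 100:
        raise ValueError("sampling rate must be >= 100 Hz")
    if x.size < 2 * fs:
        raise ValueError("need at least 2 s of signal")
    w = max(int(round(0.020 * fs)), 1)
    sm = np.convolve(x, np.ones(w) / w, mode="same")
    d = np.gradient(sm)
    wi = max(int(round(0.030 * fs)), 1)
    energy = np.convolve(d * d, np.ones(wi) / wi, mode="same")
    emax = energy.max()
    if emax <= 1e-12:
        warnings.warn("no QRS-like peaks found (flat signal)")
        return np.array([], dtype=int)
    peaks, _ = find_peaks(energy, height=0.25 * emax,
                          distance=max(int(round(0.2 * fs)), 1))
    if peaks.size == 0:
        warnings.warn("no QRS-like peaks found")
        return peaks
    half = max(int(round(0.050 * fs)), 1)
    refined = [lo + int(np.argmax(x[lo:hi])) for p in peaks
               for lo, hi in [(max(p - half, 0), min(p + half + 1, x.size))]]
    out = np.asarray(sorted(set(refined)), dtype=int)
    # merging after refinement can still leave duplicates within refractory
    keep = [0]
    for i in range(1, out.size):
        if out[i] - out[keep[-1]] >= int(round(0.2 * fs)):
            keep.append(i)
    return out[keep]


def _derivative_bounds(x, fs, r, direction):
    """QRS onset (direction=-1) or J point (+1) by 10%-of-max |slope| crossing."""
    win = int(round(0.080 * fs))
    d = np.gradient(x)
    if direction < 0:
        lo, hi = max(r - win, 0), r + 1
        seg = np.abs(d[lo:hi])
        thr = 0.10 * seg.max()
        above = np.nonzero(seg >= thr)[0]
        return lo + above[0] if above.size else None
    lo, hi = r, min(r + win, x.size)
    seg = np.abs(d[lo:hi])
    if seg.size == 0:
        return None
    thr = 0.10 * np.abs(d[max(r - win, 0):hi]).max()
    above = np.nonzero(seg >= thr)[0]
    return lo + above[-1] if above.size else None


def locate_fiducials(signal: np.ndarray, fs: float,
                     r_peaks: np.ndarray) -> FiducialPoints:
    """Delineate each detected beat.

    QRS onset and J point are the first/last crossings of 10% of the maximum
    absolute derivative within ±80 ms of the R peak; T onset defaults to
    J + 40 ms; the T peak is the maximum between T onset + 40 ms and
    min(R + 500 ms, next onset); T end comes from the tangent at the steepest
    descent of the T limb intersected with the PQ baseline, clamped so that
    QT ≤ 600 ms.  Beats with missing or out-of-order landmarks are flagged
    unusable.
    """
    x = np.asarray(signal, dtype=float)
    r_peaks = np.asarray(r_peaks, dtype=int)
    n = len(r_peaks)
    cols = {k: np.zeros(n, dtype=int) for k in
            ("qrs_onset", "r_peak", "j_point", "t_onset", "t_peak", "t_end")}
    usable = np.zeros(n, dtype=bool)
    ms = fs / 1000.0

    for i, r in enumerate(r_peaks):
        cols["r_peak"][i] = r
        onset = _derivative_bounds(x, fs, r, -1)
        j = _derivative_bounds(x, fs, r, +1)
        if onset is None or j is None or not onset < r < j:
            continue
        if (j - onset) > 0.200 * fs:  # QRS must be <= 200 ms
            continue
        t_on = j + int(round(40 * ms))
        next_limit = (r_peaks[i + 1] - int(round(120 * ms))
                      if i + 1 < n else x.size)
        t_hi = min(r + int(round(500 * ms)), next_limit, x.size)
        if t_hi - t_on < int(round(60 * ms)):
            continue
        seek_lo = t_on + int(round(40 * ms))
        t_pk = seek_lo + int(np.argmax(x[seek_lo:t_hi]))
        # baseline from the PQ segment preceding QRS onset
        b_lo = max(onset - int(round(40 * ms)), 0)
        baseline = np.median(x[b_lo:onset]) if onset > b_lo else 0.0
        # tangent method on the descending limb
        limb_hi = min(t_pk + int(round(250 * ms)), x.size - 1)
        if limb_hi - t_pk < int(round(20 * ms)):
            continue
        d = np.gradient(x[t_pk:limb_hi + 1])
        k = int(np.argmin(d))
        slope = d[k]
        if slope >= 0:
            continue
        t0 = t_pk + k
        t_end = t0 + (baseline - x[t0]) / slope
        t_end = int(round(min(t_end, onset + 0.600 * fs, x.size - 1)))
        if not (onset < r < j < t_on < t_pk < t_end):
            continue
        cols["qrs_onset"][i] = onset
        cols["j_point"][i] = j
        cols["t_onset"][i] = t_on
        cols["t_peak"][i] = t_pk
        cols["t_end"][i] = t_end
        usable[i] = True

    return FiducialPoints(usable=usable, fs=fs, **cols)


def conventional_indices(signal: np.ndarray, fiducials: FiducialPoints):
    """Per-beat conventional indices: (ST level mV, QT ms, RRI ms).

    ST level is the mean amplitude over [J+60 ms, J+80 ms] minus the PQ
    baseline (median of the 40 ms before QRS onset).  Beats whose ST window
    runs past the record end, and unusable beats, yield NaN.
    """
    x = np.asarray(signal, dtype=float)
    fs = fiducials.fs
    ms = fs / 1000.0
    st = np.full(fiducials.n_beats, np.nan)
    for i in range(fiducials.n_beats):
        if not fiducials.usable[i]:
            continue
        j = fiducials.j_point[i]
        lo, hi = j + int(round(60 * ms)), j + int(round(80 * ms))
        if hi > x.size:
            continue
        onset = fiducials.qrs_onset[i]
        b_lo = max(onset - int(round(40 * ms)), 0)
        baseline = np.median(x[b_lo:onset]) if onset > b_lo else 0.0
        st[i] = float(np.mean(x[lo:hi]) - baseline)
    return st, fiducials.qt_ms(), fiducials.rri_ms()
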