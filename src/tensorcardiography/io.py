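"""Reading and writing ECG records and parameter tables.

Two record formats are supported:

* **CSV** — a ``# fs=<Hz> units=mV`` comment line, then a header row
  ``time_ms,<lead>,<lead>,...`` and one row per sample.  The sampling rate
  is taken from the comment line, or, failing that, derived from a strictly
  uniform time column; anything else is an error — the rate is never
  guessed.  Units must be declared as mV.
* **WFDB subset** — a text ``.hea`` header plus a format-16 (little-endian
  int16, interleaved) ``.dat`` signal file, the layout used by PhysioNet
  records.  The reader honours per-signal gain and baseline and converts to
  mV; the writer quantises at a configurable gain.  Only single-segment
  format-16 records are handled; this is a deliberately small hand-written
  codec, not a full WFDB implementation.

Parameter tables round-trip through :class:`~tensorcardiography.tensor.
ParameterTensor.to_frame` CSV with masked beats serialised as empty cells.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .segmentation import ECGRecord
from .tensor import ParameterTensor

__all__ = ["read_record", "write_record", "write_parameters",
           "read_parameters"]


class RecordFormatError(ValueError):
    """Raised for malformed or under-specified record files."""


# ---------------------------------------------------------------- CSV -----

def _read_csv(path: Path) -> ECGRecord:
    fs = None
    units = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        m = re.search(r"fs\s*=\s*([0-9.]+)", first)
        fs = float(m.group(1)) if m else None
        m = re.search(r"units\s*=\s*(\S+)", first)
        units = m.group(1) if m else None
        df = pd.read_csv(path, comment="#")
    else:
        df = pd.read_csv(path)
    if df.shape[1] < 2 or "time_ms" not in df.columns:
        raise RecordFormatError(
            f"{path}: expected a 'time_ms' column plus one column per lead")
    if units is None:
        raise RecordFormatError(
            f"{path}: units not declared (need '# fs=... units=mV' header)")
    if units != "mV":
        raise RecordFormatError(f"{path}: unsupported units {units!r}; "
                                "only mV is handled")
    t = df["time_ms"].to_numpy(dtype=float)
    if fs is None:
        dt = np.diff(t)
        if t.size < 2 or not np.allclose(dt, dt[0], rtol=1e-6):
            raise RecordFormatError(
                f"{path}: no fs declared and time column is not uniform")
        fs = 1000.0 / dt[0]
    leads = [c for c in df.columns if c != "time_ms"]
    return ECGRecord(signals=df[leads].to_numpy(dtype=float), fs=fs,
                     lead_names=leads)


def _write_csv(rec: ECGRecord, path: Path) -> None:
    t = np.arange(rec.n_samples) * 1000.0 / rec.fs
    df = pd.DataFrame({"time_ms": t})
    for i, name in enumerate(rec.lead_names):
        df[name] = rec.signals[:, i]
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:g} units=mV\n")
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


# --------------------------------------------------------------- WFDB -----

def _read_wfdb(path: Path) -> ECGRecord:
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    lines = [ln for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    if len(head) < 3:
        raise RecordFormatError(f"{hea}: malformed record line {lines[0]!r}")
    try:
        n_sig = int(head[1])
        fs = float(head[2])
    except ValueError as e:
        raise RecordFormatError(f"{hea}: malformed record line: {e}") from e
    sig_lines = lines[1:1 + n_sig]
    if len(sig_lines) != n_sig:
        raise RecordFormatError(f"{hea}: expected {n_sig} signal lines")
    gains, baselines, names, dat_names = [], [], [], []
    for ln in sig_lines:
        parts = ln.split()
        if len(parts) < 3:
            raise RecordFormatError(f"{hea}: malformed signal line {ln!r}")
        dat_names.append(parts[0])
        if parts[1] != "16":
            raise RecordFormatError(
                f"{hea}: only format 16 is supported, got {parts[1]}")
        gspec = parts[2]
        m = re.match(r"([-0-9.eE+]+)(?:\(([-0-9]+)\))?(?:/(\S+))?$", gspec)
        if not m:
            raise RecordFormatError(f"{hea}: bad gain spec {gspec!r}")
        gain = float(m.group(1)) or 200.0
        baseline = int(m.group(2) or 0)
        unit = m.group(3) or "mV"
        if unit != "mV":
            raise RecordFormatError(f"{hea}: unsupported units {unit!r}")
        gains.append(gain)
        baselines.append(baseline)
        names.append(parts[-1])
    if len(set(dat_names)) != 1:
        raise RecordFormatError(f"{hea}: multi-file records not supported")
    dat = path.parent / dat_names[0]
    raw = np.fromfile(dat, dtype="<i2")
    n = raw.size // n_sig
    adc = raw[: n * n_sig].reshape(n, n_sig).astype(float)
    sig = (adc - np.asarray(baselines)) / np.asarray(gains)
    return ECGRecord(signals=sig, fs=fs, lead_names=names)


def _write_wfdb(rec: ECGRecord, path: Path, gain: float = 1000.0) -> None:
    path = path.with_suffix("")
    dat_name = path.name + ".dat"
    adc = np.round(rec.signals * gain).astype("<i2")
    adc.tofile(path.parent / dat_name)
    with open(path.with_suffix(".hea"), "w") as fh:
        fh.write(f"{path.name} {rec.signals.shape[1]} {rec.fs:g} "
                 f"{rec.n_samples}\n")
        for i, name in enumerate(rec.lead_names):
            first = int(adc[0, i]) if rec.n_samples else 0
            fh.write(f"{dat_name} 16 {gain:g}(0)/mV 16 0 {first} 0 0 "
                     f"{name}\n")


# ---------------------------------------------------------- public API ----

def read_record(path, fmt: str | None = None) -> ECGRecord:
    """Read an ECG record from CSV or a WFDB-subset header/signal pair.

    ``fmt`` is ``"csv"`` or ``"wfdb"``; by default it is inferred from the
    extension (``.csv`` → CSV, ``.hea``/``.dat``/bare name → WFDB).
    """
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix == ".csv" else "wfdb"
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "wfdb":
        return _read_wfdb(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_record(rec: ECGRecord, path, fmt: str | None = None,
                 gain: float = 1000.0) -> None:
    """Write a record as CSV or as a WFDB-subset pair.

    WFDB output quantises amplitudes to ``1/gain`` mV steps (default
    0.001 mV), the usual resolution of digitised clinical ECGs.
    """
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix == ".csv" else "wfdb"
    if fmt == "csv":
        _write_csv(rec, path)
    elif fmt == "wfdb":
        _write_wfdb(rec, path, gain=gain)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_parameters(tensor: ParameterTensor, path) -> None:
    """Serialise a parameter tensor to CSV (masked entries as empty cells)."""
    df = tensor.to_frame()
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def read_parameters(path) -> ParameterTensor:
    """Read back a tensor written by :func:`write_parameters` (lossless)."""
    df = pd.read_csv(path)
    return ParameterTensor.from_frame(df)
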