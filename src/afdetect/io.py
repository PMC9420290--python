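"""Readers and writers for electrogram records and activation annotations.

Supported on-disk formats:

* records -- two-column CSV ``time_ms,amplitude_mV`` (header required,
  '.' decimal, comma separator) or WFDB records (optional extra);
* annotations -- CSV (``lat_ms`` column) or JSON
  ``{"record_id": ..., "source": ..., "lats_ms": [...]}``; WFDB annotation
  files store LATs as sample indices under symbol 'N'.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .core import ActivationSequence, IegmRecord, Source

#: maximum relative deviation of the time grid from uniformity
_UNIFORMITY_PPM = 1e-6


def read_record(path, format: str = "csv") -> IegmRecord:
    """Read an electrogram record from ``path``.

    CSV files must carry a header and two columns (time in ms, amplitude in
    mV); the sampling rate is inferred from the time column, which must be
    uniform within 1 ppm.  WFDB records require the optional ``wfdb`` extra.
    """
    path = Path(path)
    if format == "csv":
        return _read_record_csv(path)
    if format == "wfdb":
        return _read_record_wfdb(path)
    raise ValueError(f"unknown record format: {format!r}")


def _read_record_csv(path: Path) -> IegmRecord:
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        lines = sum(1 for _ in fh)
    if lines < 2:
        raise ValueError(f"{path}: empty record file")
    data = np.genfromtxt(path, delimiter=",", skip_header=1, dtype=float)
    data = np.atleast_2d(data)
    if data.shape[1] != 2:
        raise ValueError(
            f"{path}: expected two columns (time_ms, amplitude_mV), "
            f"got {data.shape[1]}"
        )
    t, x = data[:, 0], data[:, 1]
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples to infer fs")
    dt = np.diff(t)
    dt0 = float(np.median(dt))
    if dt0 <= 0:
        raise ValueError(f"{path}: time column must be strictly increasing")
    if np.max(np.abs(dt - dt0)) > _UNIFORMITY_PPM * dt0 + 1e-12:
        raise ValueError(
            f"{path}: non-uniform time grid (spacing varies by more than "
            f"1 ppm); resample before loading"
        )
    fs = 1000.0 / dt0
    return IegmRecord(record_id=path.stem, samples=x, fs=fs, t0=float(t[0]))


def _read_record_wfdb(path: Path) -> IegmRecord:
    try:
        import wfdb
    except ImportError as exc:  # pragma: no cover - optional extra
        raise ImportError(
            "WFDB support requires the optional 'wfdb' package "
            "(pip install afdetect[wfdb])"
        ) from exc
    rec = wfdb.rdrecord(str(path))
    sig = np.asarray(rec.p_signal)[:, 0]
    return IegmRecord(
        record_id=rec.record_name, samples=sig, fs=float(rec.fs), t0=0.0
    )


def write_record(rec: IegmRecord, path) -> None:
    """Write a record as two-column CSV (time_ms, amplitude_mV)."""
    path = Path(path)
    t = rec.times_ms
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_ms", "amplitude_mV"])
        for ti, xi in zip(t, rec.samples):
            w.writerow([f"{ti:.9g}", f"{xi:.12g}"])


def write_annotations(seq: ActivationSequence, path, format: str = "json") -> None:
    """Write an activation sequence to ``path`` (CSV or JSON)."""
    path = Path(path)
    if format == "json":
        payload = {
            "record_id": seq.record_id,
            "source": seq.source.value,
            "lats_ms": [float(v) for v in seq.lats],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["record_id", "source", "lat_ms"])
            for v in seq.lats:
                w.writerow([seq.record_id, seq.source.value, f"{v:.9f}"])
    else:
        raise ValueError(f"unknown annotation format: {format!r}")


def read_annotations(path, format: str | None = None) -> ActivationSequence:
    """Read an activation sequence written by :func:`write_annotations`."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "json"
    if format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        return ActivationSequence(
            record_id=payload["record_id"],
            lats=np.asarray(payload["lats_ms"], dtype=float),
            source=Source(payload["source"]),
        )
    if format == "csv":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        if not rows:
            raise ValueError(f"{path}: annotation CSV has no data rows")
        return ActivationSequence(
            record_id=rows[0]["record_id"],
            lats=np.asarray([float(r["lat_ms"]) for r in rows]),
            source=Source(rows[0]["source"]),
        )
    raise ValueError(f"unknown annotation format: {format!r}")
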