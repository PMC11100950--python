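"""Readers and writers for standard formats.

* **EDF** (European Data Format): one file per record, one 16-bit signal
  per channel, physical dimensions uV / mV / mmHg / "" (dimensionless).
  Both the writer and the reader are implemented here against the EDF
  field layout; physical values are reconstructed with exactly the
  writer's gain/offset arithmetic, so a record already on the 16-bit
  quantization grid round-trips bit-exact.  :func:`edf_quantized`
  projects a record onto that grid up front, which makes the in-memory
  and the through-file analysis paths identical.
* **Track tables** (VitalDB-style exports): plain CSV with either a
  ``(time, value)`` pair of columns or a single value column at a known
  rate.  Gaps in the time grid become missing values (NaN);
  :func:`fill_missing` materializes them as a constant fill so the
  constant-data rule catches the loss.
* **Annotation tables**: ground-truth artifact lists as CSV.
"""

from __future__ import annotations

import math
import struct
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, FormatError
from .segmentation import MODALITY_UNITS, Modality, SignalRecord
from .synthetic import ArtifactAnnotation

__all__ = [
    "write_edf",
    "read_edf",
    "edf_quantized",
    "read_track_table",
    "fill_missing",
    "write_annotations",
    "read_annotations",
]

_DMIN, _DMAX = -32768, 32767

#: EDF physical dimension -> modality (the reverse of MODALITY_UNITS).
_DIM_TO_MODALITY = {
    "uV": Modality.EEG,
    "µV": Modality.EEG,
    "mV": Modality.ECG,
    "mmHg": Modality.RESP_CAPNO,
    "": Modality.RESP_AIRFLOW,
}


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.encode("ascii").ljust(width)


def _fmt8(value: float) -> str:
    """Format a float into <= 8 ASCII chars, parseable by float()."""
    for prec in (7, 6, 5, 4, 3, 2, 1):
        s = f"{value:.{prec}g}"
        if len(s) <= 8:
            return s
    return f"{value:.0e}"[:8]


def _physical_bounds(x: np.ndarray) -> tuple[float, float]:
    """Header physical min/max covering the data after ASCII rounding."""
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        hi = lo + 1.0
    span = hi - lo
    pmin, pmax = lo, hi
    for _ in range(8):
        pmin_f = float(_fmt8(pmin))
        pmax_f = float(_fmt8(pmax))
        if pmin_f <= lo and pmax_f >= hi and pmin_f < pmax_f:
            return pmin_f, pmax_f
        pmin -= 0.01 * span
        pmax += 0.01 * span
    raise FormatError("could not encode physical bounds in 8 ASCII characters")


def _gain_offset(pmin: float, pmax: float) -> tuple[float, float]:
    gain = (pmax - pmin) / (_DMAX - _DMIN)
    return gain, pmin


def _quantize(x: np.ndarray, pmin: float, pmax: float) -> np.ndarray:
    gain, _ = _gain_offset(pmin, pmax)
    d = np.rint((x - pmin) / gain) + _DMIN
    return np.clip(d, _DMIN, _DMAX).astype("<i2")


def _dequantize(d: np.ndarray, pmin: float, pmax: float) -> np.ndarray:
    gain, _ = _gain_offset(pmin, pmax)
    return (d.astype(np.int64) - _DMIN) * gain + pmin


def _record_duration(rates: Sequence[float]) -> int:
    for d in range(1, 11):
        if all(abs(fs * d - round(fs * d)) < 1e-9 for fs in rates):
            return d
    raise FormatError(f"no EDF data-record duration <= 10 s fits rates {rates}")


def edf_quantized(record: SignalRecord) -> SignalRecord:
    """Project a record's samples onto the EDF 16-bit quantization grid.

    Applies exactly the quantization :func:`write_edf` would, so writing
    the result and reading it back is bit-exact.
    """
    pmin, pmax = record.physical_range or _physical_bounds(record.samples)
    d = _quantize(record.samples, pmin, pmax)
    from dataclasses import replace

    return replace(record, samples=_dequantize(d, pmin, pmax), physical_range=(pmin, pmax))


def write_edf(records: Sequence[SignalRecord], path) -> None:
    """Write one multichannel record (one signal per channel) as EDF.

    All channels must share the record_id and total duration; samples
    are quantized to 16 bits over each channel's own physical range.
    A trailing partial data record is padded with the channel's last
    sample value.
    """
    if not records:
        raise ConfigurationError("write_edf needs at least one channel")
    durations = {round(r.duration, 9) for r in records}
    if len(durations) != 1:
        raise FormatError("all EDF channels must share the total duration")
    total_s = durations.pop()
    d = _record_duration([r.fs for r in records])
    n_records = int(math.ceil(total_s / d))
    ns = len(records)

    bounds = [r.physical_range or _physical_bounds(r.samples) for r in records]
    spr = [int(round(r.fs * d)) for r in records]  # samples per data record

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X", 80),
            _ascii("synthetic sigsuit", 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(256 * (ns + 1), 8),
            _ascii("", 44),
            _ascii(n_records, 8),
            _ascii(d, 8),
            _ascii(ns, 4),
        ]
    )
    labels = b"".join(_ascii(r.channel or r.modality.value, 16) for r in records)
    transducers = b"".join(_ascii("", 80) for _ in records)
    dims = b"".join(_ascii(r.units, 8) for r in records)
    pmins = b"".join(_ascii(_fmt8(b[0]), 8) for b in bounds)
    pmaxs = b"".join(_ascii(_fmt8(b[1]), 8) for b in bounds)
    dmins = b"".join(_ascii(_DMIN, 8) for _ in records)
    dmaxs = b"".join(_ascii(_DMAX, 8) for _ in records)
    prefilter = b"".join(_ascii("", 80) for _ in records)
    sprs = b"".join(_ascii(s, 8) for s in spr)
    reserved = b"".join(_ascii("", 32) for _ in records)

    quantized = []
    for r, (pmin, pmax), s in zip(records, bounds, spr):
        q = _quantize(r.samples, pmin, pmax)
        need = n_records * s
        if q.size < need:
            q = np.concatenate([q, np.full(need - q.size, q[-1], dtype="<i2")])
        quantized.append(q)

    with open(path, "wb") as fh:
        fh.write(header + labels + transducers + dims + pmins + pmaxs)
        fh.write(dmins + dmaxs + prefilter + sprs + reserved)
        for k in range(n_records):
            for q, s in zip(quantized, spr):
                fh.write(q[k * s : (k + 1) * s].tobytes())


def read_edf(
    path,
    modality_map: Optional[Mapping[str, Modality]] = None,
    record_id: Optional[str] = None,
) -> list[SignalRecord]:
    """Read an EDF/EDF+ file into one SignalRecord per signal.

    Physical units and per-signal sampling rates are preserved; no
    resampling.  Modalities are taken from ``modality_map`` (by channel
    label) when given, else inferred from the physical dimension.

    Raises
    ------
    FormatError
        On a malformed header, with the byte offset of the bad field.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise FormatError(f"{path}: truncated EDF header (< 256 bytes at offset 0)")

    def field(offset: int, width: int, kind=str):
        text = raw[offset : offset + width].decode("ascii", errors="replace").strip()
        if kind is str:
            return text
        try:
            return kind(text)
        except ValueError as exc:
            raise FormatError(f"{path}: bad header field at byte offset {offset}") from exc

    header_bytes = field(184, 8, int)
    n_data_records = field(236, 8, int)
    record_dur = field(244, 8, float)
    ns = field(252, 4, int)
    if ns < 1 or header_bytes != 256 * (ns + 1):
        raise FormatError(f"{path}: inconsistent signal count at byte offset 252")
    if len(raw) < header_bytes:
        raise FormatError(f"{path}: truncated signal headers at offset 256")

    def sig_fields(base: int, width: int, kind=str):
        return [field(base + i * width, width, kind) for i in range(ns)]

    base = 256
    labels = sig_fields(base, 16)
    base += ns * (16 + 80)
    dims = sig_fields(base, 8)
    base += ns * 8
    pmins = sig_fields(base, 8, float)
    base += ns * 8
    pmaxs = sig_fields(base, 8, float)
    base += ns * 8
    dmins = sig_fields(base, 8, int)
    base += ns * 8
    dmaxs = sig_fields(base, 8, int)
    base += ns * (8 + 80)
    spr = sig_fields(base, 8, int)

    data = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    rec_len = sum(spr)
    if n_data_records < 0:  # EDF allows -1 for "unknown"
        n_data_records = data.size // rec_len
    if data.size < n_data_records * rec_len:
        raise FormatError(f"{path}: truncated data section at offset {header_bytes}")
    data = data[: n_data_records * rec_len].reshape(n_data_records, rec_len)

    rid = record_id or path.stem
    records = []
    col = 0
    for i in range(ns):
        block = data[:, col : col + spr[i]].reshape(-1)
        col += spr[i]
        if dmins[i] != _DMIN or dmaxs[i] != _DMAX:
            gain = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
            x = (block.astype(np.int64) - dmins[i]) * gain + pmins[i]
        else:
            x = _dequantize(block, pmins[i], pmaxs[i])
        label = labels[i]
        if modality_map and label in modality_map:
            modality = Modality(modality_map[label])
        elif dims[i] in _DIM_TO_MODALITY:
            modality = _DIM_TO_MODALITY[dims[i]]
        else:
            raise FormatError(
                f"{path}: cannot infer modality for signal {label!r} (dim {dims[i]!r})"
            )
        records.append(
            SignalRecord(
                record_id=rid,
                modality=modality,
                samples=x,
                fs=spr[i] / record_dur,
                channel=label,
                units=dims[i],
                physical_range=(pmins[i], pmaxs[i]),
            )
        )
    return records


def read_track_table(
    path,
    fs: float,
    modality: Modality | str,
    record_id: Optional[str] = None,
    channel: str = "",
) -> SignalRecord:
    """Read a VitalDB-style per-track sample table (CSV).

    Two columns are treated as ``(time, value)`` and placed on the
    uniform ``fs`` grid (missing grid points become NaN); one column is
    taken as consecutive samples at ``fs``.  Non-monotone time raises a
    format error.
    """
    df = pd.read_csv(path)
    if df.shape[1] not in (1, 2):
        raise FormatError(f"{path}: expected 1 or 2 columns, got {df.shape[1]}")
    if df.shape[1] == 1:
        samples = df.iloc[:, 0].to_numpy(dtype=float)
    else:
        t = df.iloc[:, 0].to_numpy(dtype=float)
        v = df.iloc[:, 1].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            raise FormatError(f"{path}: time column is not non-decreasing")
        idx = np.rint((t - t[0]) * fs).astype(int)
        samples = np.full(int(idx[-1]) + 1, np.nan)
        samples[idx] = v
    return SignalRecord(
        record_id=record_id or Path(path).stem,
        modality=Modality(modality),
        samples=samples,
        fs=fs,
        channel=channel,
    )


def fill_missing(record: SignalRecord, fill_value: float = 0.0) -> SignalRecord:
    """Replace NaN spans with a constant fill value.

    Data loss then appears as constant data and is caught by the
    constant-data rule, mirroring how loss manifests in real exports.
    """
    from dataclasses import replace

    x = record.samples
    if not np.isnan(x).any():
        return record
    y = x.copy()
    y[np.isnan(y)] = fill_value
    return replace(record, samples=y)


_ANN_COLUMNS = ["record_id", "channel", "kind", "start_s", "duration_s", "params"]


def write_annotations(annotations: Sequence[ArtifactAnnotation], path) -> None:
    """Write ground-truth artifact annotations as a CSV sidecar."""
    rows = [
        {
            "record_id": a.record_id,
            "channel": a.channel,
            "kind": a.kind.value,
            "start_s": a.start,
            "duration_s": a.duration,
            "params": ";".join(f"{k}={v}" for k, v in sorted(a.parameters.items())),
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=_ANN_COLUMNS).to_csv(path, index=False)


def read_annotations(path) -> list[ArtifactAnnotation]:
    """Read an annotation sidecar written by :func:`write_annotations`."""
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        params = {}
        if row.get("params"):
            for item in str(row["params"]).split(";"):
                k, _, v = item.partition("=")
                try:
                    params[k] = float(v)
                except ValueError:
                    params[k] = v
        out.append(
            ArtifactAnnotation(
                kind=row["kind"],
                start=float(row["start_s"]),
                duration=float(row["duration_s"]),
                channel=str(row["channel"]),
                record_id=str(row["record_id"]),
                parameters=params,
            )
        )
    return out
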