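"""Minimal EDF (European Data Format) reader/writer plus annotation parsing.

Implements the plain 16-bit EDF dialect (fixed 256-byte header + 256 bytes
per signal, little-endian int16 data records) sufficient for round-tripping
synthetic recordings and reading clinical-style files with a configured
channel list.  Seizure annotations live in sidecar files: a two-column CSV
(``onset_s,offset_s``) or a CHB-MIT-style plain-text summary.

All annotation times are seconds from the start of the recording, 0-based,
half-open intervals ``[onset, offset)``.
"""
from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .synthetic import Recording

__all__ = [
    "EdfError",
    "SeizureAnnotations",
    "read_edf",
    "write_edf",
    "read_annotations",
    "write_annotations",
    "read_manifest",
    "load_manifest",
]

_DIG_MIN, _DIG_MAX = -32768, 32767


class EdfError(ValueError):
    """Raised for malformed EDF files or invalid write requests."""


@dataclass
class SeizureAnnotations:
    """Sorted seizure events with their provenance dialect."""

    events: list[tuple[float, float]]
    source: str = "csv"

    def __post_init__(self) -> None:
        self.events = sorted((float(a), float(b)) for a, b in self.events)
        prev = -np.inf
        for onset, offset in self.events:
            if offset <= onset:
                raise ValueError(f"annotation offset {offset} <= onset {onset}")
            if onset <= prev:
                raise ValueError("annotation onsets must be strictly increasing")
            prev = onset


def _fmt8(value: float) -> str:
    """Format a float into <= 8 ASCII chars (EDF numeric header field)."""
    for fmt in ("%g", "%.6g", "%.5g", "%.4g", "%.3g", "%.2g", "%.1e"):
        s = fmt % value
        if len(s) <= 8:
            return s
    raise EdfError(f"cannot format {value} into 8 characters")


def _pad(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")[:width]
    return raw.ljust(width)


def write_edf(
    path: Union[str, Path],
    recording: Recording,
    patient_id: str = "X",
    recording_id: str = "synthetic",
) -> None:
    """Write *recording* as a plain EDF file.

    Requires an integer sampling rate and a whole number of seconds of data
    (one data record per second).  Samples are quantized to 16 bits over each
    channel's physical range; the quantization step is
    ``(phys_max - phys_min) / 65535``.
    """
    sig = np.asarray(recording.signal, dtype=float)
    n_ch, n_samp = sig.shape
    spr = int(round(recording.fs))
    if abs(recording.fs - spr) > 1e-9 or spr <= 0:
        raise EdfError(f"EDF writer requires an integer sampling rate, got {recording.fs}")
    if n_samp % spr != 0:
        raise EdfError("EDF writer requires a whole number of seconds of data")
    n_rec = n_samp // spr

    # physical ranges are written through the 8-char header format and the
    # *formatted* values are used for quantization so decode is consistent
    pmins, pmaxs, digital = [], [], np.empty((n_ch, n_samp), dtype="<i2")
    for c in range(n_ch):
        lo, hi = float(sig[c].min()), float(sig[c].max())
        if hi <= lo:
            hi = lo + 1.0
        lo_s, hi_s = _fmt8(lo), _fmt8(hi)
        lo_f, hi_f = float(lo_s), float(hi_s)
        if hi_f <= lo_f:
            hi_f = lo_f + 1.0
            hi_s = _fmt8(hi_f)
        scale = (_DIG_MAX - _DIG_MIN) / (hi_f - lo_f)
        d = np.rint((sig[c] - lo_f) * scale) + _DIG_MIN
        digital[c] = np.clip(d, _DIG_MIN, _DIG_MAX).astype("<i2")
        pmins.append(lo_s)
        pmaxs.append(hi_s)

    header = b"".join(
        [
            _pad("0", 8),
            _pad(patient_id, 80),
            _pad(recording_id, 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (n_ch + 1)), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),
            _pad(str(n_ch), 4),
        ]
    )
    fields = [
        [_pad(name, 16) for name in recording.channel_names],
        [_pad("synthetic EEG", 80)] * n_ch,
        [_pad("uV", 8)] * n_ch,
        [_pad(s, 8) for s in pmins],
        [_pad(s, 8) for s in pmaxs],
        [_pad(str(_DIG_MIN), 8)] * n_ch,
        [_pad(str(_DIG_MAX), 8)] * n_ch,
        [_pad("", 80)] * n_ch,
        [_pad(str(spr), 8)] * n_ch,
        [_pad("", 32)] * n_ch,
    ]
    # data records: record-major, channel-major within a record
    data = digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        for col in fields:
            fh.write(b"".join(col))
        fh.write(np.ascontiguousarray(data).tobytes())


def read_edf(path: Union[str, Path], channels: Optional[Sequence[str]] = None) -> Recording:
    """Read an EDF/EDF+ file, optionally selecting a channel list.

    Channels requested but absent from the file raise :class:`EdfError`
    naming them; selected channels must share one sampling rate.  EDF+
    'EDF Annotations' signals are skipped.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise EdfError(f"{path}: truncated EDF header")

    def f(a: int, b: int) -> str:
        return raw[a:b].decode("ascii", errors="replace").strip()

    try:
        n_rec = int(f(236, 244))
        record_dur = float(f(244, 252))
        n_sig = int(f(252, 256))
    except ValueError as exc:
        raise EdfError(f"{path}: malformed EDF header ({exc})") from None
    hdr_len = 256 + 256 * n_sig
    if len(raw) < hdr_len:
        raise EdfError(f"{path}: truncated signal header")

    def col(idx: int, width: int, count: int = n_sig) -> list[str]:
        base = 256 + idx
        return [
            raw[base + width * k : base + width * (k + 1)].decode("ascii", "replace").strip()
            for k in range(count)
        ]

    labels = col(0, 16)
    offset = 16 * n_sig + 80 * n_sig + 8 * n_sig
    pmin = [float(s) for s in col(offset, 8)]
    pmax = [float(s) for s in col(offset + 8 * n_sig, 8)]
    dmin = [int(s) for s in col(offset + 16 * n_sig, 8)]
    dmax = [int(s) for s in col(offset + 24 * n_sig, 8)]
    spr = [int(s) for s in col(offset + 32 * n_sig + 80 * n_sig, 8)]

    rec_len = sum(spr)
    expected = hdr_len + 2 * rec_len * n_rec
    if len(raw) < expected:
        raise EdfError(f"{path}: truncated data section ({len(raw)} < {expected} bytes)")
    data = np.frombuffer(raw, dtype="<i2", count=rec_len * n_rec, offset=hdr_len)
    data = data.reshape(n_rec, rec_len)

    keep = [k for k in range(n_sig) if labels[k] != "EDF Annotations"]
    if channels is not None:
        by_label = {labels[k]: k for k in keep}
        missing = [name for name in channels if name not in by_label]
        if missing:
            raise EdfError(f"{path}: requested channels not in file: {missing}")
        keep = [by_label[name] for name in channels]
    if not keep:
        raise EdfError(f"{path}: no data channels")
    rates = {spr[k] / record_dur for k in keep}
    if len(rates) != 1:
        raise EdfError(f"{path}: selected channels have differing sampling rates: {sorted(rates)}")
    fs = rates.pop()

    starts = np.concatenate(([0], np.cumsum(spr)))
    sigs = []
    for k in keep:
        d = data[:, starts[k] : starts[k + 1]].reshape(-1).astype(float)
        gain = (pmax[k] - pmin[k]) / (dmax[k] - dmin[k])
        sigs.append((d - dmin[k]) * gain + pmin[k])
    return Recording(
        signal=np.vstack(sigs),
        fs=fs,
        channel_names=[labels[k] for k in keep],
        annotations=[],
    )


def write_annotations(path: Union[str, Path], annotations: SeizureAnnotations) -> None:
    """Write events as a two-column CSV sidecar."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["onset_s", "offset_s"])
        for onset, offset in annotations.events:
            writer.writerow([repr(onset), repr(offset)])


_CHBMIT_START = re.compile(r"Seizure(?:\s+\d+)?\s+Start\s+Time:\s*([\d.]+)\s*seconds", re.I)
_CHBMIT_END = re.compile(r"Seizure(?:\s+\d+)?\s+End\s+Time:\s*([\d.]+)\s*seconds", re.I)


def read_annotations(path: Union[str, Path], dialect: str = "csv") -> SeizureAnnotations:
    """Parse seizure events from a sidecar file.

    ``dialect='csv'`` expects a header row ``onset_s,offset_s``;
    ``dialect='chbmit-summary'`` parses the plain-text summary grammar
    (``Seizure Start Time: N seconds`` / ``Seizure End Time: N seconds``
    pairs, with or without seizure numbering).  Events are returned sorted.
    """
    text = Path(path).read_text()
    if dialect == "csv":
        rows = list(csv.DictReader(text.splitlines()))
        events = [(float(r["onset_s"]), float(r["offset_s"])) for r in rows]
    elif dialect == "chbmit-summary":
        starts = [float(m.group(1)) for m in _CHBMIT_START.finditer(text)]
        ends = [float(m.group(1)) for m in _CHBMIT_END.finditer(text)]
        if len(starts) != len(ends):
            raise ValueError(
                f"{path}: {len(starts)} start times but {len(ends)} end times in summary"
            )
        events = list(zip(starts, ends))
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    return SeizureAnnotations(events=events, source=dialect)


def read_manifest(path: Union[str, Path]) -> list[dict]:
    """Read a cohort manifest: a JSON list of recording entries.

    Each entry has ``edf`` (path), optional ``annotations`` (path) and
    ``annotation_dialect``.  Relative paths resolve against the manifest
    location.  Files are treated as independent continuous recordings;
    analysis windows therefore never span file boundaries.
    """
    path = Path(path)
    entries = json.loads(path.read_text())
    if not isinstance(entries, list):
        raise ValueError(f"{path}: manifest must be a JSON list")
    out = []
    for entry in entries:
        resolved = dict(entry)
        resolved["edf"] = str((path.parent / entry["edf"]).resolve())
        if entry.get("annotations"):
            resolved["annotations"] = str((path.parent / entry["annotations"]).resolve())
        out.append(resolved)
    return out


def load_manifest(
    path: Union[str, Path], channels: Optional[Sequence[str]] = None
) -> list[tuple[Recording, SeizureAnnotations]]:
    """Load every recording + annotations referenced by a manifest."""
    pairs = []
    for entry in read_manifest(path):
        rec = read_edf(entry["edf"], channels=channels)
        if entry.get("annotations"):
            ann = read_annotations(
                entry["annotations"], dialect=entry.get("annotation_dialect", "csv")
            )
        else:
            ann = SeizureAnnotations(events=[])
        rec.annotations = list(ann.events)
        pairs.append((rec, ann))
    return pairs
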