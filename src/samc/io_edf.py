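"""Reading and writing EEG recordings and spindle annotations.

Signals travel as EDF (European Data Format) files; annotations and
detected events travel as CSV/TSV.  All amplitudes inside the library are
microvolts and all times are seconds from recording start, with events as
half-open intervals ``[onset, offset)``.

The EDF layer here is deliberately small: a fixed 256-byte global header,
one 256-byte header block per signal, then 16-bit little-endian sample
records.  Per-channel sampling rates are preserved exactly as stored —
no resampling happens at read time.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Recording",
    "AnnotationSet",
    "Annotation",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "read_events",
    "write_events",
]

#: Physical range used by the synthetic EDF writer; 16-bit quantization over
#: ±400 µV gives a step of 800/65535 ≈ 0.0122 µV.
EDF_PHYS_RANGE_UV = 400.0

_UV_DIMENSIONS = {"uv", "µv", "uV".lower()}


@dataclass
class Recording:
    """Multichannel EEG with per-channel sampling rates, amplitudes in µV.

    Channels may have different sampling rates (and hence different sample
    counts); each entry of ``data`` is a 1-D float array in microvolts.
    """

    channel_labels: list[str]
    data: list[np.ndarray]
    fs: list[float]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if len(self.channel_labels) != len(self.data) or len(self.data) != len(self.fs):
            raise ValueError("channel_labels, data and fs must have equal length")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        for lbl, rate in zip(self.channel_labels, self.fs):
            if rate <= 0:
                raise ValueError(f"channel {lbl!r}: sampling rate must be > 0")
        self.data = [np.asarray(d, dtype=float).ravel() for d in self.data]

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    @property
    def duration_s(self) -> float:
        return max(len(d) / r for d, r in zip(self.data, self.fs))

    def channel(self, label: str) -> np.ndarray:
        return self.data[self._index(label)]

    def channel_fs(self, label: str) -> float:
        return self.fs[self._index(label)]

    def _index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label {label!r}") from None

    def pick(self, labels: Sequence[str]) -> "Recording":
        """Return a copy restricted to *labels*, in the requested order."""
        idx = [self._index(lb) for lb in labels]
        return Recording(
            channel_labels=[self.channel_labels[i] for i in idx],
            data=[self.data[i].copy() for i in idx],
            fs=[self.fs[i] for i in idx],
            start_time=self.start_time,
        )

    def copy_with(self, data: list[np.ndarray]) -> "Recording":
        return Recording(
            channel_labels=list(self.channel_labels),
            data=data,
            fs=list(self.fs),
            start_time=self.start_time,
        )


@dataclass(frozen=True)
class Annotation:
    """One scored event: onset/duration in seconds, free-text label/scorer."""

    onset_s: float
    duration_s: float
    label: str = "spindle"
    scorer: str = ""
    channel: str | None = None

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class AnnotationSet:
    """A list of scored events plus the file/scorer they came from."""

    events: list[Annotation] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.onset_s < 0:
                raise ValueError(f"annotation onset must be >= 0, got {ev.onset_s}")
            if ev.duration_s < 0:
                raise ValueError(f"annotation duration must be >= 0, got {ev.duration_s}")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def sorted(self) -> "AnnotationSet":
        return AnnotationSet(sorted(self.events, key=lambda e: (e.onset_s, e.duration_s)), self.source)

    def intervals(self) -> list[tuple[float, float]]:
        return [(e.onset_s, e.offset_s) for e in self.events]


# ---------------------------------------------------------------------------
# EDF container
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")[:width]
    return raw + b" " * (width - len(raw))


def write_recording(rec: Recording, path: str | Path, *, record_dur_s: float = 1.0,
                    phys_range_uv: float = EDF_PHYS_RANGE_UV) -> Path:
    """Write *rec* as a plain EDF file.

    Every channel's samples-per-record (``fs × record_dur_s``) must be an
    integer.  Amplitudes are quantized to 16 bits over ±``phys_range_uv``;
    values outside the physical range are clipped.
    """
    path = Path(path)
    n_sig = rec.n_channels
    spr = []
    for lbl, rate in zip(rec.channel_labels, rec.fs):
        n = rate * record_dur_s
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError(f"channel {lbl!r}: fs {rate} Hz not integer per {record_dur_s}-s record")
        spr.append(int(round(n)))
    n_records = int(np.ceil(max(len(d) / (s or 1) for d, s in zip(rec.data, spr))))
    n_records = max(n_records, 1)

    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (2 * phys_range_uv)

    now = _dt.datetime(2000, 1, 1)
    buf = io.BytesIO()
    buf.write(_pad("0", 8))                               # version
    buf.write(_pad("X X X X", 80))                        # patient id
    buf.write(_pad("Startdate X X X X", 80))              # recording id
    buf.write(_pad(now.strftime("%d.%m.%y"), 8))
    buf.write(_pad(now.strftime("%H.%M.%S"), 8))
    buf.write(_pad(str(256 * (1 + n_sig)), 8))            # header bytes
    buf.write(_pad("", 44))                               # reserved
    buf.write(_pad(str(n_records), 8))
    buf.write(_pad(f"{record_dur_s:g}", 8))
    buf.write(_pad(str(n_sig), 4))

    for lbl in rec.channel_labels:
        buf.write(_pad(lbl, 16))
    for _ in range(n_sig):
        buf.write(_pad("EEG electrode", 80))              # transducer
    for _ in range(n_sig):
        buf.write(_pad("uV", 8))                          # physical dimension
    for _ in range(n_sig):
        buf.write(_pad(f"{-phys_range_uv:g}", 8))
    for _ in range(n_sig):
        buf.write(_pad(f"{phys_range_uv:g}", 8))
    for _ in range(n_sig):
        buf.write(_pad(str(dig_min), 8))
    for _ in range(n_sig):
        buf.write(_pad(str(dig_max), 8))
    for _ in range(n_sig):
        buf.write(_pad("", 80))                           # prefiltering
    for s in spr:
        buf.write(_pad(str(s), 8))
    for _ in range(n_sig):
        buf.write(_pad("", 32))                           # reserved

    digitized = []
    for d, s in zip(rec.data, spr):
        full = np.zeros(n_records * s)
        full[: len(d)] = np.clip(d, -phys_range_uv, phys_range_uv)
        digitized.append(np.round(full * scale).astype("<i2"))

    for r in range(n_records):
        for dig, s in zip(digitized, spr):
            buf.write(dig[r * s:(r + 1) * s].tobytes())

    path.write_bytes(buf.getvalue())
    return path


def _read_field(fh, width: int) -> str:
    return fh.read(width).decode("ascii", errors="replace").strip()


def read_recording(path: str | Path, channels: Sequence[str] | None = None) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording`.

    Per-channel native sampling rates are preserved; no resampling.  Only
    channels whose physical dimension is microvolts (or dimensionless blanks,
    taken as µV) are accepted — a channel in mV is converted, anything else
    is rejected by name.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    with open(path, "rb") as fh:
        version = _read_field(fh, 8)
        if version not in {"0"}:
            raise ValueError(f"{path}: not an EDF file (version field {version!r})")
        fh.read(80 + 80 + 8 + 8)                           # ids, date, time
        _read_field(fh, 8)                                 # header bytes
        reserved = _read_field(fh, 44)
        n_records = int(_read_field(fh, 8))
        record_dur = float(_read_field(fh, 8))
        n_sig = int(_read_field(fh, 4))

        labels = [_read_field(fh, 16) for _ in range(n_sig)]
        fh.read(80 * n_sig)                                # transducers
        dims = [_read_field(fh, 8) for _ in range(n_sig)]
        pmin = [float(_read_field(fh, 8)) for _ in range(n_sig)]
        pmax = [float(_read_field(fh, 8)) for _ in range(n_sig)]
        dmin = [int(_read_field(fh, 8)) for _ in range(n_sig)]
        dmax = [int(_read_field(fh, 8)) for _ in range(n_sig)]
        fh.read(80 * n_sig)                                # prefiltering
        spr = [int(_read_field(fh, 8)) for _ in range(n_sig)]
        fh.read(32 * n_sig)

        raw = np.frombuffer(fh.read(), dtype="<i2")

    rec_len = sum(spr)
    n_avail = len(raw) // rec_len
    if n_records < 0 or n_avail < n_records:               # tolerate truncated writers
        n_records = n_avail
    raw = raw[: n_records * rec_len].reshape(n_records, rec_len)

    offsets = np.concatenate([[0], np.cumsum(spr)])
    out_labels, out_data, out_fs = [], [], []
    annotation_like = {"EDF Annotations", "BDF Annotations"}
    for i, lbl in enumerate(labels):
        if lbl in annotation_like:
            continue
        sig = raw[:, offsets[i]:offsets[i + 1]].reshape(-1).astype(float)
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        phys = (sig - dmin[i]) * gain + pmin[i]
        dim = dims[i].lower()
        if dim in _UV_DIMENSIONS or dim == "":
            pass
        elif dim == "mv":
            phys = phys * 1000.0
        else:
            if channels is not None and lbl not in channels:
                continue
            raise ValueError(
                f"channel {lbl!r} has physical dimension {dims[i]!r}; only µV/mV signals are supported"
            )
        out_labels.append(lbl)
        out_data.append(phys)
        out_fs.append(spr[i] / record_dur)

    rec = Recording(out_labels, out_data, out_fs, start_time=0.0)
    if channels is not None:
        missing = [c for c in channels if c not in out_labels]
        if missing:
            raise KeyError(f"requested channel(s) not in {path.name}: {missing}")
        rec = rec.pick(list(channels))
    return rec


# ---------------------------------------------------------------------------
# Annotation CSV/TSV
# ---------------------------------------------------------------------------

def _sniff_delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_annotations(path: str | Path, *, label_filter: str | None = None) -> AnnotationSet:
    """Parse a CSV/TSV of scored events.

    Required columns: ``onset_s``, ``duration_s``, ``label``; optional
    ``scorer`` and ``channel``.  An empty duration cell is recorded as 0
    (an undurated mark — see :func:`samc.metrics.pad_undurated`).
    With *label_filter*, rows with a different label are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    events: list[Annotation] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=_sniff_delimiter(path))
        required = {"onset_s", "duration_s", "label"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: missing required columns {sorted(required)}")
        for i, row in enumerate(reader, start=2):          # header is row 1
            try:
                onset = float(row["onset_s"])
                dur_cell = (row["duration_s"] or "").strip()
                dur = float(dur_cell) if dur_cell else 0.0
            except ValueError as exc:
                raise ValueError(f"{path}: malformed numeric field at row {i}: {exc}") from None
            if onset < 0:
                raise ValueError(f"{path}: negative onset {onset} at row {i}")
            if dur < 0:
                raise ValueError(f"{path}: negative duration {dur} at row {i}")
            label = (row.get("label") or "spindle").strip()
            if label_filter is not None and label != label_filter:
                continue
            events.append(Annotation(
                onset_s=onset, duration_s=dur, label=label,
                scorer=(row.get("scorer") or "").strip(),
                channel=(row.get("channel") or "").strip() or None,
            ))
    events.sort(key=lambda e: (e.onset_s, e.duration_s))
    return AnnotationSet(events, source=str(path))


def write_annotations(annset: AnnotationSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["onset_s", "duration_s", "label", "scorer", "channel"])
        for ev in annset.events:
            w.writerow([f"{ev.onset_s:.6f}", f"{ev.duration_s:.6f}", ev.label,
                        ev.scorer, ev.channel or ""])
    return path


# ---------------------------------------------------------------------------
# Detected-event CSV (schema shared with samc.detect.SpindleEvent)
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ["onset_s", "offset_s", "duration_s", "channels",
                 "peak_freq_hz", "peak_norm_power", "area", "p2p_amp_uv", "cls"]


def write_events(events: Iterable, path: str | Path) -> Path:
    """Write detected spindle events to CSV at 6-decimal precision.

    The schema round-trips through :func:`read_events` bit-for-bit at that
    precision; an empty event list yields a header-only file.
    """
    from .detect import SpindleEvent  # local import to avoid a cycle

    path = Path(path)
    rows = []
    for ev in events:
        vals = [ev.onset_s, ev.offset_s, ev.duration_s, ev.peak_freq_hz,
                ev.peak_norm_power, ev.area, ev.p2p_amp_uv]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"event has non-finite fields: {ev}")
        rows.append([f"{ev.onset_s:.6f}", f"{ev.offset_s:.6f}", f"{ev.duration_s:.6f}",
                     "|".join(sorted(ev.channels)), f"{ev.peak_freq_hz:.6f}",
                     f"{ev.peak_norm_power:.6f}", f"{ev.area:.6f}",
                     f"{ev.p2p_amp_uv:.6f}", ev.cls])
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(EVENT_COLUMNS)
        w.writerows(rows)
    return path


def read_events(path: str | Path) -> list:
    """Read a detected-event CSV produced by :func:`write_events`."""
    from .detect import SpindleEvent

    path = Path(path)
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(EVENT_COLUMNS).issubset(reader.fieldnames):
            raise ValueError(f"{path}: not a samc event file (columns {reader.fieldnames})")
        for row in reader:
            out.append(SpindleEvent(
                onset_s=float(row["onset_s"]),
                offset_s=float(row["offset_s"]),
                channels=frozenset(c for c in row["channels"].split("|") if c),
                peak_norm_power=float(row["peak_norm_power"]),
                peak_freq_hz=float(row["peak_freq_hz"]),
                area=float(row["area"]),
                p2p_amp_uv=float(row["p2p_amp_uv"]),
                cls=row["cls"],
            ))
    return out
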