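"""Spindle candidate extraction and cross-channel agreement.

Single-channel rule set (applied to the normalized power trace):

1. samples with norm_power above the 0.5 threshold form candidate runs;
2. each run's boundaries extend outward over the full power peak — down
   to half the run's own peak, but never below 80% of the detection
   threshold (a dual-threshold design: candidacy is decided at 0.5, the
   event spans the peak wave from its start to its last point);
3. runs separated by gaps of at most 0.10 s merge into one run
   (fragmented spindles are scored as a single spindle);
4. merged runs survive iff their duration lies in [0.4 s, 2.0 s] — the
   lower bound is the 0.5-s criterion with a 0.1-s tolerance;
5. surviving runs must reach 13 µV peak-to-peak in the 11–16 Hz filtered
   signal.

Cross-channel rule ("spindles across multiple channels"): a candidate is
confirmed only when at least two channels agree on it for at least 25% of
the event.  Confirmed candidates that overlap across channels merge into
one multi-channel event spanning the union interval.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .sde import PowerTrace

__all__ = [
    "SpindleEvent",
    "BooleanRaster",
    "detect_channel",
    "classify_event",
    "to_raster",
    "raster_to_intervals",
    "samc_combine",
]


@dataclass(frozen=True)
class SpindleEvent:
    """One detected (or merged multi-channel) spindle.

    Intervals are half-open ``[onset_s, offset_s)`` seconds from recording
    start.  ``area`` is the integral of norm_power over the event (unit:
    seconds, since norm_power is dimensionless); ``cls`` is ``"slow"`` for
    peak frequency below 13 Hz and ``"fast"`` at or above.
    """

    onset_s: float
    offset_s: float
    channels: frozenset[str]
    peak_norm_power: float
    peak_freq_hz: float
    area: float
    p2p_amp_uv: float
    cls: str = ""

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise ValueError(f"event offset must exceed onset: [{self.onset_s}, {self.offset_s})")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    def overlap_s(self, other: "SpindleEvent") -> float:
        return max(0.0, min(self.offset_s, other.offset_s) - max(self.onset_s, other.onset_s))


@dataclass
class BooleanRaster:
    """Channels × samples Boolean detection mask at one sampling rate."""

    mask: np.ndarray            # bool, (n_channels, n_samples)
    channel_labels: list[str]
    fs: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or self.mask.shape[0] != len(self.channel_labels):
            raise ValueError("raster mask must be (n_channels, n_samples)")


def classify_event(peak_freq_hz: float, boundary_hz: float = 13.0) -> str:
    """Slow/fast split at the 13-Hz boundary (exactly 13 Hz counts as fast)."""
    return "slow" if peak_freq_hz < boundary_hz else "fast"


def _runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True."""
    padded = np.concatenate([[False], above, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def _merge_runs(runs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe <= max_gap:
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def detect_channel(trace: PowerTrace, band_signal: np.ndarray, *,
                   threshold: float = 0.5, min_dur_s: float = 0.4,
                   max_dur_s: float = 2.0, merge_gap_s: float = 0.10,
                   min_p2p_uv: float = 13.0,
                   boundary_peak_frac: float = 0.5,
                   boundary_floor_frac: float = 0.8,
                   slow_fast_boundary_hz: float = 13.0) -> list[SpindleEvent]:
    """Extract spindle candidates from one channel.

    *trace* is the normalized power trace; *band_signal* is the same
    channel narrowband-filtered to 11–16 Hz (for the peak-to-peak
    amplitude criterion; pass ``min_p2p_uv=0`` to disable it).  Candidates
    overlapping masked (artifact/edge) samples are suppressed.

    Event boundaries span the full power peak: each suprathreshold run is
    extended outward to where norm_power falls below
    ``max(boundary_peak_frac × run peak, boundary_floor_frac × threshold)``.
    Setting both fractions to 1 reduces boundaries to the bare
    suprathreshold run.
    """
    band_signal = np.asarray(band_signal, dtype=float).ravel()
    if len(band_signal) != len(trace.norm_power):
        raise ValueError("trace and band_signal must have the same length")
    fs = trace.fs
    n = len(band_signal)
    max_gap = int(round(merge_gap_s * fs))

    norm = trace.norm_power
    runs = []
    for s, e in _runs(norm > threshold):
        bnd = max(boundary_peak_frac * norm[s:e].max(), boundary_floor_frac * threshold)
        while s > 0 and norm[s - 1] > bnd:
            s -= 1
        while e < n and norm[e] > bnd:
            e += 1
        runs.append((s, e))
    runs.sort()
    runs = _merge_runs(runs, max_gap)

    events: list[SpindleEvent] = []
    for s, e in runs:
        dur = (e - s) / fs
        if not (min_dur_s <= dur <= max_dur_s):
            continue
        if not trace.keep_mask[s:e].all():
            continue
        seg = band_signal[s:e]
        p2p = float(seg.max() - seg.min()) if len(seg) else 0.0
        if p2p < min_p2p_uv:
            continue
        seg_pow = trace.norm_power[s:e]
        i_peak = int(np.argmax(seg_pow))
        peak_freq = float(trace.peak_freq[s + i_peak])
        events.append(SpindleEvent(
            onset_s=s / fs,
            offset_s=e / fs,
            channels=frozenset([trace.channel] if trace.channel else []),
            peak_norm_power=float(seg_pow[i_peak]),
            peak_freq_hz=peak_freq,
            area=float(seg_pow.sum() / fs),
            p2p_amp_uv=p2p,
            cls=classify_event(peak_freq, slow_fast_boundary_hz),
        ))
    return events


def to_raster(events_by_channel: Mapping[str, Sequence[SpindleEvent]],
              n_samples: int, fs: float) -> BooleanRaster:
    """Rasterize per-channel events into a Boolean channels × samples mask."""
    labels = list(events_by_channel.keys())
    mask = np.zeros((len(labels), n_samples), dtype=bool)
    for row, lbl in enumerate(labels):
        for ev in events_by_channel[lbl]:
            s = int(round(ev.onset_s * fs))
            e = int(round(ev.offset_s * fs))
            if s < 0 or e > n_samples:
                raise ValueError(f"event [{ev.onset_s}, {ev.offset_s}) outside recording on {lbl}")
            mask[row, s:e] = True
    return BooleanRaster(mask=mask, channel_labels=labels, fs=fs)


def raster_to_intervals(raster: BooleanRaster) -> dict[str, list[tuple[float, float]]]:
    """Inverse of :func:`to_raster` at interval level."""
    out: dict[str, list[tuple[float, float]]] = {}
    for row, lbl in enumerate(raster.channel_labels):
        out[lbl] = [(s / raster.fs, e / raster.fs) for s, e in _runs(raster.mask[row])]
    return out


def _channel_overlap(ev: SpindleEvent, others: Sequence[SpindleEvent]) -> float:
    """Total overlap of *ev* with a channel's (disjoint) event list."""
    return sum(ev.overlap_s(o) for o in others)


def samc_combine(events_by_channel: Mapping[str, Sequence[SpindleEvent]], *,
                 min_channels: int = 2, min_agreement: float = 0.25,
                 denominator: str = "each") -> list[SpindleEvent]:
    """Confirm candidates that agree across channels and merge them.

    A single-channel candidate E is confirmed iff at least
    ``min_channels − 1`` *other* channels each overlap E for at least
    ``min_agreement`` × a reference duration.  The reference duration is
    chosen by *denominator*: ``"each"`` (default) uses E's own duration;
    ``"shorter"``/``"longer"`` require some event on the other channel
    whose pairwise overlap reaches the fraction of the shorter/longer of
    the two durations.

    Confirmed candidates overlapping one another across channels merge
    (transitively) into a single multi-channel event spanning the union
    interval; peak fields come from the strongest contributor and the
    peak-to-peak amplitude is the maximum across contributors.
    """
    labels = list(events_by_channel.keys())
    if len(labels) < min_channels:
        raise ValueError(
            f"samc.min_channels={min_channels} but only {len(labels)} channel(s) provided")
    if denominator not in {"each", "shorter", "longer"}:
        raise ValueError(f"unknown agreement denominator {denominator!r}")

    confirmed: list[SpindleEvent] = []
    for lbl in labels:
        for ev in events_by_channel[lbl]:
            n_agree = 0
            for other_lbl in labels:
                if other_lbl == lbl:
                    continue
                others = events_by_channel[other_lbl]
                if denominator == "each":
                    need = min_agreement * ev.duration_s
                    ok = _channel_overlap(ev, others) >= need - 1e-12
                else:
                    ok = False
                    for o in others:
                        ov = ev.overlap_s(o)
                        ref = (min(ev.duration_s, o.duration_s) if denominator == "shorter"
                               else max(ev.duration_s, o.duration_s))
                        if ov >= min_agreement * ref - 1e-12:
                            ok = True
                            break
                if ok:
                    n_agree += 1
            if n_agree >= min_channels - 1:
                ch = ev.channels if ev.channels else frozenset([lbl])
                confirmed.append(replace(ev, channels=ch))

    # transitive merge of overlapping confirmed events into union intervals
    confirmed.sort(key=lambda e: (e.onset_s, e.offset_s))
    merged: list[list[SpindleEvent]] = []
    cur: list[SpindleEvent] = []
    cur_end = -np.inf
    for ev in confirmed:
        if cur and ev.onset_s < cur_end:
            cur.append(ev)
            cur_end = max(cur_end, ev.offset_s)
        else:
            if cur:
                merged.append(cur)
            cur = [ev]
            cur_end = ev.offset_s
    if cur:
        merged.append(cur)

    out: list[SpindleEvent] = []
    for group in merged:
        best = max(group, key=lambda e: e.peak_norm_power)
        out.append(SpindleEvent(
            onset_s=min(e.onset_s for e in group),
            offset_s=max(e.offset_s for e in group),
            channels=frozenset().union(*(e.channels for e in group)),
            peak_norm_power=best.peak_norm_power,
            peak_freq_hz=best.peak_freq_hz,
            area=best.area,
            p2p_amp_uv=max(e.p2p_amp_uv for e in group),
            cls=best.cls or classify_event(best.peak_freq_hz),
        ))
    return out
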