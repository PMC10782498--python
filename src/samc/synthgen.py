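"""Seeded synthetic sleep-EEG generator with ground-truth spindle labels.

Emulates the features of stage-2/3 NREM scalp EEG that the detection
pipeline actually keys on: a 1/f (pink) broadband background, optional
mains hum and brief high-frequency muscle bursts, and waxing/waning
11–16 Hz spindle bursts of 0.5–2 s reaching at least 13 µV peak-to-peak.
Each spindle is a sinusoid under a Hanning envelope (the envelope gives
the characteristic waxing/waning morphology; a Gaussian envelope is
available as an option).  A configurable fraction of spindles is shared
across two or more channels with small per-channel onset jitter — the
substrate the cross-channel agreement rule needs.

Everything is driven by one integer seed: the same spec yields bitwise
identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .io_edf import Annotation, AnnotationSet, Recording, write_annotations, write_recording

__all__ = ["SynthSpec", "generate", "write_fixture", "pink_noise"]


@dataclass
class SynthSpec:
    """Parameters of one synthetic recording.

    Defaults describe a 10-minute, 6-channel, 200-Hz nap segment with
    3 spindles/min at 30–50 µV peak-to-peak over a 15-µV-RMS pink
    background, 80% of spindles appearing on at least two channels.
    """

    n_channels: int = 6
    duration_s: float = 600.0
    fs: float = 200.0
    background_rms_uv: float = 15.0
    spindle_rate_per_min: float = 3.0
    freq_range_hz: tuple[float, float] = (11.0, 16.0)
    dur_range_s: tuple[float, float] = (0.5, 2.0)
    amp_range_uv: tuple[float, float] = (30.0, 50.0)   # peak-to-peak
    channel_jitter_s: float = 0.05
    shared_fraction: float = 0.8
    line_noise_hz: float | None = None
    line_noise_amp_uv: float = 5.0
    artifact_rate_per_min: float = 0.0
    envelope: str = "hanning"                          # or "gaussian"
    channel_labels: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("n_channels, duration_s and fs must be positive")
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ValueError("shared_fraction must be in [0, 1]")
        if self.amp_range_uv[0] < 13.0:
            raise ValueError("spindle amplitude below the 13 µV minimum")
        if self.envelope not in {"hanning", "gaussian"}:
            raise ValueError(f"unknown envelope {self.envelope!r}")
        if self.channel_labels is not None and len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must equal n_channels")

    @property
    def labels(self) -> list[str]:
        if self.channel_labels is not None:
            return list(self.channel_labels)
        std = ["F3", "F4", "C3", "C4", "O1", "O2"]
        if self.n_channels <= len(std):
            return std[: self.n_channels]
        return std + [f"EEG{i}" for i in range(len(std), self.n_channels)]


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f noise via frequency-domain shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])   # power ∝ 1/f
    scale[0] = 0.0                          # no DC
    x = np.fft.irfft(spec * scale, n)
    return x / max(x.std(), 1e-12)


def _envelope(n: int, kind: str) -> np.ndarray:
    if kind == "hanning":
        return np.hanning(n)
    t = np.arange(n) - (n - 1) / 2.0
    sigma = n / 6.0                         # ±3σ inside the burst
    return np.exp(-(t ** 2) / (2 * sigma ** 2))


def _place_events(rng: np.random.Generator, n_events: int, duration_s: float,
                  max_dur: float, margin_s: float = 3.0, min_gap_s: float = 1.0,
                  ) -> list[float]:
    """Draw non-overlapping onsets (uniform, rejection-sampled)."""
    usable = duration_s - 2 * margin_s - max_dur
    if n_events * (max_dur + min_gap_s) > usable + max_dur:
        raise ValueError(
            f"cannot place {n_events} spindles of up to {max_dur} s in {duration_s} s")
    onsets: list[float] = []
    attempts = 0
    while len(onsets) < n_events:
        attempts += 1
        if attempts > 100_000:
            raise ValueError("event placement failed; lower the spindle rate")
        cand = margin_s + rng.uniform(0.0, usable)
        if all(abs(cand - o) >= max_dur + min_gap_s for o in onsets):
            onsets.append(cand)
    return sorted(onsets)


def generate(spec: SynthSpec) -> tuple[Recording, AnnotationSet]:
    """Synthesize one recording plus its exact ground-truth annotations.

    Each annotation records the true onset/duration; its ``channel`` field
    holds the |-joined labels the spindle was injected on, and its scorer
    is ``"truth"``.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    labels = spec.labels

    data = [spec.background_rms_uv * pink_noise(n, rng) for _ in range(spec.n_channels)]

    if spec.line_noise_hz:
        t = np.arange(n) / spec.fs
        for x in data:
            phase = rng.uniform(0, 2 * np.pi)
            x += spec.line_noise_amp_uv * np.sin(2 * np.pi * spec.line_noise_hz * t + phase)

    n_spindles = int(round(spec.spindle_rate_per_min * spec.duration_s / 60.0))
    onsets = _place_events(rng, n_spindles, spec.duration_s, max_dur=spec.dur_range_s[1])

    events: list[Annotation] = []
    n_shared = int(round(spec.shared_fraction * n_spindles))
    shared_flags = np.zeros(n_spindles, dtype=bool)
    shared_flags[:n_shared] = True
    rng.shuffle(shared_flags)

    for onset, shared in zip(onsets, shared_flags):
        f0 = rng.uniform(*spec.freq_range_hz)
        dur = rng.uniform(*spec.dur_range_s)
        p2p = rng.uniform(*spec.amp_range_uv)
        if shared and spec.n_channels >= 2:
            k = int(rng.integers(2, spec.n_channels + 1))
            chans = sorted(rng.choice(spec.n_channels, size=k, replace=False).tolist())
        else:
            chans = [int(rng.integers(0, spec.n_channels))]
        for ci in chans:
            jitter = rng.uniform(-spec.channel_jitter_s, spec.channel_jitter_s) if len(chans) > 1 else 0.0
            s = int(round((onset + jitter) * spec.fs))
            ln = int(round(dur * spec.fs))
            s = max(0, min(s, n - ln))
            tt = np.arange(ln) / spec.fs
            phase = rng.uniform(0, 2 * np.pi)
            burst = (p2p / 2.0) * _envelope(ln, spec.envelope) * np.sin(2 * np.pi * f0 * tt + phase)
            data[ci][s:s + ln] += burst
        events.append(Annotation(
            onset_s=onset, duration_s=dur, label="spindle", scorer="truth",
            channel="|".join(labels[c] for c in chans)))

    n_artifacts = int(round(spec.artifact_rate_per_min * spec.duration_s / 60.0))
    if n_artifacts:
        art_onsets = _place_events(rng, n_artifacts, spec.duration_s, max_dur=2.5)
        for onset in art_onsets:
            ln = int(round(0.5 * spec.fs))
            s = int(round(onset * spec.fs))
            tt = np.arange(ln) / spec.fs
            burst = 200.0 * np.hanning(ln) * np.sin(2 * np.pi * 80.0 * tt)
            for x in data:
                x[s:s + ln] += burst
            events.append(Annotation(onset_s=onset, duration_s=0.5, label="artifact",
                                     scorer="truth"))

    rec = Recording(labels, data, [spec.fs] * spec.n_channels)
    annset = AnnotationSet(sorted(events, key=lambda e: (e.onset_s, e.duration_s)),
                           source=f"synth(seed={spec.seed})")
    return rec, annset


def write_fixture(spec: SynthSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate and persist one fixture: EDF + annotation CSV + manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rec, anns = generate(spec)
    paths = {
        "edf": write_recording(rec, out_dir / "recording.edf"),
        "annotations": write_annotations(anns, out_dir / "annotations.csv"),
        "manifest": out_dir / "manifest.json",
    }
    manifest = asdict(spec)
    manifest["channel_labels"] = rec.channel_labels
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths
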