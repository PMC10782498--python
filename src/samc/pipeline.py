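"""End-to-end detection pipeline.

Stages, in order: read EDF → broadband bandpass → data-driven notch →
artifact-epoch masking → 11–16 Hz narrowband copy → Gabor-taper
convolution and power normalization per channel → single-channel candidate
extraction → cross-channel agreement → event CSV (and, when reference
annotations are supplied, the metric report).

The run is deterministic given config + input; every stage's parameters
land in the returned log dict.  Channels with different native sampling
rates are harmonized by polyphase resampling to the maximum rate before
the per-sample stages.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
from scipy import signal as _signal

from . import detect as _detect
from . import metrics as _metrics
from . import preprocess as _pre
from .config import DEFAULTS, ConfigError, load_config, merge_config
from .io_edf import AnnotationSet, Recording, read_annotations, read_recording, write_events
from .sde import convolve_bank, edge_mask, normalize_power
from .taper_bank import build_bank

__all__ = ["run", "detect_events", "harmonize_fs", "plot_detection"]

logger = logging.getLogger(__name__)


def harmonize_fs(rec: Recording) -> Recording:
    """Resample every channel to the maximum sampling rate in the recording."""
    target = max(rec.fs)
    if all(abs(f - target) < 1e-9 for f in rec.fs):
        return rec
    out = []
    for x, f in zip(rec.data, rec.fs):
        if abs(f - target) < 1e-9:
            out.append(x)
            continue
        frac = Fraction(target / f).limit_denominator(1000)
        out.append(_signal.resample_poly(x, frac.numerator, frac.denominator))
    n = min(len(x) for x in out)
    return Recording(list(rec.channel_labels), [x[:n] for x in out],
                     [target] * rec.n_channels, rec.start_time)


def detect_events(rec: Recording, cfg: Mapping[str, Any] | None = None,
                  ) -> tuple[list[_detect.SpindleEvent], dict[str, Any]]:
    """Run preprocessing → SDE → detection → cross-channel agreement.

    Returns the confirmed multi-channel events and a log dict with the
    effective config, notched frequencies, artifact fraction and
    per-channel candidate counts.
    """
    cfg = merge_config(DEFAULTS, cfg)
    log: dict[str, Any] = {"config": cfg, "stages": []}

    if rec.n_channels < cfg["samc"]["min_channels"]:
        raise ConfigError(
            f"samc.min_channels={cfg['samc']['min_channels']} requires at least that many "
            f"channels; recording has {rec.n_channels}")

    rec = harmonize_fs(rec)
    fs = rec.fs[0]
    n = len(rec.data[0])
    log["stages"].append({"stage": "harmonize", "fs": fs, "n_samples": n})

    bp = cfg["preprocess"]["bandpass"]
    rec = _pre.bandpass(rec, bp["lo"], bp["hi"])
    log["stages"].append({"stage": "bandpass", **bp})

    nc = cfg["preprocess"]["notch"]
    notched: list[float] = []
    if nc["enabled"]:
        rec, notched = _pre.notch_from_peaks(
            rec, search_band=(nc["search_lo"], nc["search_hi"]),
            threshold_ratio=nc["threshold_ratio"], q=nc["q"])
    log["stages"].append({"stage": "notch", "notched_hz": notched})

    ar = cfg["preprocess"]["artifact"]
    if ar["enabled"]:
        rec, keep = _pre.reject_artifact_epochs(rec, epoch_s=ar["epoch_s"], z_mult=ar["z_mult"])
    else:
        keep = np.ones(n, dtype=bool)
    log["stages"].append({"stage": "artifact", "fraction_kept": float(keep.mean())})

    tcfg = cfg["taper"]
    band_rec = _pre.spindle_band_filter(rec, tcfg["f_lo"], tcfg["f_hi"])
    bank = build_bank(fs, tcfg["f_lo"], tcfg["f_hi"], tcfg["f_step"],
                      tcfg["min_cycles"], tcfg["max_cycles"], tcfg["support_s"])
    keep = keep & edge_mask(n, bank)

    dcfg = cfg["detect"]
    per_channel: dict[str, list[_detect.SpindleEvent]] = {}
    for lbl, x, bx in zip(rec.channel_labels, rec.data, band_rec.data):
        sde = convolve_bank(x, bank, fs, channel=lbl, taper_norm=cfg["sde"]["taper_norm"])
        trace = normalize_power(sde, keep_mask=keep, collapse=cfg["sde"]["collapse"],
                                power=cfg["sde"]["power"],
                                norm_scope=cfg["sde"]["norm_scope"],
                                epoch_s=cfg["sde"]["epoch_s"])
        per_channel[lbl] = _detect.detect_channel(
            trace, bx, threshold=dcfg["threshold"], min_dur_s=dcfg["min_dur_s"],
            max_dur_s=dcfg["max_dur_s"], merge_gap_s=dcfg["merge_gap_s"],
            min_p2p_uv=dcfg["min_p2p_uv"],
            boundary_peak_frac=dcfg["boundary_peak_frac"],
            boundary_floor_frac=dcfg["boundary_floor_frac"],
            slow_fast_boundary_hz=dcfg["slow_fast_boundary_hz"])
    log["stages"].append({"stage": "detect",
                          "candidates": {k: len(v) for k, v in per_channel.items()}})

    scfg = cfg["samc"]
    events = _detect.samc_combine(per_channel, min_channels=scfg["min_channels"],
                                  min_agreement=scfg["min_agreement"],
                                  denominator=scfg["denominator"])
    log["stages"].append({"stage": "samc", "confirmed": len(events)})
    return events, log


def run(edf_path: str | Path, out_csv: str | Path, *,
        config_path: str | Path | None = None,
        overrides: Mapping[str, Any] | None = None,
        channels: Sequence[str] | None = None,
        ref_paths: Sequence[str | Path] = ()) -> dict[str, Any]:
    """Full pipeline on one EDF file; optionally score against references.

    When two reference annotation files are given they are combined with
    the expert-union rule before scoring; undurated marks are padded to
    the standard 1.6-s window first.  Returns the run log, which includes
    the metric report when references were supplied.
    """
    cfg = load_config(config_path, overrides)
    rec = read_recording(edf_path, channels=channels)
    events, log = detect_events(rec, cfg)
    write_events(events, out_csv)
    log["events_csv"] = str(out_csv)
    log["n_events"] = len(events)

    if ref_paths:
        mcfg = cfg["metrics"]
        refs = [read_annotations(p, label_filter="spindle") for p in ref_paths]
        refs = [_metrics.pad_undurated(r, mcfg["pad_pre_s"], mcfg["pad_post_s"]) for r in refs]
        ref = refs[0]
        for other in refs[1:]:
            ref = _metrics.union_experts(ref, other, mcfg["min_overlap_s"])
        report = _metrics.score_events(events, ref.events, mcfg["min_overlap_s"])
        log["metrics"] = report.as_dict()
    return log


def plot_detection(rec: Recording, trace_by_channel: Mapping[str, Any],
                   events: Sequence[_detect.SpindleEvent], window: tuple[float, float],
                   out_path: str | Path, refs: AnnotationSet | None = None):
    """Spectrogram-style view: normalized power heat strip per channel with
    detected event spans (and reference marks) overlaid.  Presentational
    only — nothing numeric is derived from the figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty plotting window")
    labels = list(trace_by_channel.keys())
    fig, axes = plt.subplots(len(labels) + 1, 1, sharex=True,
                             figsize=(10, 1.2 * len(labels) + 2.5))
    axes = np.atleast_1d(axes)
    for ax, lbl in zip(axes[:-1], labels):
        trace = trace_by_channel[lbl]
        fs = trace.fs
        s, e = int(t0 * fs), int(t1 * fs)
        ax.imshow(trace.norm_power[np.newaxis, s:e], aspect="auto", origin="lower",
                  extent=(t0, t1, 0, 1), cmap="magma", vmin=0, vmax=1)
        ax.set_ylabel(lbl, rotation=0, ha="right", va="center")
        ax.set_yticks([])
    ax = axes[-1]
    lbl0 = labels[0]
    fs0 = trace_by_channel[lbl0].fs
    s, e = int(t0 * fs0), int(t1 * fs0)
    tt = np.arange(s, e) / fs0
    ax.plot(tt, rec.channel(lbl0)[s:e], lw=0.5, color="steelblue")
    n_overlay = 0
    for ev in events:
        if ev.offset_s > t0 and ev.onset_s < t1:
            ax.axvspan(max(ev.onset_s, t0), min(ev.offset_s, t1), color="green", alpha=0.3)
            n_overlay += 1
    if refs is not None:
        for ann in refs:
            if ann.offset_s > t0 and ann.onset_s < t1:
                ax.plot([ann.onset_s], [0], marker="v", color="magenta", ms=8, clip_on=False)
    ax.set_xlim(t0, t1)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("µV")
    fig.suptitle(f"spindle detections ({n_overlay} in window)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return n_overlay
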