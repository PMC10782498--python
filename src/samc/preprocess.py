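"""Preprocessing stages: broadband bandpass, data-driven notch, artifact
rejection, and the 11–16 Hz spindle-band filter.

All filters are 4th-order Butterworth applied forward–backward
(zero-phase), so spindle onset/offset timing is preserved — the duration
rules downstream depend on that.  No stage changes sample count or
sampling rate.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy import signal

from .io_edf import Recording

__all__ = [
    "bandpass",
    "notch_from_peaks",
    "reject_artifact_epochs",
    "spindle_band_filter",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12


def _butter_band(lo: float, hi: float, fs: float, order: int = 4):
    nyq = fs / 2.0
    return signal.butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")


def _filtfilt(sos, x: np.ndarray) -> np.ndarray:
    return signal.sosfiltfilt(sos, x)


def bandpass(rec: Recording, lo: float = 0.2, hi: float = 200.0, order: int = 4) -> Recording:
    """Zero-phase Butterworth bandpass, per channel.

    If *hi* is at or above a channel's Nyquist frequency it is clipped to
    0.45 × fs for that channel (with a logged warning) instead of failing:
    the broadband stage is a guard, not a precision filter.
    """
    if lo >= hi:
        raise ValueError(f"bandpass requires lo < hi, got ({lo}, {hi})")
    out = []
    for lbl, x, fs in zip(rec.channel_labels, rec.data, rec.fs):
        hi_eff = hi
        if hi >= fs / 2.0:
            hi_eff = 0.45 * fs
            logger.warning("bandpass: channel %s fs=%g Hz, clipping hi %g -> %g Hz",
                           lbl, fs, hi, hi_eff)
        sos = _butter_band(lo, hi_eff, fs, order)
        out.append(_filtfilt(sos, x))
    return rec.copy_with(out)


def spindle_band_filter(rec: Recording, lo: float = 11.0, hi: float = 16.0,
                        order: int = 4) -> Recording:
    """Narrowband 11–16 Hz stage; feeds the minimum-amplitude criterion."""
    if lo >= hi:
        raise ValueError(f"band requires lo < hi, got ({lo}, {hi})")
    out = []
    for lbl, x, fs in zip(rec.channel_labels, rec.data, rec.fs):
        if hi >= fs / 2.0:
            raise ValueError(f"channel {lbl}: spindle band {hi} Hz >= Nyquist ({fs/2} Hz)")
        sos = _butter_band(lo, hi, fs, order)
        out.append(_filtfilt(sos, x))
    return rec.copy_with(out)


def find_spectral_peaks(x: np.ndarray, fs: float, search_band: tuple[float, float],
                        threshold_ratio: float = 10.0, neighborhood_hz: float = 2.0,
                        ) -> list[float]:
    """Locate narrowband contaminants (mains hum and the like) in one channel.

    Welch PSD bins inside *search_band* whose power exceeds
    ``threshold_ratio`` × the median power of their ±``neighborhood_hz``
    surroundings are flagged; adjacent flagged bins collapse to the
    strongest one.
    """
    nperseg = min(len(x), int(4 * fs))
    freqs, psd = signal.welch(x, fs=fs, nperseg=nperseg)
    lo, hi = search_band
    hi = min(hi, 0.49 * fs)
    if lo >= hi:
        return []
    band = (freqs >= lo) & (freqs <= hi)
    flagged = np.zeros(len(freqs), dtype=bool)
    for i in np.flatnonzero(band):
        nb = (np.abs(freqs - freqs[i]) <= neighborhood_hz) & (freqs != freqs[i])
        ref = np.median(psd[nb]) if nb.any() else 0.0
        if psd[i] > threshold_ratio * max(ref, _EPS):
            flagged[i] = True
    peaks: list[float] = []
    idx = np.flatnonzero(flagged)
    if idx.size == 0:
        return peaks
    # collapse contiguous runs of flagged bins to their strongest bin
    run = [idx[0]]
    for j in idx[1:]:
        if j == run[-1] + 1:
            run.append(j)
        else:
            peaks.append(float(freqs[run[np.argmax(psd[run])]]))
            run = [j]
    peaks.append(float(freqs[run[np.argmax(psd[run])]]))
    return peaks


def notch_from_peaks(rec: Recording, search_band: tuple[float, float] = (45.0, 65.0),
                     harmonics: int = 2, threshold_ratio: float = 10.0,
                     q: float = 30.0) -> tuple[Recording, list[float]]:
    """Notch out spectral peaks found in the data itself.

    The mains frequency is not assumed: each channel's Welch PSD is scanned
    inside *search_band* (and its harmonic images up to *harmonics*×) and
    any outlier bin is removed with an IIR notch (quality factor *q*,
    applied zero-phase).  Returns the filtered recording and the sorted
    list of notched frequencies; with no peak the data pass through
    untouched.
    """
    if rec.duration_s < 10.0:
        raise ValueError("notch_from_peaks needs at least 10 s of data")
    all_peaks: set[float] = set()
    per_channel_peaks: list[list[float]] = []
    for x, fs in zip(rec.data, rec.fs):
        found: list[float] = []
        for h in range(1, harmonics + 1):
            band = (search_band[0] * h, search_band[1] * h)
            if band[0] >= 0.49 * fs:
                break
            found.extend(find_spectral_peaks(x, fs, band, threshold_ratio))
        per_channel_peaks.append(found)
        all_peaks.update(round(f, 2) for f in found)
    out = []
    for x, fs, found in zip(rec.data, rec.fs, per_channel_peaks):
        y = x
        for f0 in found:
            b, a = signal.iirnotch(f0, q, fs=fs)
            y = signal.filtfilt(b, a, y)
        out.append(np.asarray(y, dtype=float))
    return rec.copy_with(out), sorted(all_peaks)


def reject_artifact_epochs(rec: Recording, epoch_s: float = 2.0, z_mult: float = 5.0,
                           emg_band: tuple[float, float] = (30.0, 100.0),
                           protect_band: tuple[float, float] = (11.0, 16.0),
                           ) -> tuple[Recording, np.ndarray]:
    """Flag epochs contaminated by muscle activity or gross amplitude.

    Per *epoch_s*-second epoch and channel, two statistics are computed:
    RMS of the high-frequency (30–100 Hz) component and the peak absolute
    amplitude of the signal with its 11–16 Hz component removed (movement
    artifacts are broadband, so they survive that subtraction — while a
    genuine spindle can never trip the amplitude criterion on its own).
    An epoch is artifactual when either statistic exceeds
    ``median + z_mult × 1.4826 × MAD`` across epochs on at least one
    channel — i.e. *z_mult* is a robust z-score threshold, with the MAD
    scaled to estimate a standard deviation (and an ε floor so a flat
    recording is kept in full).

    Returns the unmodified recording and a per-sample Boolean *keep*-mask
    (True = clean).  Artifactual samples are excluded from normalization
    statistics downstream and detections overlapping them are suppressed.

    All channels must share one sampling rate/length here; harmonize first.
    """
    if len(set(rec.fs)) != 1 or len({len(d) for d in rec.data}) != 1:
        raise ValueError("reject_artifact_epochs requires a uniform sampling rate; resample first")
    fs = rec.fs[0]
    n = len(rec.data[0])
    ep_len = int(round(epoch_s * fs))
    if n <= ep_len:
        raise ValueError("recording must be longer than one epoch")
    n_ep = n // ep_len

    bad = np.zeros(n_ep, dtype=bool)
    for x in rec.data:
        lo, hi = emg_band
        hi = min(hi, 0.45 * fs)
        if lo < hi:
            sos = _butter_band(lo, hi, fs)
            hf = _filtfilt(sos, x)
        else:
            hf = np.zeros_like(x)
        if protect_band is not None and protect_band[1] < 0.45 * fs:
            sos_p = _butter_band(*protect_band, fs)
            x_amp = x - _filtfilt(sos_p, x)
        else:
            x_amp = x
        ep = np.arange(n_ep * ep_len).reshape(n_ep, ep_len)
        rms = np.sqrt(np.mean(hf[ep] ** 2, axis=1))
        peak = np.max(np.abs(x_amp[ep]), axis=1)
        for stat in (rms, peak):
            med = np.median(stat)
            sigma = 1.4826 * np.median(np.abs(stat - med))  # robust SD estimate
            bad |= stat > med + z_mult * max(sigma, _EPS)

    keep = np.ones(n, dtype=bool)
    for i in np.flatnonzero(bad):
        keep[i * ep_len:(i + 1) * ep_len] = False
    return rec, keep
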