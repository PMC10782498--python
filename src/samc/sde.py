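"""Convolution-based spectral density estimation (SDE) and the
amplitude → power → normalized-power chain.

Each Gabor taper is convolved with the EEG channel, giving one complex
trace per frequency on the spindle grid.  Per sample, the magnitude m of
the convolution output is taken as the amplitude, p = √m as the power,
the frequencies are collapsed (max by default), and the collapsed trace
is min–max normalized over the artifact-free samples:

    norm_power = (p − min p) / (max p − min p)  ∈ [0, 1]

√ and min–max are both order-preserving, so norm_power is invariant under
a global gain on the raw signal — the downstream 0.5 threshold therefore
needs no amplitude calibration.

Note the unconventional power definition p = √m (the square *root* of the
convolution magnitude); a conventional p = m² is available via
``power="square"`` but the root form is the default behavior of the
method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .taper_bank import TaperBank

__all__ = ["SDEMatrix", "PowerTrace", "convolve_bank", "normalize_power", "DegenerateInputError"]


class DegenerateInputError(ValueError):
    """Raised when the power trace is constant and cannot be normalized."""


@dataclass
class SDEMatrix:
    """Complex (n_freqs × n_samples) convolution output for one channel."""

    values: np.ndarray  # complex, shape (n_freqs, n_samples)
    freqs: np.ndarray   # Hz
    fs: float
    channel: str = ""

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.freqs):
            raise ValueError("SDE rows must match frequency grid")
        if not np.all(np.isfinite(self.values.real)) or not np.all(np.isfinite(self.values.imag)):
            raise ValueError("SDE contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class PowerTrace:
    """Normalized spindle-band power per sample, with the argmax frequency.

    ``keep_mask`` marks samples whose statistics are trustworthy (clean of
    artifacts and of convolution edge effects); over those samples the
    trace spans exactly [0, 1].
    """

    norm_power: np.ndarray  # in [0, 1]
    peak_freq: np.ndarray   # Hz per sample
    fs: float
    keep_mask: np.ndarray   # bool per sample
    channel: str = ""

    def __post_init__(self) -> None:
        n = len(self.norm_power)
        if len(self.peak_freq) != n or len(self.keep_mask) != n:
            raise ValueError("trace arrays must share one length")


def convolve_bank(channel_signal: np.ndarray, bank: TaperBank, fs: float,
                  channel: str = "", method: str = "fft",
                  taper_norm: str = "amplitude") -> SDEMatrix:
    """Convolve one channel with every taper in the bank.

    Output is same-length, center-aligned, zero-padded at the edges.  The
    FFT path (default) matches direct time-domain convolution to ~1e-12
    relative error; ``method="direct"`` forces the O(N·K) path.

    ``taper_norm="amplitude"`` (default) divides each taper by the L1 norm
    of its envelope, so a unit sinusoid at any grid frequency elicits the
    same magnitude response from its own taper.  Without it, response
    scales with the Gaussian width S, which grows along the bank — a pure
    13-Hz tone would then peak at a *wider neighboring* taper rather than
    its own.  ``taper_norm="none"`` gives the raw convolution (detection
    is invariant to any single global scale either way, but not to a
    per-frequency one).
    """
    x = np.asarray(channel_signal, dtype=float).ravel()
    if abs(fs - bank.fs) > 1e-9:
        raise ValueError(f"signal fs {fs} Hz does not match bank fs {bank.fs} Hz")
    if len(x) <= bank.support_samples:
        raise ValueError(
            f"signal ({len(x)} samples) must be longer than the taper support "
            f"({bank.support_samples} samples)")
    if taper_norm not in {"amplitude", "none"}:
        raise ValueError(f"unknown taper_norm {taper_norm!r}")
    rows = []
    for tp in bank.tapers:
        coeffs = tp.coeffs
        if taper_norm == "amplitude":
            coeffs = coeffs / np.abs(coeffs).sum()
        if method == "fft":
            row = _signal.fftconvolve(x, coeffs, mode="same")
        elif method == "direct":
            row = np.convolve(x, coeffs, mode="same")
        else:
            raise ValueError(f"unknown convolution method {method!r}")
        rows.append(row)
    return SDEMatrix(values=np.vstack(rows), freqs=bank.freqs, fs=float(fs), channel=channel)


def edge_mask(n_samples: int, bank: TaperBank) -> np.ndarray:
    """False over the first/last half-support, where taper overlap is partial."""
    half = bank.support_samples // 2
    mask = np.ones(n_samples, dtype=bool)
    if half > 0:
        mask[:half] = False
        mask[-half:] = False
    return mask


def normalize_power(sde: SDEMatrix, keep_mask: np.ndarray | None = None,
                    collapse: str = "max", power: str = "root",
                    norm_scope: str = "recording", epoch_s: float = 30.0) -> PowerTrace:
    """Collapse the SDE over frequency and min–max normalize.

    m = |SDE| per frequency; p = √m (or m² with ``power="square"``);
    frequencies collapse per sample by max (or mean); the collapsed trace
    is normalized by the min/max computed over *kept* samples only, then
    clipped to [0, 1] (only excluded samples can fall outside).  The
    per-sample peak frequency is the argmax over the grid of p.

    ``norm_scope="recording"`` (default) uses one min/max for the whole
    channel; ``"epoch"`` renormalizes every *epoch_s*-second block
    independently (adaptive to slow drifts, at the cost of inflating
    spindle-free blocks).
    """
    n = sde.n_samples
    if keep_mask is None:
        keep_mask = np.ones(n, dtype=bool)
    keep_mask = np.asarray(keep_mask, dtype=bool)
    if len(keep_mask) != n:
        raise ValueError("keep_mask length must match the SDE")
    if keep_mask.sum() < 2:
        raise ValueError("need at least 2 kept samples to normalize")

    m = np.abs(sde.values)
    if power == "root":
        p = np.sqrt(m)
    elif power == "square":
        p = m ** 2
    else:
        raise ValueError(f"unknown power convention {power!r}")

    if collapse == "max":
        trace = p.max(axis=0)
    elif collapse == "mean":
        trace = p.mean(axis=0)
    else:
        raise ValueError(f"unknown collapse {collapse!r}")
    peak_freq = sde.freqs[np.argmax(p, axis=0)]

    if norm_scope == "recording":
        kept = trace[keep_mask]
        lo, hi = float(kept.min()), float(kept.max())
        if hi - lo <= 0:
            raise DegenerateInputError(
                "power trace is constant over kept samples; cannot min–max normalize")
        norm = np.clip((trace - lo) / (hi - lo), 0.0, 1.0)
    elif norm_scope == "epoch":
        ep = max(2, int(round(epoch_s * sde.fs)))
        norm = np.empty_like(trace)
        for s in range(0, n, ep):
            sl = slice(s, min(s + ep, n))
            block = trace[sl][keep_mask[sl]] if keep_mask[sl].any() else trace[sl]
            lo, hi = float(block.min()), float(block.max())
            if hi - lo <= 0:
                raise DegenerateInputError(f"constant power trace in epoch starting at sample {s}")
            norm[sl] = np.clip((trace[sl] - lo) / (hi - lo), 0.0, 1.0)
    else:
        raise ValueError(f"unknown norm_scope {norm_scope!r}")
    return PowerTrace(norm_power=norm, peak_freq=np.asarray(peak_freq, dtype=float),
                      fs=sde.fs, keep_mask=keep_mask, channel=sde.channel)
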