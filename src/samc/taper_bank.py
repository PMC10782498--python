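"""Gabor taper construction over the spindle frequency grid.

Each taper is a complex Gabor atom — a Gaussian envelope times a complex
exponential at center frequency f_k:

    g_k(t) = exp(-t² / (2 S²)) · exp(i 2π f_k t),      S = n_k / (2π f_k)

where n_k is the number of oscillation cycles inside one Gaussian standard
deviation.  The cycle counts across the bank are log10-spaced between a
minimum and a maximum, ascending with frequency, so that time resolution
is kept at the low (slow-spindle) end and frequency resolution at the high
(fast-spindle) end.  One taper is built per evaluated frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GaborTaper", "TaperBank", "cycle_vector", "make_taper", "build_bank"]


@dataclass(frozen=True)
class GaborTaper:
    """One complex Gabor atom on a symmetric time grid (peak 1 at t = 0)."""

    f_k: float          # center frequency, Hz
    n_k: float          # cycles per Gaussian SD, dimensionless
    S: float            # Gaussian SD, seconds
    t: np.ndarray       # time grid, seconds, symmetric about 0, odd length
    coeffs: np.ndarray  # complex taper values g_k(t)

    def __post_init__(self) -> None:
        if len(self.t) % 2 != 1:
            raise ValueError("taper support must have odd sample count")

    @property
    def support_s(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class TaperBank:
    """A family of Gabor tapers, one per frequency on the spindle grid."""

    tapers: tuple[GaborTaper, ...]
    freqs: np.ndarray   # Hz, strictly increasing
    n: np.ndarray       # cycle vector, aligned with freqs
    fs: float           # sampling rate the tapers were built for, Hz

    def __post_init__(self) -> None:
        if len(self.tapers) != len(self.freqs) or len(self.freqs) != len(self.n):
            raise ValueError("one taper and one cycle count per frequency")
        if len(self.freqs) == 0:
            raise ValueError("empty frequency grid")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    def __len__(self) -> int:
        return len(self.tapers)

    @property
    def support_samples(self) -> int:
        return max(len(tp.t) for tp in self.tapers)


def cycle_vector(n_freqs: int, min_cycles: float = 3.0, max_cycles: float = 10.0) -> np.ndarray:
    """Log10-spaced cycle counts from *min_cycles* to *max_cycles*.

    With ``n_freqs == 1`` the single value is *min_cycles* (the
    single-point logspace convention).
    """
    if n_freqs < 1:
        raise ValueError("n_freqs must be >= 1")
    if min_cycles <= 0 or max_cycles <= 0:
        raise ValueError("cycle counts must be positive")
    if min_cycles > max_cycles:
        raise ValueError("min_cycles must not exceed max_cycles")
    return np.logspace(np.log10(min_cycles), np.log10(max_cycles), n_freqs)


def make_taper(f_k: float, n_k: float, fs: float, support_s: float = 2.0) -> GaborTaper:
    """Build one Gabor taper.

    The support defaults to 2 s — the maximum spindle duration — sampled
    at 1/fs on a grid symmetric about zero (odd length, so the atom has an
    exact center sample).
    """
    if f_k >= fs / 2.0:
        raise ValueError(f"taper frequency {f_k} Hz >= Nyquist ({fs/2} Hz)")
    if f_k <= 0 or n_k <= 0:
        raise ValueError("frequency and cycle count must be positive")
    S = n_k / (2.0 * np.pi * f_k)
    half = int(round(support_s * fs / 2.0))
    t = np.arange(-half, half + 1) / fs
    coeffs = np.exp(-(t ** 2) / (2.0 * S ** 2)) * np.exp(1j * 2.0 * np.pi * f_k * t)
    return GaborTaper(f_k=float(f_k), n_k=float(n_k), S=float(S), t=t, coeffs=coeffs)


def build_bank(fs: float, f_lo: float = 11.0, f_hi: float = 16.0, f_step: float = 1.0,
               min_cycles: float = 3.0, max_cycles: float = 10.0,
               support_s: float = 2.0) -> TaperBank:
    """Build the spindle-band taper bank (default 11–16 Hz in 1-Hz steps).

    Cycle counts from :func:`cycle_vector` map ascending onto the grid:
    more cycles at higher frequency, which keeps the Gaussian SD (and hence
    the spectral main-lobe width) from collapsing at the fast end.
    """
    freqs = np.arange(f_lo, f_hi + 0.5 * f_step, f_step, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency grid")
    if freqs[-1] >= fs / 2.0:
        raise ValueError(f"grid top {freqs[-1]} Hz >= Nyquist ({fs/2} Hz)")
    n = cycle_vector(len(freqs), min_cycles, max_cycles)
    tapers = tuple(make_taper(f, c, fs, support_s) for f, c in zip(freqs, n))
    return TaperBank(tapers=tapers, freqs=freqs, n=n, fs=float(fs))
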