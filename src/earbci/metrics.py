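"""Spectral estimation, narrow-band SNR and the information transfer rate.

The narrow-band SNR of a stimulation frequency f compares the PSD value at
f to the mean PSD over the K neighboring bins (K/2 on each side)::

    SNR(f) = K * F(f) / sum_{k=1..K/2} [ F(f + k*df) + F(f - k*df) ]

with df the spectral resolution and K even (K = 4 by default).  The
information transfer rate of an M-class selection with accuracy P and
selection time T seconds is::

    ITR = ( log2 M + P log2 P + (1 - P) log2((1 - P)/(M - 1)) ) / T

reported in bits/min.  T includes the decision window plus a gaze-shift
interval (default 0.5 s) between selections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)


def psd(x: np.ndarray, rate: float, method: str = "periodogram") -> tuple[np.ndarray, np.ndarray]:
    """One-sided PSD of a signal (last axis); Parseval-consistent scaling.

    ``method`` is ``periodogram`` (boxcar, df = rate/n, used for narrow-band
    SNR) or ``welch`` (8 segments, Hann, for smooth spectra).
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] == 0:
        raise ValueError("empty signal")
    if method == "periodogram":
        freqs, F = sps.periodogram(x, fs=rate, window="boxcar", detrend=False, axis=-1)
    elif method == "welch":
        nper = max(8, x.shape[-1] // 8)
        freqs, F = sps.welch(x, fs=rate, nperseg=nper, axis=-1)
    else:
        raise ValueError(f"unknown PSD method {method!r}")
    return freqs, F


@dataclass
class SNRSpectrum:
    """Narrow-band SNR evaluated on every interior bin of a PSD."""

    freq_grid_hz: np.ndarray
    F: np.ndarray  # PSD, last axis = frequency
    K: int
    snr: np.ndarray  # same shape as F; NaN where K/2 neighbors are unavailable

    @classmethod
    def from_signal(cls, x: np.ndarray, rate: float, K: int = 4) -> "SNRSpectrum":
        freqs, F = psd(x, rate, method="periodogram")
        half = K // 2
        snr = np.full_like(F, np.nan)
        n = F.shape[-1]
        if n > K:
            idx = np.arange(half, n - half)
            neigh = np.zeros_like(F[..., idx])
            for k in range(1, half + 1):
                neigh = neigh + F[..., idx + k] + F[..., idx - k]
            with np.errstate(divide="ignore", invalid="ignore"):
                snr[..., idx] = K * F[..., idx] / neigh
        return cls(freqs, F, K, snr)


def narrowband_snr(spec: SNRSpectrum | tuple, f_hz: float, K: int = 4) -> float:
    """Narrow-band SNR at a stimulation frequency.

    Accepts an :class:`SNRSpectrum` or a ``(freq_grid, F)`` pair.  ``f_hz``
    is snapped to the nearest grid bin (the offset is logged).  For
    multi-channel spectra the per-channel SNRs are averaged.
    """
    if K < 2 or K % 2:
        raise ValueError(f"K must be even and >= 2, got {K}")
    if isinstance(spec, SNRSpectrum):
        freqs, F = spec.freq_grid_hz, spec.F
        K = spec.K
    else:
        freqs, F = spec
        F = np.asarray(F, dtype=float)
    bin_i = int(np.argmin(np.abs(freqs - f_hz)))
    offset = freqs[bin_i] - f_hz
    if abs(offset) > 1e-12:
        logger.info("narrowband_snr: %g Hz snapped to bin %g Hz (offset %+.4g Hz)", f_hz, freqs[bin_i], offset)
    half = K // 2
    if bin_i - half < 0 or bin_i + half >= len(freqs):
        raise ValueError(f"insufficient neighbor bins around f = {f_hz} Hz for K = {K}")
    neigh = sum(F[..., bin_i + k] + F[..., bin_i - k] for k in range(1, half + 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        val = K * F[..., bin_i] / neigh
    return float(np.mean(val))


@dataclass
class ITRResult:
    M: int
    P: float
    T_s: float  # total selection time incl. gaze shift
    bits_per_min: float
    below_chance: bool = False


def itr(M: int, P: float, T_s: float, gaze_shift_s: float = 0.5) -> ITRResult:
    """Information transfer rate in bits/min.

    ``T_s`` is the decision-window length; ``gaze_shift_s`` is added to it
    to form the total selection time.  P -> 0 and P -> 1 use the limit
    x*log2(x) -> 0.  Below-chance values are returned unclamped and flagged.
    """
    if M < 2:
        raise ValueError(f"M must be >= 2, got {M}")
    if not 0.0 <= P <= 1.0:
        raise ValueError(f"P must be in [0, 1], got {P}")
    T = T_s + gaze_shift_s
    if T <= 0:
        raise ValueError(f"total selection time must be positive, got {T}")

    def xlog2x(x: float) -> float:
        return 0.0 if x == 0.0 else x * np.log2(x)

    bits = np.log2(M) + xlog2x(P) + (0.0 if P == 1.0 else (1 - P) * np.log2((1 - P) / (M - 1)))
    bpm = 60.0 * bits / T
    below = P < 1.0 / M
    if below:
        logger.warning("ITR below chance (P=%g < 1/%d); returned unclamped", P, M)
    return ITRResult(M=M, P=P, T_s=T, bits_per_min=float(bpm), below_chance=below)
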