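"""Band-pass filtering, resampling and epoch/channel cleaning.

Filtering is a 4th-order Butterworth applied forward and backward
(zero phase).  Cleaning flags channels by peak-to-peak amplitude and
applies the epoch rule: an epoch is rejected when more than
``reject_threshold`` channels are bad (for a 10-channel montage the
default threshold of 4 rejects epochs with 5 or more bad channels),
otherwise bad channels are replaced by the mean of the good ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .containers import Recording, TrialSet

logger = logging.getLogger(__name__)


def bandpass_array(data: np.ndarray, rate: float, lo_hz: float, hi_hz: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    nyq = rate / 2.0
    if not 0 < lo_hz < hi_hz:
        raise ValueError(f"need 0 < lo < hi, got ({lo_hz}, {hi_hz})")
    if hi_hz >= nyq:
        raise ValueError(f"upper edge {hi_hz} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, data, axis=-1)


def bandpass(rec: Recording, lo_hz: float, hi_hz: float, order: int = 4) -> Recording:
    """Zero-phase band-pass of a continuous recording; shape and rate unchanged."""
    out = rec.copy()
    out.data = bandpass_array(rec.data, rec.rate, lo_hz, hi_hz, order=order)
    logger.info("bandpass %g-%g Hz (order %d) on %s @ %g Hz", lo_hz, hi_hz, order, rec.data.shape, rec.rate)
    return out


def resample(rec: Recording, target_rate: float) -> Recording:
    """Downsample with anti-aliasing (polyphase); no upsampling path."""
    if target_rate > rec.rate:
        raise ValueError(f"target rate {target_rate} exceeds recording rate {rec.rate}")
    if target_rate == rec.rate:
        return rec.copy()
    frac = math.gcd(int(round(target_rate * 1000)), int(round(rec.rate * 1000)))
    up = int(round(target_rate * 1000)) // frac
    down = int(round(rec.rate * 1000)) // frac
    data = sps.resample_poly(rec.data, up, down, axis=-1)
    out = Recording(data, target_rate, list(rec.channel_labels), dict(rec.montage_tags))
    logger.info("resampled %g -> %g Hz: %d -> %d samples", rec.rate, target_rate, rec.n_samples, out.n_samples)
    return out


def detect_bad_channels(epoch: np.ndarray, ptp_limit_uV: float, flat_limit_uV: float) -> list[int]:
    """Channels whose peak-to-peak exceeds the artifact limit or falls below the flat limit."""
    if ptp_limit_uV <= 0 or flat_limit_uV <= 0:
        raise ValueError("limits must be positive")
    ptp = np.ptp(epoch, axis=-1)
    return [int(i) for i in np.flatnonzero((ptp > ptp_limit_uV) | (ptp < flat_limit_uV))]


@dataclass
class CleaningReport:
    """Per-epoch cleaning decisions plus totals."""

    bad_channels: list[list[int]] = field(default_factory=list)
    actions: list[str] = field(default_factory=list)  # kept | interpolated | rejected

    @property
    def n_rejected(self) -> int:
        return sum(a == "rejected" for a in self.actions)

    @property
    def n_interpolated(self) -> int:
        return sum(a == "interpolated" for a in self.actions)

    def to_rows(self) -> list[dict]:
        return [
            {"epoch": i, "action": a, "bad_channels": ";".join(map(str, b))}
            for i, (a, b) in enumerate(zip(self.actions, self.bad_channels))
        ]


def clean_epochs(
    trials: TrialSet,
    ptp_limit_uV: float = 200.0,
    flat_limit_uV: float = 0.5,
    reject_threshold: int | None = None,
) -> tuple[TrialSet, CleaningReport]:
    """Apply the bad-channel / bad-epoch rule to an epoched set.

    ``reject_threshold`` is the number of bad channels tolerated; epochs with
    strictly more bad channels are dropped.  When not given it defaults to
    4 for a 10-channel montage and scales as ``ceil(0.4 * n_channels)``
    otherwise.
    """
    if reject_threshold is None:
        reject_threshold = math.ceil(0.4 * trials.n_channels)
        logger.info("reject_threshold defaulted to %d for %d channels", reject_threshold, trials.n_channels)
    report = CleaningReport()
    keep = []
    data = trials.data.copy()
    for i in range(trials.n_trials):
        bad = detect_bad_channels(data[i], ptp_limit_uV, flat_limit_uV)
        report.bad_channels.append(bad)
        if len(bad) > reject_threshold:
            report.actions.append("rejected")
            continue
        keep.append(i)
        if bad:
            good = np.setdiff1d(np.arange(trials.n_channels), bad)
            data[i, bad, :] = data[i, good, :].mean(axis=0)
            report.actions.append("interpolated")
        else:
            report.actions.append("kept")
    if not keep:
        logger.warning("clean_epochs: all %d epochs rejected", trials.n_trials)
    cleaned = TrialSet(
        data[keep],
        trials.rate,
        trials.labels[keep],
        trials.stimuli,
        list(trials.channel_labels),
        None if trials.blocks is None else trials.blocks[keep],
    )
    logger.info(
        "clean_epochs: %d kept, %d interpolated, %d rejected",
        len(keep) - report.n_interpolated,
        report.n_interpolated,
        report.n_rejected,
    )
    return cleaned, report
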