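"""Reading and writing recordings (EDF / CSV) and event tables.

EDF files are read through MNE's reader.  Writing uses a small built-in
EDF writer (16-bit, single data record, per-channel physical scaling) so
that round trips stay within one quantization step of the stored
physical/digital ranges.

The CSV dialect is one header row of channel labels, one row per sample,
comma-separated, with the sampling rate in a JSON sidecar
(``<path>.meta.json``) or passed explicitly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EventTable, Recording

logger = logging.getLogger(__name__)

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _fmt_float(v: float) -> str:
    # must fit the 8-char EDF field and parse back to a float
    for fmt in ("%.6g", "%.5g", "%.4g", "%.3g"):
        s = fmt % v
        if len(s) <= 8:
            return s
    return ("%.2g" % v)[:8]


def write_edf(rec: Recording, path) -> None:
    """Write a Recording as a minimal EDF file (one data record, 16-bit)."""
    if rec.n_channels == 0:
        raise ValueError("EDF requires at least one channel")
    ns = rec.n_channels
    labels = []
    for lab in rec.channel_labels:
        if len(lab) > 16:
            logger.warning("EDF label %r truncated to 16 characters", lab)
        labels.append(lab[:16])

    # per-channel symmetric physical range, re-parsed from the ASCII header
    # representation so the scaling used for encoding matches what a reader sees
    pmaxs, pmins = [], []
    for ch in range(ns):
        amp = float(np.max(np.abs(rec.data[ch]))) if rec.data.shape[1] else 0.0
        if amp == 0.0:
            amp = 1.0
        s = _fmt_float(amp)
        pmaxs.append(float(s))
        pmins.append(-float(s))

    header = b""
    header += _ascii("0", 8)
    header += _ascii("X", 80)
    header += _ascii("earbci", 80)
    header += _ascii("01.01.00", 8)
    header += _ascii("00.00.00", 8)
    header += _ascii(256 * (ns + 1), 8)
    header += _ascii("", 44)
    header += _ascii(1, 8)  # one data record holding the full signal
    header += _ascii(_fmt_float(rec.n_samples / rec.rate), 8)
    header += _ascii(ns, 4)

    for vals, width in (
        (labels, 16),
        (["" for _ in range(ns)], 80),
        (["uV"] * ns, 8),
        ([_fmt_float(p) for p in pmins], 8),
        ([_fmt_float(p) for p in pmaxs], 8),
        ([str(_EDF_DIG_MIN)] * ns, 8),
        ([str(_EDF_DIG_MAX)] * ns, 8),
        (["" for _ in range(ns)], 80),
        ([str(rec.n_samples)] * ns, 8),
        (["" for _ in range(ns)], 32),
    ):
        for v in vals:
            header += _ascii(v, width)

    body = bytearray()
    for ch in range(ns):
        scale = (pmaxs[ch] - pmins[ch]) / (_EDF_DIG_MAX - _EDF_DIG_MIN)
        dig = np.round(rec.data[ch] / scale).astype(np.int64)
        dig = np.clip(dig, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")
        body += dig.tobytes()

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(bytes(body))
    logger.info("wrote EDF %s: %d channels, %d samples @ %g Hz", path, ns, rec.n_samples, rec.rate)


def read_edf(path) -> Recording:
    """Read an EDF file via MNE; returns data in microvolts."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # MNE holds EEG in volts
    return Recording(data_uv, float(raw.info["sfreq"]), list(raw.ch_names))


def write_csv(rec: Recording, path) -> None:
    """Write CSV (samples as rows) plus a JSON sidecar with the rate."""
    df = pd.DataFrame(rec.data.T, columns=rec.channel_labels)
    df.to_csv(path, index=False, float_format="%.10g")
    meta = {"rate": rec.rate, "montage_tags": rec.montage_tags}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta))
    logger.info("wrote CSV %s (+sidecar): %s @ %g Hz", path, rec.data.shape, rec.rate)


def read_csv(path, rate: float | None = None) -> Recording:
    df = pd.read_csv(path)
    tags = {}
    sidecar = Path(str(path) + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        rate = rate if rate is not None else meta.get("rate")
        tags = meta.get("montage_tags", {})
    if rate is None:
        raise ValueError(f"sampling rate for {path} missing: no sidecar and no rate given")
    return Recording(df.to_numpy(dtype=float).T, float(rate), list(df.columns), tags)


def read_recording(path, format_name: str, rate: float | None = None) -> Recording:
    """Read a Recording from ``path``; ``format_name`` is 'edf' or 'csv'."""
    if format_name not in ("edf", "csv"):
        raise ValueError(f"unknown format {format_name!r}; expected 'edf' or 'csv'")
    if not Path(path).exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    return read_edf(path) if format_name == "edf" else read_csv(path, rate=rate)


def write_recording(rec: Recording, path, format_name: str) -> None:
    if format_name == "edf":
        write_edf(rec, path)
    elif format_name == "csv":
        write_csv(rec, path)
    else:
        raise ValueError(f"unknown format {format_name!r}; expected 'edf' or 'csv'")


def write_events(events: EventTable, path) -> None:
    pd.DataFrame(
        {
            "onset_s": events.onset_s,
            "class_index": events.class_index,
            "frequency_hz": events.frequency_hz,
            "phase_rad": events.phase_rad,
            "duration_s": events.duration_s,
        }
    ).to_csv(path, index=False)


def read_events(path) -> EventTable:
    df = pd.read_csv(path)
    need = {"onset_s", "class_index", "frequency_hz", "phase_rad", "duration_s"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"event table {path} missing columns {sorted(missing)}")
    return EventTable(
        df["onset_s"].to_numpy(),
        df["class_index"].to_numpy(),
        df["frequency_hz"].to_numpy(),
        df["phase_rad"].to_numpy(),
        df["duration_s"].to_numpy(),
    )
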