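"""YAML configuration with defaults, range validation and provenance logging.

Schema (all keys optional; omitted keys take the defaults below)::

    seed: int >= 0
    simulation:
      rate: Hz                 # SSVEP simulation rate
      trial_s: seconds
      n_blocks: int
      noise_rms_uV: float
      alpha_on: bool
    preprocessing:
      band_lo_hz / band_hi_hz: band-pass edges
      ptp_limit_uV: artifact peak-to-peak limit
      flat_limit_uV: flat-channel peak-to-peak limit
      reject_threshold: bad channels tolerated before epoch rejection
    decoder:
      method: trca | fbcca
      window_s: decision window
      n_harmonics: reference harmonics
      fb_subbands: filter-bank sub-band count
      ensemble: bool
    metrics:
      snr_k: even neighbor count of the narrow-band SNR
      gaze_shift_s: added to the decision window in the ITR denominator
    aad:
      lag_lo_ms / lag_hi_ms: forward TRF lag range
      backward_lag_hi_ms: backward-decoder EEG lag range upper edge
      env_rate: envelope / AAD EEG rate
      lambda_grid: ridge penalties searched by inner CV
"""

from __future__ import annotations

import copy
import logging

import yaml

logger = logging.getLogger(__name__)

DEFAULTS: dict = {
    "seed": 0,
    "simulation": {
        "rate": 250.0,
        "trial_s": 4.0,
        "n_blocks": 6,
        "noise_rms_uV": 15.0,
        "alpha_on": False,
    },
    "preprocessing": {
        "band_lo_hz": 0.5,
        "band_hi_hz": 90.0,
        "ptp_limit_uV": 200.0,
        "flat_limit_uV": 0.5,
        "reject_threshold": 4,
    },
    "decoder": {
        "method": "trca",
        "window_s": 4.0,
        "n_harmonics": 5,
        "fb_subbands": 5,
        "ensemble": True,
    },
    "metrics": {
        "snr_k": 4,
        "gaze_shift_s": 0.5,
    },
    "aad": {
        "lag_lo_ms": 0.0,
        "lag_hi_ms": 500.0,
        "backward_lag_hi_ms": 250.0,
        "env_rate": 128.0,
        "lambda_grid": [0.1, 1.0, 10.0],
    },
}

# key -> predicate over the resolved config; message names the key
_RANGE_CHECKS = {
    "seed": lambda c: c["seed"] >= 0,
    "simulation.rate": lambda c: c["simulation"]["rate"] > 0,
    "simulation.trial_s": lambda c: c["simulation"]["trial_s"] > 0,
    "simulation.n_blocks": lambda c: c["simulation"]["n_blocks"] >= 1,
    "simulation.noise_rms_uV": lambda c: c["simulation"]["noise_rms_uV"] >= 0,
    "preprocessing.band_lo_hz": lambda c: 0
    < c["preprocessing"]["band_lo_hz"]
    < c["preprocessing"]["band_hi_hz"],
    "preprocessing.ptp_limit_uV": lambda c: c["preprocessing"]["ptp_limit_uV"] > 0,
    "preprocessing.flat_limit_uV": lambda c: c["preprocessing"]["flat_limit_uV"] > 0,
    "preprocessing.reject_threshold": lambda c: c["preprocessing"]["reject_threshold"] >= 0,
    "decoder.method": lambda c: c["decoder"]["method"] in ("trca", "fbcca"),
    "decoder.window_s": lambda c: c["decoder"]["window_s"] > 0,
    "decoder.n_harmonics": lambda c: c["decoder"]["n_harmonics"] >= 1,
    "decoder.fb_subbands": lambda c: c["decoder"]["fb_subbands"] >= 1,
    # the narrow-band SNR sums K/2 neighbor bins on each side, so K must be even
    "metrics.snr_k": lambda c: c["metrics"]["snr_k"] >= 2 and c["metrics"]["snr_k"] % 2 == 0,
    "metrics.gaze_shift_s": lambda c: c["metrics"]["gaze_shift_s"] >= 0,
    "aad.lag_hi_ms": lambda c: c["aad"]["lag_hi_ms"] > c["aad"]["lag_lo_ms"],
    "aad.env_rate": lambda c: c["aad"]["env_rate"] > 0,
    "aad.lambda_grid": lambda c: len(c["aad"]["lambda_grid"]) >= 1
    and all(l >= 0 for l in c["aad"]["lambda_grid"]),
}


class ConfigError(ValueError):
    pass


def _merge(defaults: dict, user: dict, prefix: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        full = f"{prefix}{key}"
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {full!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"configuration section {full!r} must be a mapping")
            out[key] = _merge(defaults[key], val, prefix=full + ".")
        else:
            out[key] = val
    return out


def resolve_config(user: dict | None) -> dict:
    """Merge a user config over the defaults and range-check every value."""
    cfg = _merge(DEFAULTS, user or {})
    for key, check in _RANGE_CHECKS.items():
        if not check(cfg):
            raise ConfigError(f"configuration value out of range for key {key!r}")
    logger.info("resolved configuration: %s", cfg)
    return cfg


def load_config(path) -> dict:
    """Load a YAML config file; an empty file yields the all-defaults config."""
    with open(path) as fh:
        user = yaml.safe_load(fh)
    if user is None:
        user = {}
    if not isinstance(user, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return resolve_config(user)
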