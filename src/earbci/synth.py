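"""Synthetic EEG generators for SSVEP, resting alpha and cocktail-party trials.

These emulate the statistical structure the decoding analyses assume:

* SSVEP trials are harmonic series locked to the flicker (phase of harmonic
  h is h times the fundamental phase), mixed to the in-ear montage with a
  channel-group amplitude profile that emphasises the 2nd harmonic at in-ear
  sites, over 1/f background noise and an optional ~10 Hz alpha rhythm;
* resting-state recordings are 1/f noise plus an amplitude-modulated
  narrow-band alpha oscillation;
* cocktail-party trials are the sum of two ground-truth temporal response
  functions convolved with attended/ignored speech onset envelopes plus
  noise, with the ground truth returned for recovery tests.

All generators are deterministic in (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .aad import Envelope, TRFModel
from .containers import EventTable, Recording, StimulusSpec, TrialSet, default_montage_tags

logger = logging.getLogger(__name__)

IN_EAR_LABELS = ["L1", "L2", "L3", "L4", "L5", "R1", "R2", "R3", "R4", "R5"]

#: per-harmonic amplitude profile (µV) by montage group; in-ear sites show a
#: 2nd-harmonic emphasis (A2/A1 = 1.2) whereas occipital sites follow the
#: usual descending harmonic series (A2/A1 = 0.6)
HARMONIC_PROFILES = {
    "in_ear_left": (1.0, 1.2, 0.5),
    "in_ear_right": (1.0, 1.2, 0.5),
    "mastoid": (1.0, 1.2, 0.5),
    "occipital": (2.0, 1.2, 0.6),
    "other": (1.0, 0.6, 0.3),
}


def nine_class_table(trial_s: float = 4.0) -> list[StimulusSpec]:
    """9 targets, 8-12 Hz in 0.5 Hz steps, zero phase."""
    return [StimulusSpec(8.0 + 0.5 * i, 0.0, trial_s) for i in range(9)]


def forty_class_table(trial_s: float = 6.0) -> list[StimulusSpec]:
    """40-target joint frequency/phase grid: 8.0-15.8 Hz in 0.2 Hz steps with
    phases incremented by 0.35*pi per class (speller-grid convention)."""
    return [
        StimulusSpec(8.0 + 0.2 * i, (0.35 * np.pi * i) % (2 * np.pi), trial_s)
        for i in range(40)
    ]


@dataclass
class SSVEPSimConfig:
    class_table: list[StimulusSpec] = field(default_factory=nine_class_table)
    n_harmonics: int = 3
    harmonic_amplitudes: dict = field(default_factory=lambda: dict(HARMONIC_PROFILES))
    channel_labels: list[str] = field(default_factory=lambda: list(IN_EAR_LABELS))
    mixing: np.ndarray | None = None  # channel x harmonic gains; None -> profile-based
    one_over_f_exponent: float = 1.0
    noise_rms_uV: float = 15.0
    alpha_center_hz: float = 10.0
    alpha_rms_uV: float = 2.0
    alpha_on: bool = False
    rate: float = 250.0
    trial_s: float = 4.0
    n_blocks: int = 6
    amp_uV: float = 1.0  # global scale of the harmonic profile
    seed: int = 0

    def __post_init__(self):
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        top = max(s.frequency_hz for s in self.class_table) * self.n_harmonics
        if self.rate <= 2 * top:
            raise ValueError(
                f"rate {self.rate} Hz must exceed twice the highest harmonic ({top} Hz)"
            )
        if self.mixing is None:
            self.mixing = self._default_mixing()
        self.mixing = np.asarray(self.mixing, dtype=float)
        if self.mixing.shape != (len(self.channel_labels), self.n_harmonics):
            raise ValueError(
                f"mixing shape {self.mixing.shape} != (channels, harmonics) "
                f"({len(self.channel_labels)}, {self.n_harmonics})"
            )
        if np.any(np.array([self.noise_rms_uV, self.alpha_rms_uV, self.amp_uV]) < 0):
            raise ValueError("amplitudes must be nonnegative")

    def _default_mixing(self) -> np.ndarray:
        tags = default_montage_tags(self.channel_labels)
        n_ch = len(self.channel_labels)
        # fixed per-channel gain gradient gives the spatial structure that a
        # data-driven filter can exploit
        gain = np.linspace(0.7, 1.3, n_ch)
        M = np.zeros((n_ch, self.n_harmonics))
        for c, lab in enumerate(self.channel_labels):
            prof = self.harmonic_amplitudes.get(tags[lab], HARMONIC_PROFILES["other"])
            for h in range(self.n_harmonics):
                amp = prof[h] if h < len(prof) else prof[-1] * 0.5 ** (h - len(prof) + 1)
                M[c, h] = self.amp_uV * gain[c] * amp
        return M


def one_over_f_noise(
    rng: np.random.Generator, shape: tuple, rate: float, exponent: float = 1.0, rms: float = 1.0
) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent, scaled to a target RMS."""
    if rms == 0.0:
        return np.zeros(shape)
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n=n, axis=-1)
    cur = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    cur[cur == 0] = 1.0
    return x / cur * rms


def _alpha_burst(
    rng: np.random.Generator, n_ch: int, n: int, rate: float, center_hz: float, rms: float
) -> np.ndarray:
    """Amplitude-modulated narrow-band oscillation (filtered white noise)."""
    if rms == 0.0:
        return np.zeros((n_ch, n))
    sos = sps.butter(2, [center_hz - 1.0, center_hz + 1.0], btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal((n_ch, n)), axis=-1)
    cur = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    cur[cur == 0] = 1.0
    return x / cur * rms


def ssvep_waveform(spec: StimulusSpec, n_harmonics: int, rate: float, n_samples: int) -> np.ndarray:
    """Per-harmonic unit waveforms (harmonic x sample), phase of harmonic h = h*phi."""
    t = np.arange(n_samples) / rate
    return np.stack(
        [
            np.sin(2 * np.pi * (h + 1) * spec.frequency_hz * t + (h + 1) * spec.phase_rad)
            for h in range(n_harmonics)
        ]
    )


def simulate_ssvep_trials(cfg: SSVEPSimConfig) -> TrialSet:
    """Epoched SSVEP dataset: ``n_blocks`` blocks x one trial per class, trial
    order shuffled within each block, labels and block indices recorded."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.trial_s * cfg.rate))
    n_ch = len(cfg.channel_labels)
    n_cls = len(cfg.class_table)
    sigs = [ssvep_waveform(s, cfg.n_harmonics, cfg.rate, n) for s in cfg.class_table]
    data, labels, blocks = [], [], []
    for b in range(cfg.n_blocks):
        order = rng.permutation(n_cls)
        for c in order:
            trial = cfg.mixing @ sigs[c]
            trial = trial + one_over_f_noise(
                rng, (n_ch, n), cfg.rate, cfg.one_over_f_exponent, cfg.noise_rms_uV
            )
            if cfg.alpha_on:
                trial = trial + _alpha_burst(rng, n_ch, n, cfg.rate, cfg.alpha_center_hz, cfg.alpha_rms_uV)
            data.append(trial)
            labels.append(c)
            blocks.append(b)
    logger.info("simulate_ssvep_trials: %d classes x %d blocks @ %g Hz, %g s", n_cls, cfg.n_blocks, cfg.rate, cfg.trial_s)
    return TrialSet(
        np.stack(data), cfg.rate, np.array(labels), list(cfg.class_table), list(cfg.channel_labels), np.array(blocks)
    )


def simulate_ssvep_recording(cfg: SSVEPSimConfig, gap_s: float = 0.5) -> tuple[Recording, EventTable]:
    """Continuous form of :func:`simulate_ssvep_trials`: trials concatenated
    with silent (noise-only) gaps plus the matching event table."""
    trials = simulate_ssvep_trials(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    n_gap = int(round(gap_s * cfg.rate))
    chunks, onsets = [], []
    pos = 0
    for i in range(trials.n_trials):
        gap = one_over_f_noise(
            rng, (trials.n_channels, n_gap), cfg.rate, cfg.one_over_f_exponent, cfg.noise_rms_uV
        )
        chunks += [gap, trials.data[i]]
        pos += n_gap
        onsets.append(pos / cfg.rate)
        pos += trials.n_samples
    rec = Recording(np.concatenate(chunks, axis=1), cfg.rate, list(cfg.channel_labels))
    events = EventTable(
        np.array(onsets),
        trials.labels,
        np.array([cfg.class_table[c].frequency_hz for c in trials.labels]),
        np.array([cfg.class_table[c].phase_rad for c in trials.labels]),
        np.full(trials.n_trials, cfg.trial_s),
    )
    return rec, events


def simulate_alpha_rest(cfg: SSVEPSimConfig, duration_s: float) -> Recording:
    """Eyes-closed resting EEG: 1/f noise plus an alpha rhythm at the
    configured center frequency."""
    if not cfg.alpha_on:
        raise ValueError("alpha_on must be true for a resting-alpha simulation")
    rng = np.random.default_rng(cfg.seed)
    n = int(round(duration_s * cfg.rate))
    n_ch = len(cfg.channel_labels)
    data = one_over_f_noise(rng, (n_ch, n), cfg.rate, cfg.one_over_f_exponent, cfg.noise_rms_uV)
    data = data + _alpha_burst(rng, n_ch, n, cfg.rate, cfg.alpha_center_hz, cfg.alpha_rms_uV)
    return Recording(data, cfg.rate, list(cfg.channel_labels))


# ---------------------------------------------------------------------------
# cocktail-party simulation


def make_ground_truth_trf(
    peak_lags_ms: list[float],
    peak_amps: list[float],
    lag_range_ms: tuple[float, float] = (0.0, 400.0),
    n_channels: int = 10,
    rate: float = 128.0,
    width_ms: float = 25.0,
) -> TRFModel:
    """Ground-truth TRF: a sum of Gaussian bumps at the given lags and
    amplitudes, scaled per channel by a fixed gain gradient."""
    lo, hi = lag_range_ms
    for lag in peak_lags_ms:
        if not lo <= lag <= hi:
            raise ValueError(f"peak at {lag} ms outside lag range {lag_range_ms}")
    n_lags = int(round(hi * rate / 1000.0)) - int(round(lo * rate / 1000.0)) + 1
    times = (np.arange(n_lags) + int(round(lo * rate / 1000.0))) * 1000.0 / rate
    kernel = np.zeros(n_lags)
    for lag, amp in zip(peak_lags_ms, peak_amps):
        kernel += amp * np.exp(-0.5 * ((times - lag) / width_ms) ** 2)
    gains = np.linspace(0.6, 1.4, n_channels)
    return TRFModel(kernel[:, None] * gains[None, :], lag_range_ms, rate)


def _default_attended_trf(n_channels: int, rate: float) -> TRFModel:
    return make_ground_truth_trf([80.0, 180.0], [1.0, -0.6], (0.0, 400.0), n_channels, rate)


def _default_ignored_trf(n_channels: int, rate: float) -> TRFModel:
    # to-be-ignored stream is strongly filtered: one third of the attended gain
    return make_ground_truth_trf([80.0, 180.0], [1.0 / 3.0, -0.2], (0.0, 400.0), n_channels, rate)


@dataclass
class CocktailSimConfig:
    trial_s: float = 60.0
    env_rate: float = 128.0
    pulse_rate_hz: float = 4.0  # syllabic rate
    refractory_s: float = 0.1
    trf_attended: TRFModel | None = None
    trf_ignored: TRFModel | None = None
    noise_rms_uV: float = 1.0
    n_trials: int = 24
    n_channels: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.pulse_rate_hz < 0:
            raise ValueError("pulse_rate_hz must be nonnegative")
        if self.pulse_rate_hz >= self.env_rate / 2:
            raise ValueError("pulse rate must be below half the envelope rate")
        if self.pulse_rate_hz > 0 and 1.0 / self.pulse_rate_hz <= self.refractory_s:
            raise ValueError("pulse rate incompatible with the refractory period")
        if self.trf_attended is None:
            self.trf_attended = _default_attended_trf(self.n_channels, self.env_rate)
        if self.trf_ignored is None:
            self.trf_ignored = _default_ignored_trf(self.n_channels, self.env_rate)
        for trf in (self.trf_attended, self.trf_ignored):
            if trf.n_channels != self.n_channels:
                raise ValueError("TRF channel count must match n_channels")
            if abs(trf.rate - self.env_rate) > 1e-9:
                raise ValueError("TRF rate must equal env_rate")
        if self.trf_attended.lag_range_ms != self.trf_ignored.lag_range_ms:
            raise ValueError("attended and ignored TRFs must share one lag range")


def simulate_onset_envelope(cfg: CocktailSimConfig, rng: np.random.Generator | None = None) -> Envelope:
    """Sparse nonnegative pulse train at the syllabic rate.

    Inter-pulse intervals are a refractory period plus an exponential draw
    whose mean keeps the overall rate at ``pulse_rate_hz``; pulses are
    smoothed by a short Gaussian kernel and peak-normalized.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.trial_s * cfg.env_rate))
    env = np.zeros(n)
    if cfg.pulse_rate_hz == 0.0:
        return Envelope(env, cfg.env_rate)
    mean_gap = 1.0 / cfg.pulse_rate_hz - cfg.refractory_s
    t = 0.0
    while True:
        t += cfg.refractory_s + rng.exponential(mean_gap)
        if t >= cfg.trial_s:
            break
        env[int(t * cfg.env_rate)] += rng.uniform(0.5, 1.0)
    sigma = 0.02 * cfg.env_rate  # 20 ms smoothing
    half = int(np.ceil(4 * sigma))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    env = np.convolve(env, k, mode="same")
    peak = env.max()
    if peak > 0:
        env /= peak
    return Envelope(env, cfg.env_rate)


def _causal_conv(kernel: np.ndarray, s: np.ndarray) -> np.ndarray:
    return np.convolve(s, kernel)[: len(s)]


@dataclass
class CocktailTrial:
    """One simulated two-speaker trial with ground truth attached."""

    eeg: Recording
    env_A: Envelope
    env_B: Envelope
    attended_label: str  # which stream ('A' or 'B') was attended
    trf_attended: TRFModel
    trf_ignored: TRFModel

    @property
    def env_attended(self) -> Envelope:
        return self.env_A if self.attended_label == "A" else self.env_B

    @property
    def env_ignored(self) -> Envelope:
        return self.env_B if self.attended_label == "A" else self.env_A


def simulate_cocktail_trial(cfg: CocktailSimConfig, rng: np.random.Generator | None = None) -> CocktailTrial:
    """One cocktail-party trial: EEG = TRF_att * env_att + TRF_ign * env_ign + noise."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    env_A = simulate_onset_envelope(cfg, rng)
    env_B = simulate_onset_envelope(cfg, rng)
    attended = "A" if rng.random() < 0.5 else "B"
    env_att = env_A if attended == "A" else env_B
    env_ign = env_B if attended == "A" else env_A
    n = env_A.n_samples
    n_ch = cfg.n_channels
    data = np.zeros((n_ch, n))
    for c in range(n_ch):
        data[c] = _causal_conv(cfg.trf_attended.weights[:, c], env_att.values)
        data[c] += _causal_conv(cfg.trf_ignored.weights[:, c], env_ign.values)
    data += one_over_f_noise(rng, (n_ch, n), cfg.env_rate, 1.0, cfg.noise_rms_uV)
    labels = IN_EAR_LABELS[:n_ch] if n_ch <= 10 else [f"C{i+1}" for i in range(n_ch)]
    eeg = Recording(data, cfg.env_rate, labels)
    return CocktailTrial(eeg, env_A, env_B, attended, cfg.trf_attended, cfg.trf_ignored)


def simulate_cocktail_set(cfg: CocktailSimConfig) -> list[CocktailTrial]:
    """A full session of independent cocktail trials (one shared RNG stream)."""
    rng = np.random.default_rng(cfg.seed)
    out = [simulate_cocktail_trial(cfg, rng) for _ in range(cfg.n_trials)]
    logger.info("simulate_cocktail_set: %d trials of %g s @ %g Hz", cfg.n_trials, cfg.trial_s, cfg.env_rate)
    return out
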