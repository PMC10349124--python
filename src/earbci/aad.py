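"""Auditory attention decoding for two-speaker (cocktail-party) listening.

The EEG response x(t, n) at channel n is modeled as a convolution of the
speech onset envelope s(t) with a temporal response function (TRF)
w(tau, n) plus noise:

    x(t, n) = sum_tau w(tau, n) s(t - tau) + eps(t, n)

Forward modeling estimates w by ridge regression on a lagged stimulus
design; backward modeling reverses the relationship and reconstructs the
stimulus from lagged multichannel EEG.  Attention is decoded per trial by
comparing the Pearson correlation of the reconstructed envelope with the
two candidate stream envelopes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .containers import Recording

logger = logging.getLogger(__name__)


@dataclass
class Envelope:
    """A stimulus envelope sampled at ``rate`` (nonnegative for onset envelopes)."""

    values: np.ndarray
    rate: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


def _lag_samples(lag_range_ms: tuple[float, float], rate: float) -> np.ndarray:
    lo, hi = lag_range_ms
    if hi <= lo:
        raise ValueError(f"lag range must satisfy hi > lo, got {lag_range_ms}")
    return np.arange(int(round(lo * rate / 1000.0)), int(round(hi * rate / 1000.0)) + 1)


@dataclass
class TRFModel:
    """Forward model weights w(tau, n): lag x channel, on a 1/rate lag grid."""

    weights: np.ndarray  # lag x channel
    lag_range_ms: tuple[float, float]
    rate: float
    lam: float = 0.0
    residual_rms: np.ndarray | None = None

    def __post_init__(self):
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        expected = len(_lag_samples(self.lag_range_ms, self.rate))
        if self.weights.shape[0] != expected:
            raise ValueError(
                f"weights have {self.weights.shape[0]} lags; lag range implies {expected}"
            )
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("TRF weights must be finite")

    @property
    def lags(self) -> np.ndarray:
        return _lag_samples(self.lag_range_ms, self.rate)

    @property
    def lag_times_ms(self) -> np.ndarray:
        return self.lags * 1000.0 / self.rate

    @property
    def n_channels(self) -> int:
        return self.weights.shape[1]

    def predict(self, env: Envelope) -> np.ndarray:
        """Noiseless forward simulation: channel x sample convolution output."""
        n = env.n_samples
        out = np.zeros((self.n_channels, n))
        s = env.values
        for j, tau in enumerate(self.lags):
            seg = np.zeros(n)
            if tau >= 0:
                seg[tau:] = s[: n - tau] if tau else s
            else:
                seg[:tau] = s[-tau:]
            out += self.weights[j][:, None] * seg[None, :]
        return out


@dataclass
class BackwardDecoder:
    """Stimulus-reconstruction weights g(tau, n): lag x channel, EEG lags >= 0."""

    weights: np.ndarray
    lag_range_ms: tuple[float, float]
    rate: float
    lam: float
    kind: str  # attended | ignored

    def __post_init__(self):
        if self.kind not in ("attended", "ignored"):
            raise ValueError(f"kind must be 'attended' or 'ignored', got {self.kind!r}")
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))

    @property
    def lags(self) -> np.ndarray:
        return _lag_samples(self.lag_range_ms, self.rate)


# ---------------------------------------------------------------------------
# auditory spectrogram and onset envelope


@dataclass
class Spectrogram:
    """Sub-band power (band x time) from an auditory filterbank."""

    power: np.ndarray
    center_freqs_hz: np.ndarray
    rate: float  # frame rate of the time axis


def _erb_space(f_lo: float, f_hi: float, n: int) -> np.ndarray:
    """Center frequencies equally spaced on the ERB-number scale."""
    erb = lambda f: 21.4 * np.log10(1.0 + 0.00437 * f)
    erb_inv = lambda e: (10.0 ** (e / 21.4) - 1.0) / 0.00437
    return erb_inv(np.linspace(erb(f_lo), erb(f_hi), n))


def audio_to_spectrogram(
    waveform: np.ndarray,
    audio_rate: float,
    n_bands: int = 128,
    f_lo: float = 180.0,
    f_hi: float = 7246.0,
    env_rate: float = 128.0,
) -> Spectrogram:
    """Auditory spectrogram: ``n_bands`` band-pass channels with ERB-spaced
    centers from ``f_lo`` to ``f_hi`` Hz, per-band power smoothed and
    resampled to ``env_rate`` frames/s."""
    if audio_rate < 2 * f_hi:
        raise ValueError(f"audio rate {audio_rate} Hz too low for bands up to {f_hi} Hz")
    x = np.asarray(waveform, dtype=float).ravel()
    centers = _erb_space(f_lo, f_hi, n_bands)
    # band edges at geometric midpoints between neighboring centers
    edges = np.sqrt(centers[:-1] * centers[1:])
    lo_edges = np.concatenate([[centers[0] * centers[0] / edges[0]], edges])
    hi_edges = np.concatenate([edges, [centers[-1] * centers[-1] / edges[-1]]])
    n_frames = int(round(len(x) / audio_rate * env_rate))
    frames = np.zeros((n_bands, n_frames))
    sm = sps.butter(2, min(env_rate / 2.0, 30.0), btype="low", fs=audio_rate, output="sos")
    t_frames = np.arange(n_frames) / env_rate
    t_audio = np.arange(len(x)) / audio_rate
    for b in range(n_bands):
        sos = sps.butter(2, [lo_edges[b], hi_edges[b]], btype="bandpass", fs=audio_rate, output="sos")
        band = sps.sosfiltfilt(sos, x)
        power = sps.sosfiltfilt(sm, band**2)
        frames[b] = np.interp(t_frames, t_audio, np.maximum(power, 0.0))
    return Spectrogram(frames, centers, env_rate)


def extract_onset_envelope(spec: Spectrogram | np.ndarray, rate: float | None = None) -> Envelope:
    """Onset envelope: half-wave-rectified first difference of the broadband
    envelope (the across-band sum of sub-band amplitudes)."""
    if isinstance(spec, Spectrogram):
        broadband = np.sqrt(spec.power).sum(axis=0)
        rate = spec.rate
    else:
        if rate is None:
            raise ValueError("rate required when passing a broadband envelope array")
        broadband = np.asarray(spec, dtype=float).ravel()
    onset = np.maximum(np.diff(broadband, prepend=broadband[0]), 0.0)
    return Envelope(onset, rate)


# ---------------------------------------------------------------------------
# forward TRF


def _forward_design(s: np.ndarray, lags: np.ndarray) -> tuple[np.ndarray, slice]:
    """Lagged stimulus design; rows are the time points where every lag is valid."""
    n = len(s)
    t0, t1 = max(int(lags.max()), 0), n + min(int(lags.min()), 0)
    rows = slice(t0, t1)
    D = np.empty((t1 - t0, len(lags)))
    for j, tau in enumerate(lags):
        D[:, j] = s[t0 - tau : t1 - tau]
    return D, rows


def fit_forward_trf(
    s: Envelope,
    x: Recording,
    lag_range_ms: tuple[float, float] = (0.0, 500.0),
    lam: float = 0.0,
) -> TRFModel:
    """Ridge estimate of the forward TRF, all channels jointly.

    Solves ``w = (S'S + lam I)^-1 S' x_n`` per channel, with S the lagged
    stimulus design restricted to time points where the full lag span fits
    (no zero padding).  ``lam = 0`` is ordinary least squares.
    """
    if abs(s.rate - x.rate) > 1e-9:
        raise ValueError(f"envelope rate {s.rate} != EEG rate {x.rate}")
    if s.n_samples != x.n_samples:
        raise ValueError("envelope and EEG must have the same length")
    if not np.any(s.values):
        raise ValueError("degenerate design: stimulus envelope is identically zero")
    lags = _lag_samples(lag_range_ms, x.rate)
    if len(lags) >= s.n_samples:
        raise ValueError("recording shorter than the lag span")
    D, rows = _forward_design(s.values, lags)
    X = x.data[:, rows].T  # time x channel
    A = D.T @ D + lam * np.eye(D.shape[1])
    W = np.linalg.solve(A, D.T @ X)  # lag x channel
    resid = X - D @ W
    model = TRFModel(W, lag_range_ms, x.rate, lam, residual_rms=np.sqrt(np.mean(resid**2, axis=0)))
    logger.info("fit_forward_trf: %d lags x %d channels, lam=%g", W.shape[0], W.shape[1], lam)
    return model


# ---------------------------------------------------------------------------
# backward decoding


def _backward_design(x: np.ndarray, lags: np.ndarray) -> tuple[np.ndarray, slice]:
    """Lagged EEG design: column (tau, n) holds x[n, t + tau]."""
    n_ch, n = x.shape
    t1 = n - int(lags.max())
    rows = slice(0, t1)
    D = np.empty((t1, len(lags) * n_ch))
    for j, tau in enumerate(lags):
        D[:, j * n_ch : (j + 1) * n_ch] = x[:, tau : tau + t1].T
    return D, rows


class _BackwardStats:
    """Sufficient statistics of one trial for the backward normal equations.

    Holding D'D, D's, D'1 and the envelope moments lets training-set fits,
    inner cross-validation and held-out correlation scores be formed by
    adding/subtracting per-trial blocks instead of rebuilding lagged designs.
    """

    def __init__(self, x: np.ndarray, s: np.ndarray, lags: np.ndarray):
        D, rows = _backward_design(x, lags)
        s = s[rows]
        self.DtD = D.T @ D
        self.Dts = D.T @ s
        self.Dt1 = D.sum(axis=0)
        self.s_sum = float(s.sum())
        self.ss = float(s @ s)
        self.n = D.shape[0]

    def corr(self, g: np.ndarray) -> float:
        """Pearson correlation of the reconstruction D g with the envelope,
        computed from the stored moments."""
        num = g @ self.Dts - (g @ self.Dt1) * self.s_sum / self.n
        var_r = g @ self.DtD @ g - (g @ self.Dt1) ** 2 / self.n
        var_s = self.ss - self.s_sum**2 / self.n
        if var_r <= 0.0 or var_s <= 0.0:
            return 0.0
        return float(num / np.sqrt(var_r * var_s))


def _solve_backward(stats: list[_BackwardStats], lam: float) -> np.ndarray:
    DtD = sum(st.DtD for st in stats)
    Dts = sum(st.Dts for st in stats)
    return np.linalg.solve(DtD + lam * np.eye(len(Dts)), Dts)


def _select_lambda(stats: list[_BackwardStats], grid: list[float]) -> float:
    """Inner leave-one-trial-out selection of the ridge penalty."""
    if len(grid) == 1 or len(stats) < 2:
        return float(grid[0])
    scores = []
    for lv in grid:
        rs = [
            stats[i].corr(_solve_backward(stats[:i] + stats[i + 1 :], lv))
            for i in range(len(stats))
        ]
        scores.append(np.mean(rs))
    best = float(grid[int(np.argmax(scores))])
    logger.info("backward decoder: inner-CV selected lam=%g from %s", best, grid)
    return best


def fit_backward_decoder(
    trials: list[tuple[Recording, Envelope]],
    lag_range_ms: tuple[float, float] = (0.0, 250.0),
    lam: float | list[float] = 1.0,
    kind: str = "attended",
) -> BackwardDecoder:
    """Ridge regression of the stimulus envelope on lagged multichannel EEG.

    Normal equations are pooled over the training trials.  When ``lam`` is a
    grid of several penalties, the one maximizing mean held-out reconstruction
    correlation in an inner leave-one-trial-out loop is selected (a single
    training trial falls back to the smallest penalty).
    """
    if not trials:
        raise ValueError("at least one training trial required")
    rate = trials[0][0].rate
    n_ch = trials[0][0].n_channels
    for rec, env in trials:
        if rec.n_channels != n_ch:
            raise ValueError("inconsistent channel counts across trials")
        if abs(rec.rate - rate) > 1e-9 or abs(env.rate - rate) > 1e-9:
            raise ValueError("all trials and envelopes must share one rate")
    lags = _lag_samples(lag_range_ms, rate)
    stats = [_BackwardStats(rec.data, env.values, lags) for rec, env in trials]
    grid = [float(v) for v in np.atleast_1d(lam)]
    best_lam = _select_lambda(stats, grid)
    g = _solve_backward(stats, best_lam)
    return BackwardDecoder(g.reshape(len(lags), n_ch), lag_range_ms, rate, best_lam, kind)


def reconstruct_stimulus(dec: BackwardDecoder, x: Recording) -> Envelope:
    """Reconstruct the stimulus envelope from EEG; trailing samples inside the
    lag span are trimmed (no zero padding)."""
    if x.n_channels != dec.weights.shape[1]:
        raise ValueError(
            f"recording has {x.n_channels} channels, decoder expects {dec.weights.shape[1]}"
        )
    D, rows = _backward_design(x.data, dec.lags)
    logger.debug("reconstruct_stimulus: trimmed %d edge samples", x.n_samples - D.shape[0])
    return Envelope(D @ dec.weights.ravel(), x.rate)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b / (na * nb))


def classify_attention(
    dec_att: BackwardDecoder,
    dec_ign: BackwardDecoder,
    x: Recording,
    env_A: Envelope,
    env_B: Envelope,
) -> dict:
    """Decide which of two streams was attended for one trial.

    The attended decoder's reconstruction is correlated with both candidate
    envelopes and the larger correlation wins (ties go to A).  All four
    decoder x envelope correlations are returned for diagnostics.
    """
    rec_att = reconstruct_stimulus(dec_att, x).values
    rec_ign = reconstruct_stimulus(dec_ign, x).values
    n = len(rec_att)
    a, b = env_A.values[:n], env_B.values[:n]
    rec = {
        "r_att_on_A": _pearson(rec_att, a),
        "r_att_on_B": _pearson(rec_att, b),
        "r_ign_on_A": _pearson(rec_ign, a),
        "r_ign_on_B": _pearson(rec_ign, b),
    }
    tie = rec["r_att_on_A"] == rec["r_att_on_B"]
    rec["predicted_label"] = "A" if (tie or rec["r_att_on_A"] > rec["r_att_on_B"]) else "B"
    rec["tie"] = bool(tie)
    if tie:
        logger.info("classify_attention: tie, broken toward stream A")
    return rec


@dataclass
class AADResult:
    """Leave-one-out attention-decoding outcome over a trial set."""

    records: pd.DataFrame
    accuracy: float
    corr_diff: np.ndarray  # attended-decoder correlation, attended minus ignored stream
    t_stat: float
    p_value: float
    per_trial_lambda: list[float] = field(default_factory=list)


def loo_evaluate(
    trials: list,
    lag_range_ms: tuple[float, float] = (0.0, 250.0),
    lam: float | list[float] = 1.0,
) -> AADResult:
    """Leave-one-out evaluation: for each held-out trial both decoders are
    refitted on the remaining trials and the attention decision recorded.

    ``trials`` items need ``eeg``, ``env_A``, ``env_B`` and
    ``attended_label`` attributes (as produced by the cocktail simulator).
    The attended-minus-ignored correlation differences are tested against
    zero with a two-sided one-sample t-test.
    """
    if len(trials) < 3:
        raise ValueError(f"leave-one-out needs >= 3 trials, got {len(trials)}")
    rate = trials[0].eeg.rate
    n_ch = trials[0].eeg.n_channels
    lags = _lag_samples(lag_range_ms, rate)
    grid = [float(v) for v in np.atleast_1d(lam)]
    # per-trial sufficient statistics, computed once and re-pooled per fold
    att_stats = [_BackwardStats(t.eeg.data, t.env_attended.values, lags) for t in trials]
    ign_stats = [_BackwardStats(t.eeg.data, t.env_ignored.values, lags) for t in trials]
    rows = []
    diffs = []
    lams = []
    for i, held in enumerate(trials):
        rest_att = att_stats[:i] + att_stats[i + 1 :]
        rest_ign = ign_stats[:i] + ign_stats[i + 1 :]
        best_lam = _select_lambda(rest_att, grid)
        dec_att = BackwardDecoder(
            _solve_backward(rest_att, best_lam).reshape(len(lags), n_ch),
            lag_range_ms, rate, best_lam, "attended",
        )
        dec_ign = BackwardDecoder(
            _solve_backward(rest_ign, best_lam).reshape(len(lags), n_ch),
            lag_range_ms, rate, best_lam, "ignored",
        )
        rec = classify_attention(dec_att, dec_ign, held.eeg, held.env_A, held.env_B)
        rec["true_label"] = held.attended_label
        rec["trial"] = i
        rows.append(rec)
        lams.append(best_lam)
        r_att = rec["r_att_on_A"] if held.attended_label == "A" else rec["r_att_on_B"]
        r_ign = rec["r_att_on_B"] if held.attended_label == "A" else rec["r_att_on_A"]
        diffs.append(r_att - r_ign)
    df = pd.DataFrame(rows)
    acc = float((df["predicted_label"] == df["true_label"]).mean())
    diffs = np.asarray(diffs)
    t_stat, p = stats.ttest_1samp(diffs, 0.0)
    logger.info("loo_evaluate: accuracy %.3f over %d trials, corr-diff t=%.2f p=%.2g", acc, len(trials), t_stat, p)
    return AADResult(df, acc, diffs, float(t_stat), float(p), lams)
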