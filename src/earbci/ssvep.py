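"""SSVEP target identification.

Two decoders share one decision rule — the class whose correlation
coefficient rho^(f) between the spatially filtered test trial and the
class template is largest wins:

* **TRCA** (calibrated): per class, the spatial filter maximizes inter-trial
  covariance of the training trials (generalized eigenproblem S w = lambda
  Q w with S the cross-trial and Q the within-trial covariance); the
  template is the trial average.  In ensemble mode all class filters are
  stacked and shared at test time.
* **FBCCA** (calibration-free): the canonical correlation between the trial
  and a sine/cosine harmonic reference of each candidate frequency,
  computed per filter-bank sub-band m and combined as
  ``sum_m a(m) * rho_m**2`` with ``a(m) = m**-1.25 + 0.25``.

Ties are broken toward the lowest class index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .containers import StimulusSpec, TrialSet
from .preprocess import bandpass_array

logger = logging.getLogger(__name__)


@dataclass
class FilterBankSpec:
    """Sub-band definitions and combination weights of a filter bank."""

    band_edges_hz: list[tuple[float, float]]
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.band_edges_hz) < 1:
            raise ValueError("need at least one sub-band")
        if len(self.weights) != len(self.band_edges_hz):
            raise ValueError("one weight per sub-band required")
        if np.any(self.weights <= 0):
            raise ValueError("sub-band weights must be positive")
        for lo, hi in self.band_edges_hz:
            if not 0 < lo < hi:
                raise ValueError(f"invalid sub-band ({lo}, {hi})")

    @property
    def n_subbands(self) -> int:
        return len(self.band_edges_hz)

    @classmethod
    def default(cls, n_subbands: int = 5, lo_step_hz: float = 8.0, hi_hz: float = 88.0) -> "FilterBankSpec":
        """Speller-literature constants: sub-band m spans (8*m, 88) Hz and is
        weighted a(m) = m**-1.25 + 0.25."""
        m = np.arange(1, n_subbands + 1)
        return cls([(lo_step_hz * mm, hi_hz) for mm in m], m ** (-1.25) + 0.25)

    def filter_trial(self, X: np.ndarray, rate: float) -> list[np.ndarray]:
        bands = []
        for lo, hi in self.band_edges_hz:
            hi_eff = min(hi, rate / 2 * 0.99)
            bands.append(bandpass_array(X, rate, lo, hi_eff))
        return bands


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two (flattened) signals; 0 on zero variance."""
    a = np.ravel(a) - np.mean(a)
    b = np.ravel(b) - np.mean(b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        logger.debug("pearson: zero-variance input, correlation set to 0")
        return 0.0
    return float(a @ b / (na * nb))


# ---------------------------------------------------------------------------
# TRCA


def _trca_filter(trials: np.ndarray, reg: float = 1e-8) -> np.ndarray:
    """Principal generalized eigenvector of S w = lambda Q w for one class.

    ``trials`` is trial x channel x sample; channels are mean-removed per
    trial.  S sums x_j1 x_j2' over ordered pairs j1 != j2, Q sums x_j x_j'.
    """
    X = trials - trials.mean(axis=-1, keepdims=True)
    total = X.sum(axis=0)  # channel x sample
    Q = np.einsum("jcs,jds->cd", X, X)
    S = total @ total.T - Q
    S = (S + S.T) / 2.0
    Q = (Q + Q.T) / 2.0
    try:
        _, vecs = sla.eigh(S, Q)
    except (sla.LinAlgError, ValueError):
        jitter = reg * np.trace(Q) / Q.shape[0]
        logger.info("TRCA: singular Q, ridge jitter %g added", jitter)
        _, vecs = sla.eigh(S, Q + jitter * np.eye(Q.shape[0]))
    w = vecs[:, -1]
    return w / np.linalg.norm(w)


@dataclass
class TRCAModel:
    """Per-class spatial filters and trial-averaged templates."""

    filters: np.ndarray  # band x class x channel
    templates: np.ndarray  # band x class x channel x sample
    ensemble: bool
    filter_bank: FilterBankSpec | None
    class_table: list[StimulusSpec]
    rate: float

    @property
    def n_classes(self) -> int:
        return self.filters.shape[1]


def fit_trca(
    train: TrialSet,
    filter_bank: FilterBankSpec | None = None,
    ensemble: bool = True,
) -> TRCAModel:
    """Fit TRCA filters and templates from epoched training data."""
    n_cls = train.n_classes
    counts = np.bincount(train.labels, minlength=n_cls)
    if np.any(counts < 2):
        raise ValueError(
            f"TRCA needs >= 2 training trials per class; counts {counts.tolist()}"
        )
    if filter_bank is None:
        band_data = [train.data]
    else:
        # bandpass_array filters along the last axis, broadcasting over trials
        band_data = filter_bank.filter_trial(train.data, train.rate)
    filters = np.empty((len(band_data), n_cls, train.n_channels))
    templates = np.empty((len(band_data), n_cls, train.n_channels, train.n_samples))
    for b, data in enumerate(band_data):
        for c in range(n_cls):
            cls_trials = data[train.labels == c]
            filters[b, c] = _trca_filter(cls_trials)
            templates[b, c] = cls_trials.mean(axis=0)
    logger.info(
        "fit_trca: %d classes, %d sub-band(s), ensemble=%s", n_cls, len(band_data), ensemble
    )
    return TRCAModel(filters, templates, ensemble, filter_bank, list(train.stimuli), train.rate)


def classify_trca(model: TRCAModel, X: np.ndarray) -> tuple[int, np.ndarray]:
    """Classify one trial (channel x sample); returns (class, rho per class).

    Per sub-band the correlation between the filtered trial and the filtered
    template is computed (all class filters stacked in ensemble mode);
    sub-band correlations are combined with the filter-bank weights.
    """
    if X.shape[0] != model.filters.shape[2]:
        raise ValueError("trial channel count does not match the model")
    if model.filter_bank is None:
        bands = [X]
        weights = np.ones(1)
    else:
        bands = model.filter_bank.filter_trial(X, model.rate)
        weights = model.filter_bank.weights
    n_cls = model.n_classes
    rho = np.zeros(n_cls)
    for b, Xb in enumerate(bands):
        for c in range(n_cls):
            if model.ensemble:
                W = model.filters[b].T  # channel x n_cls stack
            else:
                W = model.filters[b, c][:, None]
            rho[c] += weights[b] * pearson(W.T @ Xb, W.T @ model.templates[b, c])
    cls = int(np.argmax(rho))  # argmax takes the lowest index on ties
    return cls, rho


# ---------------------------------------------------------------------------
# CCA / FBCCA


def make_reference(spec: StimulusSpec, n_harmonics: int, rate: float, n_samples: int) -> np.ndarray:
    """Sine/cosine harmonic reference Y_f: 2*n_harmonics rows x n_samples.

    Row pairs are sin/cos at h*f Hz with phase h*phi, h = 1..n_harmonics.
    """
    if n_harmonics * spec.frequency_hz >= rate / 2:
        raise ValueError(
            f"harmonic {n_harmonics}x{spec.frequency_hz} Hz at or above Nyquist ({rate / 2} Hz)"
        )
    t = np.arange(n_samples) / rate
    rows = []
    for h in range(1, n_harmonics + 1):
        arg = 2 * np.pi * h * spec.frequency_hz * t + h * spec.phase_rad
        rows += [np.sin(arg), np.cos(arg)]
    return np.stack(rows)


def _orth_basis(A: np.ndarray, tol_factor: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the row space of A after row-centering."""
    Ac = A - A.mean(axis=1, keepdims=True)
    U, s, _ = np.linalg.svd(Ac.T, full_matrices=False)
    if s.size == 0 or s[0] == 0.0:
        return U[:, :0]
    rank = int(np.sum(s > tol_factor * s[0]))
    if rank < A.shape[0]:
        logger.debug("cca_corr: rank-deficient block (%d < %d), truncated", rank, A.shape[0])
    return U[:, :rank]


def cca_corr(X: np.ndarray, Y: np.ndarray) -> float:
    """Leading canonical correlation between the row spaces of X and Y.

    Computed via orthonormal bases (QR/SVD route): the largest singular
    value of Qx' Qy; rank-deficient blocks are truncated.  Returns a value
    in [0, 1].
    """
    Qx, Qy = _orth_basis(np.atleast_2d(X)), _orth_basis(np.atleast_2d(Y))
    if Qx.shape[1] == 0 or Qy.shape[1] == 0:
        return 0.0
    s = np.linalg.svd(Qx.T @ Qy, compute_uv=False)
    return float(np.clip(s[0], 0.0, 1.0))


def classify_fbcca(
    X: np.ndarray,
    class_table: list[StimulusSpec],
    rate: float,
    fb: FilterBankSpec | None = None,
    n_harmonics: int = 5,
) -> tuple[int, np.ndarray]:
    """Calibration-free classification of one trial against a class table.

    score_f = sum_m a(m) * rho_{f,m}^2 with rho the leading canonical
    correlation on the m-th sub-band; returns (argmax class, scores).
    """
    if fb is None:
        fb = FilterBankSpec.default()
    n_samples = X.shape[-1]
    refs = [make_reference(s, n_harmonics, rate, n_samples) for s in class_table]
    bands = fb.filter_trial(X, rate)
    scores = np.zeros(len(class_table))
    for m, Xm in enumerate(bands):
        for f, Y in enumerate(refs):
            rho = cca_corr(Xm, Y)
            scores[f] += fb.weights[m] * rho**2
    cls = int(np.argmax(scores))
    return cls, scores


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVResult:
    fold_accuracy: list[float]
    accuracy: float
    predictions: np.ndarray
    labels: np.ndarray
    folds: np.ndarray = field(default_factory=lambda: np.array([]))


def cross_validate(
    trials: TrialSet,
    method: str = "trca",
    n_train_blocks: int | None = None,
    filter_bank: FilterBankSpec | None = None,
    n_harmonics: int = 5,
    ensemble: bool = True,
    rng: np.random.Generator | None = None,
) -> CVResult:
    """Leave-one-block-out evaluation of a decoder on an epoched set.

    Each fold tests one block; the model trains on the remaining blocks
    (subsampled to ``n_train_blocks`` without replacement when given).
    FBCCA ignores the training data but is scored on the same folds.
    """
    if trials.blocks is None:
        raise ValueError("cross_validate requires block labels on the TrialSet")
    if method not in ("trca", "fbcca"):
        raise ValueError(f"unknown method {method!r}")
    blocks = np.unique(trials.blocks)
    if len(blocks) < 2:
        raise ValueError("leave-one-block-out needs >= 2 blocks")
    if n_train_blocks is not None and n_train_blocks > len(blocks) - 1:
        raise ValueError(
            f"n_train_blocks={n_train_blocks} but only {len(blocks) - 1} blocks available per fold"
        )
    if rng is None:
        rng = np.random.default_rng(0)
    if method == "trca" and filter_bank is None:
        filter_bank = FilterBankSpec.default()
    preds = np.full(trials.n_trials, -1)
    fold_acc = []
    for b in blocks:
        test_idx = np.flatnonzero(trials.blocks == b)
        train_mask = trials.blocks != b
        if n_train_blocks is not None:
            chosen = rng.choice(np.setdiff1d(blocks, [b]), size=n_train_blocks, replace=False)
            train_mask = np.isin(trials.blocks, chosen)
        if method == "trca":
            model = fit_trca(trials.select(train_mask), filter_bank, ensemble)
            for i in test_idx:
                preds[i] = classify_trca(model, trials.data[i])[0]
        else:
            for i in test_idx:
                preds[i] = classify_fbcca(
                    trials.data[i], trials.stimuli, trials.rate, filter_bank, n_harmonics
                )[0]
        fold_acc.append(float(np.mean(preds[test_idx] == trials.labels[test_idx])))
    acc = float(np.mean(preds == trials.labels))
    logger.info("cross_validate[%s]: %d folds, mean accuracy %.3f", method, len(blocks), acc)
    return CVResult(fold_acc, acc, preds, trials.labels.copy(), trials.blocks.copy())
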