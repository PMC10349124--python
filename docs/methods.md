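# Methods

## Signal model and conventions

All signals are held in microvolts, channel × sample, with 0-based sample
indices, time 0 at the first sample and half-open epoch windows
`[round(onset·rate), round(onset·rate) + round(window·rate))`. Event onsets
are rounded to the nearest sample rather than truncated, which avoids a
systematic half-sample bias. No re-referencing is applied: the montage is
assumed to come from the amplifier with its own common reference, and any
re-reference would be a user-side transform of the `Recording` matrix.

EDF files are read through MNE; writing uses a built-in minimal EDF writer
(single data record, 16-bit, per-channel symmetric physical range re-parsed
from its ASCII header representation so that encoding and decoding use
exactly the same scale). Round-trip error is therefore bounded by one
quantization step of the stored physical/digital ranges. The CSV dialect is
one header row of channel labels, one row per sample, with the rate in a
JSON sidecar.

## Preprocessing

Band-pass filtering is a 4th-order Butterworth applied forward–backward
(`sosfiltfilt`), i.e. zero-phase, with the band edges as parameters
(0.5–90 Hz for SSVEP work, 2–8 Hz as the anti-aliasing band for AAD).
Filtering is applied to continuous data before epoching so filter edge
artifacts fall outside the analysis windows. Resampling is polyphase with
built-in anti-aliasing; only downsampling is supported (250 Hz for SSVEP,
128 Hz for AAD).

Epoch cleaning uses a peak-to-peak rule per channel: a channel is invalid
when its peak-to-peak amplitude exceeds `ptp_limit_uV` (default 200 µV,
artifact) or falls below `flat_limit_uV` (default 0.5 µV, flat/disconnected).
An epoch with more than `reject_threshold` invalid channels is rejected;
otherwise each invalid channel is replaced by the mean of the valid channels
of that epoch. The threshold defaults to 4 on a 10-channel montage ("more
than 4 of 10") and scales as `ceil(0.4·n_channels)` otherwise. Mean-of-good
interpolation was chosen because spline interpolation over sensor positions
is undefined for an in-ear montage without 3-D coordinates; it keeps the
interpolated channel inside the convex hull of the good channels at every
sample.

## SSVEP decoding

**TRCA.** For each class, trials are channel-mean-removed and the spatial
filter w solves `S w = λ Q w`, where `S = Σ_{j1≠j2} x_{j1} x_{j2}ᵀ` (sum over
ordered trial pairs) and `Q = Σ_j x_j x_jᵀ`. `S` is computed as
`(Σ_j x_j)(Σ_j x_j)ᵀ − Q`. If the symmetric-definite solver fails on a
degenerate `Q`, a jitter of `1e-8 · trace(Q)/n` is added to the diagonal and
the solve retried (deterministic behavior on rank-deficient fixtures). The
class template is the arithmetic mean of its training trials. Default
operation is *ensemble* TRCA with a 5-sub-band filter bank: at test time all
class filters of a sub-band are stacked, and the class score is the
filter-bank-weighted sum of Pearson correlations between the stacked-filtered
trial and template.

**FBCCA.** Sub-band m spans (8·m, 88) Hz; weights `a(m) = m^−1.25 + 0.25`;
5 harmonics in the sine/cosine reference with the phase of harmonic h equal
to h·φ. These constants are the standard speller-literature filter-bank
design; all are configurable. The per-class score is `Σ_m a(m)·ρ_m²`. The
canonical correlation is computed from orthonormal bases of the row-centered
signal blocks (SVD route, rank-truncated at 1e-10 of the leading singular
value), which is numerically equivalent to the covariance formulation but
stable on rank-deficient inputs.

Ties in every argmax are broken toward the lowest class index. Correlations
are Pearson with mean removal; a zero-variance filtered signal contributes a
coefficient of 0 rather than NaN.

**Cross-validation** is leave-one-block-out: each fold tests one stimulation
block and trains on the remaining blocks (optionally subsampled to a fixed
number of training blocks). A 12-block session with 5 training blocks per
fold, as used in real experiments, is expressible; the simulated desk-scale
default is 6 blocks with 5 training blocks per fold.

## Metrics

The narrow-band SNR uses a full-trial boxcar periodogram so that Δf is the
reciprocal trial length, and evaluates `K·F(f) / Σ_{k≤K/2}[F(f+kΔf)+F(f−kΔf)]`
at the grid bin nearest f (off-grid targets are snapped with a logged
offset; K must be even). For multi-channel spectra the per-channel ratios
are averaged — the ratio is taken first, then the mean, so a single noisy
channel cannot dominate through its absolute power.

The ITR divides the Wolpaw bit count by the total selection time
`T = window + gaze_shift` with the gaze-shift interval defaulting to 0.5 s —
the convention of the online-speller literature, and the only reading under
which a 40-class selection at P = 0.7557 in a 6 s window yields 29.8 bits/min
(T = 6.0 s would give 32.3). The bit-count expression is nonnegative for all
P and vanishes only at chance; below-chance operating points are therefore
flagged (`below_chance`) rather than clamped or negated.

## Auditory attention decoding

The stimulus representation is the **onset envelope**: audio is passed
through 128 band-pass filters with ERB-spaced centers from 180 to 7246 Hz
(2nd-order Butterworth magnitude approximation of a gammatone bank),
per-band power is smoothed and resampled to 128 frames/s, band amplitudes
are summed into a broadband envelope, and the half-wave-rectified first
difference gives the nonnegative onset envelope. The rectification follows
the convention that onsets are increases in energy.

**Forward model:** per channel, ridge regression
`w = (SᵀS + λI)⁻¹ Sᵀ x` on the lagged stimulus design, lags 0–500 ms by
default, restricted to time points where the full lag span fits (no
zero-padding bias). λ = 0 is OLS.

**Backward model:** ridge regression of the envelope on lagged multichannel
EEG (EEG lags 0–250 ms by default), with normal equations pooled over
training trials. When a λ grid is given, leave-one-trial-out inner
cross-validation selects the penalty maximizing mean held-out reconstruction
correlation. The implementation accumulates per-trial sufficient statistics
(DᵀD, Dᵀs, Dᵀ1 and envelope moments), so fold-wise fits and held-out
correlation scores are formed by adding and subtracting trial blocks —
algebraically identical to refitting from raw designs, but linear instead of
quadratic in the number of fits.

Classification reconstructs the envelope with the attended decoder,
z-scale-invariantly correlates it with both candidate envelopes, and takes
the larger (ties toward stream A, logged). The ignored decoder's
correlations are computed and exported as diagnostics but do not enter the
decision. Leave-one-out evaluation refits both decoders for every held-out
trial and reports accuracy plus a two-sided one-sample t-test on the
attended-minus-ignored correlation differences.

## Synthetic data: what it emulates, what it does not

The SSVEP generator produces, per class, a harmonic series
`Σ_h A_h sin(2π h f t + h φ)` mixed to channels by a gain matrix, over 1/f
noise (spectrally shaped white noise, exponent 1) and an optional
amplitude-modulated ~10 Hz alpha band. The per-group harmonic amplitude
profile defaults to an in-ear 2nd-harmonic emphasis (A2/A1 = 1.2 at canal
and mastoid sites) against the usual descending occipital series
(A2/A1 = 0.6); these ratios are qualitative, not measured values. The
default *moderate-noise* condition is a 1 µV fundamental against 15 µV RMS
broadband 1/f noise — chosen as a realistic weak-in-ear-SSVEP regime in
which the calibrated decoder stays above 90% and the calibration-free one
above 80% at 6 blocks × 9 targets × 4 s, while a ~50% noise increase drives
both to chance. Desk-scale defaults (6 blocks rather than 12) keep a full
cross-validated evaluation in the low seconds.

Cocktail trials convolve ground-truth TRFs (sums of Gaussian bumps, 25 ms
width, on a 0–400 ms lag grid, channel-scaled by a fixed gain gradient) with
independent pulse-train onset envelopes (renewal process: 100 ms refractory
plus exponential gap, mean rate 4 Hz — syllable-like spacing with Poisson-
level count variability), add 1/f noise, and return the ground truth for
recovery tests. The attended kernel defaults to 3× the ignored one —
a strong attention contrast. With identical kernels the two streams are
exchangeable and decoding sits at chance, which the tests verify.

None of this emulates volume conduction, electrode impedance drift, eye or
muscle artifacts, inter-subject variability, or real speech statistics.
Passing tests therefore demonstrate the correctness of the algorithms and
the recoverability of the generative model's own structure, not expected
performance on human recordings. Because both simulated streams share one
spatial gain pattern, even noiseless AAD reconstruction correlations
saturate near 0.92 on two-stream trials (the decoder cannot separate the
streams spatially) — the single-stream self-consistency check is the one
place a >0.95 correlation is meaningful.

## Numerical and design choices

* Covariance/Gram inversions add trace-scaled 1e-8 jitter only on solver
  failure; behavior is logged.
* Filter-bank sub-band filtering reuses the preprocessing Butterworth
  realization (order 4, zero-phase).
* The backward decoder's trailing `max_lag` samples are trimmed from design
  and correlation windows rather than zero-padded.
* The ridge estimator replaces boosting-style sparse TRF estimation: it is
  closed-form, admits an exact normal-equations oracle in tests, and is the
  standard AAD baseline.
* The TRCA correlation score is invariant to global positive scaling of the
  trial and of the filters; FBCCA scores are additionally invariant to any
  invertible per-channel scaling (a CCA row-space property). The TRCA score
  is *not* invariant under arbitrary per-channel rescaling, since a diagonal
  transform changes the filtered mixture; tests assert the properties that
  actually hold.
* 40-class grids default to 8.0–15.8 Hz in 0.2 Hz steps with 0.35π phase
  increments, the joint frequency/phase speller convention.

## Known limitations

* The mean-of-good-channels interpolation ignores spatial structure; with
  coordinates available, spline interpolation would be preferable.
* The auditory filterbank approximates gammatone magnitude responses with
  Butterworth band-passes; fine temporal fine-structure effects are absent.
* Envelope extraction assumes a mono source per stream; no source
  separation is attempted.
* ITR assumes independent, identically distributed selections; dynamic
  stopping and cue overheads beyond the gaze-shift term are out of scope.
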