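"""Auditory attention decoding: envelopes, TRF estimation, reconstruction, LOO."""

import numpy as np
import pytest
from scipy import signal as sps

from earbci import (
    CocktailSimConfig,
    Envelope,
    Recording,
    audio_to_spectrogram,
    classify_attention,
    extract_onset_envelope,
    fit_backward_decoder,
    fit_forward_trf,
    loo_evaluate,
    make_ground_truth_trf,
    reconstruct_stimulus,
    simulate_cocktail_set,
    simulate_cocktail_trial,
)
from earbci.aad import _backward_design, _lag_samples, _pearson


def white_envelope(n=2560, rate=128.0, seed=0):
    rng = np.random.default_rng(seed)
    return Envelope(rng.standard_normal(n), rate)


class TestSpectrogram:
    def test_pure_tone_power_concentrates_at_nearest_band(self):
        rate = 16000.0
        t = np.arange(int(0.5 * rate)) / rate
        spec = audio_to_spectrogram(np.sin(2 * np.pi * 1000.0 * t), rate)
        band_power = spec.power.mean(axis=1)
        peak_center = spec.center_freqs_hz[np.argmax(band_power)]
        nearest = spec.center_freqs_hz[np.argmin(np.abs(spec.center_freqs_hz - 1000.0))]
        assert peak_center == pytest.approx(nearest)

    def test_silence_gives_zero_spectrogram(self):
        spec = audio_to_spectrogram(np.zeros(8000), 16000.0)
        assert np.max(np.abs(spec.power)) < 1e-20

    def test_white_noise_excites_every_band(self):
        x = np.random.default_rng(0).standard_normal(16000)
        spec = audio_to_spectrogram(x, 16000.0)
        assert np.all(spec.power.mean(axis=1) > 0)

    def test_has_128_erb_spaced_bands_in_range(self):
        spec = audio_to_spectrogram(np.zeros(4000), 16000.0)
        assert len(spec.center_freqs_hz) == 128
        assert spec.center_freqs_hz[0] == pytest.approx(180.0)
        assert spec.center_freqs_hz[-1] == pytest.approx(7246.0)

    def test_low_audio_rate_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            audio_to_spectrogram(np.zeros(1000), 8000.0)


class TestOnsetEnvelope:
    def test_constant_broadband_envelope_has_no_onsets(self):
        env = extract_onset_envelope(np.full(500, 3.0), rate=128.0)
        assert np.max(env.values) == 0.0

    def test_amplitude_step_yields_single_dominant_peak(self):
        broadband = np.concatenate([np.ones(100), 5.0 * np.ones(100)])
        env = extract_onset_envelope(broadband, rate=128.0)
        assert np.argmax(env.values) == 100
        assert np.sum(env.values > 0) == 1

    def test_click_train_onset_count_matches_click_count(self):
        rate = 128.0
        broadband = np.zeros(int(4 * rate))
        clicks = (10 + np.arange(11) * rate / 3.0).astype(int)  # 3 Hz train
        broadband[clicks] = 1.0
        env = extract_onset_envelope(broadband, rate=rate)
        peaks, _ = sps.find_peaks(env.values, height=0.5)
        assert len(peaks) == len(clicks)

    def test_onset_envelope_nonnegative(self):
        rng = np.random.default_rng(0)
        env = extract_onset_envelope(rng.uniform(0, 1, 1000), rate=128.0)
        assert env.values.min() >= 0.0


class TestForwardTRF:
    def test_recovers_ground_truth_from_noiseless_convolution(self):
        trf = make_ground_truth_trf([80.0, 200.0], [1.0, -0.5], (0.0, 400.0), 3, 128.0)
        env = white_envelope(n=5120)
        eeg = Recording(trf.predict(env), 128.0, ["L1", "L2", "L3"])
        fit = fit_forward_trf(env, eeg, (0.0, 400.0), lam=0.0)
        for ch in range(3):
            r = _pearson(fit.weights[:, ch], trf.weights[:, ch])
            assert r > 0.999

    def test_zero_stimulus_rejected(self):
        env = Envelope(np.zeros(1000), 128.0)
        eeg = Recording(np.random.default_rng(0).standard_normal((2, 1000)), 128.0, ["a", "b"])
        with pytest.raises(ValueError, match="degenerate"):
            fit_forward_trf(env, eeg, (0.0, 200.0))

    def test_ridge_shrinks_weights_monotonically(self):
        env = white_envelope()
        rng = np.random.default_rng(1)
        eeg = Recording(rng.standard_normal((2, env.n_samples)), 128.0, ["a", "b"])
        norms = [
            np.linalg.norm(fit_forward_trf(env, eeg, (0.0, 200.0), lam=lam).weights)
            for lam in [0.0, 10.0, 1e3, 1e5, 1e8]
        ]
        assert np.all(np.diff(norms) < 0)

    def test_matches_normal_equations_oracle_on_small_design(self):
        # <=5 lags, <=3 channels: literal loop-built design + matrix inverse
        rng = np.random.default_rng(2)
        n, n_lags, n_ch, lam = 60, 5, 3, 0.7
        s = rng.standard_normal(n)
        x = rng.standard_normal((n_ch, n))
        rate = 1000.0
        fit = fit_forward_trf(Envelope(s, rate), Recording(x, rate, ["a", "b", "c"]), (0.0, 4.0), lam=lam)
        D = np.array([[s[t - k] for k in range(n_lags)] for t in range(n_lags - 1, n)])
        W = np.linalg.inv(D.T @ D + lam * np.eye(n_lags)) @ D.T @ x[:, n_lags - 1 :].T
        np.testing.assert_allclose(fit.weights, W, atol=1e-8)

    def test_attended_stronger_than_ignored_preserved_in_estimates(self):
        att = make_ground_truth_trf([100.0], [0.9], (0.0, 300.0), 2, 128.0)
        ign = make_ground_truth_trf([100.0], [0.3], (0.0, 300.0), 2, 128.0)
        env_a, env_i = white_envelope(seed=3), white_envelope(seed=4)
        eeg = Recording(att.predict(env_a) + ign.predict(env_i), 128.0, ["a", "b"])
        fa = fit_forward_trf(env_a, eeg, (0.0, 300.0))
        fi = fit_forward_trf(env_i, eeg, (0.0, 300.0))
        assert np.max(np.abs(fa.weights)) > np.max(np.abs(fi.weights))


class TestBackwardDecoder:
    def test_matches_normal_equations_oracle_on_small_design(self):
        rng = np.random.default_rng(0)
        n, n_ch, lam = 80, 2, 1.3
        x = rng.standard_normal((n_ch, n))
        s = rng.standard_normal(n)
        rate = 1000.0
        dec = fit_backward_decoder(
            [(Recording(x, rate, ["a", "b"]), Envelope(s, rate))], (0.0, 3.0), lam=lam
        )
        lags = [0, 1, 2, 3]
        t1 = n - 3
        D = np.array([[x[c, t + k] for k in lags for c in range(n_ch)] for t in range(t1)])
        g = np.linalg.inv(D.T @ D + lam * np.eye(D.shape[1])) @ D.T @ s[:t1]
        np.testing.assert_allclose(dec.weights.ravel(), g, atol=1e-8)

    def test_self_reconstruction_on_noiseless_single_stream_trial(self):
        silent = make_ground_truth_trf([80.0], [0.0], (0.0, 400.0), 10, 128.0)
        cfg = CocktailSimConfig(trial_s=20.0, noise_rms_uV=0.0, trf_ignored=silent, seed=0)
        trial = simulate_cocktail_trial(cfg)
        # lag span covers the full 400 ms ground-truth kernel
        dec = fit_backward_decoder([(trial.eeg, trial.env_attended)], (0.0, 400.0), lam=1e-6)
        rec = reconstruct_stimulus(dec, trial.eeg)
        r = _pearson(rec.values, trial.env_attended.values[: rec.n_samples])
        assert r > 0.95

    def test_single_value_grid_equals_fixed_lambda(self):
        cfg = CocktailSimConfig(trial_s=10.0, seed=1)
        trial = simulate_cocktail_trial(cfg)
        pair = [(trial.eeg, trial.env_attended)]
        a = fit_backward_decoder(pair, (0.0, 100.0), lam=2.0)
        b = fit_backward_decoder(pair, (0.0, 100.0), lam=[2.0])
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_kind_recorded(self):
        cfg = CocktailSimConfig(trial_s=10.0, seed=1)
        trial = simulate_cocktail_trial(cfg)
        dec = fit_backward_decoder([(trial.eeg, trial.env_ignored)], kind="ignored")
        assert dec.kind == "ignored"

    def test_inconsistent_channel_counts_rejected(self):
        r1 = Recording(np.zeros((2, 100)), 128.0, ["a", "b"])
        r2 = Recording(np.zeros((3, 100)), 128.0, ["a", "b", "c"])
        e = Envelope(np.random.default_rng(0).standard_normal(100), 128.0)
        with pytest.raises(ValueError, match="channel counts"):
            fit_backward_decoder([(r1, e), (r2, e)])


class TestReconstruction:
    def test_zero_eeg_reconstructs_zero(self):
        cfg = CocktailSimConfig(trial_s=10.0, seed=0)
        trial = simulate_cocktail_trial(cfg)
        dec = fit_backward_decoder([(trial.eeg, trial.env_attended)])
        zero = Recording(np.zeros_like(trial.eeg.data), 128.0, trial.eeg.channel_labels)
        assert not np.any(reconstruct_stimulus(dec, zero).values)

    def test_linearity_in_eeg(self):
        cfg = CocktailSimConfig(trial_s=10.0, seed=0)
        trial = simulate_cocktail_trial(cfg)
        dec = fit_backward_decoder([(trial.eeg, trial.env_attended)])
        scaled = Recording(3.0 * trial.eeg.data, 128.0, trial.eeg.channel_labels)
        np.testing.assert_allclose(
            reconstruct_stimulus(dec, scaled).values,
            3.0 * reconstruct_stimulus(dec, trial.eeg).values,
            atol=1e-9,
        )

    def test_trim_equals_lag_span(self):
        cfg = CocktailSimConfig(trial_s=10.0, seed=0)
        trial = simulate_cocktail_trial(cfg)
        dec = fit_backward_decoder([(trial.eeg, trial.env_attended)], (0.0, 250.0))
        rec = reconstruct_stimulus(dec, trial.eeg)
        assert rec.n_samples == trial.eeg.n_samples - int(round(0.25 * 128.0))

    def test_attended_envelope_better_reconstructed_than_ignored(self):
        cfg = CocktailSimConfig(trial_s=30.0, noise_rms_uV=0.0, seed=2)
        trials = simulate_cocktail_set(CocktailSimConfig(trial_s=30.0, noise_rms_uV=0.0, n_trials=4, seed=2))
        dec = fit_backward_decoder([(t.eeg, t.env_attended) for t in trials[:3]], lam=1.0)
        held = trials[3]
        rec = reconstruct_stimulus(dec, held.eeg).values
        n = len(rec)
        r_att = _pearson(rec, held.env_attended.values[:n])
        r_ign = _pearson(rec, held.env_ignored.values[:n])
        assert r_att > r_ign


@pytest.fixture(scope="module")
def decoders_and_trials():
    trials = simulate_cocktail_set(CocktailSimConfig(trial_s=30.0, n_trials=6, seed=4))
    dec_att = fit_backward_decoder([(t.eeg, t.env_attended) for t in trials[:5]], lam=1.0)
    dec_ign = fit_backward_decoder(
        [(t.eeg, t.env_ignored) for t in trials[:5]], lam=1.0, kind="ignored"
    )
    return dec_att, dec_ign, trials[5]


class TestClassifyAttention:
    def test_high_contrast_trial_classified_correctly(self, decoders_and_trials):
        dec_att, dec_ign, held = decoders_and_trials
        rec = classify_attention(dec_att, dec_ign, held.eeg, held.env_A, held.env_B)
        assert rec["predicted_label"] == held.attended_label

    def test_swapping_stream_roles_inverts_decision(self, decoders_and_trials):
        dec_att, dec_ign, held = decoders_and_trials
        fwd = classify_attention(dec_att, dec_ign, held.eeg, held.env_A, held.env_B)
        rev = classify_attention(dec_att, dec_ign, held.eeg, held.env_B, held.env_A)
        assert fwd["predicted_label"] != rev["predicted_label"]
        assert fwd["r_att_on_A"] == pytest.approx(rev["r_att_on_B"])

    def test_identical_envelopes_tie_toward_a(self, decoders_and_trials):
        dec_att, dec_ign, held = decoders_and_trials
        rec = classify_attention(dec_att, dec_ign, held.eeg, held.env_A, held.env_A)
        assert rec["predicted_label"] == "A"
        assert rec["tie"]


class TestLOO:
    def test_record_count_matches_trial_count(self):
        trials = simulate_cocktail_set(CocktailSimConfig(trial_s=15.0, n_trials=5, seed=0))
        res = loo_evaluate(trials, lam=1.0)
        assert len(res.records) == 5

    def test_too_few_trials_rejected(self):
        trials = simulate_cocktail_set(CocktailSimConfig(trial_s=15.0, n_trials=2, seed=0))
        with pytest.raises(ValueError, match=">= 3 trials"):
            loo_evaluate(trials)

    def test_accuracy_non_increasing_in_noise(self):
        """Seed-averaged LOO accuracy must not improve with noise."""
        levels = [1.0, 12.0, 48.0]
        means = []
        for lvl in levels:
            accs = []
            for seed in range(3):
                trials = simulate_cocktail_set(
                    CocktailSimConfig(trial_s=20.0, n_trials=8, noise_rms_uV=lvl, seed=seed)
                )
                accs.append(loo_evaluate(trials, lam=1.0).accuracy)
            means.append(np.mean(accs))
        assert means[0] >= means[1] >= means[2], means


class TestDesignInternals:
    def test_backward_design_columns_are_lagged_channels(self):
        x = np.arange(12.0).reshape(2, 6)
        lags = _lag_samples((0.0, 2.0), 1000.0)  # lags 0, 1, 2 samples
        D, rows = _backward_design(x, lags)
        assert D.shape == (4, 6)
        np.testing.assert_array_equal(D[:, 0], x[0, :4])   # lag 0, ch 0
        np.testing.assert_array_equal(D[:, 3], x[1, 1:5])  # lag 1, ch 1
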