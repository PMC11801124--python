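"""Synthetic data generation: determinism, noiseless identity, feature
correlation calibration, behavior generation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from avtrack.synthetic import (
    default_truth,
    generate_behavior,
    generate_dataset,
    noiseless_response,
    pink_noise,
    syllable_envelope,
)


class TestGenerateDataset:
    def test_same_seed_is_bit_identical(self):
        t1 = default_truth(seed=7, noise_sd=0.5)
        t2 = default_truth(seed=7, noise_sd=0.5)
        d1 = generate_dataset(2, 4, 20.0, t1)
        d2 = generate_dataset(2, 4, 20.0, t2)
        for cond in d1.conditions:
            for name in d1.features[cond].features:
                assert np.array_equal(
                    d1.features[cond].features[name], d2.features[cond].features[name]
                )
        for key in d1.responses:
            assert np.array_equal(d1.responses[key].data, d2.responses[key].data)
        pd.testing.assert_frame_equal(d1.behavior, d2.behavior)

    def test_noiseless_response_is_exact_convolution(self):
        truth = default_truth(seed=9, noise_sd=0.0)
        ds = generate_dataset(2, 4, 20.0, truth)
        for (subj, cond), resp in ds.responses.items():
            s_i = ds.subjects.index(subj)
            clean = noiseless_response(
                ds.features[cond],
                truth,
                cond,
                truth.channel_gains,
                truth.subject_gains[s_i],
            )
            assert np.array_equal(resp.data, clean)

    def test_av_correlation_calibrated(self):
        for target in (0.0, 0.3, 0.5):
            truth = default_truth(seed=13, av_correlation=target)
            ds = generate_dataset(2, 2, 60.0, truth)
            feats = ds.features["single"]
            env = feats.features["spectrogram"].mean(axis=0)
            lip = feats.features["lip"][0]
            assert abs(np.corrcoef(env, lip)[0, 1] - target) < 0.05

    def test_shared_time_axes(self, small_noisy_dataset):
        ds = small_noisy_dataset
        n = ds.features["single"].n_samples
        for cond in ds.conditions:
            assert ds.features[cond].n_samples == n
            assert ds.features[cond].fs == 100.0
        for resp in ds.responses.values():
            assert resp.n_samples == n

    def test_rejects_short_duration(self):
        with pytest.raises(ValueError):
            generate_dataset(2, 2, 5.0, default_truth(seed=1))

    def test_rejects_kernel_support_outside_window(self):
        truth = default_truth(seed=1)
        lag = truth.lag_ms
        truth.kernels["lip"][0, :] = 1.0  # support down to -100 is fine
        bad = default_truth(seed=1)
        bad.lag_ms = np.arange(-200.0, 500.0, 10.0)
        bad.kernels = {k: np.ones((v.shape[0], bad.lag_ms.size)) for k, v in bad.kernels.items()}
        with pytest.raises(ValueError):
            generate_dataset(2, 2, 20.0, bad)
        del lag

    def test_condition_gains_must_be_positive(self):
        with pytest.raises(ValueError):
            default_truth(seed=1, condition_gains={"single": -1.0})


class TestSignalPrimitives:
    def test_syllable_envelope_rate(self):
        rng = np.random.default_rng(5)
        env = syllable_envelope(60 * 100, rng)
        # dominant modulation energy should sit near the syllable rate
        f = np.fft.rfftfreq(env.size, d=0.01)
        p = np.abs(np.fft.rfft(env - env.mean())) ** 2
        band = (f > 1.0) & (f < 10.0)
        f_peak = f[band][np.argmax(p[band])]
        assert 2.0 < f_peak < 7.0
        assert np.all(env >= 0)

    def test_pink_noise_spectral_slope(self):
        rng = np.random.default_rng(6)
        x = np.mean(
            [np.abs(np.fft.rfft(pink_noise(2**14, rng))) ** 2 for _ in range(20)], axis=0
        )
        f = np.fft.rfftfreq(2**14, d=0.01)
        sel = (f > 0.5) & (f < 30.0)
        slope = np.polyfit(np.log(f[sel]), np.log(x[sel]), 1)[0]
        assert -1.4 < slope < -0.6  # ~1/f power

    def test_pink_noise_unit_sd(self):
        rng = np.random.default_rng(7)
        assert pink_noise(5000, rng).std() == pytest.approx(1.0, abs=1e-9)


class TestGenerateBehavior:
    def _tracking(self, n_subjects=40, seed=0):
        rng = np.random.default_rng(seed)
        rows = [
            {"subject": f"S{i:02d}", "condition": c, "tracking": rng.standard_normal()}
            for i in range(n_subjects)
            for c in ("single", "multi")
        ]
        return pd.DataFrame(rows)

    def test_null_effect_gives_no_correlation(self):
        tr = self._tracking(n_subjects=400, seed=1)
        beh = generate_behavior(tr, 0.0, 0.2, 10.0, seed=2)
        r = np.corrcoef(beh["tracking"], beh["comprehension"])[0, 1]
        assert abs(r) < 0.1

    def test_deterministic_monotone_link(self):
        tr = self._tracking(n_subjects=20, seed=3)
        beh = generate_behavior(tr, 0.5, 0.0, 10.0, seed=4, noise_scale=0.0)
        rho = sps.spearmanr(beh["tracking"], beh["comprehension"]).statistic
        assert rho == pytest.approx(1.0)
        # difficulty is reverse-coded
        rho_d = sps.spearmanr(beh["tracking"], beh["difficulty"]).statistic
        assert rho_d == pytest.approx(-1.0)

    def test_scores_respect_scale_bounds(self):
        tr = self._tracking(n_subjects=100, seed=5)
        beh = generate_behavior(tr, 0.4, 0.5, 3.0, seed=6)
        assert beh["comprehension"].between(0, 100).all()
        assert beh["difficulty"].between(1, 5).all()
        assert beh["engagement"].between(1, 5).all()

    def test_rejects_bad_inputs(self):
        tr = self._tracking(n_subjects=10)
        with pytest.raises(ValueError):
            generate_behavior(tr, 0.3, 0.2, 0.0, seed=1)
        solo = tr[tr["subject"] == "S00"]
        with pytest.raises(ValueError):
            generate_behavior(solo, 0.3, 0.2, 5.0, seed=1)

    def test_same_seed_reproducible(self):
        tr = self._tracking(n_subjects=15, seed=8)
        b1 = generate_behavior(tr, 0.3, 0.2, 5.0, seed=9)
        b2 = generate_behavior(tr, 0.3, 0.2, 5.0, seed=9)
        pd.testing.assert_frame_equal(b1, b2)
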