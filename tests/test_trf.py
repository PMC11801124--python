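"""Boosting TRF estimation: design construction, fitting, accuracies,
post-processing, peak detection."""

import numpy as np
import pytest

from avtrack.containers import FeatureSet, NeuralResponse
from avtrack.synthetic import default_truth, generate_dataset, noiseless_response
from avtrack.trf import (
    BoostingTRF,
    build_design,
    detect_peaks,
    fisher_average,
    postprocess_trf,
    prediction_accuracy,
    time_folds,
)


class TestBuildDesign:
    def test_tiled_variant_has_14_windows(self, rng):
        fs = FeatureSet({"x": rng.standard_normal((1, 2000))})
        d = build_design(fs, -100.0, 600.0, 50.0, spacing_ms=50.0)
        assert d.n_windows == 14
        assert d.X.shape == (2000, 14)

    def test_default_overlap_spacing(self, rng):
        fs = FeatureSet({"x": rng.standard_normal((1, 2000))})
        d = build_design(fs)
        # windows every 20 ms covering -100..600, 50 ms long, plus one
        # extra window flush with the end of the lag range
        assert d.n_windows == 34
        assert d.lag_ms[0] == -100.0
        assert d.lag_ms[-1] == 590.0

    def test_zero_feature_gives_zero_columns(self):
        fs = FeatureSet({"x": np.zeros((1, 1500))})
        d = build_design(fs)
        assert np.all(d.X == 0)

    def test_impulse_reproduces_shifted_hamming(self):
        x = np.zeros((1, 1500))
        t0 = 700
        x[0, t0] = 1.0
        d = build_design(FeatureSet({"x": x}), spacing_ms=50.0)
        ham = np.hamming(5)
        for j in range(d.n_windows):
            col = d.X[:, j]
            lag0 = -10 + 5 * j
            seg = col[t0 + lag0 : t0 + lag0 + 5]
            assert np.allclose(seg, ham)
            rest = np.concatenate([col[: t0 + lag0], col[t0 + lag0 + 5 :]])
            assert np.all(rest == 0)

    def test_rejects_nondividing_basis(self, rng):
        fs = FeatureSet({"x": rng.standard_normal((1, 1000))})
        with pytest.raises(ValueError):
            build_design(fs, -100.0, 600.0, 30.0)

    def test_kernel_reconstruction_roundtrip(self, rng):
        fs = FeatureSet({"x": rng.standard_normal((2, 1200))})
        d = build_design(fs)
        coefs = rng.standard_normal(d.n_cols)
        kernels = d.kernels_from_coefs(coefs)
        assert kernels["x"].shape == (2, d.lag_ms.size)


class TestPredictionAccuracy:
    def test_perfect_and_inverted(self, rng):
        y = rng.standard_normal(50)
        assert prediction_accuracy(y, y) == pytest.approx(1.0)
        assert prediction_accuracy(y, -y) == pytest.approx(-1.0)

    def test_orthogonal_series(self):
        t = np.arange(100)
        a = np.sin(2 * np.pi * t / 100)
        b = np.cos(2 * np.pi * t / 100)
        assert abs(prediction_accuracy(a, b)) < 1e-12

    def test_matches_covariance_formula(self):
        x = np.array([1.0, 2.0, 4.0, 3.5, 0.5])
        y = np.array([0.2, 1.1, 2.9, 3.0, 1.0])
        cx = x - x.mean()
        cy = y - y.mean()
        expected = (cx @ cy) / np.sqrt((cx @ cx) * (cy @ cy))
        assert abs(prediction_accuracy(x, y) - expected) < 1e-12

    def test_zero_variance_is_signalled(self):
        with pytest.raises(ValueError):
            prediction_accuracy(np.ones(10), np.arange(10.0))


class TestFisherAverage:
    def test_identity_and_zero(self):
        assert fisher_average([0.4, 0.4]) == pytest.approx(0.4)
        assert fisher_average([0.0, 0.0]) == 0.0

    def test_closed_form(self):
        expected = np.tanh((np.arctanh(0.5) + np.arctanh(0.9)) / 2)
        assert abs(fisher_average([0.5, 0.9]) - expected) < 1e-12
        assert fisher_average([0.5, 0.9]) == pytest.approx(0.766, abs=1e-3)

    def test_bounded_by_extremes(self, rng):
        vals = rng.uniform(-0.9, 0.9, size=7)
        avg = fisher_average(vals)
        assert vals.min() <= avg <= vals.max()

    def test_rejects_unit_correlation(self):
        with pytest.raises(ValueError):
            fisher_average([0.5, 1.0])


class TestBoostingFit:
    def test_noiseless_recovery(self, noiseless_lip_dataset):
        ds = noiseless_lip_dataset
        truth = ds.truth
        model = BoostingTRF(
            ds.features["single"].subset(["lip"]), ds.responses[("S00", "single")]
        )
        res = model.fit()
        assert res.accuracies.mean() > 0.95
        est = res.band_averaged_kernels()["lip"].mean(axis=0)
        true = truth.kernels["lip"].mean(axis=0)
        assert np.corrcoef(est, true)[0, 1] > 0.95

    def test_condition_gain_reflected_in_kernels(self, noiseless_lip_dataset):
        ds = noiseless_lip_dataset
        res_a = BoostingTRF(
            ds.features["single"].subset(["lip"]), ds.responses[("S00", "single")]
        ).fit()
        res_b = BoostingTRF(
            ds.features["multi"].subset(["lip"]), ds.responses[("S00", "multi")]
        ).fit()
        peak_a = np.abs(res_a.band_averaged_kernels()["lip"]).max()
        peak_b = np.abs(res_b.band_averaged_kernels()["lip"]).max()
        assert 1.8 <= peak_b / peak_a <= 2.2

    def test_null_accuracy_near_zero(self, rng):
        n = 6000
        feats = FeatureSet({"lip": rng.standard_normal((1, n))})
        resp = NeuralResponse(rng.standard_normal((2, n)), np.zeros((2, 3)))
        res = BoostingTRF(feats, resp).fit()
        assert abs(res.accuracies.mean()) < 0.1

    def test_zero_feature_kernel_stays_zero(self, rng):
        n = 4000
        x = rng.standard_normal((1, n))
        y = np.convolve(x[0], np.hanning(10), mode="same")[None, :]
        feats = FeatureSet({"drive": x, "silent": np.zeros((1, n))})
        resp = NeuralResponse(y, np.zeros((1, 3)))
        res = BoostingTRF(feats, resp).fit()
        assert np.all(res.kernels["silent"] == 0)
        assert np.any(res.kernels["drive"] != 0)

    def test_accuracy_affine_invariance(self, rng):
        n = 4000
        x = rng.standard_normal((1, n))
        y = np.convolve(x[0], np.hanning(10), mode="same") + 0.5 * rng.standard_normal(n)
        feats = FeatureSet({"x": x})
        r1 = BoostingTRF(feats, NeuralResponse(y[None, :], np.zeros((1, 3)))).fit()
        r2 = BoostingTRF(
            feats, NeuralResponse((7.0 * y + 3.0)[None, :], np.zeros((1, 3)))
        ).fit()
        assert np.allclose(r1.accuracies, r2.accuracies, atol=1e-12)

    def test_accuracy_degrades_monotonically_with_noise(self):
        accs = []
        for noise in (0.0, 2.0, 8.0):
            truth = default_truth(
                seed=31, noise_sd=noise, av_correlation=0.0,
                condition_gains={"single": 1.0},
            )
            truth.kernels["spectrogram"][:] = 0.0
            truth.kernels["onsets"][:] = 0.0
            ds = generate_dataset(2, 2, 60.0, truth)
            res = BoostingTRF(
                ds.features["single"].subset(["lip"]), ds.responses[("S00", "single")]
            ).fit()
            accs.append(res.accuracies.mean())
        assert accs[0] > accs[1] > accs[2]

    def test_underdetermined_rejected(self, rng):
        feats = FeatureSet({"x": rng.standard_normal((1, 200))})
        resp = NeuralResponse(rng.standard_normal((1, 200)), np.zeros((1, 3)))
        with pytest.raises(ValueError, match="underdetermined"):
            BoostingTRF(feats, resp)

    def test_fold_layout_contiguous_deterministic(self):
        folds = time_folds(100, 4)
        assert [f.size for f in folds] == [25, 25, 25, 25]
        assert np.array_equal(np.concatenate(folds), np.arange(100))
        again = time_folds(100, 4)
        for a, b in zip(folds, again):
            assert np.array_equal(a, b)


class TestPostprocess:
    def _results(self, kernels, coords, groups=None):
        from avtrack.trf import TRFResults

        n_ch = coords.shape[0]
        return TRFResults(
            kernels=kernels,
            lag_ms=np.arange(-100.0, 600.0, 10.0),
            basis_ms=50.0,
            accuracies=np.linspace(0.1, 0.5, n_ch),
            fold_accuracies=np.zeros((n_ch, 4)),
            coefs=np.zeros((n_ch, 1)),
            design=None,
            coords=coords,
            orientation_groups=groups,
            n_folds=4,
            step=0.005,
            patience=10,
        )

    def test_isolated_channels_are_unchanged(self, rng):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])  # far beyond 4 SD
        k = rng.standard_normal((1, 2, 70))
        res = self._results({"x": k.copy()}, coords)
        out = postprocess_trf(res, smoothing_sd_mm=5.0)
        assert np.allclose(out.kernels["x"], k)

    def test_coincident_channels_average(self, rng):
        coords = np.zeros((2, 3))
        k = rng.standard_normal((1, 2, 70))
        out = postprocess_trf(self._results({"x": k.copy()}, coords), smoothing_sd_mm=5.0)
        mean = k.mean(axis=1, keepdims=True)
        assert np.allclose(out.kernels["x"], np.repeat(mean, 2, axis=1))

    def test_orientation_norm_pythagoras(self):
        coords = np.zeros((3, 3))
        coords[:, 0] = [0.0, 100.0, 200.0]  # isolated -> smoothing is identity
        k = np.zeros((1, 3, 70))
        k[0, 0, :] = 3.0
        k[0, 1, :] = 4.0
        k[0, 2, :] = 0.0
        groups = np.array([[0, 1, 2]])
        res = self._results({"x": k}, coords, groups)
        out = postprocess_trf(res, smoothing_sd_mm=0.0, collapse_orientations=True)
        assert np.allclose(out.kernels["x"][0, 0, :], 5.0)

    def test_norm_requires_groups(self):
        coords = np.zeros((3, 3))
        res = self._results({"x": np.zeros((1, 3, 70))}, coords)
        with pytest.raises(ValueError):
            postprocess_trf(res, collapse_orientations=True)


class TestDetectPeaks:
    lags = np.arange(-100.0, 600.0, 10.0)

    def test_single_gaussian_bump(self):
        mag = np.exp(-0.5 * ((self.lags - 160.0) / 30.0) ** 2)
        peaks = detect_peaks(self.lags, mag)
        assert len(peaks) == 1
        assert abs(peaks[0][0] - 160.0) <= 10.0

    def test_monotone_ramp_has_no_peak(self):
        mag = np.linspace(0.0, 1.0, self.lags.size)
        assert detect_peaks(self.lags, mag) == []

    def test_two_bumps_sorted_by_latency(self):
        mag = np.exp(-0.5 * ((self.lags - 70.0) / 25.0) ** 2)
        mag += 0.7 * np.exp(-0.5 * ((self.lags - 180.0) / 25.0) ** 2)
        peaks = detect_peaks(self.lags, mag)
        assert len(peaks) == 2
        assert abs(peaks[0][0] - 70.0) <= 10.0
        assert abs(peaks[1][0] - 180.0) <= 10.0

    def test_window_excludes_edge_artifacts(self):
        mag = np.zeros(self.lags.size)
        mag[1] = 5.0  # artifact at -90 ms, outside -50..550 window? -90 < -50
        mag[self.lags.tolist().index(160.0)] = 1.0
        peaks = detect_peaks(self.lags, mag)
        assert all(lat >= -50.0 for lat, _ in peaks)
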