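"""Stimulus feature extraction: FIR design rule, gammatone spectrogram,
acoustic onsets, lip aperture."""

import numpy as np
import pytest

from avtrack.containers import FeatureSet
from avtrack.features import (
    acoustic_onsets,
    design_fir,
    design_fir_order,
    erb_center_frequencies,
    fft_resample,
    gammatone_bands,
    lip_aperture,
)


class TestFirDesign:
    @pytest.mark.parametrize(
        "ftype,tw,fs,expected",
        [
            ("lowpass", 2.5, 1000.0, 1320),
            ("highpass", 2.0, 100.0, 166),
            ("lowpass", 1.65, 1.0, 2),
        ],
    )
    def test_hamming_rule_orders(self, ftype, tw, fs, expected):
        assert design_fir_order(ftype, tw, fs) == expected

    def test_order_is_even(self):
        for tw in (0.7, 1.1, 2.3, 3.9):
            assert design_fir_order("lowpass", tw, 500.0) % 2 == 0

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            design_fir_order("bandpass", 2.0, 100.0)
        with pytest.raises(ValueError):
            design_fir_order("lowpass", -1.0, 100.0)
        with pytest.raises(ValueError):
            design_fir("lowpass", 10.0, 60.0, 100.0)  # transition >= Nyquist

    def test_taps_are_linear_phase_lowpass(self):
        order, taps = design_fir("lowpass", 10.0, 2.0, 100.0)
        assert taps.size == order + 1
        assert np.allclose(taps, taps[::-1])  # symmetric -> linear phase
        assert abs(taps.sum() - 1.0) < 1e-3  # unit DC gain


class TestGammatoneBands:
    fs_in = 16_000

    def test_silence_maps_to_zero(self):
        out = gammatone_bands(np.zeros(2 * self.fs_in), self.fs_in)
        spec = out.features["spectrogram"]
        assert spec.shape == (8, 200)
        assert np.all(spec == 0)

    def test_output_shape_contract(self, rng):
        audio = rng.standard_normal(10 * self.fs_in)
        out = gammatone_bands(audio, self.fs_in)
        assert out.features["spectrogram"].shape == (8, 1000)
        assert out.fs == 100.0

    def test_pure_tone_lands_in_matching_band(self):
        t = np.arange(2 * self.fs_in) / self.fs_in
        audio = np.sin(2 * np.pi * 500.0 * t)
        out = gammatone_bands(audio, self.fs_in)
        band_means = out.features["spectrogram"].mean(axis=1)
        edges = np.geomspace(100.0, 5000.0, 9)
        expected_band = int(np.searchsorted(edges, 500.0) - 1)
        assert int(np.argmax(band_means)) == expected_band

    def test_power_law_homogeneity(self, rng):
        audio = rng.standard_normal(2 * self.fs_in)
        a = gammatone_bands(audio, self.fs_in).features["spectrogram"]
        b = gammatone_bands(3.0 * audio, self.fs_in).features["spectrogram"]
        ratio = b[a > 1e-12] / a[a > 1e-12]
        assert np.allclose(ratio, 3.0**0.6, rtol=1e-3)

    def test_rejects_bad_audio(self, rng):
        with pytest.raises(ValueError):
            gammatone_bands(rng.standard_normal((2, self.fs_in * 2)), self.fs_in)
        bad = rng.standard_normal(2 * self.fs_in)
        bad[5] = np.nan
        with pytest.raises(ValueError):
            gammatone_bands(bad, self.fs_in)
        with pytest.raises(ValueError):
            gammatone_bands(rng.standard_normal(16_000), 8_000)

    def test_erb_spacing_monotone(self):
        cfs = erb_center_frequencies(20.0, 5000.0, 256)
        assert cfs.size == 256
        assert cfs[0] == pytest.approx(20.0)
        assert cfs[-1] == pytest.approx(5000.0)
        assert np.all(np.diff(cfs) > 0)


class TestAcousticOnsets:
    def _spec(self, mat):
        return FeatureSet({"spectrogram": mat})

    def test_constant_input_gives_zero(self):
        spec = self._spec(np.full((8, 500), 3.7))
        out = acoustic_onsets(spec).features["onsets"]
        assert np.max(np.abs(out)) < 1e-9

    def test_step_gives_single_band_transient(self):
        mat = np.zeros((8, 500))
        t0 = 200
        mat[3, t0:] = 1.0
        out = acoustic_onsets(self._spec(mat)).features["onsets"]
        other = np.delete(out, 3, axis=0)
        assert np.max(other) < 1e-9
        peak = int(np.argmax(out[3]))
        assert abs(peak - t0) * 10.0 <= 50.0  # within 50 ms of the step
        assert out[3, peak] > 0

    def test_compressive_saturation(self):
        mat1 = np.zeros((8, 500))
        mat10 = np.zeros((8, 500))
        mat1[0, 250:] = 1.0
        mat10[0, 250:] = 10.0
        p1 = acoustic_onsets(self._spec(mat1)).features["onsets"].max()
        p10 = acoustic_onsets(self._spec(mat10)).features["onsets"].max()
        assert p10 / p1 < 10.0

    def test_output_nonnegative_and_finite(self, rng):
        mat = np.abs(rng.standard_normal((8, 400)))
        out = acoustic_onsets(self._spec(mat)).features["onsets"]
        assert np.all(out >= 0)
        assert np.all(np.isfinite(out))

    def test_rejects_wrong_band_count(self):
        with pytest.raises(ValueError):
            acoustic_onsets(FeatureSet({"spectrogram": np.zeros((4, 100))}))


class TestLipAperture:
    def test_circle_contour_area_is_pi(self):
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        contour = np.empty((10, 128))
        contour[:, 0::2] = np.cos(theta)
        contour[:, 1::2] = np.sin(theta)
        out = lip_aperture(contour, fps=25.0).features["lip"][0]
        # 64-gon area slightly below pi
        expected = 0.5 * 64 * np.sin(2 * np.pi / 64)
        assert np.allclose(out, expected, atol=1e-6)

    def test_axes_input_ellipse_area(self):
        frames = np.column_stack([np.full(8, 2.0), np.full(8, 1.0)])
        out = lip_aperture(frames, fps=25.0).features["lip"][0]
        assert np.allclose(out, np.pi * 2.0 * 1.0 / 4.0, atol=1e-9)

    def test_constant_upsampling_preserves_value(self):
        frames = np.column_stack([np.full(25, 1.3), np.full(25, 0.6)])
        out = lip_aperture(frames, fps=25.0).features["lip"][0]
        assert out.size == 100
        assert np.allclose(out, np.pi * 1.3 * 0.6 / 4.0, atol=1e-9)

    def test_sinusoid_matches_analytic_resampling(self):
        # 2 Hz sinusoidal area over an integer number of periods at 25 Hz
        n_frames = 50  # 2 s -> 4 full periods
        t25 = np.arange(n_frames) / 25.0
        area = 2.0 + 0.5 * np.sin(2 * np.pi * 2.0 * t25)
        # axes chosen so pi * a * b / 4 equals the target area exactly
        frames = np.column_stack([4.0 * area / np.pi, np.ones(n_frames)])
        out = lip_aperture(frames, fps=25.0).features["lip"][0]
        t100 = np.arange(out.size) / 100.0
        expected = 2.0 + 0.5 * np.sin(2 * np.pi * 2.0 * t100)
        assert np.max(np.abs(out - expected)) < 1e-6

    def test_rejects_self_intersecting_contour(self):
        bowtie = np.array([[0, 0, 1, 1, 1, 0, 0, 1.0]])
        bowtie = np.repeat(bowtie, 3, axis=0)
        with pytest.raises(ValueError):
            lip_aperture(bowtie, fps=25.0)

    def test_rejects_bad_fps(self):
        with pytest.raises(ValueError):
            lip_aperture(np.ones((5, 2)), fps=0.0)


class TestFftResample:
    def test_preserves_mean_and_power_of_bandlimited_input(self, rng):
        n = 200
        t = np.arange(n) / 25.0
        x = 1.0 + np.sin(2 * np.pi * 3.0 * t) + 0.5 * np.cos(2 * np.pi * 5.0 * t)
        y = fft_resample(x, 25.0, 100.0)
        assert y.size == 800
        assert abs(y.mean() - x.mean()) < 1e-6
        assert abs(np.mean((y - y.mean()) ** 2) - np.mean((x - x.mean()) ** 2)) < 1e-6
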