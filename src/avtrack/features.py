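"""Stimulus feature extraction: gammatone spectrogram, acoustic onsets,
lip aperture, and an FIR filter-design utility.

All features end up on a common 100 Hz time axis.  The spectrogram is an
8-band reduction of a 256-channel gammatone filterbank (20-5000 Hz, 0.01 s
window, sub-100 Hz centers discarded, power-law compression with exponent
0.6).  Acoustic onsets come from an auditory edge-detection model applied
per spectrogram band.  The lip aperture is the area enclosed by the lip
contour per video frame, upsampled from the video rate by FFT-based
interpolation.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import signal

from .containers import FS, FeatureSet

__all__ = [
    "design_fir_order",
    "design_fir",
    "erb_center_frequencies",
    "gammatone_bands",
    "acoustic_onsets",
    "lip_aperture",
    "fft_resample",
]


# ---------------------------------------------------------------------------
# FIR design rule
# ---------------------------------------------------------------------------

def design_fir_order(filter_type: str, transition_width_hz: float, fs: float) -> int:
    """Hamming-window FIR order for a given transition width.

    Uses the classic Hamming design rule ``order = 3.3 * fs / transition
    width``, rounded up to the nearest even integer so the filter has an
    integer group delay and a symmetric impulse response.

    Examples
    --------
    A 2.5 Hz transition at 1000 Hz gives order 1320; a 2.0 Hz transition at
    100 Hz gives order 166.
    """
    if filter_type not in ("lowpass", "highpass"):
        raise ValueError(f"filter_type must be 'lowpass' or 'highpass', got {filter_type!r}")
    if transition_width_hz <= 0 or fs <= 0:
        raise ValueError("transition width and fs must be positive")
    order = math.ceil(3.3 * fs / transition_width_hz)
    if order % 2:
        order += 1
    return order


def design_fir(
    filter_type: str,
    cutoff_hz: float,
    transition_width_hz: float,
    fs: float,
) -> tuple[int, np.ndarray]:
    """Design a Hamming-windowed-sinc FIR filter (order, taps).

    The taps are intended for one-pass zero-phase (forward, delay-
    compensated) application, matching common M/EEG preprocessing.
    """
    if not 0 < transition_width_hz < fs / 2:
        raise ValueError("transition width must lie in (0, Nyquist)")
    order = design_fir_order(filter_type, transition_width_hz, fs)
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    taps = signal.firwin(
        order + 1,
        cutoff_hz,
        window="hamming",
        pass_zero=(filter_type == "lowpass"),
        fs=fs,
    )
    return order, taps


# ---------------------------------------------------------------------------
# Gammatone spectrogram
# ---------------------------------------------------------------------------

def erb_center_frequencies(f_low: float, f_high: float, n: int) -> np.ndarray:
    """``n`` center frequencies equally spaced on the ERB-rate scale
    between ``f_low`` and ``f_high`` (Glasberg & Moore)."""

    def hz_to_erb(f):
        return 21.4 * np.log10(1 + 0.00437 * f)

    def erb_to_hz(e):
        return (10 ** (e / 21.4) - 1) / 0.00437

    return erb_to_hz(np.linspace(hz_to_erb(f_low), hz_to_erb(f_high), n))


def gammatone_bands(
    audio: np.ndarray,
    fs_in: float,
    *,
    f_low: float = 20.0,
    f_high: float = 5000.0,
    n_channels: int = 256,
    n_bands: int = 8,
    min_band_freq: float = 100.0,
    window_time: float = 0.01,
    exponent: float = 0.6,
    fs_out: float = FS,
) -> FeatureSet:
    """8-band gammatone spectrogram of a mono waveform.

    A 256-channel gammatone filterbank between 20 and 5000 Hz is applied,
    filter outputs are converted to energy within non-overlapping 0.01 s
    windows (landing directly on the 100 Hz output rate), channels with
    center frequency below 100 Hz are discarded, the remainder are averaged
    into 8 logarithmically spaced bands, and each band is compressed with
    exponent 0.6.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1:
        raise ValueError("audio must be a mono 1-D waveform")
    if not np.all(np.isfinite(audio)):
        raise ValueError("audio contains NaN or inf")
    if fs_in < 10_000:
        raise ValueError("audio sampling rate must be >= 10 kHz")
    if audio.size < fs_in:
        raise ValueError("audio must be at least 1 s long")

    cfs = erb_center_frequencies(f_low, f_high, n_channels)
    hop = int(round(fs_in * window_time))
    n_frames = int(audio.size // hop)

    keep = cfs >= min_band_freq
    cfs_kept = cfs[keep]
    env = np.empty((keep.sum(), n_frames))
    row = 0
    for fc in cfs_kept:
        b, a = signal.gammatone(fc, "iir", fs=fs_in)
        y = signal.lfilter(b, a, audio)
        # RMS energy within each 10 ms frame
        e = y[: n_frames * hop].reshape(n_frames, hop)
        env[row] = np.sqrt(np.mean(e * e, axis=1))
        row += 1

    # average into n_bands log-spaced bands over [min_band_freq, f_high]
    edges = np.geomspace(min_band_freq, f_high, n_bands + 1)
    edges[-1] *= 1.0 + 1e-9  # include the top center frequency
    bands = np.zeros((n_bands, n_frames))
    for i in range(n_bands):
        sel = (cfs_kept >= edges[i]) & (cfs_kept < edges[i + 1])
        if not sel.any():
            raise ValueError("empty frequency band; increase n_channels")
        bands[i] = env[sel].mean(axis=0)

    bands = np.power(bands, exponent)
    if fs_out != 1.0 / window_time:
        bands = np.vstack([fft_resample(b, 1.0 / window_time, fs_out) for b in bands])
    return FeatureSet({"spectrogram": bands}, fs=fs_out)


# ---------------------------------------------------------------------------
# Acoustic onsets (auditory edge detection)
# ---------------------------------------------------------------------------

def acoustic_onsets(
    spectrogram: FeatureSet,
    *,
    n_delays: int = 10,
    delay_min_ms: float = 3.0,
    delay_max_ms: float = 5.0,
    saturation: float = 30.0,
    rf_sd_ms: float = 2.0,
) -> FeatureSet:
    """Per-band acoustic onset representation via an auditory edge detector.

    Each band passes through a delay layer (``n_delays`` taps from
    ``delay_min_ms`` to ``delay_max_ms``, fractional-sample delays realized
    by linear interpolation), a saturating compressive nonlinearity
    ``s(u) = c*u / (1 + c*u)`` with scaling factor ``c``, and a receptive
    field given by the derivative of a Gaussian window (SD ``rf_sd_ms``)
    across the delay axis.  The output is half-wave rectified, so steady
    states map to zero and rising edges to positive transients.
    """
    if "spectrogram" not in spectrogram.features:
        raise ValueError("input FeatureSet must contain a 'spectrogram' feature")
    spec = spectrogram.features["spectrogram"]
    if spec.shape[0] != 8:
        raise ValueError(f"expected an 8-band spectrogram, got {spec.shape[0]} bands")
    if spectrogram.fs != FS:
        raise ValueError(f"expected {FS:g} Hz input, got {spectrogram.fs:g} Hz")

    delays_ms = np.linspace(delay_min_ms, delay_max_ms, n_delays)
    delays_smp = delays_ms * spectrogram.fs / 1000.0  # fractional samples

    # derivative-of-Gaussian receptive field across the delay axis, centered
    # mid-window; forced to zero sum so constant inputs yield exactly zero
    t = delays_ms - delays_ms.mean()
    rf = -t * np.exp(-0.5 * (t / rf_sd_ms) ** 2)  # positive weight at short delay
    rf -= rf.mean()
    norm = np.sum(np.abs(rf))
    if norm > 0:
        rf /= norm

    out = np.zeros_like(spec)
    for k, d in enumerate(delays_smp):
        lo = int(np.floor(d))
        frac = d - lo
        delayed = _shift_right(spec, lo) * (1 - frac) + _shift_right(spec, lo + 1) * frac
        u = np.maximum(delayed, 0.0)
        sat = saturation * u / (1.0 + saturation * u)
        out += rf[k] * sat
    return FeatureSet({"onsets": np.maximum(out, 0.0)}, fs=spectrogram.fs)


def _shift_right(x: np.ndarray, k: int) -> np.ndarray:
    """Shift along the last axis by k samples, padding with the edge value
    (so the pre-stimulus state is treated as steady)."""
    if k <= 0:
        return x
    pad = np.repeat(x[..., :1], k, axis=-1)
    return np.concatenate([pad, x[..., :-k]], axis=-1)


# ---------------------------------------------------------------------------
# Lip aperture
# ---------------------------------------------------------------------------

def lip_aperture(
    frames: np.ndarray,
    fps: float,
    *,
    kind: str = "auto",
    fs_out: float = FS,
) -> FeatureSet:
    """Lip-aperture area series from per-frame lip contours or axes.

    Parameters
    ----------
    frames
        Either ``(n_frames, 2*k)`` contour vertices ``x1, y1, ..., xk, yk``
        (closed polygons; area via the shoelace formula) or
        ``(n_frames, 2)`` horizontal/vertical axis lengths ``(a, b)``
        (ellipse area ``pi*a*b/4``).  Higher values mean a wider mouth
        opening.
    fps
        Video frame rate (25 Hz for standard PAL video).

    The per-frame area series is upsampled to ``fs_out`` with FFT-based
    interpolation.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 2 or frames.shape[0] < 2:
        raise ValueError("need at least 2 frames of contour/axis data")

    if kind == "auto":
        kind = "axes" if frames.shape[1] == 2 else "contour"
    if kind == "axes":
        a, b = frames[:, 0], frames[:, 1]
        area = np.pi * a * b / 4.0
    elif kind == "contour":
        if frames.shape[1] % 2 or frames.shape[1] < 6:
            raise ValueError("contours need >= 3 (x, y) vertex pairs")
        xs = frames[:, 0::2]
        ys = frames[:, 1::2]
        area = np.empty(frames.shape[0])
        for i in range(frames.shape[0]):
            area[i] = _polygon_area(xs[i], ys[i])
    else:
        raise ValueError(f"unknown input kind {kind!r}")

    series = fft_resample(area, fps, fs_out)
    return FeatureSet({"lip": series[None, :]}, fs=fs_out)


def _polygon_area(x: np.ndarray, y: np.ndarray) -> float:
    """Shoelace area of a closed polygon; rejects self-intersecting input."""
    if _self_intersects(x, y):
        raise ValueError("self-intersecting lip contour")
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _self_intersects(x: np.ndarray, y: np.ndarray) -> bool:
    n = len(x)
    segs = [((x[i], y[i]), (x[(i + 1) % n], y[(i + 1) % n])) for i in range(n)]

    def ccw(p, q, r):
        return (r[1] - p[1]) * (q[0] - p[0]) - (q[1] - p[1]) * (r[0] - p[0])

    for i in range(n):
        for j in range(i + 1, n):
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue  # shared vertex
            p1, p2 = segs[i]
            p3, p4 = segs[j]
            d1, d2 = ccw(p3, p4, p1), ccw(p3, p4, p2)
            d3, d4 = ccw(p1, p2, p3), ccw(p1, p2, p4)
            if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
                return True
    return False


def fft_resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """FFT-based resampling of a 1-D series from ``fs_in`` to ``fs_out``.

    Preserves the mean exactly and the power of band-limited content; this
    is the interpolation used to bring the 25 Hz lip series to 100 Hz.
    """
    x = np.asarray(x, dtype=float)
    n_out = int(round(x.size * fs_out / fs_in))
    if n_out == x.size:
        return x.copy()
    return signal.resample(x, n_out)
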