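"""Synthetic audiovisual-tracking datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes
without modeling real speech or MEG physics:

* an envelope-like 8-band spectrogram surrogate built from smoothed pulse
  trains at the ~4.1 Hz syllable rate (Gamma-distributed inter-pulse
  intervals, 50 ms smoothing), plus band-specific modulation;
* acoustic onsets derived from that surrogate with the same edge detector
  used for real stimuli;
* a lip-aperture series that leads the envelope by 120 ms and is mixed
  with an independent smooth process calibrated to a target lag-zero
  envelope-lip correlation;
* responses formed per channel as the sum of feature-kernel convolutions
  (with condition-dependent gains and spatial gain profiles on a 7 mm
  channel grid) plus 1/f noise;
* behavioral scores generated from a per-subject tracking metric with
  subject random intercepts and Student-t noise.

Everything is deterministic given the seed recorded in the truth object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import features as _features
from .containers import FS, FeatureSet, NeuralResponse, SyntheticDataset, SyntheticTruth

__all__ = [
    "default_truth",
    "generate_dataset",
    "generate_behavior",
    "pink_noise",
    "syllable_envelope",
]

#: mean syllable rate (Hz) of the surrogate pulse trains
SYLLABLE_RATE_HZ = 4.1
#: lead of the lip aperture over the acoustic envelope (ms)
LIP_LEAD_MS = 120.0
#: channel grid spacing (mm)
GRID_SPACING_MM = 7.0


def _gaussian_bump(lag_ms: np.ndarray, center_ms: float, sd_ms: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((lag_ms - center_ms) / sd_ms) ** 2)


def default_truth(
    seed: int = 0,
    noise_sd: float = 1.0,
    av_correlation: float = 0.3,
    behavior_effect: float = 0.3,
    lip_kernel_scale: float = 1.0,
    condition_gains: dict | None = None,
    lag_min_ms: float = 0.0,
    lag_max_ms: float = 400.0,
) -> SyntheticTruth:
    """A plausible ground truth: acoustic kernels peaking at 70/180 ms,
    lip kernels peaking later (160/290 ms), single- vs multispeaker gains
    that damp acoustics and boost lip responses when a distractor is
    present."""
    lag_ms = np.arange(-100.0, 600.0, 1000.0 / FS)
    support = (lag_ms >= lag_min_ms) & (lag_ms <= lag_max_ms)

    def k(centers, amps, sd=40.0):
        out = np.zeros_like(lag_ms)
        for c, a in zip(centers, amps):
            out += _gaussian_bump(lag_ms, c, sd, a)
        out[~support] = 0.0
        return out

    spec = np.vstack([k([70, 180], [1.0, 0.7]) * s for s in np.linspace(1.2, 0.8, 8)])
    ons = np.vstack([k([70, 190], [0.8, 0.5]) * s for s in np.linspace(1.1, 0.9, 8)])
    lip = k([160, 290], [0.9, 0.5])[None, :] * lip_kernel_scale
    if condition_gains is None:
        condition_gains = {
            "single": {"spectrogram": 1.0, "onsets": 1.0, "lip": 0.6},
            "multi": {"spectrogram": 0.6, "onsets": 0.6, "lip": 1.0},
        }
    return SyntheticTruth(
        kernels={"spectrogram": spec, "onsets": ons, "lip": lip},
        lag_ms=lag_ms,
        condition_gains=condition_gains,
        noise_sd=noise_sd,
        av_correlation=av_correlation,
        behavior_effect=behavior_effect,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Signal building blocks
# ---------------------------------------------------------------------------

def syllable_envelope(
    n_samples: int,
    rng: np.random.Generator,
    rate_hz: float = SYLLABLE_RATE_HZ,
    smooth_ms: float = 50.0,
    fs: float = FS,
) -> np.ndarray:
    """Smoothed pulse train at the syllable rate: Gamma-distributed
    inter-pulse intervals (shape 2) with mean 1/rate, amplitude jitter,
    smoothed with a Hann window of ``smooth_ms``."""
    env = np.zeros(n_samples)
    t = rng.gamma(2.0, 1.0 / (2.0 * rate_hz))
    while t * fs < n_samples:
        env[int(t * fs)] += 0.5 + rng.random()
        t += rng.gamma(2.0, 1.0 / (2.0 * rate_hz))
    w = np.hanning(max(int(round(smooth_ms / 1000.0 * fs)) * 2 + 1, 3))
    w /= w.sum()
    return np.convolve(env, w, mode="same")


def pink_noise(
    n_samples: int,
    rng: np.random.Generator,
    exponent: float = 1.0,
    fs: float = FS,
) -> np.ndarray:
    """1/f^exponent noise synthesized in the frequency domain, unit SD."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def _smooth_noise(n_samples: int, rng: np.random.Generator, cutoff_hz: float = 3.0) -> np.ndarray:
    """Independent low-frequency process (for band modulation / lip mixing)."""
    from scipy import signal

    x = rng.standard_normal(n_samples)
    b, a = signal.butter(2, cutoff_hz / (FS / 2))
    y = signal.filtfilt(b, a, x)
    return (y - y.mean()) / y.std()


def _z(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _shift_ms(x: np.ndarray, shift_ms: float, fs: float = FS) -> np.ndarray:
    """Shift a series so the output *leads* the input by ``shift_ms``
    (circular shift keeps stationarity for correlation calibration)."""
    k = int(round(shift_ms / 1000.0 * fs))
    return np.roll(x, -k)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _make_features(
    n_samples: int, truth: SyntheticTruth, rng: np.random.Generator
) -> FeatureSet:
    base = syllable_envelope(n_samples, rng)
    bands = np.empty((8, n_samples))
    for b in range(8):
        mod = 0.75 + 0.25 * _smooth_noise(n_samples, rng)
        bands[b] = np.maximum(base * mod, 0.0)
    spec = FeatureSet({"spectrogram": bands})
    onsets = _features.acoustic_onsets(spec)

    env = bands.mean(axis=0)
    e = _z(env)
    el = _z(_shift_ms(env, LIP_LEAD_MS))
    # the independent part of the lip signal shares the syllable-rhythm
    # bandwidth of real mouth openings (keeps deconvolution well-posed)
    indep = _z(syllable_envelope(n_samples, rng))
    # orthogonalize the independent process against both envelope versions
    # so the realized lag-zero correlation is set by the mixing weights alone
    for ref in (e, el):
        indep = indep - (indep @ ref) / (ref @ ref) * ref
    indep = _z(indep)
    c0 = float(np.corrcoef(e, el)[0, 1])
    rho = truth.av_correlation
    if abs(c0) > 1e-6 and abs(rho) <= abs(c0):
        # lip = lead-shifted envelope diluted to hit the target correlation
        w = rho / c0
        mix = w * el + np.sqrt(max(1.0 - w * w, 0.0)) * indep
    else:
        # lead autocorrelation caps the reachable correlation via the
        # shifted path alone; mix the instantaneous envelope directly and
        # keep the lead dynamics in the residual
        el_orth = el - (el @ e) / (e @ e) * e
        sd = el_orth.std()
        el_orth = el_orth / sd if sd > 0 else indep
        mix = rho * e + np.sqrt(max(1.0 - rho * rho, 0.0)) * el_orth
    lip = 3.0 + _z(mix)  # positive-mean area-like series (a.u.)
    return FeatureSet({"spectrogram": bands, "onsets": onsets.features["onsets"], "lip": lip[None, :]})


def _channel_grid(n_channels: int, spacing_mm: float = GRID_SPACING_MM) -> np.ndarray:
    side = int(np.ceil(n_channels ** (1.0 / 3.0)))
    pts = []
    for i in range(side):
        for j in range(side):
            for k in range(side):
                pts.append((i, j, k))
                if len(pts) == n_channels:
                    return np.asarray(pts, dtype=float) * spacing_mm
    return np.asarray(pts[:n_channels], dtype=float) * spacing_mm


def _gain_profiles(coords: np.ndarray, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Two spatial blobs: an 'acoustic' region (spectrogram + onsets) and a
    'visual' region (lip), Gaussian falloff from opposite corners."""
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    span = np.linalg.norm(hi - lo) or 1.0
    d_ac = np.linalg.norm(coords - lo, axis=1)
    d_vis = np.linalg.norm(coords - hi, axis=1)
    g_ac = 0.2 + np.exp(-0.5 * (d_ac / (0.45 * span)) ** 2)
    g_vis = 0.2 + np.exp(-0.5 * (d_vis / (0.45 * span)) ** 2)
    return {"spectrogram": g_ac, "onsets": g_ac, "lip": g_vis}


def _convolve_lagged(x: np.ndarray, kernel: np.ndarray, lag_ms: np.ndarray, fs: float = FS) -> np.ndarray:
    """y[t] = sum_lag kernel[lag] * x[t - lag], lags in ms (may be negative)."""
    n = x.size
    y = np.zeros(n)
    lags_smp = np.round(lag_ms / 1000.0 * fs).astype(int)
    for k, lag in zip(kernel, lags_smp):
        if k == 0.0:
            continue
        if lag >= 0:
            y[lag:] += k * x[: n - lag] if lag else k * x
        else:
            y[:lag] += k * x[-lag:]
    return y


def noiseless_response(
    feats: FeatureSet,
    truth: SyntheticTruth,
    condition: str,
    channel_gains: dict[str, np.ndarray],
    subject_gain: float = 1.0,
) -> np.ndarray:
    """Deterministic part of the response: per channel, the gain-weighted
    sum of feature-kernel convolutions."""
    n_channels = next(iter(channel_gains.values())).size
    drive = {}
    for name, kern in truth.kernels.items():
        mat = feats.features[name]
        gain = truth.gain(condition, name)
        d = np.zeros(mat.shape[1])
        for b in range(mat.shape[0]):
            d += _convolve_lagged(mat[b], kern[b] * gain, truth.lag_ms)
        drive[name] = d
    resp = np.zeros((n_channels, feats.n_samples))
    for name, d in drive.items():
        resp += channel_gains[name][:, None] * d[None, :]
    return subject_gain * resp


def generate_dataset(
    n_subjects: int,
    n_channels: int,
    duration_s: float,
    truth: SyntheticTruth,
) -> SyntheticDataset:
    """Generate a full synthetic dataset (features, responses, behavior).

    Deterministic given ``truth.seed``; with ``truth.noise_sd = 0`` the
    responses equal the stored feature-kernel convolutions exactly.
    """
    if duration_s < 10:
        raise ValueError("duration_s must be >= 10")
    if n_channels < 1 or n_subjects < 1:
        raise ValueError("need at least one channel and one subject")
    active = np.any(
        np.vstack([np.abs(k).sum(axis=0) > 0 for k in truth.kernels.values()]), axis=0
    )
    lags_used = truth.lag_ms[active]
    if lags_used.size and (lags_used.min() < -100 or lags_used.max() > 600):
        raise ValueError("kernel support must lie within [-100, 600] ms")

    rng = np.random.default_rng(truth.seed)
    n_samples = int(round(duration_s * FS))
    conditions = list(truth.condition_gains)

    feats = {cond: _make_features(n_samples, truth, rng) for cond in conditions}

    coords = _channel_grid(n_channels)
    channel_gains = _gain_profiles(coords, rng)
    truth.channel_gains = channel_gains
    subject_gains = np.exp(0.2 * rng.standard_normal(n_subjects))
    truth.subject_gains = subject_gains
    subjects = [f"S{i:02d}" for i in range(n_subjects)]

    responses = {}
    for s_i, subj in enumerate(subjects):
        for cond in conditions:
            clean = noiseless_response(
                feats[cond], truth, cond, channel_gains, subject_gains[s_i]
            )
            if truth.noise_sd > 0:
                noise = np.vstack(
                    [
                        pink_noise(n_samples, rng, truth.noise_exponent)
                        for _ in range(n_channels)
                    ]
                )
                clean = clean + truth.noise_sd * noise
            responses[(subj, cond)] = NeuralResponse(clean, coords)

    # per-subject tracking metric implied by the truth: gain in the harder
    # condition scales how strongly the subject's response follows the stimulus
    rows = []
    for s_i, subj in enumerate(subjects):
        for cond in conditions:
            g = truth.gain(cond, "spectrogram")
            rows.append({"subject": subj, "condition": cond, "tracking": subject_gains[s_i] * g})
    tracking = pd.DataFrame(rows)
    behavior = generate_behavior(
        tracking,
        behavior_effect=truth.behavior_effect,
        subject_intercept_sd=truth.subject_intercept_sd,
        noise_df=truth.behavior_noise_df,
        seed=truth.seed + 1,
    )
    return SyntheticDataset(features=feats, responses=responses, behavior=behavior, truth=truth)


# ---------------------------------------------------------------------------
# Behavior generation
# ---------------------------------------------------------------------------

def generate_behavior(
    tracking: pd.DataFrame,
    behavior_effect: float,
    subject_intercept_sd: float,
    noise_df: float,
    seed: int,
    noise_scale: float | None = None,
) -> pd.DataFrame:
    """Behavioral scores from a tracking metric with subject random
    intercepts and Student-t noise.

    ``tracking`` needs columns ``subject, condition, tracking`` with >= 2
    subjects.  On the standardized scale each measure is
    ``b * z(tracking) + u_subject + e`` with ``u ~ N(0, tau^2)`` and
    Student-t(df) noise scaled so the total variance is ~1 (making ``b``
    the standardized slope).  Comprehension maps to percent (clipped to
    [0, 100]); difficulty (reversed sign) and engagement map to a 1-5
    rating scale.
    """
    if noise_df <= 0:
        raise ValueError("noise_df must be positive")
    subjects = tracking["subject"].unique()
    if subjects.size < 2:
        raise ValueError("need >= 2 subjects")
    rng = np.random.default_rng(seed)

    z = tracking["tracking"].to_numpy(dtype=float)
    z = (z - z.mean()) / z.std() if z.std() > 0 else np.zeros_like(z)
    subj_idx = tracking["subject"].map({s: i for i, s in enumerate(subjects)}).to_numpy()

    tau2 = subject_intercept_sd**2
    t_var = noise_df / (noise_df - 2.0) if noise_df > 2 else 2.0
    if noise_scale is None:
        # calibrate the residual so the standardized-score variance is ~1,
        # making behavior_effect the standardized slope
        resid_var = max(1.0 - behavior_effect**2 - tau2, 0.05)
        e_scale = np.sqrt(resid_var / t_var)
    else:
        e_scale = float(noise_scale)

    out = tracking[["subject", "condition"]].copy()
    specs = {
        "comprehension": (behavior_effect, 70.0, 15.0, 0.0, 100.0),
        "difficulty": (-behavior_effect, 3.0, 0.8, 1.0, 5.0),
        "engagement": (behavior_effect, 3.5, 0.7, 1.0, 5.0),
    }
    for name, (b, center, scale, lo, hi) in specs.items():
        u = subject_intercept_sd * rng.standard_normal(subjects.size)
        e = e_scale * rng.standard_t(noise_df, size=z.size) if e_scale > 0 else 0.0
        score_std = b * z + u[subj_idx] + e
        out[name] = np.clip(center + scale * score_std, lo, hi)
    out["tracking"] = tracking["tracking"].to_numpy()
    return out
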