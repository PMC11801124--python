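"""Core data containers shared across the analysis stages.

The pipeline operates on continuous stimulus features and neural response
time series that share a common 100 Hz sampling rate: an 8-band gammatone
spectrogram, 8-band acoustic onsets, and a 1-D lip-aperture series on the
stimulus side; a channels x samples array with 3-D channel coordinates (mm)
on the response side.  Behavioral data live in a plain pandas DataFrame with
one row per subject x condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: sampling rate (Hz) every feature and response series is expected to share
FS = 100.0

#: canonical feature names
FEATURE_NAMES = ("spectrogram", "onsets", "lip")


@dataclass
class FeatureSet:
    """Named stimulus features on a shared 100 Hz time axis.

    Parameters
    ----------
    features : dict of str -> ndarray
        Each value is a ``(n_bands, n_samples)`` array (a.u.).  The
        spectrogram and onset features carry 8 bands, the lip aperture 1.
    fs : float
        Sampling rate in Hz; 100 Hz throughout the pipeline.
    """

    features: dict[str, np.ndarray]
    fs: float = FS

    def __post_init__(self) -> None:
        clean = {}
        n_samples = None
        for name, arr in self.features.items():
            arr = np.atleast_2d(np.asarray(arr, dtype=float))
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"feature {name!r} contains non-finite values")
            if n_samples is None:
                n_samples = arr.shape[1]
            elif arr.shape[1] != n_samples:
                raise ValueError(
                    f"feature {name!r} has {arr.shape[1]} samples, expected {n_samples}"
                )
            clean[name] = arr
        self.features = clean

    @property
    def n_samples(self) -> int:
        return next(iter(self.features.values())).shape[1]

    @property
    def n_bands_total(self) -> int:
        return sum(a.shape[0] for a in self.features.values())

    def band_matrix(self, names: list[str] | None = None) -> np.ndarray:
        """Stack the selected features into one ``(bands, samples)`` matrix."""
        names = list(self.features) if names is None else names
        return np.vstack([self.features[n] for n in names])

    def subset(self, names: list[str]) -> "FeatureSet":
        return FeatureSet({n: self.features[n] for n in names}, fs=self.fs)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class NeuralResponse:
    """Multichannel neural time series at 100 Hz with channel positions.

    ``orientation_groups``, if given, partitions the channels into disjoint
    triplets of free-orientation dipoles belonging to one source location;
    it is required for the vector-norm collapse in TRF post-processing.
    """

    data: np.ndarray  # (n_channels, n_samples)
    coords: np.ndarray  # (n_channels, 3) in mm
    fs: float = FS
    orientation_groups: np.ndarray | None = None  # (n_sources, 3) channel idx

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.data.shape[0], 3):
            raise ValueError(
                "coords must be (n_channels, 3); got "
                f"{self.coords.shape} for {self.data.shape[0]} channels"
            )
        if self.orientation_groups is not None:
            g = np.asarray(self.orientation_groups, dtype=int)
            if g.ndim != 2 or g.shape[1] != 3:
                raise ValueError("orientation_groups must be (n_sources, 3)")
            flat = g.ravel()
            if len(np.unique(flat)) != flat.size or flat.max() >= self.data.shape[0]:
                raise ValueError("orientation_groups must be disjoint valid triplets")
            self.orientation_groups = g

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class FROI:
    """A functional region of interest: channel indices selected from an
    accuracy map by a percentile threshold."""

    channel_indices: np.ndarray
    percentile: float
    defining_model: str = ""
    defining_condition: str = ""

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.channel_indices, dtype=int))
        if idx.size == 0:
            raise ValueError("fROI is empty")
        self.channel_indices = idx

    def union(self, other: "FROI") -> "FROI":
        """Set union of two fROIs (the combined audiovisual fROI)."""
        return FROI(
            np.union1d(self.channel_indices, other.channel_indices),
            percentile=self.percentile,
            defining_model=f"{self.defining_model}+{other.defining_model}",
            defining_condition=self.defining_condition,
        )

    def __len__(self) -> int:
        return len(self.channel_indices)


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic dataset.

    kernels maps feature name to a ``(n_bands, n_lags)`` lag kernel on the
    ``lag_ms`` axis; condition gains multiply the kernels per condition
    (scalar, or per-feature dict).  Channel/subject gain profiles are filled
    in by the generator and recorded here so noiseless responses can be
    reconstructed exactly.
    """

    kernels: dict[str, np.ndarray]
    lag_ms: np.ndarray
    condition_gains: dict[str, float | dict[str, float]]
    noise_sd: float = 1.0
    noise_exponent: float = 1.0
    av_correlation: float = 0.3
    behavior_effect: float = 0.3
    subject_intercept_sd: float = 0.3
    behavior_noise_df: float = 5.0
    seed: int = 0
    # filled in by the generator
    channel_gains: dict[str, np.ndarray] = field(default_factory=dict)
    subject_gains: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lag_ms = np.asarray(self.lag_ms, dtype=float)
        self.kernels = {
            k: np.atleast_2d(np.asarray(v, dtype=float)) for k, v in self.kernels.items()
        }
        for name, k in self.kernels.items():
            if k.shape[1] != self.lag_ms.size:
                raise ValueError(f"kernel {name!r} does not match the lag axis")
        for cond, g in self.condition_gains.items():
            vals = list(g.values()) if isinstance(g, dict) else [g]
            if any(v <= 0 for v in vals):
                raise ValueError(f"condition gain for {cond!r} must be > 0")

    def gain(self, condition: str, feature: str) -> float:
        g = self.condition_gains[condition]
        return float(g[feature]) if isinstance(g, dict) else float(g)


@dataclass
class SyntheticDataset:
    """A generated dataset: per-condition features, per-subject/condition
    responses, a behavior table, and the truth that produced them."""

    features: dict[str, FeatureSet]  # condition -> FeatureSet
    responses: dict[tuple[str, str], NeuralResponse]  # (subject, condition)
    behavior: "object"  # pandas DataFrame (subject, condition, measures)
    truth: SyntheticTruth

    @property
    def subjects(self) -> list[str]:
        return sorted({s for s, _ in self.responses})

    @property
    def conditions(self) -> list[str]:
        return list(self.features)
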