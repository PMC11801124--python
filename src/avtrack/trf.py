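"""Multivariate temporal response functions estimated by boosting.

The forward model predicts a continuous neural response as a convolution of
stimulus features with feature-specific lag kernels (TRFs):

    y_hat[t] = sum_i sum_tau h[i, tau] * x[i, t - tau]

Kernels are expanded in a basis of 50 ms Hamming windows tiling the lag
window (default -100..600 ms) and estimated per channel by greedy
coordinate-wise boosting: the single (feature, window, sign) increment that
most reduces the training l2 error is applied repeatedly, with early
stopping when the validation l2 error stops improving.  A fourfold nested
cross-validation (two training folds, one validation fold, one test fold;
contiguous time blocks) yields per-channel prediction accuracies as the
Fisher-z average over test folds of the Pearson correlation between
predicted and observed response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .containers import FS, FeatureSet, NeuralResponse

__all__ = [
    "LaggedDesign",
    "build_design",
    "BoostingTRF",
    "TRFResults",
    "prediction_accuracy",
    "fisher_average",
    "postprocess_trf",
    "detect_peaks",
]


# ---------------------------------------------------------------------------
# Correlation helpers
# ---------------------------------------------------------------------------

def prediction_accuracy(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Pearson correlation between predicted and observed response.

    Raises ``ValueError`` when either series has zero variance, where the
    correlation is undefined.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size < 3:
        raise ValueError("series must have equal length >= 3")
    if not (np.all(np.isfinite(predicted)) and np.all(np.isfinite(observed))):
        raise ValueError("series must be finite")
    p = predicted - predicted.mean()
    o = observed - observed.mean()
    denom = np.sqrt((p @ p) * (o @ o))
    if denom == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.clip((p @ o) / denom, -1.0, 1.0))


def fisher_average(values) -> float:
    """Average correlation coefficients via the Fisher z transform:
    ``tanh(mean(atanh(r)))``.  Rejects |r| = 1 (infinite z)."""
    values = np.asarray(values, dtype=float)
    if np.any(np.abs(values) >= 1):
        raise ValueError("|r| = 1 cannot be Fisher-averaged")
    return float(np.tanh(np.mean(np.arctanh(values))))


def _fisher_average_clipped(values: np.ndarray) -> float:
    """Fisher average tolerant of |r| == 1 (clipped), for internal fold
    aggregation where noiseless fits can hit r = 1 exactly."""
    v = np.clip(np.asarray(values, dtype=float), -1 + 1e-12, 1 - 1e-12)
    return float(np.tanh(np.mean(np.arctanh(v))))


# ---------------------------------------------------------------------------
# Lagged design
# ---------------------------------------------------------------------------

@dataclass
class LaggedDesign:
    """Time-lagged design matrix over a Hamming-window kernel basis."""

    X: np.ndarray  # (n_samples, n_cols)
    feature_names: list[str]
    n_bands: dict[str, int]
    col_feature: np.ndarray  # (n_cols,) feature index
    col_band: np.ndarray  # (n_cols,) band index within feature
    col_window: np.ndarray  # (n_cols,) basis window index
    lag_ms: np.ndarray  # (n_lags,)
    basis: np.ndarray  # (n_lags, n_windows)
    tmin_ms: float
    tmax_ms: float
    basis_ms: float
    fs: float

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]

    @property
    def n_windows(self) -> int:
        return self.basis.shape[1]

    def kernels_from_coefs(self, coefs: np.ndarray) -> dict[str, np.ndarray]:
        """Map basis coefficients ``(..., n_cols)`` to per-feature lag
        kernels ``(n_bands, ..., n_lags)``."""
        coefs = np.asarray(coefs, dtype=float)
        out = {}
        for fi, name in enumerate(self.feature_names):
            bands = []
            for b in range(self.n_bands[name]):
                sel = (self.col_feature == fi) & (self.col_band == b)
                cw = coefs[..., sel]  # (..., n_windows)
                bands.append(cw @ self.basis.T)  # (..., n_lags)
            out[name] = np.stack(bands, axis=0)
        return out


def _shift(x: np.ndarray, k: int) -> np.ndarray:
    """Shift a 1-D series right by k samples (k may be negative), zero-
    padding beyond the record."""
    out = np.zeros_like(x)
    if k == 0:
        out[:] = x
    elif k > 0:
        out[k:] = x[:-k]
    else:
        out[:k] = x[-k:]
    return out


def build_design(
    features: FeatureSet,
    tmin_ms: float = -100.0,
    tmax_ms: float = 600.0,
    basis_ms: float = 50.0,
    spacing_ms: float | None = None,
) -> LaggedDesign:
    """Build the lagged design: one column per (band, basis window).

    Basis windows are Hamming windows of length ``basis_ms`` covering
    ``[tmin_ms, tmax_ms)``, spaced ``spacing_ms`` apart (default half the
    window, i.e. overlapping — a Hamming-smoothed kernel expansion that
    can represent smooth TRFs; ``spacing_ms = basis_ms`` gives the
    non-overlapping tiling with 14 windows per band at the defaults).
    Each column is the band convolved with one shifted window.
    """
    if tmin_ms >= tmax_ms:
        raise ValueError("tmin must be < tmax")
    span = tmax_ms - tmin_ms
    n_tiles = span / basis_ms
    if abs(n_tiles - round(n_tiles)) > 1e-9:
        raise ValueError(f"basis ({basis_ms} ms) must divide the lag window ({span} ms)")

    fs = features.fs
    smp_ms = 1000.0 / fs
    basis_smp = int(round(basis_ms / smp_ms))
    if spacing_ms is None:
        stride = max(basis_smp // 2, 1)
    else:
        stride = max(int(round(spacing_ms / smp_ms)), 1)
    tmin_smp = int(round(tmin_ms / smp_ms))
    n_lags = int(round(n_tiles)) * basis_smp
    lag_ms = (tmin_smp + np.arange(n_lags)) * smp_ms
    ham = np.hamming(basis_smp)

    starts = list(range(0, n_lags - basis_smp + 1, stride))
    if starts[-1] != n_lags - basis_smp:
        starts.append(n_lags - basis_smp)  # cover the tail of the window
    n_windows = len(starts)
    basis = np.zeros((n_lags, n_windows))
    for j, s0 in enumerate(starts):
        basis[s0 : s0 + basis_smp, j] = ham

    cols, col_feature, col_band, col_window = [], [], [], []
    n_bands = {}
    for fi, (name, mat) in enumerate(features.features.items()):
        n_bands[name] = mat.shape[0]
        for b in range(mat.shape[0]):
            x = mat[b]
            for j, s0 in enumerate(starts):
                lag0 = tmin_smp + s0
                col = np.zeros_like(x)
                for s in range(basis_smp):
                    col += ham[s] * _shift(x, lag0 + s)
                cols.append(col)
                col_feature.append(fi)
                col_band.append(b)
                col_window.append(j)

    X = np.asfortranarray(np.column_stack(cols))
    return LaggedDesign(
        X=X,
        feature_names=list(features.features),
        n_bands=n_bands,
        col_feature=np.asarray(col_feature),
        col_band=np.asarray(col_band),
        col_window=np.asarray(col_window),
        lag_ms=lag_ms,
        basis=basis,
        tmin_ms=tmin_ms,
        tmax_ms=tmax_ms,
        basis_ms=basis_ms,
        fs=fs,
    )


# ---------------------------------------------------------------------------
# Boosting model / results
# ---------------------------------------------------------------------------

def time_folds(n_samples: int, n_folds: int) -> list[np.ndarray]:
    """Deterministic contiguous-in-time fold assignment."""
    return [np.asarray(f) for f in np.array_split(np.arange(n_samples), n_folds)]


class BoostingTRF:
    """Forward encoding model fit by boosting with nested cross-validation.

    Parameters
    ----------
    features : FeatureSet
        Stimulus features; each band is z-scored before lagging (bands with
        zero variance are left untouched so an all-zero feature stays zero).
    response : NeuralResponse
        Neural response; each channel is z-scored.
    tmin_ms, tmax_ms : float
        Kernel lag window, default -100..600 ms.
    basis_ms : float
        Hamming basis window length, default 50 ms.

    ``fit`` returns a :class:`TRFResults`.
    """

    def __init__(
        self,
        features: FeatureSet,
        response: NeuralResponse,
        tmin_ms: float = -100.0,
        tmax_ms: float = 600.0,
        basis_ms: float = 50.0,
        spacing_ms: float | None = None,
    ) -> None:
        if features.n_samples != response.n_samples:
            raise ValueError("features and response must have equal sample counts")
        if features.fs != response.fs:
            raise ValueError("features and response must share the sampling rate")
        self.features = features
        self.response = response
        self.tmin_ms = tmin_ms
        self.tmax_ms = tmax_ms
        self.basis_ms = basis_ms

        zfeat = {}
        self._feature_sd: dict[str, np.ndarray] = {}
        for name, mat in features.features.items():
            mat = mat.copy()
            mu = mat.mean(axis=1, keepdims=True)
            sd = mat.std(axis=1, keepdims=True)
            nz = sd[:, 0] > 0
            mat[nz] = (mat[nz] - mu[nz]) / sd[nz]
            zfeat[name] = mat
            self._feature_sd[name] = np.where(sd[:, 0] > 0, sd[:, 0], 1.0)
        self._zfeatures = FeatureSet(zfeat, fs=features.fs)
        y = response.data
        sd = y.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        self._response_sd = sd[:, 0]
        self._zresponse = (y - y.mean(axis=1, keepdims=True)) / sd
        self.design = build_design(self._zfeatures, tmin_ms, tmax_ms, basis_ms, spacing_ms)
        if response.n_samples < 10 * self.design.n_windows:
            raise ValueError(
                f"underdetermined: {response.n_samples} samples for "
                f"{self.design.n_windows} basis windows per band (need >= 10x)"
            )

    def fit(
        self,
        n_folds: int = 4,
        step: float = 0.005,
        patience: int = 10,
        max_steps: int = 50_000,
    ) -> "TRFResults":
        """Run per-channel boosting over all test folds.

        ``step`` is the coefficient increment in units of the (z-scored)
        response SD; ``patience`` the number of consecutive validation
        checks without improvement before stopping.
        """
        design, y = self.design, self._zresponse
        n_channels, n_samples = y.shape
        folds = time_folds(n_samples, n_folds)
        X = design.X
        n_cols = design.n_cols

        fold_coefs = np.zeros((n_channels, n_folds, n_cols))
        fold_r = np.zeros((n_channels, n_folds))

        for k in range(n_folds):
            test_idx = folds[k]
            val_idx = folds[(k + 1) % n_folds]
            train_mask = np.ones(n_samples, dtype=bool)
            train_mask[test_idx] = False
            train_mask[val_idx] = False
            tr_idx = np.flatnonzero(train_mask)

            Xtr = X[tr_idx]
            Xval = np.asfortranarray(X[val_idx])
            Xte = X[test_idx]
            G = Xtr.T @ Xtr  # shared across channels
            norms = np.diag(G).copy()

            for ch in range(n_channels):
                coefs = _boost_channel(
                    Xtr, G, norms, Xval, y[ch, tr_idx], y[ch, val_idx],
                    step=step, patience=patience, max_steps=max_steps,
                )
                fold_coefs[ch, k] = coefs
                pred = Xte @ coefs
                try:
                    fold_r[ch, k] = prediction_accuracy(pred, y[ch, test_idx])
                except ValueError:
                    fold_r[ch, k] = 0.0  # constant prediction: no tracking

        coefs_mean = fold_coefs.mean(axis=1)  # (n_channels, n_cols)
        accuracies = np.array([_fisher_average_clipped(fold_r[ch]) for ch in range(n_channels)])
        kernels = design.kernels_from_coefs(coefs_mean)  # name -> (bands, ch, lags)
        # back to raw units: the fit runs on z-scored features and response,
        # so h_raw = h_z * sd(y) / sd(x_band); this keeps condition gains
        # visible in the kernels while accuracies stay scale-invariant
        for name, v in kernels.items():
            kernels[name] = (
                v * self._response_sd[None, :, None] / self._feature_sd[name][:, None, None]
            )
        return TRFResults(
            kernels=kernels,
            lag_ms=design.lag_ms,
            basis_ms=self.basis_ms,
            accuracies=accuracies,
            fold_accuracies=fold_r,
            coefs=coefs_mean,
            design=design,
            coords=self.response.coords,
            orientation_groups=self.response.orientation_groups,
            n_folds=n_folds,
            step=step,
            patience=patience,
        )


def _boost_channel(
    Xtr, G, norms, Xval, ytr, yval, *, step, patience, max_steps
) -> np.ndarray:
    """Greedy coordinate boosting for one channel and one fold.

    Maintains the training gradient ``g = Xtr' (ytr - Xtr c)`` and the
    validation prediction incrementally; every accepted step strictly
    reduces the training l2 error.  Returns the coefficient vector at the
    validation optimum.
    """
    n_cols = Xtr.shape[1]
    c = np.zeros(n_cols)
    g = Xtr.T @ ytr
    pred_val = np.zeros(len(yval))
    best_val = float(yval @ yval)
    best_c = c.copy()
    bad = 0
    s2 = step * step

    for _ in range(max_steps):
        # l2-error change for the best signed increment on each column
        delta = s2 * norms - 2.0 * step * np.abs(g)
        j = int(np.argmin(delta))
        if delta[j] >= -1e-15:
            break  # no step can reduce training error
        sgn = 1.0 if g[j] > 0 else -1.0
        c[j] += sgn * step
        g -= sgn * step * G[:, j]
        pred_val += sgn * step * Xval[:, j]
        resid = yval - pred_val
        val = float(resid @ resid)
        if val < best_val:
            best_val = val
            best_c = c.copy()
            bad = 0
        else:
            bad += 1
            if bad >= patience:
                break
    return best_c


@dataclass
class TRFResults:
    """Fitted TRFs and cross-validated prediction accuracies.

    ``kernels`` maps feature name to a ``(n_bands, n_channels, n_lags)``
    array on the ``lag_ms`` axis; ``accuracies`` holds the per-channel
    Fisher-z-averaged test-fold Pearson r.
    """

    kernels: dict[str, np.ndarray]
    lag_ms: np.ndarray
    basis_ms: float
    accuracies: np.ndarray
    fold_accuracies: np.ndarray
    coefs: np.ndarray
    design: LaggedDesign | None
    coords: np.ndarray
    orientation_groups: np.ndarray | None
    n_folds: int
    step: float
    patience: float
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.accuracies.size

    def band_averaged_kernels(self) -> dict[str, np.ndarray]:
        """Kernels averaged over the frequency (band) dimension, as used
        for TRF visualization and peak analysis: name -> (channels, lags)."""
        return {k: v.mean(axis=0) for k, v in self.kernels.items()}

    def predict(self) -> np.ndarray:
        """In-sample prediction (z-scored units) from the averaged kernels."""
        if self.design is None:
            raise ValueError("results were detached from their design")
        return self.coefs @ self.design.X.T

    def summary(self) -> pd.DataFrame:
        rows = []
        for ch in range(self.n_channels):
            row = {"channel": ch, "accuracy_r": self.accuracies[ch]}
            for k in range(self.n_folds):
                row[f"fold{k}_r"] = self.fold_accuracies[ch, k]
            rows.append(row)
        return pd.DataFrame(rows)

    def plot_kernels(self, feature: str | None = None, ax=None, channels=None):
        from .plotting import plot_trf_kernels

        return plot_trf_kernels(self, feature=feature, ax=ax, channels=channels)

    def plot_accuracies(self, froi=None, ax=None):
        from .plotting import plot_accuracy_map

        return plot_accuracy_map(self, froi=froi, ax=ax)

    def __repr__(self) -> str:
        feats = ", ".join(self.kernels)
        return (
            f"<TRFResults: features [{feats}], {self.n_channels} channels, "
            f"lags {self.lag_ms[0]:g}..{self.lag_ms[-1]:g} ms, "
            f"mean r = {np.mean(self.accuracies):.3f}>"
        )


# ---------------------------------------------------------------------------
# Post-processing: spatial smoothing, orientation norm, peak detection
# ---------------------------------------------------------------------------

def postprocess_trf(
    results: TRFResults,
    smoothing_sd_mm: float = 5.0,
    collapse_orientations: bool = False,
    temporal_window_ms: float | None = None,
) -> TRFResults:
    """Spatially smooth kernels and optionally collapse orientation triplets.

    Kernels are smoothed across channels with Gaussian weights of SD
    ``smoothing_sd_mm`` on Euclidean channel distance (weights truncated at
    4 SD, rows normalized).  With ``collapse_orientations``, the lag-wise
    Euclidean vector norm reduces each free-orientation triplet to one
    kernel per source; accuracies are then Fisher-z-averaged within the
    triplet.  ``temporal_window_ms`` applies an optional Hamming smoothing
    over the lag axis (display only in typical use).

    Smoothing applies to kernels only; accuracies are never smoothed.
    """
    coords = results.coords
    kernels = {k: v.copy() for k, v in results.kernels.items()}

    if smoothing_sd_mm and smoothing_sd_mm > 0:
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        W = np.exp(-0.5 * (d / smoothing_sd_mm) ** 2)
        W[d > 4 * smoothing_sd_mm] = 0.0
        W /= W.sum(axis=1, keepdims=True)
        kernels = {k: np.einsum("ij,bjl->bil", W, v) for k, v in kernels.items()}

    accuracies = results.accuracies
    out_coords = coords
    groups = results.orientation_groups
    if collapse_orientations:
        if groups is None:
            raise ValueError("orientation groups are required for the vector norm")
        collapsed = {}
        for name, v in kernels.items():
            collapsed[name] = np.stack(
                [np.linalg.norm(v[:, trip, :], axis=1) for trip in groups], axis=1
            )
        kernels = collapsed
        accuracies = np.array(
            [_fisher_average_clipped(results.accuracies[trip]) for trip in groups]
        )
        out_coords = np.stack([coords[trip].mean(axis=0) for trip in groups])
        groups = None

    if temporal_window_ms:
        n = int(round(temporal_window_ms * results.design.fs / 1000.0)) if results.design else int(round(temporal_window_ms / 10.0))
        win = np.hamming(max(n, 1))
        win /= win.sum()
        kernels = {
            k: np.apply_along_axis(lambda m: np.convolve(m, win, mode="same"), -1, v)
            for k, v in kernels.items()
        }

    return TRFResults(
        kernels=kernels,
        lag_ms=results.lag_ms,
        basis_ms=results.basis_ms,
        accuracies=accuracies,
        fold_accuracies=results.fold_accuracies,
        coefs=results.coefs,
        design=results.design,
        coords=out_coords,
        orientation_groups=groups,
        n_folds=results.n_folds,
        step=results.step,
        patience=results.patience,
        meta={**results.meta, "smoothed_sd_mm": smoothing_sd_mm},
    )


def detect_peaks(
    lag_ms: np.ndarray,
    magnitude: np.ndarray,
    window_ms: tuple[float, float] = (-50.0, 550.0),
) -> list[tuple[float, float]]:
    """Local maxima of a TRF magnitude series, sorted by latency.

    The search is restricted to ``window_ms`` (default -50..550 ms) to
    suppress edge-of-window regression artifacts.  Returns a list of
    ``(latency_ms, magnitude)``; an empty list if no interior peak exists.
    """
    lag_ms = np.asarray(lag_ms, dtype=float)
    magnitude = np.asarray(magnitude, dtype=float)
    sel = (lag_ms >= window_ms[0]) & (lag_ms <= window_ms[1])
    lags, mags = lag_ms[sel], magnitude[sel]
    if lags.size < 3:
        return []
    idx, _ = _signal.find_peaks(mags)
    return [(float(lags[i]), float(mags[i])) for i in idx]
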