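"""Plotting helpers for fitted TRFs and posterior summaries.

Thin matplotlib wrappers; every figure can also be built directly from
the arrays on the results objects.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_trf_kernels", "plot_accuracy_map", "plot_posterior"]


def plot_trf_kernels(results, feature: str | None = None, ax=None, channels=None):
    """Band-averaged TRF kernels over the lag axis, one line per channel."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    names = [feature] if feature else list(results.kernels)
    for name in names:
        kern = results.band_averaged_kernels()[name]
        sel = channels if channels is not None else range(kern.shape[0])
        for ch in sel:
            ax.plot(results.lag_ms, kern[ch], alpha=0.7,
                    label=f"{name} ch{ch}" if len(names) > 1 else f"ch{ch}")
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_xlabel("lag (ms)")
    ax.set_ylabel("TRF amplitude (a.u.)")
    ax.set_title(", ".join(names))
    if results.n_channels <= 8:
        ax.legend(fontsize=7)
    return ax


def plot_accuracy_map(results, froi=None, ax=None):
    """Per-channel prediction accuracies, optionally marking an fROI."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    idx = np.arange(results.n_channels)
    ax.bar(idx, results.accuracies, color="0.7")
    if froi is not None:
        ax.bar(froi.channel_indices, results.accuracies[froi.channel_indices],
               color="C1", label=f"fROI (p{froi.percentile:g})")
        ax.legend(fontsize=8)
    ax.set_xlabel("channel")
    ax.set_ylabel("prediction accuracy r")
    return ax


def plot_posterior(results, ax=None, truth: float | None = None):
    """Posterior of the standardized slope with the 89% CI shaded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    draws = results.b_draws
    ax.hist(draws, bins=60, density=True, color="0.8")
    lo, hi = results.ci_89
    ax.axvspan(lo, hi, color="C0", alpha=0.2, label="89% CI")
    ax.axvline(results.b_mean, color="C0")
    ax.axvline(0.0, color="k", lw=0.8, ls="--")
    if truth is not None:
        ax.axvline(truth, color="C3", ls=":", label="truth")
    ax.set_xlabel("standardized slope b")
    ax.set_ylabel("posterior density")
    ax.legend(fontsize=8)
    return ax
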