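"""Functional ROIs and the unique contribution of lip movements.

An fROI is the set of channels whose prediction accuracy reaches the 90th
percentile (by default) of the whole-brain accuracy map, typically taken
from the harder (multispeaker) condition.  The audiovisual fROI is the
union of the acoustic and lip fROIs.  The unique contribution of lip
movements is the percentage change of the fROI-averaged accuracy of the
combined acoustic + lip model over the acoustic-only baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import FROI
from .trf import fisher_average

__all__ = [
    "define_froi",
    "fisher_average",
    "froi_average_accuracy",
    "unique_contribution",
    "contribution_table",
    "bimodality_coefficient",
    "BIMODALITY_THRESHOLD",
]

#: BC above this value indicates a bimodal sample (uniform-distribution benchmark)
BIMODALITY_THRESHOLD = 5.0 / 9.0


def define_froi(
    accuracy_map: np.ndarray,
    percentile: float = 90.0,
    union_with: FROI | None = None,
    defining_model: str = "",
    defining_condition: str = "",
) -> FROI:
    """Channels at or above the given percentile of an accuracy map.

    The percentile is computed with linear interpolation and the threshold
    applied inclusively (``>=``), so an all-equal map selects every
    channel.  ``union_with`` forms the set union with an existing fROI
    (e.g. the combined audiovisual fROI).
    """
    accuracy_map = np.asarray(accuracy_map, dtype=float)
    if not np.all(np.isfinite(accuracy_map)):
        raise ValueError("accuracy map must be finite")
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    thresh = np.percentile(accuracy_map, percentile)
    idx = np.flatnonzero(accuracy_map >= thresh)
    froi = FROI(
        idx,
        percentile=percentile,
        defining_model=defining_model,
        defining_condition=defining_condition,
    )
    if union_with is not None:
        froi = froi.union(union_with)
        froi.defining_model = defining_model or froi.defining_model
    return froi


def froi_average_accuracy(accuracy_map: np.ndarray, froi: FROI) -> float:
    """Fisher-z average of the per-channel accuracies inside an fROI."""
    vals = np.asarray(accuracy_map, dtype=float)[froi.channel_indices]
    return fisher_average(vals)


def unique_contribution(
    r_acoustic: float,
    r_combined: float,
    baseline_floor: float = 0.01,
) -> tuple[float, bool]:
    """Percentage change of the combined over the acoustic-only model:
    ``100 * (r_combined - r_acoustic) / r_acoustic``.

    Returns ``(contribution_pct, stable)``.  Baselines below
    ``baseline_floor`` are flagged unstable (the ratio explodes near
    zero); non-positive baselines are undefined and return ``nan`` with a
    warning.
    """
    if r_acoustic <= 0:
        warnings.warn(
            "non-positive baseline accuracy: unique contribution undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan"), False
    pct = 100.0 * (r_combined - r_acoustic) / r_acoustic
    return pct, r_acoustic >= baseline_floor


def contribution_table(
    acoustic: pd.DataFrame,
    combined: pd.DataFrame,
    baseline_floor: float = 0.01,
    drop_undefined: bool = True,
) -> pd.DataFrame:
    """Per-subject, per-condition unique-contribution table.

    Both inputs need columns ``subject, condition, r`` holding the
    fROI-averaged accuracies of the acoustic and combined models.  Rows
    with undefined contribution (non-positive baseline) are dropped by
    default or retained as NaN with ``drop_undefined=False``.
    """
    merged = acoustic.merge(
        combined, on=["subject", "condition"], suffixes=("_acoustic", "_combined")
    )
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for _, rec in merged.iterrows():
            pct, stable = unique_contribution(
                rec["r_acoustic"], rec["r_combined"], baseline_floor
            )
            rows.append(
                {
                    "subject": rec["subject"],
                    "condition": rec["condition"],
                    "r_acoustic": rec["r_acoustic"],
                    "r_combined": rec["r_combined"],
                    "contribution_pct": pct,
                    "stable": stable,
                }
            )
    out = pd.DataFrame(rows)
    if drop_undefined:
        out = out.dropna(subset=["contribution_pct"]).reset_index(drop=True)
    return out


def bimodality_coefficient(values: np.ndarray) -> float:
    """Sample bimodality coefficient.

    ``BC = (g1^2 + 1) / (g2 + 3 (n-1)^2 / ((n-2)(n-3)))`` with bias-
    corrected sample skewness ``g1`` and excess kurtosis ``g2``.  A normal
    sample gives ~1/3, a uniform sample ~5/9 (0.5556); values above 5/9
    indicate bimodality.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 4:
        raise ValueError("bimodality coefficient needs n >= 4")
    if np.std(values) == 0:
        raise ValueError("zero variance sample")
    g1 = sps.skew(values, bias=False)
    g2 = sps.kurtosis(values, bias=False)  # excess kurtosis, sample-corrected
    denom = g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    return float((g1 * g1 + 1.0) / denom)
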