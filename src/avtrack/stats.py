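"""Frequentist inference: TFCE cluster permutation tests and paired tests.

The permutation test compares two paired conditions element-wise (over time
points or channels) with a dependent-sample t map enhanced by threshold-
free cluster enhancement (TFCE): each element accumulates
``sum_h e(h)^E * h^H * dh`` over thresholds ``h``, where ``e(h)`` is the
extent of the supra-threshold cluster containing the element on the
adjacency graph.  Family-wise error control comes from the null
distribution of the maximum |TFCE| under within-subject sign flips.

The scalar paired test follows a Shapiro-Wilk gate: a dependent-sample t
test with Cohen's d when the differences look normal, otherwise a Wilcoxon
signed-rank test with the matched-pairs rank-biserial correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy import stats as sps
from scipy.sparse.csgraph import connected_components

__all__ = [
    "chain_adjacency",
    "coordinate_adjacency",
    "tfce_enhance",
    "tfce_permutation_test",
    "paired_test",
    "StatResult",
]


# ---------------------------------------------------------------------------
# Adjacency builders
# ---------------------------------------------------------------------------

def chain_adjacency(n: int) -> sparse.csr_matrix:
    """Nearest-neighbor adjacency for a 1-D (temporal) element axis."""
    i = np.arange(n - 1)
    rows = np.concatenate([i, i + 1])
    cols = np.concatenate([i + 1, i])
    return sparse.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))


def coordinate_adjacency(coords: np.ndarray, max_dist_mm: float) -> sparse.csr_matrix:
    """Spatial adjacency: channels within ``max_dist_mm`` of each other
    (typically 1.5x the source-grid spacing)."""
    coords = np.asarray(coords, dtype=float)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    adj = (d > 0) & (d <= max_dist_mm)
    return sparse.csr_matrix(adj.astype(float))


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------

def _neighbors_list(adjacency: sparse.spmatrix, n: int) -> list[np.ndarray]:
    adj = sparse.csr_matrix(adjacency)
    return [adj.indices[adj.indptr[i] : adj.indptr[i + 1]] for i in range(n)]


def _is_chain(adjacency: sparse.spmatrix, n: int) -> bool:
    adj = sparse.coo_matrix(adjacency)
    off = np.abs(adj.row - adj.col)
    return adj.nnz == 2 * (n - 1) and np.all(off == 1)


def tfce_enhance(
    tmap: np.ndarray,
    adjacency: sparse.spmatrix,
    E: float = 0.5,
    H: float = 2.0,
    step: float = 0.1,
) -> np.ndarray:
    """TFCE enhancement of a signed statistic map.

    Positive and negative parts are enhanced separately on the same
    threshold grid ``h = step, 2*step, ...`` and recombined with their
    signs; the discretized integral is ``sum_h e(h)^E * h^H * step``.
    """
    tmap = np.asarray(tmap, dtype=float)
    n = tmap.size
    out = np.zeros(n)
    chain = _is_chain(adjacency, n)
    adj = sparse.csr_matrix(adjacency)
    for sign in (1.0, -1.0):
        vals = sign * tmap
        vmax = vals.max(initial=0.0)
        if vmax < step:
            continue
        n_steps = int(np.floor(vmax / step + 1e-12))
        for k in range(1, n_steps + 1):
            h = k * step
            mask = vals >= h
            if not mask.any():
                break
            if chain:
                # runs of consecutive supra-threshold elements
                lbl = np.cumsum(np.concatenate([[mask[0]], np.diff(mask.astype(int)) == 1]))
                lbl = lbl * mask  # 0 outside
                sizes = np.bincount(lbl)
                ext = sizes[lbl].astype(float)
                out[mask] += sign * ext[mask] ** E * h**H * step
            else:
                idx = np.flatnonzero(mask)
                sub = adj[np.ix_(idx, idx)]
                ncomp, labels = connected_components(sub, directed=False)
                sizes = np.bincount(labels)
                out[idx] += sign * sizes[labels].astype(float) ** E * h**H * step
    return out


@dataclass
class StatResult:
    """Result of a statistical comparison."""

    test: str
    statistic: float
    p_value: float
    effect_size: float
    effect_size_name: str
    p_map: np.ndarray | None = None
    tfce_map: np.ndarray | None = None
    t_map: np.ndarray | None = None
    clusters: list[dict] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def tfce_permutation_test(
    condition_a: np.ndarray,
    condition_b: np.ndarray,
    adjacency: sparse.spmatrix,
    n_perm: int = 10_000,
    E: float = 0.5,
    H: float = 2.0,
    step: float = 0.1,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> StatResult:
    """Paired TFCE permutation test over elements (time points or channels).

    ``condition_a``/``condition_b`` are ``(n_subjects, n_elements)``.  The
    element-wise dependent-sample t map is TFCE-enhanced; the null is the
    distribution of the maximum |TFCE| over random within-subject sign
    flips of the difference maps; element-wise p values are the rank of
    the observed |TFCE| against that null.  Significant elements are
    grouped into clusters on the adjacency graph, each reported with its
    extreme t value and the Cohen's d of the cluster-averaged differences.
    """
    a = np.asarray(condition_a, dtype=float)
    b = np.asarray(condition_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("conditions must be paired (n_subjects, n_elements) arrays")
    if n_perm < 100:
        import warnings

        warnings.warn("n_perm < 100 gives a very coarse p resolution", stacklevel=2)
    diff = a - b
    n_subj, n_elem = diff.shape

    t_obs = _paired_t_map(diff)
    tfce_obs = tfce_enhance(t_obs, adjacency, E=E, H=H, step=step)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    null_max = np.empty(n_perm)
    for p in range(n_perm):
        t_p = _paired_t_map(diff * signs[p][:, None])
        null_max[p] = np.max(np.abs(tfce_enhance(t_p, adjacency, E=E, H=H, step=step)))

    abs_obs = np.abs(tfce_obs)
    p_map = (1.0 + (null_max[None, :] >= abs_obs[:, None]).sum(axis=1)) / (n_perm + 1.0)

    clusters = _extract_clusters(p_map < alpha, adjacency, t_obs, diff, p_map)
    if clusters:
        best = max(clusters, key=lambda c: abs(c["t_extreme"]))
        stat, p_val, d = best["t_extreme"], best["p_min"], best["cohens_d"]
    else:
        i = int(np.argmin(p_map))
        stat, p_val = float(t_obs[i]), float(p_map[i])
        d = float(np.mean(diff[:, i]) / np.std(diff[:, i], ddof=1)) if np.std(diff[:, i], ddof=1) > 0 else 0.0
    return StatResult(
        test="tfce_permutation",
        statistic=stat,
        p_value=p_val,
        effect_size=d,
        effect_size_name="cohens_d",
        p_map=p_map,
        tfce_map=tfce_obs,
        t_map=t_obs,
        clusters=clusters,
        extra={"n_perm": n_perm, "E": E, "H": H, "step": step, "seed": seed},
    )


def _paired_t_map(diff: np.ndarray) -> np.ndarray:
    """Element-wise one-sample t statistic of difference maps."""
    n = diff.shape[0]
    m = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, m / (sd / np.sqrt(n)), 0.0)
    return t


def _extract_clusters(sig_mask, adjacency, t_obs, diff, p_map) -> list[dict]:
    if not sig_mask.any():
        return []
    idx = np.flatnonzero(sig_mask)
    sub = sparse.csr_matrix(adjacency)[np.ix_(idx, idx)]
    ncomp, labels = connected_components(sub, directed=False)
    clusters = []
    for c in range(ncomp):
        members = idx[labels == c]
        t_vals = t_obs[members]
        t_ext = t_vals[np.argmax(np.abs(t_vals))]
        avg = diff[:, members].mean(axis=1)  # averaged extent per subject
        sd = np.std(avg, ddof=1)
        clusters.append(
            {
                "elements": members,
                "t_extreme": float(t_ext),
                "p_min": float(p_map[members].min()),
                "cohens_d": float(avg.mean() / sd) if sd > 0 else 0.0,
            }
        )
    return clusters


# ---------------------------------------------------------------------------
# Scalar paired test
# ---------------------------------------------------------------------------

def paired_test(
    a: np.ndarray,
    b: np.ndarray,
    normality_alpha: float = 0.05,
) -> StatResult:
    """Paired comparison of two per-subject scalar samples.

    Differences are first checked for normality (Shapiro-Wilk).  Normal
    differences are tested with a dependent-sample t test and Cohen's
    ``d = mean(diff) / sd(diff)``; otherwise a Wilcoxon signed-rank test
    is used (exact for small samples) with the matched-pairs rank-biserial
    correlation ``r_C = (R+ - R-) / (R+ + R-)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 5:
        raise ValueError("need paired 1-D samples with n >= 5")
    diff = a - b
    if np.all(diff == 0) or np.std(diff, ddof=1) == 0:
        raise ValueError("degenerate paired sample: all differences equal")

    sw_p = float(sps.shapiro(diff).pvalue)
    if sw_p >= normality_alpha:
        t_res = sps.ttest_rel(a, b)
        d = float(diff.mean() / diff.std(ddof=1))
        return StatResult(
            test="ttest_rel",
            statistic=float(t_res.statistic),
            p_value=float(t_res.pvalue),
            effect_size=d,
            effect_size_name="cohens_d",
            extra={"shapiro_p": sw_p, "n": a.size},
        )

    nz = diff[diff != 0]
    w_res = sps.wilcoxon(nz, method="auto")
    ranks = sps.rankdata(np.abs(nz))
    r_plus = ranks[nz > 0].sum()
    r_minus = ranks[nz < 0].sum()
    r_c = float((r_plus - r_minus) / (r_plus + r_minus))
    return StatResult(
        test="wilcoxon",
        statistic=float(w_res.statistic),
        p_value=float(w_res.pvalue),
        effect_size=r_c,
        effect_size_name="rank_biserial_r",
        extra={"shapiro_p": sw_p, "n": a.size, "n_nonzero": nz.size},
    )


def wilcoxon_exact_p(diff: np.ndarray) -> float:
    """Exact two-sided Wilcoxon signed-rank p by full sign enumeration.

    Brute-force reference for small n: enumerates all 2^n sign patterns of
    the absolute differences and returns the probability of a W+ at least
    as extreme as observed.
    """
    diff = np.asarray(diff, dtype=float)
    diff = diff[diff != 0]
    n = diff.size
    ranks = sps.rankdata(np.abs(diff))
    w_obs = ranks[diff > 0].sum()
    total = ranks.sum()
    count = 0
    for pattern in range(2**n):
        bits = (pattern >> np.arange(n)) & 1
        w = ranks[bits == 1].sum()
        # two-sided: as extreme in either direction
        if min(w, total - w) <= min(w_obs, total - w_obs):
            count += 1
    return count / 2**n
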