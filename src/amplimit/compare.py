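"""Distance-based community comparison.

Reproducibility analysis for amplicon profiles: weighted UniFrac distances
between samples (phylogeny- and abundance-aware), Shannon diversity, an exact
Mann-Whitney U test suited to the handful of replicate pairs such studies
produce, one-way PERMANOVA on a distance matrix, and principal-coordinates
embedding.  The heavy lifting for UniFrac/PERMANOVA/PCoA is delegated to
scikit-bio; the exact Mann-Whitney U is a complete enumeration of group
assignments, which stays valid under ties where large-sample approximations
do not.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import entropy, rankdata
from skbio import DistanceMatrix, TreeNode
from skbio.stats.distance import permanova as _skbio_permanova

__all__ = [
    "weighted_unifrac",
    "unifrac_distance_matrix",
    "shannon_index",
    "exact_mann_whitney_u",
    "permanova",
    "pcoa",
]


def weighted_unifrac(
    tree: TreeNode,
    counts_a: dict[str, int] | pd.Series,
    counts_b: dict[str, int] | pd.Series,
    normalized: bool = True,
) -> float:
    """Weighted UniFrac distance between two samples.

    Raw form: sum over branches b of l_b * |p_A(b) - p_B(b)|, where p_X(b) is
    the fraction of sample X's reads descending through b.  The normalized
    form divides by sum_b l_b * (p_A(b) + p_B(b)) and lies in [0, 1].

    Computed by a single postorder pass accumulating descendant read counts,
    which accepts multifurcating (e.g. star) trees that stricter
    implementations reject; on strictly bifurcating rooted trees it agrees
    with scikit-bio's weighted UniFrac.  Both samples must have positive
    totals and every counted taxon must map to a tree tip.
    """
    a = pd.Series(counts_a, dtype=float)
    b = pd.Series(counts_b, dtype=float)
    total_a = float(a.sum())
    total_b = float(b.sum())
    if total_a <= 0 or total_b <= 0:
        raise ValueError("both samples need at least one read")
    tips = {t.name for t in tree.tips()}
    missing = sorted(
        (set(a.index) | set(b.index)) - tips
    )
    if missing:
        raise ValueError(f"taxa absent from tree: {', '.join(missing)}")

    raw = norm = 0.0
    counts: dict[int, tuple[float, float]] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            ca = float(a.get(node.name, 0.0))
            cb = float(b.get(node.name, 0.0))
        else:
            ca = sum(counts[id(child)][0] for child in node.children)
            cb = sum(counts[id(child)][1] for child in node.children)
        counts[id(node)] = (ca, cb)
        if node.is_root():
            continue
        if node.length is None:
            raise ValueError(f"branch above {node.name!r} has no length")
        pa, pb = ca / total_a, cb / total_b
        raw += node.length * abs(pa - pb)
        norm += node.length * (pa + pb)
    if not normalized:
        return raw
    if norm == 0.0:
        return 0.0
    return raw / norm


def unifrac_distance_matrix(
    tree: TreeNode,
    table_counts: pd.DataFrame,
    normalized: bool = True,
) -> DistanceMatrix:
    """Pairwise weighted UniFrac over the samples (columns) of a count table."""
    samples = list(table_counts.columns)
    n = len(samples)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = weighted_unifrac(
            tree, table_counts[samples[i]], table_counts[samples[j]], normalized
        )
    return DistanceMatrix(d, ids=samples)


def shannon_index(counts: dict[str, int] | pd.Series | np.ndarray,
                  log_base: float = np.e) -> float:
    """Shannon diversity H' = -sum p_t log(p_t), natural log by default."""
    values = np.asarray(
        list(counts.values()) if isinstance(counts, dict) else counts,
        dtype=float,
    )
    if values.sum() <= 0:
        raise ValueError("sample has no reads")
    return float(entropy(values, base=log_base))


def _u_statistic(pooled_ranks: np.ndarray, x_idx: np.ndarray, m: int) -> float:
    # U_x from the rank-sum identity; mid-ranks carry ties.
    r_x = pooled_ranks[x_idx].sum()
    return r_x - m * (m + 1) / 2.0


def exact_mann_whitney_u(
    x: list[float] | np.ndarray,
    y: list[float] | np.ndarray,
    alternative: str = "two-sided",
    enumeration_bound: int = 12,
) -> tuple[float, float]:
    """Exact Mann-Whitney U by complete enumeration.

    Enumerates all C(m+n, m) assignments of the pooled observations to the
    first group, computing U (with mid-rank tie handling) for each; the
    p-value is the exact permutation tail probability.  Two-sided p is
    P(|U - mn/2| >= |U_obs - mn/2|), which respects the symmetry of the
    enumeration null even with ties.

    Raises for empty inputs or m + n beyond ``enumeration_bound`` (use a
    large-sample approximation there instead).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = x.size, y.size
    if m == 0 or n == 0:
        raise ValueError("both samples must be non-empty")
    if m + n > enumeration_bound:
        raise ValueError(
            f"m+n={m + n} exceeds enumeration bound {enumeration_bound}; "
            "use scipy.stats.mannwhitneyu with a normal approximation"
        )
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # mid-ranks for ties
    u_obs = _u_statistic(ranks, np.arange(m), m)
    total = comb(m + n, m)
    us = np.empty(total)
    for idx, combo in enumerate(combinations(range(m + n), m)):
        us[idx] = _u_statistic(ranks, np.array(combo), m)
    center = m * n / 2.0
    eps = 1e-9
    if alternative == "greater":
        p = np.count_nonzero(us >= u_obs - eps) / total
    elif alternative == "less":
        p = np.count_nonzero(us <= u_obs + eps) / total
    else:
        dev = np.abs(us - center)
        p = np.count_nonzero(dev >= abs(u_obs - center) - eps) / total
    return float(u_obs), float(p)


def permanova(
    dmatrix: DistanceMatrix,
    groups: list[str] | pd.Series,
    n_perm: int = 1000,
    seed: int | None = 0,
) -> tuple[float, float]:
    """One-way PERMANOVA: pseudo-F and permutation p-value.

    F = (SS_between/(g-1)) / (SS_within/(n-g)) from the Gower-centered
    distance partition; p = (1 + #{F_perm >= F_obs}) / (n_perm + 1) with free
    permutation of sample labels.
    """
    grouping = pd.Series(list(groups), index=dmatrix.ids)
    sizes = grouping.value_counts()
    if len(sizes) < 2:
        raise ValueError("need at least two groups")
    if (sizes == 1).all():
        raise ValueError("every group is a singleton; within-group "
                         "sum of squares is undefined")
    result = _skbio_permanova(
        dmatrix, list(grouping), permutations=n_perm, seed=seed
    )
    return float(result["test statistic"]), float(result["p-value"])


def pcoa(
    dmatrix: DistanceMatrix, n_axes: int = 2
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Principal-coordinates analysis (classical scaling).

    Eigendecomposition of the Gower-centered squared-distance matrix
    B = -1/2 J D^2 J.  Returns (coordinates on up to ``n_axes`` positive
    axes, explained fraction per returned axis, all eigenvalues in
    descending order).  Negative eigenvalues — the signature of
    non-Euclidean distance structure — are reported as-is, not dropped;
    coordinates are only built on positive axes.
    """
    d2 = dmatrix.data**2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > 1e-12 * max(1.0, abs(eigvals[0]))
    k = min(n_axes, int(positive.sum()))
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    explained = eigvals[:k] / eigvals[positive].sum()
    frame = pd.DataFrame(
        coords,
        index=list(dmatrix.ids),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return frame, explained, eigvals
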