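"""Hierarchical clustering of brain regions by cell-type composition.

Regions are compared by the Pearson correlation of their (max-normalized)
cell-type density profiles, turned into the dissimilarity ``1 - r`` and fed
to agglomerative Ward linkage.  Ward's variance-minimising update is, strictly
speaking, defined for squared Euclidean distances; applying its
Lance-Williams recurrence to correlation dissimilarities is a pragmatic and
widely used choice, and is implemented here exactly as stated (with the
caveat documented in the methods note).

The linkage is computed by a plain O(n³) agglomeration with an explicit,
platform-independent tie-break — candidate pairs at equal distance are
merged in lexicographic order of their smallest leaf indices — so trees are
bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch


def correlation_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise ``1 - Pearson r`` between region composition profiles.

    *matrix* is wide (regions x cell types).  Regions with a constant
    profile have undefined correlation and are rejected by name.
    """
    X = matrix.to_numpy(float)
    if X.shape[1] < 2:
        raise ValueError("need at least two cell types to correlate profiles")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = matrix.index[sd == 0].tolist()
        raise ValueError(f"regions with constant composition profile: {bad}")
    d = 1.0 - np.corrcoef(X)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


@dataclass
class ClusterTree:
    """Agglomeration result in SciPy linkage format.

    ``linkage`` rows are ``(node_a, node_b, height, size)`` with leaves
    numbered ``0..n-1`` and merge ``i`` creating node ``n+i``.  ``leaf_ids``
    keeps the caller's region identifiers in leaf order 0..n-1.
    """

    linkage: np.ndarray
    leaf_ids: list

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def leaf_order(self) -> list[int]:
        """Dendrogram left-to-right leaf positions."""
        return sch.leaves_list(self.linkage).tolist()

    def cut(self, k: int) -> np.ndarray:
        return cut_tree(self, k)


def _validate_distance(dist: np.ndarray) -> np.ndarray:
    d = np.asarray(dist, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(d < 0):
        raise ValueError("distance matrix must be non-negative")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    return d


def hierarchical_cluster(dist: pd.DataFrame | np.ndarray,
                         method: str = "ward") -> ClusterTree:
    """Agglomerative linkage on a precomputed dissimilarity matrix.

    ``method='ward'`` applies the Lance-Williams Ward recurrence on the
    given dissimilarities (distance scale, matching SciPy); ``'average'``
    and ``'complete'`` are available as alternatives.  Ties are broken by
    the lexicographically smallest pair of smallest-leaf indices.
    """
    if isinstance(dist, pd.DataFrame):
        leaf_ids = dist.index.tolist()
        d = _validate_distance(dist.to_numpy())
    else:
        d = _validate_distance(dist)
        leaf_ids = list(range(d.shape[0]))
    if method not in ("ward", "average", "complete"):
        raise ValueError(f"unknown linkage method {method!r}")

    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two leaves to cluster")
    # Work on squared distances for Ward (the recurrence is linear there).
    work = d.astype(float) ** 2 if method == "ward" else d.astype(float)
    active = list(range(n))               # positions into bookkeeping arrays
    node_id = list(range(n))              # scipy node id per active cluster
    size = [1] * n
    min_leaf = list(range(n))             # smallest leaf index per cluster
    D = work.copy()
    np.fill_diagonal(D, np.inf)

    merges = np.zeros((n - 1, 4))
    for step in range(n - 1):
        sub = D[np.ix_(active, active)]
        m = sub.min()
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                if sub[ai, bi] == m:
                    a, b = active[ai], active[bi]
                    key = (min(min_leaf[a], min_leaf[b]),
                           max(min_leaf[a], min_leaf[b]))
                    if best is None or key < best[0]:
                        best = (key, a, b)
        _, a, b = best
        na, nb = size[a], size[b]
        height = np.sqrt(D[a, b]) if method == "ward" else D[a, b]
        lo, hi = sorted((node_id[a], node_id[b]))
        merges[step] = (lo, hi, height, na + nb)

        # Lance-Williams update into slot a; retire slot b.
        for c in active:
            if c in (a, b):
                continue
            nc = size[c]
            if method == "ward":
                new = ((na + nc) * D[a, c] + (nb + nc) * D[b, c]
                       - nc * D[a, b]) / (na + nb + nc)
            elif method == "average":
                new = (na * D[a, c] + nb * D[b, c]) / (na + nb)
            else:  # complete
                new = max(D[a, c], D[b, c])
            D[a, c] = D[c, a] = new
        size[a] = na + nb
        node_id[a] = n + step
        min_leaf[a] = min(min_leaf[a], min_leaf[b])
        active.remove(b)

    return ClusterTree(linkage=merges, leaf_ids=leaf_ids)


def cut_tree(tree: ClusterTree, k: int) -> np.ndarray:
    """Flat labels at ``k`` clusters: undo the last ``k - 1`` merges.

    Labels are renumbered 0..k-1 by each cluster's smallest leaf index, so
    they are stable under leaf permutation up to that canonical order.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        a, b, _, _ = tree.linkage[step]
        new = n + step
        parent[find(int(a))] = new
        parent[find(int(b))] = new

    roots: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots)
        labels[leaf] = roots[r]
    return labels


def linkage_frame(tree: ClusterTree) -> pd.DataFrame:
    """Linkage as a tidy table (step, node_a, node_b, height, size)."""
    df = pd.DataFrame(tree.linkage, columns=["node_a", "node_b", "height", "size"])
    df.insert(0, "step", np.arange(len(df)))
    df["node_a"] = df["node_a"].astype(int)
    df["node_b"] = df["node_b"].astype(int)
    df["size"] = df["size"].astype(int)
    return df


def clustermap_frame(matrix: pd.DataFrame, tree: ClusterTree) -> pd.DataFrame:
    """Reorder the matrix rows by dendrogram leaf order (for heatmaps)."""
    order = [tree.leaf_ids[i] for i in tree.leaf_order]
    return matrix.loc[order]


def save_clustermap(matrix: pd.DataFrame, tree: ClusterTree, path: str) -> None:
    """Render a simple region x cell-type heatmap ordered by the dendrogram."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = clustermap_frame(matrix, tree)
    fig, ax = plt.subplots(figsize=(1 + 0.4 * frame.shape[1],
                                    1 + 0.25 * frame.shape[0]))
    im = ax.imshow(frame.to_numpy(float), aspect="auto", cmap="viridis")
    ax.set_xticks(range(frame.shape[1]), frame.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(frame.shape[0]), frame.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="normalized density")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
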