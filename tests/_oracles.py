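"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive (all-pairs loops, exhaustive
enumeration) and shares only the *conventions* with the package under test:
neighbor counts exclude the point itself and are boundary-inclusive, a core
point has >= minpoints neighbors, border points join the cluster of their
lowest-index core neighbor.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_neighbor_counts(pts: np.ndarray, eps: float) -> np.ndarray:
    """All-pairs O(n²) neighbor counts (self excluded, distance <= eps)."""
    n = len(pts)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        d = np.sqrt(((pts - pts[i]) ** 2).sum(1))
        counts[i] = int((d <= eps).sum()) - 1
    return counts


def brute_dbscan(pts: np.ndarray, eps: float, minpoints: int) -> tuple[np.ndarray, np.ndarray]:
    """Reference DBSCAN: adjacency matrix + BFS over core points.

    Returns (labels with noise=-1, core mask).  Cluster ids are numbered by
    the smallest core index in each cluster; border points take the cluster
    of their lowest-index core neighbor.
    """
    n = len(pts)
    if n == 0:
        return np.zeros(0, int), np.zeros(0, bool)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    adj = d <= eps
    np.fill_diagonal(adj, False)
    core = adj.sum(1) >= minpoints
    labels = np.full(n, -1, dtype=int)
    cid = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        queue = [i]
        labels[i] = cid
        while queue:
            j = queue.pop()
            for k in np.flatnonzero(adj[j] & core):
                if labels[k] == -1:
                    labels[k] = cid
                    queue.append(int(k))
        cid += 1
    for i in range(n):
        if core[i] or not adj[i].any():
            continue
        core_nbrs = np.flatnonzero(adj[i] & core)
        if len(core_nbrs):
            labels[i] = labels[core_nbrs[0]]  # lowest index
    return labels, core


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True if two labelings induce the same partition (noise fixed at -1)."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        return False
    if not np.array_equal(a == -1, b == -1):
        return False
    mapping: dict[int, int] = {}
    back: dict[int, int] = {}
    for x, y in zip(a, b):
        if x == -1:
            continue
        if mapping.setdefault(x, y) != y or back.setdefault(y, x) != x:
            return False
    return True


def interpolated_percentile(values, level: float) -> float:
    """Order-statistic percentile with linear interpolation, written plainly."""
    xs = sorted(values)
    n = len(xs)
    if n == 1:
        return float(xs[0])
    h = (level / 100.0) * (n - 1)
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    return float(xs[lo] + (h - lo) * (xs[hi] - xs[lo]))


def brute_match(detected: np.ndarray, truth: np.ndarray, radius: float):
    """Exhaustive optimal matching: maximise matches within radius, then
    minimise total distance over all injective assignments (n <= ~6)."""
    n_d, n_t = len(detected), len(truth)
    best_matches = 0
    best_dist = float("inf")
    small, big = (detected, truth) if n_d <= n_t else (truth, detected)
    for combo in itertools.permutations(range(len(big)), len(small)):
        m, dist = 0, 0.0
        for i, j in enumerate(combo):
            d = float(np.sqrt(((small[i] - big[j]) ** 2).sum()))
            if d <= radius:
                m += 1
                dist += d
        if m > best_matches or (m == best_matches and dist < best_dist):
            best_matches, best_dist = m, dist
    tp = best_matches
    return tp, n_d - tp, n_t - tp


def pearson_two_pass(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook two-pass Pearson correlation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum()))
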