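"""Density-based spatial parcellation of cell point clouds.

The procedure: for each cell type and each subject ("dataset"), count every
cell's neighbors within a fixed radius ε (default 150 μm).  The nine deciles
(10th..90th percentile) of those per-cell neighbor counts, averaged over
subjects and multiplied by the number of subjects, give nine pooled DBSCAN
``MinPoints`` thresholds.  Running DBSCAN on the pooled cloud at each
threshold yields a nested series of spatial clusters: low percentiles trace
broad territories, high percentiles isolate only the densest foci.

Neighbor counts exclude the cell itself and are boundary-inclusive
(distance ≤ ε); a core point is one with at least ``MinPoints`` neighbors.
A count ``k`` converts to a per-brain density ``(k / n_subjects) / V_ε``
with ``V_ε = (4/3)π(ε/1000)³`` mm³ (≈ 0.01414 mm³ at ε = 150 μm, i.e. one
neighbor ≈ 70.7 cells/mm³).

The DBSCAN here is the textbook algorithm with a deterministic border rule
(a border point joins the cluster of its lowest-index core neighbor), but
implemented so that dense clouds never require materialising the full
ε-neighborhood graph: core connectivity is resolved on a grid of cells of
diameter ε (points sharing a cell are mutually ε-close by construction),
with exact minimum-distance checks between nearby cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

DEFAULT_EPSILON_UM = 150.0
DEFAULT_LEVELS = (10, 20, 30, 40, 50, 60, 70, 80, 90)
NOISE = -1


def epsilon_ball_volume_mm3(epsilon_um: float) -> float:
    """Volume of the ε-ball in mm³."""
    if epsilon_um <= 0:
        raise ValueError("epsilon must be positive")
    return (4.0 / 3.0) * math.pi * (epsilon_um / 1000.0) ** 3


def _coords(points) -> np.ndarray:
    if isinstance(points, pd.DataFrame):
        return points[["x_um", "y_um", "z_um"]].to_numpy(float)
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (n, 3) coordinates in μm")
    return pts


def neighbor_counts(points, epsilon_um: float = DEFAULT_EPSILON_UM) -> np.ndarray:
    """Number of other points within ``epsilon_um`` of each point.

    Self-excluded, boundary-inclusive: count(p) = #{q != p : |p - q| <= ε}.
    Identical to the all-pairs definition; computed with a k-d tree.
    """
    if epsilon_um <= 0:
        raise ValueError("epsilon must be positive")
    pts = _coords(points)
    if len(pts) == 0:
        return np.zeros(0, dtype=np.int64)
    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, r=epsilon_um, return_length=True, workers=-1)
    return np.asarray(counts, dtype=np.int64) - 1  # ball includes the point itself


def round_half_up(x) -> np.ndarray | int:
    """Round to nearest integer with .5 going up (not banker's rounding)."""
    out = np.floor(np.asarray(x, float) + 0.5).astype(int)
    return int(out) if out.ndim == 0 else out


def minpoints_to_density(k: float, epsilon_um: float = DEFAULT_EPSILON_UM,
                         n_subjects: int = 1) -> float:
    """Per-brain density (cells/mm³) equivalent of a pooled MinPoints value."""
    if k < 0:
        raise ValueError("minpoints must be >= 0")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    return (k / n_subjects) / epsilon_ball_volume_mm3(epsilon_um)


def density_to_minpoints(density_per_mm3: float,
                         epsilon_um: float = DEFAULT_EPSILON_UM,
                         n_subjects: int = 1) -> int:
    """Pooled MinPoints equivalent of a per-brain density (inverse, rounded)."""
    if density_per_mm3 < 0:
        raise ValueError("density must be >= 0")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    return round_half_up(
        density_per_mm3 * epsilon_ball_volume_mm3(epsilon_um) * n_subjects)


# ---------------------------------------------------------------------------
# percentile thresholds

def percentile_thresholds(
    per_subject_counts: Mapping[str, np.ndarray],
    levels: Sequence[int] = DEFAULT_LEVELS,
    epsilon_um: float = DEFAULT_EPSILON_UM,
    cell_type: str = "",
) -> pd.DataFrame:
    """Pooled MinPoints thresholds from per-subject neighbor-count distributions.

    For each percentile level: take that percentile of every subject's count
    distribution (linear interpolation between order statistics), average
    over subjects, and multiply by the number of subjects — the MinPoints
    for DBSCAN on the pooled cloud (rounded to nearest, .5 up).  The same
    subject-mean percentile divided by V_ε is the per-brain density
    equivalent reported alongside.

    Subjects with no points are excluded with a warning; if all are empty
    the cell type cannot be thresholded.
    """
    import warnings

    counts = {s: np.asarray(c) for s, c in per_subject_counts.items()}
    empty = [s for s, c in counts.items() if c.size == 0]
    if empty:
        warnings.warn(f"subjects with no points excluded: {sorted(empty)}",
                      stacklevel=2)
        counts = {s: c for s, c in counts.items() if c.size > 0}
    if not counts:
        raise ValueError("all subjects empty: cannot compute percentile thresholds")

    n_subjects = len(counts)
    v_eps = epsilon_ball_volume_mm3(epsilon_um)
    rows = []
    for level in levels:
        if not 0 < level < 100:
            raise ValueError(f"percentile level must be in (0, 100), got {level}")
        per_subject = [np.percentile(c, level) for c in counts.values()]
        mean_pct = float(np.mean(per_subject))
        rows.append({
            "cell_type": cell_type,
            "level": int(level),
            "per_subject_percentile_mean": mean_pct,
            "minpoints_pooled": round_half_up(mean_pct * n_subjects),
            "density_cells_per_mm3": mean_pct / v_eps,
            "n_subjects": n_subjects,
            "epsilon_um": float(epsilon_um),
        })
    return pd.DataFrame(rows)


def threshold_table(
    points: pd.DataFrame,
    epsilon_um: float = DEFAULT_EPSILON_UM,
    levels: Sequence[int] = DEFAULT_LEVELS,
) -> pd.DataFrame:
    """Percentile-threshold table for every cell type in a multi-subject cloud.

    Neighbor counts are computed per (cell type, subject) on that subject's
    own points, as each imaged brain is an independent dataset.
    """
    tables = []
    for ctype, sub in points.groupby("cell_type", sort=True):
        per_subject = {
            str(sid): neighbor_counts(s, epsilon_um)
            for sid, s in sub.groupby("subject_id", sort=True)
        }
        tables.append(percentile_thresholds(per_subject, levels, epsilon_um,
                                            cell_type=str(ctype)))
    if not tables:
        raise ValueError("no points: cannot build a threshold table")
    return pd.concat(tables, ignore_index=True)


# ---------------------------------------------------------------------------
# DBSCAN

@dataclass
class ParcellationResult:
    """One DBSCAN run: per-point labels (noise = -1) and core flags."""

    labels: np.ndarray
    core: np.ndarray
    epsilon_um: float
    minpoints: int
    level: int | None = None
    neighbor_count: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max() + 1) if len(self.labels) else 0

    def summaries(self, points=None) -> pd.DataFrame:
        """Per-cluster size, core size, centroid and bounding box (μm)."""
        rows = []
        coords = _coords(points) if points is not None else None
        for cid in range(self.n_clusters):
            mask = self.labels == cid
            row = {"cluster_id": cid, "n_points": int(mask.sum()),
                   "n_core": int((mask & self.core).sum())}
            if coords is not None:
                sub = coords[mask]
                for i, ax in enumerate("xyz"):
                    row[f"centroid_{ax}_um"] = float(sub[:, i].mean())
                    row[f"min_{ax}_um"] = float(sub[:, i].min())
                    row[f"max_{ax}_um"] = float(sub[:, i].max())
            rows.append(row)
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"point_index": np.arange(len(self.labels)),
                           "cluster_id": self.labels,
                           "is_core": self.core})
        if self.level is not None:
            df.insert(1, "level", self.level)
        return df


def _min_cross_distance_leq(a: np.ndarray, b: np.ndarray, eps: float) -> bool:
    """Exact test: does any pair (p in a, q in b) satisfy |p - q| <= eps?"""
    if a.shape[0] * b.shape[0] <= 250_000:
        return bool((cdist(a, b) <= eps).any())
    small, big = (a, b) if len(a) <= len(b) else (b, a)
    tree = cKDTree(big)
    d, _ = tree.query(small, k=1, distance_upper_bound=eps * (1 + 1e-12))
    return bool(np.any(d <= eps))


def _core_components(core_pts: np.ndarray, eps: float) -> np.ndarray:
    """Connected components of core points under ε-adjacency.

    Core points are binned into grid cells of side ε/√3 (cell diameter ε, so
    points in one cell are pairwise ε-close).  Cells are then united whenever
    an exact check finds a cross pair within ε; only cell pairs whose boxes
    can be within ε are candidates, and pairs already in one component are
    skipped, which keeps the work near-linear for dense blobs.
    """
    n = len(core_pts)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    s = eps / math.sqrt(3.0)
    cells = np.floor(core_pts / s).astype(np.int64)
    uniq, inverse = np.unique(cells, axis=0, return_inverse=True)
    n_cells = len(uniq)

    parent = np.arange(n_cells)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    cell_index = {tuple(c): i for i, c in enumerate(uniq)}
    order = np.argsort(inverse, kind="stable")
    bounds = np.searchsorted(inverse[order], np.arange(n_cells + 1))
    members = [order[bounds[i]:bounds[i + 1]] for i in range(n_cells)]

    # Candidate offsets: neighbor cells whose boxes may contain an ε-pair,
    # sorted so that nearest cells are tried (and united) first.
    offsets = []
    for dx in range(-2, 3):
        for dy in range(-2, 3):
            for dz in range(-2, 3):
                if (dx, dy, dz) <= (0, 0, 0):
                    continue  # each unordered pair once
                gap = sum(max(abs(d) - 1, 0) ** 2 for d in (dx, dy, dz))
                if gap * s * s <= eps * eps:
                    offsets.append((gap, (dx, dy, dz)))
    offsets = [o for _, o in sorted(offsets)]

    for i, c in enumerate(uniq):
        for off in offsets:
            j = cell_index.get((c[0] + off[0], c[1] + off[1], c[2] + off[2]))
            if j is None or find(i) == find(j):
                continue
            if _min_cross_distance_leq(core_pts[members[i]], core_pts[members[j]],
                                       eps):
                union(i, j)

    cell_root = np.array([find(i) for i in range(n_cells)])
    return cell_root[inverse]


def dbscan(
    points,
    epsilon_um: float = DEFAULT_EPSILON_UM,
    minpoints: int = 1,
    counts: np.ndarray | None = None,
    level: int | None = None,
) -> ParcellationResult:
    """DBSCAN with self-excluded neighbor counts and deterministic borders.

    A point is *core* iff it has ≥ ``minpoints`` neighbors within ε (itself
    excluded); clusters are the ε-connected components of core points;
    a non-core point within ε of some core point joins the cluster of its
    lowest-index core neighbor (border), otherwise it is noise (-1).
    Cluster ids are numbered by each cluster's smallest core point index.

    Precomputed ``counts`` (from :func:`neighbor_counts` at the same ε) can
    be passed to avoid recomputation across a percentile sweep.
    """
    if epsilon_um <= 0:
        raise ValueError("epsilon must be positive")
    if minpoints < 0:
        raise ValueError("minpoints must be >= 0")
    pts = _coords(points)
    n = len(pts)
    if n == 0:
        return ParcellationResult(np.zeros(0, int), np.zeros(0, bool),
                                  epsilon_um, minpoints, level)
    if counts is None:
        counts = neighbor_counts(pts, epsilon_um)
    counts = np.asarray(counts)
    if counts.shape != (n,):
        raise ValueError("counts must have one entry per point")

    core = counts >= minpoints
    labels = np.full(n, NOISE, dtype=np.int64)
    core_idx = np.flatnonzero(core)
    if len(core_idx) == 0:
        return ParcellationResult(labels, core, epsilon_um, minpoints, level, counts)

    comp = _core_components(pts[core_idx], epsilon_um)
    # canonical cluster ids: order components by their smallest core index
    first = {}
    for ci, c in zip(core_idx, comp):
        if c not in first:
            first[c] = len(first)
    labels[core_idx] = np.array([first[c] for c in comp])

    # border points: lowest-index core neighbor decides the cluster
    noncore_idx = np.flatnonzero(~core)
    if len(noncore_idx):
        core_tree = cKDTree(pts[core_idx])
        chunk = 50_000
        for start in range(0, len(noncore_idx), chunk):
            block = noncore_idx[start:start + chunk]
            block_tree = cKDTree(pts[block])
            pairs = core_tree.sparse_distance_matrix(
                block_tree, max_distance=epsilon_um, output_type="ndarray")
            if len(pairs) == 0:
                continue
            ci = core_idx[pairs["i"]]        # original index of the core point
            bj = pairs["j"]                  # position within the block
            best = np.full(len(block), n, dtype=np.int64)
            np.minimum.at(best, bj, ci)
            hit = best < n
            labels[block[hit]] = labels[best[hit]]

    return ParcellationResult(labels, core, epsilon_um, minpoints, level, counts)


def percentile_sweep(
    points,
    thresholds: pd.DataFrame,
    epsilon_um: float | None = None,
) -> list[ParcellationResult]:
    """One DBSCAN per percentile level of a threshold table (same ε).

    Neighbor counts on the pooled cloud are computed once and shared, so
    core sets are nested across levels by construction.  ``thresholds``
    must cover a single cell type.
    """
    if thresholds["cell_type"].nunique() > 1:
        raise ValueError("percentile_sweep expects thresholds for one cell type")
    eps_vals = thresholds["epsilon_um"].unique()
    if epsilon_um is None:
        if len(eps_vals) != 1:
            raise ValueError("threshold table mixes epsilon values")
        epsilon_um = float(eps_vals[0])
    pts = _coords(points)
    counts = neighbor_counts(pts, epsilon_um)
    results = []
    for _, row in thresholds.sort_values("level").iterrows():
        results.append(dbscan(pts, epsilon_um, int(row["minpoints_pooled"]),
                              counts=counts, level=int(row["level"])))
    return results


# ---------------------------------------------------------------------------
# overlap scoring against atlas regions

def cluster_region_overlap(parcellation: ParcellationResult,
                           points: pd.DataFrame) -> pd.DataFrame:
    """Dice/Jaccard overlap between each spatial cluster and each atlas region.

    Both are treated as sets of point indices: A = points of one cluster
    (noise excluded), B = points of one region.  ``cluster_in_region_frac``
    is |A∩B| / |A|.
    """
    if "region_id" not in points.columns:
        raise ValueError("points must carry region_id (run assign_regions)")
    if len(points) != len(parcellation.labels):
        raise ValueError("points and parcellation sizes differ")
    region_ids = points["region_id"].to_numpy()
    labels = parcellation.labels
    mask = labels != NOISE
    if not mask.any():
        return pd.DataFrame(columns=["cluster_id", "region_id", "dice",
                                     "jaccard", "cluster_in_region_frac"])
    ct = pd.crosstab(labels[mask], region_ids[mask])
    cluster_sizes = pd.Series(labels[mask]).value_counts()
    region_sizes = pd.Series(region_ids).value_counts()
    rows = []
    for cid in ct.index:
        for rid in ct.columns:
            inter = int(ct.loc[cid, rid])
            if inter == 0:
                continue
            na = int(cluster_sizes[cid])
            nb = int(region_sizes[rid])
            rows.append({
                "cluster_id": int(cid), "region_id": int(rid),
                "dice": 2.0 * inter / (na + nb),
                "jaccard": inter / (na + nb - inter),
                "cluster_in_region_frac": inter / na,
            })
    return pd.DataFrame(rows, columns=["cluster_id", "region_id", "dice",
                                       "jaccard", "cluster_in_region_frac"])
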