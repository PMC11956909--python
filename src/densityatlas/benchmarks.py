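"""Self-contained benchmark experiments exercising every pipeline stage.

Each function simulates its own data (reproducibly from a seed), runs the
relevant stage, and returns summary numbers.  They power the reproducibility
script (``scripts/acceptance.py``) and the end-to-end test suite; densities
used as generating parameters are the published regional percentile
densities for cortical-type markers (e.g. 49,797 and 529,455 cells/mm³ for
the 10th/90th percentile of a layer-2/3 pyramidal marker), so parameter
recovery is checked on realistic scales.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .composition_clustering import (correlation_distance, cut_tree,
                                     hierarchical_cluster)
from .density_parcellation import (dbscan, epsilon_ball_volume_mm3,
                                   neighbor_counts, percentile_thresholds)
from .group_comparison import compare_groups
from .image_detection import detect_nuclei, match_detections
from .synthetic_data import (ImageSpec, planted_block_matrix,
                             render_nuclei_stack, sample_nuclei_scene)

#: Published per-cell-type percentile densities (cells/mm³) reused as
#: generating intensities: (marker, percentile level, density).
REFERENCE_DENSITIES = (
    ("cux2_p10", 49_797.0),
    ("cux2_p90", 529_455.0),
    ("vglut1_p10", 202_445.0),
    ("rbp4_p10", 25_606.0),
)


def recover_poisson_density(lam: float, seed: int,
                            epsilon_um: float = 150.0) -> dict:
    """Estimate a homogeneous Poisson intensity from ε-neighbor counts.

    Points are simulated in a cube; the density estimate is the mean
    neighbor count of interior points (≥ ε from every face, avoiding edge
    truncation of the ε-ball) divided by V_ε.
    """
    side_mm = max(0.55, (60_000.0 / lam) ** (1 / 3))
    rng = np.random.default_rng(seed)
    n = rng.poisson(lam * side_mm ** 3)
    pts = rng.random((n, 3)) * side_mm * 1000.0
    counts = neighbor_counts(pts, epsilon_um)
    interior = np.all((pts >= epsilon_um)
                      & (pts <= side_mm * 1000.0 - epsilon_um), axis=1)
    est = counts[interior].mean() / epsilon_ball_volume_mm3(epsilon_um)
    return {"estimate": float(est), "generating": lam, "n": int(n),
            "n_interior": int(interior.sum())}


def dbscan_oracle_agreement(seed: int, n_fixtures: int = 20) -> dict:
    """Fraction of random fixtures where DBSCAN matches a brute-force
    all-pairs + BFS reference exactly (partition and core set)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_fixtures):
        kind = rng.integers(3)
        n = int(rng.integers(50, 501))
        if kind == 0:  # uniform
            pts = rng.random((n, 3)) * 900.0
        elif kind == 1:  # gaussian blobs
            k = int(rng.integers(2, 5))
            centers = rng.random((k, 3)) * 1500.0
            pts = np.vstack([c + rng.normal(0, 80.0, (n // k + 1, 3))
                             for c in centers])[:n]
        else:  # blobs plus uniform outliers
            c = rng.random((2, 3)) * 1200.0
            pts = np.vstack([c[0] + rng.normal(0, 60.0, (n // 2, 3)),
                             c[1] + rng.normal(0, 60.0, (n // 4, 3)),
                             rng.random((n // 4 + 2, 3)) * 1200.0])[:n]
        minpoints = int(rng.integers(0, 15))
        res = dbscan(pts, 150.0, minpoints)
        ref_labels, ref_core = _reference_dbscan(pts, 150.0, minpoints)
        if np.array_equal(res.core, ref_core) and _same_partition(
                res.labels, ref_labels):
            agree += 1
    return {"agreement": agree / n_fixtures, "n": n_fixtures}


def _reference_dbscan(pts, eps, minpoints):
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    adj = d <= eps
    np.fill_diagonal(adj, False)
    core = adj.sum(1) >= minpoints
    labels = np.full(len(pts), -1, dtype=int)
    cid = 0
    for i in range(len(pts)):
        if not core[i] or labels[i] != -1:
            continue
        stack = [i]
        labels[i] = cid
        while stack:
            j = stack.pop()
            for k in np.flatnonzero(adj[j] & core):
                if labels[k] == -1:
                    labels[k] = cid
                    stack.append(int(k))
        cid += 1
    for i in np.flatnonzero(~core):
        nbrs = np.flatnonzero(adj[i] & core)
        if len(nbrs):
            labels[i] = labels[nbrs[0]]
    return labels, core


def _same_partition(a, b) -> bool:
    if not np.array_equal(a == -1, b == -1):
        return False
    fwd: dict[int, int] = {}
    back: dict[int, int] = {}
    for x, y in zip(a, b):
        if x == -1:
            continue
        if fwd.setdefault(x, y) != y or back.setdefault(y, x) != x:
            return False
    return True


def neighbor_count_oracle_agreement(seed: int, n_points: int = 2000,
                                    n_seeds: int = 10) -> dict:
    """Fraction of random clouds where the k-d-tree neighbor counts equal
    the O(n²) all-pairs counts exactly."""
    exact = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        pts = rng.random((n_points, 3)) * 1000.0
        fast = neighbor_counts(pts, 150.0)
        diff = np.abs(pts[:, None, :] - pts[None, :, :])
        brute = ((diff ** 2).sum(-1) <= 150.0 ** 2).sum(1) - 1
        exact += int(np.array_equal(fast, brute))
    return {"agreement": exact / n_seeds, "n": n_seeds * n_points}


def core_nestedness_violations(sweep) -> int:
    """Number of core-set inclusion violations across adjacent sweep levels."""
    violations = 0
    for lo, hi in zip(sweep, sweep[1:]):
        violations += int((hi.core & ~lo.core).sum())
    return violations


def planted_insert_scene(seed: int,
                         lam_in: float = 529_455.0,
                         lam_out: float = 49_797.0) -> tuple[np.ndarray, np.ndarray]:
    """A dense spherical nucleus inside sparse background.

    The insert radius (185 μm, just above ε) and background box are sized so
    the high-percentile DBSCAN core erodes inside the insert while staying
    resolvable; densities default to the 90th/10th-percentile values of the
    reference cortical marker (ratio ≈ 10.6).
    """
    rng = np.random.default_rng(seed)
    box = np.array([800.0, 750.0, 450.0])
    center = np.array([400.0, 375.0, 225.0])
    radius = 185.0
    n_bg = rng.poisson(lam_out * np.prod(box) * 1e-9)
    bg = rng.random((n_bg, 3)) * box
    bg = bg[np.sum((bg - center) ** 2, axis=1) > radius ** 2]
    n_in = rng.poisson(lam_in * (4 / 3) * np.pi * (radius / 1000.0) ** 3)
    dirs = rng.standard_normal((n_in, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = radius * rng.random(n_in) ** (1 / 3)
    insert = center + dirs * radii[:, None]
    pts = np.vstack([bg, insert])
    is_insert = np.arange(len(pts)) >= len(bg)
    return pts, is_insert


def planted_insert_dice(seed: int, epsilon_um: float = 150.0) -> dict:
    """Dice overlap between the top-percentile DBSCAN cluster and the
    planted dense insert."""
    pts, is_insert = planted_insert_scene(seed)
    counts = neighbor_counts(pts, epsilon_um)
    table = percentile_thresholds({"s1": counts}, levels=[90],
                                  epsilon_um=epsilon_um)
    res = dbscan(pts, epsilon_um, int(table["minpoints_pooled"].iloc[0]),
                 counts=counts)
    sizes = pd.Series(res.labels[res.labels >= 0]).value_counts()
    if sizes.empty:
        return {"dice": 0.0, "n": len(pts)}
    members = res.labels == sizes.index[0]
    inter = int((members & is_insert).sum())
    dice = 2.0 * inter / (members.sum() + is_insert.sum())
    return {"dice": float(dice), "n": int(len(pts))}


def planted_block_ari(seed: int, noise: float = 0.05, k: int = 4) -> dict:
    """ARI of correlation-distance + Ward clustering vs planted blocks."""
    matrix, truth = planted_block_matrix(noise=noise, seed=seed)
    norm = matrix / matrix.max(axis=0)
    tree = hierarchical_cluster(correlation_distance(norm))
    labels = cut_tree(tree, k)
    return {"ari": float(adjusted_rand_score(truth, labels)),
            "n": len(truth)}


def null_calibration(seed: int, reps: int = 200, m_regions: int = 50,
                     n_types: int = 5, n: int = 8, cv: float = 0.10) -> dict:
    """Monte-Carlo null: raw per-test rejection rate and BH behaviour."""
    rng = np.random.default_rng(seed)
    raw_rej = total = bh_discoveries = bh_reps = 0
    for _ in range(reps):
        table = compare_groups(_simulated_cohort(rng, None, m_regions,
                                                 n_types, n, cv), "A", "B")
        raw_rej += int((table["p"] < 0.05).sum())
        total += len(table)
        bh_discoveries += int(table["significant"].sum())
        bh_reps += int(table["significant"].any())
    return {"raw_rate": raw_rej / total,
            "bh_mean_discoveries": bh_discoveries / reps,
            "bh_any_fraction": bh_reps / reps,
            "n": total}


def planted_effect_power(seed: int, reps: int = 50, effect: float = 1.2,
                         m_regions: int = 50, n_types: int = 5, n: int = 8,
                         cv: float = 0.10) -> dict:
    """Fraction of replicates in which the planted cell type is discovered
    (at least one of its regions significant at q <= 0.05)."""
    rng = np.random.default_rng(seed)
    hits = 0
    row_hits = row_total = 0
    for _ in range(reps):
        table = compare_groups(_simulated_cohort(rng, 0, m_regions, n_types,
                                                 n, cv, effect), "A", "B")
        planted = table[table["cell_type"] == "t0"]
        hits += int(planted["significant"].any())
        row_hits += int(planted["significant"].sum())
        row_total += len(planted)
    return {"power": hits / reps, "per_region_power": row_hits / row_total,
            "n": reps}


def _simulated_cohort(rng, effect_type, m_regions, n_types, n, cv,
                      effect=1.2) -> pd.DataFrame:
    rows = []
    for rid in range(m_regions):
        for t in range(n_types):
            mult = effect if t == effect_type else 1.0
            for i in range(n):
                rows.append((rid, f"t{t}", f"a{i}", "A",
                             1e5 * mult * np.exp(cv * rng.standard_normal())))
            for i in range(n):
                rows.append((rid, f"t{t}", f"b{i}", "B",
                             1e5 * np.exp(cv * rng.standard_normal())))
    return pd.DataFrame(rows, columns=["region_id", "cell_type", "subject_id",
                                       "group", "density_cells_per_mm3"])


def detection_benchmark(seed: int, n_nuclei: int = 200,
                        shape=(8, 512, 512)) -> dict:
    """Detect nuclei on the standard synthetic stack (SNR 10) and score
    against ground truth (5 μm matching radius)."""
    spec = ImageSpec(shape=shape, nucleus_radius_um=3.0, amplitude=100.0,
                     background=10.0, noise_sd=10.0)
    truth = sample_nuclei_scene(n_nuclei, spec, seed=seed)
    stack, _ = render_nuclei_stack(truth, spec, seed=seed + 1)
    result = detect_nuclei(stack, tensor_sigma_um=3.0,
                           response_percentile=99.7, min_size_voxels=5)
    metrics = match_detections(result.centroids, truth, radius_um=5.0)
    return {"f1": metrics.f1, "precision": metrics.precision,
            "recall": metrics.recall,
            "inplane_error_um": metrics.mean_inplane_error_um,
            "n": n_nuclei}
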