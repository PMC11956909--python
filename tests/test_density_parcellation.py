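import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import densityatlas as da
from _oracles import (brute_dbscan, brute_neighbor_counts,
                      interpolated_percentile, same_partition)
from conftest import points_frame

EPS = 150.0
V_EPS = (4.0 / 3.0) * np.pi * 0.15 ** 3


class TestNeighborCounts:
    def test_single_point_has_zero(self):
        assert da.neighbor_counts(np.array([[0.0, 0.0, 0.0]]), EPS).tolist() == [0]

    def test_boundary_inclusive(self):
        near = np.array([[0, 0, 0], [100.0, 0, 0]])
        far = np.array([[0, 0, 0], [151.0, 0, 0]])
        exact = np.array([[0, 0, 0], [150.0, 0, 0]])
        assert da.neighbor_counts(near, EPS).tolist() == [1, 1]
        assert da.neighbor_counts(far, EPS).tolist() == [0, 0]
        assert da.neighbor_counts(exact, EPS).tolist() == [1, 1]

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((500, 3)) * 1000.0
        assert np.array_equal(da.neighbor_counts(pts, EPS),
                              brute_neighbor_counts(pts, EPS))

    def test_accepts_point_table(self):
        pts = points_frame(np.array([[0, 0, 0], [50.0, 0, 0]]))
        assert da.neighbor_counts(pts, EPS).tolist() == [1, 1]


class TestPercentileThresholds:
    def test_median_of_decile_counts_rounds_up(self):
        counts = {"s1": np.repeat(np.arange(10), 10)}  # 0..9, x10 each
        table = da.percentile_thresholds(counts, levels=[50], epsilon_um=EPS)
        assert table["per_subject_percentile_mean"].iloc[0] == pytest.approx(4.5)
        assert table["minpoints_pooled"].iloc[0] == 5  # .5 rounds up

    def test_two_identical_subjects_double_minpoints(self):
        c = np.arange(100)
        one = da.percentile_thresholds({"s1": c}, levels=[30], epsilon_um=EPS)
        two = da.percentile_thresholds({"s1": c, "s2": c.copy()},
                                       levels=[30], epsilon_um=EPS)
        single = one["per_subject_percentile_mean"].iloc[0]
        assert two["minpoints_pooled"].iloc[0] == round(2 * single)
        assert two["n_subjects"].iloc[0] == 2

    def test_matches_order_statistic_oracle_at_all_levels(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 400, size=10)
        table = da.percentile_thresholds({"s1": counts}, epsilon_um=EPS)
        for _, row in table.iterrows():
            expect = interpolated_percentile(counts, row["level"])
            assert row["per_subject_percentile_mean"] == pytest.approx(expect)

    def test_density_column_is_mean_percentile_over_ball_volume(self):
        table = da.percentile_thresholds({"s1": np.full(50, 704)},
                                         levels=[50], epsilon_um=EPS)
        assert table["density_cells_per_mm3"].iloc[0] == \
            pytest.approx(704 / V_EPS)

    def test_empty_subject_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            table = da.percentile_thresholds(
                {"s1": np.arange(10), "s2": np.array([])},
                levels=[50], epsilon_um=EPS)
        assert table["n_subjects"].iloc[0] == 1

    def test_all_subjects_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            da.percentile_thresholds({"s1": np.array([])}, epsilon_um=EPS)

    def test_minpoints_nondecreasing_in_level(self):
        rng = np.random.default_rng(1)
        counts = {f"s{i}": rng.poisson(300, size=rng.integers(50, 200))
                  for i in range(4)}
        table = da.percentile_thresholds(counts, epsilon_um=EPS)
        assert (np.diff(table["minpoints_pooled"]) >= 0).all()


class TestDensityConversion:
    def test_zero_minpoints_zero_density(self):
        assert da.minpoints_to_density(0, EPS, 1) == 0.0

    def test_printed_decile_density_converts_to_704_neighbors(self):
        # 49,797 cells/mm3 x (4/3)pi(0.15 mm)^3 = 703.99 -> 704
        assert da.density_to_minpoints(49797.0, EPS, n_subjects=1) == 704

    def test_round_trip_identity_for_all_k(self):
        ks = np.arange(0, 10_001)
        dens = np.array([da.minpoints_to_density(k, EPS, 3) for k in ks[:100]])
        back = np.array([da.density_to_minpoints(d, EPS, 3) for d in dens])
        assert np.array_equal(back, ks[:100])
        # vectorised full-range check via the same formulas
        dens_all = (ks / 3) / V_EPS
        back_all = np.floor(dens_all * V_EPS * 3 + 0.5).astype(int)
        assert np.array_equal(back_all, ks)

    def test_density_round_trip_error_below_one_neighbor(self):
        for d in [1234.5, 49797.0, 3.3e5]:
            k = da.density_to_minpoints(d, EPS, 1)
            assert abs(da.minpoints_to_density(k, EPS, 1) - d) < 1 / V_EPS

    def test_nonpositive_epsilon_rejected(self):
        with pytest.raises(ValueError):
            da.minpoints_to_density(5, 0.0, 1)


def blobs_and_outliers(seed: int, n_blob=100, n_out=30) -> np.ndarray:
    rng = np.random.default_rng(seed)
    centers = np.array([[500, 500, 500], [2500, 500, 500], [1500, 2500, 500]],
                       dtype=float)
    parts = [c + rng.normal(0, 60.0, size=(n_blob, 3)) for c in centers]
    parts.append(rng.random((n_out, 3)) * 3000.0)
    return np.vstack(parts)


class TestDbscan:
    def test_minpoints_above_n_all_noise(self):
        pts = np.random.default_rng(0).random((20, 3)) * 100.0
        res = da.dbscan(pts, EPS, minpoints=20)
        assert (res.labels == -1).all() and not res.core.any()

    def test_minpoints_zero_is_epsilon_components(self):
        rng = np.random.default_rng(2)
        pts = rng.random((200, 3)) * 1500.0
        res = da.dbscan(pts, EPS, minpoints=0)
        assert res.core.all()
        ref_labels, _ = brute_dbscan(pts, EPS, 0)
        assert same_partition(res.labels, ref_labels)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_blob_fixture_matches_reference(self, seed):
        pts = blobs_and_outliers(seed)
        for minpoints in (5, 15, 40):
            res = da.dbscan(pts, EPS, minpoints=minpoints)
            ref_labels, ref_core = brute_dbscan(pts, EPS, minpoints)
            assert np.array_equal(res.core, ref_core)
            assert same_partition(res.labels, ref_labels)

    def test_border_points_follow_lowest_index_core_neighbor(self):
        # two core chains; one border point exactly eps from a core of each
        left = np.array([[0.0, 0, 0], [30.0, 0, 0], [60.0, 0, 0], [90.0, 0, 0]])
        right = left + [390.0, 0.0, 0.0]
        border = np.array([[240.0, 0.0, 0.0]])  # 150 from points at 90 and 390
        pts = np.vstack([left, right, border])
        res = da.dbscan(pts, EPS, minpoints=3)
        assert not res.core[8]
        assert res.labels[0] != res.labels[4]  # two distinct clusters
        assert res.labels[8] == res.labels[3]  # lowest-index core neighbor wins

    def test_core_invariants_hold(self):
        pts = blobs_and_outliers(9)
        res = da.dbscan(pts, EPS, minpoints=10)
        counts = da.neighbor_counts(pts, EPS)
        assert np.array_equal(res.core, counts >= 10)
        # every non-noise non-core point is within eps of a core point of
        # its own cluster; noise points have no core neighbor
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        for i in np.flatnonzero(~res.core):
            core_near = np.flatnonzero(res.core & (d[i] <= EPS))
            if res.labels[i] == -1:
                assert len(core_near) == 0
            else:
                assert res.labels[i] in set(res.labels[core_near])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), minpoints=st.integers(0, 12),
           n=st.integers(1, 80))
    def test_random_clouds_match_reference(self, seed, minpoints, n):
        rng = np.random.default_rng(seed)
        pts = rng.random((n, 3)) * 600.0
        res = da.dbscan(pts, EPS, minpoints=minpoints)
        ref_labels, ref_core = brute_dbscan(pts, EPS, minpoints)
        assert np.array_equal(res.core, ref_core)
        assert same_partition(res.labels, ref_labels)

    def test_empty_input(self):
        res = da.dbscan(np.empty((0, 3)), EPS, 1)
        assert res.n_clusters == 0 and len(res.labels) == 0

    def test_summaries_and_frame(self):
        pts = blobs_and_outliers(1)
        res = da.dbscan(pts, EPS, minpoints=10, level=50)
        summ = res.summaries(pts)
        assert (summ["n_points"] >= summ["n_core"]).all()
        frame = res.to_frame()
        assert set(frame.columns) == {"point_index", "level", "cluster_id",
                                      "is_core"}
        # centroid lies inside the cluster bounding box
        for _, row in summ.iterrows():
            for ax in "xyz":
                assert row[f"min_{ax}_um"] <= row[f"centroid_{ax}_um"] \
                    <= row[f"max_{ax}_um"]


# An ε much smaller than the insert makes the high-percentile core erode
# deeper than ε, so its border stays inside the insert; the insert is 40%
# of all points, so the broad low-percentile cluster is mostly background.
SWEEP_EPS = 37.5


@pytest.fixture(scope="module")
def sweep_fixture():
    rng = np.random.default_rng(12)
    bg = rng.random((8550, 3)) * [650, 550, 500]
    inside = np.all((bg >= [212, 162, 137]) & (bg < [437, 387, 362]), axis=1)
    bg = bg[~inside]
    insert = rng.random((5700, 3)) * 225.0 + [212, 162, 137]
    coords = np.vstack([bg, insert])
    pts = points_frame(coords, subject_id="s1")
    table = da.threshold_table(pts, epsilon_um=SWEEP_EPS)
    return pts, table, len(bg)


class TestPercentileSweep:

    def test_nine_levels_nine_results(self, sweep_fixture):
        pts, table, _ = sweep_fixture
        sweep = da.percentile_sweep(pts, table)
        assert len(sweep) == 9
        assert [r.level for r in sweep] == list(range(10, 100, 10))

    def test_core_sets_nested_across_levels(self, sweep_fixture):
        pts, table, _ = sweep_fixture
        sweep = da.percentile_sweep(pts, table)
        for lo, hi in zip(sweep, sweep[1:]):
            assert not (hi.core & ~lo.core).any()  # core(90) ⊆ core(10)

    def test_high_level_isolates_dense_insert(self, sweep_fixture):
        pts, table, n_bg = sweep_fixture
        sweep = da.percentile_sweep(pts, table)
        is_insert = np.arange(len(pts)) >= n_bg
        top = sweep[-1]
        sizes = pd.Series(top.labels[top.labels >= 0]).value_counts()
        largest = sizes.index[0]
        members = top.labels == largest
        assert is_insert[members].mean() >= 0.95
        low = sweep[0]
        sizes_low = pd.Series(low.labels[low.labels >= 0]).value_counts()
        members_low = low.labels == sizes_low.index[0]
        assert is_insert[members_low].mean() < 0.5


class TestClusterRegionOverlap:
    def overlap(self, labels, regions):
        n = len(labels)
        res = da.ParcellationResult(np.asarray(labels), np.ones(n, bool), EPS, 1)
        pts = points_frame(np.zeros((n, 3)))
        pts["region_id"] = regions
        return da.cluster_region_overlap(res, pts)

    def test_perfect_overlap(self):
        table = self.overlap([0, 0, 0, -1], [5, 5, 5, 7])
        row = table.iloc[0]
        assert row["dice"] == 1.0 and row["jaccard"] == 1.0

    def test_disjoint_clusters_absent(self):
        table = self.overlap([0, 0, 1, 1], [5, 5, 9, 9])
        pairs = set(zip(table["cluster_id"], table["region_id"]))
        assert (0, 9) not in pairs and (1, 5) not in pairs

    def test_formula_arithmetic(self):
        # |A| = 10 (cluster 0), |B| = 11 (region 5), |A ∩ B| = 7
        labels = [0] * 10 + [1] * 4 + [-1] * 0
        regions = [5] * 7 + [6] * 3 + [5] * 4
        table = self.overlap(labels, regions)
        row = table.query("cluster_id == 0 and region_id == 5").iloc[0]
        assert row["dice"] == pytest.approx(14 / 21)
        assert row["jaccard"] == pytest.approx(0.5)
        assert row["cluster_in_region_frac"] == pytest.approx(0.7)
        assert (table["dice"] >= table["jaccard"] - 1e-12).all()
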