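import numpy as np
import pandas as pd
import pytest

import densityatlas as da
from conftest import points_frame


def make_spec(regions, extent=(2000.0, 2000.0, 2000.0), spacing=50.0):
    return da.AtlasSpec(extent_um=extent, spacing_um=(spacing,) * 3,
                        regions=regions)


class TestBuildToyAtlas:
    def test_unit_cube_volume_and_voxel_count(self):
        spec = make_spec([da.RegionSpec(1, "cube",
                                        da.Box((500, 500, 500), (1500, 1500, 1500)))])
        atlas = da.build_toy_atlas(spec)
        assert (atlas.labels == 1).sum() == 20 ** 3
        assert atlas.region_volume_mm3(1) == pytest.approx(1.000, abs=1e-12)

    def test_empty_region_list(self):
        atlas = da.build_toy_atlas(make_spec([]))
        assert not atlas.labels.any()
        assert len(atlas.regions) == 0

    def test_face_sharing_boxes_accepted_and_additive(self):
        a = da.Box((0, 0, 0), (1000, 1000, 1000))
        b = da.Box((1000, 0, 0), (2000, 1000, 1000))
        atlas = da.build_toy_atlas(make_spec([da.RegionSpec(1, "a", a),
                                              da.RegionSpec(2, "b", b)]))
        assert atlas.region_volume_mm3(1) + atlas.region_volume_mm3(2) == \
            pytest.approx(2.0)

    def test_overlapping_regions_rejected_naming_pair(self):
        a = da.Box((0, 0, 0), (1000, 1000, 1000))
        b = da.Box((900, 0, 0), (1900, 1000, 1000))
        with pytest.raises(ValueError, match="1 and 2"):
            da.build_toy_atlas(make_spec([da.RegionSpec(1, "a", a),
                                          da.RegionSpec(2, "b", b)]))

    def test_geometry_outside_extent_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            make_spec([da.RegionSpec(1, "big",
                                     da.Sphere((1900, 1000, 1000), 200.0))])

    @pytest.mark.parametrize("geom", [
        da.Box((130, 220, 310), (870, 660, 540)),
        da.Sphere((1000, 1000, 1000), 430.0),
    ])
    def test_volumes_match_brute_force_center_count(self, geom):
        # independent oracle: test every voxel center directly
        atlas = da.build_toy_atlas(make_spec([da.RegionSpec(1, "r", geom)]))
        s = 50.0
        idx = np.indices(atlas.labels.shape).reshape(3, -1).T
        centers = (idx + 0.5) * s
        inside = geom.contains(centers)
        assert (atlas.labels == 1).sum() == inside.sum()
        assert atlas.region_volume_mm3(1) == pytest.approx(
            inside.sum() * (0.05 ** 3))

    def test_duplicate_and_nonpositive_ids_rejected(self):
        g = da.Box((0, 0, 0), (500, 500, 500))
        h = da.Box((1000, 1000, 1000), (1500, 1500, 1500))
        with pytest.raises(ValueError, match="unique"):
            make_spec([da.RegionSpec(1, "a", g), da.RegionSpec(1, "b", h)])
        with pytest.raises(ValueError, match="> 0"):
            make_spec([da.RegionSpec(0, "a", g)])


@pytest.fixture(scope="module")
def cube_atlas():
    return da.build_toy_atlas(make_spec(
        [da.RegionSpec(1, "cube", da.Box((500, 500, 500), (1500, 1500, 1500)))]))


class TestSamplePointCloud:
    def intensities(self, lam, group_effects=None):
        return da.IntensityTable(
            entries=pd.DataFrame([(1, "t", lam)],
                                 columns=["region_id", "cell_type",
                                          "density_per_mm3"]),
            group_effects=group_effects)

    def test_zero_intensity_empty_table(self, cube_atlas):
        pts = da.sample_point_cloud(cube_atlas, self.intensities(0.0), "s1")
        assert len(pts) == 0

    def test_same_seed_identical(self, cube_atlas):
        a = da.sample_point_cloud(cube_atlas, self.intensities(5e4), "s1", seed=7)
        b = da.sample_point_cloud(cube_atlas, self.intensities(5e4), "s1", seed=7)
        pd.testing.assert_frame_equal(a, b)
        c = da.sample_point_cloud(cube_atlas, self.intensities(5e4), "s1", seed=8)
        assert len(c) == 0 or not a.equals(c)

    def test_poisson_mean_recovered(self, cube_atlas):
        lam = 1e5  # cells/mm3 in a 1 mm3 region
        totals = [len(da.sample_point_cloud(cube_atlas, self.intensities(lam),
                                            "s1", seed=s))
                  for s in range(200)]
        assert abs(np.mean(totals) - lam) < 3 * np.sqrt(lam)

    def test_points_inside_region_and_columns(self, cube_atlas):
        pts = da.sample_point_cloud(cube_atlas, self.intensities(2e4), "s9",
                                    group="F", seed=3)
        assert set(da.core.POINT_COLUMNS).issubset(pts.columns)
        coords = pts[["x_um", "y_um", "z_um"]].to_numpy()
        assert np.all((coords >= 500) & (coords < 1500))
        assert (pts["subject_id"] == "s9").all() and (pts["group"] == "F").all()

    def test_group_multiplier_scales_intensity(self, cube_atlas):
        eff = pd.DataFrame([("t", "M", 2.0)],
                           columns=["cell_type", "group", "multiplier"])
        lam = 2e4
        totals = [len(da.sample_point_cloud(
            cube_atlas, self.intensities(lam, eff), "s1", group="M", seed=s))
            for s in range(100)]
        assert abs(np.mean(totals) - 2 * lam) < 3 * np.sqrt(2 * lam)

    def test_unknown_region_rejected(self, cube_atlas):
        bad = da.IntensityTable(entries=pd.DataFrame(
            [(9, "t", 1e4)], columns=["region_id", "cell_type", "density_per_mm3"]))
        with pytest.raises(ValueError, match="unknown region"):
            da.sample_point_cloud(cube_atlas, bad, "s1")

    def test_invalid_intensity_tables_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            da.IntensityTable(entries=pd.DataFrame(
                [(1, "t", -5.0)],
                columns=["region_id", "cell_type", "density_per_mm3"]))
        with pytest.raises(ValueError, match="duplicate"):
            da.IntensityTable(entries=pd.DataFrame(
                [(1, "t", 1.0), (1, "t", 2.0)],
                columns=["region_id", "cell_type", "density_per_mm3"]))

    def test_cohort_reproducible_and_multisubject(self, cube_atlas):
        subjects = [("s1", "M"), ("s2", "F")]
        a = da.sample_cohort(cube_atlas, self.intensities(3e4), subjects, seed=5)
        b = da.sample_cohort(cube_atlas, self.intensities(3e4), subjects, seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert set(a["subject_id"]) == {"s1", "s2"}


class TestEmpiricalDensity:
    def test_density_within_three_se_per_region_and_type(self, small_atlas):
        entries = pd.DataFrame(
            [(1, "a", 4e4), (1, "b", 1e4), (2, "a", 8e4)],
            columns=["region_id", "cell_type", "density_per_mm3"])
        table = da.IntensityTable(entries=entries)
        counts = {(rid, ct): [] for rid, ct, _ in entries.itertuples(index=False)}
        n_seeds = 100
        for s in range(n_seeds):
            pts = da.sample_point_cloud(small_atlas, table, "s1", seed=s)
            labelled = da.assign_regions(pts, small_atlas)
            for (rid, ct), acc in counts.items():
                acc.append(((labelled["region_id"] == rid)
                            & (labelled["cell_type"] == ct)).sum())
        for (rid, ct), acc in counts.items():
            vol = small_atlas.region_volume_mm3(rid)
            lam = float(entries.query("region_id == @rid and cell_type == @ct")
                        ["density_per_mm3"].iloc[0])
            expected = lam * vol
            se = np.sqrt(expected / n_seeds)
            assert abs(np.mean(acc) - expected) < 3 * se


class TestRenderNucleiStack:
    def spec(self, **kw):
        base = dict(shape=(4, 64, 64), spacing_um=(1.0, 1.0, 50.0),
                    nucleus_radius_um=3.0, amplitude=100.0, background=7.0,
                    noise_sd=0.0)
        base.update(kw)
        return da.ImageSpec(**base)

    def test_no_points_no_noise_constant_background(self):
        stack, truth = da.render_nuclei_stack(points_frame(np.empty((0, 3))),
                                              self.spec(), seed=0)
        assert np.all(stack.data == 7.0)
        assert len(truth) == 0

    def test_single_point_gives_global_max_at_its_voxel(self):
        pts = points_frame(np.array([[32.5, 20.5, 75.0]]))  # voxel (1, 20, 32)
        stack, _ = da.render_nuclei_stack(pts, self.spec(), seed=0)
        assert np.unravel_index(np.argmax(stack.data), stack.data.shape) == \
            (1, 20, 32)

    def test_noise_sd_recovered_in_blob_free_corner(self):
        spec = self.spec(shape=(6, 128, 128), noise_sd=10.0)
        pts = points_frame(np.array([[100.0, 100.0, 150.0]]))
        stack, _ = da.render_nuclei_stack(pts, spec, seed=11)
        corner = stack.data[:, :40, :40]  # > 8 sigma from the blob
        assert abs(corner.std() - 10.0) / 10.0 < 0.05

    def test_point_outside_extent_rejected(self):
        pts = points_frame(np.array([[10.0, 10.0, 100.0],
                                     [100.0, 10.0, 100.0]]))
        with pytest.raises(ValueError, match="outside"):
            da.render_nuclei_stack(pts, self.spec(shape=(4, 32, 32)), seed=0)

    def test_reproducible(self):
        spec = self.spec(noise_sd=5.0)
        pts = points_frame(np.array([[30.0, 30.0, 100.0]]))
        a, _ = da.render_nuclei_stack(pts, spec, seed=3)
        b, _ = da.render_nuclei_stack(pts, spec, seed=3)
        assert np.array_equal(a.data, b.data)


class TestPlantedBlocks:
    def test_shapes_and_labels(self):
        matrix, labels = da.planted_block_matrix(
            n_regions_per_block=3, n_blocks=4, n_types=8, noise=0.05, seed=1)
        assert matrix.shape == (12, 8)
        assert np.array_equal(np.unique(labels), np.arange(4))
        assert (matrix.to_numpy() > 0).all()
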