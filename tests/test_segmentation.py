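"""Thresholding, connectivity analysis and object measurement."""

import numpy as np
import pytest

import angiomorph as am

from conftest import flood_fill_partition, labels_to_partition


class TestThreshold:
    def test_strict_inequality_convention(self):
        field = np.array([[[2100.0, 2200.0, 2300.0]]])
        mask = am.threshold_volume(field, 2200.0)
        assert mask.tolist() == [[[False, False, True]]]

    def test_all_below_gives_empty_all_above_gives_full(self):
        field = np.full((4, 4, 4), 10.0)
        assert not am.threshold_volume(field, 10.0).any()
        assert am.threshold_volume(field, 9.999).all()

    def test_nonfinite_rejected(self):
        field = np.zeros((2, 2, 2))
        field[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            am.threshold_volume(field, 0.0)


class TestLabeling:
    def test_two_separated_cubes(self):
        mask = np.zeros((10, 6, 6), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        mask[6:8, 1:3, 1:3] = True
        objs = am.label_components(mask)
        assert objs.n_objects == 2
        assert objs.table["voxel_count"].tolist() == [8, 8]

    def test_corner_touch_connectivity(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 1, 1] = True
        mask[2, 2, 2] = True
        assert am.label_components(mask, connectivity=26).n_objects == 1
        assert am.label_components(mask, connectivity=6).n_objects == 2
        assert am.label_components(mask, connectivity=18).n_objects == 2

    def test_labels_follow_raster_order(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[4, 4, 4] = True  # later in raster order
        mask[0, 0, 0] = True
        objs = am.label_components(mask)
        assert objs.labels[0, 0, 0] == 1
        assert objs.labels[4, 4, 4] == 2

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(11)
        for _ in range(10):
            mask = rng.random((16, 16, 16)) < 0.25
            objs = am.label_components(mask, connectivity=connectivity)
            assert labels_to_partition(objs.labels) == flood_fill_partition(mask, connectivity)

    def test_partition_and_volume_conservation(self):
        rng = np.random.default_rng(4)
        mask = rng.random((14, 14, 14)) < 0.3
        objs = am.label_components(mask)
        assert (objs.labels > 0).sum() == mask.sum()
        assert objs.table["voxel_count"].sum() == mask.sum()
        measured = am.measure_objects(objs, (0.31, 0.31, 0.40))
        vox_vol = 0.31 * 0.31 * 0.40
        assert measured.table["volume_mm3"].sum() == pytest.approx(mask.sum() * vox_vol)


class TestMinSizeFilter:
    def _objects_with_sizes(self, sizes):
        mask = np.zeros((len(sizes) * 4, 12, 12), dtype=bool)
        for i, s in enumerate(sizes):
            # a 1-voxel-wide bar of length s
            mask[i * 4, 1:1 + s, 1] = True
        return am.label_components(mask)

    def test_minimum_four_voxels(self):
        objs = am.filter_min_size(self._objects_with_sizes([1, 3, 4, 10]), min_voxels=4)
        assert sorted(objs.table["voxel_count"]) == [4, 10]
        assert sorted(np.unique(objs.labels).tolist()) == [0, 1, 2]

    def test_min_one_is_identity(self):
        objs = self._objects_with_sizes([1, 3, 4])
        filtered = am.filter_min_size(objs, min_voxels=1)
        assert np.array_equal(filtered.labels, objs.labels)

    def test_filtering_everything_leaves_empty_result(self):
        objs = am.filter_min_size(self._objects_with_sizes([2, 3]), min_voxels=99)
        assert objs.n_objects == 0
        assert not objs.mask.any()


class TestMeasurement:
    def test_cube_surface_and_volume(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        objs = am.measure_objects(am.label_components(mask), (1.0, 1.0, 1.0))
        row = objs.table.iloc[0]
        assert row["volume_mm3"] == pytest.approx(27.0)
        assert row["exposed_face_count"] == 54
        assert row["surface_mm2"] == pytest.approx(54.0)
        assert row["surface_voxel_count"] == 26

    def test_single_voxel_anisotropic(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        objs = am.measure_objects(am.label_components(mask), (0.31, 0.31, 0.40))
        row = objs.table.iloc[0]
        assert row["volume_mm3"] == pytest.approx(0.31 * 0.31 * 0.40)
        assert row["surface_mm2"] == pytest.approx(2 * 0.31 * 0.31 + 4 * 0.31 * 0.40)

    def test_grid_boundary_faces_count_as_exposed(self):
        mask = np.ones((2, 2, 2), dtype=bool)
        objs = am.measure_objects(am.label_components(mask), (1.0, 1.0, 1.0))
        assert objs.table.iloc[0]["surface_mm2"] == pytest.approx(24.0)

    def test_digitized_sphere_face_count_exceeds_smooth_surface(self):
        # exposed-face area of a digitized sphere converges to 1.5x the
        # smooth area 4 pi r^2 (faces are axis-aligned)
        r = 10.0
        n = 26
        idx = np.stack(np.meshgrid(*[np.arange(n)] * 3, indexing="ij"), axis=-1)
        center = (n - 1) / 2
        mask = ((idx - center) ** 2).sum(axis=-1) <= r * r
        surf = am.mask_surface_mm2(mask, (1.0, 1.0, 1.0))
        ratio = surf / (4 * np.pi * r**2)
        assert ratio == pytest.approx(1.5, abs=0.06)
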