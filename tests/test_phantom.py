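"""Synthetic phantom generator: geometry, rasterization, intensity model."""

import math

import numpy as np
import pytest

import angiomorph as am
from angiomorph.phantom import Segment

from conftest import make_cylinder_mask


def _single_segment_tree(p0, p1, radius, spec):
    seg = Segment(points=np.array([p0, p1], dtype=float), radius=radius, tree_id=0)
    return am.VesselTree(segments=[seg], branch_points=[],
                         endpoints=[np.asarray(p0, float), np.asarray(p1, float)],
                         spec=spec)


class TestTreeGeneration:
    def test_segment_count_is_density_times_volume(self):
        # 64^3 at 0.31x0.31x0.40 mm is 10.07 cm^3 -> 10 segments at 1.0/cm^3
        spec = am.PhantomSpec(branches_per_cm3_target=1.0, seed=3)
        assert spec.voi_volume_cm3 == pytest.approx(10.077, abs=0.01)
        tree = am.generate_vessel_tree(spec)
        assert tree.n_segments == 10

    def test_zero_tortuosity_gives_straight_two_point_polylines(self):
        spec = am.PhantomSpec(tortuosity=0.0, seed=1, branches_per_cm3_target=1.5)
        tree = am.generate_vessel_tree(spec)
        assert all(len(s.points) == 2 for s in tree.segments)

    def test_seeded_determinism(self):
        trees = [am.generate_vessel_tree(am.tumor_preset(seed=7)) for _ in range(2)]
        a, b = trees
        assert a.n_segments == b.n_segments
        for sa, sb in zip(a.segments, b.segments):
            assert np.array_equal(sa.points, sb.points)
            assert sa.radius == sb.radius

    def test_tree_lies_inside_grid(self):
        spec = am.tumor_preset(seed=9)
        tree = am.generate_vessel_tree(spec)
        size = spec.physical_size_mm
        for s in tree.segments:
            assert np.all(s.points >= 0) and np.all(s.points <= size)

    def test_segment_lengths_respect_truncation(self):
        spec = am.tumor_preset(seed=4, branch_length_sd_mm=2.0)
        tree = am.generate_vessel_tree(spec)
        min_len = 2.0 * max(spec.spacing_mm)
        assert tree.segment_lengths_mm().min() >= min_len - 1e-9

    def test_overfull_grid_raises(self):
        with pytest.raises(ValueError, match="grid too small"):
            am.generate_vessel_tree(
                am.PhantomSpec(grid_shape=(24, 24, 24), branches_per_cm3_target=400.0)
            )


class TestRasterization:
    def test_cylinder_analytic_volume(self):
        # radius 0.5 mm, length 10 mm: pi r^2 l = 7.854 mm^3
        spec = am.PhantomSpec(grid_shape=(16, 8, 8), spacing_mm=(1, 1, 1), seed=0)
        tree = _single_segment_tree([3, 4, 4], [13, 4, 4], 0.5, spec)
        _, truth = am.rasterize_tree(tree, spec)
        assert truth.analytic["total_volume_mm3"] == pytest.approx(math.pi * 0.25 * 10, rel=1e-12)
        assert truth.analytic["n_branches"] == 1

    def test_empty_tree_gives_empty_mask(self):
        spec = am.PhantomSpec(grid_shape=(8, 8, 8), seed=0)
        tree = am.VesselTree(segments=[], branch_points=[], endpoints=[], spec=spec)
        mask, truth = am.rasterize_tree(tree, spec)
        assert not mask.any()
        assert truth.analytic["total_length_mm"] == 0.0
        assert truth.voxelized["volume_mm3"] == 0.0

    def test_matches_brute_force_voxel_center_distance(self):
        # anisotropic grid, cylinder radius 1.0 mm, length 20 mm
        spec = am.PhantomSpec(grid_shape=(80, 20, 16), seed=0)
        p0, p1 = [2.0, 3.1, 3.2], [22.0, 3.1, 3.2]
        tree = _single_segment_tree(p0, p1, 1.0, spec)
        mask, truth = am.rasterize_tree(tree, spec)
        oracle = make_cylinder_mask(spec.grid_shape, spec.spacing_mm, p0, p1, 1.0)
        assert np.array_equal(mask, oracle)
        # voxelized volume near the analytic 62.83 mm^3 (caps add ~5%)
        assert truth.voxelized["volume_mm3"] == pytest.approx(62.83, rel=0.10)

    def test_voxelized_volume_converges_with_refinement(self):
        # one cylinder at two refinement levels: finer spacing, smaller error
        errs = []
        for spacing, shape in (((0.5, 0.5, 0.5), (48, 16, 16)),
                               ((0.25, 0.25, 0.25), (96, 32, 32))):
            spec = am.PhantomSpec(grid_shape=shape, spacing_mm=spacing, seed=0)
            p0 = [2.0, shape[1] * spacing[1] / 2, shape[2] * spacing[2] / 2]
            p1 = [p0[0] + 16.0, p0[1], p0[2]]
            tree = _single_segment_tree(p0, p1, 0.9, spec)
            _, truth = am.rasterize_tree(tree, spec)
            # compare against the capsule volume (cylinder + end caps, the
            # rasterizer's continuous limit)
            capsule = math.pi * 0.9**2 * 16.0 + 4 / 3 * math.pi * 0.9**3
            errs.append(abs(truth.voxelized["volume_mm3"] - capsule) / capsule)
        assert errs[1] < errs[0]

    def test_voxelized_volume_within_25pct_of_analytic(self, tumor_phantom):
        _, _, _, _, truth = tumor_phantom
        assert truth.voxelized["volume_mm3"] == pytest.approx(
            truth.analytic["total_volume_mm3"], rel=0.25
        )


class TestIntensityModel:
    def test_noiseless_image_has_exactly_two_values(self):
        spec = am.tumor_preset(seed=2, noise_sd=0.0)
        tree = am.generate_vessel_tree(spec)
        mask, _ = am.rasterize_tree(tree, spec)
        img = am.apply_tof_intensity_model(mask, spec)
        assert set(np.unique(img.data)) == {spec.background_intensity, spec.vessel_intensity}

    def test_seeded_noise_is_reproducible(self):
        spec = am.tumor_preset(seed=2, noise_sd=50.0)
        tree = am.generate_vessel_tree(spec)
        mask, _ = am.rasterize_tree(tree, spec)
        a = am.apply_tof_intensity_model(mask, spec)
        b = am.apply_tof_intensity_model(mask, spec)
        assert np.array_equal(a.data, b.data)

    def test_rician_mean_matches_analytic(self):
        # MC mean of the Rician magnitude vs scipy's closed form, and
        # convergence to the noiseless signal at high SNR
        from scipy.stats import rice

        sd = 50.0

        def mc_mean(signal):
            spec = am.PhantomSpec(
                grid_shape=(40, 40, 40), vessel_intensity=signal + 1,
                background_intensity=signal, noise_sd=sd, noise_model="rician", seed=8,
            )
            img = am.apply_tof_intensity_model(np.zeros(spec.grid_shape, dtype=bool), spec)
            return img.data.mean()

        # moderate SNR: matches the closed-form Rician mean
        assert mc_mean(200.0) == pytest.approx(rice.mean(b=4.0, scale=sd), rel=3e-3)
        # SNR -> infinity: converges to the noiseless signal
        assert mc_mean(3000.0) == pytest.approx(3000.0, abs=1.0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            am.PhantomSpec(noise_sd=-1.0)

    def test_vessel_must_exceed_background(self):
        with pytest.raises(ValueError):
            am.PhantomSpec(vessel_intensity=100.0, background_intensity=200.0)

    def test_grid_mismatch_rejected(self):
        spec = am.PhantomSpec(grid_shape=(8, 8, 8))
        with pytest.raises(ValueError, match="does not match"):
            am.apply_tof_intensity_model(np.zeros((4, 4, 4), dtype=bool), spec)
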