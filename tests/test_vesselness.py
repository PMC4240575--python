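"""Hessian computation and vesselness score: closed forms and geometry."""

import numpy as np
import pytest

import angiomorph as am
from angiomorph.vesselness import auto_c

from conftest import make_cylinder_mask


def _vol(data, spacing=(1.0, 1.0, 1.0)):
    return am.ImageVolume(np.asarray(data, dtype=float), spacing)


class TestHessian:
    def test_constant_volume_has_zero_hessian(self):
        h = am.hessian_at_scale(_vol(np.full((12, 12, 12), 7.0)), 1.0)
        for comp in (h.xx, h.yy, h.zz, h.xy, h.xz, h.yz):
            assert np.allclose(comp, 0.0, atol=1e-6)

    def test_quadratic_image_gives_exact_second_derivative(self):
        # I = x^2 in mm: Gaussian smoothing preserves the second derivative
        # of a polynomial, so the xx component is 2 everywhere (gamma=0).
        nx = 31
        x = np.arange(nx) * 0.5
        data = np.broadcast_to((x**2)[:, None, None], (nx, 15, 15)).copy()
        h = am.hessian_at_scale(_vol(data, (0.5, 0.5, 0.5)), sigma_mm=1.0, gamma=0.0)
        interior = h.xx[13:-13, 5:-5, 5:-5]
        assert np.allclose(interior, 2.0, rtol=1e-6)
        assert np.allclose(h.yy[13:-13, 5:-5, 5:-5], 0.0, atol=1e-7)

    def test_gaussian_ridge_curvature_signs(self):
        # bright ridge along x: strong negative curvature across it (yy),
        # none along it (xx)
        ny = 41
        y = (np.arange(ny) - ny // 2) * 1.0
        profile = np.exp(-(y**2) / (2 * 3.0**2))
        data = np.broadcast_to(profile[None, :, None], (21, ny, 21)).copy()
        h = am.hessian_at_scale(_vol(data), sigma_mm=2.0)
        crest = (10, ny // 2, 10)
        assert h.yy[crest] < -1e-4
        assert abs(h.xx[crest]) < 1e-8 + 0.01 * abs(h.yy[crest])

    def test_anisotropic_spacing_consistency(self):
        # the same physical ridge sampled on two grids gives matching
        # physical-unit derivatives at the crest
        w = 2.0
        field = lambda y: np.exp(-(y**2) / (2 * w**2))
        y_fine = (np.arange(81) - 40) * 0.25
        y_coarse = (np.arange(41) - 20) * 0.5
        fine = np.broadcast_to(field(y_fine)[None, :, None], (15, 81, 15)).copy()
        coarse = np.broadcast_to(field(y_coarse)[None, :, None], (15, 41, 15)).copy()
        h_f = am.hessian_at_scale(_vol(fine, (0.5, 0.25, 0.5)), 1.0)
        h_c = am.hessian_at_scale(_vol(coarse, (0.5, 0.5, 0.5)), 1.0)
        assert h_f.yy[7, 40, 7] == pytest.approx(h_c.yy[7, 20, 7], rel=1e-3)


class TestEigenvalues:
    def _field_from_matrices(self, mats):
        mats = np.asarray(mats, dtype=float).reshape(-1, 1, 1, 3, 3)
        return am.HessianField(
            xx=mats[..., 0, 0], yy=mats[..., 1, 1], zz=mats[..., 2, 2],
            xy=mats[..., 0, 1], xz=mats[..., 0, 2], yz=mats[..., 1, 2],
            sigma_mm=1.0,
        )

    def test_diagonal_and_zero_matrices(self):
        h = self._field_from_matrices([np.diag([0.0, -4.0, -9.0]), np.zeros((3, 3))])
        eigs = am.eigenvalues_sorted(h)
        assert np.allclose(eigs[0, 0, 0], [0.0, -4.0, -9.0])
        assert np.allclose(eigs[1, 0, 0], [0.0, 0.0, 0.0])

    def test_random_symmetric_matches_characteristic_polynomial_roots(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(50, 3, 3))
        mats = (a + a.transpose(0, 2, 1)) / 2
        eigs = am.eigenvalues_sorted(self._field_from_matrices(mats))
        for i, m in enumerate(mats):
            # brute-force: roots of det(m - x I)
            c2 = -np.trace(m)
            c1 = 0.5 * (np.trace(m) ** 2 - np.trace(m @ m))
            c0 = -np.linalg.det(m)
            roots = np.roots([1.0, c2, c1, c0])
            roots = np.sort_complex(roots).real
            expected = sorted(roots, key=abs)
            assert np.allclose(eigs.reshape(-1, 3)[i], expected, atol=1e-8)


class TestVesselnessScore:
    def _score(self, lams, **kw):
        eigs = np.asarray(lams, dtype=float).reshape(1, 1, 1, 3)
        params = am.VesselnessParams(**{"alpha": 0.5, "beta": 0.5, "c": 5.0, **kw})
        return float(am.vesselness_at_scale(eigs, params).item())

    def test_zero_eigenvalues_score_zero(self):
        assert self._score([0.0, 0.0, 0.0]) == 0.0

    def test_positive_eigenvalue_gate(self):
        assert self._score([0.0, -1.0, 5.0]) == 0.0

    def test_closed_form_value(self):
        # l = (0, -10, -10): R_A=1, R_B=0, S=sqrt(200)
        expected = (1 - np.exp(-2.0)) * (1 - np.exp(-200.0 / 50.0))
        assert self._score([0.0, -10.0, -10.0]) == pytest.approx(expected, rel=1e-12)

    def test_two_eigenvalue_compatibility_mode(self):
        v = self._score([0.0, -10.0, -10.0], mode="as_printed_2eig", beta=0.5)
        expected = np.exp(-1.0 / (2 * 0.25)) * (1 - np.exp(-200.0 / 50.0))
        assert v == pytest.approx(expected, rel=1e-12)

    def test_output_bounded(self, tumor_phantom):
        _, image, voi, _, _ = tumor_phantom
        v = am.multiscale_vesselness(image, am.VesselnessParams(scales_mm=(0.3, 0.6)))
        assert v.min() >= 0.0 and v.max() <= 1.0

    def test_intensity_scaling_never_decreases_score_at_fixed_c(self):
        rng = np.random.default_rng(3)
        from scipy.ndimage import gaussian_filter

        data = gaussian_filter(rng.normal(size=(16, 16, 16)), 2.0)
        params = am.VesselnessParams(scales_mm=(1.0,), c=0.5)
        v1 = am.multiscale_vesselness(_vol(data), params)
        v2 = am.multiscale_vesselness(_vol(3.0 * data), params)
        assert np.all(v2 >= v1 - 1e-12)


class TestMultiscale:
    def test_single_scale_equals_per_scale_call(self):
        rng = np.random.default_rng(5)
        from scipy.ndimage import gaussian_filter

        vol = _vol(gaussian_filter(rng.normal(size=(14, 14, 14)), 1.5))
        params = am.VesselnessParams(scales_mm=(0.8,), c=None)
        v_multi = am.multiscale_vesselness(vol, params)
        h = am.hessian_at_scale(vol, 0.8, gamma=2.0)
        v_single = am.vesselness_at_scale(
            am.eigenvalues_sorted(h), params, c=auto_c(h)
        )
        assert np.allclose(v_multi, v_single)

    def test_constant_volume_scores_zero(self):
        v = am.multiscale_vesselness(_vol(np.full((10, 10, 10), 42.0)))
        assert np.all(v == 0.0)

    def test_empty_scale_list_rejected(self):
        with pytest.raises(ValueError):
            am.VesselnessParams(scales_mm=())

    def test_argmax_scale_tracks_vessel_radius(self):
        # one phantom holding a thin (r=0.4 mm) and a thick (r=1.0 mm) tube,
        # scales 0.3/0.9 mm: on each centerline the winning scale is the one
        # nearest that tube's radius
        shape, spacing = (40, 36, 24), (0.4, 0.4, 0.4)
        thin = make_cylinder_mask(shape, spacing, (2, 4.0, 4.8), (14, 4.0, 4.8), 0.4)
        thick = make_cylinder_mask(shape, spacing, (2, 10.4, 4.8), (14, 10.4, 4.8), 1.0)
        vol = _vol(1000.0 * (thin | thick), spacing)
        params = am.VesselnessParams(scales_mm=(0.3, 0.9))
        _, scale = am.multiscale_vesselness(vol, params, return_scales=True)
        for j, expected in ((9, 0.3), (25, 0.9)):
            winner = scale[8:28, j, 11]
            assert (winner == expected).mean() > 0.7

    def test_approximate_rotation_invariance(self):
        # equal-radius cylinders, axis-aligned vs body-diagonal: centerline
        # response within 10%
        shape, spacing = (34, 34, 34), (0.4, 0.4, 0.4)
        size = np.array(shape) * np.array(spacing)
        mid = size / 2
        r = 1.0
        axis_mask = make_cylinder_mask(shape, spacing, (2, mid[1], mid[2]),
                                       (size[0] - 2, mid[1], mid[2]), r)
        diag_mask = make_cylinder_mask(shape, spacing, (2.5, 2.5, 2.5),
                                       (size[0] - 2.5, size[1] - 2.5, size[2] - 2.5), r)
        params = am.VesselnessParams(scales_mm=(0.5, 0.7, 1.0), c=50.0)

        def centerline_response(mask, p0, p1):
            # per-station maximum near the axis: robust to how the voxel
            # lattice samples the (possibly oblique) centerline
            vol = _vol(1000.0 * mask, spacing)
            v = am.multiscale_vesselness(vol, params)
            idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
            centers = (idx + 0.5) * np.asarray(spacing)
            p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
            ab = p1 - p0
            t = ((centers - p0) @ ab) / (ab @ ab)
            proj = p0 + t[..., None] * ab
            d = np.linalg.norm(centers - proj, axis=-1)
            stations = []
            for lo in np.arange(0.25, 0.75, 0.05):
                sel = (d < 0.5 * r) & (t >= lo) & (t < lo + 0.05)
                if sel.any():
                    stations.append(v[sel].max())
            return float(np.mean(stations))

        v_axis = centerline_response(axis_mask, (2, mid[1], mid[2]), (size[0] - 2, mid[1], mid[2]))
        v_diag = centerline_response(diag_mask, (2.5, 2.5, 2.5),
                                     (size[0] - 2.5, size[1] - 2.5, size[2] - 2.5))
        assert v_diag == pytest.approx(v_axis, rel=0.10)
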