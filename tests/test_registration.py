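"""Stage-level oracles: ICP recovery, TPS exactness, demons refinement,
chain composition and the registration QC metrics."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

import lungexpand as lx
from lungexpand import (AffineTransform, BinaryMask, DemonsParams,
                        DisplacementField, TransformChain, Volume3D,
                        affine_icp, compose, demons, extract_surface_points,
                        registration_error, tps_fit_points, volume_difference)
from lungexpand.volume_io import LandmarkSet

from conftest import rng_points


class TestSurfacePoints:
    def test_cube_points_on_faces(self):
        arr = np.zeros((14, 14, 14), bool)
        arr[2:12, 2:12, 2:12] = True
        m = BinaryMask(arr, spacing=(1, 1, 1))
        pts = extract_surface_points(m, 200, seed=1)
        on_face = np.any((pts == 2.0) | (pts == 11.0), axis=1)
        assert on_face.all()

    def test_seed_determinism(self):
        arr = np.zeros((14, 14, 14), bool)
        arr[2:12, 2:12, 2:12] = True
        m = BinaryMask(arr, spacing=(1, 1, 1))
        np.testing.assert_array_equal(extract_surface_points(m, 50, seed=4),
                                      extract_surface_points(m, 50, seed=4))

    def test_sphere_points_near_radius(self):
        n = 33
        c = (n - 1) / 2.0
        idx = np.indices((n, n, n)).transpose(1, 2, 3, 0)
        r = np.linalg.norm(idx - c, axis=-1)
        m = BinaryMask(r <= 12.0, spacing=(1, 1, 1))
        pts = extract_surface_points(m, 300, seed=0)
        d = np.linalg.norm(pts - c, axis=1)
        half_diag = np.sqrt(3) / 2
        assert np.all(np.abs(d - 12.0) <= 1.0 + half_diag)


class TestAffineICP:
    def test_identity(self):
        pts = rng_points(0, 200)
        t = affine_icp(pts, pts)
        moved = t.apply(pts)
        assert np.sqrt(np.mean(np.sum((moved - pts) ** 2, axis=1))) < 1e-6

    def test_known_affine_recovery(self):
        pts = rng_points(1, 300)
        A = np.array([[1.1, 0.05, 0.0], [0.0, 0.95, 0.02], [0.03, 0.0, 1.2]])
        b = np.array([5.0, -3.0, 10.0])
        target = pts @ A.T + b
        t = affine_icp(pts, target)
        rms = np.sqrt(np.mean(np.sum((t.apply(pts) - target) ** 2, axis=1)))
        assert rms < 0.1

    def test_isotropic_scale(self):
        pts = rng_points(2, 400)
        t = affine_icp(pts, pts * 1.2)
        assert np.allclose(np.diag(t.matrix), 1.2, rtol=0.02)

    def test_coplanar_rejected(self):
        pts = rng_points(3, 50)
        pts[:, 2] = 0.0
        with pytest.raises(ValueError, match="coplanar"):
            affine_icp(pts, pts + 1.0)


class TestTPS:
    def test_identity_zero_weights(self):
        src = rng_points(4, 12)
        t = tps_fit_points(src, src)
        assert np.abs(t.kernel_weights).max() < 1e-8
        np.testing.assert_allclose(t.apply(src), src, atol=1e-8)

    def test_translation_reproduced_affinely(self):
        src = rng_points(5, 15)
        dst = src + np.array([5.0, 0.0, 0.0])
        t = tps_fit_points(src, dst)
        assert np.abs(t.kernel_weights).max() < 1e-8
        np.testing.assert_allclose(t.affine_part.translation[0], 5.0, atol=1e-8)
        np.testing.assert_allclose(t.affine_part.matrix, np.eye(3), atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_interpolation(self, seed):
        src = rng_points(seed, 10)
        dst = src + rng_points(seed + 100, 10, -10, 10)
        t = tps_fit_points(src, dst)
        assert np.abs(t.apply(src) - dst).max() < 1e-8

    def test_orthogonality_conditions(self):
        src = rng_points(6, 20)
        dst = src + rng_points(7, 20, -5, 5)
        t = tps_fit_points(src, dst)
        assert np.abs(t.kernel_weights.sum(axis=0)).max() < 1e-8
        assert np.abs(src.T @ t.kernel_weights).max() < 1e-8

    def test_duplicate_points_rejected(self):
        src = rng_points(8, 6)
        src[1] = src[0]
        with pytest.raises(ValueError, match="duplicate|singular"):
            tps_fit_points(src, src + 1.0)


class TestDemons:
    def test_zero_force_returns_init(self, small_phantom):
        exp_vol, exp_mask, _ = small_phantom
        rng = np.random.default_rng(0)
        init = DisplacementField(
            ndimage.gaussian_filter(
                rng.normal(0, 1.0, exp_vol.shape + (3,)), (4, 4, 4, 0)),
            spacing=exp_vol.spacing)
        out = demons(exp_vol, exp_vol, init_field=init,
                     params=DemonsParams(levels=1, iterations=5),
                     mask=exp_mask)
        # identical images -> zero update (up to the field smoothing)
        assert np.abs(out.vectors - init.vectors).max() < 0.5

    def test_translation_recovery(self, small_phantom):
        exp_vol, exp_mask, _ = small_phantom
        shifted = ndimage.shift(exp_vol.values, (0, 0, -1.0), order=1,
                                mode="nearest")
        target = Volume3D(shifted, spacing=exp_vol.spacing)
        f = demons(target, exp_vol, mask=exp_mask)
        err = f.vectors[exp_mask.values] - np.array([0.0, 0.0, 4.0])
        assert np.linalg.norm(err, axis=1).mean() < 1.0

    def test_msd_never_increases(self, small_pair):
        exp_vol = small_pair["exp_vol"]
        insp_vol = small_pair["insp_vol"]
        mask = small_pair["exp_mask"]
        f = demons(exp_vol, insp_vol, mask=mask)
        idx = np.argwhere(mask.values)
        pts = mask.index_to_physical(idx) + f.vectors[mask.values]
        warped = ndimage.map_coordinates(
            insp_vol.values, exp_vol.physical_to_index(pts).T, order=1,
            mode="nearest")
        before = np.mean((exp_vol.values[mask.values]
                          - insp_vol.values[mask.values]) ** 2)
        after = np.mean((exp_vol.values[mask.values] - warped) ** 2)
        assert after <= before


class TestCompose:
    def test_identity_chain_zero_field(self):
        grid = Volume3D(np.zeros((8, 8, 8)), spacing=(2, 2, 2))
        f = compose(TransformChain(), grid)
        assert np.abs(f.vectors).max() == 0.0

    def test_pure_translation(self):
        grid = Volume3D(np.zeros((8, 8, 8)), spacing=(2, 2, 2))
        aff = AffineTransform(np.eye(3), [3.0, 0.0, 0.0])
        f = compose(TransformChain(affine=aff), grid)
        np.testing.assert_allclose(f.vectors[..., 0], 3.0)
        np.testing.assert_allclose(f.vectors[..., 1:], 0.0)

    def test_matches_sequential_evaluation(self):
        rng = np.random.default_rng(9)
        aff = AffineTransform(np.eye(3) + rng.normal(0, 0.02, (3, 3)),
                              rng.normal(0, 2, 3))
        src = rng_points(10, 8, 10, 54)
        tps = tps_fit_points(src, src + rng.normal(0, 1.5, (8, 3)))
        chain = TransformChain(affine=aff, tps=tps)
        grid = Volume3D(np.zeros((16, 16, 16)), spacing=(4, 4, 4))
        f = compose(chain, grid)
        # on-grid probes must agree exactly with sequential application
        idx = rng.integers(0, 16, size=(100, 3))
        pts = grid.index_to_physical(idx)
        direct = chain.apply(pts) - pts
        sampled = f.vectors[idx[:, 0], idx[:, 1], idx[:, 2]]
        assert np.abs(direct - sampled).max() < 1e-6


class _TrueChain:
    """Chain wrapper evaluating the generator's analytic field exactly."""

    def __init__(self, field):
        self.field = field

    def apply(self, pts):
        pts = np.atleast_2d(pts)
        return pts + self.field(pts)


class TestRegistrationQC:
    def test_perfect_chain_error_vanishes(self, small_pair):
        truth = small_pair["truth"]
        err = registration_error(truth.landmark_pairs,
                                 _TrueChain(truth.field))
        assert all(m < 1e-3 for m, _ in err.values())

    def test_identity_chain_constant_offset(self):
        pts = rng_points(11, 10, 0, 50)
        lm = LandmarkSet(pts, pts + [0, 0, 5.0],
                         ["bronchial"] * 10, ["right", "left"] * 5)
        err = registration_error(lm, TransformChain())
        for mean, sd in err.values():
            assert mean == pytest.approx(5.0)
            assert sd == pytest.approx(0.0, abs=1e-12)

    def test_missing_side_error(self):
        pts = rng_points(12, 6, 0, 50)
        lm = LandmarkSet(pts, pts, ["vascular"] * 6, ["right"] * 6)
        with pytest.raises(ValueError, match="no landmarks for side"):
            registration_error(lm, TransformChain())

    def test_volume_difference_identity_same_masks(self, small_pair):
        m = small_pair["exp_mask"]
        d, ok = volume_difference(m, m, TransformChain())
        assert d == pytest.approx(0.0)
        assert ok

    def test_volume_difference_true_chain(self):
        # 3 mm voxels: the nearest-neighbour boundary band must stay well
        # below 3% of the inspiratory volume
        from lungexpand import mask_volume
        spec = lx.PhantomSpec(grid_shape=(64, 64, 64), spacing=(3, 3, 3),
                              seed=3)
        exp_vol, exp_mask, truth = lx.make_phantom(spec)
        _, insp_mask, _ = lx.warp_to_inspiration(exp_vol, truth)
        grid = Volume3D(np.zeros(exp_mask.shape), spacing=exp_mask.spacing)
        field = DisplacementField(truth.field.dense(grid),
                                  spacing=exp_mask.spacing)
        d, _ = volume_difference(insp_mask, exp_mask,
                                 TransformChain(residual=field))
        assert d < 0.03 * mask_volume(insp_mask)

    def test_volume_difference_identity_equals_inflation(self, small_pair):
        from lungexpand import mask_volume
        exp_mask, insp_mask = small_pair["exp_mask"], small_pair["insp_mask"]
        d, _ = volume_difference(insp_mask, exp_mask, TransformChain())
        true_change = abs(mask_volume(insp_mask) - mask_volume(exp_mask))
        assert d == pytest.approx(true_change, rel=0.03)
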