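"""B-spline FFD registration: identity, constructed motion, sequences,
point propagation and mask warping."""

import numpy as np
import pytest
from scipy import ndimage

from conftest import constant_field, constant_flow_tset, linear_field
from morphomap.imaging import BinaryMask, Hyperstack
from morphomap.registration import (
    RegistrationParams,
    TransformField,
    TransformSet,
    _n_control,
    apply_transform_to_mask,
    downscale_for_registration,
    load_transform_set,
    propagate_points,
    register_pair,
    register_sequence,
    save_transform_set,
)


def smooth_texture(shape=(40, 40, 40), seed=0, sigma=3):
    rng = np.random.default_rng(seed)
    img = ndimage.gaussian_filter(rng.random(shape), sigma)
    return (img - img.min()) / (img.max() - img.min())


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RegistrationParams(grid_spacing=0)
        with pytest.raises(ValueError):
            RegistrationParams(lambda_reg=-1)
        with pytest.raises(ValueError):
            RegistrationParams(levels=0)
        with pytest.raises(ValueError):
            RegistrationParams(similarity="MI")


class TestTransformField:
    def test_zero_control_is_exact_identity(self):
        fld = constant_field((20, 22, 24), (0, 0, 0))
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 19, size=(50, 3))
        mapped, flags = fld.evaluate(pts)
        assert np.array_equal(mapped, pts)
        assert not flags.any()

    def test_out_of_domain_clamped_and_flagged(self):
        fld = constant_field((20, 20, 20), (1.0, 0, 0))
        mapped, flags = fld.evaluate(np.array([[25.0, 5.0, 5.0]]))
        assert flags[0]
        assert mapped[0, 0] == pytest.approx(20.0)  # 19 clamped + 1 shift

    def test_linear_field_is_reproduced_exactly(self):
        A = np.array([[0.1, 0.02, 0], [0, -0.05, 0.01], [0.03, 0, 0.08]])
        b = np.array([1.0, -2.0, 0.5])
        fld = linear_field((30, 30, 30), A, b)
        rng = np.random.default_rng(1)
        pts = rng.uniform(2, 27, size=(40, 3))
        disp = fld.displacement(pts)
        assert np.allclose(disp, pts @ A.T + b, atol=1e-9)


class TestRegisterPair:
    def test_identity_pair_near_zero_field(self):
        img = smooth_texture()
        fld, _ = register_pair(img, img, RegistrationParams(
            grid_spacing=6, levels=3, max_iter=40))
        assert fld.max_control_displacement() < 0.1

    def test_constructed_shift_recovered(self):
        ref = smooth_texture(seed=2)
        mov = ndimage.shift(ref, (3, 0, 0), order=1, mode="nearest")
        fld, _ = register_pair(ref, mov, RegistrationParams(
            grid_spacing=6, levels=4, max_iter=60))
        pts = np.stack(np.meshgrid(*[np.arange(10, 30)] * 3,
                                   indexing="ij")).reshape(3, -1).T
        mapped, _ = fld.evaluate(pts.astype(float))
        mean_disp = (mapped - pts).mean(axis=0)
        assert np.allclose(mean_disp, (3, 0, 0), atol=0.5)

    def test_known_bspline_warp_recovered(self):
        mov = smooth_texture(seed=3)
        rng = np.random.default_rng(4)
        n_ctl = tuple(_n_control(s, 8) for s in mov.shape)
        control = ndimage.gaussian_filter(
            rng.normal(0, 4.0, (3,) + n_ctl), (0, 1, 1, 1)
        )
        control = np.clip(control, -4, 4)
        true = TransformField(control=control, spacing=8,
                              domain=mov.shape, direction=(0, 1))
        coords = np.stack(np.meshgrid(
            *[np.arange(s, dtype=float) for s in mov.shape], indexing="ij"))
        pts = coords.reshape(3, -1).T
        warped_pts, _ = true.evaluate(pts)
        ref = ndimage.map_coordinates(mov, warped_pts.T, order=1,
                                      mode="nearest").reshape(mov.shape)
        est, _ = register_pair(ref, mov, RegistrationParams(
            grid_spacing=6, levels=4, max_iter=80))
        inner = np.stack(np.meshgrid(*[np.arange(8, 32)] * 3,
                                     indexing="ij")).reshape(3, -1).T
        t_est, _ = est.evaluate(inner.astype(float))
        t_true, _ = true.evaluate(inner.astype(float))
        err = np.linalg.norm(t_est - t_true, axis=1)
        assert err.mean() < 1.0

    def test_shape_mismatch_and_nonfinite_rejected(self):
        a = np.zeros((8, 8, 8))
        with pytest.raises(ValueError):
            register_pair(a, np.zeros((8, 8, 9)))
        b = a.copy()
        b[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            register_pair(a, b)


class TestRegisterSequence:
    def test_two_frames_bidirectional_layout(self):
        img = smooth_texture((24, 24, 24))
        stack = Hyperstack(intensity=np.stack([img, img], axis=-1),
                           voxel_size=1.0)
        tset = register_sequence(stack, RegistrationParams(
            grid_spacing=6, levels=2, max_iter=10))
        assert tset.anchor == 1
        assert len(tset.backward) == 1
        assert len(tset.forward) == 0

    def test_static_sequence_near_identity_fields(self):
        img = smooth_texture((24, 24, 24), seed=5)
        stack = Hyperstack(intensity=np.stack([img] * 6, axis=-1),
                           voxel_size=1.0)
        tset = register_sequence(stack, RegistrationParams(
            grid_spacing=6, levels=2, max_iter=20))
        for fld in tset.forward + tset.backward:
            assert fld.max_control_displacement() < 0.1

    def test_single_frame_rejected(self):
        stack = Hyperstack(intensity=np.zeros((8, 8, 8, 1)), voxel_size=1.0)
        with pytest.raises(ValueError):
            register_sequence(stack)


class TestPropagatePoints:
    def test_same_frame_is_identity(self):
        tset = constant_flow_tset((30, 30, 30), 5, (2, 0, 0))
        pts = np.array([[10.0, 10, 10]])
        out, flags = propagate_points(pts, tset, 2, 2)
        assert np.array_equal(out, pts)
        assert not flags.any()

    def test_identity_fields_leave_points_unchanged(self):
        tset = constant_flow_tset((30, 30, 30), 7, (0, 0, 0))
        rng = np.random.default_rng(6)
        pts = rng.uniform(5, 25, (20, 3))
        out, _ = propagate_points(pts, tset, tset.anchor, 6)
        assert np.allclose(out, pts, atol=1e-12)

    def test_constant_flow_accumulates_exactly(self):
        tset = constant_flow_tset((40, 40, 40), 6, (2, 0, 0), anchor=0)
        pts = np.array([[5.0, 20, 20], [10.0, 15, 25]])
        out, _ = propagate_points(pts, tset, 0, 5)
        assert np.allclose(out - pts, [[10, 0, 0], [10, 0, 0]], atol=0.5)

    def test_direction_outside_anchor_paths_rejected(self):
        tset = constant_flow_tset((30, 30, 30), 6, (1, 0, 0))  # anchor 3
        pts = np.array([[10.0, 10, 10]])
        with pytest.raises(ValueError):
            propagate_points(pts, tset, 1, 4)  # forward from below anchor
        with pytest.raises(ValueError):
            propagate_points(pts, tset, 5, 2)  # backward from above anchor

    def test_world_um_scaling(self):
        tset = constant_flow_tset((30, 30, 30), 3, (2, 0, 0), anchor=0,
                                  voxel_size=2.0)
        out, _ = propagate_points(np.array([[20.0, 20, 20]]), tset, 0, 1)
        assert np.allclose(out, [[22.0, 20, 20]])  # 1 voxel = 2 um


class TestMaskWarp:
    def _box_mask(self, shape=(36, 36, 36), lo=12, hi=24):
        vox = np.zeros(shape, bool)
        vox[lo:hi, lo:hi, lo:hi] = True
        return BinaryMask(voxels=vox, voxel_size=1.0)

    def test_identity_field_preserves_mask(self):
        mask = self._box_mask()
        out = apply_transform_to_mask(
            mask, constant_field(mask.voxels.shape, (0, 0, 0)))
        assert np.array_equal(out.voxels, mask.voxels)

    def test_translation_preserves_volume(self):
        mask = self._box_mask()
        out = apply_transform_to_mask(
            mask, constant_field(mask.voxels.shape, (3, 0, 0)))
        assert abs(out.voxels.sum() / mask.voxels.sum() - 1) < 0.05

    def test_uniform_dilation_scales_volume_by_jacobian(self):
        mask = self._box_mask()
        c = np.full(3, 18.0)
        # T(x) = c + 1.1 (x - c): pulls the mask's 10%-dilated copy back,
        # so the warped mask *shrinks* by 1.1^3; invert to compare
        fld = linear_field(mask.voxels.shape, 0.1 * np.eye(3), -0.1 * c)
        out = apply_transform_to_mask(mask, fld)
        ratio = mask.voxels.sum() / out.voxels.sum()
        assert abs(ratio - 1.1**3) / 1.1**3 < 0.1

    def test_domain_mismatch_rejected(self):
        mask = self._box_mask()
        with pytest.raises(ValueError):
            apply_transform_to_mask(mask, constant_field((20, 20, 20),
                                                         (0, 0, 0)))


class TestDownscale:
    @pytest.mark.parametrize("fraction,expected_grid", [
        (0.10, 2), (0.15, 3), (0.20, 3), (0.25, 4),
    ])
    def test_supported_fraction_grid_spacing(self, fraction, expected_grid):
        stack = Hyperstack(intensity=np.random.default_rng(7).random(
            (20, 20, 20, 2)), voxel_size=0.593)
        small, grid = downscale_for_registration(stack, fraction)
        assert grid == expected_grid
        assert small.voxel_size[0] == pytest.approx(0.593 / fraction)

    def test_quarter_resolution_voxel_size(self):
        # 0.593 um at 25% -> ~2.37 um voxels
        stack = Hyperstack(intensity=np.zeros((16, 16, 16, 2)),
                           voxel_size=0.593)
        small, grid = downscale_for_registration(stack, 0.25)
        assert small.voxel_size[0] == pytest.approx(2.372, abs=0.01)
        assert grid == 4

    def test_unsupported_fraction_warns_and_computes(self):
        stack = Hyperstack(intensity=np.zeros((16, 16, 16, 2)),
                           voxel_size=1.0)
        with pytest.warns(UserWarning):
            small, grid = downscale_for_registration(stack, 1.0)
        assert grid == max(2, round(10.0 / 1.0))


class TestSerialization:
    def test_round_trip(self, tmp_path):
        tset = constant_flow_tset((20, 20, 20), 4, (1.5, -0.5, 0))
        path = tmp_path / "t.mmr"
        save_transform_set(tset, path)
        back = load_transform_set(path)
        assert back.anchor == tset.anchor
        assert back.n_frames == tset.n_frames
        pts = np.array([[8.0, 8, 8]])
        a, _ = propagate_points(pts, tset, tset.anchor, 3)
        b, _ = propagate_points(pts, back, back.anchor, 3)
        assert np.allclose(a, b)


class TestInverseConsistency:
    def test_forward_then_backward_registration_near_inverse(self):
        ref = smooth_texture((32, 32, 32), seed=8)
        mov = ndimage.shift(ref, (2, -1, 0), order=1, mode="nearest")
        p = RegistrationParams(grid_spacing=6, levels=3, max_iter=40)
        fwd, _ = register_pair(ref, mov, p)
        bwd, _ = register_pair(mov, ref, p)
        rng = np.random.default_rng(9)
        pts = rng.uniform(8, 24, (30, 3))
        there, _ = fwd.evaluate(pts)
        back, _ = bwd.evaluate(there)
        err = np.linalg.norm(back - pts, axis=1)
        assert err.mean() < 1.0
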