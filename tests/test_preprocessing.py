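import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from massfuse.data_io import ModalityVolume, SegmentationMask
from massfuse.preprocessing import (BoundingCube, compute_bounding_cube,
                                    crop_and_resample, fuse_channels,
                                    minmax_normalize, sobel_channel,
                                    sobel_gradient_2d, ModelInputTensor,
                                    SOBEL_KX, SOBEL_KY)


def brute_force_box(mask_voxels):
    """Exhaustive scan over every voxel, comparing coordinates one by one."""
    mins = [None] * 3
    maxs = [None] * 3
    shape = mask_voxels.shape
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if mask_voxels[i, j, k]:
                    for ax, v in enumerate((i, j, k)):
                        if mins[ax] is None or v < mins[ax]:
                            mins[ax] = v
                        if maxs[ax] is None or v > maxs[ax]:
                            maxs[ax] = v
    return tuple(mins), tuple(maxs)


class TestBoundingCube:
    def test_single_voxel(self):
        vox = np.zeros((10, 10, 10))
        vox[3, 5, 7] = 1
        mask = SegmentationMask(voxels=vox, reference_modality="d2")
        cube = compute_bounding_cube(mask, make_cube=False)
        assert cube.min_index == (3, 5, 7) and cube.max_index == (3, 5, 7)
        assert cube.cube_side == 1

    def test_full_support(self):
        mask = SegmentationMask(voxels=np.ones((10, 10, 10)), reference_modality="d2")
        cube = compute_bounding_cube(mask, make_cube=False)
        assert cube.min_index == (0, 0, 0) and cube.max_index == (9, 9, 9)

    def test_matches_exhaustive_scan_on_random_masks(self):
        rng = np.random.default_rng(7)
        for trial in range(100):
            shape = tuple(rng.integers(4, 16, size=3))
            vox = (rng.random(shape) < 0.08).astype(np.uint8)
            if vox.sum() == 0:
                vox[tuple(rng.integers(0, s) for s in shape)] = 1
            mask = SegmentationMask(voxels=vox, reference_modality="d2")
            cube = compute_bounding_cube(mask, make_cube=False)
            mins, maxs = brute_force_box(vox)
            assert cube.min_index == mins, f"trial {trial}"
            assert cube.max_index == maxs, f"trial {trial}"

    def test_cube_expansion_is_cubic_and_covers_box(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            shape = (20, 20, 20)
            vox = np.zeros(shape)
            a = rng.integers(0, 10, size=3)
            b = a + rng.integers(1, 10, size=3)
            vox[a[0]:b[0] + 1, a[1]:b[1] + 1, a[2]:b[2] + 1] = 1
            mask = SegmentationMask(voxels=vox, reference_modality="d2")
            cube = compute_bounding_cube(mask, make_cube=True)
            extents = [hi - lo + 1 for lo, hi in zip(cube.min_index, cube.max_index)]
            assert extents == [cube.cube_side] * 3
            assert all(lo <= aa and hi >= bb for lo, hi, aa, bb
                       in zip(cube.min_index, cube.max_index, a, b))
            assert all(lo >= 0 and hi < 20 for lo, hi
                       in zip(cube.min_index, cube.max_index))

    def test_invalid_cube_rejected(self):
        with pytest.raises(ValueError):
            BoundingCube((3, 3, 3), (2, 5, 5), cube_side=3)


class TestCropAndResample:
    def test_identity_when_cube_matches_target(self, rng):
        vox = rng.normal(size=(70, 70, 70))
        vol = ModalityVolume(voxels=vox, spacing=(1, 1, 1), modality="d2")
        cube = BoundingCube((3, 4, 5), (66, 67, 68), cube_side=64)
        out = crop_and_resample(vol, cube, target_side=64)
        np.testing.assert_allclose(out, vox[3:67, 4:68, 5:69], atol=1e-10)

    def test_upsample_round_trip(self, rng):
        # smooth input so trilinear up/down approximately inverts
        from scipy import ndimage
        vox = ndimage.gaussian_filter(rng.normal(size=(40, 40, 40)), sigma=3)
        vol = ModalityVolume(voxels=vox, spacing=(1, 1, 1), modality="d2")
        cube = BoundingCube((4, 4, 4), (35, 35, 35), cube_side=32)
        out = crop_and_resample(vol, cube, target_side=64)
        # nearest-neighbor downsample of the 64^3 output back onto the 32 grid
        sel = np.rint(np.arange(32) * 63 / 31).astype(int)
        back = out[np.ix_(sel, sel, sel)]
        np.testing.assert_allclose(back, vox[4:36, 4:36, 4:36], atol=0.05)

    def test_out_of_bounds_is_zero(self, rng):
        vox = np.abs(rng.normal(size=(20, 20, 20))) + 1.0  # strictly positive
        vol = ModalityVolume(voxels=vox, spacing=(1, 1, 1), modality="d2")
        cube = BoundingCube((-8, 2, 2), (7, 17, 17), cube_side=16)
        out = crop_and_resample(vol, cube, target_side=16)
        assert np.all(out[:7] == 0.0)       # samples at indices < -0.5
        assert np.all(out[9:] > 0.0)

    def test_fully_outside_errors(self, rng):
        vol = ModalityVolume(voxels=np.ones((10, 10, 10)), spacing=(1, 1, 1),
                             modality="d2")
        cube = BoundingCube((30, 30, 30), (40, 40, 40), cube_side=11)
        with pytest.raises(ValueError, match="outside"):
            crop_and_resample(vol, cube, target_side=8)

    def test_physical_extent_mapping_across_grids(self):
        # same physical object sampled at 1 mm and 2 mm; crops must agree
        fine = np.zeros((40, 40, 40))
        fine[10:30, 10:30, 10:30] = 1.0
        coarse = fine[::2, ::2, ::2]
        vol_fine = ModalityVolume(voxels=fine, spacing=(1, 1, 1), modality="d2")
        vol_coarse = ModalityVolume(voxels=coarse, spacing=(2, 2, 2), modality="t2wi")
        cube = BoundingCube((8, 8, 8), (31, 31, 31), cube_side=24, spacing=(1, 1, 1))
        a = crop_and_resample(vol_fine, cube, target_side=16)
        b = crop_and_resample(vol_coarse, cube, target_side=16)
        assert np.mean(np.abs(a - b)) < 0.1


class TestMinMaxNormalize:
    def test_three_values(self):
        out = minmax_normalize(np.array([[[1.0, 2.0, 3.0]]]))
        np.testing.assert_allclose(out.voxels, [[[0.0, 0.5, 1.0]]])

    def test_single_min_voxel(self):
        cube = np.full((4, 4, 4), 7.0)
        cube[0, 0, 0] = 3.0
        out = minmax_normalize(cube)
        assert out.voxels[0, 0, 0] == 0.0
        assert np.all(out.voxels.ravel()[1:] == 1.0)

    def test_constant_cube_warns_and_zeroes(self, caplog):
        with caplog.at_level(logging.WARNING):
            out = minmax_normalize(np.full((3, 3, 3), 5.0), modality="d2")
        assert np.all(out.voxels == 0.0)
        assert "constant cube" in caplog.text

    @given(arrays(np.float64, (3, 3, 3),
                  elements=st.floats(-1e6, 1e6, allow_nan=False)))
    @settings(max_examples=50, deadline=None)
    def test_range_and_idempotence(self, cube):
        out = minmax_normalize(cube)
        if cube.max() > cube.min():
            assert out.voxels.min() == 0.0 and out.voxels.max() == 1.0
            twice = minmax_normalize(out.voxels)
            np.testing.assert_allclose(twice.voxels, out.voxels, atol=1e-12)
        else:
            assert np.all(out.voxels == 0.0)


def hand_convolve(image, kernel):
    """Reflect-padded correlation, written as explicit loops (test oracle)."""
    padded = np.pad(image, 1, mode="reflect")
    out = np.zeros_like(image, dtype=float)
    for r in range(image.shape[0]):
        for c in range(image.shape[1]):
            acc = 0.0
            for dr in range(3):
                for dc in range(3):
                    acc += kernel[dr, dc] * padded[r + dr, c + dc]
            out[r, c] = acc
    return out


class TestSobel2d:
    def test_constant_image_zero_gradient(self):
        gx, gy, g, _ = sobel_gradient_2d(np.full((8, 8), 3.7))
        assert np.all(gx == 0) and np.all(gy == 0) and np.all(g == 0)

    def test_vertical_step_edge(self):
        img = np.zeros((6, 8))
        img[:, 4:] = 1.0
        gx, gy, g, _ = sobel_gradient_2d(img)
        # interior pixels adjacent to the step: |Gx| = 4, Gy = 0, G = 4
        assert np.all(np.abs(gx[1:-1, 3]) == 4.0)
        assert np.all(np.abs(gx[1:-1, 4]) == 4.0)
        assert np.all(gy[1:-1, 3:5] == 0.0)
        assert np.all(g[1:-1, 3:5] == 4.0)

    def test_matches_hand_convolution(self, rng):
        img = rng.normal(size=(7, 9))
        gx, gy, g, theta = sobel_gradient_2d(img)
        np.testing.assert_allclose(gx, hand_convolve(img, SOBEL_KX), atol=1e-12)
        np.testing.assert_allclose(gy, hand_convolve(img, SOBEL_KY), atol=1e-12)
        np.testing.assert_allclose(g, np.hypot(gx, gy))
        np.testing.assert_allclose(theta, np.arctan2(gy, gx))

    def test_transpose_swaps_components(self, rng):
        img = rng.normal(size=(8, 8))
        gx, gy, g, _ = sobel_gradient_2d(img)
        gx_t, gy_t, g_t, _ = sobel_gradient_2d(img.T)
        np.testing.assert_allclose(gx_t, -gy.T, atol=1e-12)
        np.testing.assert_allclose(g_t, g.T, atol=1e-12)

    def test_too_small_image(self):
        with pytest.raises(ValueError):
            sobel_gradient_2d(np.zeros((2, 5)))

    def test_theta_quadrant_aware(self):
        # diagonal ramp: both gradients positive -> theta in first quadrant
        img = np.add.outer(np.arange(6.0), np.arange(6.0))
        gx, gy, _, theta = sobel_gradient_2d(img)
        interior = theta[2:-2, 2:-2]
        assert np.all((interior > 0) & (interior < np.pi / 2)) or \
            np.all((interior > -np.pi) & (interior < 0))


class TestSobelChannel:
    def test_zero_cube(self):
        out = sobel_channel(np.zeros((8, 8, 8)))
        assert np.all(out.magnitude == 0)

    @pytest.mark.parametrize("mode", ["slicewise_2d", "full_3d"])
    def test_ball_shell_gradient(self, mode):
        idx = np.indices((17, 17, 17))
        dist = np.sqrt(((idx - 8.0) ** 2).sum(axis=0))
        ball = (dist <= 5.0).astype(float)
        out = sobel_channel(ball, mode=mode)
        # max gradient sits on the shell; deep interior is exactly 0
        peak = np.unravel_index(np.argmax(out.magnitude), out.magnitude.shape)
        assert 3.5 <= dist[peak] <= 6.5
        assert out.magnitude[8, 8, 8] == 0.0

    def test_homogeneity_before_renormalization(self, rng):
        cube = rng.normal(size=(8, 8, 8))
        g1 = sobel_channel(cube, renormalize=False).magnitude
        g2 = sobel_channel(2.0 * cube, renormalize=False).magnitude
        np.testing.assert_allclose(g2, 2.0 * g1, rtol=1e-10)

    def test_renormalized_range(self, rng):
        out = sobel_channel(rng.normal(size=(8, 8, 8)), renormalize=True)
        assert out.magnitude.min() >= 0.0 and out.magnitude.max() == 1.0

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            sobel_channel(np.zeros((8, 8, 8)), mode="diagonal")


class TestFuseChannels:
    def _cubes(self, rng, mods, case="c1"):
        from massfuse.preprocessing import NormalizedCube
        return [NormalizedCube(voxels=rng.random((8, 8, 8)), source_modality=m,
                               case_id=case) for m in mods]

    def test_four_modalities_with_sobel_gives_eight(self, rng):
        tensor = fuse_channels(self._cubes(rng, ["t2wi", "nonfs_t1wi", "d1", "d2"]),
                               include_sobel=True, label="benign")
        assert tensor.channels.shape[0] == 8
        assert tensor.channel_labels == ["t2wi", "nonfs_t1wi", "d1", "d2",
                                         "t2wi_sobel", "nonfs_t1wi_sobel",
                                         "d1_sobel", "d2_sobel"]

    def test_single_modality_no_sobel(self, rng):
        tensor = fuse_channels(self._cubes(rng, ["d2"]), include_sobel=False)
        assert tensor.channels.shape[0] == 1

    @pytest.mark.parametrize("n_mods", range(1, 7))
    @pytest.mark.parametrize("sobel", [False, True])
    def test_channel_count_formula(self, rng, n_mods, sobel):
        mods = ["t2wi", "nonfs_t1wi", "d1", "d2", "d4", "d6"][:n_mods]
        tensor = fuse_channels(self._cubes(rng, mods), include_sobel=sobel)
        assert tensor.channels.shape[0] == n_mods * (1 + int(sobel))

    def test_mixed_case_ids_rejected(self, rng):
        cubes = self._cubes(rng, ["d1"]) + self._cubes(rng, ["d2"], case="other")
        with pytest.raises(ValueError, match="case_id"):
            fuse_channels(cubes)

    def test_shape_mismatch_rejected(self, rng):
        from massfuse.preprocessing import NormalizedCube
        cubes = self._cubes(rng, ["d1"])
        cubes.append(NormalizedCube(voxels=rng.random((4, 4, 4)),
                                    source_modality="d2", case_id="c1"))
        with pytest.raises(ValueError, match="shape"):
            fuse_channels(cubes)

    def test_intensity_channels_in_unit_range(self, rng):
        tensor = fuse_channels(self._cubes(rng, ["t2wi", "d2"]), include_sobel=True)
        assert tensor.channels.min() >= 0.0 and tensor.channels.max() <= 1.0


class TestTensorIO:
    def test_npz_round_trip_with_sidecar(self, tmp_path, rng):
        from massfuse.preprocessing import NormalizedCube
        cubes = [NormalizedCube(voxels=rng.random((8, 8, 8)).astype(np.float32),
                                source_modality="d2", case_id="c9")]
        tensor = fuse_channels(cubes, include_sobel=True, label="malignant")
        cube = BoundingCube((1, 2, 3), (8, 9, 10), cube_side=8)
        path = tensor.save(tmp_path / "c9.npz", cube=cube,
                           norm_ranges={"d2": {"x_min": 0.0, "x_max": 1.0}})
        back = ModelInputTensor.load(path)
        np.testing.assert_array_equal(back.channels, tensor.channels)
        assert back.label == "malignant" and back.case_id == "c9"
        import json
        sidecar = json.loads((tmp_path / "c9.json").read_text())
        assert sidecar["bounding_cube"]["cube_side"] == 8
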