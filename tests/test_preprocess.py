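"""Stack I/O, rescaling, cropping, hemiside splitting, binning and length."""

import numpy as np
import pytest
import tifffile
from hypothesis import given, settings, strategies as st

from vncorr import (
    VolumeStack,
    bin_and_project,
    crop_vnc,
    read_stack,
    rescale_isotropic,
    split_hemisegment,
    vnc_length,
    write_stack,
)


def _stack(arr, pitch=(1.0, 1.0, 1.0)):
    return VolumeStack(intensities=np.asarray(arr, float), voxel_pitch=pitch)


class TestIO:
    def test_ome_round_trip_preserves_data_and_calibration(self, tmp_path, tiny_phantom):
        stack, _ = tiny_phantom
        path = tmp_path / "phantom.ome.tif"
        write_stack(stack, path)
        back = read_stack(path)
        assert back.voxel_pitch == pytest.approx(stack.voxel_pitch)
        assert np.allclose(back.intensities, stack.intensities, atol=1e-5)

    def test_plain_tiff_requires_explicit_pitches(self, tmp_path):
        path = tmp_path / "plain.tif"
        tifffile.imwrite(path, np.random.default_rng(0).random((5, 6, 7)).astype(np.float32))
        with pytest.raises(ValueError, match="voxel_pitch"):
            read_stack(path)
        stack = read_stack(path, voxel_pitch=(2.0, 0.5, 0.5))
        assert stack.voxel_pitch == (2.0, 0.5, 0.5)
        assert stack.shape == (5, 6, 7)

    def test_axis_spec_rank_mismatch_raises(self, tmp_path):
        path = tmp_path / "plain.tif"
        tifffile.imwrite(path, np.zeros((4, 5, 6), dtype=np.float32))
        with pytest.raises(ValueError, match="axis_spec"):
            read_stack(path, axis_spec="ZCYX", voxel_pitch=(1, 1, 1))

    def test_axis_reordering(self, tmp_path):
        arr = np.random.default_rng(1).random((3, 4, 5)).astype(np.float32)  # (Y, X, Z)
        path = tmp_path / "yxz.tif"
        tifffile.imwrite(path, arr)
        stack = read_stack(path, axis_spec="YXZ", voxel_pitch=(1, 1, 1))
        assert stack.shape == (5, 3, 4)
        assert np.allclose(stack.intensities, np.transpose(arr, (2, 0, 1)))


class TestRescale:
    def test_isotropic_stack_is_unchanged(self, tiny_phantom):
        stack, _ = tiny_phantom
        out = rescale_isotropic(stack, target_pitch=stack.voxel_pitch[0])
        assert out is stack

    def test_anisotropic_z_doubles_plane_count(self):
        rng = np.random.default_rng(0)
        stack = _stack(rng.random((20, 16, 16)), pitch=(2.0, 1.0, 1.0))
        out = rescale_isotropic(stack, target_pitch=1.0)
        assert abs(out.shape[0] - 40) <= 1
        assert out.shape[1:] == (16, 16)
        assert out.is_isotropic

    def test_extent_preserved_within_one_voxel(self):
        stack = _stack(np.ones((13, 9, 7)), pitch=(1.7, 0.9, 1.1))
        out = rescale_isotropic(stack, target_pitch=0.8)
        for old, new in zip(stack.extent_um(), out.extent_um()):
            assert abs(old - new) <= 0.8

    def test_constant_stack_stays_constant(self):
        stack = _stack(np.full((10, 8, 8), 3.7), pitch=(2.0, 1.0, 1.0))
        out = rescale_isotropic(stack, target_pitch=1.0)
        assert np.allclose(out.intensities, 3.7, atol=1e-9)


class TestCrop:
    def test_explicit_full_box_is_identity(self, tiny_phantom):
        stack, _ = tiny_phantom
        box = tuple((0, n) for n in stack.shape)
        out = crop_vnc(stack, box=box)
        assert np.array_equal(out.intensities, stack.intensities)

    def test_auto_crop_contains_fascicle_voxels(self, noiseless_phantom):
        stack, _ = noiseless_phantom
        out = crop_vnc(stack)
        fg = stack.intensities > 0.1 * stack.intensities.max()
        # the cropped volume must retain every strong fascicle voxel
        assert out.intensities[out.intensities > 0.1 * stack.intensities.max()].sum() \
            == pytest.approx(stack.intensities[fg].sum(), rel=1e-6)

    def test_all_zero_stack_raises(self):
        with pytest.raises(ValueError, match="foreground"):
            crop_vnc(_stack(np.zeros((5, 5, 5))))

    def test_bad_box_raises(self, tiny_phantom):
        stack, _ = tiny_phantom
        with pytest.raises(ValueError, match="box"):
            crop_vnc(stack, box=((0, stack.shape[0] + 5), (0, 5), (0, 5)))


class TestHemisegment:
    def test_mirror_symmetric_phantom_halves_match_after_flip(self, noiseless_phantom):
        stack, _ = noiseless_phantom
        left = split_hemisegment(stack, "left")
        right = split_hemisegment(stack, "right")
        assert np.allclose(left.intensities, right.intensities[:, :, ::-1], atol=1e-9)

    def test_odd_width_midline_goes_left(self):
        stack = _stack(np.random.default_rng(0).random((4, 4, 7)))
        assert split_hemisegment(stack, "left").shape[2] == 4
        assert split_hemisegment(stack, "right").shape[2] == 3

    def test_halves_reassemble_to_original(self):
        stack = _stack(np.random.default_rng(1).random((4, 4, 9)))
        left = split_hemisegment(stack, "left").intensities
        right = split_hemisegment(stack, "right").intensities
        assert np.array_equal(np.concatenate([left, right], axis=2), stack.intensities)

    def test_unknown_side_raises(self, tiny_phantom):
        with pytest.raises(ValueError, match="side"):
            split_hemisegment(tiny_phantom[0], "dorsal")


class TestBinning:
    def test_published_binning_arithmetic(self):
        # 550 planes of 0.15 μm -> 50 bins of eleven planes, 1.65 μm each
        stack = _stack(np.random.default_rng(0).random((550, 6, 6)),
                       pitch=(0.15, 0.15, 0.15))
        slabs = bin_and_project(stack, bin_length=1.65)
        assert len(slabs) == 50
        assert slabs.planes_per_bin == 11
        assert slabs.bin_length == pytest.approx(1.65)

    def test_constant_stack_gives_identical_sections(self):
        slabs = bin_and_project(_stack(np.full((12, 5, 5), 2.0)), bin_length=3.0)
        assert np.allclose(slabs.sections, 2.0)

    def test_single_bright_voxel_lands_in_its_bin(self):
        arr = np.zeros((12, 4, 4))
        arr[7, 2, 1] = 5.0
        slabs = bin_and_project(_stack(arr), bin_length=3.0)  # 3 planes per bin
        bright = [i for i in range(len(slabs)) if slabs.sections[i].max() == 5.0]
        assert bright == [7 // 3]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n_planes=st.integers(4, 30),
        ppb=st.integers(1, 5),
        seed=st.integers(0, 100),
    )
    def test_matches_brute_force_mip(self, n_planes, ppb, seed):
        rng = np.random.default_rng(seed)
        arr = rng.random((n_planes, 3, 4))
        if n_planes // ppb < 2:
            return
        slabs = bin_and_project(_stack(arr), bin_length=float(ppb))
        for i in range(len(slabs)):
            expected = arr[i * ppb : (i + 1) * ppb].max(axis=0)
            assert np.array_equal(slabs.sections[i], expected)

    def test_trailing_partial_bin_dropped(self):
        slabs = bin_and_project(_stack(np.ones((11, 4, 4))), bin_length=3.0)
        assert len(slabs) == 3

    def test_too_few_bins_raises(self):
        with pytest.raises(ValueError, match="bins"):
            bin_and_project(_stack(np.ones((4, 4, 4))), bin_length=4.0)

    def test_anisotropic_stack_rejected(self):
        stack = _stack(np.ones((10, 4, 4)), pitch=(2.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="isotropic"):
            bin_and_project(stack, bin_length=2.0)

    def test_save_load_round_trip(self, tmp_path, tiny_slabs):
        path = tmp_path / "slabs.tif"
        tiny_slabs.save(path)
        back = type(tiny_slabs).load(path)
        assert back.bin_length == pytest.approx(tiny_slabs.bin_length)
        assert np.allclose(back.sections, tiny_slabs.sections, atol=1e-5)


class TestVncLength:
    def test_phantom_length_matches_construction(self, tiny_params, tiny_phantom):
        stack, _ = tiny_phantom
        expected = tiny_params.n_segments * tiny_params.period
        assert vnc_length(stack) == pytest.approx(expected, abs=2 * tiny_params.voxel_pitch)

    def test_length_scales_with_ap_stretch(self):
        rng = np.random.default_rng(0)
        arr = np.zeros((20, 6, 6))
        arr[5:15] = rng.random((10, 6, 6)) + 1.0
        short = vnc_length(_stack(arr), threshold_method=0.5)
        doubled = vnc_length(_stack(np.repeat(arr, 2, axis=0)), threshold_method=0.5)
        assert doubled == pytest.approx(2 * short, abs=2.0)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="foreground"):
            vnc_length(_stack(np.zeros((5, 5, 5))))
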