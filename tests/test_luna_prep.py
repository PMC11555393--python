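"""CT preprocessing: MetaImage IO, coordinate maps, windowing, patches,
class rebalancing, and the on-disk split format."""

import numpy as np
import pandas as pd
import pytest
import SimpleITK as sitk
from hypothesis import given, settings, strategies as st

from mifnet.config import ConfigurationError
from mifnet.luna_prep import (Annotation, BalancingError, FormatError,
                              OutOfBoundsError, PatchSample, VolumeRecord,
                              balance_dataset, export_split, extract_patch,
                              load_patch_dir, patches_from_annotations,
                              read_annotations, read_metaimage, rescale_hu,
                              voxel_to_world, world_to_voxel)


class TestReadMetaImage:
    def test_round_trip_of_synthetic_scan(self, synthetic_scan):
        spec, header, _ = synthetic_scan
        vol = read_metaimage(header)
        nx, ny, nz = spec.volume_shape
        assert vol.voxels.shape == (nz, ny, nx)
        assert vol.origin == pytest.approx(spec.origin)
        assert vol.spacing == pytest.approx(spec.spacing)

    def test_consistent_header_and_payload(self, tmp_path):
        img = sitk.GetImageFromArray(
            np.arange(10 * 20 * 30, dtype=np.int16).reshape(30, 20, 10))
        path = tmp_path / "vol.mhd"
        sitk.WriteImage(img, str(path), useCompression=False)
        vol = read_metaimage(path)
        assert vol.voxels.shape == (30, 20, 10)
        assert vol.voxels[0, 0, 3] == 3

    def test_truncated_raw_payload(self, tmp_path):
        img = sitk.GetImageFromArray(np.zeros((4, 4, 4), dtype=np.int16))
        path = tmp_path / "vol.mhd"
        sitk.WriteImage(img, str(path), useCompression=False)
        raw = tmp_path / "vol.raw"
        raw.write_bytes(raw.read_bytes()[:-8])
        with pytest.raises(FormatError, match="bytes"):
            read_metaimage(path)

    def test_missing_header(self, tmp_path):
        with pytest.raises(FormatError, match="not found"):
            read_metaimage(tmp_path / "absent.mhd")


class TestWorldToVoxel:
    def test_origin_maps_to_first_voxel(self):
        assert world_to_voxel((1.5, -2.0, 7.0), (1.5, -2.0, 7.0),
                              (0.7, 0.7, 2.5)) == (0, 0, 0)

    def test_unit_geometry_is_identity(self):
        assert world_to_voxel((3, 4, 5), (0, 0, 0), (1, 1, 1)) == (3, 4, 5)

    def test_worked_example(self):
        assert world_to_voxel((10, -5, 3), (0, -10, 0),
                              (2, 5, 1.5)) == (5, 1, 2)

    def test_out_of_bounds_names_axis(self):
        with pytest.raises(OutOfBoundsError, match="axis y") as err:
            world_to_voxel((0, 99, 0), (0, 0, 0), (1, 1, 1),
                           shape_xyz=(10, 10, 10))
        assert err.value.axis == "y"

    def test_matches_simpleitk_oracle(self):
        """SimpleITK's physical-point transform is the independent oracle."""
        img = sitk.Image(20, 15, 10, sitk.sitkInt16)
        img.SetOrigin((-30.0, 12.5, -4.0))
        img.SetSpacing((0.65, 0.65, 2.5))
        rng = np.random.default_rng(3)
        for _ in range(25):
            idx_true = tuple(int(rng.integers(0, n)) for n in (20, 15, 10))
            world = img.TransformIndexToPhysicalPoint(idx_true)
            ours = world_to_voxel(world, img.GetOrigin(), img.GetSpacing())
            theirs = img.TransformPhysicalPointToIndex(world)
            assert ours == tuple(theirs) == idx_true

    @given(w=st.tuples(*[st.floats(-200, 200) for _ in range(3)]),
           o=st.tuples(*[st.floats(-50, 50) for _ in range(3)]),
           s=st.tuples(*[st.floats(0.3, 5.0) for _ in range(3)]))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_within_half_spacing(self, w, o, s):
        """voxel_to_world(world_to_voxel(w)) is within spacing/2 per axis."""
        idx = world_to_voxel(w, o, s)
        back = voxel_to_world(idx, o, s)
        for wi, bi, si in zip(w, back, s):
            assert abs(wi - bi) <= si / 2 + 1e-9


class TestRescaleHU:
    def test_window_endpoints_and_clipping(self):
        x = np.array([-1000.0, 400.0, 2000.0, -5000.0, -300.0])
        out = rescale_hu(x)
        np.testing.assert_allclose(out, [0.0, 1.0, 1.0, 0.0, 0.5])

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            rescale_hu(np.zeros(3), 100, 100)


class TestExtractPatch:
    @pytest.fixture()
    def volume(self):
        rng = np.random.default_rng(0)
        voxels = rng.uniform(-1000, 400, size=(8, 60, 70))
        return VolumeRecord(voxels=voxels, origin=(0, 0, 0),
                            spacing=(1, 1, 1), series_id="v")

    def test_center_pixel_matches_source(self, volume):
        patch = extract_patch(volume, (35, 30, 4), size=50)
        assert patch.image.shape == (50, 50)
        assert patch.image[25, 25] == pytest.approx(
            rescale_hu(volume.voxels[4, 30, 35]))

    def test_corner_is_zero_padded(self, volume):
        patch = extract_patch(volume, (0, 0, 0), size=50)
        assert np.all(patch.image[:25, :] == 0)  # above the volume
        assert np.all(patch.image[:, :25] == 0)  # left of the volume
        assert patch.image[25, 25] == pytest.approx(
            rescale_hu(volume.voxels[0, 0, 0]))

    def test_deterministic(self, volume):
        a = extract_patch(volume, (35, 30, 4))
        b = extract_patch(volume, (35, 30, 4))
        np.testing.assert_array_equal(a.image, b.image)

    def test_center_outside_volume(self, volume):
        with pytest.raises(OutOfBoundsError, match="axis z"):
            extract_patch(volume, (35, 30, 9))


def _dummy_patches(n, label, seed=0):
    rng = np.random.default_rng(seed + label)
    return [PatchSample(image=rng.random((50, 50)), label=label)
            for _ in range(n)]


class TestBalanceDataset:
    def test_undersampling_ratio(self):
        """100 positives and 10,000 negatives keep 500 negatives (1-in-6
        positives before augmentation)."""
        pos = _dummy_patches(100, 1)
        neg = _dummy_patches(10_000, 0)
        out = balance_dataset(pos, neg, rotations=(), seed=0)
        labels = [p.label for p in out]
        assert labels.count(0) == 500
        assert labels.count(1) == 100
        assert labels.count(1) / len(labels) == pytest.approx(1 / 6)

    def test_rotations_quadruple_positives(self):
        pos = _dummy_patches(5, 1)
        neg = _dummy_patches(100, 0)
        out = balance_dataset(pos, neg, seed=1)
        labels = [p.label for p in out]
        assert labels.count(1) == 20  # original + three quarter-turns
        rotated = [p.image for p in out if p.label == 1]
        base = pos[0].image
        for k in range(4):  # every orientation of each positive is present
            assert any(np.array_equal(img, np.rot90(base, k))
                       for img in rotated), f"missing {90 * k} degree turn"

    def test_seeded_determinism(self):
        pos = _dummy_patches(4, 1)
        neg = _dummy_patches(60, 0)
        a = balance_dataset(pos, neg, seed=5)
        b = balance_dataset(pos, neg, seed=5)
        assert len(a) == len(b)
        for pa, pb in zip(a, b):
            assert pa.label == pb.label
            np.testing.assert_array_equal(pa.image, pb.image)

    def test_empty_class_rejected(self):
        with pytest.raises(BalancingError):
            balance_dataset([], _dummy_patches(5, 0), seed=0)


class TestExportSplit:
    def test_split_counts_and_round_trip(self, tmp_path):
        samples = _dummy_patches(6, 1) + _dummy_patches(4, 0)
        train_m, test_m = export_split(samples, tmp_path,
                                       train_fraction=0.8, seed=0)
        assert len(train_m) == 8 and len(test_m) == 2
        images, labels = load_patch_dir(tmp_path / "train")
        assert images.shape == (8, 50, 50)
        assert images.min() >= 0 and images.max() <= 1
        assert sorted(labels) == sorted(train_m["label"])

    def test_same_seed_same_membership(self, tmp_path):
        samples = _dummy_patches(5, 1) + _dummy_patches(5, 0)
        m1, _ = export_split(samples, tmp_path / "a", seed=3)
        m2, _ = export_split(samples, tmp_path / "b", seed=3)
        pd.testing.assert_frame_equal(m1, m2)

    def test_fraction_one_rejected(self, tmp_path):
        with pytest.raises(ConfigurationError, match="train_fraction"):
            export_split(_dummy_patches(4, 1), tmp_path, train_fraction=1.0)


class TestEndToEnd:
    def test_scan_to_patches(self, synthetic_scan):
        """Every annotation of the synthetic scan yields a valid patch with
        the right label; nodule patches are brighter at center than edge."""
        spec, header, csv = synthetic_scan
        vol = read_metaimage(header)
        anns = read_annotations(csv)
        patches = patches_from_annotations(vol, anns)
        assert len(patches) == len(anns)
        assert sum(p.label for p in patches) == len(spec.nodules)
        for p in patches:
            assert p.image.shape == (50, 50)
            assert 0 <= p.image.min() and p.image.max() <= 1
        pos = [p for p in patches if p.label == 1]
        for p in pos:
            center = p.image[23:28, 23:28].mean()
            border = np.concatenate([p.image[:3].ravel(),
                                     p.image[-3:].ravel()]).mean()
            assert center > border
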