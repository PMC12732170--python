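import numpy as np
import pytest
from PIL import Image

from thymixer.ct_io import (CTVolume, load_volume, normalize_volume,
                            quality_filter, save_image_stack)
from thymixer.errors import DegenerateVolumeError, EmptyVolumeError, FormatError


def _write_stack(tmp_path, arrays):
    for i, a in enumerate(arrays):
        Image.fromarray(a.astype(np.uint8), mode="L").save(
            tmp_path / f"slice_{i:04d}.png")


class TestLoadVolume:
    def test_png_stack_order_and_count(self, tmp_path):
        rng = np.random.default_rng(0)
        arrays = [rng.integers(0, 255, (12, 12)) for _ in range(10)]
        _write_stack(tmp_path, arrays)
        v = load_volume(tmp_path, format="image_stack")
        assert v.n_slices == 10
        np.testing.assert_array_equal(v.slices[3], arrays[3])

    def test_nifti_slice_axis(self, tmp_path):
        import nibabel as nib

        data = np.random.default_rng(1).random((8, 9, 5))
        nib.save(nib.Nifti1Image(data, np.eye(4)), tmp_path / "vol.nii.gz")
        v = load_volume(tmp_path / "vol.nii.gz")
        assert v.n_slices == 5
        assert v.slice_shape == (8, 9)
        np.testing.assert_allclose(v.slices[2], data[:, :, 2], rtol=1e-6)

    def test_dicom_series_sorted_by_position(self, tmp_path):
        pydicom = pytest.importorskip("pydicom")
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        # write three slices with shuffled file order; z positions 30, 10, 20
        for fname, z, fill in (("a.dcm", 30.0, 3), ("b.dcm", 10.0, 1),
                               ("c.dcm", 20.0, 2)):
            meta = FileMetaDataset()
            meta.MediaStorageSOPClassUID = generate_uid()
            meta.MediaStorageSOPInstanceUID = generate_uid()
            meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds = FileDataset(str(tmp_path / fname), {}, file_meta=meta,
                             preamble=b"\0" * 128)
            ds.Rows = ds.Columns = 4
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.BitsAllocated = ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 0
            ds.ImagePositionPatient = [0.0, 0.0, z]
            ds.InstanceNumber = fill
            ds.PixelData = np.full((4, 4), fill, dtype=np.uint16).tobytes()
            ds.save_as(str(tmp_path / fname), enforce_file_format=True)
        v = load_volume(tmp_path, format="dicom")
        assert v.n_slices == 3
        assert [int(s[0, 0]) for s in v.slices] == [1, 2, 3]

    def test_mixed_shapes_raise(self, tmp_path):
        Image.fromarray(np.zeros((9, 9), dtype=np.uint8), "L").save(
            tmp_path / "a.png")
        Image.fromarray(np.zeros((12, 12), dtype=np.uint8), "L").save(
            tmp_path / "b.png")
        with pytest.raises(FormatError, match="mixed"):
            load_volume(tmp_path, format="image_stack")

    def test_missing_and_empty_paths(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_volume(tmp_path / "nope")
        empty = tmp_path / "empty"
        empty.mkdir()
        with pytest.raises(FileNotFoundError):
            load_volume(empty, format="image_stack")

    def test_save_load_round_trip_preserves_order(self, tmp_path):
        vol = CTVolume(np.linspace(0, 1, 5 * 6 * 6).reshape(5, 6, 6))
        save_image_stack(vol, tmp_path / "s")
        v2 = load_volume(tmp_path / "s", format="image_stack")
        assert v2.n_slices == 5
        np.testing.assert_allclose(v2.slices / 255.0, vol.slices, atol=1 / 255)


class TestNormalize:
    def test_minmax_linear_map(self):
        v = CTVolume(np.array([[[100.0, 300.0], [200.0, 100.0]]]))
        out = normalize_volume(v, "minmax_volume")
        assert out.slices[0, 1, 0] == pytest.approx(0.5)
        assert out.slices.min() == 0.0 and out.slices.max() == 1.0

    def test_fixed_window_endpoints(self):
        v = CTVolume(np.array([[[-160.0, 240.0], [40.0, -500.0]]]))
        out = normalize_volume(v, "fixed_window", level=40, width=400)
        assert out.slices[0, 0, 0] == 0.0
        assert out.slices[0, 0, 1] == 1.0
        assert out.slices[0, 1, 0] == pytest.approx(0.5)
        assert out.slices[0, 1, 1] == 0.0  # clipped below the window

    def test_constant_volume_is_degenerate(self):
        with pytest.raises(DegenerateVolumeError, match="constant"):
            normalize_volume(CTVolume(np.zeros((2, 3, 3))), "minmax_volume")

    def test_minmax_idempotent_on_normalized(self):
        v = CTVolume(np.random.default_rng(0).random((3, 4, 4)))
        once = normalize_volume(v)
        twice = normalize_volume(once)
        np.testing.assert_allclose(twice.slices, once.slices, atol=1e-12)


class TestQualityFilter:
    def test_uniform_slice_dropped(self):
        slices = np.random.default_rng(0).random((3, 5, 5))
        slices[1] = 0.5
        v, dropped = quality_filter(CTVolume(slices), min_std=0.01)
        assert dropped == [1]
        assert v.n_slices == 2
        np.testing.assert_array_equal(v.slices[0], slices[0])
        np.testing.assert_array_equal(v.slices[1], slices[2])

    def test_zero_threshold_is_identity(self):
        slices = np.random.default_rng(1).random((4, 5, 5))
        v, dropped = quality_filter(CTVolume(slices), min_std=0.0)
        assert dropped == []
        np.testing.assert_array_equal(v.slices, slices)

    def test_count_matches_direct_std(self):
        rng = np.random.default_rng(2)
        slices = rng.random((10, 6, 6))
        for i in (2, 5, 9):
            slices[i] = 0.3
        v, dropped = quality_filter(CTVolume(slices), min_std=0.01)
        assert v.n_slices == 7 and len(dropped) == 3
        assert dropped == [2, 5, 9]

    def test_all_dropped_raises(self):
        with pytest.raises(EmptyVolumeError):
            quality_filter(CTVolume(np.full((3, 4, 4), 0.2)), min_std=0.01)
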