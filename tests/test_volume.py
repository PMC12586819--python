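"""Volume IO, resampling, HU thresholding, mesh extraction, ROI statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nodulefab import (
    HUClassSpec,
    HUVolume,
    default_classes,
    extract_class_meshes,
    load_volume,
    measure_roi_hu,
    resample_isotropic,
    threshold_classes,
)
from nodulefab.errors import (
    ConfigurationError,
    DomainError,
    EmptySelectionError,
    InputError,
)
from nodulefab.volume import LabelVolume


def _write_nifti(path, data, spacing=(1.0, 1.0, 1.0)):
    import nibabel as nib

    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, np.float32), affine), str(path))


class TestLoad:
    def test_nifti_identity_read(self, tmp_path):
        p = tmp_path / "air.nii.gz"
        _write_nifti(p, np.full((8, 8, 8), -1000.0))
        vol = load_volume(str(p))
        assert np.all(vol.data == -1000.0)

    def test_hu_clamped_on_load(self, tmp_path):
        p = tmp_path / "wild.nii.gz"
        _write_nifti(p, np.array([[[-3000.0, 5000.0, 100.0]]]))
        vol = load_volume(str(p))
        assert vol.data.min() == -1024.0 and vol.data.max() == 3071.0

    def test_roi_crop(self, tmp_path):
        p = tmp_path / "v.nii.gz"
        _write_nifti(p, np.arange(64 ** 3, dtype=np.float64).reshape(64, 64, 64) % 100)
        vol = load_volume(str(p), roi=[(10, 20), (10, 20), (10, 20)])
        assert vol.shape == (10, 10, 10)
        assert np.allclose(vol.origin, [10.0, 10.0, 10.0])

    def test_roi_outside_bounds_rejected(self, tmp_path):
        p = tmp_path / "v.nii.gz"
        _write_nifti(p, np.zeros((8, 8, 8)))
        with pytest.raises(DomainError):
            load_volume(str(p), roi=[(0, 9), (0, 8), (0, 8)])

    def test_missing_file_rejected(self):
        with pytest.raises(InputError):
            load_volume("/nonexistent/vol.nii.gz")

    def test_dicom_rescale_applied(self, tmp_path):
        import pydicom
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        d = tmp_path / "series"
        d.mkdir()
        for i in range(2):
            meta = FileMetaDataset()
            meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
            meta.MediaStorageSOPInstanceUID = generate_uid()
            meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds = FileDataset(str(d / f"s{i}.dcm"), {}, file_meta=meta, preamble=b"\0" * 128)
            ds.Rows = ds.Columns = 4
            ds.BitsAllocated = 16
            ds.BitsStored = 16
            ds.HighBit = 15
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.PixelRepresentation = 0
            ds.RescaleSlope = 1.0
            ds.RescaleIntercept = -1024.0
            ds.PixelSpacing = [0.5, 0.5]
            ds.SliceThickness = 1.0
            ds.ImagePositionPatient = [0.0, 0.0, float(i)]
            ds.InstanceNumber = i + 1
            ds.PixelData = np.zeros((4, 4), np.uint16).tobytes()
            ds.save_as(str(d / f"s{i}.dcm"), enforce_file_format=True)
        vol = load_volume(str(d))
        # stored value 0 with slope 1, intercept -1024 -> HU -1024
        assert np.all(vol.data == -1024.0)
        assert vol.shape == (4, 4, 2)


class TestResample:
    def test_extent_conserved(self):
        vol = HUVolume(np.zeros((10, 10, 10)), spacing=0.5)
        out = resample_isotropic(vol, 0.1)
        assert out.shape == (50, 50, 50)
        assert np.allclose(out.spacing, 0.1)

    def test_constant_preserved(self):
        vol = HUVolume(np.full((7, 9, 5), -350.0), spacing=(0.3, 0.7, 1.1))
        out = resample_isotropic(vol, 0.25)
        assert np.allclose(out.data, -350.0)

    def test_linear_ramp_preserved_interior(self):
        data = np.tile(np.arange(20, dtype=float)[:, None, None] * 10.0, (1, 4, 4))
        vol = HUVolume(data, spacing=0.5)
        out = resample_isotropic(vol, 0.2)
        centers = (np.arange(out.shape[0]) + 0.5) * 0.2
        expected = (centers / 0.5 - 0.5) * 10.0
        interior = slice(3, -3)
        assert np.max(np.abs(out.data[interior, 2, 2] - expected[interior])) < 1.0

    def test_nonpositive_spacing_rejected(self):
        vol = HUVolume(np.zeros((4, 4, 4)), spacing=1.0)
        with pytest.raises(DomainError):
            resample_isotropic(vol, 0.0)


class TestThreshold:
    @pytest.mark.parametrize(
        "hu,label",
        [(5.0, 1), (0.0, 2), (-400.0, 3), (-500.0, 4), (-750.0, 4), (-800.0, 0)],
    )
    def test_default_band_membership(self, hu, label):
        vol = HUVolume(np.full((2, 2, 2), hu), spacing=1.0)
        out = threshold_classes(vol)
        assert np.all(out.labels == label)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(-749.999, 3000, allow_nan=False))
    def test_default_classes_tile_above_minus750(self, hu):
        matches = [c for c in default_classes() if c.contains(np.array([hu]))[0]]
        assert len(matches) == 1

    def test_below_minus750_is_background(self):
        assert not any(c.contains(np.array([-750.001]))[0] for c in default_classes())

    def test_overlapping_classes_rejected(self):
        vol = HUVolume(np.zeros((2, 2, 2)), spacing=1.0)
        bad = [HUClassSpec("a", -100, 100), HUClassSpec("b", 0, 200)]
        with pytest.raises(ConfigurationError):
            threshold_classes(vol, bad)

    def test_mask_limits_assignment(self):
        vol = HUVolume(np.full((4, 4, 4), 50.0), spacing=1.0)
        mask = np.zeros((4, 4, 4), bool)
        mask[0] = True
        out = threshold_classes(vol, mask=mask)
        assert out.labels[0].min() == 1 and out.labels[1:].max() == 0


class TestMeshExtraction:
    def test_ball_volume_matches_analytic(self):
        spacing = 0.1
        n = 70
        c = (np.arange(n) + 0.5) * spacing - n * spacing / 2
        r = np.sqrt(c[:, None, None] ** 2 + c[None, :, None] ** 2 + c[None, None, :] ** 2)
        labels = LabelVolume((r <= 3.0).astype(np.uint8), spacing=spacing)
        mesh = extract_class_meshes(labels, 1)
        assert mesh.is_watertight
        assert mesh.volume == pytest.approx(4 / 3 * np.pi * 27.0, rel=0.05)

    def test_cuboid_volume_matches_voxel_count(self):
        labels = np.zeros((30, 30, 30), np.uint8)
        labels[5:25, 5:20, 5:15] = 1
        lv = LabelVolume(labels, spacing=0.2)
        mesh = extract_class_meshes(lv, 1)
        assert mesh.volume == pytest.approx(20 * 15 * 10 * 0.2 ** 3, rel=0.01)

    def test_absent_class_raises(self):
        lv = LabelVolume(np.zeros((4, 4, 4), np.uint8), spacing=1.0)
        with pytest.raises(EmptySelectionError):
            extract_class_meshes(lv, 3)

    def test_mesh_volume_converges_with_spacing(self):
        def ball_error(spacing):
            n = int(np.ceil(8.0 / spacing))
            c = (np.arange(n) + 0.5) * spacing - n * spacing / 2
            r = np.sqrt(
                c[:, None, None] ** 2 + c[None, :, None] ** 2 + c[None, None, :] ** 2
            )
            lv = LabelVolume((r <= 3.0).astype(np.uint8), spacing=spacing)
            mesh = extract_class_meshes(lv, 1)
            return abs(mesh.volume - 4 / 3 * np.pi * 27.0)

        assert ball_error(0.1) < ball_error(0.3)


class TestROI:
    def test_constant_volume(self):
        vol = HUVolume(np.full((20, 20, 20), -123.0), spacing=0.5)
        s = measure_roi_hu(vol, center_mm=(5, 5, 5), radius_mm=2.0)
        assert s.mean == -123.0 and s.sd == 0.0 and s.n > 0

    def test_two_value_halves(self):
        data = np.empty((20, 20, 20))
        data[:10] = -200.0
        data[10:] = -400.0
        vol = HUVolume(data, spacing=1.0)
        # box-symmetric ROI centered on the interface plane
        s = measure_roi_hu(vol, center_mm=(9.5, 10, 10), radius_mm=4.0)
        assert s.mean == pytest.approx(-300.0)
        assert s.sd == pytest.approx(100.0)

    def test_gaussian_volume_statistics(self, rng):
        data = rng.normal(-500.0, 30.0, size=(40, 40, 40))
        vol = HUVolume(data, spacing=1.0)
        s = measure_roi_hu(vol, center_mm=(20, 20, 20), radius_mm=15.0)
        assert s.mean == pytest.approx(-500.0, abs=5.0)
        assert s.sd == pytest.approx(30.0, abs=5.0)

    def test_roi_outside_volume_rejected(self):
        vol = HUVolume(np.zeros((5, 5, 5)), spacing=1.0)
        with pytest.raises(DomainError):
            measure_roi_hu(vol, center_mm=(100, 100, 100), radius_mm=1.0)

    def test_disc_mode_confined_to_slab(self):
        data = np.zeros((11, 11, 11))
        data[:, :, 5] = 100.0  # only the central slice is hot
        vol = HUVolume(data, spacing=1.0)
        s = measure_roi_hu(vol, center_mm=(5, 5, 5), radius_mm=3.0, thickness_mm=0.5, axis=2)
        assert s.mean == 100.0

    def test_roi_invariant_under_resampling_constant(self):
        vol = HUVolume(np.full((12, 12, 12), -640.0), spacing=0.4)
        fine = resample_isotropic(vol, 0.1)
        a = measure_roi_hu(vol, (2.4, 2.4, 2.4), 1.5)
        b = measure_roi_hu(fine, (2.4, 2.4, 2.4), 1.5)
        assert a.mean == b.mean == -640.0
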