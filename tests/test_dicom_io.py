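import numpy as np
import pytest

import strokevol as sv
from strokevol.dicom_io import DicomIOError, SpacingError


@pytest.fixture
def phantom(sphere_phantom):
    return sphere_phantom


class TestDicomRoundtrip:
    def test_write_read_is_lossless(self, phantom, tmp_path):
        study, _ = phantom
        sv.write_dicom_series(study, tmp_path / "series")
        back = sv.read_dicom_series(tmp_path / "series")
        assert np.array_equal(back.voxels, study.voxels)
        assert back.pixel_spacing_mm == study.pixel_spacing_mm
        assert back.slice_thickness_mm == study.slice_thickness_mm
        assert back.original_size == study.original_size
        assert back.patient_id == study.patient_id

    def test_shuffled_files_read_in_spatial_order(self, phantom, tmp_path):
        study, _ = phantom
        sv.write_dicom_series(study, tmp_path / "series")
        # scramble filenames so lexical order no longer matches slice order
        files = sorted((tmp_path / "series").glob("*.dcm"))
        rng = np.random.default_rng(4)
        names = [f"x{rng.integers(1e9):09d}_{i}.dcm" for i in range(len(files))]
        rng.shuffle(names)
        for f, n in zip(files, names):
            f.rename(tmp_path / "series" / n)
        back = sv.read_dicom_series(tmp_path / "series")
        assert np.array_equal(back.voxels, study.voxels)

    def test_mixed_series_rejected(self, phantom, tmp_path):
        from dataclasses import replace

        study, _ = phantom
        other = replace(study, patient_id="someone-else")
        sv.write_dicom_series(study, tmp_path / "series")
        sv.write_dicom_series(other, tmp_path / "extra")
        for f in (tmp_path / "extra").glob("*.dcm"):
            f.rename(tmp_path / "series" / ("b_" + f.name))
        with pytest.raises(DicomIOError, match="mixed series"):
            sv.read_dicom_series(tmp_path / "series")

    def test_non_integer_voxels_rejected(self, phantom, tmp_path):
        from dataclasses import replace

        study, _ = phantom
        bad = replace(study, voxels=study.voxels + 0.5)
        with pytest.raises(DicomIOError, match="integer"):
            sv.write_dicom_series(bad, tmp_path / "series")


class TestThroughPlaneSpacing:
    def _study(self, thickness, between):
        v = np.zeros((3, 16, 16), dtype=np.uint16)
        return sv.DwiStudy(
            voxels=v, pixel_spacing_mm=(1.0, 1.0),
            slice_thickness_mm=thickness, spacing_between_slices_mm=between,
            original_size=(16, 16), patient_id="p",
        )

    def test_thickness_alone_resolves_to_thickness(self):
        assert sv.resolve_through_plane_spacing(self._study(3.0, None)) == 3.0

    def test_between_slices_takes_precedence(self):
        assert sv.resolve_through_plane_spacing(self._study(3.0, 3.5)) == 3.5

    def test_neither_field_is_a_construction_error(self):
        with pytest.raises(SpacingError):
            self._study(None, None)

    def test_header_configurations_resolve_identically_through_dicom(self, tmp_path):
        """A series carrying only SliceThickness=3 and one carrying only
        SpacingBetweenSlices=3 yield the same resolved spacing and volume."""
        spec = sv.PhantomSpec(
            matrix_size=32, n_slices=30, pixel_spacing_mm=(1.0, 1.0),
            slice_thickness_mm=3.0,
            lesions=(sv.LesionBlob(center_mm=(45.0, 16.0, 16.0), radii_mm=(8.0, 8.0, 8.0)),),
            seed=9,
        )
        study, mask = sv.generate_phantom(spec)
        from dataclasses import replace

        with_between = replace(study, slice_thickness_mm=None, spacing_between_slices_mm=3.0)
        sv.write_dicom_series(study, tmp_path / "thickness_only")
        sv.write_dicom_series(with_between, tmp_path / "between_only")
        a = sv.read_dicom_series(tmp_path / "thickness_only")
        b = sv.read_dicom_series(tmp_path / "between_only")
        assert sv.resolve_through_plane_spacing(a) == sv.resolve_through_plane_spacing(b) == 3.0
        assert sv.estimate_volume(mask, a).volume_cc == sv.estimate_volume(mask, b).volume_cc


class TestMaskIO:
    def test_dicom_series_roundtrip(self, phantom, tmp_path):
        study, mask = phantom
        sv.write_mask(mask, tmp_path / "mask", study=study)
        back = sv.read_mask(tmp_path / "mask")
        assert np.array_equal(back.voxels, mask.voxels)

    def test_hdf5_file_roundtrip(self, phantom, tmp_path):
        _, mask = phantom
        sv.write_mask(mask, tmp_path / "mask.h5")
        back = sv.read_mask(tmp_path / "mask.h5")
        assert np.array_equal(back.voxels, mask.voxels)
        assert back.alignment == mask.alignment

    def test_all_zero_mask_roundtrip(self, phantom, tmp_path):
        study, _ = phantom
        empty = sv.LesionMask(voxels=np.zeros_like(study.voxels, dtype=np.uint8))
        sv.write_mask(empty, tmp_path / "mask", study=study)
        assert sv.read_mask(tmp_path / "mask").voxels.sum() == 0

    def test_random_mask_pixel_count_preserved(self, phantom, tmp_path):
        study, _ = phantom
        rng = np.random.default_rng(8)
        mask = sv.LesionMask(voxels=(rng.random(study.shape) < 0.3).astype(np.uint8))
        p_before = sv.count_pixels(mask)
        sv.write_mask(mask, tmp_path / "mask", study=study)
        assert sv.count_pixels(sv.read_mask(tmp_path / "mask")) == p_before

    def test_non_binary_mask_rejected_at_construction(self):
        with pytest.raises(DicomIOError, match="0, 1"):
            sv.LesionMask(voxels=np.full((3, 16, 16), 2, dtype=np.uint8))


class TestHdf5Cache:
    def test_cache_load_roundtrip(self, tmp_path):
        cohort = sv.make_cohort(3, sv.CohortRanges(
            matrix_size=32, n_slices=(6, 8), fov_mm=224.0), seed=1)
        sv.cache_hdf5(cohort, tmp_path / "cache.h5")
        back = sv.load_hdf5(tmp_path / "cache.h5")
        by_id = {s.patient_id: (s, m) for s, m in cohort}
        assert len(back) == 3
        for study, mask in back:
            orig_s, orig_m = by_id[study.patient_id]
            assert np.array_equal(study.voxels, orig_s.voxels)
            assert np.array_equal(mask.voxels, orig_m.voxels)
            assert study.pixel_spacing_mm == orig_s.pixel_spacing_mm
            assert study.original_size == orig_s.original_size

    def test_cache_twice_is_identical(self, tmp_path):
        cohort = sv.make_cohort(2, sv.CohortRanges(
            matrix_size=32, n_slices=(6, 6), fov_mm=224.0), seed=2)
        sv.cache_hdf5(cohort, tmp_path / "a.h5")
        sv.cache_hdf5(cohort, tmp_path / "b.h5")
        a, b = sv.load_hdf5(tmp_path / "a.h5"), sv.load_hdf5(tmp_path / "b.h5")
        for (sa, ma), (sb, mb) in zip(a, b):
            assert sa.patient_id == sb.patient_id
            assert np.array_equal(sa.voxels, sb.voxels)
            assert np.array_equal(ma.voxels, mb.voxels)

    def test_volume_from_cache_equals_volume_from_dicom(self, tmp_path):
        cohort = sv.make_cohort(3, sv.CohortRanges(
            matrix_size=32, n_slices=(6, 8), fov_mm=224.0,
            lesion_radius_mm=(8.0, 30.0)), seed=3)
        for study, _ in cohort:
            sv.write_dicom_series(study, tmp_path / "dicom" / study.patient_id)
        sv.cache_hdf5(cohort, tmp_path / "cache.h5")
        cached = {s.patient_id: s for s, _ in sv.load_hdf5(tmp_path / "cache.h5")}
        for study, mask in cohort:
            from_dicom = sv.read_dicom_series(tmp_path / "dicom" / study.patient_id)
            v1 = sv.estimate_volume(mask, from_dicom).volume_cc
            v2 = sv.estimate_volume(mask, cached[study.patient_id]).volume_cc
            assert v1 == v2  # bit-identical through both storage routes

    def test_corrupt_cache_raises(self, tmp_path):
        bad = tmp_path / "bad.h5"
        bad.write_bytes(b"this is not hdf5")
        with pytest.raises(DicomIOError, match="cache"):
            sv.load_hdf5(bad)


class TestResize:
    def test_identity_resize_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(256, 256)).astype(np.float32)
        assert np.array_equal(sv.resize_for_model(img, (256, 256)), img)

    def test_all_ones_mask_stays_all_ones(self):
        for size in [(64, 64), (512, 512), (448, 384)]:
            ones = np.ones(size, dtype=np.uint8)
            out = sv.resize_mask(ones, (256, 256))
            assert out.shape == (256, 256)
            assert (out == 1).all()

    def test_resized_disk_area_scales_quadratically(self):
        yy, xx = np.mgrid[:512, :512]
        disk = (((yy - 256) ** 2 + (xx - 256) ** 2) <= 100**2).astype(np.uint8)
        out = sv.resize_mask(disk, (256, 256))
        assert set(np.unique(out)) <= {0, 1}
        assert abs(int(out.sum()) - disk.sum() / 4) / (disk.sum() / 4) < 0.05

    def test_resize_study_keeps_spacing_and_original_size(self, sphere_phantom):
        study, _ = sphere_phantom
        resized = sv.resize_study(study, (32, 32))
        assert resized.voxels.shape == (study.n_slices, 32, 32)
        assert resized.pixel_spacing_mm == study.pixel_spacing_mm
        assert resized.original_size == study.original_size

    def test_zero_target_rejected(self):
        with pytest.raises(DicomIOError, match="positive"):
            sv.resize_for_model(np.zeros((32, 32)), (0, 256))
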