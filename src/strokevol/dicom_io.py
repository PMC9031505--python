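"""DICOM series and mask I/O, HDF5 caching, and the model-input resize.

Conventions fixed repo-wide:

* arrays are indexed ``(slice, row, column)``, 0-based;
* ``pixel_spacing_mm`` is ``(row, column)`` as in the DICOM PixelSpacing tag;
* the through-plane spacing used for volumetry is SpacingBetweenSlices when
  present (the physical center-to-center distance, which differs from the
  thickness when inter-slice gaps exist), else SliceThickness;
* images are resampled with bilinear interpolation, masks with
  nearest-neighbor so they stay binary;
* resizing never touches the spacing metadata — the original acquisition
  size travels with the study so the volumetry's scale factors can undo the
  resize arithmetically.
"""

from __future__ import annotations


from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from skimage.transform import resize as _sk_resize

__all__ = [
    "DwiStudy",
    "LesionMask",
    "read_dicom_series",
    "write_dicom_series",
    "read_mask",
    "write_mask",
    "resolve_through_plane_spacing",
    "cache_hdf5",
    "load_hdf5",
    "resize_for_model",
    "resize_mask",
    "resize_study",
    "resize_mask_volume",
]

_ROOT_UID = "1.2.826.0.1.3680043.10.1534"  # private UID root for generated series


class DicomIOError(ValueError):
    pass


class SpacingError(DicomIOError):
    """Spacing metadata required for volumetry is missing."""


@dataclass(frozen=True)
class DwiStudy:
    """An intensity volume plus the spacing metadata volumetry needs.

    ``original_size`` is the in-plane acquisition size in pixels; it equals
    the array shape at read time and is carried unchanged through any resize
    so scale factors can be computed later.
    """

    voxels: np.ndarray  # (slices, height, width)
    pixel_spacing_mm: tuple[float, float]  # (row, column)
    slice_thickness_mm: float | None
    spacing_between_slices_mm: float | None
    original_size: tuple[int, int]  # (height, width)
    patient_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise DicomIOError(f"voxels must be 3D (slices, H, W), got ndim={v.ndim}")
        if v.shape[0] < 1 or v.shape[1] < 16 or v.shape[2] < 16:
            raise DicomIOError(f"voxels shape {v.shape} too small (need >=1 slice, >=16 px in-plane)")
        if any(s <= 0 for s in self.pixel_spacing_mm):
            raise SpacingError(f"pixel_spacing_mm must be positive, got {self.pixel_spacing_mm}")
        for name in ("slice_thickness_mm", "spacing_between_slices_mm"):
            val = getattr(self, name)
            if val is not None and val <= 0:
                raise SpacingError(f"{name} must be positive when present, got {val}")
        if self.slice_thickness_mm is None and self.spacing_between_slices_mm is None:
            raise SpacingError("at least one of slice_thickness_mm / spacing_between_slices_mm required")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "pixel_spacing_mm", tuple(float(s) for s in self.pixel_spacing_mm))
        object.__setattr__(self, "original_size", tuple(int(s) for s in self.original_size))

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class LesionMask:
    """A binary lesion volume (label or prediction).

    ``alignment`` records which geometry the mask indexes: ``"native"`` for
    the acquisition grid or ``"resized"`` for the model-input grid.
    """

    voxels: np.ndarray
    alignment: str = "native"

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise DicomIOError(f"mask voxels must be 3D, got ndim={v.ndim}")
        uniq = np.unique(v)
        if not np.isin(uniq, (0, 1)).all():
            raise DicomIOError(f"mask values must be in {{0, 1}}, got {uniq[:10]}")
        if self.alignment not in ("native", "resized"):
            raise DicomIOError(f"alignment must be 'native' or 'resized', got {self.alignment!r}")
        object.__setattr__(self, "voxels", v.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def resolve_through_plane_spacing(study: DwiStudy) -> float:
    """Slice-direction spacing in mm: SpacingBetweenSlices if present, else
    SliceThickness.  This is the per-slice depth entering the per-pixel
    volume."""
    if study.spacing_between_slices_mm is not None:
        return float(study.spacing_between_slices_mm)
    if study.slice_thickness_mm is not None:
        return float(study.slice_thickness_mm)
    raise SpacingError("study carries neither SpacingBetweenSlices nor SliceThickness")


# ---------------------------------------------------------------------------
# DICOM series


def _series_dataset(
    pixel_array: np.ndarray,
    *,
    instance: int,
    n_total: int,
    study_uid: str,
    series_uid: str,
    patient_id: str,
    pixel_spacing: tuple[float, float],
    slice_thickness: float | None,
    spacing_between: float | None,
    z_position: float,
) -> Dataset:
    ds = Dataset()
    ds.file_meta = FileMetaDataset()
    ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta.MediaStorageSOPClassUID = "1.2.840.10008.5.1.4.1.1.4"  # MR Image Storage
    ds.file_meta.MediaStorageSOPInstanceUID = generate_uid(
        prefix=_ROOT_UID + ".", entropy_srcs=[series_uid, str(instance)]
    )
    ds.SOPClassUID = ds.file_meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "MR"
    ds.PatientID = patient_id
    ds.PatientName = patient_id
    ds.StudyInstanceUID = study_uid
    ds.SeriesInstanceUID = series_uid
    ds.InstanceNumber = instance
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.ImagePositionPatient = [0.0, 0.0, float(z_position)]
    ds.PixelSpacing = [float(pixel_spacing[0]), float(pixel_spacing[1])]
    if slice_thickness is not None:
        ds.SliceThickness = float(slice_thickness)
    if spacing_between is not None:
        ds.SpacingBetweenSlices = float(spacing_between)
    ds.Rows, ds.Columns = pixel_array.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = np.ascontiguousarray(pixel_array, dtype=np.uint16).tobytes()
    return ds


def write_dicom_series(study: DwiStudy, path: str | Path) -> Path:
    """Write a study as one single-frame DICOM file per slice.

    Voxels must be integer-valued in the uint16 range; the round-trip through
    :func:`read_dicom_series` is then lossless.  UIDs are derived
    deterministically from the patient id so repeated writes are comparable.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    v = study.voxels
    if not np.issubdtype(v.dtype, np.integer):
        if not np.array_equal(v, np.rint(v)):
            raise DicomIOError("DICOM write requires integer-valued voxels")
        v = v.astype(np.int64)
    if v.min() < 0 or v.max() > np.iinfo(np.uint16).max:
        raise DicomIOError("voxel values outside uint16 range")
    v = v.astype(np.uint16)

    si = resolve_through_plane_spacing(study)
    study_uid = generate_uid(prefix=_ROOT_UID + ".", entropy_srcs=[study.patient_id, "study"])
    series_uid = generate_uid(prefix=_ROOT_UID + ".", entropy_srcs=[study.patient_id, "series"])
    for k in range(study.n_slices):
        ds = _series_dataset(
            v[k],
            instance=k + 1,
            n_total=study.n_slices,
            study_uid=study_uid,
            series_uid=series_uid,
            patient_id=study.patient_id,
            pixel_spacing=study.pixel_spacing_mm,
            slice_thickness=study.slice_thickness_mm,
            spacing_between=study.spacing_between_slices_mm,
            z_position=k * si,
        )
        ds.save_as(path / f"slice_{k:04d}.dcm", enforce_file_format=True)
    return path


def _slice_sort_key(ds: Dataset):
    # Project ImagePositionPatient on the slice normal; fall back to
    # InstanceNumber when position or orientation is absent.
    if "ImagePositionPatient" in ds and "ImageOrientationPatient" in ds:
        o = np.asarray(ds.ImageOrientationPatient, dtype=float)
        normal = np.cross(o[:3], o[3:])
        return (0, float(np.dot(normal, np.asarray(ds.ImagePositionPatient, dtype=float))))
    return (1, float(getattr(ds, "InstanceNumber", 0)))


def read_dicom_series(path: str | Path) -> DwiStudy:
    """Read a directory of single-frame DICOM files as one sorted volume.

    Slices are ordered by spatial position along the slice normal (fallback:
    InstanceNumber), so the on-disk file order is irrelevant.  Raw stored
    intensities are returned — no windowing or rescale is applied.
    """
    path = Path(path)
    files = sorted(path.glob("*.dcm")) or sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise DicomIOError(f"no DICOM files found in {path}")
    datasets = [pydicom.dcmread(str(f)) for f in files]

    series_uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(series_uids) > 1:
        raise DicomIOError(f"mixed series in {path}: {sorted(map(str, series_uids))}")

    datasets.sort(key=_slice_sort_key)
    first = datasets[0]
    if "PixelSpacing" not in first:
        raise SpacingError(f"PixelSpacing missing in {path}; volumetry impossible")
    thickness = float(first.SliceThickness) if "SliceThickness" in first else None
    between = float(first.SpacingBetweenSlices) if "SpacingBetweenSlices" in first else None
    if thickness is None and between is None:
        raise SpacingError(f"neither SliceThickness nor SpacingBetweenSlices present in {path}")

    voxels = np.stack([ds.pixel_array for ds in datasets])
    return DwiStudy(
        voxels=voxels,
        pixel_spacing_mm=(float(first.PixelSpacing[0]), float(first.PixelSpacing[1])),
        slice_thickness_mm=thickness,
        spacing_between_slices_mm=between,
        original_size=(voxels.shape[1], voxels.shape[2]),
        patient_id=str(getattr(first, "PatientID", "")),
    )


def write_mask(mask: LesionMask, path: str | Path, study: DwiStudy | None = None) -> Path:
    """Write a mask as a parallel DICOM series (directory) or a single HDF5
    volume file (``.h5``/``.hdf5`` suffix)."""
    path = Path(path)
    v = mask.voxels
    if not np.isin(np.unique(v), (0, 1)).all():
        raise DicomIOError("mask must be binary on write")
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("mask", data=v, dtype=np.uint8)
            f.attrs["alignment"] = mask.alignment
        return path
    spacing = study.pixel_spacing_mm if study is not None else (1.0, 1.0)
    thickness = study.slice_thickness_mm if study is not None else 1.0
    between = study.spacing_between_slices_mm if study is not None else None
    pid = (study.patient_id if study is not None else "mask") + "-mask"
    carrier = DwiStudy(
        voxels=v.astype(np.uint16),
        pixel_spacing_mm=spacing,
        slice_thickness_mm=thickness,
        spacing_between_slices_mm=between,
        original_size=(v.shape[1], v.shape[2]),
        patient_id=pid,
    )
    return write_dicom_series(carrier, path)


def read_mask(path: str | Path, alignment: str = "native") -> LesionMask:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            v = f["mask"][()]
            alignment = f.attrs.get("alignment", alignment)
        return LesionMask(voxels=v, alignment=str(alignment))
    carrier = read_dicom_series(path)
    return LesionMask(voxels=carrier.voxels.astype(np.uint8), alignment=alignment)


# ---------------------------------------------------------------------------
# HDF5 cache


def cache_hdf5(
    studies_masks: Sequence[tuple[DwiStudy, LesionMask | None]], path: str | Path
) -> Path:
    """Cache image + spacing (+ optional mask) per patient into one HDF5 file.

    Groups are written in sorted patient-id order so identical inputs produce
    identical cache content.  Loading never consults the DICOM files again.
    """
    path = Path(path)
    items = sorted(studies_masks, key=lambda sm: sm[0].patient_id)
    with h5py.File(path, "w") as f:
        for study, mask in items:
            g = f.create_group(study.patient_id)
            g.create_dataset("image", data=study.voxels)
            if mask is not None:
                g.create_dataset("mask", data=mask.voxels, dtype=np.uint8)
                g.attrs["mask_alignment"] = mask.alignment
            g.attrs["pixel_spacing_mm"] = study.pixel_spacing_mm
            g.attrs["slice_thickness_mm"] = (
                study.slice_thickness_mm if study.slice_thickness_mm is not None else np.nan
            )
            g.attrs["spacing_between_slices_mm"] = (
                study.spacing_between_slices_mm
                if study.spacing_between_slices_mm is not None
                else np.nan
            )
            g.attrs["original_size"] = study.original_size
    return path


def load_hdf5(path: str | Path) -> list[tuple[DwiStudy, LesionMask | None]]:
    path = Path(path)
    out: list[tuple[DwiStudy, LesionMask | None]] = []
    try:
        with h5py.File(path, "r") as f:
            for pid in sorted(f.keys()):
                g = f[pid]
                thickness = float(g.attrs["slice_thickness_mm"])
                between = float(g.attrs["spacing_between_slices_mm"])
                study = DwiStudy(
                    voxels=g["image"][()],
                    pixel_spacing_mm=tuple(g.attrs["pixel_spacing_mm"]),
                    slice_thickness_mm=None if np.isnan(thickness) else thickness,
                    spacing_between_slices_mm=None if np.isnan(between) else between,
                    original_size=tuple(int(s) for s in g.attrs["original_size"]),
                    patient_id=pid,
                )
                mask = None
                if "mask" in g:
                    mask = LesionMask(
                        voxels=g["mask"][()],
                        alignment=str(g.attrs.get("mask_alignment", "native")),
                    )
                out.append((study, mask))
    except OSError as exc:
        raise DicomIOError(f"cannot read HDF5 cache {path}: {exc}") from exc
    if not out:
        raise DicomIOError(f"HDF5 cache {path} contains no patients")
    return out


# ---------------------------------------------------------------------------
# Resizing


def resize_for_model(image_slice: np.ndarray, target: tuple[int, int] = (256, 256)) -> np.ndarray:
    """Bilinear resize of one intensity slice to the model input size."""
    if any(t <= 0 for t in target):
        raise DicomIOError(f"resize target must be positive, got {target}")
    if image_slice.shape == tuple(target):
        return image_slice.astype(np.float32)
    out = _sk_resize(
        image_slice.astype(np.float32), target, order=1,
        preserve_range=True, anti_aliasing=False,
    )
    return out.astype(np.float32)


def resize_mask(mask_slice: np.ndarray, target: tuple[int, int] = (256, 256)) -> np.ndarray:
    """Nearest-neighbor resize of one binary mask slice (stays binary)."""
    if any(t <= 0 for t in target):
        raise DicomIOError(f"resize target must be positive, got {target}")
    if mask_slice.shape == tuple(target):
        return mask_slice.astype(np.uint8)
    out = _sk_resize(
        mask_slice.astype(np.uint8), target, order=0,
        preserve_range=True, anti_aliasing=False,
    )
    return out.astype(np.uint8)


def resize_study(study: DwiStudy, target: tuple[int, int] = (256, 256)) -> DwiStudy:
    """Resize every slice; spacing metadata and original_size are untouched
    (scale factors, not spacing, absorb the resize)."""
    voxels = np.stack([resize_for_model(s, target) for s in study.voxels])
    return replace(study, voxels=voxels)


def resize_mask_volume(mask: LesionMask, target: tuple[int, int] = (256, 256)) -> LesionMask:
    voxels = np.stack([resize_mask(s, target) for s in mask.voxels])
    return LesionMask(voxels=voxels, alignment="resized")
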