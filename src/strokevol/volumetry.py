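"""Indirect lesion volumetry: pixel counting with header-derived scale factors.

The estimator never resamples the predicted mask back to acquisition
resolution.  Instead each resized-mask pixel is assigned its physical
footprint

    sfw = pixel_spacing_col * (W_original / W_resized)   [mm]
    sfh = pixel_spacing_row * (H_original / H_resized)   [mm]

so the per-pixel volume is ``V = sfw * sfh * si`` (mm^3) with ``si`` the
through-plane spacing from the DICOM header, and the patient's lesion volume
is ``V * P / 1000`` cc where ``P`` is the total count of predicted-positive
pixels over all slices.  The scale factors carry the in-plane pixel spacing
because V must be a physical volume; the (original/resized) ratio alone is
dimensionless.  Without a resize the estimate reduces exactly to voxel count
times voxel volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dicom_io import DwiStudy, LesionMask, resolve_through_plane_spacing

__all__ = ["VolumeEstimate", "scale_factors", "count_pixels", "estimate_volume"]


@dataclass(frozen=True)
class VolumeEstimate:
    """P, V and the resulting physical volume for one patient."""

    pixel_count: int
    per_pixel_volume_mm3: float
    volume_cc: float
    scale_factors_mm: tuple[float, float]  # (sfw, sfh)
    through_plane_mm: float
    patient_id: str = ""

    def __post_init__(self) -> None:
        sfw, sfh = self.scale_factors_mm
        assert self.per_pixel_volume_mm3 == sfw * sfh * self.through_plane_mm
        assert self.volume_cc == self.pixel_count * self.per_pixel_volume_mm3 / 1000.0

    def as_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "pixel_count": self.pixel_count,
            "sfw_mm": self.scale_factors_mm[0],
            "sfh_mm": self.scale_factors_mm[1],
            "si_mm": self.through_plane_mm,
            "volume_cc": self.volume_cc,
        }


def scale_factors(
    original_size: tuple[int, int],
    resized_size: tuple[int, int],
    pixel_spacing_mm: tuple[float, float],
) -> tuple[float, float]:
    """Physical side lengths (sfw, sfh) in mm of one resized-mask pixel.

    ``original_size`` and ``resized_size`` are (height, width) in pixels;
    ``pixel_spacing_mm`` is (row, column).  Total in-plane area is conserved:
    sfw*sfh*(resized pixel count) equals spacing-area*(original pixel count).
    """
    (h0, w0), (h1, w1) = original_size, resized_size
    sr, sc = pixel_spacing_mm
    if h1 <= 0 or w1 <= 0:
        raise ValueError(f"resized size must be positive, got {resized_size}")
    if h0 <= 0 or w0 <= 0 or sr <= 0 or sc <= 0:
        raise ValueError("original size and pixel spacing must be positive")
    return sc * (w0 / w1), sr * (h0 / h1)


def count_pixels(mask: LesionMask) -> int:
    """Total predicted-positive pixel count P, summed over all slices."""
    v = mask.voxels
    if not np.isin(np.unique(v), (0, 1)).all():
        raise ValueError("mask must be binary")
    return int(v.sum())


def estimate_volume(mask: LesionMask, study: DwiStudy) -> VolumeEstimate:
    """Lesion volume in cc from a (possibly resized) binary mask.

    The mask must have one slice per study slice; its in-plane size may
    differ from the acquisition size, in which case the scale factors absorb
    the resize.  Reported in cc (1 cc = 1000 mm^3).
    """
    if mask.voxels.shape[0] != study.n_slices:
        raise ValueError(
            f"mask has {mask.voxels.shape[0]} slices but study has {study.n_slices}"
        )
    sfw, sfh = scale_factors(
        study.original_size, mask.voxels.shape[1:], study.pixel_spacing_mm
    )
    si = resolve_through_plane_spacing(study)
    p = count_pixels(mask)
    v_mm3 = sfw * sfh * si
    return VolumeEstimate(
        pixel_count=p,
        per_pixel_volume_mm3=v_mm3,
        volume_cc=p * v_mm3 / 1000.0,
        scale_factors_mm=(sfw, sfh),
        through_plane_mm=si,
        patient_id=study.patient_id,
    )
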