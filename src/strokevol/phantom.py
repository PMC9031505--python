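"""Synthetic DWI-like phantoms with exactly known lesion volumes.

A phantom is an ellipsoidal "brain" of uniform intensity containing one or
more hyperintense ellipsoidal lesions, plus additive Gaussian noise.  The
geometry (matrix size, pixel spacing, slice thickness) mirrors a clinical
axial DWI acquisition, so every downstream stage — DICOM round-trips,
resizing, segmentation, spacing-aware volumetry — can be exercised against
a brute-force ground truth.

Voxel membership is decided by the voxel *center*: a voxel belongs to a blob
iff its center satisfies the (possibly perturbed) ellipsoid inequality.  This
rule is deliberately simple so an independent loop can recount any mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace


import numpy as np

from .dicom_io import DwiStudy, LesionMask

__all__ = [
    "LesionBlob",
    "PhantomSpec",
    "CohortRanges",
    "generate_phantom",
    "true_volume_cc",
    "make_cohort",
]


class PhantomSpecError(ValueError):
    """A phantom specification violates an invariant."""


@dataclass(frozen=True)
class LesionBlob:
    """An ellipsoidal lesion in physical (mm) coordinates.

    ``center_mm`` is (z, y, x) — slice axis first, matching the (slice, row,
    column) array convention used repo-wide.  ``perturb_amp`` adds a smooth,
    direction-dependent modulation of the boundary radius (fractional, so 0.2
    moves the surface by up to ~20%); the default 0 keeps the volume analytic.
    """

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    perturb_amp: float = 0.0

    def __post_init__(self) -> None:
        if len(self.center_mm) != 3 or len(self.radii_mm) != 3:
            raise PhantomSpecError("center_mm and radii_mm must be length-3")
        if any(r <= 0 for r in self.radii_mm):
            raise PhantomSpecError(f"radii_mm must be positive, got {self.radii_mm}")
        if self.perturb_amp < 0:
            raise PhantomSpecError("perturb_amp must be nonnegative")

    def analytic_volume_cc(self) -> float:
        """Exact ellipsoid volume in cc (ignores perturbation and clipping)."""
        a, b, c = self.radii_mm
        return 4.0 / 3.0 * math.pi * a * b * c / 1000.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one synthetic study.

    Defaults follow a typical stroke-protocol axial DWI: 256 matrix over a
    ~230 mm field of view (0.9 mm in-plane), 30 slices of 3 mm.  Intensities
    are arbitrary scanner units stored as 12-bit integers; the lesion must be
    hyperintense relative to brain, as infarcts are on b=1000 DWI.
    """

    matrix_size: int = 256
    n_slices: int = 30
    pixel_spacing_mm: tuple[float, float] = (0.9, 0.9)  # (row, column)
    slice_thickness_mm: float = 3.0
    spacing_between_slices_mm: float | None = None
    lesions: tuple[LesionBlob, ...] = ()
    noise_sigma: float = 0.0
    background_intensity: float = 400.0
    lesion_intensity: float = 900.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.matrix_size < 16:
            raise PhantomSpecError(f"matrix_size must be >= 16, got {self.matrix_size}")
        if self.n_slices < 3:
            raise PhantomSpecError(f"n_slices must be >= 3, got {self.n_slices}")
        if any(s <= 0 for s in self.pixel_spacing_mm):
            raise PhantomSpecError(f"pixel_spacing_mm must be positive, got {self.pixel_spacing_mm}")
        if self.slice_thickness_mm <= 0:
            raise PhantomSpecError(f"slice_thickness_mm must be positive, got {self.slice_thickness_mm}")
        if self.spacing_between_slices_mm is not None and self.spacing_between_slices_mm <= 0:
            raise PhantomSpecError("spacing_between_slices_mm must be positive when present")
        if self.lesion_intensity <= self.background_intensity:
            raise PhantomSpecError("lesion_intensity must exceed background_intensity (DWI hyperintensity)")
        if self.noise_sigma < 0:
            raise PhantomSpecError(f"noise_sigma must be nonnegative, got {self.noise_sigma}")
        object.__setattr__(self, "lesions", tuple(self.lesions))

    @property
    def through_plane_mm(self) -> float:
        """Center-to-center slice distance used for rasterization and volume."""
        if self.spacing_between_slices_mm is not None:
            return self.spacing_between_slices_mm
        return self.slice_thickness_mm

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical (z, y, x) extent of the sampled grid."""
        return (
            self.n_slices * self.through_plane_mm,
            self.matrix_size * self.pixel_spacing_mm[0],
            self.matrix_size * self.pixel_spacing_mm[1],
        )


def _voxel_center_grids(spec: PhantomSpec):
    """Open (broadcastable) grids of voxel-center coordinates in mm.

    Voxel (n, h, w) has its center at ((n+.5)*si, (h+.5)*sr, (w+.5)*sc).
    """
    si = spec.through_plane_mm
    sr, sc = spec.pixel_spacing_mm
    z = (np.arange(spec.n_slices, dtype=np.float64) + 0.5) * si
    y = (np.arange(spec.matrix_size, dtype=np.float64) + 0.5) * sr
    x = (np.arange(spec.matrix_size, dtype=np.float64) + 0.5) * sc
    return z[:, None, None], y[None, :, None], x[None, None, :]


def _blob_mask(blob: LesionBlob, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    z, y, x = _voxel_center_grids(spec)
    dz = (z - blob.center_mm[0]) / blob.radii_mm[0]
    dy = (y - blob.center_mm[1]) / blob.radii_mm[1]
    dx = (x - blob.center_mm[2]) / blob.radii_mm[2]
    r = np.sqrt(dz * dz + dy * dy + dx * dx)
    if blob.perturb_amp == 0.0:
        return r <= 1.0
    # Low-frequency angular modulation: the admissible radius becomes
    # 1 + amp * g(direction) with g a fixed random quadratic form on the
    # unit sphere, |g| <= 1.  Coefficients are drawn from the phantom rng so
    # the shape is reproducible.
    coef = rng.uniform(-1.0, 1.0, size=6)
    with np.errstate(invalid="ignore", divide="ignore"):
        uz, uy, ux = dz / r, dy / r, dx / r
    g = (
        coef[0] * uz + coef[1] * uy + coef[2] * ux
        + coef[3] * uz * uy + coef[4] * uy * ux + coef[5] * ux * uz
    )
    g = np.nan_to_num(g / 2.25, nan=0.0)  # bound |g| <= 1 (3 linear + 1.5 cross terms max)
    return r <= 1.0 + blob.perturb_amp * g


def _brain_mask(spec: PhantomSpec) -> np.ndarray:
    """Ellipsoidal brain occupying ~90% of the grid in-plane, ~96% through-plane."""
    z, y, x = _voxel_center_grids(spec)
    ez, ey, ex = spec.extent_mm
    cz, cy, cx = ez / 2.0, ey / 2.0, ex / 2.0
    return ((z - cz) / (0.48 * ez)) ** 2 + ((y - cy) / (0.45 * ey)) ** 2 + (
        (x - cx) / (0.45 * ex)
    ) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[DwiStudy, LesionMask]:
    """Rasterize a phantom into an intensity volume and its ground-truth mask.

    The intensity volume is background_intensity inside the brain ellipsoid,
    lesion_intensity inside any lesion blob, 0 outside the head, plus
    N(0, noise_sigma) noise, rounded and clipped to the 12-bit range.  Output
    is bit-identical for identical (spec, seed).
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.n_slices, spec.matrix_size, spec.matrix_size)

    mask = np.zeros(shape, dtype=bool)
    for blob in spec.lesions:
        mask |= _blob_mask(blob, spec, rng)

    img = np.zeros(shape, dtype=np.float64)
    img[_brain_mask(spec)] = spec.background_intensity
    img[mask] = spec.lesion_intensity
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=shape)
    voxels = np.clip(np.rint(img), 0, 4095).astype(np.uint16)

    study = DwiStudy(
        voxels=voxels,
        pixel_spacing_mm=spec.pixel_spacing_mm,
        slice_thickness_mm=spec.slice_thickness_mm,
        spacing_between_slices_mm=spec.spacing_between_slices_mm,
        original_size=(spec.matrix_size, spec.matrix_size),
        patient_id=f"phantom-{spec.seed:06d}",
    )
    lesion_mask = LesionMask(voxels=mask.astype(np.uint8), alignment="native")
    return study, lesion_mask


def true_volume_cc(mask: LesionMask, study: DwiStudy) -> float:
    """Brute-force ground-truth volume: voxel count x voxel volume, in cc.

    This is the oracle the spacing-aware volume estimator is checked against;
    at native geometry the two must agree to the last bit.
    """
    from .dicom_io import resolve_through_plane_spacing

    if mask.voxels.shape != study.voxels.shape:
        raise ValueError(
            f"mask shape {mask.voxels.shape} does not match study shape {study.voxels.shape}"
        )
    sr, sc = study.pixel_spacing_mm
    si = resolve_through_plane_spacing(study)
    voxel_mm3 = (sc * sr) * si
    return float(int(mask.voxels.sum()) * voxel_mm3 / 1000.0)


@dataclass(frozen=True)
class CohortRanges:
    """Sampling ranges for a cohort of phantoms.

    Defaults mirror the clinical acquisition the phantoms emulate (256-512
    matrix, 20-50 slices, 3 mm thickness) scaled to the configured matrix.
    Lesion radii are drawn log-uniformly so the cohort spans both sub-cc
    ("small") and multi-ten-cc ("large") lesion regimes.
    """

    matrix_size: int = 256
    n_slices: tuple[int, int] = (20, 50)
    fov_mm: float = 230.0
    slice_thickness_mm: float = 3.0
    n_lesions: tuple[int, int] = (1, 3)
    lesion_radius_mm: tuple[float, float] = (2.0, 20.0)
    radius_anisotropy: float = 0.3  # per-axis jitter factor around the drawn radius
    perturb_amp: tuple[float, float] = (0.0, 0.0)
    noise_sigma: tuple[float, float] = (20.0, 20.0)
    background_intensity: float = 400.0
    lesion_intensity: float = 900.0

    def __post_init__(self) -> None:
        if self.matrix_size < 16:
            raise PhantomSpecError("matrix_size must be >= 16")
        for name in ("n_slices", "n_lesions", "lesion_radius_mm", "perturb_amp", "noise_sigma"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise PhantomSpecError(f"{name} range is empty: ({lo}, {hi})")
        if self.n_slices[0] < 3:
            raise PhantomSpecError("n_slices must be >= 3")
        if self.lesion_radius_mm[0] <= 0:
            raise PhantomSpecError("lesion_radius_mm must be positive")
        if self.fov_mm <= 0 or self.slice_thickness_mm <= 0:
            raise PhantomSpecError("fov_mm and slice_thickness_mm must be positive")

    @classmethod
    def compact(cls) -> "CohortRanges":
        """The package's standard compact cohort for CPU-scale experiments.

        A 64x64 matrix over a 224 mm field of view (3.5 mm in-plane) with 12
        slices of 3 mm keeps the acquisition's physical extent while shrinking
        the pixel grid, so training the segmentation paths end to end takes
        minutes on one CPU.  Lesion radii of 4-20 mm span sub-cc "small" to
        multi-ten-cc "large" lesions at this resolution.
        """
        return cls(
            matrix_size=64,
            n_slices=(12, 12),
            fov_mm=224.0,
            slice_thickness_mm=3.0,
            n_lesions=(1, 3),
            lesion_radius_mm=(4.0, 20.0),
            noise_sigma=(20.0, 20.0),
        )


def sample_spec(ranges: CohortRanges, rng: np.random.Generator, seed: int) -> PhantomSpec:
    """Draw one phantom specification from the cohort ranges."""
    n_slices = int(rng.integers(ranges.n_slices[0], ranges.n_slices[1] + 1))
    pixel = ranges.fov_mm / ranges.matrix_size
    spec = PhantomSpec(
        matrix_size=ranges.matrix_size,
        n_slices=n_slices,
        pixel_spacing_mm=(pixel, pixel),
        slice_thickness_mm=ranges.slice_thickness_mm,
        lesions=(),
        noise_sigma=float(rng.uniform(*ranges.noise_sigma)),
        background_intensity=ranges.background_intensity,
        lesion_intensity=ranges.lesion_intensity,
        seed=seed,
    )
    ez, ey, ex = spec.extent_mm
    center = (ez / 2.0, ey / 2.0, ex / 2.0)
    # lesion centers stay well inside the brain ellipsoid
    semi = (0.35 * ez, 0.33 * ey, 0.33 * ex)
    lo, hi = ranges.lesion_radius_mm
    lesions = []
    for _ in range(int(rng.integers(ranges.n_lesions[0], ranges.n_lesions[1] + 1))):
        r = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        jit = rng.uniform(1.0 - ranges.radius_anisotropy, 1.0 + ranges.radius_anisotropy, size=3)
        radii = tuple(float(r * j) for j in jit)
        u = rng.uniform(-1.0, 1.0, size=3)
        c = tuple(float(center[i] + u[i] * semi[i]) for i in range(3))
        lesions.append(
            LesionBlob(center_mm=c, radii_mm=radii,
                       perturb_amp=float(rng.uniform(*ranges.perturb_amp)))
        )
    return replace(spec, lesions=tuple(lesions))


def make_cohort(
    n: int, ranges: CohortRanges | None = None, seed: int = 0
) -> list[tuple[DwiStudy, LesionMask]]:
    """Generate ``n`` phantoms with specs sampled reproducibly from ``ranges``.

    Patient ids are suffixed with the cohort index so a cohort can be written
    to disk without collisions.  Identical (n, ranges, seed) yields an
    identical cohort.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    ranges = ranges or CohortRanges()
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        spec_seed = int(rng.integers(0, 2**31 - 1))
        spec = sample_spec(ranges, rng, seed=spec_seed)
        study, mask = generate_phantom(spec)
        study = replace(study, patient_id=f"phantom-{seed:04d}-{i:03d}")
        cohort.append((study, mask))
    return cohort
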