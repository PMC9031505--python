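"""Generate a phantom, round-trip it through DICOM, and estimate its volume.

Builds a noise-free brain phantom with one 9 mm spherical lesion, writes it
as a single-frame DICOM series, reads it back, and compares the
spacing-aware volume estimate (pixel count x per-pixel volume from the
header spacing) against the analytic sphere volume and the brute-force
voxel-count ground truth.
"""

import math
import tempfile
from pathlib import Path

import strokevol as sv

spec = sv.PhantomSpec(
    matrix_size=128,
    n_slices=20,
    pixel_spacing_mm=(1.0, 1.0),
    slice_thickness_mm=3.0,
    lesions=(sv.LesionBlob(center_mm=(30.0, 64.0, 64.0), radii_mm=(9.0, 9.0, 9.0)),),
    noise_sigma=0.0,
    seed=1,
)
study, mask = sv.generate_phantom(spec)

with tempfile.TemporaryDirectory() as tmp:
    series_dir = Path(tmp) / "series"
    sv.write_dicom_series(study, series_dir)
    reloaded = sv.read_dicom_series(series_dir)

est = sv.estimate_volume(mask, reloaded)
analytic = 4.0 / 3.0 * math.pi * 9.0**3 / 1000.0

print(f"lesion pixels counted (P):     {est.pixel_count}")
print(f"per-pixel volume (V, mm^3):    {est.per_pixel_volume_mm3:.3f}")
print(f"estimated volume (P*V):        {est.volume_cc:.3f} cc")
print(f"voxel-count ground truth:      {sv.true_volume_cc(mask, reloaded):.3f} cc")
print(f"analytic sphere volume:        {analytic:.3f} cc")
# The estimate equals the voxel-count truth exactly (same grid); both differ
# from the analytic volume only by rasterization at the 3 mm slice spacing.
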