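import numpy as np
import pytest

import strokevol as sv


@pytest.fixture
def sphere_phantom():
    """Noise-free phantom with one 6 mm sphere on a 1 x 1 x 3 mm grid."""
    spec = sv.PhantomSpec(
        matrix_size=64,
        n_slices=20,
        pixel_spacing_mm=(1.0, 1.0),
        slice_thickness_mm=3.0,
        lesions=(sv.LesionBlob(center_mm=(30.0, 32.0, 32.0), radii_mm=(6.0, 6.0, 6.0)),),
        noise_sigma=0.0,
        seed=1,
    )
    return sv.generate_phantom(spec)


@pytest.fixture
def small_cohort():
    """Eight small noisy phantoms for fast end-to-end checks."""
    ranges = sv.CohortRanges(
        matrix_size=32,
        n_slices=(8, 8),
        fov_mm=224.0,
        lesion_radius_mm=(8.0, 30.0),
        noise_sigma=(20.0, 20.0),
    )
    return sv.make_cohort(8, ranges, seed=11)


def random_binary_mask(shape, rng, p=0.2, alignment="native"):
    return sv.LesionMask(voxels=(rng.random(shape) < p).astype(np.uint8), alignment=alignment)
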