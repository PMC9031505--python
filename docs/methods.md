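# Methods

## The problem

Acute ischemic stroke (AIS) lesions are hyperintense on diffusion-weighted
MRI (DWI, b = 1000 s/mm²), and the lesion *volume* in cc drives triage
decisions (thrombectomy-eligibility trials gate on infarct-core volumes
such as < 70 mL). `strokevol` implements two routes from a DWI volume to
that number:

* **Indirect volume estimation** — segment each axial slice with a 2D
  encoder–decoder whose three input channels are the previous, current and
  next slice; count the predicted-positive pixels across all slices; and
  convert the count to a physical volume using scale factors derived from
  the DICOM header.
* **Direct volume estimation** — segment the 3D volume with a patch-based
  3D encoder–decoder and measure the volume of the stitched 3D mask.

The package also ships a synthetic phantom generator so the full pipeline —
DICOM round-trips, HDF5 caching, resizing, training, inference, volumetry,
evaluation — is exercised end to end against exactly known ground truth,
with no access to clinical data.

## Volumetry

A predicted mask lives on the model grid (in-plane size possibly resized,
canonically 256×256) while the acquisition has its own matrix size and
pixel spacing. Each resized-mask pixel is assigned a physical footprint

    sfw = pixel_spacing_col · (W_original / W_resized)     [mm]
    sfh = pixel_spacing_row · (H_original / H_resized)     [mm]

so one pixel's volume is `V = sfw · sfh · si` mm³, where `si` is the
through-plane spacing. The lesion volume is `V · P / 1000` cc, with
`P = Σₙ Σₕ Σ_w p(h,w,n)` the total predicted-positive pixel count over all
slices. Two choices deserve note:

* **Scale factors carry units.** The original/resized size ratio alone is
  dimensionless; multiplying it by the in-plane pixel spacing is the only
  reading under which `V` is a physical volume. This makes per-slice
  in-plane area exactly conserved under resize: `sfw·sfh·(resized count of
  an all-ones slice) = spacing-area·(original count)`.
* **Through-plane spacing** `si` resolves to the DICOM
  `SpacingBetweenSlices` when present, else `SliceThickness`.
  Between-slices is the physically correct center-to-center distance when
  inter-slice gaps exist; thickness is the usual fallback when the tag is
  absent. The phantom generator uses the identical rule so oracle and
  pipeline always agree.

Counting happens at the model grid with scale factors, not after
upsampling the mask back to native resolution; without any resize the
estimator reduces bit-exactly to voxel count × voxel volume, which is also
the package's brute-force oracle (`true_volume_cc`). Volume is reported per
patient as a single scalar (the triple sum runs over all slices);
per-lesion decomposition is out of scope.

## Segmentation models

Both paths use the same symmetric encoder–decoder: `depth` levels of
(3^d convolution → batch normalization → ReLU) × 2, 2× max pooling between
levels, a mirrored decoder with 2× up-convolution and skip concatenation
from the matching encoder level, and a final 1×1(×1) convolution with
sigmoid. The 2D variant takes three channels (adjacent slices, edges
replicated so N slices yield N outputs); the 3D variant takes one channel
and runs on overlapping patches whose probability outputs are averaged
where they overlap and cropped back to the study shape.

The training objective is soft Dice loss,

    L = 1 − 2·Σ(y·p) / (Σy² + Σp² + ε),

reduced per batch item and then averaged. `ε = 1e−6` is added to the
denominator only, which silences the 0/0 of an empty-vs-empty pair without
measurably biasing nonempty ones; `ε = 0` reproduces the analytic values
(perfect overlap → 0, disjoint → 1, uniform 0.5 prediction on a
half-positive 8-pixel image → 1/3) used in the tests.

Because no deep-learning framework is part of the package's dependency
set, the layers (2D/3D convolution, batch norm, max pooling, transposed
convolution, Adam) are implemented directly on numpy with hand-written
backward passes, kept channels-last internally so every convolution is a
BLAS matrix product per kernel offset. The gradients are verified against
central-difference numerical differentiation in the test suite; the
attainable agreement is limited by float32 forward-pass roundoff (~1e-2
relative on this loss scale), so the check uses a 5e-2 relative bound.

Training protocol: patients (never slices) are shuffle-split 8:1:1 with
the run seed — per-patient splitting avoids leakage between adjacent
slices of one brain. Each batch is augmented with independently drawn
horizontal/vertical flips and 90° rotations, applied identically to image
and mask. Input volumes are z-scored per volume (intensity normalization
across heterogeneous scanners; exposed in config). Optimization is Adam at
learning rate 1e−3; the returned model is the epoch with the lowest
validation Dice loss. Predicted probabilities are binarized at a
configurable threshold, default 0.5.

Patch configuration for the direct path defaults to 16×64×64 voxels
(slices × rows × cols) with 50% overlap and mean blending. Patch sampling
is deliberately *not* foreground-biased by default: small sparse lesions
can then be underrepresented or absent in training patches, which is the
documented structural weakness of patch-based 3D segmentation that the
indirect path is designed to avoid. A foreground-oversampling switch
exists but is off in the comparison experiment. A weight-loading hook
(`UNet.load_pretrained`) accepts externally produced parameter sets for
transfer-learning workflows; no pretrained weights ship with the package.

## Evaluation metrics

Per-patient confusion counts (TP, FP, FN, TN over pixels) feed:

* sensitivity TP/(TP+FN);
* `specificity_as_printed` TP/(TP+FP) — kept verbatim because the result
  tables this mirrors label that ratio "specificity", although it is
  conventionally precision/PPV; the conventional specificity TN/(TN+FP) is
  reported separately as `true_specificity`, and no guess is made about
  which was intended;
* F1 (harmonic mean of precision and recall) and Jaccard TP/(TP+FP+FN),
  related by J = F1/(2−F1);
* volume similarity VS = 1 − |FN−FP|/(2TP+FP+FN), identical to
  1 − ||m|−|g||/(|m|+|g|) on the predicted/labeled pixel totals. VS is 1
  whenever the two volumes agree in pixel count, regardless of overlap —
  it measures volume agreement, not localization;
* MAE, the mean |estimated − reference| volume in cc, both volumes through
  the same spacing-aware estimator.

Aggregation is macro (average of per-patient rates) by default, with a
pooled-counts mode available. Degenerate denominators are defined as 0,
and patients with no labeled-positive pixels (lesion-free controls) are
excluded from rate averages unless requested — controls are evaluated
through MAE, which an all-background predictor drives to exactly 0. Two
empty masks give VS = 1 (identical empties).

## Synthetic phantoms

A phantom is an ellipsoidal "brain" at uniform intensity (default 400)
containing hyperintense ellipsoidal lesions (default 900) with optional
smooth boundary perturbation, plus additive Gaussian noise (σ default 20,
i.e. contrast-to-noise ≈ 25 for the lesion–brain step), rounded to 12-bit
integers so DICOM round-trips are bit-exact. Geometry defaults mirror a
stroke-protocol acquisition: 256 matrix, ~230 mm field of view, 3 mm
slices, 20–50 slices per study. Voxel membership is decided by the voxel
center against the implicit surface, so an independent loop can recount
any mask, and an ellipsoid's rasterized volume converges to 4/3·π·abc.

What the phantoms deliberately do **not** emulate: DWI contrast physics
and b-value dependence, Rician noise statistics, susceptibility/ghosting
artifacts, anatomical texture, and ill-defined infarct boundaries. Noise
here is a pure SNR knob (additive Gaussian). Passing tests therefore
demonstrate that the *pipeline machinery* — geometry handling, metadata
propagation, optimization, volumetry arithmetic — is correct and that the
models can learn a high-contrast segmentation task; they say nothing about
segmentation accuracy on clinical DWI, which depends on data that cannot
ship with a package.

The standard compact cohort (`CohortRanges.compact()`) used by the
training experiments is 40 phantoms at 64×64 over a 224 mm field of view
(3.5 mm pixels), 12 slices of 3 mm, 1–3 lesions each with radii drawn
log-uniformly from 4–20 mm — spanning sub-cc "small" to multi-ten-cc
"large" lesions. The reduced grid keeps a full two-path training
comparison to minutes on one CPU while preserving the acquisition's
physical extent; model capacity (depth 3, base 8 channels) and epoch
budgets (15 for 2D, 12 for 3D) are sized to that grid.

## Numerical and design choices

* Arrays are indexed (slice, row, column), 0-based, repo-wide;
  `pixel_spacing_mm` is (row, column) as in the DICOM tag; sfw maps to
  column spacing and sfh to row spacing.
* Slices are ordered by the projection of `ImagePositionPatient` onto the
  slice normal, falling back to `InstanceNumber`; file order on disk is
  irrelevant. Mixed series in one directory are rejected.
* Images are resized bilinearly; masks with nearest-neighbor (binarity is
  required by pixel counting). Resizing never alters spacing metadata —
  the original size travels with the study and the scale factors absorb
  the resize. Both segmentation paths see identically resized inputs, so
  their metrics are comparable.
* Masks are serialized as parallel single-frame DICOM series (or a single
  HDF5 volume file); image+spacing(+mask) cohorts are cached per patient
  in one HDF5 file that is written in sorted patient order and never falls
  back to the DICOM files once built.
* Validation/test split sizes round to the nearest patient but never to
  zero; a 10-patient cohort splits 8/1/1, a 40-patient cohort 32/4/4.
* The phantom's through-plane rasterization uses the same
  between-slices-else-thickness rule as the volumetry, so the generator's
  ground truth and the pipeline's estimate share one geometry definition.
* Ties in max pooling route the gradient to the first maximal element;
  batch-norm running statistics use momentum 0.9 and are used only at
  inference.

## Known limitations

* The numpy layer stack targets small models; it is single-threaded apart
  from BLAS and keeps per-layer caches in memory, so it does not scale to
  clinical-resolution 3D training.
* Batch normalization with small batches makes training runs sensitive to
  batch composition; results are reproducible only under fixed seeds and
  a fixed BLAS backend.
* The direct-vs-indirect comparison on phantoms reproduces a *direction*
  (slice-wise 2D ≥ patch-based 3D under a matched small budget), not any
  clinical magnitude.
* Multi-frame/enhanced DICOM, DICOM-SEG, b-value parsing and anonymization
  are out of scope, as are surface-distance metrics and per-lesion
  volumetry (a connected-component decomposition could sit on top of the
  mask but is not the implemented algorithm).
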