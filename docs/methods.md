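# Methods

This note documents the models, conventions and numerical choices behind
gutgaze, and what the phantom-based tests do and do not establish.

## Coordinate and grid conventions

All annotation geometry lives in physical world coordinates (mm). A voxel
grid is `origin + index · spacing` with 0-based indices at voxel centers and
a strictly diagonal, positive affine; rotated or sheared orientations are
rejected at I/O time rather than silently resampled. This convention is what
makes the reconstruction bit-reproducible: thick-slice CT voxels are highly
anisotropic (e.g. 0.75 × 0.75 × 3.72 mm), and any geometry done in index
space would distort distances and rotations.

## The nearest-segment reconstruction model

A visual segment is an ordered polyline of gaze points with a diameter at
each point. For every voxel center the closest segment is found; the voxel
takes the segment's label when its distance is within half the local
diameter, and the diameter map takes the local diameter of the closest
segment.

Choices within that contract:

- **Polyline distance with interpolated diameter (default).** Gaze points
  are ~7 mm apart on average; distance to the points alone leaves scalloped
  gaps between them, so the distance is measured to the line pieces between
  consecutive points, with the diameter interpolated linearly at the closest
  parameter. A `points` mode is retained for ablation.
- **Masked diameter map by default.** Whether the diameter map should carry
  a value outside the bowel is genuinely ambiguous (a dense map is useful
  for visualization; a mostly-zero map matches the foreground-weighted
  training target). Both behaviours are exposed (`masked_diameter`); masked
  is the default.
- **Ties** between equidistant segments go to the earliest-recorded segment
  (strict `<` update in recording order); within a segment, to the earliest
  piece. Deterministic tie-breaking is required for the oracle equivalence
  below.
- **Oracle equivalence.** `brute_force_reconstruct` re-implements the
  contract as a naive scalar scan over every (voxel, sub-segment) pair. Both
  paths evaluate the same arithmetic expressions in the same order, so they
  agree *bit-exactly*; the tests enforce this on random annotations and
  grids. Because the two are interchangeable, the phantom generator derives
  its ground truth through the fast path.

## The phantom generator

Phantoms emulate the conditions the pipeline is meant for — unprepared
abdominal CT around tubes of known geometry — not anatomical realism:

- Tubes run the volume in z as smoothed random walks with slowly varying
  diameters (default range 10–60 mm, the span from collapsed small bowel to
  obstructed colon), placed by rejection sampling so they never overlap.
  Real bowel loops touch; non-overlap keeps the ground truth unambiguous.
- Intensities: fat background (−100 HU) with random soft-tissue regions
  (40 HU), a 3 mm soft-tissue wall, and a gas (−1000 HU) or fluid (10 HU)
  lumen per tube, plus Gaussian noise (default SD 15 HU).
- The gaze simulator walks the true centerline emitting raw samples, adds
  isotropic Gaussian jitter, and averages blocks of round(60 Hz × 0.75 s) =
  45 samples into gaze points; the trailing partial block still yields a
  point (the end of a traced segment is still seen). Recorded diameters get
  Gaussian error and are quantized to the 1 mm knob step (floored at one
  step). Default jitter and diameter-error SDs are 1 mm — a plausible
  in-volume precision for a calibrated tracker; the real error structure is
  heteroskedastic over the monitor and is not modelled.
- Unit normal deviates are drawn in an order independent of the noise
  magnitudes and scaled afterwards, so recordings with the same seed but
  different noise levels share randomness (common random numbers). The
  repeatability-vs-jitter curve is therefore smooth per seed, which is what
  lets a 10-seed study resolve the small effect of jitter that survives
  45-sample averaging (effective centerline error ≈ jitter/√45).
- The caliper simulator picks centerline sites where the tube runs within
  30° of the z-axis (en-face cross-sections) and perturbs short/long axes
  with independent relative errors, swapped so short ≤ long.

What phantom results do **not** show: performance on real bowel (touching
loops, peristalsis, contrast phases, heterogeneous disease), or gaze errors
beyond isotropic jitter. They establish correctness of the pipeline's
mechanics and the qualitative degradation of repeatability with noise.

## Preprocessing and augmentation

- HU windowing: `clip(2·(v − 40)/400, −1, 1)` (soft-tissue window 400/level
  40; values at the window edges clip to ±1).
- The 13-part scheme reduces to foregut (esophagus–duodenum), midgut
  (jejunum, ileum), hindgut (cecum–anus) — an obstruction-threshold
  grouping, not an embryologic one.
- Diameters are divided by the in-plane voxel size to give voxel units
  (field-of-view independent); slice thickness is not a natural diameter
  unit since measurements are axial. In-plane anisotropy is rejected.
- Resizing: images bilinear, labels/diameters/weights nearest neighbour
  (nearest preserves label validity and leaves diameter *values* untouched —
  they count original-scan voxels). The volumetric path zero-pads the slice
  axis to the next multiple of the target slice count and then decimates by
  an integer stride, so nothing is interpolated along z. Padded image voxels
  take −1 (the normalized background value).
- Augmentation composes translate ∘ rotate ∘ scale about the volume center
  in physical mm (rotations Rz·Ry·Rx), then resamples once onto the original
  grid; ±30 mm in-plane translation, ±30° rotations, magnification 0.7–1.3.
  Diameter values are multiplied by the magnification factor so voxel-unit
  diameters stay consistent. Identity parameters short-circuit to a
  bit-exact no-op. The number of augmented copies is a config parameter (at
  full scale it was bounded by memory, which is hardware-specific).

## Network and training

The dual-output U-net halves every spatial dimension per level and doubles
channels; each block is conv-relu-conv-relu-batchnorm-dropout plus a maxpool
(descending) or nearest-neighbour upsample (ascending), with skip
concatenation between equal-shape levels, giving 2·levels blocks (14 for the
2d reference: 256² input, 8 base channels, 7 levels; 10 for the 3d: 128²×64,
16 base channels, 5 levels — midpoint 4×4×2). Heads are 1×1 convolutions: a
4-class softmax and a softplus diameter output (non-negative with smooth
gradients; the activation type was an open choice). Convolution activations
are ReLU; per-level filter counts follow a ×2 schedule, so parameter counts
grow roughly ×4 per level (the reference models' exact filter schedules are
under-specified and not reproduced).

The loss is the per-voxel sum of 4-class cross-entropy, binary cross-entropy
of the bowel/background dichotomy and λ times the squared diameter error,
multiplied by the sample weight (default 10 on foreground voxels) and
averaged over voxels. λ defaults to 0.01 (diameters of tens of voxels give
squared errors of order 100); `lam="auto"` estimates it on the first batch
to equalize the orders of magnitude of the terms. With λ = 0 the diameter
gradient is identically zero.

Everything is implemented in NumPy with explicit backward passes (verified
against finite differences) and Adam; single-threaded runs are
bit-reproducible from the seed. Training defaults mirror the full-scale
protocol — Adam, lr 1e-3, 100 epochs, 10% validation split, best-validation
weights returned. The **desk preset** (64² input, 4 base channels, 3 levels,
no dropout) exists for CPU experiments; its training recipe (lr 0.01,
batch size 1, λ auto, no hold-out) differs deliberately: with 8 samples
there are only ~8 optimizer steps per epoch, and Adam moves parameters at
most ~lr per step, so lr 1e-3 cannot reach diameter outputs of ~15 voxels in
200 epochs. `val_fraction=0` is an explicit no-validation mode used when the
point is memorization.

## Agreement statistics

- Dice uses the standard `2|A∩B|/(|A|+|B|)` (the factor 2 is part of the
  statistic's standard definition); a comparison where both masks are empty
  is undefined and excluded rather than scored.
- ICC is McGraw–Wong ICC(A,1) — two-way random effects, absolute agreement,
  single rater — from two-way ANOVA mean squares, with the F-based 95% CI.
  A zero-variance table is reported as ICC 1 with a collapsed CI and a
  `degenerate` flag. The implementation is checked against a brute-force
  ANOVA oracle (1e-10) and cross-checked against pingouin's ICC2.
- Limits of agreement: bias = mean(a−b), half-width = 1.96·SD(a−b) with the
  sample (n−1) standard deviation.
- `compare` excludes a (scan, part) empty in *both* sources (the part is
  simply absent there); empty in only one source counts as Dice 0. An
  `either_empty` rule is available. Manual caliper pairs enter diameter
  comparisons as the mean of short and long axis by default (configurable to
  short- or long-only); repetitions are pooled, not averaged per site.
- `sample_diameter_at` reads the nearest voxel and, on a masked map, falls
  back to the nearest non-zero voxel within a 5 mm search radius — caliper
  sites sit on the bowel and may land one voxel outside the reconstructed
  tube.

## Problem sizes of the standard self-experiments

`gutgaze.experiments` fixes the desk-scale study sizes: the noise-free
round-trip uses the default 3-tube, 1 mm 128³ phantom; the repeatability
curve uses ten 2-tube 80³ phantoms with diameters 10–30 mm, two repetitions
each at jitter 0/1/2/4 mm; the capacity check trains the desk preset on the
8 bowel-richest 64×64 slices of a 2-tube phantom for 200 epochs. Round-trip
diameter error is measured over in-tube voxels that the reconstruction
covers: an uncovered voxel is a segmentation miss, already captured by Dice,
not a diameter error.

## Known limitations

- The phantom's non-overlapping tubes and isotropic gaze noise are
  simplifications; clinical agreement values cannot be reproduced without
  the (private) CT cohort.
- The NumPy network is desk-scale by design: float64, single-threaded, no
  GPU or mixed precision; the reference parameter counts (~8–9 M) are not
  targeted.
- Recording-time accounting counts retained gaze points only; time spent
  navigating, calibrating or redoing segments is not represented.
- NRRD/NIfTI support is restricted to axis-aligned orientations; DICOM is
  out of scope.
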