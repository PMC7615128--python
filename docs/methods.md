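# Methods

## Coordinate conventions

All 3-D computation happens in a single LPS-like anatomical frame: x =
patient-left / medial (+), y = posterior (+), z = superior (+), lengths in
millimetres. This is the DICOM patient frame, so landmark sets can be used
directly against DICOM-derived volumes. 3DSlicer files declaring RAS (the
common Slicer default) are converted on ingest by negating x and y; the
conversion is involutive and no file without an explicit coordinate-system
declaration is accepted. The estimators themselves are frame-invariant up to
landmark labelling, so side (left/right shoulder) is handled entirely by the
anterior/posterior/medial role labels and never by image orientation
metadata.

## The estimators

Version is reported signed, retroversion positive. All four estimators reduce
to one angle kernel, `angle_deg(u, v) = atan2(|u×v|, u·v)` — mathematically
the arccos of the normalised dot product, but well-conditioned at 0° and
180°, which matters because neutral glenoids produce near-perpendicular
configurations where the arccos form loses half the available precision.

**Two-plane.** Fossa plane F from (superior, anterior, posterior) rim points;
scapular plane S from (centre, medial border, inferior angle). Plane fitting
uses exactly three points (the clinical definition), with a degeneracy
threshold of 1e-9 mm² on triangle area — far below the ~0.1 mm precision of
manual landmarking, so real annotations are never falsely rejected. The fossa
normal is oriented laterally (positive dot with centre − medial border), the
scapular normal posteriorly (positive dot with posterior − anterior); a
reference perpendicular to its normal raises an orientation-ambiguity error
rather than guessing. Version = 90° − ∠(n̂_F, n̂_S), so perpendicular planes
read 0° and a posteriorly tilted fossa reads positive. The source method
description states only "the angle between" the planes; the 90°-complement
signed realisation is this package's choice, making the two-plane output
dimensionally commensurate with the 2-D line methods and obeying the same
sign convention.

**Friedman / vault (2-D).** g = posterior − anterior rim point, m = medial
reference − midpoint(anterior, posterior); version = 90° − ∠(g, m). The sign
falls out of the landmark roles (a fossa line leaning toward the medial
reference is retroverted) without reference to image axes, and the value is
invariant to rigid 2-D motion and uniform scaling. The medial reference is
the medial scapular border for Friedman and the vault tip for the vault
method. Whether the rim pair and the medial reference must come from the same
axial slice index is left to the annotator; the package requires only a
single 2-D constellation.

**Corrected Friedman.** The corrected transverse frame has its origin at the
glenoid centre, `axis_u` along the transverse scapular axis (centre → medial
border) and `axis_v` along the scapular-plane normal oriented posteriorly
(using the rim pair as the hint when available, else the +y hemisphere). Its
plane therefore contains the transverse axis and is perpendicular to the
scapular plane. The three Friedman landmarks are orthogonally projected into
this frame and the 2-D rule applied. Because the frame is constructed from
the (identically transformed) landmarks, the measurement is rigid-motion
invariant. The manual workflow — re-picking the points on an image slice
resampled along this frame — is supported as an alternative entry point
(`corrected_friedman_version_2d`); with exactly projected points the two
paths agree to machine precision.

Estimates are validated to lie in [−90°, 90°]; values outside raise rather
than wrap, since they indicate mislabelled landmarks, not anatomy.

## Reslicing

Trilinear interpolation in the volume's continuous index space (node-centred
voxels, orthonormal direction matrix), delegating to
`scipy.ndimage.map_coordinates`; points strictly outside the index range
return the fill value (default −1024, air in HU). Trilinear interpolation is
exact on affine intensity fields, which supplies a machine-precision oracle:
reslicing an `a + bx + cy − dz` volume along any oblique frame must reproduce
the analytic field, and an axis-aligned frame with pixel centres on voxel
centres must reproduce the stored plane bit-for-bit. Slice resolution and
extent are free parameters (defaults 256×256 px at 0.5 mm, centred on the
frame origin — the glenoid centre is the natural slice centre here); the
source workflow does not specify them.

## The synthetic scapula

The generator is the test bed standing in for patient CTs, which cannot be
redistributed. Canonical frame: glenoid centre at the origin, scapular plane
= the y = 0 plane with the medial border at (100, 0, 10) mm, the inferior
angle at (80, 0, −120) mm and the vault tip at (30, 0, 0) mm — dimensions
loosely scaled to an adult scapula; they are conventions, and only angle
recovery is asserted, never absolute geometry.

For a true version v the fossa constellation is built so that *every*
estimator's noise-free neutral-pose answer is exactly v:

- fossa line direction `g ∝ (sin v, cos v, ε·sin v)` with
  `ε = (|M| − M_x)/M_z` for medial offset M. The axial projection of g makes
  exactly the angle v with the projected transverse axis, and so does its
  projection into the corrected transverse frame: the small out-of-plane term
  compensates for the transverse axis being tilted by M's superior offset.
  With M_z = 0 the term vanishes and g is a pure rotation of the neutral
  fossa line about z. Anterior/posterior rim points sit at the lower third of
  a rim of radius 15 mm: `(0, 0, −r sin30°) ∓ r cos30° · ĝ`.
- fossa plane normal `n_F = (−cos v, sin v, 0)` — the neutral lateral normal
  (−1, 0, 0) rotated v toward posterior; the superior rim pole is placed in
  the plane through the rim midpoint with this normal. This gives the
  two-plane method the same ground truth, and the rotation-matrix identity is
  asserted in the tests, not assumed.

Per-coordinate Gaussian noise (annotation error) is added in the canonical
frame *before* the rigid pose transform (acquisition orientation), modelling
error in the anatomy followed by how the patient lies in the scanner. One
seeded NumPy generator per case; batches derive per-case seeds from a single
batch seed, so whole experiment grids are reproducible.

What the generator does **not** emulate: real rim curvature and the ambiguity
of picking "the" anterior/posterior rim point, erosion and pathological
morphology (Walch B/C glenoids), slice-selection variability for the 2-D
methods, and image-level effects (partial volume, segmentation error).
Passing recovery tests therefore demonstrate correctness of the geometry, not
clinical accuracy on pathological anatomy.

## Statistics

Per-method mean, sample SD (n−1 denominator — the natural choice for small
clinical cohorts), min and max; Pearson r between paired method outputs with
the two-sided p from the t transform `t = r√((n−2)/(1−r²))` on n−2 df. r is
computed from the centred covariance formula and clipped to [−1, 1], so
perfectly (anti)correlated series return exactly ±1. Repeated-measures ANOVA
is deliberately out of scope; paired differences are reported descriptively.

## Numerical choices and limitations

- Degeneracy thresholds: 1e-9 mm² (triangle area), 1e-12 mm (zero-length
  vectors); orientation references perpendicular to a normal (within 1e-12
  relative) are errors, not coin flips.
- Frame axes are validated orthonormal to 1e-12; the corrected frame
  re-orthogonalises the scapular normal against the transverse axis to
  absorb floating-point drift.
- The two-plane sign convention (90° minus the oriented dihedral angle) is a
  design choice: the alternative of reporting the unsigned plane angle loses
  the retro/ante distinction that the other methods carry.
- Problem sizes in the validation script (1000 rigid transforms, 200 jitter
  replicates, a 20-case noisy cohort) were chosen so the whole run completes
  in seconds while keeping Monte-Carlo error on the reported SDs below a few
  percent.
- The vault method's tendency to read higher than Friedman is reproduced
  geometrically (a posteriorly displaced vault tip adds `atan(d/x)` to the
  reading) but the package makes no claim about its clinical magnitude.
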