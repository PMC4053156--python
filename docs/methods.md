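# Methods

This note documents the models, conventions and numerical choices behind
`ki67calib`, in the order the pipeline runs them, together with what the
synthetic benchmark can and cannot say about real tissue.

## Synthetic TMA spots

A spot is a disc of diameter 1000 µm rasterized at 0.5 µm/px (a 20×
whole-slide scan), carrying a tumour region (concentric disc by default;
irregular "blob" and annulus masks are available), tumour nuclei, and
optional stromal and lymphocytic admixture.

**Placement** is a hard-core point process by rejection sampling: centre
distances must satisfy `(r1 + r2)·(1 − overlap_allowance)` across all cell
classes, with `overlap_allowance = 0` meaning nuclei may touch but not
overlap.  Raising the allowance produces the confluent clumps that defeat
nuclear segmentation in highly cellular tumours — deliberately, so that
failure mode can be studied on demand.  The attempt budget is 200 per
requested cell; an infeasible density raises an explicit error rather than
silently under-filling.

**Classes and stains.**  Each tumour cell is Ki67-positive independently
with probability `true_li_percent/100`; the spot records the *realized*
ratio exactly, and all downstream accuracy statements compare against that
realized value.  Nuclear radii follow a truncated normal (default mean
5.0 µm, SD 0.6, minimum 2.5 — breast-carcinoma-sized nuclei, giving mean
areas near 80 µm²).  Staining is a single nuclear-intensity value per cell:
positives dark (DAB-like; normal, mean 140, SD 12, clipped to [95, 185]),
negatives light (hematoxylin-like; mean 218, SD 4, clipped to [206, 228])
against a glass background of 245.  The clips keep nuclei separable from
glass while letting the class distributions brush against the staining-bin
thresholds of the detector, as real weakly stained nuclei do.

**Rendering** embeds that intensity in the green channel of an RGB image
(both DAB and hematoxylin absorb green, so one channel carries "total
nuclear stain"), with a brown tint (R up, B down) for positives and a blue
tint for negatives; where nuclei touch, the darker value wins, so clumps
merge visually.  I.i.d. Gaussian read noise (SD 3 grey levels) is added
everywhere.  Identical spec + seed gives bit-identical truth tables, masks
and rasters.

Defaults encode the study conditions: one 1-mm spot per case, 2000 tumour
cells/mm² (about 1300 tumour profiles per spot, matching observed per-spot
profile totals in the low thousands), admixture off unless configured.

**What the generator does not emulate:** chromatin texture, out-of-focus
blur, staining gradients, section-thickness effects, non-circular nuclei
and scanner colour variation.  Passing tests therefore demonstrate
correctness of the *counting, comparison and correction machinery* and
qualitative realism of the detection failure modes — not performance of the
detector on real histology.

## Counting-frame stereology

Frames of side b = 125 px on a lattice of period a = 250 px sample 25 % of
the area.  Frame interiors are half-open pixel rectangles, so a tiling
(a = b) partitions the image.  Forbidden lines are the *boundaries between
pixels*: an object "intersects" a line when it has pixels on both sides at
the same row/column.  (Treating the lines as pixel columns instead would
make a tiling lose every object that touches its frame's bottom row, which
contradicts exact-census behaviour; the boundary convention is the discrete
analogue of the classical rule.)

Two rule variants:

- `simple` — excluded if crossing the left or bottom frame edge, exactly as
  drawn in classical counting-frame figures;
- `gundersen` — additionally excluded when crossing the upward extension of
  the left edge or the downward extension below the bottom-right corner.
  This is the classical unbiased frame; it is the only variant for which a
  full tiling counts every convex profile exactly once, which the test
  suite asserts against exhaustive enumeration.  (An "upward left +
  rightward bottom" extension pair, sometimes sketched informally, fails
  exactly-once counting for objects that span four frames but miss the
  bottom-left one; the package therefore uses the corner-down form.)

Sampling uncertainty: `CE = t·sqrt(Cg·m/n²)` with Cg = 0.049 tabulated for
b/a = ½ (the package stores the constant; it does not re-derive grid
factors) and t = 2.  *m* is defined as the boundary edge count of the union
of occupied lattice cells, `4n − 2·(adjacent pairs)` — the unique reading
consistent with a six-frame tree exposing 14 sides.  The per-spot interval
is **relative**, `LI·(1 ± CE)`, since CE is a relative error already
carrying the coverage factor; an absolute form `LI ± 100·CE` would also be
defensible, and the relative one was adopted and is used consistently.
Frames count as "inside the tumour" on any positive mask overlap
(configurable minimum overlap fraction), since an observer marks whatever
tumour shows in a frame.

Observer imperfection is modelled on the counts: each profile is missed
with `miss_prob` and class-flipped with `class_flip_prob`.  Agreement
between observers is CI-overlap: two counts agree when their CE intervals
intersect; all agree when the common intersection is non-empty.

## The DIA stand-in

The detector reproduces the *parameter surface* of a commercial
Genie/Nuclear-style pipeline, not its internals.  Pipeline: tumour mask
(generator oracle, or a transparent nuclear-density classifier: nuclear
pixels averaged in a 25-µm window, thresholded at 6 % cover) → nuclear
intensity channel (green) → mean smoothing with `averaging_radius_um` →
candidate pixels with `black < v ≤ upper` inside the mask → connected
components → declumping → morphometric filtering → staining bins.

Numerical conventions, where the vendor leaves gaps:

- **Thresholding** is global on the smoothed channel (the vendor's "edge
  threshold" mode is not reproduced); dark nuclei therefore appear
  slightly dilated and light nuclei slightly eroded at the boundary —
  size-filter interactions near the minimum-area setting are real and
  intentional.
- **Declumping**: watershed on the Euclidean distance transform, seeded by
  h-maxima with `curvature_threshold` as the minimum peak prominence (in
  distance units); seeds and plateaus are 8-connected, and a component
  without a prominent peak keeps its global maximum so nothing is silently
  dropped.
- **Morphometry**: compactness `4πA/P²`, elongation = minor/major axis of
  the best-fit ellipse, roundness `4A/(π·major²)`, each clipped to [0, 1];
  filters reject strictly below the configured minima; areas in µm² via
  `pixels · resolution²`.
- **Edge trimming "weighted"**: object mean intensity is measured on the
  object *core* (pixels deeper than the averaging radius), because rim
  pixels blend with glass and neighbours; thin objects fall back to all
  pixels.  "Cytoplasm rejection" remains a configuration-fidelity no-op.
- **Bins**: negative if mean > weak; weak 1+ if moderate < mean ≤ weak;
  moderate 2+ if strong < mean ≤ moderate; strong 3+ otherwise.  All
  positive bins count toward the LI.

Three profiles ship with the package — `DIA_0` (vendor-style defaults:
wide size window 20–10⁶ µm², upper threshold 220, weak 210), `DIA_1`
(visually tuned: sizes 45–1000, upper 230) and `DIA_2` (bias-tuned: min
size 40, compactness/elongation 0.2, weak 229) — representing successive
calibration cycles.  On the synthetic world their behaviour differs from
any particular tissue cohort; what the suite asserts is the mechanics:
raising the weak threshold can only raise the LI on a fixed object set,
raising the minimum size can only lower the detected total, and growing
overlap can only reduce detections.

`calibrate_settings` automates a calibration cycle: a cartesian grid over
candidate settings values, scored by `|mean(LI_DIA − LI_ref)|` with the
R² against the references as tie-break, logging every evaluation.
Candidates that differ only in staining-bin thresholds share one detection
pass, since binning does not affect detection.

## Method comparison

Forward fits are OLS of method on reference (standardized slope = Pearson r
for the simple model; two-sided t-tests on coefficients, no
multiple-testing correction).  Orthogonal regression takes the first
principal axis of the centred cloud (line through the centroid,
slope = tan(tilt)); an isotropic cloud has no axis and errors out.

Confidence ellipses are PCA-aligned coverage ellipses; when per-point CEs
are supplied, each point is augmented with its four CI-extreme replicates
`(x(1±ce), y(1±ce))` before fitting — a documented convention, chosen so
subsampling uncertainty can widen but never shrink the ellipse.  Axis
lengths are full lengths at the 95 % Mahalanobis quantile.

The **accuracy factor** is `tilt(regression line) / tilt(ellipse major
axis)`, both in degrees — a ratio of tilts, not slopes; this is the
convention under which the two printed worked values (0.82 for the forward
fit against a 45.36° axis; 0.92-level values for orthogonal fits against a
45° axis) are reproduced, and both the forward and orthogonal variants are
reported.

Duncan's multiple-range test uses studentized-range critical values at the
stepwise protection level `1 − (1−α)^(p−1)` for a span of p ordered means
(α = 0.05), with the standard letter display: non-significance of a span
protects its sub-spans, letters are maximal non-significant intervals, and
columns sharing a letter are indistinguishable.  Critical values are
computed from `scipy.stats.studentized_range` and cached.  Under the null
the whole-range level for k = 3 is 1 − 0.95² ≈ 9.75 %, so the letter-split
rate sits just under 10 % by construction.

## Inverse-regression correction and dichotomization

The correction model regresses *reference on measurement* and applies
`slope·value + intercept`, clamped to [0, 100] (a negative corrected
percentage is meaningless; the clamp is this package's choice).  The
range-restricted variant fits only cases with reference < 40 % — the
clinically dense range — but is applied to the full scale, mirroring how
such corrections are deployed.  A two-predictor variant (DIA + visual
estimate) is available.

Dichotomization at a cutoff c counts a case positive when its value is
*strictly above* c.  Underestimation rate is relative to reference-positive
cases, overestimation to reference-negative cases, total to all cases.

`default_bias_simulation` packages the bias pattern that motivates the
correction: references from a right-skewed scaled Beta(1.0, 1.7) (skewness
≈ 0.5, matching clinical Ki67 cohorts), measurements
`5.9692 + 0.7588·ref + N(0, 6)` clamped to the percentage scale — a
proportional attenuation with positive offset, i.e. overestimation at the
low end and underestimation at the high end, with forward R² ≈ 0.9.  Seed
42, n = 164 by default.

## Pipeline

One spot per simulated case; per-case true LI from the same scaled Beta;
per-case lymphocyte admixture uniform over a configurable range (variable
inflammation makes the uncalibrated wide-open size filter noisy, which is
what the calibration search then fixes).  The reference arm uses a random
grid offset per spot; a "visual estimate" method is emulated as a
whole-spot count through a heavy observer-error model (miss 0.25, flip
0.05), reported to the nearest 5 % as pathologists do.  Calibration runs on
the first cases (default 20) and the winning settings are then applied to
the whole cohort — like tuning on the study material itself.  All
randomness derives from `SeedSequence([seed, case_index])`, so runs are
reproducible file-for-file; spots whose measurements are undefined (no
counted profiles) are excluded from fits and listed in the report warnings.

## Problem sizes in the test suite

The statistical guarantees are exercised at sizes chosen to make their
Monte-Carlo error small relative to the asserted bounds while keeping the
suite quick: tiling exactness on twenty 250-µm spots at 4000 cells/mm²
(~160 profiles each, exact equality), unbiasedness over 200 random grid
offsets on one default 1-mm spot, coefficient recovery over 100 replicate
fits at n = 164, Duncan null behaviour over 1000 simulated triples at
n = 30, and DIA agreement on three 500-µm spots in an easy regime (sparse,
nuclei ≥ 4.5 µm radius, stain distributions strictly inside their bins) —
the regime in which detection errors reflect implementation faults rather
than designed-in confounders.

## Known limitations

- The detector is a stand-in: no claim of equivalence with any vendor
  algorithm, only of an honest, fully documented parameter surface.
- The CE grid-factor table contains the single shipped geometry
  (b/a = ½ → 0.049); other geometries require supplying Cg.
- The relative-vs-absolute CI reading, the ellipse construction from CI
  limits, and the tilt-ratio accuracy factor are documented conventions
  where the underlying practice is ambiguous; alternatives are one-line
  changes.
- Dichotomization reports use strictly-greater cutoffs; ties at the cutoff
  belong to the negative class.
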