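# Methods

## Scope and data model

`qperf` quantifies stress myocardial blood flow (MBF) from dynamic
contrast-enhanced short-axis CMR and reports perfusion defects on a
standardised high-resolution bullseye. Inputs are assumed to be already
motion-corrected and saturation-corrected upstream: a time-resolved 2D
signal stack per slice (basal, mid, apical), an arterial input function
(AIF) sampled in the LV blood pool, endo-/epicardial contours plus the two
RV insertion points per slice, and optionally binary reference defect
masks. The package does not segment the myocardium, detect insertion
points, or correct motion or AIF saturation.

## Tracer kinetics

**Concentration proxy.** Signal is converted to a dimensionless
concentration proxy by relative enhancement, `c(t) = (S(t) − S0)/S0`,
where `S0` is the mean of the first `baseline_frame_count` frames
(default 3). Pixels with `S0 ≤ ε` (`ε = 1e−6`) are flagged invalid rather
than raising. No further scaling constant is applied: MBF units emerge
from the deconvolution, and all downstream thresholds are derived from the
same maps, so the absolute scale of the proxy cancels.

**Forward model.** The tissue curve is the discrete causal convolution of
the AIF with a Fermi impulse response

    R(t) = MBF · (1 + e^{−w·k}) / (1 + e^{(t − t_d − w)·k}),  t ≥ t_d
    R(t) = 0,                                                  t < t_d

normalised so that `R(t_d) = MBF` — MBF is a direct fit parameter, not a
post-hoc amplitude extraction. Convolution is `(a * r)[j] · dt` on a
common uniform grid; irregularly timed acquisitions are first resampled by
linear interpolation onto a grid at the median frame interval. Because
the concentration proxy is dimensionless and `dt` is in seconds, the
modelled tissue-curve magnitudes exceed physiologic relative enhancement;
this is an internal scale convention shared exactly by the phantom's
forward model and the fitting inverse, and has no effect on thresholds or
statistics.

**Fitting protocol.** Parameters are bounded: MBF ∈ [0, 10] mL/min/g,
w ∈ [0, 60] s, k ∈ [0, 5] /s, t_d ∈ [0, 20] s; tolerances 1e−8. Two
structural facts shape the optimiser:

1. Given (w, k, t_d) the model is linear in MBF, so the amplitude is
   solved in closed form (variable projection, clipped to its bounds) and
   only (w, k) are optimised smoothly (trust-region reflective least
   squares seeded at w = 10 s, k = 0.3 /s).
2. The causality cutoff `R(t < t_d) = 0` makes the objective
   *discontinuous* in t_d at every frame-time crossing — and flat between
   crossings, because the samples cannot see where the onset sits inside
   a frame interval. Gradient descent on t_d is therefore unreliable by
   construction. Instead the delay is searched over a deterministic grid
   of whole frame intervals (0 to 8 s): every candidate is ranked by its
   projected residual at the nominal shape, and the three best-ranked
   candidates are refined fully; the lowest final cost wins (ties go to
   the smaller delay).

The protocol is deterministic, with no random restarts. On noiseless
curves generated by the same forward model, recovery is exact (to solver
tolerance) when the true delay lies on the frame grid, and within ~1.1%
in MBF when it does not (the within-frame delay position is genuinely
unidentifiable from the sampled data; the residual MBF error comes from
the width/delay trade-off along that ridge). With 2% signal noise the
median absolute MBF error is below 1% across 0.5–4.0 mL/min/g.

**Flat-pixel rule.** A pixel whose maximum enhancement is below 5× its
baseline concentration SD is classified flat and reported as MBF = 0 with
a flag, skipping the fit.

## Bullseye cartography

Each slice is resampled onto 10 transmural layers × 60 angular positions
(600 points per slice, 1800 per patient). Rays emanate from the centroid
of the endocardial polygon; contours are resampled to 360 vertices by arc
length and converted to a polar radius function (linear interpolation
between vertices), which is exact ray-casting for star-shaped contours;
non-star-shaped contours are rejected as degenerate. Sample points sit at
transmural fractions `(i + 0.5)/10` between the endo- and epicardial
crossings, at angle-bin centres `(j + 0.5)·6°`, and are interpolated from
the MBF map with a cubic b-spline. Invalid pixels are filled with their
nearest valid myocardial value before spline evaluation; an angular column
whose samples all lie more than 2 px from any valid pixel is marked
missing.

**Angular convention.** θ = 0 at the anterior RV insertion point,
increasing toward the inferior insertion point through the septum (the
short arc between the insertion-point angles fixes the direction). AHA
segment boundaries coincide with bin edges: basal and mid slices are six
60° sectors (segments 1–6 and 7–12), the apical slice four 90° sectors
(13–16), numbered from the anterior insertion point in the same
direction. No 17th apical-cap segment is used. Rotating the insertion
points by a multiple of 6° cyclically shifts the angle axis — a property
the tests assert exactly.

**Median filter.** A 5×5 median on each slice's (layer, angle) plane:
circular wrap along the angle axis (anatomy is periodic), mirror
reflection along the transmural axis (it is not). The filter is built on
`sliding_window_view` + `nanmedian` so missing cells stay missing and are
ignored in their neighbours' windows; it matches a brute-force
sliding-window oracle to machine precision. The window interpretation of
"size 5" as 5×5 2D (rather than length-5 1D) is a documented choice.

## Defect analysis

- **Thresholds**: ROC over the rule "positive iff MBF < cutoff".
  Candidate cut-offs are midpoints of consecutive sorted unique sample
  values (plus the one-sided extremes); the Youden index J is maximised;
  among tied candidates the middle one is reported (sample-symmetric and
  deterministic). AUC is the trapezoidal area under the empirical ROC.
- **Resolution levels**: pixel samples come from the native-resolution
  maps (bullseye thresholding is a reporting step); a segment's MBF is the
  mean of its valid pixels and it is positive iff *strictly* more than
  half its pixels lie in a reference defect; a territory's MBF is the mean
  of its two lowest segments (LAD = {1,2,7,8,13,14}, RCA = {3,4,9,10,15},
  LCX = {5,6,11,12,16}) and it is positive if any segment is; a patient's
  MBF is the mean over all valid myocardial pixels and it is positive if
  any territory is.
- **Burden** is pooled defect area over pooled myocardial area, in
  percent. Dichotomised 16-segment reporting can only move in steps of
  100/16 = 6.25%.
- **Agreement**: Dice `2|A∩B|/(|A|+|B|)` (two empty masks score 1, needed
  for visually normal patients); Bland–Altman on burdens with differences
  `manual − quant` (negative bias ⇒ manual underestimates), limits of
  agreement ±1.96 SD, proportional bias as the OLS slope of differences on
  pair means; Mann–Whitney U (exact for small untied samples,
  tie-corrected normal approximation otherwise) comparing MBF inside vs
  outside reference defects. Patient-level means exclude flagged/invalid
  pixels.

## Synthetic phantom

The phantom emulates the study inputs with known ground truth: circular
annular myocardium per slice (defaults: endo/epi radii 11/19, 10/18, 8/15
px in a 96² image — at a typical 2×2 mm² resolution this gives roughly
one pixel per bullseye point), a gamma-variate AIF
`A·((t−t0)/β)^α·e^{−(t−t0)/β}` (t0 = 5 s, α = 2.5, β = 3.5 s, A = 5;
peak at t0 + αβ ≈ 13.8 s), 50 frames at 1 s intervals, and an MBF field
equal to a remote level (2.35 mL/min/g) except inside planted polar
defect regions (default 1.1 mL/min/g) — flow levels chosen at typical
stress values for normal and ischaemic myocardium so synthetic statistics
are commensurate with clinical ranges. Tissue curves are the package's own
forward model with response shape w = 10 s, k = 0.3 /s, t_d = 2 s; signal
is `S0·(1 + c)` plus seeded Gaussian noise of SD `noise_sd·S0` (default
2%). Noise is Gaussian on signal, not Rician — a documented
simplification; the phantom also omits respiratory motion, saturation/T1
signal physics, coil shading, partial-volume mixing at tissue borders and
anatomic wall-thickness variation. Passing recovery tests therefore
demonstrates correctness of the inverse computation under the model's own
assumptions, not robustness to those real-data effects.

**Threshold-ordering cohort.** The qualitative property that the
pixel-level cut-off does not exceed the segment-level cut-off is
reproduced on a cohort whose defects occupy *fractions* of segments:
positive segments at 60–92% angular coverage (their means are diluted
toward remote flow, pushing the segment threshold up), spill-over into
neighbouring segments kept below ~25% coverage. Coverages are kept away
from the 50% positivity boundary deliberately: with two flow levels a
segment's mean is linear in its coverage, so a segment sitting at ~50%
coverage has a mean at the class boundary and its label (and with few
segment samples, the empirical cut-off) flips with estimation noise —
a degenerate labelling condition, not a property of the method.

## Numerical and interface choices

- Coordinates are 0-based `[x, y]` = (column, row) pixel indices; angles
  in user-facing files are degrees; times seconds; MBF mL/min/g.
- Dynamic series: 3D NIfTI `[time, row, col]` with a JSON sidecar for
  frame times, or a read-only DICOM directory ordered by trigger time
  (fallback: instance number). Geometry: documented JSON schema. Bullseyes:
  long-format CSV and JSON. Cohorts: manifest CSV with per-slice rows
  (`aif_path` is required — the AIF is an input to quantification).
- Determinism: identical inputs, configuration and seeds give identical
  maps, grids and reports; the phantom is bit-reproducible per seed.
- Problem sizes in the test suite and acceptance script use compact
  phantoms (48–64 px images, 3–4 patients) so the whole suite runs in a
  few minutes on one CPU; the physics and every processing step are
  identical at the default 96 px size.

## Known limitations

- The Fermi parameterisation and the choice of fitted (grid-searched)
  delay follow the constrained-deconvolution literature but are one of
  several defensible conventions; absolute MBF from Fermi deconvolution is
  known to be implementation-dependent in general.
- Contours must be star-shaped about the endocardial centroid; extreme
  crescent-shaped ventricles would be rejected rather than resampled.
- No bootstrap confidence intervals for AUC or cut-offs; no LGE/scar
  integration; no inter-slice interpolation into a continuous volume.
- Threshold estimates on small synthetic cohorts are midpoints of class
  gaps and inherit their width; they demonstrate the machinery and its
  ordering properties, not population-level cut-off values.
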