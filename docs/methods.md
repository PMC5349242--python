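# Methods note

This note records the model, parameter choices, numerical details and
known limitations of the `ishprofiler` implementation.

## Imaging model

A dual-colour chromogenic/silver in situ hybridization stains the gene
locus as black (silver) dots and the chromosome-10 centromere as red
dots, both roughly circular with radii 1–7 px at the working
resolution, on hematoxylin-stained tissue (pale blue-violet nuclei on a
near-white background).  High-resolution scans are acquired at
0.11 µm/px, standard scans at 0.23 µm/px; cores are analysed at a
working side of 4,096 px (2¹²), reached by bicubic resampling.  Whole
slides (e.g. 108,000×138,000 px or 84,000×110,000 px) are processed as
2,000 px tiles, giving 3,726 and 2,310 tiles respectively
(`ceil(w/t)·ceil(h/t)`).

## Detection

* **Edge map.** Sobel gradient magnitude of Rec. 601 luminance,
  thresholded by Otsu's method on a 256-bin histogram (`edge_threshold
  = "auto"`); an explicit numeric threshold is also accepted.  A
  constant image yields an empty edge map.
* **Hough accumulator.** `skimage.transform.hough_circle` over integer
  radii 1–7 (normalized).  OpenCV's `imfindcircles`-style detector is
  not available in the environment; the accumulator is the standard
  circular Hough and the surrounding logic (below) is implemented
  here.
* **Sensitivity semantics.** Per radius, candidates are local maxima
  (3×3 maximum filter) of the accumulator at or above
  `(1 − sensitivity) · max`, so a higher sensitivity is strictly more
  permissive.  Defaults: 0.85 (high-resolution profile), 0.95
  (standard profile).
* **Blob-contrast verification.** Hough responses at small radii fire
  along *any* thin edge curve, not only closed circles.  Each
  candidate must therefore be a genuine dark blob: mean inverted
  luminance inside the disc minus the **darkest of eight angular
  sectors** of the surrounding annulus must reach `min_contrast = 30`
  (8-bit units).  Real signals are ≳ 100 units darker than background;
  a candidate sitting on the boundary of a larger dark structure (a
  nucleus edge, a bigger signal) has at least one dark sector and
  scores near zero.  The sector minimum — rather than the annulus
  mean — is what rejects candidates just *inside* nucleus boundaries.
* **Non-maximum suppression.** Strongest-first; a candidate is
  suppressed when its centre lies within
  `max(min_centre_distance, r_kept, r_candidate)` of a kept centre
  (`min_centre_distance = 2` px).  Including both radii removes
  larger-radius satellite responses around small signals and vice
  versa while still allowing truly adjacent 1 px signals.
* **Sub-pixel refinement.** Centre: intensity centroid of the 3×3
  accumulator neighbourhood.  Radius: parabolic interpolation across
  neighbouring radius bins, clipped to ±0.5.  Refinement can pull two
  integer-grid candidates onto the same blob, so a second
  deduplication pass runs on the refined centres with the same rule.
* Detections within `radius_max` of the border are flagged
  `near_border` rather than dropped.

On 1,024 px synthetic cores with 150 planted signals at the default
noise level, recall and precision are both ≈ 1.0 at 2 px matching.

## Classification

Each detection yields a 13×13 RGB patch centred on its rounded centre
(border overhang filled with the background colour), flattened
channel-major (R-plane | G | B) and scaled to [0, 1]: 169 pixels × 3 =
507 features.  An RBF-kernel SVM is selected by 5-fold stratified
cross-validation over the full grid C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}, γ ∈ {2⁻¹⁵,
…, 2³} (110 pairs, ≈ 45 s for 1,000 samples) and refitted on all data
with one-vs-rest decision scores.  The grid loop is written out rather
than delegated to `GridSearchCV` because the tie-break is specified
exactly (smallest C, then smallest γ on equal CV accuracy): iterating
the grid in ascending order with strict-improvement selection
implements it deterministically.  Folds are drawn from a seeded
`StratifiedKFold`; an explicit per-sample fold assignment can be
supplied instead, which makes the selection invariant to sample order.

Five classes: `PTEN` (black), `CEP10` (red), `MIXED` (overlapping
red+black), `WHITE` (background false positive), `BLUE` (nuclear false
positive).  White and blue detections are discarded before
quantification.

Training patches come from the synthetic generator: one planted signal
(or background/nucleus site) per patch, over the full radius range
1–7, with the patch centre jittered ±1.5 px around the true centre.
The jitter matters: the detector localises centres to ≈ 1 px, and a
model trained only on perfectly centred patches misclassifies a
fraction of slightly off-centre small signals.

## Quantification

* **Automated (DISH) route.** Global ratio = ΣPTEN/ΣCEP10 over a core
  or slide, capped at 3 (blunting false-positive gene signals);
  deletion called at ratio ≤ 0.60 (inclusive).  Mixed signals are
  excluded by default (option to add them to both numerator and
  denominator).  A core with gene but no reference signals is reported
  at the cap and flagged `capped`; a core with neither is
  non-evaluable.  `informative_fraction` reports the share of
  detections that were PTEN or CEP10.
* **Manual (FISH) rules.** A nucleus with fewer gene than centromere
  signals is *aberrant*.  Hemizygous deletion: ≥ 60 % of counted
  nuclei aberrant.  Homozygous deletion: ≥ ⅓ of the aberrant nuclei
  show zero gene signals (the denominator can be switched to all
  counted nuclei).  The homozygous definition additionally presumes
  adjacent normal cells carrying one or two gene signals — a
  microscope-level observation modelled as an optional
  `adjacent_normal_cells` attestation; passing `False` vetoes the
  homozygous call.  The mean ratio is **pooled** (Σgene/Σcentromere)
  by default, matching the per-core total-signal columns of the
  clinical table; mean-of-ratios is available as an option.  All
  thresholds are inclusive.

## Colour maps and tiling

Classified signals are re-rendered as solid marker discs — black
(gene), red (centromere), green (mixed) — on a white background,
preserving positions.  Tiled processing merges per-tile maps by
translating signals into the slide frame and re-rendering, so a marker
crossing a tile seam is drawn once, seamlessly; merging requires the
complete tile set.  For detection over tiled slides, tiles are read
with a `2·radius_max` overlap margin on their right/bottom edges and
detections falling in the margin are deferred to the neighbouring
tile, so no signal is counted twice across a seam.

## Clinical schema

The per-patient table is validated field-by-field against the printed
ranges and vocabularies, with dichotomization boundary semantics as
published: `age_d64` = 1 at age ≥ 64; `BMI_d25` = 1 at BMI > 25;
`PSA_d10` = 1 at PSA ≥ 10; `PTEN_FISH_ratio_d60` = 1 at ratio ≤ 0.6
but `PTEN_FISH_percent_d60` = 1 at percent aberrant ≥ 0.6 (the two
dichotomizations point in opposite directions).  Cross-field
consistency between continuous values and their dichotomized codes is
checked.  Cohort composition constants: 339 RPE + 28 CRPC + 17 LNM +
11 DM + 29 BPH = 424 patients; imaging subset 38/10/6/1/16 = 71.

One caveat is propagated to users: the printed description of the `pN`
codes ("0: no tumour, 1: positive surgical margin") duplicates the
surgical-margin wording of `R1` and is likely a transcription slip in
the source data dictionary; the field is validated against the printed
{0, 1} vocabulary as-is.

The synthetic table generator derives every dichotomized code from a
sampled continuous value, so its output always validates cleanly; an
explicit tissue composition summing exactly to the row count is
reproduced exactly (shuffled), otherwise compositions act as sampling
weights.

## Synthetic image generator

* Palette: background (245, 242, 240); nuclei (150, 140, 190),
  soft-edged ellipses with semi-axes 10–18 px; gene signals
  (40, 35, 30); centromere signals (185, 60, 70).  Discs are rendered
  with an error-function edge profile (σ = 0.5 px) for realistic
  anti-aliasing; Gaussian pixel noise (σ = 5 by default) is added and
  clipped.
* Mixed signals are a full-radius red disc with a black core of
  radius 0.6 r (minimum 1 px) at ≤ 1 px offset, so visible red remains
  at every radius in 1–7.
* Placement by rejection sampling: minimum separation 2·r_max between
  signal centres, margins from the border, keep-out zones around
  nuclei; a `CapacityError` is raised when the requested density does
  not fit.  Whole-slide rendering supports rectangular deletion zones
  with zone-specific planted ratios, and refuses allocations beyond
  2 GiB with a pointer to tiled processing.
* Ground truth (class, sub-pixel position, radius, zone) is carried
  alongside every rendering and round-trips through TSV.

### Generator limitations

The generator is deliberately simple: no tissue texture,
out-of-focus blur, staining gradients, overlapping signal clusters,
touching nuclei, or scanner-specific colour response.  Nuclei are
single ellipses at 10–18 px semi-axes — realistic for the stated
resolutions, but smaller or rounder nuclei than generated would
stress the blob-contrast gate more than these images do.  Detection
and classification figures measured on synthetic data are therefore
upper bounds on real-tissue performance, and the detector parameters
(contrast 30, sensitivity defaults) should be revalidated on real
scans.

## Numerical choices

* All image arithmetic in float64; uint8 only at I/O boundaries.
* Luminance = Rec. 601 (0.299 R + 0.587 G + 0.114 B).
* Deterministic seeding throughout (`numpy.random.default_rng`);
  rendering, training and the acceptance script are bit-reproducible
  per seed.
* Thresholds at published boundaries are compared inclusively
  (`<=`/`>=`) with exact rational inputs where possible; the test
  suite pins the boundary cases 0.60 and ⅓ exactly.
* PNG for lossless image I/O; 16-bit inputs are rejected rather than
  silently rescaled.
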