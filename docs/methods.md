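# Methods

This note documents the models and procedures `micromorph` implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical conventions a user should know before trusting a
number.

## Coordinate and unit conventions

Images are held as `(z, channel, y, x)` arrays with an explicit lateral
calibration (µm/px) and, for stacks, an axial step (µm). Calibration is a
required input — it is never inferred from image size and its absence is a
hard error. Channels are addressed by biological role (`vinculin`, `actin`,
`nucleus`, `centrosome`, `pattern`, `apical`, `basolateral`), never by index
convention, because the stain-to-channel assignment varies between assays.
All exported geometry is in µm. Angles live in (−180°, 180°], measured from
the +x axis of the pattern-aligned frame; where z-stacks are reduced to 2D
(nucleus and centrosome detection) the maximum-intensity projection is used
and logged.

## Segmentation primitives

**Rolling-ball background.** The background is the grayscale opening of the
intensity surface with a spherical structuring element of the given radius
(default 5 µm, configurable): the surface traced by a ball rolled under the
image. Structures narrower than the ball survive subtraction; smooth
background does not. For radii well above a pixel the exact opening is
computed on a down-sampled copy (ball ≈ 12 px), re-interpolated, and capped
at the local minimum filter — the background is smooth at that scale by
construction, and the exact path (`fast=False`) remains available and is
what the equivalence tests exercise. Note that with photon noise the rolled
ball tracks the lower noise envelope, so a residual pedestal of roughly two
noise standard deviations survives subtraction; the thresholding step must
(and does) account for this.

**Thresholding.** Otsu thresholds are computed exactly (prefix sums over the
sorted sample, maximising between-class variance over every possible split)
rather than on a binned histogram, so results on discrete data match an
exhaustive search bit for bit. Thresholds can be restricted to an ROI and a
fixed value can always be supplied instead — the assays this package serves
traditionally adapted thresholds per experiment; here any such choice is an
explicit, logged configuration value.

**Whole-cell edge mask.** Gradient magnitude (Sobel of a Gaussian-smoothed
image, smoothing 1.0 µm default) → Otsu on the gradient → morphological
closing → hole filling gives an edge-bounded region. Because the gradient
band is ~±σ wide, using it directly biases the area high by ~20%; the
boundary is therefore refined to the half-way intensity between the median
interior and median exterior level, which for a blurred step is the physical
edge. Measured areas land within ~5% of truth across the generator sweep
(typical bias −2%). A field whose interior/exterior contrast is below four
times the robust exterior noise is reported as "no cell" rather than
segmented. If several candidate regions survive, the largest is kept (ties:
smallest label) and the event logged — these are single-cell assays.

**Connected components.** 8-connectivity in 2D, 26-connectivity in 3D,
fixed so that region counts are comparable across runs. Areas are pixel
counts × (µm/px)²; sub-minimum regions are removed and labels renumbered
contiguously.

## Adhesion analysis

Pipeline per field: edge mask on the vinculin stain → rolling-ball
subtraction of the vinculin channel → mild denoise (Gaussian, σ = 0.1 µm)
→ threshold → components ≥ 0.1 µm² → metrics. The threshold is Otsu within
the ROI, floored at median + 3.5×MAD of the corrected ROI intensities: with
very few adhesion sites the foreground occupies a vanishing fraction of the
ROI and plain Otsu can collapse into the noise; the robust floor prevents
this without affecting well-populated cells. Circularity is the
minor/major axis ratio of the best-fit ellipse — the "length to width"
wording of shape indices is oriented so a circle scores 1 and elongation
scores lower. Spreading area is the filled cell-mask area, not the pattern
area. Exclusion rules (< 400 µm², < ⅓ pattern cover) mark records rather
than dropping them. Group comparison is a two-way ANOVA
(treatment × confinement) with Tukey-adjusted pairwise contrasts via
statsmodels; effect direction is reported as percent change against a
declared reference group.

## One-cell polarity

The pattern frame is established from the thresholded pattern channel: its
centre of mass is the origin; the symmetry (front–rear) axis is the
principal axis with non-zero third moment (the crossbow is mirror-symmetric
about it), and the front is the heavier side (the arc outweighs the stem).
This makes the frame independent of how the chip was mounted; rotating the
field rotates nothing but the extracted pattern frame. The nucleus is the
largest thresholded region in a configurable area window (20–400 µm²
projected); the centrosome is the centroid of up to two bright puncta
(two centrioles can resolve separately), detected at mean + 5 sd of the
projected plane — appropriate for spots occupying a vanishing pixel
fraction where histogram thresholds are unstable. Vectors shorter than
0.2 µm are below localization precision: the angle is reported undefined and
the record excluded (and counted). More than two surviving puncta flags the
record.

Mean vectors and resultant lengths are computed from the full angular range;
the mirror fold into [−90°, 90°] is a display transform only, reflecting
that the sign of the x-component carries no information on a symmetric
pattern.

**The common-median test.** Fisher's statistic
P = N²/(M(N−M)) Σ m_i²/n_i − N·M/(N−M) on the per-group side counts about
the pooled circular median. Two conventions matter numerically. First, the
pooled median is taken at a data point and that observation is removed from
the counts — it lies on the dividing diameter and carries no side
information. Second, for two groups the p-value uses the exact conditional
null: given the pooled sample, the group membership of the M negative-side
observations is hypergeometric under H0. The asymptotic χ² reference is
noticeably anti-conservative at the sample sizes these assays produce
(measured 7.3% empirical size at nominal 5% with n = 50 per group over 2000
simulations; the exact conditional version measures 4.5%, with full power
retained at a 90° mean separation). For more than two groups the χ²(s−1)
reference is used and reported as such.

## Two-cell stages

Exactly two nuclei (after size filtering) and two to four centrosome puncta
are required. Puncta are matched to nuclei by minimum-total-distance optimal
assignment with at most two per cell and pooled to one intensity-weighted
centroid per cell; d_cc below 0.2 µm flags the record. Since any common
normalisation cancels in d_nn/d_cc, the ratio itself is the exported
statistic; d_nn and d_cc normalised by the pattern diameter are exported
alongside for transparency. Group comparison is the two-sided Mann–Whitney
rank-sum test on ratios with the percent difference of medians.

## Spheroid classification

Stacks are resampled to an approximately isotropic 0.5 µm grid (block mean
in x/y, physical units throughout, so anisotropic voxels are handled). Each
channel's smooth background — lamp tilt plus pedestal — is removed by
subtracting a plane fitted to the per-column z-minimum image, which is pure
background because every column contains planes above and below the
spheroid; the channel is then smoothed (σ = 1 voxel). The body is the
largest component of the summed channels thresholded at median + 4×MAD (a
robust noise floor; a histogram split such as Otsu can land between dim
cytoplasm and bright marker bands and cut the shell in two). Geometry is
then measured by ray casting over 500 near-uniform sphere directions from
the centre of a least-squares sphere fitted to the exterior surface — the
raw centroid of a partial shell shifts away from the missing cap and makes
the opening look smaller from inside, which the sphere fit corrects.

* **Coverage**: fraction of directions whose outermost body radius reaches
  ≥ 85% of the median outer radius. ≥ 90% counts as a complete shell,
  40–90% partial, below 40% no coherent shell.
* **Lumina**: connected background regions lying inside the body envelope
  (per-direction outer radius minus 1 µm) with volume ≥ 30 µm³. Components
  are joined across one-voxel gaps before counting so a noise tendril
  crossing a cavity cannot split it in two.
* **Orientation**: apical enrichment is compared between the cavity-facing
  boundary shell (≤ 1.2 µm from a lumen; the body core when there is none)
  and the matrix-facing shell (≤ 1.2 µm from the exterior). A polarity call
  requires *complementary* placement — apical enriched on one boundary and
  basolateral on the other (enrichment ratio ≥ 1.5 on both, with a noise
  floor from the exterior voxels) — as a human rater would demand; an
  apical-only criterion misreads patchy aggregates as inverted cysts.
* **Cell count**: maxima of the euclidean distance transform of the
  thresholded nucleus mask (euclidean non-maximum suppression, plateau
  de-duplication at 1.5 µm). Distance-transform maxima are set by blob
  geometry, so nearly-touching nuclei that merge into a single intensity
  blob still contribute two centres — the standard watershed-seeding idea.

Rules, in order: inner orientation + exactly one lumen + coverage ≥ 40% →
group 1 (complete) or 2 (partial); outer orientation + coverage ≥ 40% →
group 3 or 4; everything else → group 5. The thresholds (90/40% coverage,
1.5× enrichment, 30 µm³ lumen floor) are declared configuration of this
classifier, not claimed equivalents of any human rater's internal criteria;
the classification is deterministic given stack and configuration.

## Support computations

ΔΔCT assumes amplification efficiency 2 (no efficiency correction).
Reference level per sample = arithmetic mean of the three most stable
reference CTs (equivalently the geometric mean of their expression levels).
Stability ranks each candidate by the mean cross-sample standard deviation
of its pairwise CT differences with the other candidates (the geNorm ranking
step reduced to a single pass); the chosen subset is always reported.
Technical replicates are averaged before anything else. The computation is
invariant under per-sample plate offsets by construction. Blot
normalisation divides the target band by the geometric mean of the two
loading controls, making cross-lane ratios invariant under per-lane scaling.

## Synthetic data: what it emulates, and what it does not

The generator renders 16-bit fields at 0.1 µm/px (63×/high-NA-class
sampling): 512² px for single- and two-cell scenes — the largest pattern,
the 1600 µm² disc, spans 451 px — and 256² × 40 planes at 0.5 µm z-step for
spheroids, whose 8.5 µm outer radius fits that axial extent. These sizes
keep the full recovery sweeps (hundreds of rendered scenes) at desk-scale
runtimes. Noise is Poisson shot noise on the expected photon count plus
Gaussian read noise (σ = 3 counts) on a background of 100 counts with a
random smooth tilt (±10 counts); punctum SNR is defined against
√(background + read²). The point-spread function is a Gaussian
(σ = 0.08 µm) — sufficient to exercise threshold and centroid logic, smaller
than a real widefield PSF.

Defaults encode the study conditions: disc patterns of 700/1600 µm²,
crossbows of 1100 µm² (envelope area; the printed shape is an arc plus
stem with the arc at +y), cells of 630/690/950 µm² with circularity
0.92/0.65/0.90 respectively, 30 adhesion sites in 0.1–2 µm², nucleus-offset
centrosomes, two-cell stages with exact planted d_nn/d_cc, spheroids of
16–20 cells in five canonical phenotypes (partial shells cover 75% of the
sphere), CT tables with four reference genes of which one (B2M) can carry a
planted condition-dependent shift to exercise reference selection.

Ground truth is serialized alongside every image, and identical seeds
reproduce pixels bit-exactly.

What passing tests therefore show: the measurement chain recovers known
geometry, counts, angles, ratios and class labels from realistically noisy
renderings of the assay layouts, at the stated tolerances. What they do not
show: performance on real micrographs with textured cytoplasm, overlapping
or out-of-focus structures, photobleaching, uneven illumination beyond a
smooth tilt, segmentation-resistant cell shapes, or stain cross-talk. The
five spheroid phenotypes are idealized spherical geometries; real cysts are
lumpier and their rater-assigned classes fuzzier.

## Numerical choices and degenerate inputs

* Otsu on a constant image raises with a pointer to fixed thresholds.
* Empty ROIs, missing channels, missing calibration, non-finite CTs and
  non-positive band intensities raise immediately rather than propagating.
* A blank field yields a "no cell" outcome (logged), not a crash; a field
  with several cells yields the largest with a logged note.
* Circular means carry an explicit undefined flag when R ≈ 0.
* The common-median test returns p = 1 on a degenerate all-one-side split
  and rejects groups below n = 10.
* Spheroid bodies touching the lateral image border are flagged
  "truncated".
* All randomness flows through `numpy.random.default_rng(seed)`; no global
  state.

## Known limitations

* The edge-based cell mask assumes a single dominant cell with cytoplasmic
  signal above background; confluent fields are out of scope.
* Centrosome detection assumes diffraction-limited puncta well above
  background (mean + 5 sd); dim or clustered centrosomes beyond two puncta
  are flagged rather than resolved.
* The >2-group branch of the common-median test uses the asymptotic χ²
  reference, which is anti-conservative below ~100 observations per group.
* The spheroid classifier's thresholds were chosen for the canonical
  phenotypes; spheroids near a class boundary (e.g. 88% coverage) are
  assigned deterministically, with the evidence exported so borderline
  calls can be audited.
* As marker SNR drops towards ~5 the classifier degrades by refusing
  polarity calls (orientation "none"/"mixed") and assigning group 5, rather
  than by guessing between polarized classes; near the completeness
  boundary errors are of the 1↔2 / 3↔4 kind. Below SNR ≈ 4 it may find no
  body at all and raises instead of classifying.
* The fast rolling-ball path is an approximation; sub-pixel-accurate
  background work should use `fast=False`.
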