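# Methods

## The problem

Autologous chondrocyte implantation requires expanding a patient's
chondrocytes in monolayer culture, during which the cells progressively
dedifferentiate: they stop expressing hyaline-cartilage markers, adopt a
fibroblast-like morphology, and lose chondrogenic capacity.
Dedifferentiation is biphasic — an early, still-rescuable "plastic"
stage (glycolytic phenotype, high RBP4/SOD3) precedes a late
"dysfunctional" stage (mitochondrial damage, high IFITM3/F-actin,
enlarged cells and nuclei).  Passage number alone is a poor proxy for
where a given donor's cells sit on this axis, so `chondrostage`
formalizes an image-based staging system: quantify a six-indicator
visual panel per cell, capture it into a normalized feature matrix, and
place unknown samples against a staged P0/P2/P4/P8 reference.

## Staging model

**Panel and profile.** One sample is described by 20 detection rounds
(one randomly selected cell per round) for each of six indicators:
mean immunofluorescence gray value of RBP4, SOD3, IFITM3 and F-actin
(phalloidin), plus cell area and nucleus area in um^2.

**Normalization.** Per indicator, across all samples and rounds of the
fitted set, values are min-max mapped linearly onto integers 0..14000
(half-up rounding).  Per-indicator scope keeps indicators comparable
while preserving between-sample contrasts; a whole-matrix scope is
available behind `normalize_matrix(..., scope="global")`.  A constant
indicator maps to all zeros with a warning.  Query samples reuse the
*frozen* reference (min, max); values outside that range are clipped,
not extrapolated, because the reference range defines the model's
domain (clips are counted and logged).

**Round sorting.** Rounds are exchangeable — the 20 cells measured for
RBP4 are not the 20 cells measured for SOD3 — so each (sample,
indicator) column is sorted ascending before any distance is computed.
This turns robustness to round reordering from an empirical observation
into an exact invariant: any within-indicator permutation of rounds
yields a bit-identical staging result.

**Distance and assignment.** Each sample becomes a 120-vector (6
indicators x 20 sorted rounds, normalized).  Distances are plain
Euclidean; PCA (2 components, column-centered, deterministic sign
convention) provides the embedding for visual inspection.  A query is
assigned the stage of its nearest reference sample.  Confidence is
`d_other / (d_other + d_assigned)` with `d_other` the distance to the
nearest reference of any *other* stage: 1.0 for an exact match, 0.5 at
a tie.  Ties break toward the earlier stage (the clinically
conservative direction: an early call implies rescuable cells, and
false "late" calls would discard usable material) and are flagged
ambiguous.  A query whose nearest-reference distance exceeds 1.5x the
median reference-to-reference distance is flagged `out_of_model` rather
than force-assigned — heterogeneous low-quality samples are often far
from every reference.  The original workflow fed this matrix to a
count-model package's distance/PCA utilities whose variance-stabilizing
transforms are undefined for intensity data; plain Euclidean distance
on the normalized vectors is the well-defined equivalent, with `log1p`
available upstream if variance stabilization is wanted.

**Batch harmonization.** When batches share only the Model-P2 healthy
control, quantile normalization is not identifiable; instead a robust
affine map per batch and indicator sends the batch anchor's
(median, IQR) onto the first batch's anchor.  Zero anchor IQR degrades
to a median shift with a warning.  The map is exact (anchor distance 0)
whenever batches differ by a positive-gain affine transform.

## Image quantification

The measurement workflow replaces manual per-cell annotation with a
standard transparent recipe: Otsu thresholding, distance-transform
watershed, regionprops.  Two numerical choices matter:

* **Thresholding scale.** Per-cell intensities are right-skewed
  (log-normal-like), so Otsu on raw values can split dim cells from
  bright cells instead of background from foreground.  Thresholds are
  therefore computed on `log1p` intensities.  The threshold is
  *selected* on a lightly smoothed copy (Gaussian sigma 1 px) so that
  read-noise speckle does not form its own histogram mode, but *applied*
  to the unsmoothed pixels so mask edges are never displaced by blur.
* **Watershed seeding.** Nuclei seeds are h-maxima of the distance
  transform (prominence 2 px by default): an elongated nucleus has a
  ridge-shaped distance map and yields one seed, while genuinely
  touching nuclei yield one seed each.  Cells are partitioned from the
  phalloidin foreground by a watershed seeded at the nuclei, so each
  cell inherits its nucleus label; foreground without a nucleus is
  discarded.

Cells touching the image border are excluded by default (truncated
areas), cells whose matched nucleus is larger than the cell are
excluded, and exclusion counts are logged.  Areas are pixel counts x
pixel_size^2 (default 0.5 um/px).  `select_cells` draws the k = 20
detection rounds without replacement under a mandatory seed.

## Trajectory patterns

**QC.** Three filters in fixed order — cells expressing < 500 genes,
then genes expressed in < 10 cells, then cells with total counts
outside mean +/- 2 sd (sample sd, n-1; closed interval, so boundary
cells are retained).  The order is part of the contract: gene-first
filtering can change which cells survive.

**Dynamic-gene ranking.** Per gene, log1p expression is regressed on a
cubic B-spline basis of pseudotime (6 columns, interior knots at
quantiles) and on a constant; the Gaussian likelihood-ratio statistic
`n log(RSS0/RSS1)` is referred to chi-square with 5 df, p-values are
BH-adjusted, and genes with q < 0.01 are ranked by q then effect size,
capped at 1000.  The underlying study named neither the statistic nor
the assignment rule, so this spline-LRT is this package's explicit
formalization of the usual trajectory-tooling behavior.

**Classification.** A gene's trajectory is reduced to 10 equal-width
pseudotime bin means (log1p scale; empty bins interpolated), min-max
scaled to [0, 1].  Features: relative range R (range / magnitude of the
binned values), net change delta = last - first scaled bin, internal
extrema count E (sign alternations of 3-bin-smoothed steps larger than
0.05), and midpoint crossing time t1/2 (center of the first bin
crossing 0.5 in the direction of the net change).  Decision rule:

1. R < 0.1 -> FLAT (rejection class so background genes are never
   forced into a dynamic class);
2. E >= 2, or E >= 1 with |delta| < 0.2 -> TIDE_WAVE;
3. delta < 0: t1/2 <= 0.3 -> IMMEDIATE_DOWN, else GRADUAL_DOWN;
4. delta >= 0: t1/2 >= 0.7 -> DELAYED_UP, else GRADUAL_UP.

The tide-wave template is one full sine period, the minimal
non-monotone archetype with two internal extrema.  All thresholds live
in `QcConfig`.  The rule is invariant to positive affine rescaling of
a gene (min-max scaling happens per gene) and recovers the five
canonical templates exactly at zero noise.

## Synthetic data: what it emulates, and what it does not

The generator encodes the *ordinal* structure of the biphasic model:
RBP4/SOD3 intensity means peak at P2, IFITM3/F-actin rise strictly
P0 -> P8, and cell/nucleus diameters grow with passage.  The default
magnitudes in `data/stage_defaults.yaml` are illustrative configuration
— the underlying observations are images and ordinal contrasts, not
published per-cell numbers.  Intensities are log-normal (positive,
right-skewed, CV 0.25 by default); diameters are correlated truncated
normals (cell-nucleus correlation 0.6); cells are ellipses with aspect
ratio uniform on [1.0, a_max], a_max rising from 1.6 (P0) to 2.2 (P8)
to mimic the round-to-fibroblast-like transition.  By default each
marker's rounds come from an independent cell draw (stains on separate
coverslips); a shared-cell mode exists.  Rendered images (default
1024x1024 px at 0.5 um/px, 16 bit) add Poisson shot noise and Gaussian
read noise (sd 2); cells are placed by rejection sampling with a 2 um
clearance, and the bundled ground truth records what is actually in
the image — quantized intensities and mask-pixel areas — so the
zero-noise oracle equivalence is exact.

Not emulated: illumination gradients, point-spread blur (optional flag,
off by default), autofluorescence, segmentation-hostile cell clumping,
scRNA-seq library-size and dropout structure, and donor-to-donor
heterogeneity of real human chondrocytes.  Passing recovery tests on
these simulations therefore demonstrates correctness of the pipeline's
logic under its own model assumptions, not clinical performance on
real donor material.

## Problem sizes and determinism

The standard synthetic study uses a 4-sample reference (one per stage),
40 queries (10 per stage), 20 rounds; the pattern study uses 10 genes
per dynamic class + 950 flat genes x 300 cells at noise sd 0.2; the
imaging study uses 20-cell fields of view.  These sizes match the
original study design (20 cells per marker per batch; 1000 ranked
genes) while keeping a full evaluation run in seconds.  Every stochastic
step derives its generator from one root seed via SHA-256-hashed named
substreams (`pipeline.derive_seed`), so reports are reproducible
bit-for-bit; timestamps are deliberately excluded from report payloads.

## Known limitations

* The nearest-reference rule formalizes what was originally a visual
  PCA-proximity judgement; with one reference sample per stage the
  confidence ratio is a geometric heuristic, not a calibrated
  probability.
* Late-stage discrimination is weaker than early-stage discrimination
  in real data (heterogeneous low-quality samples); the `out_of_model`
  flag mitigates but does not resolve this.
* The 0-14000 integer normalization quantizes: values closer than
  ~(max-min)/28000 can collapse to the same integer, so order
  preservation is non-strict.
* Cell "relative viability" is accepted as an optional seventh
  indicator but excluded from the default panel, which mirrors the
  six-indicator heatmap actually used for staging.
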