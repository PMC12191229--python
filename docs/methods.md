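# Methods

`imcpheno` implements a bespoke single-cell analysis chain for imaging mass
cytometry (IMC): metal-tagged antibodies imaged by laser-ablation mass
spectrometry yield one intensity channel per marker at roughly 1 um/pixel.
The chain runs from raw multichannel images to per-cluster biology:
segmentation, quantification, normalization, phenotyping, spatial statistics,
condition contrasts, and a histological burden score. Every stage is testable
against synthetic scenes with known ground truth.

## Synthetic scenes

The generator renders discs on a background. Each cell is a disc of radius
`cell_radius_um` (default 5 um at 1 um/pixel) with a nuclear core of 0.6x the
radius and a membrane annulus covering the remainder. DNA channels and
nucleus-scored markers are painted into the core, surface markers into the
annulus. Placement is dart-throwing with a hard minimum center distance of
2x the radius (configurable), which guarantees the label grid is a valid
partition; if a cell cannot be placed within 50 retries the generator raises
and names the achieved count.

Intensities follow a cytometry-like right-skewed model: each cell draws one
multiplicative lognormal factor per expressed marker,
`level = mean * exp(sigma * Z)` with `sigma = intensity_noise_sd` (default
0.3), and every channel additionally receives an additive Gaussian background
truncated at zero (level 1.0, SD 0.3 by default). The default 23-marker panel
carries two iridium DNA channels and five populations — tumor
(Vimentin/CD44/Pan-CK/Ki67, 40%), macrophages (F4/80/CD68/CD11b, 20%),
neutrophils (S100A8/S100A9/Ly6G, 15%), T cells (CD4/CD8a/CD62L/CD127, 15%)
and B cells (B220, 10%) — with expressed-marker means of 3-8 over a
background of 1, i.e. populations separated by far more than 5 noise SDs in
log space. The default scene is 256 x 256 px with 200 cells.

What the generator does *not* emulate: real tissue texture and cell-shape
variety, channel spillover, ablation artifacts, and spatial correlation
between phenotype and position (cells are placed uniformly). Tests passing on
these scenes demonstrate the pipeline's internal correctness and parameter
recovery under its stated model, not segmentation accuracy on real tissue.

`make_cell_table` bypasses imaging and draws the same intensity model
directly as a cell table (with DNA and background included), so the
phenotyping and differential-state stages can be exercised at known truth
without segmentation error. Lesion series for the scoring stage draw a
Poisson number of lesions per section (default rate 2/section, 10 sections
per sample spaced 150 um) with lognormal diameters (log-mean ln 0.8, log-SD
0.9, spanning all four score bins); the true per-sample score is recorded
with the same bin map the scorer uses.

All generators consume a single `numpy` Generator seeded explicitly; no
global RNG state is touched, and identical specs and seeds reproduce outputs
bit-for-bit.

## Segmentation

Composite images are per-pixel sums of a compartment's channels rescaled to
[0, 1]: the nuclear composite includes the DNA channels, the combined
composite is nuclear + membrane + DNA and is the default segmentation input.

The interactive threshold step of the original ImageJ recipe is replaced by a
quantile rule for reproducibility: the threshold is the
`1 - target_fraction` quantile of composite intensities, with
`target_fraction = 0.475`, the midpoint of the 40-55% in-cell window the
workflow aims for. The achieved fraction equals the target up to ties; with
heavy ties (e.g. large exact-zero areas) it can overshoot, which the
diagnostics report. The window presumes tissue-covered ROIs; sparse scenes
need a matched target.

Seeds are h-maxima of the Gaussian-smoothed composite (sigma 1 px by
default): a maximum survives only if it rises at least `prominence` above its
surrounding saddle (default 0.10 of the unit-rescaled range), the same
semantics as an ImageJ Find Maxima noise tolerance. Smoothing is applied
because raw IMC-like pixel noise makes unsmoothed maxima detection
degenerate; both sigma and prominence are exposed rather than hard-coded
since the upstream workflow does not document them. Plateaus collapse to one
seed at the plateau centroid. Particles are then grown by seeded watershed on
the inverted smoothed composite, restricted to the in-cell mask, with
watershed-line pixels left as background (8-connected flooding), and labels
relabeled consecutively from 1.

## Quantification and normalization

Per cell and marker the quantifier sums pixel intensities over the labeled
region (total intensity, not mean), and records the area centroid in
micrometers (origin at the center of pixel (0,0), x along columns) and the
pixel area. Splitting a region splits totals exactly.

Normalization is `ln(1 + x)` followed by two z-score passes: first each
marker column is standardized across cells, then each cell row across
markers (sample SD, `ddof=1`; constant vectors map to 0 instead of dividing
by zero). The 1 + x offset handles zero totals. The pass order follows the
reading that "across cells"/"across markers" name the dimension over which
mean and SD are computed; because the opposite reading is defensible, the
order is switchable via the `order` argument and is recorded in the matrix's
provenance and in a JSON sidecar by the pipeline.

## Phenotyping

Clustering is Lloyd's K-means restarted from many random initializations
(initial centroids are k distinct cells), keeping the restart with the
smallest within-cluster sum of squares. One RNG stream drives all restarts,
so results are deterministic given the seed and the best objective is
non-increasing in the restart count. An empty cluster during iteration is
reseeded at the point farthest from its assigned centroid. The desk-scale
default is 100 restarts and k = 20; the study-scale setting of 100,000
restarts is a config choice, not a code change. The implementation is
hand-rolled because the restart/reseeding/determinism semantics are part of
the contract; scikit-learn's KMeans serves as an independent cross-check in
the test suite.

Differential markers per cluster use all one-vs-one comparisons: marker m is
significant for cluster c against cluster o when a two-sided Wilcoxon
rank-sum test gives p < alpha (default 0.05) *and* the median of m in c
exceeds that in o — "expressed in the cluster" means upregulated. m is
differential for c when at least `min_significant` of the k - 1 comparisons
are significant; the default `min_significant = k - 3` requires 17 of 19 at
k = 20. No multiplicity correction is applied inside the counting — the rule
thresholds raw per-comparison significance by design; stringency comes from
requiring near-unanimity across comparisons. At small k the default
threshold is lenient (2 of 4 at k = 5) and spurious extras can enter the
lists through the row-standardization coupling between markers; the defining
markers still rank on top. Clusters with fewer than 2 cells are skipped in
comparisons (counted non-significant) with a warning.

Clusters are named by their differential markers joined with "/", ordered by
descending significant-comparison count with ties broken by panel order; an
empty list yields the placeholder name `unnamed`. Annotation applies ordered
rules — neutrophils (any of S100A8/S100A9), macrophages (F4/80), tumor cells
(any of Vimentin/CD44) — the first matching rule wins and unmatched clusters
are `unidentified` (deliberately distinct from the naming placeholder).

## Differential state

For each (cluster, marker) pair the per-sample median of normalized
expression is computed (raw totals optional), and the two conditions are
compared by an ordinary pooled-variance two-sample t-test on those medians;
the estimate is mean(medians | condition b) - mean(medians | a). This
deliberately replaces a moderated-variance (empirical-Bayes) test: with only
3 samples per arm the plain t-test is transparent about its low power and
shares no information across pairs, and the null calibration test verifies
its type-I behavior at the nominal 5% under the generator's model.
Benjamini-Hochberg adjustment is applied jointly across all tested pairs
(statsmodels' step-up implementation, cross-checked against the definition).
Pairs where a condition contributes fewer than 2 samples with cells in the
cluster are reported untested (NaN); two literally identical condition
groups (zero difference and zero variance) get p = 1.

## Spatial statistics

Nearest-neighbor distances are Euclidean between cell centroids, in
micrometers, computed within each sample/ROI independently via a k-d tree
and verified against an exhaustive scan. Centroid (not boundary) distance is
a declared choice — the cell table is the unit of analysis downstream.  When
query and reference type coincide each cell excludes itself. The summary
reports, per sample and immune cell type (default CD8, CD4, neutrophils,
macrophages), the median distance to the nearest tumor cell; samples lacking
the reference type or the query type are omitted rather than zero-filled.

## Metastatic-burden scoring

Lesion diameters map to scores 1-4 by bins <1, 1-3, 3-5, >=5 mm. The
interior bin edges are half-open, [low, high), so a 1.0 mm lesion scores 2
and a 5.0 mm lesion scores 4. A sample's total is the plain sum of lesion
scores over all its sections (per-section subtotals are also emitted);
group-level statistics on the totals are left to generic tooling.

## Pipeline and problem sizes

`run_pipeline` executes simulate, segment, quantify, normalize, phenotype,
annotate, spatial, ds and score in fixed order, writes every intermediate in
an open format plus a manifest (parameters, seed, per-stage counts, timing),
and never mutates an upstream artifact. Per-sample seeds are spawned from
the master seed, so reruns reproduce all outputs.

Default problem sizes are chosen for interactive use: 256 x 256 px scenes
with 200 cells, 3 + 3 samples, 100 K-means restarts, 200 replicates for the
null-calibration suite. All are parameters; study-scale settings (larger
ROIs, 100,000 restarts) change only the config.

## Known limitations

- The double z-score couples markers within a cell; background markers can
  acquire apparent cluster structure from the row pass. This is a property
  of the normalization itself and is visible in the differential lists at
  lenient thresholds.
- The t-test on 3-per-arm sample medians has low power; it calibrates
  correctly under the null but misses modest effects that a moderated test
  might flag.
- Quantile thresholding meets the 40-55% window only when tissue actually
  covers a comparable share of the ROI.
- Segmentation accuracy is validated on disc-shaped synthetic cells only.
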