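# Methods

This note records the statistical model the package implements, the
choices made where the procedure was genuinely open, and what the
synthetic-data tests do and do not establish.

## Screen design and data model

The screen compares two substrate topographies (electrospun fiber vs
flat/smooth), each run as triplicate 96-well plates over two siRNA
libraries (636 kinases, 237 phosphatases; one pooled siRNA well per gene
per plate).  Each well is read on two channels: `alamar_blue` (resazurin
viability/metabolism) and `runx2` (in-cell-western intensity of the
osteogenic transcription factor RUNX2).  Every plate carries one well per
internal control: mock transfection (reagent only), scrambled siRNA,
universal cell-death siRNA, untreated cells in growth and in
mineralization media, cells with secondary antibody only, and a no-cell
background well.  Only the background well's coordinate (H12) is fixed by
the assay; the remaining controls occupy column 12 by package convention,
since all analysis keys on roles rather than coordinates.  That leaves 89
sample wells per plate; a mock well is required on every plate because the
fold-change step is anchored to mock-transfected behaviour.

## Normalization chain

Applied per channel, in fixed order; all steps use the 20% trimmed mean
`TM`(x) = mean after dropping `floor(0.2·n)` values from each tail (the
standard reading of an "X% trimmed mean"; the fraction is configurable).

1. *Background*: subtract the per-plate mean of BACKGROUND wells.
   Negative values may appear and are handled by the outlier filter.
2. *Edge correction*: factor `f = TM(interior cells) / TM(edge cells)`
   multiplies all 36 outer-ring wells.  The edge set is the outermost ring
   (rows A/H, columns 1/12) — the standard high-throughput-screening
   convention matching evaporation physics.  Because positive scaling
   commutes with trimming, edge and interior trimmed means agree to float
   precision afterwards; the correction is exact (recovers `1/f`) when a
   pure multiplicative edge attenuation is planted without noise.
3. *Plate scaling*: divide the whole plate by `TM` over wells that are not
   assay controls.  "Assay controls" are cell-death, both media controls,
   secondary-only and background wells; mock and scrambled wells behave
   like null samples and stay in the scale.  Eligible wells have trimmed
   mean exactly 1 afterwards.
4. *Fold change*: divide by the per-channel median of all normalized mock
   wells pooled across plates (both topographies — the screen-wide mock
   reference).  The median mock fold change is exactly 1 by construction.

Both channels receive the identical chain: they share the same plate
physics.  A switch to restrict edge correction to one channel is not
provided; nothing in the method depends on it.

## Gene filtering

Replicate fold changes are aggregated by the arithmetic mean (median
available by config) *before* filtering, so filters act on per-gene scores.
Within each (library, topography) stratum, in order:

1. *Outliers*: genes with negative viability score are dropped, then the
   `floor(0.10·m)` highest of the m non-negative scores (ties broken by
   descending score then ascending gene id).  The top cut is computed over
   non-negative scores only, mirroring the rationale that roughly a tenth
   of background-subtracted values fall negative and the positive tail is
   trimmed symmetrically.
2. *Viability*: surviving genes with score strictly below 0.5 are dropped;
   exactly 0.5 is retained.  The 0.5 default reflects the observed minimum
   of healthy-control distributions in this assay family.

Nothing is deleted — records carry a `filter_status` — so survivor counts
per stage remain auditable in the run log.

## Hit categorization and testing

The osteogenic score is `osteo = FC(RUNX2)/FC(AlamarBlue)`, i.e. RUNX2
signal per unit of viable cell mass, computed per gene and also per
replicate (for testing).  Scores are partitioned around the
scrambled-relative reference 1.0:

* positive tail = scores > 1; its top `floor(0.4·n)` by count → **UR**;
* lower tail = scores < 1; its bottom `floor(0.4·n)` by count → **DR**;
* everything else → **NC**.

The by-count reading makes the partition exhaustive and reference-anchored;
it also means the UR/DR sets are at most 40% of their tails, so when planted
effects are recovered the criterion is "categorized genes carry the planted
effect", not "all planted genes are categorized".  Partitions are computed
per library and topography, then intersected across topographies per
category (the Venn decomposition reported by `venn_summary`).

Genes categorized identically on both substrates are tested for a
fiber-vs-smooth difference on their replicate osteo scores with a pooled-
variance two-sample t statistic whose null distribution comes from label
permutations: `p* = (1/B)·#{b : |t(b)| ≥ |t|}`, ties counted as extreme.
With 3+3 replicates the assignment space has C(6,3) = 20 elements and is
enumerated exhaustively (auto-selected whenever the space is ≤ 10,000);
otherwise B = 1000 uniform relabelings are drawn with replacement.
Consequences, documented and tested:

* the smallest attainable exhaustive two-sided p is 2/20 = 0.1 — the
  test can never reject at α = 0.05 in exhaustive mode;
* in Monte-Carlo mode p = 0 is possible and is stored as 0 (no add-one
  correction), matching the estimator's literal definition.

Bonferroni correction is applied within each intersection group
(m = group size).  The default significance flag for downstream exports is
Bonferroni-adjusted p < 0.05 (α is a convention here, not a fitted value).

Because intersection membership conditions on cross-topography agreement,
p-values *restricted to intersection groups* are conservative under the
null (measured rejection ≈ 0.007 at α = 0.1).  For calibration studies the
model exposes `test_scope="all"`, testing every QC-passing gene; there the
type-I error at α = 0.1 is ≈ 0.07–0.10 across seeds, consistent with the
0.1 granularity of the exhaustive test.

Secondary-screen candidates are the most extreme `max(1, floor(0.10·n))`
genes per category (UR: highest scores; DR: lowest; NC: closest to 1).
The enrichment export assigns pseudo fold changes +2 (UR), −2 (DR), 1 (NC)
and pseudo p-values 10⁻⁵ (significant) or 1, the input format expected by
pathway-comparison tools; NC's neutral 1 is a package choice.

## Morphometrics

Masks are binary, 0-based (row, col), one 8-connected component, ≥ 4 px.
Measures: area = pixel count · px²; ellipse-equivalent major/minor axes
from second central moments; axis-aligned bounding box.  Perimeter is the
polyline length of the 0.5-level marching-squares contour simplified with
Douglas–Peucker tolerance 1 px.  This estimator was chosen after measuring
the alternatives on reference shapes: raw chain-code lengths (steps 1/√2)
overestimate a digitized r = 50 disk's circumference by ≈ 5.8% (form
factor 0.89), and Crofton 4-direction perimeters underestimate axis-aligned
squares (form factor 0.88 vs π/4); the simplified-contour estimator gives
0.990 for the disk and 0.801 for the square, inside ±0.05 of the closed
forms.  It underestimates perimeters of deeply concave few-pixel shapes
(simplification cuts narrow notches) — acceptable at cell scale, and the
tolerance is configurable.

Compactness follows the screen's literal definition — population variance
of boundary radii divided by area — with boundary = mask pixels having a
non-mask 4-neighbour and radii from the area centroid to pixel centers.
Note this differs from CellProfiler's current compactness definition, and
it is *not* scale-invariant: the radius variance of a digitized boundary
has a discretization floor of ~0.08 px² regardless of size, so
compactness ≈ 0.08/area for smooth shapes (≈ 1.1 × 10⁻⁵ for an r = 50
disk, shrinking only as 1/r²).  An idealized circle has compactness 0; a
rasterized one cannot go below this floor, which the test suite records.

Group comparisons: one-way ANOVA pooled error, then Fisher's LSD pairwise
t with N−k degrees of freedom ("ANOVA with a Fisher's test" in the
morphometry literature).  The LSD tests are not protected by a prior F
threshold; with exactly two groups LSD coincides with the classical pooled
two-sample t-test (verified to 10⁻⁹).  A comparison is classified up/down
only when p < α (default 0.05); otherwise none.  The standard comparison
plan holds the three contrasts of the secondary screen per siRNA: treated
fibers vs treated flat, untreated fibers vs untreated flat, and treated vs
untreated on flat.

## Synthetic data

The generator emulates the study conditions: 636 + 237 genes, triplicate
plates per topography, control pattern as above, multiplicative edge
attenuation (default 0.8), lognormal plate drift (SD 0.1), additive
background (50 units against channel bases of 1000/600), lognormal
per-well noise with CV 0.1, and planted per-gene effects — 8% of genes
upregulate RUNX2 ×2, 8% downregulate ×0.5, 5% are lethal (viability ×0.2),
and 5% carry a ×1.5 fiber-specific differential.  The RUNX2 signal of a
well scales with both the planted RUNX2 effect and the viability effect
(fewer cells → less total signal), which is what the osteo-score ratio is
designed to cancel.  Fractions and effect sizes are package choices
representative of kinome screens; library sizes, replicate count, the 0.5
threshold, the trimmed-mean fraction and tail fractions are the published
analysis constants.  Noise is multiplicative lognormal because plate
fluorescence is strictly positive and right-skewed; negatives then arise
only from background subtraction.  Unused sample wells are modeled as
untransfected cells (cells are seeded plate-wide before transfection), so
partially filled plates keep well-behaved trimmed means.

What the generator does *not* emulate: spatial noise structure beyond the
edge ring (no gradients or corner effects), siRNA off-target effects,
well-to-well cross-contamination, or the image-level properties of the
in-cell-western readout.  Passing recovery tests therefore demonstrates
correctness of the statistical chain under its own assumptions, not
robustness to those real-data pathologies; a B-score/median-polish spatial
normalization is deliberately out of scope.

Cell masks are generated as rasterized disks, ellipses, rectangles and
stars with lognormal size jitter and, for stars, random orientation, each
paired with closed-form area/perimeter/extent/form-factor expectations
(Ramanujan's approximation for ellipse perimeters).  Shapes with minimum
radius under 3 px are rejected as unreliable to rasterize.  Group sizes in
morphology fixtures are drawn in the 5–26 cells-per-group range typical of
this assay.

## Numerical conventions

* Trimmed mean: `floor(trim·n)` removed per tail; rejects empty input or
  full trimming.
* All tie-breaks (outlier top cut, partition cuts, candidate ranking) fall
  back to gene id, making every stage order-independent and deterministic.
* Permutation tie counting uses |t(b)| ≥ |t_obs| − 10⁻¹², so the original
  labeling always counts even across vectorized/scalar float paths.
* Degenerate permutation inputs (all six values identical) are rejected;
  zero pooled variance inside a relabeling yields t = ±∞ (counted extreme)
  or 0 when means also agree.
* Every stochastic component is a pure function of (config, seed); model
  seeds fan out per gene via `SeedSequence` spawning.

## Problem sizes used in validation

Unit and acceptance tests run the full pipeline at the study scale
(873 genes × 2 topographies × 3 replicates, 66 plates) for recovery
checks — ≥ 80% of planted UR/DR genes recover their category and ≥ 95% of
lethal genes are removed, averaged over 5 seeds — and a 2000-gene null
screen for type-I-error calibration; both complete in seconds.  Smaller
fixtures (80–160 genes) exercise exactness properties, including the
noise-free screen whose fold changes reproduce planted effects to 10⁻⁹.
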