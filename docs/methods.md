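# Methods

This note documents the models, conventions and design choices behind
`dhiregio`: what each stage computes, which parameters matter, what the
synthetic-data generator does and does not emulate, and where the design was
genuinely open.

## Dynamic Habitat Indices

A phenology stack holds fPAR observations indexed by (pixel, step, year)
with a parallel integer quality (QA) array. Compositing and index
computation follow two rules:

1. **QA screening** is a strict pass rule `qa < qa_threshold`
   (default 83). An observation at exactly the threshold is rejected.
2. **Compositing** takes, per step, the median across years of the passing
   observations; with an even count, the midpoint of the two central values.
   Steps with zero passing observations are invalid.

From the composite curve over its valid steps:

- `DHI_cum` — plain sum of the composite values (step-sum units; no ×8-day
  rescaling — any integral convention is a monotone transform of this sum);
- `DHI_min` — minimum composite value (fPAR units);
- `DHI_var` — coefficient of variation, sample (n−1) standard deviation
  divided by the mean (dimensionless). CV is the convention of the DHI
  literature; the variation index has also been defined elsewhere as a raw
  sd or range, so the choice is documented here and `DHI_var`'s semantics
  should not be compared across toolchains without checking.

A pixel is invalid when it has fewer than `min_valid_steps` valid steps
(default 23, half the 46-step year; the threshold is a convention, chosen
because "insufficient observations" has no canonical cutoff) or a zero curve
mean (CV undefined; such pixels are also excluded downstream as
zero-cumulative). The sample (n−1) standard deviation is used everywhere so
that test oracles match exactly.

## Feature construction and two-stage clustering

Features per valid pixel: `DHI_cum`, `DHI_min`, `DHI_var`, and absolute
latitude in degrees from the equator (a proxy for the global temperature
gradient; the absolute value makes the northern and southern mid-latitudes
comparable). Pixels with zero cumulative fPAR are masked. Outliers are
winsorised per column at the (q, 1−q) quantiles (default q = 0.001) rather
than deleted — clipping keeps every retained pixel labelled, whereas row
deletion would punch holes in the output map. Columns are then z-scored
(sample sd), and the scaling parameters are stored for reproducibility.

**Stage one** is a *one-pass* k-means++: D² seeding (delegated to
scikit-learn's `kmeans_plusplus`), then exactly one nearest-centroid
assignment sweep and one centroid update. "One-pass" is taken literally — it
is a vector-quantisation step, not an optimisation run — because stage two,
not k-means, decides the final partition; Lloyd-to-convergence is available
behind `full=True`. Assignment ties break to the lowest centroid index;
empty pre-clusters are dropped with a warning. The default pre-cluster count
is 867.

**Stage two** agglomerates pre-cluster centroids with Ward's
minimum-variance linkage on Euclidean distances. By default each centroid
counts as one observation, treating pre-clusters as exchangeable summaries;
a size-weighted mode carries pixel counts through Lance–Williams updates so
populous pre-clusters resist merging (merge cost
`2 w_A w_B/(w_A+w_B) · ||c_A − c_B||²`).

**Cutting.** The static cut slices the merge sequence into exactly k groups.
The dynamic cut is a hybrid branch-pruning procedure: candidate cut heights
are placed at midpoints between the top merge heights, branches smaller than
a minimum size are merged into the branch they join lowest in the tree, and
(height, minimum-size) pairs are searched until the cluster count equals the
target, falling back to the static cut with a warning. The exact parameters
that a published dynamic-tree-cut run used are generally not recoverable, so
the search contract — "reach the requested k, prefer pruned solutions" — is
this package's own construction.

**Label raster.** Pixel labels compose pixel → pre-cluster → cluster;
clusters are renumbered 1..k by descending pixel count so outputs are stable
and comparable across runs; masked pixels are 0.

**Sieve.** Connected components (8-connectivity by default; 4 available)
smaller than `min_pixels` (default 20 — the "minimum map unit" expressed in
pixels; strictly *fewer than*, so a 20-pixel patch survives) are dissolved
into the modal label of their border neighbours, ties to the lower label id,
smallest components first, iterating to a fixed point. Masked pixels are
never reassigned and never absorb labels; a small component entirely
enclosed by mask has no labelled neighbours and is left alone.

**Validity metrics** along static cuts: mean centroid silhouette (optionally
size-weighted), total within-cluster sum of squares of the centroids, and
the between/within mean-distance ratio.

The `DhiRegionalization` model class packages these stages behind a
statsmodels-style `fit()` → results interface because the regionalisation
*is* a model fitted to the pixel cloud: the results object carries the label
raster together with everything needed to reproduce or diagnose it
(centroids, dendrogram, mapping, provenance, validity curves) plus the
evaluation methods below.

## Evaluation statistics

**Homogeneity.** Three scale-free dispersion measures per region, averaged
(unweighted) across regions:

- CV = sample sd / mean. (Sources occasionally print this ratio inverted;
  the conventional definition is used here — an inverted ratio would rank
  *heterogeneous* regions as homogeneous.)
- IQR-CV = (Q3 − Q1)/median with linear-interpolation ("type 7") quantiles.
- L-CV = l₂/l₁ from probability-weighted moments on the sorted sample:
  b₀ = mean, b₁ = Σ (i−1)/(n−1)·x₍ᵢ₎/n, l₁ = b₀, l₂ = 2b₁ − b₀. The PWM
  estimator is identical (to rounding) to the U-statistic form
  l₂ = mean pairwise |difference|/2, which the tests verify.

Regions with too few values or an undefined ratio (zero mean/median) are
skipped and logged. The across-region mean is unweighted; an area-weighted
mean is a defensible alternative but changes the statistic's meaning from
"typical region" to "typical pixel".

**Games-Howell.** For each pair (i, j): Welch standard error
√(s²ᵢ/nᵢ + s²ⱼ/nⱼ), Welch–Satterthwaite df, studentized-range statistic
q = |Δ|√2/SE, p from the studentized-range distribution with k = number of
groups. With `on_ranks=True` (default) all values are first replaced by
global midranks — the "nonparametric" variant; the raw-value mode is also
available, and neither is claimed to be the only reading of a
loosely-specified "nonparametric Games-Howell". With k = 2 the procedure is
exactly the two-sided Welch t-test (q = √2|t|), a property used as a test
oracle. Degenerate pairs (both variances zero) record p = 1 for equal means,
p = 0 otherwise.

**Discriminant power.** Per repetition (default 500): draw n = 100 values
per region without replacement, run Games-Howell over all regions, record
the proportion of significant pairs at α = 0.05. Regions smaller than n are
sampled with replacement (keeping region sets comparable across
regionalisations) rather than excluded; both behaviours are selectable.
Note a calibration consequence of the familywise construction: under a
common null distribution the *mean proportion* of significant pairs is well
below α for k > 2 (≈ 0.012 at k = 4, since a pair needs
|t| > q₍α,k,df₎/√2), while the probability that at least one pair is
significant stays ≈ α. The tests document both behaviours.

**Overlap tables.** Percent-of-region-area cross-tabulations in both
normalisations over jointly labelled pixels, with cos-latitude per-pixel
area weights (equal-angle cells shrink poleward). A display threshold
(default 10%) blanks small entries at render time only.

**Cluster summaries.** Percentile rankings bin each cluster's mean into
seven ranges (<10, 10–25, 25–40, 40–60, 60–75, 75–90, >90) using midrank
percentiles (r − 0.5)/n, so ties land in the 40–60 median band. The combined
DHI score is z(cum) + z(min) − z(var) across clusters, zero-spread
components contributing 0.

## The synthetic world

The generator produces worlds with the statistical structure the pipeline
assumes, plus the ground truth needed for parameter-recovery tests. Defaults
(64×128 grid over ±60° latitude, 6 archetypes, 46 steps × 12 years,
observation noise sd 0.03, QA dropout 0.1, 3000 species, energy coupling 1,
comparator perturbation 0.3) are the package's standard study conditions.

- **Archetypes** are sinusoid families
  `f(t) = b + a·sin(2πt/T + φ)`: baselines descend linearly from 0.85
  (tropics-like constant-high) to 0.15 (desert-like constant-low) while
  amplitudes peak mid-gradient (boreal-like strong seasonality), kept inside
  [0, 1] so noiseless templates never clip. Distinct baselines make the
  archetypes pairwise distinct in DHI space by construction. A sinusoid is
  deliberately simpler than a double-logistic green-up model; for testing a
  productivity/seasonality gradient, controllable cumulative/minimum/
  variation is all that matters.
- **The truth map** is latitude bands (one per archetype) with smooth
  sinusoidal boundary wiggle — latitude is informative but bands are not
  trivial stripes.
- **Observations** are template + Gaussian noise clipped to [0, 1]; QA
  integers are drawn < 83 for passing observations and ≥ 83 with the
  dropout probability, so the DHI QA filter is exercised with the real
  threshold semantics.
- **Species ranges** are disks whose centres are drawn with probability
  ∝ (1 − c) + c·P/mean(P), where P is cumulative template productivity and
  c the energy coupling (c = 0 ⇒ uniform). Radii are lognormal (many small
  ranges, few large), and centres may fall up to one radius beyond the
  top/bottom window edge with edge-replicated weights, so the window behaves
  like a cut from a larger stationary world and edge bands are not
  artificially species-poor. The species count (1000 per taxon across three
  taxa) puts overall richness in the hundreds per cell — the magnitude real
  range stacks produce, and necessary for ratio-to-median dispersion
  measures to be stable. No global range-construction model exists to copy;
  this coupling model is an assumption and is labelled as such.
- **Canopy height** is affine in cumulative template productivity minus
  seasonality plus Gaussian noise, clipped at 0 — a qualitative
  productivity–structure gradient; the coefficients are generator
  configuration, not ecological claims.
- **The comparator** degrades the truth map by reassigning 3×3 blocks along
  the (evolving) region boundaries to a neighbouring label until roughly the
  requested fraction of pixels disagree — a stand-in for an independently
  drawn conventional regionalisation that is broadly right but imprecise at
  boundaries.

**What passing tests do and do not show.** The generator reproduces the
*statistical* structure the method assumes — archetype-driven phenology,
energy-coupled richness, productivity-driven height — not real geography:
no projection or real MODIS tile geometry, no spatially correlated noise or
cloud seasons, no range-shape realism beyond disks, no land/ocean mask.
Recovery of synthetic archetypes therefore validates the machinery
(features, clustering, cuts, sieve, statistics), not the ecological claim
that real DHI clusters out-perform conventional biomes; that claim is only
*directionally* reproduced here, on worlds where it is true by construction.

## Problem sizes and numerical conventions

Default test and acceptance runs use 64×128 to 128×256 grids, 150–200
pre-clusters and 5 seeds — sizes chosen so the full study re-runs in
minutes on one core while keeping every stage's behaviour observable.
Further conventions: quantiles are linear-interpolation throughout;
weighted-Ward heights are made exactly monotone against floating-point
jitter; k-means++ and all resampling derive from explicit integer seeds, and
every public entry point is deterministic given (configuration, seed);
rasters are exchanged as ESRI ASCII grids and ranges as GeoJSON — plain-text
formats that round-trip exactly and need no GIS stack; richness
rasterization uses exact polygon–cell-rectangle intersection tests (the
any-part rule), not centre-point or all-touched approximations.

## Known limitations

- The sieve's modal-neighbour dissolution is order-dependent in principle;
  processing smallest-first with lower-label tie-breaks makes it
  deterministic, but other orderings could yield slightly different fixed
  points.
- The dynamic cut's parameter search targets an exact cluster count; when
  the dendrogram cannot produce it (rare, e.g. tied heights), the static
  cut is used and a warning raised.
- Discriminant power compares regionalisations fairly only when both are
  evaluated with the same group count k, since the Games-Howell reference
  distribution depends on k.
- The synthetic comparator is a perturbation of the truth, not an
  independent map; overlap tables against it are structurally diagonal.
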