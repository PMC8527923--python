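# Methods

## Scope and model

`immunotme` quantifies the tumor immune microenvironment from two data
families: multiplexed marker-intensity images (with derived single-cell
tables) and sequence-derived summaries (mutation catalogs, TCR repertoires,
expression matrices). The target contrast throughout is a two-group patient
comparison — durable benefit (DB) vs no durable benefit (nDB) from anti-PD1
therapy — built up as region-level measurements → per-patient means →
two-sided Wilcoxon rank-sum with Benjamini–Hochberg correction over an
explicitly declared family of tests.

## Pixel analysis

A marker mask is the set of pixels with intensity at or above a threshold.
All threshold comparisons in the package are **inclusive (≥)**: a cell or
pixel exactly at a gate is positive, which matches the naming convention
"CD74+" for cells selected *at* the gate. Masks carry a provenance string
(the boolean expression that produced them) and combine with AND/OR/NOT.
The positive area statistic is |numerator ∩ denominator| / |denominator|;
an empty denominator is an error, never a silent zero, because zero would
bias cohort averages where the normalization is actually undefined.

Compartments: the tissue mask is the union of all channels above a low
floor (default 0.01) after morphological closing; the tumor mask is the
union of tumor-associated marker masks (E-cadherin, pan-keratin; default
pixel threshold 0.2) closed with a configurable radius (default 3 px) and
restricted to tissue; stroma is tissue minus tumor, so the two partition
the tissue exactly. Despeckling (removal of connected components below
`min_object_px`, 8-connectivity) is available but off at the function level
(`min_object_px=0`); the pipeline configuration defaults to 4 px. The
instrument-independent definition of "tissue" is necessarily a dialect
choice; both knobs are exposed in `PipelineConfig`.

## Single-cell phenotyping

Raw per-cell mean intensities are normalized per marker: values are clipped
at the 99.9th percentile and min–max scaled to [0, 1]. The percentile is
taken as an order statistic (`numpy` interpolation `"higher"`), which makes
the transform exactly idempotent and keeps the scaling constants actual
data values. Per-marker (rather than global) scaling is used because the
fixed gates (0.05–0.35) are only meaningful on per-marker comparable
scales. Constant markers normalize to zero with a logged warning.

Cell identity is assigned by **highest mask overlap**: each segmented cell
takes the lineage whose marker mask covers the largest fraction of its
pixels; zero overlap everywhere yields "other"; exact ties are broken by a
fixed priority order (T_cell > macrophage > B_cell > dendritic > neutrophil
> tumor), a deterministic convention the overlap rule itself does not fix.

Gates are (parent, marker, threshold) triples applied in order, so gates
chain (CD8 T cell → CD8+GzB+ → CD8+GzB+PD1+). The shipped defaults are the
published gates: CD74 ≥ 0.1 on all macrophages (0.35 for the deep
phenotyping panel on CD68+ cells), GzB ≥ 0.05 and Ki67 ≥ 0.15 on CD8 T
cells. Population proportions return *missing* (None), not zero, for an
empty denominator so cohort statistics can exclude the region.

## Spatial statistics

Distances are centroid-to-centroid Euclidean distances in μm within one
region. Nearest-neighbour queries exclude self-matches by cell id.
Distance histograms use half-open bins [k·1.1, (k+1)·1.1) μm; a distance
exactly at an edge falls in the upper bin. The smoothed density curve is a
Gaussian KDE with bandwidth equal to the bin width — a documented choice;
the median is reported alongside.

Density clusters use DBSCAN implemented from first principles: core points
have ≥ `min_pts` neighbours within `eps` (counting themselves), clusters
are connected components of core points, and border points join the
cluster of their lowest-cell-id core neighbour (a deterministic tie-break
absent from the algorithm's definition; it makes the partition invariant
to input order). The published criterion is a density (≥5 cells/10,000
μm²), not DBSCAN parameters; the defaults map the criterion to
eps = √(10,000/π) ≈ 56.42 μm (the radius of a 10,000-μm² disc) and
min_pts = 5, so a core point realizes the stated density, and every
cluster is additionally annotated with its convex-hull density and a
`high_density` flag. Degenerate hulls (<3 distinct or collinear points)
are treated as infinitely dense. The implementation is tested for exact
agreement (core sets, partitions up to relabeling) with an exhaustive
O(n²) region-query oracle.

Proximity contrasts compare nearest-target distance distributions of
flag-positive vs remaining cells by two-sided Wilcoxon; the effect
direction is the difference of medians (negative = attraction). Both
query-splitting (default) and target-splitting modes exist because the
published phrasing is ambiguous about which side "the rest of the cells"
refers to. "Normalized" cell abundance defaults to the proportion of total
cells per region; the high/low-infiltration ratio pools counts over regions
within each stratum before dividing.

## Immunogenomics

TMB is mutations per callable megabase; every cataloged mutation counts
(the catalog is the exonic/splicing call set), and the callable size in Mb
is a required configuration input. Hypermutation is declared at TMB ≥ 12
inclusive: a burden *below* 12/Mb marks the non-hypermutated group. The
neoantigenic index is immunogenic/nonsilent; immunogenicity is an input
flag from upstream neoantigen prediction.

Mutation clonality uses the standard closed-form CCF estimator
`CCF = VAF · (p·CNt + (1−p)·2) / (p·m)` capped at 1, with p the tumor
purity, CNt the local total tumor copy number and m the mutation
multiplicity (default 1). A Clopper–Pearson 95% CI on the VAF is pushed
through the same transform; a mutation is clonal when the point estimate
reaches 0.8 (configurable) or the CI upper bound reaches 1. This
transparent rule deliberately replaces Dirichlet-process clustering, which
is used upstream only to label mutations clonal/subclonal; the closed form
is testable and recovers planted clonal fractions within binomial error at
depth 500. Regions with purity ≤ 0.3 are excluded from clonality analysis
(the VAF→CCF mapping is unreliable at low purity).

Productive TCR clonality is 1 − H/ln R over productive clonotypes with
positive template counts, H the Shannon entropy (natural log) of clonotype
frequencies and R their number; a monoclonal repertoire is 1 by convention,
and the value is base-invariant because H and log R share a base.

## Statistics

Wilcoxon rank-sum uses the exact null distribution when the pooled sample
size is ≤ 12 and tie-free, otherwise the normal approximation with
mid-rank tie correction and continuity correction (the switch point is
configurable). BH-FDR takes a **declared family size** m that may exceed
the number of p-values computed here, because several published families
(e.g. 9 phenotype clusters, 14 deep-panel markers) are larger than the
subset re-tested in any one analysis; q = min over j ≥ i of m·p(j)/j,
capped at 1. Pearson p-values come from the t transform with n−2 df.

ssGSEA ranks genes per sample in descending expression (ties broken by
gene name for determinism) and accumulates the difference between the
weighted in-set ECDF (weights rank^α, α = 0.25, rank counted from the
bottom) and the unweighted out-of-set ECDF. NES rescales ES by the
across-sample range (max − min), the common single-sample convention; with
one sample NES is undefined (NaN). Because only ranks enter, scores are
invariant under strictly monotone per-sample transforms; the
implementation is pinned to an independently coded direct summation to
1e-10.

## Synthetic data

The generator emulates one imaging "region" as a multi-channel raster in
which each cell is a constant-radius disk (default 4 μm — the simplest
shape that exercises overlap-based identity assignment) with per-population
marker intensities (truncated normal on [0, 1]; markers not in a
population's signature draw from a low baseline with small dispersion), on
additive half-normal background noise (sd 0.02). Placement is uniform,
clustered (uniform in a disc of given radius around each cluster seed), or
satellite (folded-normal distance from a random parent cell — positive
distances with a controllable mean). Collisions are resolved by rejection
sampling with a 10× oversampling cap; shortfalls are logged, never silent,
and infeasible requests (cells per cluster beyond a packing bound) raise.
Population counts are deterministic (`round(abundance × area)`), so planted
proportions are exact up to gating noise.

The default scenario is a 600 × 600 μm region at 1 μm/px, a half-plane
tumor/stroma split, 400 tumor cells/mm² (half B2M+), 250 macrophages/mm²
of which 40% are CD74+ and half of those sit in 3 clusters of ~40 μm
radius (cluster macrophages are PDL1+), 200 CD8 T cells/mm² with 30% GzB+
and 25% Ki67+, and 30% of GzB+ cells PD1+, placed as satellites of the
macrophage clusters at a configurable mean distance (default 20 μm). Cohort
generation plants group effects as base ± Δ/2 on named scenario parameters,
so an effect size is exactly a DB − nDB difference of means. Cohorts are
generated as cell tables by default; raster rendering is opt-in (the
imaging stages are exercised on single rendered regions, and rendering
~1,800 rasters for cohort-level statistics would add nothing to the
statistical claim).

What the generator does **not** emulate: real segmentation errors, marker
spillover/compensation, spatially varying background, cell-size and shape
variation, and biological correlation structure between markers beyond the
planted signatures. Passing tests therefore demonstrate that the analysis
recovers what it claims to measure under controlled conditions, not that
real-data preprocessing is solved (segmentation masks are an input).

All randomness flows from a single integer seed through
`numpy.random.SeedSequence` spawning: placement, intensities, and
background use independent child streams, and identical seeds reproduce
bit-identical outputs.

## Problem sizes and numerical choices

Validation runs use sizes chosen to make the statistical criteria
informative at interactive cost: oracle equivalence on 100 random
200-point fixtures; parameter recovery at n = 1,000 mutations (binomial
error), 200 immunogenic mutations at depth 500, ~500 satellites and ~500
macrophages; cohort discrimination on 50 simulated cohorts of 6 + 6
patients × 3 regions (and 50 null cohorts). Fold changes use a 1e-6
denominator floor; clonality is clamped to [0, 1] against floating-point
drift; empty inputs raise or return missing per the contracts above,
never a silent default.

## Known limitations

* Segmentation is out of scope; label masks and per-cell tables are inputs.
* The CCF estimator assumes an accurate local copy number and multiplicity;
  no subclonal deconvolution or phylogeny is attempted.
* The density-cluster criterion is evaluated on convex-hull area, which is
  conservative for strongly non-convex clusters.
* The ssGSEA normalization convention varies across published pipelines;
  the across-sample range convention used here is documented and pinned by
  an oracle, but absolute NES values are not comparable across conventions.
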