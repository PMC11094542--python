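# Methods

This note documents the models, numerical choices and known limitations of
`crust_assembly`. Statements about behaviour refer to what the test suite and
`scripts/acceptance.py` actually compute.

## Eco-enzymatic stoichiometry

Activities are combined into log-ratios
ln(BG)/ln(LAP+NAG), ln(BG)/ln(AP) and ln(LAP+NAG)/ln(AP); each ln argument
must be strictly positive and an activity of exactly 1 makes a denominator
zero, which is rejected as undefined rather than returned as infinity. The
identity cn = cp/np holds whenever all three are defined and is property-
tested.

The vector summary uses X = (BG+CB)/(BG+CB+AP) and
Y = (BG+CB)/(BG+CB+NAG+LAP). The angle is the polar angle of the point
(X, Y) measured from the positive x-axis — the spreadsheet `ATAN2(X, Y)`
convention, i.e. arctan(Y/X) in degrees. Written out, angle > 45° ⇔ Y > X ⇔
AP > NAG+LAP: proportionally more P-enzyme investment reads as P limitation,
which is the directional behaviour the angle classifier tests enforce
(monotone increasing in AP, decreasing in NAG+LAP). Both ratios and vector
are invariant to rescaling all activities by a common factor.

Two classifiers ship. The vector call compares the angle to 45° with a
configurable tolerance band (default 0: any deviation is a call). The
quadrant call places ((LAP+NAG)/AP, BG/(LAP+NAG)) against the 1:1 reference
lines, with values exactly 1.0 assigned to the non-C-limited side. The two
classifiers encode *different published conventions* and need not agree on
the same sample; the package reports both rather than reconciling them.

Z-scores use the population standard deviation (divide by n); a `ddof`
argument switches to the sample convention. Constant vectors are an error.

## Abundant/rare structure

The taxon partition compares each taxon's mean relative abundance across all
samples with strict cutoffs: > 1% abundant, < 0.1% rare; the band in between
— including the cutoff values themselves — is an explicit intermediate class
so the partition is total. Relative abundances are always computed from
whole-community per-sample totals before any subsetting.

The copiotroph:oligotroph ratio sums relative abundances over phyla mapped to
each strategy; the default map (Proteobacteria, Bacteroidota, Firmicutes,
Actinobacteriota, Gemmatimonadota → copiotroph; Acidobacteriota, Chloroflexi,
Verrucomicrobiota, Planctomycetota, Nitrospirota → oligotroph) is an
editable stand-in for a literature-derived annotation, not a reproduction of
any published list; users can replace it entirely via a two-column TSV.
Unlisted phyla are excluded from both sums, and a zero oligotroph sum yields
a missing value.

PERMANOVA uses the distance-based sums of squares
(SS_T = Σ_{i<j} d²/n, SS_W accumulated within groups), pseudo-F with (a−1,
n−a) degrees of freedom, and the add-one permutation p-estimator so p ≥
1/(n_perm+1). The statistic matches scikit-bio's implementation to 1e-9 in a
cross-check test; type-I error at α = 0.05 is verified to sit in [0.03,
0.07] over 500 exchangeable simulations. PCoA is classical scaling of the
Gower-centred −½D² matrix; negative eigenvalues are dropped from both axes
and the variance-explained denominator, and axis signs are arbitrary.

## Assembly partitioning

βMNTD is the abundance-weighted mean distance from each taxon to its nearest
relative in the partner community, averaged over both directions; shared
taxa contribute zero. An incidence-weighted form is available by flag. The
implementation is verified against an independent brute-force double loop on
all nonempty community pairs over three fixed six-tip trees to 1e-12.

βNTI standardizes observed βMNTD against a null that permutes taxon
identities across the tips of the patristic distance matrix; one permutation
per replicate is shared by all sample pairs. The null *pool* is every taxon
of the supplied table — including taxa with zero counts everywhere, which
represent the regional pool. A `null_scope="union"` option restricts the
shuffle to each pair's own taxa; note that under strong selection the union
collapses onto the favoured clades and the union-scope null loses nearly all
power to detect homogeneous selection, which is why pool scope is the
default. Pairs whose null distribution has zero spread (e.g. star
phylogenies, where the statistic is shuffle-invariant) are reported as
undefined, never as 0.

RC_bray rebuilds each community n_null times preserving its observed
richness and total count: membership is drawn without replacement weighted
by occupancy (fraction of samples occupied), each member gets one count, and
the remainder is distributed multinomially by metacommunity relative
abundance over the drawn members. RC = 2·[(#{null<obs} + ½#{null=obs})/n_null
− ½] ∈ [−1, 1]. Bray–Curtis is computed on the count vectors as drawn.

Process calls use strict inequalities at the published thresholds: βNTI
exactly ±2 and RC exactly ±0.95 fall in the inner (non-selection,
non-dispersal) bands. All randomness is seeded; n_null defaults to 999.

Abundant/rare subsets are analysed on the partitioned sub-tables (the
patristic matrix restricted accordingly); samples that lose all taxa in a
subset are dropped from that subset's analysis.

Mantel tests correlate upper triangles (Pearson or Spearman), permuting
rows/columns of the environmental matrix jointly, one-sided (greater),
add-one p. Per-variable environmental distances are absolute differences.

## Co-occurrence networks

Correlations are Pearson on ln(count+1); the pseudo-count is configurable.
Taxa constant after the transform are excluded up front. No p-value/FDR edge
filter is applied by default — edge significance is handled entirely by the
RMT threshold.

The RMT scan thresholds the correlation matrix over a grid (0.30–0.90, step
0.01), drops rows with no off-diagonal entries, and tests the nearest-
neighbour spacing distribution (NNSD) of the eigenvalues against the Poisson
form e^(−s): eigenvalues are unfolded with a cubic smoothing spline through
the cumulative spectral density over unique eigenvalues, spacings normalized
to unit mean, and a χ² goodness-of-fit computed on bins of width 0.1 up to
s = 3 (plus tail), pooled to expected counts ≥ 5. The smallest threshold
with p > 0.05 is returned. The unfolding machinery is validated directly:
dense GOE matrices are rejected (p ≈ 1e-14) and i.i.d. (Poisson) spectra are
accepted. Degenerate spectra (identity-like matrices, too few distinct
eigenvalues, too few spacings) are skipped, and an error advising a wider
grid is raised if no threshold qualifies. Because a *sparsely* thresholded
pure-noise matrix genuinely has Poisson-like local spectral statistics, the
method's noise-stripping behaviour is statistically reliable only with
enough taxa (the implementation requires ≥ 30; the noise-stripping property
test uses 200).

Topology: average degree 2E/N; mean local clustering with degree-<2 nodes
counting 0; diameter and average path length on the largest connected
component; modularity is Newman Q of the partition found by a deterministic
CNM-style greedy agglomeration (merge with largest ΔQ, ties broken by the
smallest node id, best level along the full merge chain returned). The
greedy partition matches exhaustive search over all set partitions on every
fixture graph up to 8 nodes in the test suite, but greedy agglomeration is
not globally optimal in general — the 8-cycle is a known case where the
optimum (three arcs, Q = 0.28125) cannot be reached by pairwise merges
(greedy finds four pairs, Q = 0.25). Relative modularity is
(Q − mean Q_null)/mean Q_null over degree-preserving edge-rewiring nulls
(seeded; 4E swap attempts per null).

Per-sample complexity is a reconstruction choice: each sample induces the
subgraph on its present taxa; avg_degree, avg_clustering and n_edges
(configurable) are z-scored across samples with the population SD and
averaged. Properties constant across samples are dropped with a warning; if
all are, scores are missing. The composite is re-centred to mean 0 over
non-missing samples. Complexity-vs-ratio relations are ordinary least
squares with Pearson r and a two-sided t-test.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
validated; its defaults were designed once, against the regime signatures
below, and frozen.

**Phylogeny.** A Yule process (per-lineage rate 1, exponential waiting
times) grown to n tips, made ultrametric with root depth exactly 1, then
time-warped piecewise-linearly: the first 80% of the timeline is stretched
over 95% of the depth (`backbone_fraction=0.8`, `backbone_depth=0.95`).
This yields shallow terminal radiations hanging off deep backbone branches —
the geometry of marker-gene (16S) phylogenies, where exact sequence variants
are nearly identical within clusters. The warp matters: on an unwarped Yule
clock the pendant edges are so long that "close relatives" are not close,
and the βNTI z-score cannot resolve selection at desk-scale community sizes.
Setting both parameters equal disables the warp.

**Environmental optima.** Brownian motion along branches from a root value
of 0. `depth_power` (default 1 in `simulate_optima_bm`; the regime generator
uses 0.5 via `RegimeSpec.trait_depth_power`) accumulates variance along
power-transformed node depths, a Pagel-δ-style transform that concentrates
trait divergence on deep branches so the optimum behaves as a clade-
conserved niche; total tip variance is σ² either way.

**Communities.** The metacommunity is lognormal(0, σ=1.5) over the taxa,
normalized — heavy-tailed enough that the 0.1%/1% partition is non-
degenerate. Per regime (counts are multinomial at the configured depth):

* *homogeneous/heterogeneous selection*: weights = metacommunity ×
  exp(−S·(optimum − env)²); S defaults to 100. Homogeneous uses identical
  env (0) for all samples; heterogeneous spreads env over [−1.5, 1.5].
* *dispersal limitation*: each sample draws an independent random pool of
  20% of the taxa and fresh lognormal relative abundances within it (local
  drift). The drift is essential: with shared metacommunity weights the
  Raup–Crick null reproduces the observed turnover and RC_bray stays near 0.
* *homogenizing dispersal*: one shared realized community (a single
  multinomial draw from the metacommunity) resampled per sample.
* *neutral*: the unweighted metacommunity.

Defaults (12 samples, depth 1,000, 800 taxa, S=100) satisfy the regime →
signature map across multiple seeds: homogeneous selection gives median
βNTI < −2, heterogeneous > +2, dispersal limitation |βNTI| ≤ 2 with median
RC_bray > 0.95, homogenizing dispersal median RC_bray < −0.95, and the modal
pairwise process call equals the generating regime. Note that *neutral*
sampling is generatively close to homogenizing dispersal (every sample from
one distribution), and its pairs classify accordingly; its tested signature
is only that βNTI stays within ±2.

**Soils and enzymes.** Ten soil variables are drawn from karst-topsoil-scale
baselines with site-level multipliers and multiplicative lognormal noise.
Enzyme baselines are constructed so the expected vector angle is exactly 45°
(balanced: AP = NAG+LAP), below (N scenario) or above (P scenario), then
jittered with lognormal noise of the configured scale. One global seed
expands into fixed per-stage child seeds, and the serialized truth record
regenerates a bundle bit-for-bit.

**What the generator does not emulate:** compositional sequencing artefacts
(it samples true multinomials), chimeras/contamination, spatially explicit
dispersal kernels, copy-number variation, or any coupling between the
simulated soil chemistry and the community — soil/enzyme tables are
independent of the counts, so cross-stage regressions on synthetic data test
plumbing and calibration, not ecology. Passing tests therefore show the
statistics are implemented and calibrated correctly, not that any particular
field system behaves this way.

## Numerical conventions and degenerate inputs

Seeded `numpy` Generators everywhere; any global seed expands to child seeds
by fixed offsets and stays below 2³¹. Relative-abundance rows must sum to 1
within 1e-9. βNTI with null SD ≤ 1e-12 → undefined. PERMANOVA requires ≥ 2
groups with ≥ 2 samples each. Mantel requires non-constant matrices.
Quadrant/vector inputs must be positive where logs or ratios are taken.
Tables are TSV with the ID in the first column; trees are Newick with branch
lengths mandatory and non-negative; missing samples abort a run while ASVs
missing from the tree are dropped with a warning (or error, configurably).

## Problem sizes

The test suite and acceptance script run seeded simulations at the
generator's default sizes (12 samples × 800 taxa for regime recovery, 20 ×
100 at depth 5,000 for neutral-model coverage, 500 replicates for PERMANOVA
calibration, 40-taxon block matrices for RMT separation); the full suite
completes in about 90 seconds and the acceptance script in about a minute on
one CPU.
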