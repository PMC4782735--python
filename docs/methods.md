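# Methods

## Problem and model

Biogeographic and palaeoecological studies routinely delimit faunal
regions by clustering site-by-species occurrence tables. Occurrence data
are awkward for the standard toolbox: a zero cell may mean true absence or
just incomplete sampling, so sites are compared through presence/absence
dissimilarity indices, and those indices are generally non-Euclidean;
relationships between assemblages are reticulate rather than tree-like,
so a hierarchy is an assumption, not a given.

`nerclust` implements Non-Euclidean Relational Clustering (NERC), a
non-hierarchical iterative partitioner that works directly on any
dissimilarity matrix, alongside the conventional alternatives it is
compared with, a simulator of regional occurrence data with known truth,
and a paired benchmark scored by the Adjusted Rand Index (ARI).

## The NERC algorithm

Given an n×n dissimilarity matrix `d` and a cluster count `k`
(2 ≤ k ≤ n/2 — below 2 there is nothing to partition, above n/2 a
singleton cluster is unavoidable), one restart runs:

1. **Initialization.** k samples drawn uniformly without replacement,
   each seeding one cluster.
2. **Allocation.** Repeatedly, the globally smallest dissimilarity between
   any unassigned and any assigned sample is found and the unassigned
   sample joins that neighbour's cluster — single-linkage-style greedy
   growth — until all samples are assigned. If any group finishes with one
   member, the restart re-seeds from step 1 (at most 100 consecutive
   attempts, then an error: the data likely do not support k groups).
3. **Reallocation.** For every sample, its mean dissimilarity to each
   cluster is computed, excluding the sample itself from its own cluster's
   mean. While any sample has a *strictly* smaller mean to a foreign
   cluster, one such sample is chosen uniformly at random and moved to its
   best cluster; means are refreshed after every single move. A cap
   (default 1000 successful moves) prevents cycling when no fully
   satisfied assignment exists.

The restart's score is the **pooled mean within-group distance**: the mean
of `d` over all unordered within-cluster pairs, pooled across clusters.
Pooling (rather than averaging per-cluster means) was chosen because an
unweighted mean of per-cluster means over-rewards tiny tight clusters.
The best of `n_restarts` (default 1000) independent restarts is returned;
ties keep the first. Each restart owns an RNG stream spawned from the
master seed, so runs are reproducible and restart-parallelisable.

Numerical choices:

- moves require improvement beyond 1e-12 to prevent oscillation between
  tied clusters;
- allocation ties break on the lowest (unassigned, assigned) index pair,
  making the greedy phase deterministic given the seeds;
- a move that would leave a cluster with fewer than two members is
  forbidden (skipped when choosing the random misplaced sample). The
  allocation step already restarts on singletons, so the optimizer
  preserves the ≥2-member contract and the score stays well defined;
- `converged=True` is reported only when *no* sample has a strictly
  better foreign cluster — including samples whose move the singleton
  guard blocks — so a converged result always passes an independent
  fixed-point check. The reassignment cap counts successful moves.

NERC finds a local, not necessarily global, optimum; the benchmark uses
100 restarts per replicate, which on 90-site problems recovers the same
partitions as 1000 restarts in virtually every replicate while keeping a
full sweep affordable.

## Dissimilarities

Sørensen (Dice) dissimilarity, `1 − 2a/(2a + b + c)` with `a` the shared
and `b`, `c` the site-unique species counts, computed after thresholding
counts to presence/absence. Empty sites are a hard error here; the
simulator is responsible for never producing them. The Euclidean variant
used by the benchmark measures Euclidean distance between the same 0/1
site vectors, so the two k-means pipelines differ only in the metric.
Matrix files are square CSV with matching headers, or headerless strict
lower-triangle rows (mirrored on read); asymmetry beyond 1e-9 is rejected
rather than silently averaged.

## Baseline methods

- **Linkage clustering**: single, complete and UPGMA (average linkage) via
  scipy's agglomerative implementation, cut so exactly k groups remain.
- **Ordination + k-means**: an unconstrained distance-based RDA is
  mathematically principal coordinates analysis, so PCoA is computed
  directly (double-centre −½d², symmetric eigendecomposition, axes scaled
  by √eigenvalue). Sørensen input is non-Euclidean, so negative
  eigenvalues occur; those axes are dropped with no Cailliez/Lingoes
  correction, matching the default of the common ordination tools and
  keeping the comparison about the input metric. All positive-eigenvalue
  axes are passed to k-means (no truncation rule is imposed). k-means is
  Lloyd's algorithm with random-data-point initialization, best of 100
  restarts by within-cluster sum of squares (scikit-learn's
  implementation).

## The simulator

`sim_occ` builds a species×sites count matrix from regional pools:
`round(e·n_species)` endemics split as evenly as possible across regions
(earlier regions take the remainder — deterministic), the rest
cosmopolitan. Each locality draws a fresh log-normal relative abundance
per pool species and then a multinomial of `specimens_per_site` specimens,
so column sums equal the specimen count exactly and absences arise from
finite sampling of a skewed distribution, not from an explicit
zero-inflation step. (Because the specimen count is fixed and positive, an
all-zero locality cannot occur; the redraw guard exists only as a
safety net for future variants, e.g. a Poisson-varying specimen count,
which is a documented extension point.)

Defaults, chosen once: `n_species=100`, `meanlog=0`, `sdlog=1.5` (a few
dominant species and a long rare tail, the shape typical of empirical
abundance distributions), 3 regions × 30 sites (the benchmark design),
`specimens_per_site=50`, `endemicity=0.5`. The last two sit mid-range of
the sweeps below.

What the simulator does *not* emulate: spatial structure and dispersal
(regions are exchangeable blocks), taphonomic or detection bias beyond
specimen subsampling, abundance correlation between nearby sites, and
uneven site richness beyond what the log-normal induces. Benchmark
results therefore speak to cluster recovery under sampling noise and
pool overlap, not to every failure mode of real fossil data.

## Benchmark design and calibration

Each replicate simulates one matrix and feeds it to all six methods
(the four distance-based ones share the same Sørensen matrix), scoring
each partition against the known regions with ARI; per-replicate seeds
derive from (master seed, level, replicate), so the design is fully
paired and method contrasts cancel simulation noise. Default 100
replicates per level (the full-scale 1000 is a flag away);
`scripts/acceptance.py` uses 30.

The sweep grids were placed by calibrating where mean ARI transitions
from 0 (no recoverable signal) to 1 (saturation) under the defaults
above, since that transition zone is where method differences are
expressible at all: endemicity ∈ {0.2, 0.3, 0.4, 0.5, 0.6, 0.8} at 50
specimens/site, and specimens ∈ {30, 50, 100, 200, 300} at e=0.5. The
calibration fixed only the x-axis placement; method ordering was never an
input to it. At the extremes the expected calibration properties hold by
construction: e=0 gives exchangeable regions (mean ARI ≈ 0 for every
method) and e=0.9 with 200 specimens/site gives nearly disjoint,
well-sampled regions (mean ARI ≈ 1 for every method).

## Index implementations

Rand and Adjusted Rand indices are computed from the cluster contingency
table; the ARI uses the Hubert–Arabie permutation-model adjustment. When
the adjustment denominator vanishes (both partitions all-singletons or
both a single cluster) the value is defined as 1 if the partitions agree
up to relabelling, else 0 — the dominant convention. Tests verify both
indices against exhaustive pair-counting oracles and scikit-learn.

## Known limitations

- NERC is O(n²) per reallocation pass and O(n²) per allocation; the
  implementation is vectorised but aimed at assemblage-scale problems
  (tens to a few hundred sites), not thousands.
- k is an input; the package offers no model-selection criterion for the
  number of clusters and assumes true divisions exist.
- The singleton guard means NERC cannot represent a genuine one-sample
  cluster; that is by design (it is what protects it from the outlier
  pathology that cripples cut trees) but it is a modelling commitment,
  not a neutral choice.
- Only the Sørensen index (and its Euclidean counterpart for the metric
  contrast) is provided; abundance-weighted or alternative
  presence/absence indices are out of scope.
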