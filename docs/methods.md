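# Methods

This note documents the statistical model behind each pipeline stage, the
synthetic study that the tests run against, the numerical conventions, and
the design choices that were genuinely open.

## Marker dependency filtering

Markers are joined to genes through two evidence channels: tissue QTL
tables (eQTL/sQTL records taken as given assertions — no QTL p-value
filtering happens inside the tool; filter upstream if needed) and a
symmetric distance window of ±20 kb (default) around the gene body, with
1-based inclusive coordinates and inclusive window boundaries. The enabled
channels are configurable (`mapping_sources`); a (marker, gene) pair
supported by several channels keeps one record per channel.

LD pruning is greedy clumping over the supra-threshold LD graph
(r² > 0.5 by default): markers are visited in order of ascending p-value
(ties broken lexicographically by marker id, making every output
deterministic), each visited marker is retained, and all still-unclaimed
markers linked to it above the threshold are discarded. Markers absent
from the LD table are treated as unlinked. This is standard clumping; we
chose it over connected-component blocks because components chain weakly
linked markers into unreasonably large blocks.

Properties that hold and are tested: the retained set is an independent
set of the supra-threshold graph; the globally strongest marker always
survives; clumping is idempotent; unlinked markers are always retained.
One property that does *not* hold, although it is intuitively tempting:
raising the r² threshold can reshuffle which markers are retained and can
even shrink the retained set slightly (greedy seeding interacts with edge
removal non-monotonically — e.g. chain A–B r²=0.6, B–C r²=0.9 with
p(A)<p(B)<p(C) retains {A,C} at threshold 0.5 but {A,B} at 0.7). The test
suite deliberately asserts only the former invariants.

No GWAS p-value cutoff is applied at any point; the full association
spectrum feeds the downstream null estimation.

## Marker set enrichment analysis

Let M be the number of retained markers, ranked by −log10 p descending
(ties lexicographic by marker id). A module's marker set is the union of
distinct retained markers mapped to its genes in its tissue. With
m = |module markers|, at quantile q the positive set is the top
k_q = ⌊(1−q)·M⌋ ranks (a 1e−9 guard absorbs float noise in the product),
O_q is the module's count inside it, and E_q = m·k_q/M. The statistic is

    χ = Σ_q (O_q − E_q)/√(E_q + κ),  κ = 1 by default,

summed over n = 10 equally spaced quantiles from 0.5 to
q_upper = 1 − 1/μ, where μ is the median module marker-set size across all
tested modules in the run (computed once, after size filtering). μ ≤ 2
makes the quantile range degenerate and is an error.

E_q is the module's share of the global positive fraction — the "equal
proportion of positive associations" null. The null distribution is built
by drawing, per module gene count, random gene sets without replacement
from the tissue's genes that have at least one retained marker, pooling
their distinct markers, and computing χ with that set's own m.
Z = (χ_obs − null mean)/null SD, p is the one-sided Gaussian upper tail
(enrichment is directional; deficits get p > 0.5 and are never flagged),
and BH-FDR is computed over all modules in the run (`fdr_family="global"`,
matching a joint module ranking; per-tissue families are available).

Numerical and design conventions:

* 1000 permutations by default; null moments are cached per (tissue, gene
  count) and the cache key also seeds the permutation stream, so results
  are independent of module iteration order.
* A degenerate null (every permutation identical, e.g. constant p-values)
  is flagged, with p set to 1 rather than dropped silently.
* `min_module_size` = 10 genes after intersecting with marker-bearing
  genes; undersized modules are reported in a skipped table. Small modules
  destabilize both q_upper and the Gaussian approximation.
* E[χ] ≈ 0 under the null holds over the joint randomness of the marker
  map and the gene sampling. Conditional on one fixed map the permutation
  null mean carries a small map-specific offset; this is expected and is
  exactly what the Z-standardization removes. Type-I calibration of the
  final p-values is asserted directly on signal-free synthetic studies
  (nominal p < 0.05 rate within 0.05 ± 0.02 across seeds).

## Key driver analysis

Degree is total in+out degree with each directed edge counted once. Hub
candidates are nodes at or above the degree value at the (1 − 0.25)
quantile of the degree distribution (upper order statistic; ties at the
cutoff kept, so the candidate set holds at least 25% of nodes). A hub's
subnetwork is itself plus every node within `depth` hops ignoring edge
direction (depth 1 by default — direction encodes regulatory semantics,
not reachability for neighborhood membership).

The statistic is the overlap between subnetwork and disease set (the
union of genes in MSEA-significant modules, intersected with the network).
The null reshuffles subnetworks of the same size as uniform random node
sets; because the overlap of a uniform size-s node set with a fixed gene
set is exactly hypergeometric, the permutation draws are taken from the
hypergeometric sampler — an exact implementation of that null, not an
approximation. Z and the one-sided Gaussian p follow as in MSEA, and the
analytic hypergeometric upper tail is reported alongside (`P_HYPERGEOM`)
as a cross-check; the two agree in rank order (Spearman ρ > 0.95 at the
default network scale). A degree-preserving rewiring null was considered
and rejected: the stated size-matching is fully captured by node-set
permutation, which additionally admits the exact cross-check.

Calibration caveat: the Gaussian tail on a *discrete* overlap count is
slightly anti-conservative when the expected overlap is ≪ 1 (smallest
subnetworks). Calibration checks therefore use disease sets covering
~20% of nodes, where expected overlaps are comfortably above the discrete
floor; with sparser disease sets, prefer the exact `P_HYPERGEOM` column.

## Convergence of rare and common variants

The rare catalog maps each gene to one confidence level (S, 1, 2, 3) and
is analyzed both collectively and per level. A gene is a common-variant
gene when its best retained mapped marker (union over tissues) has
p < 1e−4 (configurable); the continuous per-gene −log10 p is always
exported for annotation, so the binary cut loses nothing downstream.
Fisher's one-sided exact test and the hypergeometric upper tail are the
same test and are implemented once (scipy's hypergeometric survival
function); fold enrichment is (overlap/unit)/(catalog/background). The
default background is the per-network node set; a transcriptome gene list
can be substituted. BH-FDR runs within each variant class across units,
and each key driver is classified rare-only / common-only / both /
neither at FDR < 0.05. Group comparisons report Shapiro–Wilk normality on
the pooled values plus a Mann–Whitney rank-sum test with a configurable
alternative.

## Pathway report

ORA uses the same exact-test core against user-supplied GMT libraries,
BH-adjusted within library. System summaries score each pathway per organ
system by the median −log10 adjusted p across the contributing module
tables, and partition significant pathways by the exact subset of systems
sharing them (a true partition: regions are disjoint and sum to the
union). Tissues may map to several systems; counts are per system, not
deduplicated. Subnetwork exports are plain node/edge tables (gene,
key-driver flag, rare level, common-variant strength) loadable by
Cytoscape; unannotated nodes keep empty fields rather than being dropped.

## The synthetic study

The generator emulates the *shape* of the real inputs, not their content:

* **Markers/LD**: one synthetic chromosome, markers 1 kb apart,
  block-diagonal LD (all within-block pairs at one r², cross-block r² = 0).
  Defaults: 10,000 markers, 200 blocks of 5 at r² = 0.8.
* **GWAS**: null markers draw p ~ Uniform(0,1); designated signal markers
  draw p ~ Beta(a, 1) with a = 0.2 — a single-knob monotone enrichment of
  small p-values (P(p < t) = t^a).
* **Genes/maps**: 5,000 genes spaced 100 kb apart, so only ~2% overlap the
  dense marker region and acquire distance mappings (placing every gene on
  1 kb marker spacing would hand ~40 distance markers to all genes and
  drown any mapped signal); every gene gets 2–5 eQTL markers per tissue
  plus an sQTL marker with probability 0.3, drawn uniformly — the
  many-to-many structure of real QTL maps without their locality.
* **Modules**: 2 tissues × 100 modules, sizes uniform in 15–60. The first
  5 modules of the first tissue are planted: half of each planted module's
  full mapped marker pool (QTL plus distance window) is designated signal.
* **Networks**: directed preferential attachment (2,000 nodes, 3 edges per
  new node) per group (brain, peripheral); planted hubs are re-wired to
  exactly 40 neighbors of which 80% are disease (planted-module) genes.
* **Rare catalog**: 100 genes at levels S/1/2/3 = 10/20/30/40 (~2% of the
  universe, a SFARI-like fraction), with 50% drawn from planted hub
  neighborhoods.

These defaults are a ~1:4 scale-down of a transcriptome-wide study chosen
once as the standard test conditions; the planted-signal gene density
(~2.5%) is the quantity that matters for MSEA power, since null gene sets
that absorb signal genes inflate the null SD. Identical (config, seed)
bundles are byte-identical.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: realistic LD decay and population
structure, allele frequencies and effect-size architectures, locality of
QTLs, correlated module memberships from shared coexpression, scale-free
exponents of real regulatory networks, or any biological content of the
catalogs. The tests establish that the statistics are computed correctly,
calibrated under their own null, and able to recover signal of the planted
form at the stated strength.

## Problem sizes used by the test and acceptance runs

Unit tests run a miniature study (600 markers, 300 genes, 30 modules);
study-level checks use the default scale above: 10 signal-free studies for
type-I calibration, 20 seeds for planted-module recovery, 20 seeds of
2,000-node networks for hub recovery, 1,000 random graphs for the clumping
oracle, 1,000 vectors for BH, and every feasible 2×2 table with background
≤ 25 for the exact test. `scripts/acceptance.py` re-measures the same
quantities on freshly generated data (3 planted and 3 null studies, plus
the oracle sweeps) and reports them as JSON.
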