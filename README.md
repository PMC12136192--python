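# convergene

Integration of GWAS summary statistics with tissue-specific gene modules
and regulatory networks, to ask where common-variant disease signal
concentrates and whether it converges with rare-variant gene catalogs.

The package is built for analysts who have (i) per-marker association
p-values from a GWAS, (ii) marker-to-gene evidence (eQTL/sQTL tables and/or
gene positions), (iii) tissue gene modules in GMT format, (iv) directed
regulatory networks as edge lists, and (v) a leveled rare-variant gene
catalog (Syndromic/1/2/3 confidence tiers). A synthetic-study generator
with recorded ground truth stands in for all of these, so the entire
pipeline is testable offline.

## The method

**MDF — marker dependency filtering.** Markers are mapped to genes per
tissue through QTL tables and a ±20 kb distance window, then pruned by
greedy LD clumping: visiting markers best-p first, each retained marker
discards every unclaimed marker linked to it at r² > 0.5, keeping the
strongest association per LD block. No GWAS p-value cutoff is applied.

**MSEA — marker set enrichment analysis.** Retained markers are ranked by
−log10 p. For a module with m distinct mapped markers out of M total, at
each of n = 10 rank quantiles q ∈ [0.5, 1 − 1/μ] (μ = median module marker
count) the top k_q = ⌊(1−q)·M⌋ markers are "positive" and the module is
scored by the chi-like statistic

    χ = Σᵢ (Oᵢ − Eᵢ) / √(Eᵢ + κ),   κ = 1,

with Oᵢ the module's positive-marker count and Eᵢ = m·k_q/M its expected
share. χ is standardized against a null of random gene sets matching the
module's gene count (Z-score → one-sided Gaussian p → Benjamini–Hochberg
FDR).

**KDA — key driver analysis.** In each directed network, hubs are nodes in
the top 25% of edge connections. A hub's subnetwork (itself plus its
first-degree neighbors, direction ignored) is tested for enrichment of
MSEA-significant module genes against size-matched random node sets, with
the exact hypergeometric tail reported as a cross-check.

**Convergence.** Rare-variant catalogs (collectively and per confidence
level) and a common-variant gene set (genes whose best retained marker has
p < 1e-4) are intersected with networks and KD subnetworks: raw and
size-normalized counts, fold enrichment = (overlap/unit)/(catalog/background)
with one-sided Fisher/hypergeometric p-values, Wilcoxon rank-sum group
comparisons, and a rare-only / common-only / both / neither classification
per key driver.

**Report.** Local pathway over-representation (ORA) against GMT libraries,
cross-system pathway sharing partitions, and Cytoscape-ready subnetwork
exports with variant annotations.

## Worked example

```bash
convergene simulate --out bundle --seed 7
convergene run --bundle bundle --out results --seed 7
```

which prints (exact numbers for seed 7):

```
bundle written to bundle (12 files + truth.json)
7 modules at FDR<5%; top key driver g3115 (brain, p=2.25e-85)
```

The synthetic study plants 5 signal-enriched modules among 200 and 2 hub
genes whose neighborhoods are 80% disease genes. Here MSEA finds 7
modules at FDR < 5% — the 5 planted ones occupy the top 5 ranks
(Z = 7.3–13.1), trailed by two borderline null modules — and the
top-ranked key driver `g3115` is one of the planted hubs: 32 of its
41 subnetwork genes belong to significant modules, against roughly 2
expected under the size-matched null. Stage
tables land under `results/` (`msea/msea.results.tsv`,
`kda/kda.results.tsv`, `convergence/convergence.results.tsv`, ...) together
with `manifest.json` echoing every analysis parameter (r² = 0.5, window =
20 kb, 10 quantiles from 0.5, κ = 1, hub fraction 0.25, FDR 0.05).

Python API:

```python
from convergene import SyntheticConfig, pipeline

res = pipeline.simulate_and_run(SyntheticConfig(), "work", seed=7)
print(res["msea"].results.head())      # modules ranked by p
print(res["kda"].results.head())       # key drivers ranked by p
```

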