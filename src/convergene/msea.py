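"""Marker set enrichment analysis (MSEA).

Scores a gene module for over-representation of strong GWAS associations
among the distinct markers mapped to its genes.  Markers are ranked by
association strength (−log10 p, ties broken lexicographically by marker
id); at each of ``n`` rank quantiles q the top ``k_q = floor((1 − q)·M)``
markers are "positive" and the module contributes an observed count
``O = |module markers ∩ top-k_q|`` against the expectation
``E = m·k_q/M`` (its share of the global positive fraction).  The summary
statistic is the chi-like sum

    χ = Σ_i (O_i − E_i) / sqrt(E_i + κ)

with a stability constant κ (default 1) guarding low expected counts.
Quantiles run from 0.5 to ``q_upper = 1 − 1/μ`` where μ is the median
module marker-set size, so the upper tail adapts to module size.  The null
is built from random gene sets matching each module's gene count, drawn
from the tissue's genes with at least one retained marker: under it a
random set's markers contain an equal proportion of positive associations
at every quantile, so E[χ] ≈ 0.  χ is standardized against the null
(Z-score), converted to a one-sided Gaussian upper-tail p, and adjusted by
Benjamini–Hochberg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_fdr

RESULT_COLS = ["MODULE", "TISSUE", "N_GENES", "N_MARKERS", "CHI",
               "NULL_MEAN", "NULL_SD", "Z", "P", "FDR"]


@dataclass
class EnrichmentConfig:
    n_quantile_points: int = 10
    kappa: float = 1.0
    n_permutations: int = 1000
    seed: int = 0
    min_module_size: int = 10
    max_module_size: int | None = None
    fdr_threshold: float = 0.05
    fdr_family: str = "global"  # "global" | "tissue"

    def validate(self) -> None:
        if self.n_quantile_points < 2:
            raise ValueError("n_quantile_points must be >= 2")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.fdr_family not in ("global", "tissue"):
            raise ValueError("fdr_family must be 'global' or 'tissue'")


def quantile_cutpoints(median_module_size: float, n_points: int = 10
                       ) -> np.ndarray:
    """n equally spaced quantiles from 0.5 to q_upper = 1 − 1/μ inclusive."""
    mu = float(median_module_size)
    q_upper = 1.0 - 1.0 / mu if mu > 0 else 0.0
    if q_upper <= 0.5:
        raise ValueError(
            f"degenerate quantile range: median module size {mu} gives "
            f"q_upper = {q_upper} <= 0.5")
    return np.linspace(0.5, q_upper, n_points)


def marker_ranking(retained: pd.DataFrame) -> pd.DataFrame:
    """Retained markers with 1-based RANK by −log10 p descending.

    Ties in association strength resolve lexicographically by marker id so
    the ranking (and everything downstream) is deterministic.
    """
    df = retained.sort_values(["PVALUE", "MARKER"], kind="stable",
                              ignore_index=True)
    df = df.assign(RANK=np.arange(1, len(df) + 1))
    return df


def positive_thresholds(cutpoints, n_markers: int) -> np.ndarray:
    """k_q = floor((1 − q)·M) for each cutpoint (small float-noise guard)."""
    q = np.asarray(cutpoints, dtype=float)
    return np.floor((1.0 - q) * n_markers + 1e-9).astype(int)


def positive_counts(module_markers, ranking: pd.DataFrame, cutpoint: float
                    ) -> tuple[int, float]:
    """(O, E) at one quantile for a module's distinct marker set."""
    module = set(module_markers)
    unknown = module - set(ranking["MARKER"])
    if unknown:
        raise ValueError(f"module markers missing from the global ranking: "
                         f"{sorted(unknown)[:3]}")
    m_total = len(ranking)
    k = int(positive_thresholds([cutpoint], m_total)[0])
    top = set(ranking["MARKER"].iloc[:k])
    o = len(module & top)
    e = len(module) * k / m_total
    return o, e


def chi_statistic(observed, expected, kappa: float = 1.0) -> float:
    """χ = Σ (O − E)/sqrt(E + κ); deficits subtract (signed sum)."""
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if o.shape != e.shape:
        raise ValueError("observed/expected length mismatch")
    return float(np.sum((o - e) / np.sqrt(e + kappa)))


class TissueIndex:
    """Gene → marker-rank arrays for one tissue, built once per run.

    The eligible gene universe is every gene with at least one retained
    marker in the tissue; marker ids are replaced by their global ranks so
    positive counts reduce to a sorted-array search.
    """

    def __init__(self, gene_markers: dict[str, list[str]],
                 ranking: pd.DataFrame):
        rank_of = dict(zip(ranking["MARKER"], ranking["RANK"]))
        self.n_markers_global = len(ranking)
        self.genes: list[str] = []
        self.rank_arrays: list[np.ndarray] = []
        for g in sorted(gene_markers):
            ranks = [rank_of[m] for m in gene_markers[g] if m in rank_of]
            if ranks:
                self.genes.append(g)
                self.rank_arrays.append(np.asarray(sorted(ranks), dtype=np.int64))
        self._pos = {g: i for i, g in enumerate(self.genes)}

    def module_ranks(self, module_genes) -> np.ndarray | None:
        """Distinct marker ranks of a module; None if no gene has markers."""
        idx = [self._pos[g] for g in module_genes if g in self._pos]
        if not idx:
            return None
        return np.unique(np.concatenate([self.rank_arrays[i] for i in idx]))

    def n_genes_eligible(self, module_genes) -> int:
        return sum(1 for g in module_genes if g in self._pos)


def _profile(ranks: np.ndarray, ks: np.ndarray, m_global: int):
    o = np.searchsorted(ranks, ks, side="right").astype(float)
    e = ranks.size * ks / m_global
    return o, e


def null_distribution(module_n_genes: int, index: TissueIndex,
                      cutpoints, kappa: float, n_permutations: int,
                      rng: np.random.Generator):
    """Null χ sample from random gene sets of the module's gene count.

    Each permutation draws ``module_n_genes`` genes uniformly without
    replacement from the tissue's eligible universe, pools their distinct
    markers and computes χ with the set's own marker count.  Returns
    (mean, sd, sample) with the (n−1)-denominator SD.
    """
    n_univ = len(index.genes)
    if module_n_genes > n_univ:
        raise ValueError("module larger than the eligible gene universe")
    ks = positive_thresholds(cutpoints, index.n_markers_global)
    arrays = index.rank_arrays
    kap = float(kappa)
    m_global = index.n_markers_global
    sample = np.empty(n_permutations)
    for it in range(n_permutations):
        idx = rng.choice(n_univ, size=module_n_genes, replace=False)
        ranks = np.unique(np.concatenate([arrays[i] for i in idx]))
        o, e = _profile(ranks, ks, m_global)
        sample[it] = np.sum((o - e) / np.sqrt(e + kap))
    mean = float(sample.mean())
    if n_permutations > 1 and np.ptp(sample) > 0:
        sd = float(sample.std(ddof=1))
    else:
        sd = 0.0
    return mean, sd, sample


def score_module(module_id: str, tissue: str, module_genes,
                 index: TissueIndex, cutpoints, config: EnrichmentConfig,
                 null_mean: float, null_sd: float) -> dict:
    """Observed χ, null-standardized Z and one-sided Gaussian p for a module."""
    ranks = index.module_ranks(module_genes)
    if ranks is None:
        raise ValueError(f"module {module_id} has no markers in {tissue}")
    ks = positive_thresholds(cutpoints, index.n_markers_global)
    o, e = _profile(ranks, ks, index.n_markers_global)
    chi = float(np.sum((o - e) / np.sqrt(e + config.kappa)))
    if null_sd > 0:
        z = (chi - null_mean) / null_sd
        p = float(stats.norm.sf(z))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        flag = ""
    else:
        z, p, flag = float("nan"), 1.0, "null_sd_zero"
    return {"MODULE": module_id, "TISSUE": tissue,
            "N_GENES": index.n_genes_eligible(module_genes),
            "N_MARKERS": int(ranks.size), "CHI": chi,
            "NULL_MEAN": null_mean, "NULL_SD": null_sd,
            "Z": z, "P": p, "FLAG": flag}


@dataclass
class MseaResult:
    results: pd.DataFrame
    skipped: pd.DataFrame
    cutpoints: np.ndarray
    median_module_size: float
    tissue_counts: pd.DataFrame = field(default=None)


def run_msea(gene_markers: dict[str, dict[str, list[str]]],
             retained: pd.DataFrame,
             modules: dict[str, dict[str, list[str]]],
             config: EnrichmentConfig | None = None) -> MseaResult:
    """Score every tissue module; rank by p and adjust by BH.

    Parameters
    ----------
    gene_markers : tissue -> {gene: retained markers}, from MDF.
    retained : retained association table from MDF.
    modules : tissue -> {module_id: gene list} (GMT content).
    """
    config = config or EnrichmentConfig()
    config.validate()
    ranking = marker_ranking(retained)
    indexes = {t: TissueIndex(gm, ranking) for t, gm in gene_markers.items()}

    # First pass: size filters and marker-set sizes (for the median μ).
    tested, skipped = [], []
    for tissue in sorted(modules):
        if tissue not in indexes:
            for mid in modules[tissue]:
                skipped.append((mid, tissue, "no_mdf_index"))
            continue
        idx = indexes[tissue]
        for mid, genes in modules[tissue].items():
            n_genes = idx.n_genes_eligible(genes)
            ranks = idx.module_ranks(genes)
            if ranks is None or n_genes < config.min_module_size:
                skipped.append((mid, tissue, "below_min_size"))
                continue
            if config.max_module_size and n_genes > config.max_module_size:
                skipped.append((mid, tissue, "above_max_size"))
                continue
            tested.append((mid, tissue, genes, n_genes, ranks.size))
    if not tested:
        raise ValueError("no module passes the size filters")

    mu = float(np.median([t[4] for t in tested]))
    cutpoints = quantile_cutpoints(mu, config.n_quantile_points)

    # Null distributions are cached per (tissue, module gene count); the
    # cache key also seeds the permutation stream, so results do not depend
    # on module iteration order.
    tissue_pos = {t: i for i, t in enumerate(sorted(indexes))}
    null_cache: dict[tuple[str, int], tuple[float, float]] = {}
    rows = []
    for mid, tissue, genes, n_genes, _ in tested:
        key = (tissue, n_genes)
        if key not in null_cache:
            rng = np.random.default_rng(
                [config.seed % (2**31), tissue_pos[tissue], n_genes])
            mean, sd, _sample = null_distribution(
                n_genes, indexes[tissue], cutpoints, config.kappa,
                config.n_permutations, rng)
            null_cache[key] = (mean, sd)
        mean, sd = null_cache[key]
        rows.append(score_module(mid, tissue, genes, indexes[tissue],
                                 cutpoints, config, mean, sd))

    res = pd.DataFrame(rows)
    if config.fdr_family == "global":
        res["FDR"] = bh_fdr(res["P"])
    else:
        res["FDR"] = np.nan
        for tissue, sub in res.groupby("TISSUE"):
            res.loc[sub.index, "FDR"] = bh_fdr(sub["P"])
    res = res.sort_values("P", kind="stable", ignore_index=True)

    counts = (res[res["FDR"] < config.fdr_threshold]
              .groupby("TISSUE").size().rename("N_SIGNIFICANT"))
    all_tissues = pd.Index(sorted(modules), name="TISSUE")
    counts = counts.reindex(all_tissues, fill_value=0).reset_index()
    counts = counts.sort_values(["N_SIGNIFICANT", "TISSUE"],
                                ascending=[False, True], ignore_index=True)

    skipped_df = pd.DataFrame(skipped, columns=["MODULE", "TISSUE", "REASON"])
    return MseaResult(results=res[RESULT_COLS + ["FLAG"]],
                      skipped=skipped_df, cutpoints=cutpoints,
                      median_module_size=mu, tissue_counts=counts)


def write_msea(result: MseaResult, out_dir) -> None:
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.results.to_csv(out / "msea.results.tsv", sep="\t", index=False)
    result.tissue_counts.to_csv(out / "msea.tissue_counts.tsv", sep="\t",
                                index=False)
    result.skipped.to_csv(out / "msea.skipped.tsv", sep="\t", index=False)


def significant_genes(result_df: pd.DataFrame,
                      modules: dict[str, dict[str, list[str]]],
                      fdr_threshold: float = 0.05) -> set[str]:
    """Union of genes in modules significant at the FDR threshold."""
    sig = result_df[result_df["FDR"] < fdr_threshold]
    genes: set[str] = set()
    for mid, tissue in zip(sig["MODULE"], sig["TISSUE"]):
        genes.update(modules.get(tissue, {}).get(mid, ()))
    return genes
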