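"""Rare/common variant convergence in networks and key-driver subnetworks.

Quantifies how strongly a rare-variant gene catalog (confidence levels
S/1/2/3) and a common-variant gene set (genes whose best retained GWAS
marker clears a p-value threshold) concentrate in whole networks and in
individual key-driver subnetworks: raw and size-normalized counts,
percentages of key drivers carrying variants, exact one-sided
over-representation tests with fold enrichment, rank-sum group comparisons,
and a convergence classification (rare-only / common-only / both / neither)
per key driver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_fdr, fold_enrichment, hypergeom_enrichment

VARIANT_CLASSES = ("rare_all", "rare_S", "rare_1", "rare_2", "rare_3",
                   "common")


@dataclass
class ConvergenceConfig:
    common_p_threshold: float = 1e-4
    fdr_threshold: float = 0.05

    def validate(self) -> None:
        if not 0.0 < self.common_p_threshold <= 1.0:
            raise ValueError("common_p_threshold must lie in (0, 1]")


def common_variant_genes(gene_markers: dict[str, dict[str, list[str]]],
                         retained: pd.DataFrame,
                         p_threshold: float = 1e-4) -> set[str]:
    """Genes whose best retained mapped marker has p below the threshold.

    The union over tissues is returned; the continuous per-gene −log10 p is
    available via :func:`gene_association_strength` for annotation.
    """
    strength = gene_association_strength(gene_markers, retained)
    cut = -np.log10(p_threshold)
    return {g for g, s in strength.items() if s > cut}


def gene_association_strength(gene_markers, retained) -> dict[str, float]:
    """Gene -> −log10 p of its best retained mapped marker (union of tissues)."""
    pv = dict(zip(retained["MARKER"], retained["PVALUE"]))
    best: dict[str, float] = {}
    for index in gene_markers.values():
        for g, ms in index.items():
            pmin = min((pv[m] for m in ms if m in pv), default=None)
            if pmin is not None:
                s = -np.log10(pmin)
                if s > best.get(g, -np.inf):
                    best[g] = float(s)
    return best


def variant_catalog_sets(rare_catalog: pd.DataFrame,
                         common_set: set[str]) -> dict[str, set[str]]:
    """Gene sets per variant class: rare collective, per level, and common."""
    sets = {"rare_all": set(rare_catalog["GENE"])}
    for lvl in ("S", "1", "2", "3"):
        sets[f"rare_{lvl}"] = set(
            rare_catalog.loc[rare_catalog["LEVEL"] == lvl, "GENE"])
    sets["common"] = set(common_set)
    return sets


def variant_counts(network_nodes: set[str], rare_catalog: pd.DataFrame,
                   common_set: set[str]) -> pd.DataFrame:
    """Raw and size-normalized variant-gene counts inside one network."""
    if not network_nodes:
        raise ValueError("empty network")
    rows = []
    for cls, genes in variant_catalog_sets(rare_catalog, common_set).items():
        raw = len(network_nodes & genes)
        rows.append({"CLASS": cls, "RAW": raw,
                     "NORMALIZED": raw / len(network_nodes)})
    return pd.DataFrame(rows)


def kd_variant_percentage(key_drivers, variant_set) -> float:
    """Percentage of key drivers that are themselves variant genes."""
    kds = list(key_drivers)
    if not kds:
        raise ValueError("empty key driver list")
    return 100.0 * len(set(kds) & set(variant_set)) / len(kds)


def set_enrichment(unit_genes, catalog_genes, background_genes,
                   unit_id: str = "", variant_class: str = "") -> dict:
    """Exact one-sided over-representation of a catalog in a gene unit.

    The catalog is intersected with the background first; p is the
    hypergeometric upper tail (== one-sided Fisher).
    """
    background = set(background_genes)
    if not background:
        raise ValueError("empty background")
    unit = set(unit_genes)
    if unit - background:
        raise ValueError("unit must be a subset of the background")
    catalog = set(catalog_genes) & background
    overlap = len(unit & catalog)
    fold = fold_enrichment(overlap, len(unit), len(catalog), len(background))
    if np.isnan(fold):
        fold = 0.0
    p = hypergeom_enrichment(overlap, len(unit), len(catalog),
                             len(background)) if catalog else 1.0
    return {"UNIT": unit_id, "CLASS": variant_class, "OVERLAP": overlap,
            "UNIT_SIZE": len(unit), "CATALOG_SIZE": len(catalog),
            "BACKGROUND_SIZE": len(background), "FOLD": fold, "P": p}


def compare_groups(values_a, values_b, alternative: str = "two-sided",
                   label_a: str = "a", label_b: str = "b") -> dict:
    """Shapiro–Wilk normality report plus a rank-sum (Mann–Whitney) test."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 values per group")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        shapiro_p, shapiro_flag = float("nan"), "constant_data"
    else:
        shapiro_p = float(stats.shapiro(pooled).pvalue)
        shapiro_flag = ""
    stat = stats.mannwhitneyu(a, b, alternative=alternative)
    return {"GROUP_A": label_a, "GROUP_B": label_b,
            "N_A": int(a.size), "N_B": int(b.size),
            "MEDIAN_A": float(np.median(a)), "MEDIAN_B": float(np.median(b)),
            "SHAPIRO_P": shapiro_p, "SHAPIRO_FLAG": shapiro_flag,
            "ALTERNATIVE": alternative, "U": float(stat.statistic),
            "P": float(stat.pvalue)}


def classify_convergence(overlap_results: pd.DataFrame,
                         fdr_threshold: float = 0.05,
                         rare_class: str = "rare_all",
                         common_class: str = "common") -> pd.DataFrame:
    """Label each key-driver unit rare-only / common-only / both / neither."""
    need = {rare_class, common_class}
    have = set(overlap_results["CLASS"])
    if not need <= have:
        raise ValueError(f"missing variant classes {sorted(need - have)}")
    wide = overlap_results[overlap_results["CLASS"].isin(need)].pivot_table(
        index=["GROUP", "UNIT"], columns="CLASS", values="FDR")
    if wide[[rare_class, common_class]].isna().any().any():
        raise ValueError("some units lack a scored variant class")
    rare_sig = wide[rare_class] < fdr_threshold
    common_sig = wide[common_class] < fdr_threshold
    cls = np.select(
        [rare_sig & common_sig, rare_sig, common_sig],
        ["both", "rare_only", "common_only"], default="neither")
    out = wide.reset_index()[["GROUP", "UNIT"]]
    out["CLASS"] = cls
    return out.sort_values(["GROUP", "UNIT"], ignore_index=True)


def rank_kd_by_variant_enrichment(results: pd.DataFrame, variant_class: str,
                                  k: int = 15) -> pd.DataFrame:
    """Top-k units by p ascending (ties: higher fold, then unit id)."""
    if k <= 0:
        raise ValueError("k must be positive")
    sub = results[results["CLASS"] == variant_class].copy()
    sub = sub.sort_values(["P", "FOLD", "UNIT"],
                          ascending=[True, False, True], kind="stable",
                          ignore_index=True)
    return sub.head(k)


def run_convergence(kd_subnetworks: dict, networks_nodes: dict[str, set[str]],
                    rare_catalog: pd.DataFrame, common_set: set[str],
                    config: ConvergenceConfig | None = None,
                    background_by_group: dict[str, set[str]] | None = None
                    ) -> dict[str, pd.DataFrame]:
    """Score every KD subnetwork against every variant class.

    Parameters
    ----------
    kd_subnetworks : (group, kd) -> node set, from KDA.
    networks_nodes : group -> node set (the default enrichment background).
    background_by_group : optional replacement backgrounds (e.g. a per-tissue
        transcriptome gene list).

    Returns ``{"results", "classes", "groupstats"}`` tables; the results
    carry a BH FDR computed within each variant class across units.
    """
    config = config or ConvergenceConfig()
    config.validate()
    catalogs = variant_catalog_sets(rare_catalog, common_set)
    rows = []
    for (group, kd), subnet in sorted(kd_subnetworks.items()):
        background = (background_by_group or networks_nodes)[group]
        for cls, genes in catalogs.items():
            r = set_enrichment(subnet & set(background), genes, background,
                               unit_id=kd, variant_class=cls)
            r["GROUP"] = group
            rows.append(r)
    results = pd.DataFrame(rows)
    results["FDR"] = np.nan
    for cls, sub in results.groupby("CLASS"):
        results.loc[sub.index, "FDR"] = bh_fdr(sub["P"])

    classes = classify_convergence(results, config.fdr_threshold)

    # Fig-4-style group summaries: per-network variant counts plus the
    # percentage of key drivers that are themselves variant genes.
    gs_rows = []
    for group, nodes in sorted(networks_nodes.items()):
        counts = variant_counts(nodes, rare_catalog, common_set)
        kds = sorted({kd for (g, kd) in kd_subnetworks if g == group})
        for _, row in counts.iterrows():
            gs_rows.append({"GROUP": group, "CLASS": row["CLASS"],
                            "RAW": int(row["RAW"]),
                            "NORMALIZED": row["NORMALIZED"],
                            "KD_PERCENT": kd_variant_percentage(
                                kds, catalogs[row["CLASS"]]) if kds
                            else float("nan")})
    groupstats = pd.DataFrame(gs_rows)
    order = ["GROUP", "UNIT", "CLASS", "OVERLAP", "UNIT_SIZE", "CATALOG_SIZE",
             "BACKGROUND_SIZE", "FOLD", "P", "FDR"]
    return {"results": results[order], "classes": classes,
            "groupstats": groupstats}


def write_convergence(tables: dict[str, pd.DataFrame], out_dir) -> None:
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables["results"].to_csv(out / "convergence.results.tsv", sep="\t",
                             index=False)
    tables["classes"].to_csv(out / "convergence.classes.tsv", sep="\t",
                             index=False)
    tables["groupstats"].to_csv(out / "convergence.groupstats.tsv", sep="\t",
                                index=False)
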