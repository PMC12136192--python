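"""Pathway annotation, cross-system sharing summaries, and subnetwork export.

Replaces a web-based annotation service with a local over-representation
analysis (ORA) against user-supplied GMT pathway libraries, summarizes
which pathways recur across organ systems (median −log10 adjusted p across
contributing module tables, plus a sharing partition of significant
pathways), and exports key-driver subnetworks as Cytoscape-loadable node
and edge tables with rare-variant level and common-variant association
strength annotations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._stats import bh_fdr, fold_enrichment, hypergeom_enrichment


def ora(gene_set, library: dict[str, set[str]], background) -> pd.DataFrame:
    """One-sided exact over-representation of a gene set in each pathway.

    Same exact-test core as the convergence module; BH adjustment within
    the library.
    """
    if not library:
        raise ValueError("empty pathway library")
    background = set(background)
    genes = set(gene_set) & background
    if not background >= set(gene_set):
        raise ValueError("background must contain the query gene set")
    rows = []
    for pid in sorted(library):
        members = set(library[pid]) & background
        overlap = len(genes & members)
        fold = fold_enrichment(overlap, len(genes), len(members),
                               len(background))
        rows.append({"PATHWAY": pid, "OVERLAP": overlap,
                     "SET_SIZE": len(genes), "PATHWAY_SIZE": len(members),
                     "BACKGROUND_SIZE": len(background),
                     "FOLD": 0.0 if np.isnan(fold) else fold,
                     "P": hypergeom_enrichment(overlap, len(genes),
                                               len(members), len(background))
                     if members else 1.0})
    df = pd.DataFrame(rows)
    df["ADJ_P"] = bh_fdr(df["P"])
    return df.sort_values(["P", "PATHWAY"], kind="stable", ignore_index=True)


def rank_pathways_across_modules(ora_by_system: dict[str, list[pd.DataFrame]]
                                 ) -> pd.DataFrame:
    """Median −log10 adjusted p per pathway per system.

    Each system contributes one ORA table per module; a pathway's score in
    a system is the median of its −log10 adjusted p across those tables.
    """
    rows = []
    for system, tables in sorted(ora_by_system.items()):
        if not tables:
            continue
        merged = pd.concat(
            [t[["PATHWAY", "ADJ_P"]] for t in tables], ignore_index=True)
        merged["NEG_LOG10_ADJ_P"] = -np.log10(merged["ADJ_P"])
        med = merged.groupby("PATHWAY")["NEG_LOG10_ADJ_P"].median()
        for pid, val in med.items():
            rows.append({"SYSTEM": system, "PATHWAY": pid,
                         "MEDIAN_NEG_LOG10_ADJ_P": float(val)})
    out = pd.DataFrame(rows, columns=["SYSTEM", "PATHWAY",
                                      "MEDIAN_NEG_LOG10_ADJ_P"])
    return out.sort_values(["SYSTEM", "MEDIAN_NEG_LOG10_ADJ_P", "PATHWAY"],
                           ascending=[True, False, True], ignore_index=True)


def system_sharing(significant_by_system: dict[str, set[str]]
                   ) -> pd.DataFrame:
    """Partition of significant pathways by the exact set of systems sharing
    them.

    Every pathway lands in exactly one region keyed by the sorted system
    combination; region counts therefore sum to the size of the union.
    """
    union: set[str] = set()
    for s in significant_by_system.values():
        union |= s
    rows = []
    regions: dict[tuple[str, ...], list[str]] = {}
    for pw in sorted(union):
        member = tuple(sorted(s for s, pws in significant_by_system.items()
                              if pw in pws))
        regions.setdefault(member, []).append(pw)
    n_systems = len(significant_by_system)
    for member, pws in sorted(regions.items()):
        kind = ("fully_shared" if len(member) == n_systems and n_systems > 1
                else "unique" if len(member) == 1 else "partially_shared")
        rows.append({"SYSTEMS": "|".join(member), "N_SYSTEMS": len(member),
                     "KIND": kind, "N_PATHWAYS": len(pws),
                     "PATHWAYS": ";".join(pws)})
    return pd.DataFrame(rows, columns=["SYSTEMS", "N_SYSTEMS", "KIND",
                                       "N_PATHWAYS", "PATHWAYS"])


def export_subnetwork(network, hub: str, subnet: set[str],
                      rare_levels: dict[str, str] | None = None,
                      common_strength: dict[str, float] | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cytoscape-ready node and edge tables for one key-driver subnetwork.

    Node rows carry the gene, a key-driver flag, the rare-variant confidence
    level (empty if unannotated) and the common-variant −log10 p (empty if
    none); edges are the induced directed edges among subnetwork nodes.
    """
    if hub not in network:
        raise ValueError(f"key driver {hub!r} absent from the network")
    rare_levels = rare_levels or {}
    common_strength = common_strength or {}
    nodes = pd.DataFrame(
        [{"GENE": n, "IS_KD": n == hub,
          "RARE_LEVEL": rare_levels.get(n, ""),
          "COMMON_NEG_LOG10_P": common_strength.get(n, "")}
         for n in sorted(subnet)])
    edges = pd.DataFrame(
        [(a, b) for a, b in sorted(network.edges())
         if a in subnet and b in subnet],
        columns=["SOURCE", "TARGET"])
    return nodes, edges


def run_report(msea_results: pd.DataFrame,
               modules: dict[str, dict[str, list[str]]],
               library: dict[str, set[str]],
               system_map: pd.DataFrame,
               background,
               fdr_threshold: float = 0.05,
               pathway_sig_threshold: float = 0.05) -> dict:
    """ORA for every significant module, system ranking and sharing tables.

    ``system_map`` (TISSUE, SYSTEM) may map one tissue to several systems;
    counts are per system, not deduplicated across systems.
    """
    sys_of: dict[str, list[str]] = {}
    for t, s in zip(system_map["TISSUE"], system_map["SYSTEM"]):
        sys_of.setdefault(t, []).append(s)

    sig = msea_results[msea_results["FDR"] < fdr_threshold]
    ora_tables: dict[str, pd.DataFrame] = {}
    ora_by_system: dict[str, list[pd.DataFrame]] = {}
    sig_by_system: dict[str, set[str]] = {}
    for mid, tissue in zip(sig["MODULE"], sig["TISSUE"]):
        genes = modules.get(tissue, {}).get(mid)
        if not genes:
            continue
        table = ora(genes, library, background)
        ora_tables[mid] = table
        hits = set(table.loc[table["ADJ_P"] < pathway_sig_threshold,
                             "PATHWAY"])
        for system in sys_of.get(tissue, []):
            ora_by_system.setdefault(system, []).append(table)
            sig_by_system.setdefault(system, set()).update(hits)

    ranking = rank_pathways_across_modules(ora_by_system)
    sharing = system_sharing(sig_by_system)
    return {"ora": ora_tables, "ranking": ranking, "sharing": sharing}


def write_report(tables: dict, out_dir) -> None:
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for unit, df in tables["ora"].items():
        df.to_csv(out / f"ora.{unit}.tsv", sep="\t", index=False)
    tables["ranking"].to_csv(out / "pathway_ranking.tsv", sep="\t",
                             index=False)
    tables["sharing"].to_csv(out / "system_sharing.tsv", sep="\t",
                             index=False)
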