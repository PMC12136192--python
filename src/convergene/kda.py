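"""Key driver analysis (KDA).

Identifies hub genes in a directed regulatory network whose local
subnetworks are enriched for disease-associated genes (here: the union of
genes in MSEA-significant modules).  Hubs are nodes in the top quartile of
edge connections (total in+out degree, each directed edge counted once;
ties at the cutoff kept).  A hub's subnetwork is itself plus every node
within ``depth`` undirected hops.  Enrichment compares the observed overlap
between subnetwork and disease set with a null of size-matched random node
sets drawn uniformly from the network: that null is exactly hypergeometric,
so the permutation draws are taken from the hypergeometric sampler, the
overlap is standardized into a Z-score with a one-sided Gaussian p, and the
exact hypergeometric tail is reported alongside as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_fdr

RESULT_COLS = ["KD", "GROUP", "DEGREE", "SUBNET_SIZE", "OVERLAP", "NULL_MEAN",
               "NULL_SD", "Z", "P", "P_HYPERGEOM", "FDR"]


@dataclass
class KdaConfig:
    hub_top_fraction: float = 0.25
    neighborhood_depth: int = 1
    n_permutations: int = 1000
    seed: int = 0
    fdr_threshold: float = 0.05

    def validate(self) -> None:
        if not 0.0 < self.hub_top_fraction <= 1.0:
            raise ValueError("hub_top_fraction must lie in (0, 1]")
        if self.neighborhood_depth < 1:
            raise ValueError("neighborhood_depth must be >= 1")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")


def node_degree(network: nx.DiGraph) -> pd.Series:
    """Total degree (in + out), each directed edge counted once."""
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    deg = pd.Series(dict(network.degree()), name="DEGREE")
    return deg.sort_index()


def hub_candidates(degree_table: pd.Series,
                   hub_top_fraction: float = 0.25) -> list[str]:
    """Nodes at or above the top-fraction degree cutoff (ties kept).

    The cutoff is the attained degree value at the (1 − fraction) quantile
    (lower interpolation), so the candidate set always holds at least
    ``fraction × n`` nodes.
    """
    if not 0.0 < hub_top_fraction <= 1.0:
        raise ValueError("hub_top_fraction must lie in (0, 1]")
    if len(degree_table) == 0:
        raise ValueError("empty degree table")
    cutoff = np.quantile(degree_table.to_numpy(), 1.0 - hub_top_fraction,
                         method="higher")
    return sorted(degree_table.index[degree_table >= cutoff])


def subnetwork(network: nx.DiGraph, hub: str, depth: int = 1) -> set[str]:
    """Hub plus all nodes within ``depth`` hops ignoring edge direction."""
    if hub not in network:
        raise ValueError(f"hub {hub!r} not in network")
    seen = {hub}
    frontier = {hub}
    for _ in range(depth):
        nxt = set()
        for node in frontier:
            nxt.update(network.successors(node))
            nxt.update(network.predecessors(node))
        frontier = nxt - seen
        seen |= frontier
        if not frontier:
            break
    return seen


def kd_enrichment(subnet: set[str], disease_genes: set[str],
                  network_nodes: set[str], n_permutations: int,
                  rng: np.random.Generator) -> dict:
    """Overlap statistic vs a size-matched random-node-set null.

    Uniform node sets of size |subnet| have a hypergeometric overlap with
    the disease set, so null draws come straight from that sampler; the
    exact upper-tail probability is returned as ``p_hypergeom``.
    """
    n = len(network_nodes)
    k_disease = len(disease_genes & network_nodes)
    if k_disease == 0:
        raise ValueError("disease set does not intersect the network")
    s = len(subnet)
    obs = len(subnet & disease_genes)
    null = rng.hypergeometric(k_disease, n - k_disease, s,
                              size=n_permutations).astype(float)
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    if sd > 0:
        z = (obs - mean) / sd
        p = float(stats.norm.sf(z))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        flag = ""
    else:
        z, p, flag = float("nan"), 1.0, "null_sd_zero"
    p_hyp = float(stats.hypergeom.sf(obs - 1, n, k_disease, s))
    return {"OVERLAP": obs, "NULL_MEAN": mean, "NULL_SD": sd, "Z": z,
            "P": p, "P_HYPERGEOM": p_hyp, "FLAG": flag}


@dataclass
class KdaResult:
    results: pd.DataFrame
    subnetworks: dict  # (group, kd) -> set of nodes


def run_kda(networks: dict[str, nx.DiGraph],
            disease_genes_by_group: dict[str, set[str]],
            config: KdaConfig | None = None) -> KdaResult:
    """Score every hub candidate in every network group.

    Parameters
    ----------
    networks : group label -> directed network.
    disease_genes_by_group : group label -> disease gene set (e.g. the union
        of MSEA-significant module genes); groups whose disease set misses
        the network are skipped.
    """
    config = config or KdaConfig()
    config.validate()
    rows = []
    subnets: dict[tuple[str, str], set[str]] = {}
    for gi, group in enumerate(sorted(networks)):
        g = networks[group]
        nodes = set(g.nodes())
        disease = set(disease_genes_by_group.get(group, set())) & nodes
        if not disease:
            import logging
            logging.getLogger(__name__).warning(
                "group %s: empty disease set after intersection; skipped",
                group)
            continue
        deg = node_degree(g)
        hubs = hub_candidates(deg, config.hub_top_fraction)
        rng = np.random.default_rng([config.seed % (2**31), gi])
        for hub in hubs:
            sn = subnetwork(g, hub, config.neighborhood_depth)
            subnets[(group, hub)] = sn
            stat = kd_enrichment(sn, disease, nodes, config.n_permutations,
                                 rng)
            rows.append({"KD": hub, "GROUP": group,
                         "DEGREE": int(deg[hub]), "SUBNET_SIZE": len(sn),
                         **stat})
    if not rows:
        raise ValueError("no network group had a usable disease set")
    res = pd.DataFrame(rows)
    res["FDR"] = bh_fdr(res["P"])
    res = res.sort_values(["P", "KD"], kind="stable", ignore_index=True)
    return KdaResult(results=res[RESULT_COLS + ["FLAG"]], subnetworks=subnets)


def write_kda(result: KdaResult, out_dir) -> None:
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.results.to_csv(out / "kda.results.tsv", sep="\t", index=False)
    rows = [(group, kd, node)
            for (group, kd), nodes in sorted(result.subnetworks.items())
            for node in sorted(nodes)]
    pd.DataFrame(rows, columns=["GROUP", "KD", "NODE"]).to_csv(
        out / "kda.subnetworks.tsv", sep="\t", index=False)


def read_kda(out_dir) -> KdaResult:
    from pathlib import Path
    out = Path(out_dir)
    res = pd.read_csv(out / "kda.results.tsv", sep="\t",
                      dtype={"KD": str, "GROUP": str})
    sub = pd.read_csv(out / "kda.subnetworks.tsv", sep="\t", dtype=str)
    subnets: dict[tuple[str, str], set[str]] = {}
    for group, kd, node in sub.itertuples(index=False):
        subnets.setdefault((group, kd), set()).add(node)
    return KdaResult(results=res, subnetworks=subnets)
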