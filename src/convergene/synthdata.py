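"""Synthetic study-bundle generator.

Emulates the input side of a common-variant / network integration study —
GWAS summary statistics, an LD panel, tissue QTL marker-to-gene maps,
coexpression-style gene modules, directed regulatory networks, and a leveled
rare-variant gene catalog — with a recorded ground truth so that every
downstream stage (marker filtering, module enrichment, key-driver analysis,
convergence scoring) can be validated without any external data.

The generative model is deliberately minimal:

* markers sit on one synthetic chromosome, 1 kb apart, with block-diagonal
  LD (all within-block pairs share one r² value, cross-block r² is 0);
* null markers draw association p-values from Uniform(0,1); planted signal
  markers draw from Beta(a, 1) with a < 1, a monotone enrichment of small
  p-values governed by a single knob;
* genes are spaced 100 kb apart so only a minority overlap the dense marker
  region and acquire distance-based mappings; every gene gets at least one
  QTL-mapped marker per tissue;
* networks grow by degree-weighted (preferential) attachment, then planted
  hub neighborhoods are wired with a fixed fraction of disease genes;
* the rare-variant catalog assigns one confidence level per gene
  (S/1/2/3) and places a configurable fraction of catalog genes inside
  planted hub neighborhoods.

Identical ``(config, seed)`` reproduce byte-identical bundles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io

SYSTEMS = ("Brain", "Digestive", "Adipose/Immune", "Cardiovascular",
           "Endocrine", "FemaleReproductive", "MaleReproductive")


class ConfigError(ValueError):
    """Raised when a synthetic-study configuration is infeasible."""


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic study; defaults define the standard bundle."""

    n_markers: int = 10000
    n_genes: int = 5000
    n_blocks: int = 200
    block_size: int = 5
    r2_within: float = 0.8
    n_tissues: int = 2
    n_modules_per_tissue: int = 100
    module_size_range: tuple[int, int] = (15, 60)
    n_planted_modules: int = 5
    signal_fraction: float = 0.5
    signal_beta_a: float = 0.2
    network_nodes: int = 2000
    edges_per_node: int = 3
    n_planted_hubs: int = 2
    hub_neighbors: int = 40
    hub_disease_fraction: float = 0.8
    rare_level_sizes: dict = field(
        default_factory=lambda: {"S": 10, "1": 20, "2": 30, "3": 40})
    rare_hub_overlap: float = 0.5
    network_groups: tuple[str, ...] = ("brain", "peripheral")
    # layout / nuisance knobs
    marker_spacing_bp: int = 1000
    gene_spacing_bp: int = 100_000
    gene_length_bp: int = 10_000
    qtl_markers_per_gene: tuple[int, int] = (2, 5)
    assumed_window_kb: float = 20.0
    sqtl_fraction: float = 0.3
    n_pathways: int = 60
    pathway_size_range: tuple[int, int] = (10, 40)
    seed: int = 0

    def validate(self) -> None:
        counts = dict(n_markers=self.n_markers, n_genes=self.n_genes,
                      n_blocks=self.n_blocks, block_size=self.block_size,
                      n_tissues=self.n_tissues,
                      n_modules_per_tissue=self.n_modules_per_tissue,
                      network_nodes=self.network_nodes,
                      edges_per_node=self.edges_per_node,
                      hub_neighbors=self.hub_neighbors)
        for name, v in counts.items():
            if v <= 0:
                raise ConfigError(f"{name} must be positive, got {v}")
        for name, v in [("r2_within", self.r2_within),
                        ("signal_fraction", self.signal_fraction),
                        ("hub_disease_fraction", self.hub_disease_fraction),
                        ("rare_hub_overlap", self.rare_hub_overlap),
                        ("sqtl_fraction", self.sqtl_fraction)]:
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.signal_beta_a <= 0:
            raise ConfigError("signal_beta_a must be positive")
        if self.n_blocks * self.block_size > self.n_markers:
            raise ConfigError("n_blocks * block_size exceeds n_markers")
        if self.module_size_range[0] < 3:
            raise ConfigError("module_size_range.min must be >= 3")
        if self.module_size_range[0] > self.module_size_range[1]:
            raise ConfigError("module_size_range must be (min, max)")
        if self.module_size_range[1] > self.n_genes:
            raise ConfigError("module size exceeds the gene universe")
        if self.n_planted_modules > self.n_modules_per_tissue:
            raise ConfigError("more planted modules than modules per tissue")
        if self.n_planted_modules < 0 or self.n_planted_hubs < 0:
            raise ConfigError("planted counts must be >= 0")
        if self.network_nodes > self.n_genes:
            raise ConfigError("network_nodes exceeds the gene universe")
        if self.edges_per_node >= self.network_nodes:
            raise ConfigError("edges_per_node must be < network_nodes")
        if sum(self.rare_level_sizes.values()) > self.n_genes:
            raise ConfigError("rare catalog larger than the gene universe")
        if set(self.rare_level_sizes) - {"S", "1", "2", "3"}:
            raise ConfigError("rare levels must be within {S,1,2,3}")


@dataclass
class SyntheticTruth:
    """Planted ground truth written alongside every bundle."""

    planted_module_ids: list
    planted_hub_ids: list
    signal_gene_ids: list
    disease_gene_ids: list
    signal_marker_ids: list
    hub_neighborhoods: dict
    files: list
    config_echo: dict

    def to_dict(self) -> dict:
        return asdict(self)


def null_config(**overrides) -> SyntheticConfig:
    """A configuration with no planted signal of any kind."""
    base = dict(n_planted_modules=0, n_planted_hubs=0, rare_hub_overlap=0.0)
    base.update(overrides)
    return SyntheticConfig(**base)


def marker_ids(config: SyntheticConfig) -> list[str]:
    return [f"m{i:05d}" for i in range(1, config.n_markers + 1)]


def gene_ids(config: SyntheticConfig) -> list[str]:
    return [f"g{i:04d}" for i in range(1, config.n_genes + 1)]


# ---------------------------------------------------------------- markers/LD

def simulate_ld(config: SyntheticConfig):
    """Marker table plus block-diagonal LD pairs.

    Returns ``(markers, ld)``: markers have unique ids and strictly
    increasing positions on chromosome "1"; the LD table lists every
    within-block pair at ``r2_within`` and nothing else (cross-block r² is
    implicitly zero).
    """
    config.validate()
    ids = marker_ids(config)
    pos = (np.arange(config.n_markers) + 1) * config.marker_spacing_bp
    markers = pd.DataFrame({"MARKER": ids, "CHR": "1", "POS": pos})
    rows = []
    for b in range(config.n_blocks):
        block = ids[b * config.block_size:(b + 1) * config.block_size]
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                rows.append((block[i], block[j], config.r2_within))
    ld = pd.DataFrame(rows, columns=io.LD_COLS) if rows else \
        pd.DataFrame(columns=io.LD_COLS)
    return markers, ld


def simulate_gwas(config: SyntheticConfig, markers: pd.DataFrame,
                  signal_markers, rng: np.random.Generator) -> pd.DataFrame:
    """Association p-values: Uniform(0,1) null, Beta(a,1) for signal markers."""
    if config.signal_beta_a <= 0:
        raise ConfigError("signal_beta_a must be positive")
    signal = set(signal_markers)
    unknown = signal - set(markers["MARKER"])
    if unknown:
        raise ConfigError(f"signal markers outside the universe: "
                          f"{sorted(unknown)[:3]}...")
    n = len(markers)
    p = 1.0 - rng.random(n)  # (0, 1]
    is_signal = markers["MARKER"].isin(signal).to_numpy()
    if is_signal.any():
        draws = rng.beta(config.signal_beta_a, 1.0, size=int(is_signal.sum()))
        p[is_signal] = np.maximum(draws, 1e-300)
    out = markers.copy()
    out["PVALUE"] = p
    return out[io.GWAS_COLS]


# -------------------------------------------------------------- genes & maps

def simulate_genes(config: SyntheticConfig) -> pd.DataFrame:
    ids = gene_ids(config)
    start = np.arange(config.n_genes) * config.gene_spacing_bp + 45_000
    return pd.DataFrame({"GENE": ids, "CHR": "1", "START": start,
                         "END": start + config.gene_length_bp})


def tissue_names(config: SyntheticConfig) -> list[str]:
    return [f"tissue{i:02d}" for i in range(1, config.n_tissues + 1)]


def distance_window_markers(config: SyntheticConfig, gene: str) -> list[str]:
    """Marker ids inside a gene's ±assumed_window_kb distance window."""
    i = int(gene[1:]) - 1  # gene ids are g<index+1>
    w = config.assumed_window_kb * 1000.0
    start = i * config.gene_spacing_bp + 45_000
    end = start + config.gene_length_bp
    sp = config.marker_spacing_bp
    j_lo = max(1, math.ceil((start - w) / sp))
    j_hi = min(config.n_markers, math.floor((end + w) / sp))
    return [f"m{j:05d}" for j in range(j_lo, j_hi + 1)]


def simulate_maps_and_modules(config: SyntheticConfig,
                              rng: np.random.Generator):
    """QTL maps and module GMTs per tissue, plus the planted-signal record.

    Every gene receives at least one mapped marker per tissue.  Planted
    modules live in the first tissue; for each, ``ceil(signal_fraction *
    n_distinct_mapped_markers)`` of its distinct mapped markers are
    designated signal markers.

    Returns ``(maps, modules, signal_markers, signal_genes,
    planted_module_ids)`` where maps is tissue -> DataFrame and modules is
    tissue -> {module_id: [genes]}.
    """
    config.validate()
    genes = gene_ids(config)
    mids = np.asarray(marker_ids(config))
    tissues = tissue_names(config)
    lo, hi = config.qtl_markers_per_gene
    maps: dict[str, pd.DataFrame] = {}
    for t in tissues:
        rows = []
        for g in genes:
            k = int(rng.integers(lo, hi + 1))
            for m in rng.choice(mids, size=k, replace=False):
                rows.append((m, g, "eqtl"))
            if rng.random() < config.sqtl_fraction:
                rows.append((str(rng.choice(mids)), g, "sqtl"))
        df = pd.DataFrame(rows, columns=io.MAP_COLS).drop_duplicates()
        maps[t] = df.sort_values(["GENE", "MARKER", "SOURCE"],
                                 ignore_index=True)

    slo, shi = config.module_size_range
    modules: dict[str, dict[str, list[str]]] = {}
    for t in tissues:
        mods = {}
        for j in range(1, config.n_modules_per_tissue + 1):
            size = int(rng.integers(slo, shi + 1))
            members = sorted(rng.choice(genes, size=size, replace=False))
            mods[f"{t}_M{j:03d}"] = members
        modules[t] = mods

    planted_ids: list[str] = []
    signal_markers: set[str] = set()
    signal_genes: set[str] = set()
    if config.n_planted_modules > 0:
        t0 = tissues[0]
        gmap = maps[t0].groupby("GENE")["MARKER"].agg(list)
        planted_ids = list(modules[t0])[:config.n_planted_modules]
        for mid in planted_ids:
            members = modules[t0][mid]
            signal_genes.update(members)
            # the designated pool is the module's full mapped marker set as
            # the pipeline will see it: QTL links plus the distance window
            mod_markers = {m for g in members for m in gmap[g]}
            for g in members:
                mod_markers.update(distance_window_markers(config, g))
            mod_markers = sorted(mod_markers)
            k = math.ceil(config.signal_fraction * len(mod_markers))
            chosen = rng.choice(mod_markers, size=k, replace=False)
            signal_markers.update(str(m) for m in chosen)
    return maps, modules, sorted(signal_markers), sorted(signal_genes), \
        planted_ids


# ------------------------------------------------------------------ networks

def simulate_network(config: SyntheticConfig, gene_universe,
                     disease_genes, rng: np.random.Generator,
                     n_planted_hubs: int | None = None):
    """Directed preferential-attachment network with planted hub wiring.

    Growth: nodes are added one at a time; each new node sends
    ``edges_per_node`` edges to distinct existing nodes chosen with
    probability proportional to current total degree.  Planted hubs are then
    re-wired: all their incident edges are removed and replaced with
    ``hub_neighbors`` out-edges of which ``round(hub_disease_fraction *
    hub_neighbors)`` point at disease genes.

    Returns ``(edges_df, hub_ids, neighborhoods)`` with neighborhoods as
    hub -> sorted neighbor list.
    """
    config.validate()
    if n_planted_hubs is None:
        n_planted_hubs = config.n_planted_hubs
    m = config.edges_per_node
    universe = list(gene_universe)
    if config.network_nodes > len(universe):
        raise ConfigError("network_nodes exceeds the gene universe")
    nodes = [str(x) for x in
             rng.choice(universe, size=config.network_nodes, replace=False)]

    edges: set[tuple[str, str]] = set()
    repeated: list[int] = [0]
    for i in range(1, len(nodes)):
        if i <= m:
            targets = list(range(i))
        else:
            targets_set: set[int] = set()
            while len(targets_set) < m:
                targets_set.add(repeated[int(rng.integers(len(repeated)))])
            targets = sorted(targets_set)
        for t in targets:
            edges.add((nodes[i], nodes[t]))
            repeated.append(t)
        repeated.extend([i] * len(targets))

    disease = sorted(set(str(g) for g in disease_genes))
    hubs: list[str] = []
    neighborhoods: dict[str, list[str]] = {}
    if n_planted_hubs > 0:
        n_dis = int(round(config.hub_disease_fraction * config.hub_neighbors))
        eligible = [n for n in nodes if n not in disease]
        if len(eligible) < n_planted_hubs:
            raise ConfigError("not enough non-disease nodes for planted hubs")
        hubs = [str(h) for h in rng.choice(eligible, size=n_planted_hubs,
                                           replace=False)]
        for hub in hubs:
            if n_dis > 0 and len(disease) < n_dis:
                raise ConfigError("disease gene pool too small for hub wiring")
            edges = {(a, b) for a, b in edges if a != hub and b != hub}
            pool_dis = [g for g in disease if g != hub]
            chosen = list(rng.choice(pool_dis, size=n_dis, replace=False)) \
                if n_dis else []
            pool_other = [n for n in nodes
                          if n != hub and n not in disease
                          and n not in set(chosen) and n not in hubs]
            n_other = config.hub_neighbors - n_dis
            if len(pool_other) < n_other:
                raise ConfigError("node pool too small for hub wiring")
            chosen += list(rng.choice(pool_other, size=n_other, replace=False))
            for nbr in chosen:
                edges.add((hub, str(nbr)))
            neighborhoods[hub] = sorted(str(c) for c in chosen)

    df = pd.DataFrame(sorted(edges), columns=["SOURCE", "TARGET"])
    return df, hubs, neighborhoods


# -------------------------------------------------------------- rare catalog

def simulate_rare_catalog(config: SyntheticConfig, hub_neighborhoods: dict,
                          gene_universe, rng: np.random.Generator
                          ) -> pd.DataFrame:
    """Leveled gene catalog with a fixed overlap with planted neighborhoods."""
    config.validate()
    sizes = {lvl: int(config.rare_level_sizes.get(lvl, 0))
             for lvl in ("S", "1", "2", "3")}
    total = sum(sizes.values())
    pool_in = sorted({g for hub, nbrs in hub_neighborhoods.items()
                      for g in [hub, *nbrs]})
    n_in = int(round(config.rare_hub_overlap * total))
    if n_in > len(pool_in):
        raise ConfigError("rare_hub_overlap infeasible: planted "
                          f"neighborhoods hold {len(pool_in)} genes, "
                          f"need {n_in}")
    pool_out = sorted(set(str(g) for g in gene_universe) - set(pool_in))
    if total - n_in > len(pool_out):
        raise ConfigError("rare catalog larger than the available universe")
    chosen = list(rng.choice(pool_in, size=n_in, replace=False)) if n_in \
        else []
    chosen += list(rng.choice(pool_out, size=total - n_in, replace=False))
    chosen = [str(c) for c in chosen]
    rng.shuffle(chosen)
    levels = [lvl for lvl in ("S", "1", "2", "3") for _ in range(sizes[lvl])]
    return pd.DataFrame({"GENE": chosen, "LEVEL": levels}).sort_values(
        ["LEVEL", "GENE"], ignore_index=True)


# ---------------------------------------------------------------- pathways

def simulate_pathways(config: SyntheticConfig, signal_genes,
                      rng: np.random.Generator) -> dict[str, list[str]]:
    """Random pathway library; a few early pathways are signal-gene heavy."""
    genes = gene_ids(config)
    lo, hi = config.pathway_size_range
    signal = sorted(set(signal_genes))
    sets = {}
    for j in range(1, config.n_pathways + 1):
        size = int(rng.integers(lo, hi + 1))
        name = f"PW{j:03d}"
        if signal and j <= 5:
            k = min(size // 2, len(signal))
            members = set(rng.choice(signal, size=k, replace=False))
            rest = [g for g in genes if g not in members]
            members |= set(rng.choice(rest, size=size - k, replace=False))
        else:
            members = set(rng.choice(genes, size=size, replace=False))
        sets[name] = sorted(str(g) for g in members)
    return sets


def default_system_map(config: SyntheticConfig) -> pd.DataFrame:
    tissues = tissue_names(config)
    rows = [(t, SYSTEMS[i % len(SYSTEMS)]) for i, t in enumerate(tissues)]
    return pd.DataFrame(rows, columns=["TISSUE", "SYSTEM"])


# ------------------------------------------------------------- orchestration

def generate_study(config: SyntheticConfig, out_dir) -> SyntheticTruth:
    """Write a complete study bundle and its ground-truth record.

    Files: gwas.tsv, ld.tsv, genes.tsv, map.<tissue>.tsv and
    modules.<tissue>.gmt per tissue, network.<group>.edges.tsv per group,
    rare_catalog.tsv, pathways.gmt, systems.tsv, truth.json.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    files: list[str] = []

    markers, ld = simulate_ld(config)
    io.write_ld(ld, out / "ld.tsv")
    files.append("ld.tsv")

    genes = simulate_genes(config)
    genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    files.append("genes.tsv")

    maps, modules, signal_markers, signal_genes, planted_modules = \
        simulate_maps_and_modules(config, rng)
    for t, df in maps.items():
        df[io.MAP_COLS].to_csv(out / f"map.{t}.tsv", sep="\t", index=False)
        files.append(f"map.{t}.tsv")
    for t, mods in modules.items():
        io.write_gmt(mods, out / f"modules.{t}.gmt",
                     description=f"synthetic {t} module")
        files.append(f"modules.{t}.gmt")

    gwas = simulate_gwas(config, markers, signal_markers, rng)
    io.write_gwas(gwas, out / "gwas.tsv")
    files.append("gwas.tsv")

    universe = gene_ids(config)
    hub_ids: list[str] = []
    neighborhoods: dict[str, list[str]] = {}
    for gi, group in enumerate(config.network_groups):
        planted = config.n_planted_hubs if gi == 0 else 0
        edges, hubs, nbrs = simulate_network(
            config, universe, signal_genes, rng, n_planted_hubs=planted)
        edges.to_csv(out / f"network.{group}.edges.tsv", sep="\t", index=False)
        files.append(f"network.{group}.edges.tsv")
        hub_ids += hubs
        neighborhoods.update(nbrs)

    catalog = simulate_rare_catalog(config, neighborhoods, universe, rng)
    catalog.to_csv(out / "rare_catalog.tsv", sep="\t", index=False)
    files.append("rare_catalog.tsv")

    pathways = simulate_pathways(config, signal_genes, rng)
    io.write_gmt(pathways, out / "pathways.gmt", description="synthetic pathway")
    files.append("pathways.gmt")

    default_system_map(config).to_csv(out / "systems.tsv", sep="\t",
                                      index=False)
    files.append("systems.tsv")

    truth = SyntheticTruth(
        planted_module_ids=planted_modules,
        planted_hub_ids=hub_ids,
        signal_gene_ids=list(signal_genes),
        disease_gene_ids=list(signal_genes),
        signal_marker_ids=list(signal_markers),
        hub_neighborhoods=neighborhoods,
        files=sorted(files),
        config_echo={**asdict(config),
                     "module_size_range": list(config.module_size_range),
                     "qtl_markers_per_gene": list(config.qtl_markers_per_gene),
                     "pathway_size_range": list(config.pathway_size_range),
                     "network_groups": list(config.network_groups)},
    )
    io.write_json(truth.to_dict(), out / "truth.json")
    return truth


def with_overrides(config: SyntheticConfig, **overrides) -> SyntheticConfig:
    return replace(config, **overrides)
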