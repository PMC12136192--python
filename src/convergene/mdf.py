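"""Marker dependency filtering (MDF).

Maps GWAS markers to genes through tissue QTL tables and a symmetric
distance window, then prunes LD-redundant markers by greedy clumping:
markers are visited in order of ascending association p-value and each
retained marker removes every still-unclaimed marker linked to it at
r² above the threshold.  No GWAS p-value cutoff is applied anywhere, so the
full spectrum of association strengths survives for downstream null
estimation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_SOURCES = ("eqtl", "sqtl", "distance")


@dataclass
class MdfConfig:
    r2_threshold: float = 0.5
    window_kb: float = 20.0
    mapping_sources: tuple[str, ...] = VALID_SOURCES

    def validate(self) -> None:
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must lie in [0, 1]")
        if self.window_kb < 0:
            raise ValueError("window_kb must be >= 0")
        bad = set(self.mapping_sources) - set(VALID_SOURCES)
        if bad:
            raise ValueError(f"unknown mapping sources {sorted(bad)}")


@dataclass
class MdfResult:
    """Per-tissue gene→marker-set index plus the retained association table."""

    retained: pd.DataFrame           # MARKER, CHR, POS, PVALUE, NEG_LOG10_P
    gene_markers: dict               # tissue -> {gene: sorted marker list}
    n_dropped_ld: int
    config: MdfConfig = field(default_factory=MdfConfig)


def neg_log10(p: pd.Series | np.ndarray) -> np.ndarray:
    return -np.log10(np.asarray(p, dtype=float))


def map_by_distance(associations: pd.DataFrame, gene_annotations: pd.DataFrame,
                    window_kb: float = 20.0) -> pd.DataFrame:
    """Marker→gene records for markers within ±window of a gene body.

    A marker maps to a gene iff they share a chromosome label and the marker
    position falls in ``[start - W, end + W]`` (1-based inclusive,
    ``W = window_kb * 1000``).  Records are tagged with source "distance".
    """
    if window_kb < 0:
        raise ValueError("window_kb must be >= 0")
    w = window_kb * 1000.0
    shared = set(associations["CHR"]) & set(gene_annotations["CHR"])
    if len(associations) and len(gene_annotations) and not shared:
        logger.warning("no shared chromosome labels between markers and "
                       "genes; zero distance mappings")
    rows = []
    for chrom, genes_c in gene_annotations.groupby("CHR", sort=True):
        assoc_c = associations[associations["CHR"] == chrom]
        if assoc_c.empty:
            continue
        order = np.argsort(assoc_c["POS"].to_numpy(), kind="stable")
        pos = assoc_c["POS"].to_numpy()[order]
        mk = assoc_c["MARKER"].to_numpy()[order]
        lo = np.searchsorted(pos, genes_c["START"].to_numpy() - w, side="left")
        hi = np.searchsorted(pos, genes_c["END"].to_numpy() + w, side="right")
        for g, a, b in zip(genes_c["GENE"], lo, hi):
            for m in mk[a:b]:
                rows.append((m, g, "distance"))
    return pd.DataFrame(rows, columns=["MARKER", "GENE", "SOURCE"])


def merge_maps(qtl_map: pd.DataFrame, distance_map: pd.DataFrame,
               mapping_sources=VALID_SOURCES) -> pd.DataFrame:
    """Union of mapping records restricted to the enabled evidence sources.

    Exact duplicates collapse; the same (marker, gene) pair supported by
    different sources keeps one record per source.
    """
    frames = [df for df in (qtl_map, distance_map) if df is not None
              and len(df)]
    cols = ["MARKER", "GENE", "SOURCE"]
    if frames:
        merged = pd.concat([f[cols] for f in frames], ignore_index=True)
    else:
        merged = pd.DataFrame(columns=cols)
    merged = merged[merged["SOURCE"].isin(mapping_sources)]
    merged = merged.drop_duplicates(ignore_index=True)
    if merged.empty:
        raise ValueError("no mappings after source restriction")
    return merged


def ld_clump(associations: pd.DataFrame, ld_pairs: pd.DataFrame,
             r2_threshold: float = 0.5) -> pd.DataFrame:
    """Greedy LD clumping keeping the strongest association per LD block.

    Markers are taken best-p first (ties broken lexicographically by marker
    id); each retained marker discards every unclaimed marker linked to it
    by a pair with r² strictly above the threshold.  Markers never named in
    a supra-threshold pair are always retained.  Output preserves the input
    row order restricted to the retained set.
    """
    if not 0.0 <= r2_threshold <= 1.0:
        raise ValueError("r2_threshold must lie in [0, 1]")
    if len(ld_pairs) and (((ld_pairs["R2"] < 0) | (ld_pairs["R2"] > 1)).any()):
        raise ValueError("r2 outside [0, 1]")

    known = set(associations["MARKER"])
    adj: dict[str, set[str]] = {}
    n_unresolvable = 0
    strong = ld_pairs[ld_pairs["R2"] > r2_threshold] if len(ld_pairs) else \
        ld_pairs
    for a, b in zip(strong["MARKER_A"], strong["MARKER_B"]) if len(strong) \
            else []:
        if a not in known or b not in known:
            n_unresolvable += 1
            continue
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    if n_unresolvable:
        logger.info("dropped %d LD pairs with unresolvable marker ids",
                    n_unresolvable)

    order = associations.sort_values(["PVALUE", "MARKER"],
                                     kind="stable")["MARKER"]
    removed: set[str] = set()
    retained: set[str] = set()
    for m in order:
        if m in removed:
            continue
        retained.add(m)
        for nbr in adj.get(m, ()):
            if nbr not in retained:
                removed.add(nbr)
    return associations[associations["MARKER"].isin(retained)].reset_index(
        drop=True)


def run_mdf(associations: pd.DataFrame, maps: dict[str, pd.DataFrame],
            ld_pairs: pd.DataFrame, gene_annotations: pd.DataFrame | None,
            config: MdfConfig | None = None) -> MdfResult:
    """Full MDF stage: map, merge, clump, and index genes by marker set.

    Parameters
    ----------
    associations : GWAS table (MARKER, CHR, POS, PVALUE).
    maps : tissue -> QTL mapping table (MARKER, GENE, SOURCE).
    ld_pairs : LD pair table (MARKER_A, MARKER_B, R2).
    gene_annotations : gene table for distance mapping, or None to disable.
    """
    config = config or MdfConfig()
    config.validate()
    dist = None
    if gene_annotations is not None and "distance" in config.mapping_sources:
        dist = map_by_distance(associations, gene_annotations,
                               config.window_kb)

    retained = ld_clump(associations, ld_pairs, config.r2_threshold)
    if retained.empty:
        raise ValueError("no markers retained after LD clumping")
    retained = retained.copy()
    retained["NEG_LOG10_P"] = neg_log10(retained["PVALUE"])
    kept = set(retained["MARKER"])

    gene_markers: dict[str, dict[str, list[str]]] = {}
    for tissue, qtl in maps.items():
        merged = merge_maps(qtl, dist, config.mapping_sources)
        merged = merged[merged["MARKER"].isin(kept)]
        index = {g: sorted(set(sub["MARKER"]))
                 for g, sub in merged.groupby("GENE")}
        gene_markers[tissue] = {g: ms for g, ms in index.items() if ms}
    return MdfResult(retained=retained, gene_markers=gene_markers,
                     n_dropped_ld=len(associations) - len(retained),
                     config=config)


def write_mdf(result: MdfResult, out_dir) -> None:
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.retained.to_csv(out / "mdf.retained.tsv", sep="\t", index=False)
    for tissue, index in result.gene_markers.items():
        rows = [(g, ";".join(ms)) for g, ms in sorted(index.items())]
        pd.DataFrame(rows, columns=["GENE", "MARKERS"]).to_csv(
            out / f"mdf.{tissue}.genes.tsv", sep="\t", index=False)


def read_mdf(out_dir) -> MdfResult:
    from pathlib import Path
    from . import io as _io
    out = Path(out_dir)
    retained = pd.read_csv(out / "mdf.retained.tsv", sep="\t",
                           dtype={"MARKER": str, "CHR": str})
    gene_markers = {}
    for tissue, path in _io.find_tissue_files(out, "mdf", ".genes.tsv").items():
        df = pd.read_csv(path, sep="\t", dtype=str)
        gene_markers[tissue] = {g: m.split(";")
                                for g, m in zip(df["GENE"], df["MARKERS"])}
    return MdfResult(retained=retained, gene_markers=gene_markers,
                     n_dropped_ld=-1)
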