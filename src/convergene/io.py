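"""Readers and writers for the pipeline's tab-delimited interchange formats.

All on-disk formats are plain TSV (or GMT/JSON) so that bundles diff cleanly
and byte-identical reproduction under a fixed seed is checkable with a plain
file compare.  Column vocabularies:

``gwas.tsv``            MARKER, CHR, POS, PVALUE
``ld.tsv``              MARKER_A, MARKER_B, R2
``map.<tissue>.tsv``    MARKER, GENE, SOURCE      (source: eqtl | sqtl)
``genes.tsv``           GENE, CHR, START, END     (1-based inclusive)
``modules.<tissue>.gmt``   standard GMT: name, description, genes...
``network.<group>.edges.tsv``  SOURCE, TARGET     (directed)
``rare_catalog.tsv``    GENE, LEVEL               (level: S | 1 | 2 | 3)
``systems.tsv``         TISSUE, SYSTEM            (multi-membership allowed)
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

GWAS_COLS = ["MARKER", "CHR", "POS", "PVALUE"]
LD_COLS = ["MARKER_A", "MARKER_B", "R2"]
MAP_COLS = ["MARKER", "GENE", "SOURCE"]
GENE_COLS = ["GENE", "CHR", "START", "END"]


def read_gwas(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"MARKER": str, "CHR": str})
    _require(df, GWAS_COLS, path)
    if ((df["PVALUE"] <= 0) | (df["PVALUE"] > 1)).any():
        raise ValueError(f"{path}: p-values must lie in (0, 1]")
    if df["MARKER"].duplicated().any():
        raise ValueError(f"{path}: duplicate marker ids")
    return df


def write_gwas(df: pd.DataFrame, path) -> None:
    df[GWAS_COLS].to_csv(path, sep="\t", index=False)


def read_ld(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"MARKER_A": str, "MARKER_B": str})
    _require(df, LD_COLS, path)
    if ((df["R2"] < 0) | (df["R2"] > 1)).any():
        raise ValueError(f"{path}: r2 outside [0, 1]")
    if (df["MARKER_A"] == df["MARKER_B"]).any():
        raise ValueError(f"{path}: self-pairs are not allowed")
    return df


def write_ld(df: pd.DataFrame, path) -> None:
    df[LD_COLS].to_csv(path, sep="\t", index=False)


def read_map(path, tissue: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require(df, MAP_COLS, path)
    df = df.copy()
    df["TISSUE"] = tissue
    return df


def read_genes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"GENE": str, "CHR": str})
    _require(df, GENE_COLS, path)
    if (df["START"] > df["END"]).any():
        raise ValueError(f"{path}: gene START must be <= END")
    return df


def read_gmt(path) -> dict[str, set[str]]:
    """GMT: one set per line — name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: GMT line with fewer than 3 fields")
        name = fields[0]
        if name in sets:
            raise ValueError(f"{path}: duplicate set id {name!r}")
        sets[name] = set(fields[2:])
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_network(path, group: str | None = None) -> nx.DiGraph:
    """Directed edge list; self-loops rejected, duplicate edges collapsed."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require(df, ["SOURCE", "TARGET"], path)
    if (df["SOURCE"] == df["TARGET"]).any():
        raise ValueError(f"{path}: self-loops are not allowed")
    g = nx.DiGraph()
    g.add_edges_from(df.itertuples(index=False, name=None))
    if group is not None:
        g.graph["group"] = group
    return g


def write_network(g: nx.DiGraph, path) -> None:
    df = pd.DataFrame(sorted(g.edges()), columns=["SOURCE", "TARGET"])
    df.to_csv(path, sep="\t", index=False)


def read_rare_catalog(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require(df, ["GENE", "LEVEL"], path)
    bad = set(df["LEVEL"]) - {"S", "1", "2", "3"}
    if bad:
        raise ValueError(f"{path}: unknown confidence levels {sorted(bad)}")
    if df["GENE"].duplicated().any():
        raise ValueError(f"{path}: one confidence level per gene")
    return df


def read_systems(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require(df, ["TISSUE", "SYSTEM"], path)
    return df


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def find_tissue_files(directory, prefix: str, suffix: str) -> dict[str, Path]:
    """Map ``<prefix>.<tissue><suffix>`` files in a directory to tissue ids."""
    directory = Path(directory)
    out = {}
    for p in sorted(directory.glob(f"{prefix}.*{suffix}")):
        tissue = p.name[len(prefix) + 1:len(p.name) - len(suffix)]
        out[tissue] = p
    return out


def _require(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
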