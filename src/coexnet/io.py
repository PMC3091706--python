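"""Readers and writers for every on-disk format the pipeline touches.

Dialects
--------
Expression matrix
    TSV; first column is the gene id (header ``gene``), remaining columns
    are sample ids; one row per gene.
Edge list
    3-column TSV ``gene_a  gene_b  pcc`` (header included), pairs ordered
    lexicographically within and across lines, one line per undirected
    edge. A 2-column weightless variant and SIF (``gene_a  co  gene_b``)
    are also written.
GMT
    One gene set per line: term id, description, then member gene ids,
    tab-separated.
Ground truth
    2-column TSV ``gene  module``.
Clusters
    2-column TSV ``gene  cluster`` and the canonical MCL tool dialect
    (one cluster per line, members tab-separated).

All readers validate structure and raise :class:`~coexnet.errors.ParseError`
naming the offending line.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import ParseError
from .mcl import ClusterSet
from .synthetic import GeneSetCollection

__all__ = [
    "read_expression_tsv", "write_expression_tsv",
    "read_gmt", "write_gmt",
    "read_edge_list", "write_edge_list", "write_sif",
    "read_ground_truth", "write_ground_truth",
    "write_clusters_tsv", "write_clusters_mcl",
    "write_json",
]


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV into a float DataFrame indexed by gene id."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse expression TSV: {exc}") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate gene ids: {dupes[:5]}")
    if df.columns.has_duplicates:
        raise ParseError(f"{path}: duplicate sample ids")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        bad = [
            c for c in df.columns
            if not pd.api.types.is_numeric_dtype(pd.to_numeric(df[c], errors="coerce"))
            or pd.to_numeric(df[c], errors="coerce").isna().any()
        ]
        raise ParseError(
            f"{path}: non-numeric cells in column(s) {bad[:3]}"
        ) from exc
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()
        raise ParseError(f"{path}: missing values in rows {rows[:5]}")
    df.index.name = "gene"
    return df


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr = expr.copy()
    expr.index.name = "gene"
    expr.to_csv(path, sep="\t", float_format="%.10g")


def read_gmt(path: str | Path, category: str | None = None) -> GeneSetCollection:
    """Read a standard GMT file (term, description, genes...)."""
    path = Path(path)
    terms: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs term, description and "
                    f">= 1 gene (got {len(fields)} fields)"
                )
            term, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if term in terms:
                raise ParseError(f"{path}:{lineno}: duplicate term id {term!r}")
            if not genes:
                raise ParseError(f"{path}:{lineno}: term {term!r} has no genes")
            terms[term] = frozenset(genes)
            descriptions[term] = desc
    return GeneSetCollection(terms=terms, descriptions=descriptions, category=category)


def write_gmt(annot: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(annot.terms):
            desc = annot.descriptions.get(term, "")
            genes = "\t".join(sorted(annot.terms[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read the 3-column (or weightless 2-column) edge-list TSV."""
    path = Path(path)
    g = nx.Graph()
    seen: set[frozenset] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) not in (2, 3) or header[0] != "gene_a":
            raise ParseError(
                f"{path}:1: expected header 'gene_a\\tgene_b[\\tpcc]', got {header!r}"
            )
        weighted = len(header) == 3
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            u, v = fields[0], fields[1]
            if u == v:
                raise ParseError(f"{path}:{lineno}: self-loop on {u!r}")
            key = frozenset((u, v))
            if key in seen:
                raise ParseError(f"{path}:{lineno}: duplicate edge {u!r}-{v!r}")
            seen.add(key)
            if weighted:
                try:
                    w = float(fields[2])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric pcc {fields[2]!r}"
                    ) from exc
                g.add_edge(u, v, weight=w)
            else:
                g.add_edge(u, v)
    return g


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    """Write edges as gene_a/gene_b/pcc TSV, lexicographically ordered."""
    weighted = all("weight" in d for _, _, d in net.edges(data=True))
    rows = []
    for u, v, data in net.edges(data=True):
        a, b = sorted((str(u), str(v)))
        rows.append((a, b, data.get("weight")))
    rows.sort()
    with open(path, "w") as fh:
        if weighted and rows:
            fh.write("gene_a\tgene_b\tpcc\n")
            for a, b, w in rows:
                fh.write(f"{a}\t{b}\t{w:.6g}\n")
        else:
            fh.write("gene_a\tgene_b\n")
            for a, b, _ in rows:
                fh.write(f"{a}\t{b}\n")


def write_sif(net: nx.Graph, path: str | Path, relation: str = "co") -> None:
    """SIF-compatible output (gene_a, relation, gene_b)."""
    rows = sorted(tuple(sorted((str(u), str(v)))) for u, v in net.edges())
    with open(path, "w") as fh:
        for a, b in rows:
            fh.write(f"{a}\t{relation}\t{b}\n")


def read_ground_truth(path: str | Path) -> dict[str, str]:
    path = Path(path)
    out: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene", "module"]:
            raise ParseError(f"{path}:1: expected header 'gene\\tmodule'")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields")
            gene, module = fields
            if gene in out:
                raise ParseError(f"{path}:{lineno}: duplicate gene {gene!r}")
            out[gene] = module
    return out


def write_ground_truth(module_map: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tmodule\n")
        for gene in sorted(module_map):
            fh.write(f"{gene}\t{module_map[gene]}\n")


def write_clusters_tsv(cs: ClusterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tcluster\n")
        for i, cluster in enumerate(cs.clusters):
            for gene in cluster:
                fh.write(f"{gene}\t{i}\n")


def write_clusters_mcl(cs: ClusterSet, path: str | Path) -> None:
    """One cluster per line, members tab-separated (canonical MCL dialect)."""
    with open(path, "w") as fh:
        for cluster in cs.clusters:
            fh.write("\t".join(str(g) for g in cluster) + "\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
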