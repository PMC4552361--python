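"""Readers and writers for all input and output file formats.

Inputs: FunCoup-style gene edge lists, GO annotations (two-column TSV or
GAF 2.x), expression matrices with a sample design table, and DEG tables.
Outputs: Cytoscape-importable SIF, GraphML and attribute TSVs for GO–GO
networks. All TSVs are UTF-8, tab-delimited; lines starting with ``#`` (and
``!`` in GAF) are ignored.
"""

from __future__ import annotations

import math
import os
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .types import (
    ConsistencyError,
    DegTable,
    ExpressionData,
    GoAnnotation,
    GoGoNetwork,
    ParseError,
    check_gene_network,
)

__all__ = [
    "read_network",
    "write_network",
    "read_go_annotation",
    "write_go_annotation",
    "read_deg_table",
    "write_deg_table",
    "read_expression",
    "write_expression",
    "write_gogo",
    "read_gogo_graphml",
]

_HEADER_TOKENS = {
    "gene",
    "genea",
    "geneb",
    "gene1",
    "gene2",
    "protein1",
    "protein2",
    "source",
    "target",
    "score",
    "confidence",
    "pfc",
}


def _data_lines(path: str | os.PathLike, comment: str = "#"):
    """Yield (line_number, stripped_line) skipping blanks and comments."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith(comment):
                continue
            yield lineno, line


def _looks_like_header(fields: list[str]) -> bool:
    return any(f.strip().lower() in _HEADER_TOKENS for f in fields[:3])


# ---------------------------------------------------------------------------
# Interactome edge list (FunCoup dialect)
# ---------------------------------------------------------------------------


def read_network(
    path: str | os.PathLike,
    min_score: float | None = None,
    score_column: int = 2,
) -> nx.Graph:
    """Read an undirected gene network from a FunCoup-style edge list.

    The first two whitespace/tab-separated columns are gene identifiers; the
    column at ``score_column`` (0-based, default the third column), if
    present and numeric, is stored as edge attribute ``score``. Self-loops
    are dropped, duplicate edges (in either orientation) are merged, and a
    header line is auto-detected. With ``min_score``, edges whose score is
    below it — or that have no score — are dropped.
    """
    graph = nx.Graph()
    first = True
    n_rows = 0
    for lineno, line in _data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if first:
            first = False
            if _looks_like_header(fields):
                continue
        if len(fields) < 2:
            raise ParseError(
                f"{path}: line {lineno}: expected >=2 columns, got {len(fields)}"
            )
        a, b = fields[0].strip(), fields[1].strip()
        n_rows += 1
        if a == b:
            continue
        score = None
        if score_column < len(fields):
            try:
                score = float(fields[score_column])
            except ValueError:
                score = None
        if min_score is not None and (score is None or score < min_score):
            continue
        if score is not None:
            graph.add_edge(a, b, score=score)
        else:
            graph.add_edge(a, b)
    if n_rows == 0:
        raise ParseError(f"{path}: no edges found (empty network)")
    return check_gene_network(graph)


def write_network(graph: nx.Graph, path: str | os.PathLike) -> None:
    """Write a gene network as a 2- or 3-column TSV (deterministic order)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#geneA\tgeneB\tscore\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            score = graph.edges[a, b].get("score")
            if score is None:
                fh.write(f"{a}\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\t{score:.12g}\n")


# ---------------------------------------------------------------------------
# GO annotation: two-column TSV or GAF 2.x
# ---------------------------------------------------------------------------


def read_go_annotation(
    path: str | os.PathLike,
    format: str = "tsv",
    aspect: str = "P",
) -> GoAnnotation:
    """Read gene → GO-term annotations.

    ``format="tsv"``: two columns (gene, term). ``format="gaf"``: GAF 2.x;
    rows are filtered to the given ontology aspect (default ``P``, biological
    process) and rows whose qualifier contains ``NOT`` are excluded.
    """
    gene_to_terms: dict[str, set[str]] = {}
    if format == "tsv":
        first = True
        for lineno, line in _data_lines(path):
            fields = line.split("\t") if "\t" in line else line.split()
            if first:
                first = False
                if _looks_like_header(fields):
                    continue
            if len(fields) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
                )
            gene, term = fields[0].strip(), fields[1].strip()
            gene_to_terms.setdefault(gene, set()).add(term)
    elif format == "gaf":
        for lineno, line in _data_lines(path, comment="!"):
            fields = line.split("\t")
            if len(fields) < 15:
                raise ParseError(
                    f"{path}: line {lineno}: GAF rows need >=15 columns, "
                    f"got {len(fields)}"
                )
            qualifier = fields[3]
            if "NOT" in qualifier.split("|"):
                continue
            if fields[8].strip() != aspect:
                continue
            gene = fields[2].strip() or fields[1].strip()
            term = fields[4].strip()
            gene_to_terms.setdefault(gene, set()).add(term)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return GoAnnotation({g: frozenset(ts) for g, ts in gene_to_terms.items()})


def write_go_annotation(annot: GoAnnotation, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#gene\tterm\n")
        for gene in sorted(annot.gene_to_terms):
            for term in sorted(annot.gene_to_terms[gene]):
                fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# DEG table
# ---------------------------------------------------------------------------


def read_deg_table(path: str | os.PathLike) -> DegTable:
    """Read a (gene, day, adj_p) TSV produced by an upstream DE analysis."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["gene", "day", "adj_p"], dtype=str)
    if len(df) and df.iloc[0]["gene"].strip().lower() in ("gene", "geneid"):
        df = df.iloc[1:]
    if df.empty:
        raise ParseError(f"{path}: no DEG records found")
    return DegTable(df)


def write_deg_table(table: DegTable, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#gene\tday\tadj_p\n")
        df = table.records.sort_values(["gene", "day"])
        for _, row in df.iterrows():
            fh.write(f"{row['gene']}\t{row['day']}\t{row['adj_p']:.12g}\n")


# ---------------------------------------------------------------------------
# Expression matrix + design
# ---------------------------------------------------------------------------


def read_expression(
    values_path: str | os.PathLike,
    design_path: str | os.PathLike,
    log2_cpm: bool = False,
) -> ExpressionData:
    """Read a genes × samples matrix TSV and its sample design TSV.

    The design table has columns ``sample``, ``treatment``, ``day``,
    ``replicate``. Columns of the matrix are matched to design rows by
    sample name. With ``log2_cpm=True`` raw counts are converted to
    log2(1 + counts-per-million) as a convenience; by default values are
    assumed already normalised.
    """
    values = pd.read_csv(values_path, sep="\t", comment="#", index_col=0)
    values.columns = values.columns.map(str)
    design = pd.read_csv(design_path, sep="\t", comment="#", dtype=str)
    design.columns = [c.lstrip("#").strip().lower() for c in design.columns]
    required = {"sample", "treatment", "day", "replicate"}
    if not required.issubset(design.columns):
        raise ParseError(
            f"{design_path}: design table must have columns {sorted(required)}"
        )
    if log2_cpm:
        total = values.sum(axis=0)
        values = np.log2(1.0 + 1e6 * values / total)
    return ExpressionData(values=values, design=design)


def write_expression(
    expr: ExpressionData,
    values_path: str | os.PathLike,
    design_path: str | os.PathLike,
) -> None:
    expr.values.to_csv(values_path, sep="\t", index_label="gene",
                       float_format="%.12g")
    design = expr.design.reset_index()
    design.to_csv(design_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GO–GO network export (Cytoscape-importable)
# ---------------------------------------------------------------------------


def _interaction_label(data: dict) -> str:
    if "day_pair" in data and data["day_pair"] is not None:
        d, dn = data["day_pair"]
        return f"t{d}->t{dn}"
    return "coexpr"


def write_gogo(
    network: GoGoNetwork,
    out_dir: str | os.PathLike,
    formats: Iterable[str] = ("sif", "graphml", "edge_tsv", "node_tsv"),
    prefix: str = "gogo",
) -> list[Path]:
    """Export a GO–GO network in Cytoscape-importable formats.

    SIF uses interaction type ``t{d}->t{d+1}`` for temporal edges and
    ``coexpr`` for condition edges. The edge TSV carries ``link_count``,
    ``p_value`` and ``neg_log10_p``; the node TSV carries ``gene_count`` and
    ``de_fraction``. GraphML keeps every attribute, typed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    formats = set(formats)
    unknown = formats - {"sif", "graphml", "edge_tsv", "node_tsv"}
    if unknown:
        raise ValueError(f"unknown export formats: {sorted(unknown)}")
    written: list[Path] = []

    edges = sorted(network.graph.edges(data=True), key=lambda e: (e[0], e[1]))

    if "sif" in formats:
        path = out_dir / f"{prefix}.sif"
        with open(path, "w", encoding="utf-8") as fh:
            for u, v, data in edges:
                fh.write(f"{u}\t{_interaction_label(data)}\t{v}\n")
        written.append(path)

    if "edge_tsv" in formats:
        path = out_dir / f"{prefix}_edges.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\tinteraction\ttarget\tlink_count\tp_value\tneg_log10_p\n")
            for u, v, data in edges:
                fh.write(
                    f"{u}\t{_interaction_label(data)}\t{v}\t"
                    f"{data.get('link_count', '')}\t"
                    f"{data.get('p_value'):.12g}\t"
                    f"{data.get('neg_log10_p'):.12g}\n"
                )
        written.append(path)

    if "node_tsv" in formats:
        path = out_dir / f"{prefix}_nodes.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("term\tname\tgene_count\tde_fraction\n")
            for n in sorted(network.graph.nodes):
                data = network.graph.nodes[n]
                name = network.term_names.get(n, n)
                gc = data.get("gene_count", "")
                frac = data.get("de_fraction")
                frac_s = "" if frac is None else f"{frac:.12g}"
                fh.write(f"{n}\t{name}\t{gc}\t{frac_s}\n")
        written.append(path)

    if "graphml" in formats:
        path = out_dir / f"{prefix}.graphml"
        g = network.graph.copy()
        g.graph["kind"] = network.kind
        for u, v, data in g.edges(data=True):
            # GraphML cannot carry tuples; flatten day_pair
            if data.get("day_pair") is not None:
                d, dn = data.pop("day_pair")
                data["day_from"] = int(d)
                data["day_to"] = int(dn)
            else:
                data.pop("day_pair", None)
            data["interaction"] = _interaction_label(
                {"day_pair": (data["day_from"], data["day_to"])}
                if "day_from" in data
                else {}
            )
            for k in list(data):
                if data[k] is None:
                    del data[k]
        for n, data in g.nodes(data=True):
            data["name"] = network.term_names.get(n, n)
            for k in list(data):
                if data[k] is None:
                    del data[k]
        nx.write_graphml(g, path)
        written.append(path)

    return written


def read_gogo_graphml(path: str | os.PathLike) -> GoGoNetwork:
    """Read back a GO–GO network written by :func:`write_gogo` (GraphML)."""
    g = nx.read_graphml(path)
    kind = g.graph.get("kind", "condition")
    if kind == "temporal" and not g.is_multigraph():
        g = nx.read_graphml(path, force_multigraph=True)
    term_names = {n: data.pop("name", n) for n, data in g.nodes(data=True)}
    for _, _, data in g.edges(data=True):
        if "day_from" in data:
            data["day_pair"] = (int(data.pop("day_from")), int(data.pop("day_to")))
        data.pop("interaction", None)
    g.graph.pop("kind", None)
    return GoGoNetwork(graph=g, kind=kind, term_names=term_names)


def neg_log10(p: float) -> float:
    return -math.log10(p)
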