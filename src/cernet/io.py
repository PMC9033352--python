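"""Readers and writers for every file format the pipeline touches.

Formats
-------
* interaction pair TSV: two tab-separated identifier columns, ``#`` comments;
* DE table TSV: named columns ``gene``, ``logFC``, ``pvalue`` (case-insensitive,
  optional ``adj_pvalue``); the numeric parser accepts both the ASCII minus
  and the typographic minus (U+2212) found in published tables;
* expression matrix TSV: header row of sample ids, a second ``group`` line of
  case/control labels, then one row per gene;
* GMT gene sets (term, description, members);
* network export: SIF, GraphML and a round-trippable edge TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import TYPE_CHECKING, Union

import numpy as np
import networkx as nx

from .types import (
    EDGE_KINDS,
    LNC_MI,
    MI_M,
    DERecord,
    ExpressionMatrix,
    FormatError,
    GeneSetCollection,
    InteractionTable,
)

if TYPE_CHECKING:  # pragma: no cover
    from .network import TripleNetwork

logger = logging.getLogger("cernet")

PathLike = Union[str, Path]

# header aliases for DE tables, normalised by _norm_header
_GENE_KEYS = {"gene", "geneid", "genesymbol"}
_LOGFC_KEYS = {"logfc"}
_P_KEYS = {"pvalue", "p", "pval"}
_ADJ_KEYS = {"adjpvalue", "adjp", "padj", "fdr", "adjpval"}


def _norm_header(token: str) -> str:
    return token.strip().lower().replace(" ", "").replace(".", "").replace("_", "").replace("-", "")


def parse_number(token: str, *, path: PathLike = "<str>", lineno: int = 0) -> float:
    """Parse a float, accepting the typographic minus sign (U+2212)."""
    try:
        return float(token.strip().replace("−", "-"))
    except ValueError:
        raise FormatError(f"{path}:{lineno}: not a number: {token!r}") from None


def _data_lines(path: PathLike):
    """Yield (lineno, line) for non-empty, non-comment lines."""
    p = Path(path)
    if not p.exists():
        raise FormatError(f"file not found: {p}")
    with p.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_interaction_table(path: PathLike, edge_kind: str) -> InteractionTable:
    """Read a two-column interaction pair TSV.

    Column 1 is the source (lncRNA or miRNA), column 2 the target.
    Duplicate pairs are collapsed (count logged); first-occurrence order is
    preserved.  An empty table or a line with fewer than two columns is an
    error naming the line.
    """
    if edge_kind not in EDGE_KINDS:
        raise ValueError(f"edge_kind must be one of {EDGE_KINDS}")
    pairs: list[tuple[str, str]] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise FormatError(
                f"{path}:{lineno}: expected at least 2 tab-separated identifier columns"
            )
        pairs.append((fields[0].strip(), fields[1].strip()))
    if not pairs:
        raise FormatError(f"{path}: interaction table is empty")
    return InteractionTable.from_pairs(pairs, edge_kind)


def write_interaction_table(table: InteractionTable, path: PathLike) -> None:
    with Path(path).open("w") as handle:
        handle.write(f"# {table.edge_kind} interaction pairs\n")
        for src, tgt in table.pairs:
            handle.write(f"{src}\t{tgt}\n")


def read_de_table(path: PathLike) -> list[DERecord]:
    """Read a differential-expression TSV with a named header row.

    Required columns (case-insensitive): ``gene``, ``logFC``, ``pvalue``;
    optional ``adj_pvalue``.  P-values outside [0, 1] or non-numeric cells
    raise :class:`FormatError` naming the line.
    """
    lines = list(_data_lines(path))
    if not lines:
        raise FormatError(f"{path}: DE table is empty")
    header_lineno, header = lines[0]
    columns = {_norm_header(tok): i for i, tok in enumerate(header.split("\t"))}

    def find(keys: set[str]):
        for key in keys:
            if key in columns:
                return columns[key]
        return None

    i_gene, i_logfc, i_p = find(_GENE_KEYS), find(_LOGFC_KEYS), find(_P_KEYS)
    i_adj = find(_ADJ_KEYS)
    if i_gene is None or i_logfc is None or i_p is None:
        raise FormatError(
            f"{path}:{header_lineno}: header must name gene, logFC and pvalue columns"
        )

    records = []
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        needed = max(i_gene, i_logfc, i_p)
        if len(fields) <= needed:
            raise FormatError(f"{path}:{lineno}: too few columns")
        pvalue = parse_number(fields[i_p], path=path, lineno=lineno)
        if not 0.0 <= pvalue <= 1.0:
            raise FormatError(f"{path}:{lineno}: p-value {pvalue} outside [0, 1]")
        adj = None
        if i_adj is not None and i_adj < len(fields) and fields[i_adj].strip() not in ("", "NA"):
            adj = parse_number(fields[i_adj], path=path, lineno=lineno)
            if not 0.0 <= adj <= 1.0:
                raise FormatError(f"{path}:{lineno}: adjusted p-value {adj} outside [0, 1]")
        records.append(
            DERecord(
                gene_id=fields[i_gene].strip(),
                logfc=parse_number(fields[i_logfc], path=path, lineno=lineno),
                pvalue=pvalue,
                adj_pvalue=adj,
            )
        )
    return records


def write_de_table(records: list[DERecord], path: PathLike) -> None:
    has_adj = any(r.adj_pvalue is not None for r in records)
    with Path(path).open("w") as handle:
        handle.write("gene\tlogFC\tpvalue" + ("\tadj_pvalue\n" if has_adj else "\n"))
        for r in records:
            row = f"{r.gene_id}\t{r.logfc:.6g}\t{r.pvalue:.6g}"
            if has_adj:
                row += f"\t{r.adj_pvalue:.6g}" if r.adj_pvalue is not None else "\tNA"
            handle.write(row + "\n")


def read_expression_matrix(path: PathLike) -> ExpressionMatrix:
    """Read a genes × samples log2 expression TSV.

    Line 1: ``gene`` then sample ids.  Line 2: ``group`` then a
    case/control label per sample.  Remaining lines: gene id and one value
    per sample.
    """
    lines = list(_data_lines(path))
    if len(lines) < 3:
        raise FormatError(f"{path}: expression matrix needs header, group line and data")
    _, header = lines[0]
    sample_ids = [tok.strip() for tok in header.split("\t")[1:]]
    grp_lineno, grp_line = lines[1]
    grp_fields = grp_line.split("\t")
    if _norm_header(grp_fields[0]) != "group":
        raise FormatError(f"{path}:{grp_lineno}: second line must start with 'group'")
    group_labels = [tok.strip() for tok in grp_fields[1:]]

    gene_ids, rows = [], []
    for lineno, line in lines[2:]:
        fields = line.split("\t")
        if len(fields) != len(sample_ids) + 1:
            raise FormatError(
                f"{path}:{lineno}: expected {len(sample_ids) + 1} columns, got {len(fields)}"
            )
        gene_ids.append(fields[0].strip())
        rows.append([parse_number(tok, path=path, lineno=lineno) for tok in fields[1:]])
    return ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=np.array(rows, dtype=float),
        group_labels=group_labels,
    )


def write_expression_matrix(matrix: ExpressionMatrix, path: PathLike) -> None:
    with Path(path).open("w") as handle:
        handle.write("gene\t" + "\t".join(matrix.sample_ids) + "\n")
        handle.write("group\t" + "\t".join(matrix.group_labels) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            handle.write(gid + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def read_gmt(path: PathLike) -> GeneSetCollection:
    """Read a GMT gene-set file: term, description, then member ids."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in _data_lines(path):
        fields = [tok.strip() for tok in line.split("\t")]
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs term, description, >=1 member")
        term_id, description = fields[0], fields[1]
        if term_id in sets:
            raise FormatError(f"{path}:{lineno}: duplicate term id {term_id!r}")
        members = frozenset(tok for tok in fields[2:] if tok)
        if not members:
            raise FormatError(f"{path}:{lineno}: gene set {term_id!r} has no members")
        sets[term_id] = (description, members)
    if not sets:
        raise FormatError(f"{path}: GMT file is empty")
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: PathLike) -> None:
    with Path(path).open("w") as handle:
        for term_id, (description, members) in collection.sets.items():
            handle.write("\t".join([term_id, description, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# network export / import

_SIF_LABELS = {LNC_MI: "lnc-mi", MI_M: "mi-m"}
_SIF_KINDS = {v: k for k, v in _SIF_LABELS.items()}


def write_network(network: "TripleNetwork", path: PathLike, format: str = "tsv") -> None:
    """Export a tripartite network for external viewers.

    ``sif`` writes Cytoscape simple-interaction lines with relation labels
    ``lnc-mi`` / ``mi-m``; ``graphml`` carries a ``partition`` node
    attribute and a ``kind`` edge attribute; ``tsv`` is a three-column edge
    list whose read-back reproduces the edge set exactly.
    """
    if len(network.graph) == 0:
        raise ValueError("refusing to export an empty network")
    fmt = format.lower()
    if fmt == "graphml":
        nx.write_graphml(network.graph, str(path))
    elif fmt in ("sif", "tsv"):
        with Path(path).open("w") as handle:
            if fmt == "tsv":
                handle.write("source\tinteraction\ttarget\n")
            for src, tgt, kind in network.iter_edges():
                handle.write(f"{src}\t{_SIF_LABELS[kind]}\t{tgt}\n")
    else:
        raise ValueError(f"unknown network format {format!r}; use sif, graphml or tsv")


def read_network(path: PathLike, format: str = "tsv") -> "TripleNetwork":
    """Read a network previously written by :func:`write_network`."""
    from .network import TripleNetwork, _graph_from_edge_lists

    fmt = format.lower()
    if fmt == "graphml":
        graph = nx.read_graphml(str(path))
        clean = nx.Graph()
        for node, data in graph.nodes(data=True):
            clean.add_node(str(node), partition=data["partition"])
        for u, v, data in graph.edges(data=True):
            clean.add_edge(str(u), str(v), kind=data["kind"])
        return TripleNetwork(clean)
    if fmt != "tsv":
        raise ValueError(f"unknown network format {format!r}; use graphml or tsv")

    lnc_mi, mi_m = [], []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if _norm_header(fields[0]) == "source":
            continue
        if len(fields) != 3 or fields[1] not in _SIF_KINDS:
            raise FormatError(f"{path}:{lineno}: expected 'source<TAB>lnc-mi|mi-m<TAB>target'")
        kind = _SIF_KINDS[fields[1]]
        (lnc_mi if kind == LNC_MI else mi_m).append((fields[0].strip(), fields[2].strip()))
    if not lnc_mi and not mi_m:
        raise FormatError(f"{path}: network file has no edges")
    return TripleNetwork(_graph_from_edge_lists(lnc_mi, mi_m))
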