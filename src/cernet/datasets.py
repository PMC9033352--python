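"""Bundled example tables.

Small published screening and centrality tables for atherosclerotic plaque
formation vs control vascular tissue (GEO series GSE97210 for lncRNAs,
GSE43292 for mRNAs), transcribed as plain TSV.  They are the package's
worked-example inputs: the DE tables feed :func:`cernet.diffexp.screen`
and the centrality table feeds :func:`cernet.topology.select_hub_lncrna`.
"""

from __future__ import annotations

from importlib import resources

from .io import read_de_table
from .types import CentralityRecord, DERecord


def _data_path(name: str):
    return resources.files("cernet.data") / name


def load_plaque_del_table() -> list[DERecord]:
    """The 39 differentially expressed lncRNAs screened from GSE97210."""
    return read_de_table(_data_path("gse97210_dels.tsv"))


def load_plaque_dem_table() -> list[DERecord]:
    """The 9 differentially expressed mRNAs screened from GSE43292."""
    return read_de_table(_data_path("gse43292_dems.tsv"))


def _read_centrality(name: str) -> list[CentralityRecord]:
    records = []
    with _data_path(name).open() as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("node\t"):
                continue
            node, partition, degree, closeness, betweenness = line.split("\t")
            records.append(
                CentralityRecord(
                    node=node,
                    partition=partition,
                    degree=int(degree),
                    closeness=float(closeness),
                    betweenness=float(betweenness),
                )
            )
    return records


def load_plaque_centrality_table() -> list[CentralityRecord]:
    """Published centralities of the plaque ceRNA network's ranked nodes
    (6 lncRNAs, top-3 miRNAs, 8 mRNAs)."""
    return (
        _read_centrality("cerna_centrality_lncrna.tsv")
        + _read_centrality("cerna_centrality_mirna.tsv")
        + _read_centrality("cerna_centrality_mrna.tsv")
    )
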