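"""End-to-end pipeline orchestration with a run manifest.

``run_all`` wires the stages in order — simulate (or load inputs) →
differential-expression screening → global triple network → candidate
subnetwork → hypergeometric competing-pair test → ceRNA network assembly →
centrality/hub analysis → enrichment — writing every intermediate table
plus a ``manifest.json`` with config snapshot, input digests, per-stage
record counts and the seed, so a rerun with identical inputs is verifiably
identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Optional

import yaml

from . import __version__
from .cerna import assemble_cerna_network, test_all_pairs
from .diffexp import compute_de, screen, split_by_regulation
from .enrichment import enrich, group_terms
from .io import (
    read_de_table,
    read_expression_matrix,
    read_gmt,
    read_interaction_table,
    write_de_table,
    write_expression_matrix,
    write_gmt,
    write_interaction_table,
    write_network,
)
from .network import build_global, map_degs
from .simulate import (
    SyntheticConfig,
    generate_expression,
    generate_gmt,
    generate_interactions,
)
from .topology import compute_centralities, hub_ego_network, select_hub_lncrna, select_key_mirna
from .types import LNC_MI, MI_M, CernetError, ScreenConfig

logger = logging.getLogger("cernet")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {"enabled": True},
    "inputs": {},
    "screen": {"preset": "methods"},
    "cerna": {"fdr": 0.01, "universe": "auto", "tail": "literal"},
    "topology": {"min_degree": 5, "top_k": 3},
    "enrichment": {"enabled": True, "kappa": 0.4, "p": 0.05},
}


def load_config(path) -> dict[str, Any]:
    """Read a YAML run config, layered over the defaults."""
    with Path(path).open() as handle:
        user = yaml.safe_load(handle) or {}
    config = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _screen_config(section: dict[str, Any]) -> ScreenConfig:
    base = ScreenConfig.preset(section.get("preset", "methods"))
    overrides = {
        k: section[k]
        for k in ("logfc_threshold", "p_threshold", "use_adjusted")
        if k in section
    }
    if overrides:
        base = ScreenConfig(
            logfc_threshold=overrides.get("logfc_threshold", base.logfc_threshold),
            p_threshold=overrides.get("p_threshold", base.p_threshold),
            use_adjusted=overrides.get("use_adjusted", base.use_adjusted),
        )
    return base


def run_all(config: dict[str, Any] | str | Path, outdir, seed: Optional[int] = None) -> dict[str, Any]:
    """Run the full pipeline; returns the manifest dictionary.

    ``config`` is either a loaded config dict or a path to a YAML file.
    ``seed`` overrides the config seed.  All outputs (de.tsv, net.graphml,
    pairs.tsv, centrality.tsv, hub.txt, enrich.tsv, manifest.json) land in
    ``outdir``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    if seed is not None:
        config = {**config, "seed": int(seed)}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    inputs_digests: dict[str, str] = {}

    # -- stage: inputs ------------------------------------------------------
    sim_section = dict(config.get("simulate") or {})
    simulate_enabled = sim_section.pop("enabled", False)
    truth = None
    if simulate_enabled:
        logger.info("[simulate] generating synthetic inputs")
        sim_config = SyntheticConfig(**{**sim_section, "seed": int(config.get("seed", 0))})
        lnc_mi, mi_m, truth = generate_interactions(sim_config)
        matrix = generate_expression(sim_config, truth)
        gene_sets = generate_gmt(sim_config, truth)
        indir = outdir / "inputs"
        indir.mkdir(exist_ok=True)
        write_interaction_table(lnc_mi, indir / "lnc_mi.tsv")
        write_interaction_table(mi_m, indir / "mi_m.tsv")
        write_expression_matrix(matrix, indir / "expression.tsv")
        write_gmt(gene_sets, indir / "sets.gmt")
        truth.to_json(indir / "truth.json")
        de_records = compute_de(matrix)
    else:
        inputs = config.get("inputs") or {}
        for key in ("lnc_mi", "mi_m"):
            if key not in inputs:
                raise CernetError(
                    f"[inputs] missing interaction table {key!r} and simulation is disabled"
                )
        lnc_mi = read_interaction_table(inputs["lnc_mi"], LNC_MI)
        mi_m = read_interaction_table(inputs["mi_m"], MI_M)
        gene_sets = read_gmt(inputs["gmt"]) if inputs.get("gmt") else None
        if inputs.get("expression"):
            de_records = compute_de(read_expression_matrix(inputs["expression"]))
        elif inputs.get("de_table"):
            de_records = read_de_table(inputs["de_table"])
        else:
            raise CernetError("[inputs] need 'expression' or 'de_table' when not simulating")
        for key, value in inputs.items():
            inputs_digests[key] = _digest(Path(value))

    # -- stage: differential expression -------------------------------------
    logger.info("[de-screen] screening %d records", len(de_records))
    screened = screen(de_records, _screen_config(config.get("screen") or {}))
    up, down = split_by_regulation(screened)
    counts["de_records"] = len(de_records)
    counts["screened"] = len(screened)
    counts["upregulated"] = len(up)
    counts["downregulated"] = len(down)
    write_de_table(screened, outdir / "de.tsv")

    lnc_universe = lnc_mi.sources
    m_universe = mi_m.targets
    dels = [r for r in screened if r.gene_id in lnc_universe]
    dems = [r for r in screened if r.gene_id in m_universe]
    counts["dels"] = len(dels)
    counts["dems"] = len(dems)
    logger.info("[de-screen] %d DELs, %d DEMs after screening", len(dels), len(dems))

    # -- stage: networks -----------------------------------------------------
    global_net = build_global(lnc_mi, mi_m)
    counts["global_nodes"] = len(global_net.graph)
    counts["global_edges"] = global_net.n_edges
    logger.info("[build-net] global network: %d nodes, %d edges",
                counts["global_nodes"], counts["global_edges"])
    candidate = map_degs(global_net, dels, dems)
    counts["candidate_nodes"] = len(candidate.graph)

    # -- stage: competing-pair test ------------------------------------------
    cerna_section = config.get("cerna") or {}
    pairs = test_all_pairs(
        candidate,
        global_network=global_net,
        universe_size=cerna_section.get("universe", "auto"),
        tail=cerna_section.get("tail", "literal"),
    )
    fdr_threshold = float(cerna_section.get("fdr", 0.01))
    cerna_net = assemble_cerna_network(pairs, fdr_threshold=fdr_threshold)
    counts["tested_pairs"] = len(pairs)
    counts["significant_pairs"] = len(cerna_net.pairs)
    logger.info("[cerna-test] %d candidate pairs, %d significant at FDR < %g",
                len(pairs), len(cerna_net.pairs), fdr_threshold)
    _write_pairs(pairs, outdir / "pairs.tsv")
    if cerna_net.n_edges:
        write_network(cerna_net, outdir / "net.graphml", format="graphml")
        write_network(cerna_net, outdir / "net.sif", format="sif")

    # -- stage: topology -----------------------------------------------------
    hub_name, key_mirna = None, None
    if cerna_net.n_edges:
        topo_section = config.get("topology") or {}
        records = compute_centralities(cerna_net)
        _write_centrality(records, outdir / "centrality.tsv")
        hub = select_hub_lncrna(records, min_degree=int(topo_section.get("min_degree", 5)))
        hub_name = hub.node
        ego = hub_ego_network(cerna_net, hub.node)
        if ego.n_edges:
            write_network(ego, outdir / "hub_ego.graphml", format="graphml")
        try:
            key_mirna = select_key_mirna(
                records, cerna_net, hub.node, top_k=int(topo_section.get("top_k", 3))
            )
        except CernetError as exc:
            logger.warning("[topology] key-miRNA selection failed: %s", exc)
        (outdir / "hub.txt").write_text(
            f"hub_lncrna\t{hub.node}\n"
            f"dominant\t{hub.dominant}\n"
            f"key_mirna\t{key_mirna if key_mirna else 'NA'}\n"
        )
        counts["hub_ego_nodes"] = len(ego.graph)
        logger.info("[topology] hub lncRNA: %s (dominant=%s), key miRNA: %s",
                    hub.node, hub.dominant, key_mirna)

    # -- stage: enrichment ---------------------------------------------------
    enrich_section = config.get("enrichment") or {}
    if enrich_section.get("enabled", True) and gene_sets is not None and dems:
        universe = gene_sets.all_members
        query = {r.gene_id for r in dems}
        enriched = enrich(query, gene_sets, universe=universe,
                          p_threshold=float(enrich_section.get("p", 0.05)))
        grouped = group_terms(enriched, gene_sets, universe,
                              kappa_threshold=float(enrich_section.get("kappa", 0.4)))
        counts["enriched_terms"] = len(grouped)
        _write_enrichment(grouped, outdir / "enrich.tsv")
        logger.info("[enrich] %d terms significant", len(grouped))

    manifest = {
        "tool": "cernet",
        "version": __version__,
        "seed": int(config.get("seed", 0)),
        "config": config,
        "input_digests": inputs_digests,
        "counts": counts,
        "hub": hub_name,
        "key_mirna": key_mirna,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


def _write_pairs(pairs, path) -> None:
    with Path(path).open("w") as handle:
        handle.write("lnc\tmrna\tK\tM\tN\tX\tshared\tpvalue\tfdr\n")
        for p in sorted(pairs, key=lambda q: (q.pvalue, q.lnc, q.mrna)):
            handle.write(
                f"{p.lnc}\t{p.mrna}\t{p.K}\t{p.M}\t{p.N}\t{p.X}\t"
                f"{','.join(sorted(p.shared))}\t{p.pvalue:.6g}\t{p.fdr:.6g}\n"
            )


def _write_centrality(records, path) -> None:
    with Path(path).open("w") as handle:
        handle.write("node\tpartition\tdegree\tcloseness\tbetweenness\n")
        for r in records:
            handle.write(
                f"{r.node}\t{r.partition}\t{r.degree}\t{r.closeness:.12g}\t{r.betweenness:.12g}\n"
            )


def _write_enrichment(records, path) -> None:
    with Path(path).open("w") as handle:
        handle.write("term_id\tterm_name\toverlap\tset_size\tquery_size\t"
                     "universe_size\tpvalue\tgroup\n")
        for r in records:
            handle.write(
                f"{r.term_id}\t{r.term_name}\t{r.overlap}\t{r.set_size}\t"
                f"{r.query_size}\t{r.universe_size}\t{r.pvalue:.6g}\t{r.group_id}\n"
            )
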