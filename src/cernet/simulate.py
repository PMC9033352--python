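"""Synthetic interaction, expression and gene-set data with planted truth.

The generator emulates the three inputs the pipeline consumes in a real
study — an lncRNA–miRNA pair table, a miRNA–mRNA pair table, and a
case/control expression matrix — at desk scale, with a known planted
competing-RNA structure so every stage can be validated end to end:

* background interactions are independent Bernoulli edges;
* a set of planted lncRNA–mRNA pairs is wired through *dedicated* shared
  miRNAs (never reused by the background), making the ground-truth sponge
  relations unambiguous.  One designated hub lncRNA is paired with every
  planted mRNA through two blocks of miRNAs, each co-targeting half the
  planted mRNAs; each remaining planted lncRNA gets its own block shared
  with one mRNA (round-robin).  Every planted pair therefore shares
  exactly ``planted_shared_mirnas`` dedicated miRNAs, and the hub has the
  most planted partners, the highest degree, and bridges the two halves
  of the resulting competing-RNA network;
* planted genes receive a ±planted_logfc shift in the case group of the
  expression matrix, on top of per-gene baselines and Gaussian noise.

All three generators are pure functions of (config, seed); a single seed
drives three fixed independent sub-streams, so regenerating one table
never perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .types import (
    LNC_MI,
    MI_M,
    CernetError,
    ExpressionMatrix,
    GeneSetCollection,
    InteractionTable,
)

# sub-stream tags: interactions / expression / gene sets
_STREAM_INTERACTIONS = 0
_STREAM_EXPRESSION = 1
_STREAM_GENESETS = 2


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    Defaults follow the recommended desk-scale scenario: 40 lncRNAs, 300
    miRNAs and 60 mRNAs with sparse (p = 0.02) background wiring, 8 planted
    lncRNAs and 8 planted mRNAs whose pairs each share 10 dedicated
    miRNAs, and a 5 vs 5 expression design with a ±3 log2-fold planted
    shift over noise of sd 0.5.
    """

    n_lnc: int = 40
    n_mi: int = 300
    n_mrna: int = 60
    background_edge_prob: float = 0.02
    n_planted_lnc: int = 8
    n_planted_mrna: int = 8
    planted_shared_mirnas: int = 10
    n_case: int = 5
    n_control: int = 5
    planted_logfc: float = 3.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.background_edge_prob < 1:
            raise ValueError("background_edge_prob must lie in (0, 1)")
        if self.n_planted_lnc > self.n_lnc or self.n_planted_mrna > self.n_mrna:
            raise ValueError("planted counts cannot exceed totals")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if min(self.n_lnc, self.n_mi, self.n_mrna) < 1:
            raise ValueError("node counts must be positive")


@dataclass
class TruthRecord:
    """Ground truth of one synthetic dataset."""

    planted_pairs: list[tuple[str, str]]
    planted_de_genes: list[tuple[str, str]]  # (gene, "up"/"down")
    planted_hub: str | None

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        data = json.loads(Path(path).read_text())
        return cls(
            planted_pairs=[tuple(p) for p in data["planted_pairs"]],
            planted_de_genes=[tuple(p) for p in data["planted_de_genes"]],
            planted_hub=data["planted_hub"],
        )


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1:04d}" for i in range(n)]


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _planted_pairs(config: SyntheticConfig, lncs: list[str], mrnas: list[str]):
    """Hub lncRNA × every planted mRNA, plus round-robin singles."""
    if config.n_planted_lnc == 0 or config.n_planted_mrna == 0:
        return [], [], None
    hub = lncs[0]
    hub_pairs = [(hub, mrnas[j]) for j in range(config.n_planted_mrna)]
    single_pairs = []
    for i in range(1, config.n_planted_lnc):
        single_pairs.append((lncs[i], mrnas[(i - 1) % config.n_planted_mrna]))
    return hub_pairs, list(dict.fromkeys(single_pairs)), hub


def generate_interactions(
    config: SyntheticConfig,
) -> tuple[InteractionTable, InteractionTable, TruthRecord]:
    """Emit the two interaction layers and the planted ground truth."""
    rng = _rng(config, _STREAM_INTERACTIONS)
    lncs = _ids("LNC", config.n_lnc)
    mis = _ids("MIR", config.n_mi)
    mrnas = _ids("GENE", config.n_mrna)

    planted_lncs = lncs[: config.n_planted_lnc]
    planted_mrnas = mrnas[: config.n_planted_mrna]
    hub_pairs, single_pairs, hub = _planted_pairs(config, planted_lncs, planted_mrnas)
    pairs = hub_pairs + single_pairs

    # One dedicated block per non-hub pair, plus two blocks for the hub, each
    # co-targeting half of the planted mRNAs: every planted pair then shares
    # exactly `planted_shared_mirnas` dedicated miRNAs, while the hub keeps a
    # small miRNA neighbourhood, the most planted partners, the highest
    # degree, and bridges the two halves of the competing-RNA network.
    hub_halves: list[list[str]] = []
    if hub_pairs:
        hub_targets = [mrna for _, mrna in hub_pairs]
        mid = (len(hub_targets) + 1) // 2
        hub_halves = [half for half in (hub_targets[:mid], hub_targets[mid:]) if half]
    n_blocks = len(hub_halves) + len(single_pairs)
    n_dedicated = n_blocks * config.planted_shared_mirnas
    if n_dedicated > config.n_mi:
        raise CernetError(
            f"config infeasible: {n_blocks} planted miRNA blocks x "
            f"{config.planted_shared_mirnas} shared miRNAs need {n_dedicated} "
            f"dedicated miRNAs but only {config.n_mi} exist"
        )
    background_mis = mis[: config.n_mi - n_dedicated]
    dedicated_mis = mis[config.n_mi - n_dedicated:]

    lnc_mi: list[tuple[str, str]] = []
    mi_m: list[tuple[str, str]] = []
    if background_mis:
        mask = rng.random((config.n_lnc, len(background_mis))) < config.background_edge_prob
        lnc_mi += [(lncs[i], background_mis[j]) for i, j in zip(*np.nonzero(mask))]
        mask = rng.random((len(background_mis), config.n_mrna)) < config.background_edge_prob
        mi_m += [(background_mis[i], mrnas[j]) for i, j in zip(*np.nonzero(mask))]

    for k, half in enumerate(hub_halves):
        block = dedicated_mis[k * config.planted_shared_mirnas:(k + 1) * config.planted_shared_mirnas]
        lnc_mi += [(hub, mi) for mi in block]
        mi_m += [(mi, mrna) for mi in block for mrna in half]
    for k, (lnc, mrna) in enumerate(single_pairs, start=len(hub_halves)):
        block = dedicated_mis[k * config.planted_shared_mirnas:(k + 1) * config.planted_shared_mirnas]
        lnc_mi += [(lnc, mi) for mi in block]
        mi_m += [(mi, mrna) for mi in block]

    if not lnc_mi or not mi_m:
        raise CernetError("generated interaction tables are empty; raise "
                          "background_edge_prob or plant at least one pair")

    de_genes = []
    for idx, gene in enumerate(planted_lncs + planted_mrnas):
        de_genes.append((gene, "up" if idx % 2 == 0 else "down"))
    truth = TruthRecord(planted_pairs=pairs, planted_de_genes=de_genes, planted_hub=hub)
    return (
        InteractionTable.from_pairs(lnc_mi, LNC_MI),
        InteractionTable.from_pairs(mi_m, MI_M),
        truth,
    )


def generate_expression(config: SyntheticConfig, truth: TruthRecord) -> ExpressionMatrix:
    """Log2 expression for every lncRNA and mRNA under the planted design.

    Values are per-gene baselines ~ Normal(8, 1) plus Normal(0, noise_sd)
    noise; planted genes additionally get ±planted_logfc added to their
    case samples.
    """
    if config.n_case < 2 or config.n_control < 2:
        raise CernetError("need at least 2 samples per group")
    rng = _rng(config, _STREAM_EXPRESSION)
    genes = _ids("LNC", config.n_lnc) + _ids("GENE", config.n_mrna)
    n_samples = config.n_case + config.n_control

    baseline = rng.normal(8.0, 1.0, size=len(genes))
    values = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(len(genes), n_samples))

    shift = dict(truth.planted_de_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    for gene, direction in shift.items():
        if gene not in gene_index:
            continue
        delta = config.planted_logfc if direction == "up" else -config.planted_logfc
        values[gene_index[gene], : config.n_case] += delta

    return ExpressionMatrix(
        gene_ids=genes,
        sample_ids=[f"case_{i + 1}" for i in range(config.n_case)]
        + [f"control_{i + 1}" for i in range(config.n_control)],
        values=values,
        group_labels=["case"] * config.n_case + ["control"] * config.n_control,
    )


def generate_gmt(
    config: SyntheticConfig,
    truth: TruthRecord,
    n_decoy_terms: int = 19,
    term_size: int = 12,
) -> GeneSetCollection:
    """A gene-set collection with one true term and random decoys.

    The true term contains every planted mRNA plus a few random extras;
    decoy terms are random draws from the mRNA space.
    """
    rng = _rng(config, _STREAM_GENESETS)
    mrnas = _ids("GENE", config.n_mrna)
    planted = [g for g, _ in truth.planted_de_genes if g.startswith("GENE")]

    sets: dict[str, tuple[str, frozenset[str]]] = {}
    extras = [g for g in mrnas if g not in planted]
    n_extra = min(max(term_size - len(planted), 2), len(extras))
    chosen = list(rng.choice(extras, size=n_extra, replace=False)) if n_extra else []
    true_members = frozenset(planted) | frozenset(chosen)
    if not true_members:
        true_members = frozenset(rng.choice(mrnas, size=min(term_size, len(mrnas)), replace=False))
    sets["TERM_TRUE"] = ("planted disease module", true_members)

    for k in range(n_decoy_terms):
        members = rng.choice(mrnas, size=min(term_size, len(mrnas)), replace=False)
        sets[f"TERM_D{k + 1:03d}"] = (f"decoy term {k + 1}", frozenset(members))
    return GeneSetCollection(sets=sets)
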