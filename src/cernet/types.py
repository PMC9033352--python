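"""Shared domain types for the ceRNA inference pipeline.

The pipeline moves four kinds of data between stages: interaction pair
tables (the putative lncRNA–miRNA and miRNA–mRNA binding relations),
differential-expression records, log2-scale expression matrices with a
case/control design, and gene-set collections for enrichment.  Each type
validates its own invariants at construction time so downstream stages can
assume clean input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

logger = logging.getLogger("cernet")

#: Edge kinds of the tripartite network.
LNC_MI = "lncRNA-miRNA"
MI_M = "miRNA-mRNA"
EDGE_KINDS = (LNC_MI, MI_M)

#: Node partition labels.
PARTITIONS = ("lncRNA", "miRNA", "mRNA")


class CernetError(Exception):
    """Base class for user-facing pipeline errors."""


class FormatError(CernetError):
    """A file could not be parsed; the message names the offending line."""


@dataclass(frozen=True)
class InteractionTable:
    """A deduplicated edge list of regulator→target identifier pairs.

    Parameters
    ----------
    pairs
        Ordered ``(source_id, target_id)`` tuples. For ``lncRNA-miRNA``
        tables the source is the lncRNA; for ``miRNA-mRNA`` tables the
        source is the miRNA.
    edge_kind
        Either ``"lncRNA-miRNA"`` or ``"miRNA-mRNA"``.
    n_duplicates_dropped
        How many repeated pairs were collapsed when the table was built.
    """

    pairs: tuple[tuple[str, str], ...]
    edge_kind: str
    n_duplicates_dropped: int = 0

    def __post_init__(self) -> None:
        if self.edge_kind not in EDGE_KINDS:
            raise ValueError(f"edge_kind must be one of {EDGE_KINDS}, got {self.edge_kind!r}")
        for src, tgt in self.pairs:
            if not src or not tgt:
                raise ValueError("interaction identifiers must be non-empty strings")

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], edge_kind: str
    ) -> "InteractionTable":
        """Build a table, stripping whitespace and collapsing duplicates.

        First occurrence order is preserved; the number of dropped
        duplicates is recorded and logged.
        """
        seen: dict[tuple[str, str], None] = {}
        dropped = 0
        for src, tgt in pairs:
            key = (str(src).strip(), str(tgt).strip())
            if key in seen:
                dropped += 1
            else:
                seen[key] = None
        if dropped:
            logger.info("collapsed %d duplicate %s pairs", dropped, edge_kind)
        return cls(pairs=tuple(seen), edge_kind=edge_kind, n_duplicates_dropped=dropped)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def sources(self) -> set[str]:
        return {s for s, _ in self.pairs}

    @property
    def targets(self) -> set[str]:
        return {t for _, t in self.pairs}


@dataclass
class DERecord:
    """One gene or lncRNA with its differential-expression statistics.

    ``logfc`` is the log2 fold change, case mean minus control mean.  The
    regulation direction is derived from its sign; a zero logFC has no
    direction and is rejected at screening time, not here.
    """

    gene_id: str
    logfc: float
    pvalue: float
    adj_pvalue: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError(f"pvalue {self.pvalue} outside [0, 1] for {self.gene_id}")
        if self.adj_pvalue is not None and not 0.0 <= self.adj_pvalue <= 1.0:
            raise ValueError(
                f"adj_pvalue {self.adj_pvalue} outside [0, 1] for {self.gene_id}"
            )

    @property
    def regulation(self) -> Optional[str]:
        """``"up"`` for positive logFC, ``"down"`` for negative, None at 0."""
        if self.logfc > 0:
            return "up"
        if self.logfc < 0:
            return "down"
        return None


@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of log2 expression with a two-group design."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    group_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.group_labels) != len(self.sample_ids):
            raise ValueError("one group label required per sample")
        bad = set(self.group_labels) - {"case", "control"}
        if bad:
            raise ValueError(f"group labels must be 'case'/'control', got {sorted(bad)}")
        for grp in ("case", "control"):
            if self.group_labels.count(grp) < 2:
                raise ValueError(f"need at least 2 '{grp}' samples")

    def group_columns(self, group: str) -> np.ndarray:
        """Column indices belonging to ``group``."""
        return np.array([i for i, g in enumerate(self.group_labels) if g == group])


@dataclass
class GeneSetCollection:
    """Named gene sets, as read from a GMT file: term_id → (name, members)."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for term_id, (name, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {term_id!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, term_id: str) -> frozenset[str]:
        return self.sets[term_id][1]

    @property
    def all_members(self) -> set[str]:
        """Union of every set's members (default ORA universe)."""
        out: set[str] = set()
        for _, members in self.sets.values():
            out |= members
        return out


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds for differential-expression screening.

    A record is retained when ``|logFC| > logfc_threshold`` and its p-value
    (raw, or BH-adjusted when ``use_adjusted``) is strictly below
    ``p_threshold``.  Two named presets ship: ``"methods"`` (raw P < 0.05)
    and ``"results"`` (adjusted P < 0.01); both use |logFC| > 1.5.
    """

    logfc_threshold: float = 1.5
    p_threshold: float = 0.05
    use_adjusted: bool = False

    def __post_init__(self) -> None:
        if self.logfc_threshold <= 0:
            raise ValueError("logfc_threshold must be > 0")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")

    @classmethod
    def preset(cls, name: str) -> "ScreenConfig":
        if name == "methods":
            return cls(logfc_threshold=1.5, p_threshold=0.05, use_adjusted=False)
        if name == "results":
            return cls(logfc_threshold=1.5, p_threshold=0.01, use_adjusted=True)
        raise ValueError(f"unknown preset {name!r}; expected 'methods' or 'results'")


@dataclass
class CeRNAPair:
    """One candidate competing lncRNA–mRNA pair with its test statistics.

    ``K`` is the miRNA universe size, ``M`` the number of miRNAs related to
    the mRNA, ``N`` the number related to the lncRNA, and ``X`` the number
    they share.  ``pvalue`` is the excess-tail hypergeometric probability
    P(T > X); ``fdr`` its Benjamini–Hochberg adjusted value.
    """

    lnc: str
    mrna: str
    K: int
    M: int
    N: int
    X: int
    shared: frozenset[str]
    pvalue: float
    fdr: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 <= self.X <= min(self.M, self.N)):
            raise ValueError(f"X={self.X} outside [0, min(M={self.M}, N={self.N})]")
        if self.M > self.K or self.N > self.K:
            raise ValueError(f"M={self.M} or N={self.N} exceeds universe K={self.K}")
        if len(self.shared) != self.X:
            raise ValueError("|shared| must equal X")
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError("pvalue outside [0, 1]")


@dataclass(frozen=True)
class CentralityRecord:
    """Degree, closeness and betweenness of one network node."""

    node: str
    partition: str
    degree: int
    closeness: float
    betweenness: float

    def __post_init__(self) -> None:
        if self.partition not in PARTITIONS:
            raise ValueError(f"partition must be one of {PARTITIONS}")
        if self.degree < 0:
            raise ValueError("degree must be >= 0")
        if not 0.0 <= self.closeness <= 1.0 or not 0.0 <= self.betweenness <= 1.0:
            raise ValueError("closeness/betweenness must lie in [0, 1]")
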