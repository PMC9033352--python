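"""Differential expression screening.

``compute_de`` performs a per-gene two-group comparison on a log2-scale
expression matrix: logFC = mean(case) − mean(control) and a two-sided
Welch unequal-variance t-test, with Benjamini–Hochberg adjustment across
all genes.  ``screen`` then applies the fold-change and p-value thresholds
(strict inequalities) and ``split_by_regulation`` partitions the survivors
by direction.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import CernetError, DERecord, ExpressionMatrix, ScreenConfig


def compute_de(matrix: ExpressionMatrix) -> list[DERecord]:
    """Welch t-test differential expression for every gene of a matrix.

    Returns one :class:`DERecord` per gene, in the matrix's gene order.
    A gene with zero variance in both groups gets P = 1 when the group
    means are equal and P = 0 otherwise (the test is degenerate there).
    """
    case = matrix.values[:, matrix.group_columns("case")]
    control = matrix.values[:, matrix.group_columns("control")]

    logfc = case.mean(axis=1) - control.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        result = stats.ttest_ind(case, control, axis=1, equal_var=False)
        pvalues = np.asarray(result.pvalue, dtype=float)

    # degenerate genes: no within-group variability at all
    flat = (case.var(axis=1) == 0) & (control.var(axis=1) == 0)
    pvalues[flat & (logfc == 0)] = 1.0
    pvalues[flat & (logfc != 0)] = 0.0
    if np.isnan(pvalues).any():
        raise CernetError("t-test produced NaN p-values for a non-degenerate gene")

    adjusted = multipletests(pvalues, method="fdr_bh")[1]
    return [
        DERecord(gene_id=g, logfc=float(f), pvalue=float(p), adj_pvalue=float(q))
        for g, f, p, q in zip(matrix.gene_ids, logfc, pvalues, adjusted)
    ]


def screen(records: list[DERecord], config: ScreenConfig | str = "methods") -> list[DERecord]:
    """Apply the screening thresholds and sort by descending logFC.

    A record survives when ``|logFC| > logfc_threshold`` and its p-value
    (raw, or adjusted when ``config.use_adjusted``) is strictly below
    ``p_threshold``.  Both comparisons are strict, so a record sitting
    exactly on a threshold is excluded.
    """
    if isinstance(config, str):
        config = ScreenConfig.preset(config)
    kept = []
    for record in records:
        if config.use_adjusted:
            if record.adj_pvalue is None:
                raise CernetError(
                    f"screening on adjusted p-values, but {record.gene_id} has none"
                )
            p = record.adj_pvalue
        else:
            p = record.pvalue
        if abs(record.logfc) > config.logfc_threshold and p < config.p_threshold:
            kept.append(record)
    return sorted(kept, key=lambda r: -r.logfc)


def split_by_regulation(records: list[DERecord]) -> tuple[list[DERecord], list[DERecord]]:
    """Partition records into (upregulated, downregulated) by logFC sign.

    A zero logFC has no direction and is a fatal error naming the gene.
    """
    up, down = [], []
    for record in records:
        if record.logfc > 0:
            up.append(record)
        elif record.logfc < 0:
            down.append(record)
        else:
            raise CernetError(f"gene {record.gene_id} has logFC == 0: no direction")
    return up, down
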