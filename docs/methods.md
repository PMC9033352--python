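# Methods

## Model and assumptions

The package operationalises the competing-endogenous-RNA hypothesis as a
purely combinatorial statement about a tripartite interaction graph: a
lncRNA and an mRNA are candidate competitors when they bind overlapping
miRNA sets, and the strength of evidence is the improbability of that
overlap under random, independent miRNA-set assignment.  Expression data
enter only through the screening step; no expression correlation between
the lncRNA and mRNA is required or used.  Interactions are treated as
binary and undirected (direction is implied by the partition), identifiers
as opaque case-sensitive strings — no `hsa-` prefix normalisation or alias
resolution is attempted, so inputs must be pre-harmonised.

## Differential-expression screening

`compute_de` uses logFC = mean(log2 case) − mean(log2 control) and a
two-sided Welch unequal-variance t-test per gene, with Benjamini–Hochberg
adjustment across all genes.  This is a deliberate, self-contained
substitute for moderated-variance microarray pipelines (limma-style
empirical Bayes, RMA normalisation are out of scope); at the package's
synthetic scale the Welch test is adequate, but on very small designs
(e.g. 3 vs 3 arrays) moderated statistics would be more powerful, and
users with such data should screen externally and feed the precomputed
DE table in.

Two screening presets exist because published threshold descriptions are
often ambiguous between raw and adjusted p-values: `"methods"` (raw
P < 0.05, the default) and `"results"` (BH-adjusted P < 0.01), both with
|logFC| > 1.5.  All comparisons are strict; a record with logFC exactly
1.5 is excluded, and a zero logFC is directionless and rejected at the
split step.

## The shared-miRNA test

For a pair with K universe miRNAs, M related to the mRNA, N to the lncRNA
and X shared, the statistic is the hypergeometric tail.  Two variants:

* `tail="literal"` (default): P(T > X) — one minus the CDF through X.
* `tail="inclusive"`: P(T ≥ X), the conventional over-representation
  p-value.

The literal form is the package's primary definition.  Users should know
its statistical character: because it excludes the probability mass of the
observed overlap itself, it is strictly smaller than the proper inclusive
p-value and is therefore **anti-conservative** on discrete overlap
distributions.  Under null wiring (independent random miRNA sets) the
fraction of pairs with literal P < 0.05 measures ≈ 0.12 rather than
≤ 0.05, while the inclusive tail is super-uniform as expected (≈ 0.02 at
the same settings; both numbers are recomputed by `scripts/acceptance.py`).
Calibration guarantees in the test suite are therefore asserted for the
inclusive tail; with the strong planted effects used in the recovery
benchmark the two variants select identical pair sets.

Numerics: terms are accumulated as log-binomials via `scipy.special.gammaln`
and combined with `logsumexp`, so K in the hundreds of thousands (real
database scale) is exact to working precision; the result is clamped to
[0, 1], and tails that cover the whole support (or none of it) return
exactly 1.0 or 0.0.  The implementation is verified against exhaustive
draw enumeration on the full valid grid for K ≤ 12 (tolerance 1e−12) and
cross-checked against `scipy.stats.hypergeom.sf` at large K.

Counting conventions: M, N, X and the shared miRNA sets are measured on
the **global** network, not the DEG-induced subnetwork; K defaults to the
global network's miRNA count (`universe_size="auto"`) since real universes
("all human miRNAs") are version-dependent.  Pairs sharing no miRNA cannot
compete and are excluded from testing rather than diluting the FDR, which
is controlled globally over all tested pairs at the strict threshold
FDR < 0.01.

## Topology

Degree is the raw edge count.  Closeness is (number of reachable nodes) /
(sum of shortest-path distances), the reciprocal-of-average-distance
convention used by Cytoscape's NetworkAnalyzer — chosen over the literal
"average path length" reading because centrality tables in this field lie
in (0, 1) and increase toward the centre, which only the reciprocal form
does.  Betweenness is exact shortest-path betweenness, endpoints excluded,
normalised by (n−1)(n−2)/2 with n the connected-component size, so values
stay within [0, 1] even when the assembled ceRNA network is disconnected.
Both are delegated to networkx and verified against independent
BFS/path-counting oracles to 1e−12.

Hub selection keeps lncRNAs with degree ≥ 5 (a common hub rule; the
threshold is configurable) and returns the node simultaneously maximal in
all three measures when one exists.  When no node dominates, the smallest
sum of per-measure ranks wins (ties by id) and the result is flagged
non-dominant — a deliberate package decision for a case the dominant-hub
rule leaves undefined.  The key miRNA is chosen among the `top_k = 3`
miRNAs ranked by degree (ties: closeness, betweenness, id) as the
best-ranked one directly adjacent to the hub; if none touches the hub the
selection fails loudly rather than silently relaxing `top_k`.

## Enrichment

`ora_test` is the inclusive hypergeometric upper tail over a finite gene
universe, which defaults to the union of all GMT members because any
externally curated universe is annotation-version dependent.  Term
significance is raw P < 0.05 (no FDR at this stage, matching common
ClueGO-style practice).  Enriched terms are linked when the Cohen's kappa
of their membership indicator vectors reaches 0.4 (ClueGO's published
default); connected components of that graph become term groups, numbered
by each group's best p-value.  Kappa is returned as 1.0 by convention when
chance agreement is exactly 1 (both sets empty or both the whole
universe).

## Synthetic benchmark

The generator emulates the pipeline's three inputs at desk scale with
planted, machine-readable truth.  Defaults (fixed once as the package's
study conditions): 40 lncRNAs, 300 miRNAs, 60 mRNAs,
`background_edge_prob = 0.02` independent Bernoulli wiring per possible
lncRNA–miRNA and miRNA–mRNA edge, 8 planted lncRNAs × 8 planted mRNAs with
10 dedicated shared miRNAs per planted pair, and a 5 vs 5 expression
design with ±3.0 planted log2 fold change over per-gene Normal(8, 1)
baselines and Normal(0, 0.5) noise.  The 5 + 5 / 3.0 / 0.5 expression
setting gives a logFC standard error of ≈ 0.32, so planted genes clear the
|logFC| > 1.5 screen with large margin while null genes essentially never
do — the screening stage is exercised without being the bottleneck of the
benchmark.

Planted wiring: the designated hub lncRNA is paired with every planted
mRNA through two dedicated miRNA blocks, each co-targeting half of the
planted mRNAs; every other planted lncRNA gets one dedicated block shared
with a single mRNA (round-robin).  Consequently each planted pair shares
exactly `planted_shared_mirnas` dedicated miRNAs (plus rare background
coincidences), the hub participates in the most planted pairs, keeps a
small miRNA neighbourhood (so each of its pairs is individually
significant under the hypergeometric test), attains the highest lncRNA
degree in the assembled network, and bridges the two halves of it (highest
betweenness).  Dedicated miRNAs are never reused by the background, so
ground truth is unambiguous — testability is deliberately preferred over
realism here.  One integer seed drives three fixed independent sub-streams
(interactions, expression, gene sets), so regenerating one input never
perturbs the others.

What the generator does *not* emulate: scale-free degree distributions of
real interaction databases, sequence-level miRNA seed matching, correlated
expression noise, batch effects, or probe-level artefacts.  Passing the
recovery benchmark therefore demonstrates the pipeline's correctness and
internal consistency, not its power on real, noisier data.

## Problem sizes and numerical conventions

The recovery benchmark runs the full pipeline over 20 seeds at the default
configuration (a few seconds total); the oracle grids use K ≤ 12 for the
exhaustive hypergeometric enumeration and 50 random graphs of ≤ 30 nodes
for the centrality oracles — sizes chosen so brute force remains exact and
fast.  Ties in hub rank-sums break lexicographically by id; empty
significant-pair sets yield an empty network with a warning rather than an
error; network export refuses empty graphs; numeric parsing accepts both
ASCII and typographic (U+2212) minus signs because published tables mix
them.

## Known limitations

* The Welch screen is underpowered versus moderated statistics on very
  small array designs; use precomputed DE tables where that matters.
* The literal excess-tail p-value is anti-conservative under the null (see
  above); interpret raw significance fractions accordingly or switch to
  the inclusive tail.
* The FDR is controlled over all tested pairs jointly; per-lncRNA
  correction is not offered.
* Isolated nodes are dropped by edge-list export formats (SIF/TSV);
  GraphML preserves them.
* Enrichment quality is entirely determined by the user-supplied GMT; the
  package bundles no annotation databases.
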