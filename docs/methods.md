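# Methods

This note documents the models, parameter choices and numerical conventions
behind `netpharm`, and what the synthetic fixtures do and do not establish
about real data.

## Screening model

The pipeline is a deterministic filter cascade over set- and graph-valued
intermediates:

compounds →(OB ≥ 30%, DL ≥ 0.18)→ active compounds →(per-source score
cutoffs, union)→ compound targets; disease catalogs →(union)→ disease
targets; intersection → OGEs → confidence-filtered PPI network → degree
screen → six-metric screen → MCODE key module → enrichment + expression.

All ADME, prediction-score and edge-confidence thresholds are **inclusive**
(≥), matching the cutoff notation these filters are quoted with; the two
median screens are **strictly greater** (>) by default, matching the
convention of "above the median" hub selection. Both choices are
configurable (`ScreenConfig.strict`, `ScreenThresholds.strict`) for
sensitivity analysis. Gene symbols are upper-cased before any set operation
so mixed human/rodent capitalization cannot defeat deduplication.

The per-source prediction thresholds (defaults 0.1 for a probability-scaled
source, 1.5 for a confidence-scaled one) are treated as opaque numbers on
each source's own scale; the package makes no attempt to reconcile the
scales.

## The six centralities

On the screening network (undirected, simple, no isolated nodes):

- **DC** — degree.
- **BC** — shortest-path betweenness, each unordered pair counted once;
  reported normalized by (n−1)(n−2)/2 by default (hub cutoffs quoted on a
  unit-like scale are only plausible normalized); raw values by flag.
- **CNC** — closeness restricted to the node's component with the
  Wasserman–Faust size correction ((|C|−1)/Σd) · ((|C|−1)/(n−1)), defined
  and in [0, 1] even on disconnected screening networks.
- **NC** — mean degree of the node's neighbors.
- **LAC** — 2·|E(G[N(v)])| / |N(v)|: the mean intra-neighborhood degree of
  the node's neighbors.
- **SC** — exp(A)_vv via symmetric eigendecomposition; the truncated
  closed-walk series Σ_l (A^l)_vv/l! serves as the independent test oracle,
  never the implementation.

DC, BC, CNC and NC are computed through networkx (whose conventions match
the definitions above exactly); LAC and SC are implemented in-package. The
whole table is cross-checked in the test suite against brute-force oracles
(path enumeration for BC, hand BFS for CNC, direct neighborhood counting
for NC/LAC, the walk series for SC) on hundreds of random graphs.

## Two-stage hub screen

Stage 1 keeps nodes with degree > multiplier × median degree (multiplier 2)
and induces the preliminary hub network, removing isolated survivors. Stage
2 recomputes all six centralities **on the preliminary hub network** (the
alternative — inheriting full-network values — is selectable via
`stage2_on="full"`) and keeps nodes strictly above the median in **all six
simultaneously**; a disjunctive mode exists but is off by default. The
medians actually applied are recorded in the screening result and the run
report.

Numerical convention: comparisons against a median cutoff treat values
within a relative 1e-9 as ties (excluded under strict, included under
inclusive). Spectral quantities carry last-ulp jitter, and without the
tolerance two mathematically equal SC values can straddle their own median,
which would make vertex-transitive graphs behave non-deterministically.

An empty outcome at either stage is a first-class, signaled result
(`EmptyNetworkError` → pipeline halt with the stage named), not an error:
strict median screens are genuinely empty on vertex-transitive inputs.

## MCODE

Vertex weight = k_max · density of the highest k-core of the closed
neighborhood G[N[v]]. Complexes grow breadth-first from unvisited seeds in
descending weight order (ties broken by node name, making the result
independent of node insertion order), admitting neighbors with weight ≥
(1 − node_score_cutoff) · seed weight up to max_depth; each node joins at
most one complex. Post-processing discards complexes lacking a k_core-core;
haircut iteratively removes members with intra-complex degree below
degree_cutoff; fluff (off by default) absorbs neighbors whose
closed-neighborhood density exceeds 0.1. Parameters default to the widely
published plugin defaults (degree cutoff 2, node score cutoff 0.2, k-core
2, max depth 100, haircut on, fluff off). Cluster score = density · n;
clusters sort by score, then size, then lexicographically smallest member;
the key module is the top cluster.

## Enrichment

Upper-tail hypergeometric p = P(X ≥ k) for overlap k between the query and
a term of size K in a background of N genes (scipy's stable implementation;
verified against exhaustive draw enumeration for all N ≤ 12). An EASE-style
variant (tail at k−1) is available by flag since annotation servers differ
in which statistic they report; neither is claimed to replicate any
specific server. Filtering uses raw p < 0.05; Benjamini–Hochberg adjusted
values are computed within each category (over the terms with k ≥ 1) and
reported alongside. Rows are ranked by overlap count descending, ties by p
then term id. The background defaults to the number of distinct genes in
the PPI edge input, because the screen's universe — not the genome — is
what the key targets were drawn from; it is configurable.

## Expression contrast

Per-gene two-sided Welch t-test, case minus control. Welch rather than
pooled variance is the default because emulated case/control series are
typically unbalanced; pooled mode exists. When a gene is constant within
both groups the statistic is degenerate and flagged: p = 1 and t = 0 when
the constants agree, p = 0 and |t| = ∞ when they differ (the noiseless
designed-shift limit). No multiple-testing adjustment is applied by
default, matching per-gene significance reporting.

## Synthetic fixtures

One integer seed feeds a package-owned seed sequence; each generator draws
from its own numbered sub-stream in a fixed order (compounds, predictions,
disease, PPI, expression, gene sets), so any fixture subset is reproducible
independently. Defaults describe the study conditions the pipeline targets:

- **Compounds**: 12 herbs × 25 candidate compounds, 20% of identities
  shared across herbs (shared compounds keep consistent OB/DL); OB ~
  U(0, 100), DL ~ U(0, 1), so both sides of the 30 / 0.18 cutoffs are
  populated and roughly 57% of rows survive the ADME filter.
- **Predictions**: two sources, Poisson(6) targets per compound per source;
  scores U(0, 0.2) against cutoff 0.1 and U(0, 3) against cutoff 1.5, so
  each source retains about half its rows.
- **Disease sources**: four catalogs of 80 genes over a 1000-gene universe;
  a 30% core appears in all four and the non-core members are sampled
  disjointly, so the overlap knob alone controls the union size.
- **PPI**: background edges appear independently with probability 0.05 and
  carry confidences U(400, 1000) on the 0–1000 integer scale (a 0–1 float
  dialect is a switch); planted-module edges are guaranteed ≥ the 0.7
  cutoff so module-recovery questions are well-posed. The default plants
  two modules on the OGE set: a strong one (14 nodes, within-probability
  0.9) that the screen should isolate, and a weaker, larger one (20 nodes,
  0.45) that survives the degree screen but should lose the six-metric
  screen. The contrast is deliberate: an Erdős–Rényi background is too
  light-tailed for background nodes to clear 2 × median degree, so without
  a second module the preliminary hub would be a single near-symmetric
  block and the strict six-metric conjunction would have nothing to
  discriminate. A perfectly symmetric planted clique (within-probability 1)
  empties the screen by design — all its metrics tie.
- **Expression**: per-gene baselines U(4, 12) (log2-intensity-like), unit
  Gaussian noise, 10 + 10 samples; in the pipeline's synthetic mode the key
  targets are designated the true DE genes with log2 fold changes ±2.
- **Gene sets**: 15 random terms per category (BP/CC/MF/pathway), sizes
  U{10..60}; in pipeline mode the first term of each category contains the
  key targets so an enrichment signal exists.

What the fixtures do **not** emulate: scale-free interactome topology,
correlated prediction errors between sources, probe-level microarray
artifacts, or real gene nomenclature. Passing tests therefore establish the
correctness and calibration of the algorithms under the stated generative
model, not the biological validity of any particular screen.

## Problem sizes and determinism

The default end-to-end run uses a 1000-gene universe (~140 OGEs, ~135-node
network) — large enough for a realistic cascade (≈30-node preliminary hub,
≈5-node hub, key module recovered from the strong planted module in every
completed run observed), small enough that a full run takes well under a
second. Acceptance-level measurements use 200 random graphs (≤ 7 nodes)
for oracle equivalence, 50 graphs (≤ 50 nodes) for the SC series check, 50
replicates for planted-K8 recovery, and 2000 null genes for type-I-error
calibration. Some seeds legitimately halt at the hub or MCODE stage (the
strict conjunction can empty a small screen); the acceptance script scans a
few derived seeds and reports how many halted.

## Known limitations

- The six-metric conjunction is sensitive to ties and to anti-assortative
  NC behavior on star-like fixtures; hand-built test fixtures attach
  periphery via chains so the dense block dominates all six metrics.
- MCODE's greedy, at-most-one-complex-per-node assignment means marginal
  nodes between two dense regions join whichever seed is processed first
  (deterministically, by weight then name).
- Scores quoted on unfamiliar scales are used as opaque thresholds; no
  cross-database score normalization is attempted.
- The expression module assumes a pre-summarized genes × samples matrix;
  probe mapping and normalization are out of scope.
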