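"""Two-stage median-threshold hub screen and MCODE key-module extraction.

Stage 1 keeps nodes whose degree exceeds twice the network-wide median and
induces the *preliminary hub* network. Stage 2 recomputes all six centralities
on that preliminary hub and keeps nodes exceeding the median of every metric
simultaneously (a conjunction), inducing the *hub* network. Both stages use
strictly-greater comparisons by default. MCODE (molecular complex detection)
then extracts dense complexes from the hub; the top-scoring complex is the key
module whose members are the key target genes.

MCODE follows the Bader–Hogue procedure: each vertex is weighted by
k_max · density of the highest k-core of its closed neighborhood; complexes
grow outward from high-weight seeds, admitting neighbors within a score
fraction of the seed weight; post-processing discards complexes without a
2-core and optionally shaves low-degree periphery (haircut) or absorbs dense
neighbors (fluff).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
from pydantic import BaseModel, ConfigDict, Field

from . import ppi
from .errors import EmptyNetworkError, NetpharmError, NoModuleError


class ScreenThresholds(BaseModel):
    """Settings for the two-stage median screen.

    ``strict`` selects strictly-greater comparisons (the default, matching
    cutoffs quoted as "degree > 24" style); ``metric_mode`` selects whether a
    stage-2 survivor must exceed all six medians ("all") or any one ("any");
    ``stage2_on`` selects whether stage-2 metrics and medians are computed on
    the preliminary hub network (default) or inherited from the full network.
    """

    model_config = ConfigDict(extra="forbid")

    degree_multiplier: float = Field(default=2.0, gt=0)
    strict: bool = True
    metric_mode: str = "all"  # "all" (conjunction) or "any"
    stage2_on: str = "preliminary"  # or "full"


class MCODEParams(BaseModel):
    """MCODE parameters; defaults mirror the plugin's published defaults."""

    model_config = ConfigDict(extra="forbid")

    degree_cutoff: int = Field(default=2, ge=1)
    node_score_cutoff: float = Field(default=0.2, ge=0, le=1)
    k_core: int = Field(default=2, ge=1)
    max_depth: int = Field(default=100, ge=1)
    haircut: bool = True
    fluff: bool = False
    fluff_density_cutoff: float = Field(default=0.1, ge=0, le=1)


@dataclass
class MCODECluster:
    """One MCODE complex: node set, seed vertex, density and score = density·n."""

    nodes: tuple[str, ...]
    seed: str
    density: float
    score: float

    @property
    def n(self) -> int:
        return len(self.nodes)


@dataclass
class ScreeningResult:
    """Output of the two-stage screen (key module attached by the pipeline)."""

    preliminary_hub: nx.Graph
    hub: nx.Graph
    thresholds_used: ScreenThresholds
    degree_median: float = 0.0
    per_metric_medians: dict[str, float] = field(default_factory=dict)
    key_module: MCODECluster | None = None


# ---------------------------------------------------------------------------
# median screen
# ---------------------------------------------------------------------------

#: Relative tolerance for comparisons against a median cutoff. Spectral
#: metrics (SC, and BC/CNC on symmetric graphs) carry last-ulp jitter, so
#: values this close to the cutoff are treated as ties: excluded under strict
#: comparison, included under inclusive.
MEDIAN_RTOL = 1e-9


def median_threshold_nodes(
    values: Mapping[str, float], multiplier: float, strict: bool = True
) -> set[str]:
    """Nodes whose value exceeds multiplier × median.

    The median uses the midpoint-of-middle-two convention for even counts.
    Comparison is strictly-greater when ``strict`` (default), else >=; values
    within a relative 1e-9 of the cutoff count as equal to it.
    """
    if not values:
        raise NetpharmError("median threshold on empty value map")
    cutoff = multiplier * statistics.median(values.values())
    tol = MEDIAN_RTOL * max(1.0, abs(cutoff))
    if strict:
        return {v for v, x in values.items() if x > cutoff + tol}
    return {v for v, x in values.items() if x >= cutoff - tol}


def _induced_without_isolates(net: nx.Graph, nodes: set[str]) -> nx.Graph:
    sub = net.subgraph(nodes).copy()
    sub.remove_nodes_from([v for v, d in list(sub.degree()) if d == 0])
    return sub


def preliminary_hub(
    net: nx.Graph, thresholds: ScreenThresholds | None = None
) -> tuple[nx.Graph, float]:
    """Stage 1: induced subgraph on nodes with degree > multiplier × median degree.

    Isolated survivors are removed. Returns (network, median degree used).

    Raises
    ------
    EmptyNetworkError
        If no node (with at least one edge) survives.
    """
    thresholds = thresholds or ScreenThresholds()
    deg = ppi.degree(net)
    if not deg:
        raise EmptyNetworkError("preliminary hub of empty network")
    med = statistics.median(deg.values())
    keep = median_threshold_nodes(deg, thresholds.degree_multiplier, thresholds.strict)
    sub = _induced_without_isolates(net, keep)
    if sub.number_of_nodes() == 0:
        raise EmptyNetworkError(
            f"degree screen (cutoff {thresholds.degree_multiplier}×{med}) left no connected node"
        )
    return sub, med


def screen_hubs(net: nx.Graph, thresholds: ScreenThresholds | None = None) -> ScreeningResult:
    """Run both screening stages and record the medians actually applied.

    Stage-2 centralities are computed on the preliminary hub network (or on the
    full network when ``stage2_on='full'``); a node survives when its value
    exceeds the median for all six metrics (conjunction) under the configured
    comparison.
    """
    thresholds = thresholds or ScreenThresholds()
    prelim, degree_median = preliminary_hub(net, thresholds)

    metric_net = prelim if thresholds.stage2_on == "preliminary" else net
    table = ppi.centrality_table(metric_net).loc[sorted(prelim.nodes)]
    medians = {m: float(table[m].median()) for m in ppi.METRIC_NAMES}

    survivors: set[str] | None = None
    per_metric_sets = []
    for m in ppi.METRIC_NAMES:
        passing = median_threshold_nodes(table[m].to_dict(), 1.0, thresholds.strict)
        per_metric_sets.append(passing)
    if thresholds.metric_mode == "all":
        survivors = set.intersection(*per_metric_sets)
    elif thresholds.metric_mode == "any":
        survivors = set.union(*per_metric_sets)
    else:
        raise NetpharmError(f"unknown metric_mode {thresholds.metric_mode!r}")

    hub = _induced_without_isolates(prelim, survivors)
    if hub.number_of_nodes() == 0:
        raise EmptyNetworkError("six-metric median screen left no connected node")
    return ScreeningResult(
        preliminary_hub=prelim,
        hub=hub,
        thresholds_used=thresholds,
        degree_median=degree_median,
        per_metric_medians=medians,
    )


# ---------------------------------------------------------------------------
# MCODE
# ---------------------------------------------------------------------------

def _density(n_nodes: int, n_edges: int) -> float:
    if n_nodes < 2:
        return 0.0
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def mcode_vertex_weights(net: nx.Graph) -> dict[str, float]:
    """Bader–Hogue vertex weight: k_max × density of the highest k-core of G[N[v]]."""
    weights: dict[str, float] = {}
    for v in net:
        closed = set(net[v]) | {v}
        sub = net.subgraph(closed)
        core = nx.core_number(sub)
        kmax = max(core.values())
        if kmax == 0:
            weights[v] = 0.0
            continue
        core_nodes = [u for u, k in core.items() if k >= kmax]
        core_sub = sub.subgraph(core_nodes)
        weights[v] = kmax * _density(core_sub.number_of_nodes(), core_sub.number_of_edges())
    return weights


def _grow_complex(
    net: nx.Graph,
    seed: str,
    weights: Mapping[str, float],
    visited: set[str],
    params: MCODEParams,
) -> set[str]:
    """Breadth-first expansion from the seed, admitting unvisited neighbors whose
    weight is within node_score_cutoff of the seed weight, out to max_depth."""
    threshold = (1.0 - params.node_score_cutoff) * weights[seed]
    members = {seed}
    frontier = [seed]
    depth = 0
    while frontier and depth < params.max_depth:
        nxt = []
        for v in frontier:
            for u in net[v]:
                if u in members or u in visited:
                    continue
                if weights[u] >= threshold:
                    members.add(u)
                    nxt.append(u)
        frontier = nxt
        depth += 1
    return members


def _haircut(net: nx.Graph, members: set[str], degree_cutoff: int) -> set[str]:
    """Iteratively shave members with intra-complex degree below the cutoff."""
    members = set(members)
    while True:
        sub = net.subgraph(members)
        low = [v for v, d in sub.degree() if d < degree_cutoff]
        if not low:
            return members
        members -= set(low)
        if not members:
            return members


def _fluff(
    net: nx.Graph, members: set[str], weights: Mapping[str, float], cutoff: float
) -> set[str]:
    """Absorb neighbors whose closed-neighborhood density exceeds the fluff cutoff."""
    extra = set()
    for v in members:
        for u in net[v]:
            if u in members or u in extra:
                continue
            closed = set(net[u]) | {u}
            sub = net.subgraph(closed)
            if _density(sub.number_of_nodes(), sub.number_of_edges()) > cutoff:
                extra.add(u)
    return members | extra


def mcode_find_complexes(
    net: nx.Graph, params: MCODEParams | None = None
) -> list[MCODECluster]:
    """Find MCODE complexes, best first.

    Seeds are taken in descending weight order (node name breaks ties, so the
    result is independent of node insertion order); each node joins at most one
    complex. Complexes lacking a ``k_core``-core are discarded; haircut removes
    intra-complex degree < degree_cutoff periphery. Clusters are sorted by
    score descending, ties by larger size, then by lexicographically smallest
    member.
    """
    params = params or MCODEParams()
    weights = mcode_vertex_weights(net)
    order = sorted(weights, key=lambda v: (-weights[v], v))
    visited: set[str] = set()
    clusters: list[MCODECluster] = []

    for seed in order:
        if seed in visited or weights[seed] <= 0:
            continue
        members = _grow_complex(net, seed, weights, visited, params)
        visited |= members

        sub = net.subgraph(members)
        core = nx.core_number(sub) if sub.number_of_nodes() else {}
        if not core or max(core.values()) < params.k_core:
            continue
        if params.haircut:
            members = _haircut(net, members, params.degree_cutoff)
            if not members:
                continue
        if params.fluff:
            members = _fluff(net, members, weights, params.fluff_density_cutoff)

        final = net.subgraph(members)
        dens = _density(final.number_of_nodes(), final.number_of_edges())
        clusters.append(
            MCODECluster(
                nodes=tuple(sorted(members)),
                seed=seed,
                density=dens,
                score=dens * final.number_of_nodes(),
            )
        )

    clusters.sort(key=lambda c: (-c.score, -c.n, c.nodes))
    return clusters


def key_module(clusters: Sequence[MCODECluster]) -> list[str]:
    """Sorted gene list of the top-scoring MCODE complex."""
    if not clusters:
        raise NoModuleError("MCODE found no complex")
    return sorted(clusters[0].nodes)


def write_clusters_tsv(clusters: Sequence[MCODECluster], path) -> None:
    import pandas as pd

    rows = [
        (i + 1, c.score, c.density, c.n, c.seed, ";".join(c.nodes))
        for i, c in enumerate(clusters)
    ]
    pd.DataFrame(rows, columns=["rank", "score", "density", "n", "seed", "nodes"]).to_csv(
        path, sep="\t", index=False
    )
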