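"""PPI network construction and the six topological screening metrics.

The network is built from a STRING-dialect edge table (``protein1 protein2
combined_score``) restricted to a gene whitelist (the OGEs) at a confidence
cutoff, and each node is scored with the six centralities used by the two-stage
hub screen:

DC   degree connectivity — incident-edge count
BC   betweenness connectivity — fraction of shortest paths through the node
CNC  closeness connectivity — component-restricted closeness with the
     Wasserman–Faust (|C|-1)/(n-1) size correction, so values lie in [0, 1]
     even on disconnected screening networks
NC   neighborhood connectivity — mean degree of the node's neighbors
LAC  local average connectivity — mean degree, within the subgraph induced on
     the node's open neighborhood, of those neighbors (2·|E(G[N(v)])|/|N(v)|)
SC   subgraph centrality — sum over l of closed walks of length l weighted by
     1/l!, i.e. exp(A)_vv, computed by symmetric eigendecomposition

BC is reported normalized by default (divide by (n-1)(n-2)/2); a flag yields
raw values. Scores >1 anywhere in the table mean the 0-1000 integer confidence
scale, and a fractional cutoff such as 0.7 is interpreted as 700.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .errors import EmptyNetworkError, InputFormatError

EDGE_COLUMNS = ["protein1", "protein2", "combined_score"]


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

@dataclass
class NetworkBuild:
    """Result of building a screening network.

    ``unmapped`` lists whitelist genes absent from the edge table (the analogue
    of query identifiers the interaction database could not map); ``dropped``
    lists genes that had edges but lost all of them to the confidence filter or
    whitelist restriction ("interact without other genes").
    """

    graph: nx.Graph
    unmapped: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)
    scale: str = "unit"  # "unit" (0-1) or "int1000" (0-1000)
    min_score_applied: float = 0.7


def read_string_edges(path: str | Path) -> pd.DataFrame:
    """Read a STRING-dialect TSV edge table, reporting the line of any bad row."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != EDGE_COLUMNS:
            raise InputFormatError(
                f"expected header {EDGE_COLUMNS}, got {header[:3]}", line=1
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise InputFormatError("expected 3 tab-separated fields", line=lineno)
            try:
                score = float(parts[2])
            except ValueError:
                raise InputFormatError(
                    f"non-numeric combined_score {parts[2]!r}", line=lineno
                ) from None
            rows.append((parts[0], parts[1], score))
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def detect_score_scale(scores: Iterable[float]) -> str:
    """'int1000' if any score exceeds 1, else 'unit'."""
    return "int1000" if any(s > 1 for s in scores) else "unit"


def build_network(
    edges: pd.DataFrame,
    min_score: float = 0.7,
    whitelist: Iterable[str] | None = None,
) -> NetworkBuild:
    """Build the screening network from a STRING-dialect edge table.

    Keeps edges with both endpoints in ``whitelist`` (when given) and
    confidence >= ``min_score``; collapses duplicate unordered pairs keeping
    the maximum score; drops self-loops; removes nodes left without any edge.

    Raises
    ------
    EmptyNetworkError
        If no edge survives the filters.
    """
    wl = {g.upper() for g in whitelist} if whitelist is not None else None

    scale = detect_score_scale(edges["combined_score"]) if len(edges) else "unit"
    cutoff = min_score
    if scale == "int1000" and min_score <= 1:
        cutoff = min_score * 1000.0

    g = nx.Graph()
    seen_in_table: set[str] = set()
    for p1, p2, score in edges.itertuples(index=False):
        a, b = str(p1).upper(), str(p2).upper()
        seen_in_table.update((a, b))
        if a == b:
            continue
        if wl is not None and (a not in wl or b not in wl):
            continue
        if score < cutoff:
            continue
        if g.has_edge(a, b):
            g[a][b]["score"] = max(g[a][b]["score"], float(score))
        else:
            g.add_edge(a, b, score=float(score))

    unmapped = sorted(wl - seen_in_table) if wl is not None else []
    candidates = (wl & seen_in_table) if wl is not None else seen_in_table
    dropped = sorted(candidates - set(g.nodes))

    build = NetworkBuild(
        graph=g, unmapped=unmapped, dropped=dropped, scale=scale, min_score_applied=cutoff
    )
    if g.number_of_nodes() == 0:
        raise EmptyNetworkError(
            f"no edges survive min_score={min_score} on the {scale} scale"
            + (f" within the {len(wl)}-gene whitelist" if wl is not None else "")
        )
    return build


# ---------------------------------------------------------------------------
# centralities
# ---------------------------------------------------------------------------

def degree(net: nx.Graph) -> dict[str, int]:
    """Incident-edge count per node."""
    return {v: d for v, d in net.degree()}


def betweenness(net: nx.Graph, normalized: bool = True) -> dict[str, float]:
    """Shortest-path betweenness; pairs in different components contribute 0.

    Raw values count each unordered pair once; normalization divides by
    (n-1)(n-2)/2.
    """
    if net.number_of_nodes() == 0:
        raise EmptyNetworkError("betweenness of empty network")
    return nx.betweenness_centrality(net, normalized=normalized)


def closeness(net: nx.Graph) -> dict[str, float]:
    """Component-restricted closeness with the (|C|-1)/(n-1) size correction.

    CNC(v) = ((|C_v|-1) / sum_{u in C_v} d(v,u)) * ((|C_v|-1)/(n-1)); an
    isolated node gets 0. Values lie in [0, 1].
    """
    if net.number_of_nodes() == 0:
        raise EmptyNetworkError("closeness of empty network")
    return nx.closeness_centrality(net, wf_improved=True)


def neighborhood_connectivity(net: nx.Graph) -> dict[str, float]:
    """Mean degree of each node's neighbors (0 for an isolated node)."""
    deg = dict(net.degree())
    out = {}
    for v in net:
        nbrs = list(net[v])
        out[v] = sum(deg[u] for u in nbrs) / len(nbrs) if nbrs else 0.0
    return out


def local_avg_connectivity(net: nx.Graph) -> dict[str, float]:
    """LAC(v) = 2 |E(G[N(v)])| / |N(v)|: mean intra-neighborhood degree.

    High LAC means the node sits in a locally dense region; a star center,
    whose neighbors are mutually non-adjacent, scores 0.
    """
    out = {}
    for v in net:
        nbrs = set(net[v])
        if not nbrs:
            out[v] = 0.0
            continue
        induced_edges = sum(1 for u in nbrs for w in net[u] if w in nbrs) // 2
        out[v] = 2.0 * induced_edges / len(nbrs)
    return out


def subgraph_centrality(net: nx.Graph) -> dict[str, float]:
    """SC(v) = exp(A)_vv via symmetric eigendecomposition of the adjacency matrix.

    Equals the closed-walk series sum_l (A^l)_vv / l!; every node scores at
    least 1 (the l=0 term).
    """
    if net.number_of_nodes() == 0:
        raise EmptyNetworkError("subgraph centrality of empty network")
    nodes = sorted(net.nodes)
    a = nx.to_numpy_array(net, nodelist=nodes, weight=None)
    w, vecs = np.linalg.eigh(a)
    sc = (vecs**2) @ np.exp(w)
    return {v: float(s) for v, s in zip(nodes, sc)}


METRIC_NAMES = ["DC", "BC", "CNC", "LAC", "NC", "SC"]


def centrality_table(net: nx.Graph, bc_normalized: bool = True) -> pd.DataFrame:
    """All six screening metrics for every node, one row per node.

    Columns are DC, BC, CNC, LAC, NC, SC; the index is the sorted node set.
    """
    if net.number_of_nodes() == 0:
        raise EmptyNetworkError("centrality table of empty network")
    table = pd.DataFrame(
        {
            "DC": degree(net),
            "BC": betweenness(net, normalized=bc_normalized),
            "CNC": closeness(net),
            "LAC": local_avg_connectivity(net),
            "NC": neighborhood_connectivity(net),
            "SC": subgraph_centrality(net),
        }
    ).sort_index()
    table.index.name = "gene"
    if not np.isfinite(table.to_numpy()).all():
        raise ArithmeticError("non-finite centrality value")
    return table


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_graphml(net: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(net, str(path))


def write_edge_tsv(net: nx.Graph, path: str | Path) -> None:
    """Write the network back out in the STRING dialect (score 1.0 if unscored)."""
    rows = [
        (min(a, b), max(a, b), data.get("score", 1.0))
        for a, b, data in net.edges(data=True)
    ]
    df = pd.DataFrame(sorted(rows), columns=EDGE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def write_centrality_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")
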