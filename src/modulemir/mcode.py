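"""Molecular-complex detection (MCODE-style) on interaction graphs.

Vertices are weighted by the density of the highest k-core of their open
neighbourhood times its core number, then complexes are grown from
high-weight seeds: the seed's neighbourhood (breadth-first to a configurable
depth, default one step) is admitted when a node's weight stays within
``node_score_cutoff`` of the seed weight.  Post-processing removes
singly connected members (haircut, on by default) and pulls in boundary
neighbours adjacent to at least a set fraction of the complex (fluff, on by
default) so that a dense region is not truncated when its members' weights
spread below the seed-relative admission threshold.  Complexes are
node-disjoint — every member, including fluffed ones, is marked visited —
and scored by density times size.

Growth is depth-limited (default: the seed's immediate neighbourhood)
because the core-density weighting gives bridge nodes between two dense
regions the same weight as interior nodes, so unbounded expansion would
merge well-separated complexes across single bridge edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx


@dataclass
class Complex:
    """One detected complex: member nodes and density x size score."""

    nodes: tuple[str, ...]
    score: float

    def __len__(self) -> int:
        return len(self.nodes)


def filter_edges(graph: nx.Graph, min_confidence: float = 0.7) -> nx.Graph:
    """Keep edges with confidence >= cutoff (inclusive); nodes are retained."""
    out = nx.Graph()
    out.add_nodes_from(graph.nodes(data=True))
    for a, b, data in graph.edges(data=True):
        conf = data.get("confidence")
        if conf is None:
            raise ValueError(f"edge ({a!r}, {b!r}) has no confidence attribute")
        if conf >= min_confidence:
            out.add_edge(a, b, **data)
    return out


def graph_density(graph: nx.Graph, *, loops: bool = False) -> float:
    """Edge density; ``loops=True`` uses the self-loop-corrected denominator."""
    v = graph.number_of_nodes()
    e = graph.number_of_edges()
    if v < 2:
        return 0.0
    denom = v * (v + 1) / 2.0 if loops else v * (v - 1) / 2.0
    return e / denom


def _neighborhood_weight(graph: nx.Graph, node) -> float:
    """Core number of the node's open neighbourhood times the core's density."""
    neighbors = list(graph[node])
    if len(neighbors) < 2:
        return 0.0
    sub = graph.subgraph(neighbors)
    if sub.number_of_edges() == 0:
        return 0.0
    cores = nx.core_number(sub)
    k = max(cores.values())
    if k == 0:
        return 0.0
    core_sub = sub.subgraph([n for n, c in cores.items() if c >= k])
    return k * graph_density(core_sub)


def _neighborhood_density(graph: nx.Graph, node) -> float:
    neighbors = list(graph[node])
    if len(neighbors) < 2:
        return 0.0
    return graph_density(graph.subgraph(neighbors))


def mcode_vertex_weights(graph: nx.Graph) -> dict:
    """MCODE weight for every node (0 for isolated or star-centre nodes)."""
    return {node: _neighborhood_weight(graph, node) for node in graph.nodes}


def mcode_find_complexes(
    graph: nx.Graph,
    weights: dict | None = None,
    *,
    node_score_cutoff: float = 0.2,
    node_density_cutoff: float = 0.0,
    haircut: bool = True,
    fluff: bool = True,
    fluff_connectivity: float = 0.5,
    max_depth: int = 1,
    loops: bool = False,
    min_size: int = 2,
) -> list[Complex]:
    """Grow node-disjoint complexes from high-weight seeds.

    Nodes join a complex when their weight is at least
    ``(1 - node_score_cutoff)`` times the seed weight and their
    neighbourhood density is at least ``node_density_cutoff``.  Fluff then
    admits unvisited boundary nodes adjacent to at least
    ``fluff_connectivity`` of the complex, compensating for members whose
    weight falls below the seed-relative threshold.  Complexes are scored
    by density times node count (``loops`` selects the density convention)
    and returned sorted by decreasing score; ties break on the
    lexicographically smallest member so runs are reproducible.
    """
    if weights is None:
        weights = mcode_vertex_weights(graph)
    visited: set = set()
    complexes: list[Complex] = []
    seeds = sorted(graph.nodes, key=lambda v: (-weights[v], str(v)))
    for seed in seeds:
        if seed in visited:
            continue
        threshold = (1.0 - node_score_cutoff) * weights[seed]
        members = {seed}
        frontier = [seed]
        for _depth in range(max_depth):
            nxt = []
            for node in frontier:
                for nb in graph[node]:
                    if nb in visited or nb in members:
                        continue
                    if weights[nb] < threshold:
                        continue
                    if _neighborhood_density(graph, nb) < node_density_cutoff:
                        continue
                    members.add(nb)
                    nxt.append(nb)
            if not nxt:
                break
            frontier = nxt
        if haircut:
            while True:
                sub = graph.subgraph(members)
                trim = [v for v in members if sub.degree(v) < 2]
                if not trim or len(members) - len(trim) < 2:
                    break
                members -= set(trim)
        if fluff and len(members) >= min_size:
            boundary = set()
            for node in members:
                for nb in graph[node]:
                    if nb in visited or nb in members or nb in boundary:
                        continue
                    attached = sum(1 for u in graph[nb] if u in members)
                    if attached / len(members) >= fluff_connectivity:
                        boundary.add(nb)
            members |= boundary
        visited |= members
        if len(members) >= min_size:
            sub = graph.subgraph(members)
            score = graph_density(sub, loops=loops) * len(members)
            complexes.append(Complex(nodes=tuple(sorted(members)), score=score))
    complexes.sort(key=lambda c: (-c.score, c.nodes))
    return complexes
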