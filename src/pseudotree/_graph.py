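"""Tree-graph helpers shared by the synthetic generator and the staging code.

A "branch" of a tree is a maximal path whose internal vertices all have
degree 2; branches are delimited by leaves and by vertices of degree >= 3.
Branch ids are 1-based, ordered by the smallest vertex index they contain.
"""

from __future__ import annotations

import networkx as nx


def check_tree(graph: nx.Graph) -> None:
    """Raise ValueError unless *graph* is a connected acyclic graph."""
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph is not a tree")
    if graph.number_of_edges() != n - 1 or not nx.is_connected(graph):
        raise ValueError("graph is not a spanning tree (connected, acyclic)")


def branch_decomposition(graph: nx.Graph) -> dict[tuple[int, int], int]:
    """Map every edge (i, j) with i < j to a 1-based branch id.

    Branches are maximal degree-2 paths; they are cut at every vertex of
    degree != 2.  Ids are assigned by sorting branches on their smallest
    vertex index (ties on the next-smallest, which cannot collide).
    """
    check_tree(graph)
    if graph.number_of_edges() == 0:
        return {}
    breakpoints = {v for v in graph.nodes if graph.degree(v) != 2}
    if not breakpoints:  # cannot happen in a tree with >= 1 edge
        raise ValueError("tree has no leaf")
    branches: list[list[tuple[int, int]]] = []
    seen: set[tuple[int, int]] = set()
    for start in sorted(breakpoints):
        for nb in sorted(graph.neighbors(start)):
            e = (min(start, nb), max(start, nb))
            if e in seen:
                continue
            # walk along the degree-2 chain
            path = [e]
            seen.add(e)
            prev, cur = start, nb
            while cur not in breakpoints:
                nxt = [u for u in graph.neighbors(cur) if u != prev][0]
                e2 = (min(cur, nxt), max(cur, nxt))
                path.append(e2)
                seen.add(e2)
                prev, cur = cur, nxt
            branches.append(path)
    branches.sort(key=lambda path: sorted(v for e in path for v in e))
    out: dict[tuple[int, int], int] = {}
    for bid, path in enumerate(branches, start=1):
        for e in path:
            out[e] = bid
    return out


def vertex_distances(graph: nx.Graph, source: int, weight: str = "length") -> dict[int, float]:
    """Geodesic (edge-length) distance from *source* to every vertex."""
    return nx.single_source_dijkstra_path_length(graph, source, weight=weight)
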