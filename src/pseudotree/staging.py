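"""From a fitted latent tree to pseudotimes and branch labels.

The spanning tree over centers is realized geometrically (Euclidean edge
lengths in latent space); samples are projected to their closest point on
the tree; the root is chosen on the maximum-diameter path; pseudotime is
the geodesic distance from the root, min-max scaled to [0, 1]; branches
are the maximal degree-2 paths of the tree, and each sample inherits the
branch of its projected edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._graph import branch_decomposition, vertex_distances
from .ddrtree import DDRTreeParams, LatentTreeModel, check_model, fit

__all__ = [
    "PrincipalTreeGraph",
    "StagingResult",
    "build_principal_graph",
    "project_samples",
    "find_root",
    "compute_pseudotime",
    "assign_branches",
    "stage_samples",
    "loo_stability",
]


@dataclass
class PrincipalTreeGraph:
    """The learned principal tree: center coordinates, edges with
    Euclidean lengths, leaves, and the edge -> branch decomposition."""

    vertices: np.ndarray  # K x d center coordinates
    edges: list[tuple[int, int]]  # i < j
    lengths: np.ndarray  # per-edge Euclidean length
    leaves: list[int]
    branch_of_edge: dict[tuple[int, int], int]  # 1-based branch ids

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.vertices)))
        for (i, j), ln in zip(self.edges, self.lengths):
            g.add_edge(i, j, length=float(ln))
        return g

    @property
    def n_branches(self) -> int:
        return max(self.branch_of_edge.values(), default=0)


@dataclass
class StagingResult:
    """Per-sample staging: projected point (edge + offset), raw geodesic
    distance from the root, scaled pseudotime in [0, 1], branch label."""

    edge_index: np.ndarray  # index into graph.edges
    offset: np.ndarray  # position along the edge, in [0, 1]
    raw_distance: np.ndarray
    pseudotime: np.ndarray
    branch: np.ndarray
    root_vertex: int
    diameter_endpoints: tuple[int, int]

    def to_frame(self, sample_ids: list[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "branch": self.branch,
                "raw_distance": self.raw_distance,
                "pseudotime": self.pseudotime,
            }
        )
        if sample_ids is not None:
            df.index = pd.Index(sample_ids, name="sample_id")
        return df


def build_principal_graph(model: LatentTreeModel) -> PrincipalTreeGraph:
    """Realize the spanning tree B geometrically over the centers Y."""
    check_model(model)
    Y = model.Y
    iu, ju = np.nonzero(np.triu(model.B))
    edges = [(int(i), int(j)) for i, j in zip(iu, ju)]
    lengths = np.array([np.linalg.norm(Y[:, i] - Y[:, j]) for i, j in edges])
    g = nx.Graph()
    g.add_nodes_from(range(model.n_centers))
    for (i, j), ln in zip(edges, lengths):
        g.add_edge(i, j, length=float(ln))
    if g.number_of_nodes() > 1 and not nx.is_connected(g):
        raise ValueError("B is disconnected")
    leaves = [v for v in g.nodes if g.degree(v) == 1]
    branch_of = branch_decomposition(g) if edges else {}
    return PrincipalTreeGraph(Y.T.copy(), edges, lengths, leaves, branch_of)


def project_samples(
    Z: np.ndarray, graph: PrincipalTreeGraph, centers_only: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project each latent sample (columns of Z) to its closest point on
    the tree.

    Returns (edge_index, offset, distance).  The offset is the clamped
    parameter t in [0, 1] along the edge; ties go to the lowest edge id.
    ``centers_only`` restricts candidate points to the centers themselves
    (projections land on vertices).
    """
    if not graph.edges:
        raise ValueError("graph has no edges")
    P = Z.T  # N x d
    n = P.shape[0]
    E = len(graph.edges)
    dist = np.empty((E, n))
    toff = np.empty((E, n))
    for e, ((i, j), ln) in enumerate(zip(graph.edges, graph.lengths)):
        a = graph.vertices[i]
        b = graph.vertices[j]
        if ln == 0:
            warnings.warn(f"zero-length edge {(i, j)} treated as a point")
            t = np.zeros(n)
        else:
            t = np.clip((P - a) @ (b - a) / ln**2, 0.0, 1.0)
        if centers_only:
            t = np.round(t)
        proj = a + t[:, None] * (b - a)
        dist[e] = np.linalg.norm(P - proj, axis=1)
        toff[e] = t
    edge_index = np.argmin(dist, axis=0)  # first minimum -> lowest edge id
    offset = toff[edge_index, np.arange(n)]
    return edge_index, offset, dist[edge_index, np.arange(n)]


def _distance_to_projection(
    graph: PrincipalTreeGraph,
    source: int,
    edge_index: np.ndarray,
    offset: np.ndarray,
) -> np.ndarray:
    """Geodesic distance from a vertex to each projected point."""
    dv = vertex_distances(graph.graph(), source)
    out = np.empty(edge_index.size)
    for s in range(edge_index.size):
        i, j = graph.edges[edge_index[s]]
        ln = graph.lengths[edge_index[s]]
        t = offset[s]
        out[s] = min(dv[i] + t * ln, dv[j] + (1 - t) * ln)
    return out


def find_root(
    graph: PrincipalTreeGraph,
    orientation_labels: np.ndarray | None = None,
    projections: tuple[np.ndarray, np.ndarray] | None = None,
    root_override: int | None = None,
) -> tuple[int, tuple[int, int]]:
    """Choose the root on one end of the maximum-diameter path.

    The diameter is the leaf pair with the largest tree distance.  With
    binary *orientation_labels* (1 = case) and sample *projections*
    (edge_index, offset), each sample is attributed to the nearer diameter
    endpoint and the endpoint with the lower case fraction becomes the
    root — the "controls early" convention.  Without labels the smaller
    vertex index wins; *root_override* bypasses everything.
    """
    g = graph.graph()
    if root_override is not None:
        if root_override not in g.nodes:
            raise ValueError(f"root_override {root_override} is not a vertex")
    if not graph.leaves:
        raise ValueError("graph has no leaf")
    best = (-1.0, (0, 0))
    for a in sorted(graph.leaves):
        da = vertex_distances(g, a)
        for b in sorted(graph.leaves):
            if b <= a:
                continue
            if da[b] > best[0] + 1e-15:
                best = (da[b], (a, b))
    endpoints = best[1]
    if root_override is not None:
        return int(root_override), endpoints
    a, b = endpoints
    if orientation_labels is not None and projections is not None:
        labels = np.asarray(orientation_labels, dtype=float)
        edge_index, offset = projections
        dist_a = _distance_to_projection(graph, a, edge_index, offset)
        dist_b = _distance_to_projection(graph, b, edge_index, offset)
        near_a = dist_a <= dist_b
        frac_a = labels[near_a].mean() if near_a.any() else np.inf
        frac_b = labels[~near_a].mean() if (~near_a).any() else np.inf
        if frac_b < frac_a:
            return b, endpoints
        return a, endpoints
    return min(a, b), endpoints


def assign_branches(
    projections: tuple[np.ndarray, np.ndarray], graph: PrincipalTreeGraph
) -> np.ndarray:
    """Each sample inherits the branch of its projected edge; a sample
    sitting exactly on a degree-!=2 vertex takes the smallest-id incident
    branch (which the lowest-edge-id projection tie rule already yields)."""
    edge_index, offset = projections
    g = graph.graph()
    out = np.empty(edge_index.size, dtype=int)
    for s in range(edge_index.size):
        e = graph.edges[edge_index[s]]
        t = offset[s]
        vertex = e[0] if t == 0.0 else e[1] if t == 1.0 else None
        if vertex is not None and g.degree(vertex) != 2:
            incident = [
                graph.branch_of_edge[(min(vertex, u), max(vertex, u))]
                for u in g.neighbors(vertex)
            ]
            out[s] = min(incident)
        else:
            out[s] = graph.branch_of_edge[e]
    return out


def compute_pseudotime(
    projections: tuple[np.ndarray, np.ndarray],
    graph: PrincipalTreeGraph,
    root: int,
    diameter_endpoints: tuple[int, int] | None = None,
) -> StagingResult:
    """Geodesic distance from the root to each projected point, min-max
    scaled to [0, 1]; branch labels are attached from the projection."""
    edge_index, offset = projections
    raw = _distance_to_projection(graph, root, edge_index, offset)
    if raw.max() == raw.min():
        raise ValueError("degenerate staging: all samples project to the same point")
    pt = (raw - raw.min()) / (raw.max() - raw.min())
    branch = assign_branches(projections, graph)
    return StagingResult(
        edge_index=edge_index,
        offset=offset,
        raw_distance=raw,
        pseudotime=pt,
        branch=branch,
        root_vertex=int(root),
        diameter_endpoints=diameter_endpoints if diameter_endpoints is not None else (-1, -1),
    )


def stage_samples(
    model: LatentTreeModel,
    orientation_labels: np.ndarray | None = None,
    root_override: int | None = None,
    centers_only: bool = False,
) -> tuple[PrincipalTreeGraph, StagingResult]:
    """Convenience wrapper: graph construction, projection, root choice
    and pseudotime in one call."""
    graph = build_principal_graph(model)
    edge_index, offset, _ = project_samples(model.Z, graph, centers_only=centers_only)
    root, endpoints = find_root(
        graph,
        orientation_labels=orientation_labels,
        projections=(edge_index, offset),
        root_override=root_override,
    )
    result = compute_pseudotime((edge_index, offset), graph, root, endpoints)
    return graph, result


def loo_stability(
    X: np.ndarray,
    params: DDRTreeParams,
    orientation_labels: np.ndarray | None = None,
) -> np.ndarray:
    """Leave-one-out robustness of pseudotime: drop each sample, refit
    with the same parameters and seed, and report the absolute Pearson
    correlation between reduced-fit and full-fit pseudotimes over the
    shared samples.  Refit failures yield NaN with a warning."""
    X = np.asarray(X, dtype=float)
    N = X.shape[1]
    if N < 3:
        raise ValueError("need at least 3 samples")
    full = fit(X, params)
    _, full_stage = stage_samples(full, orientation_labels=orientation_labels)
    # a fixed K valid for N-1 samples keeps refits comparable
    resolved = params.resolved(N - 1)
    out = np.full(N, np.nan)
    for i in range(N):
        keep = np.arange(N) != i
        labels_i = None if orientation_labels is None else np.asarray(orientation_labels)[keep]
        try:
            m = fit(X[:, keep], resolved)
            _, st = stage_samples(m, orientation_labels=labels_i)
            r = stats.pearsonr(st.pseudotime, full_stage.pseudotime[keep])[0]
            out[i] = abs(r)
        except Exception as exc:  # refit failure is recorded, not fatal
            warnings.warn(f"leave-one-out refit failed for sample {i}: {exc}")
    return out
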