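"""Skeleton evaluation: Chamfer distance, simplified-graph node/edge deltas,
and the tree-rate check.

Skeletons are compared as point clouds sampled densely along their edges
(fixed spacing, endpoints included). The Chamfer distance is the sum of the
two directional means of squared nearest-neighbor distances; a linear
(non-squared) variant is available since reported magnitudes in this field
are sometimes plain distances. Topology is compared on simplified graphs in
which every degree-2 node has been contracted, leaving only endpoints and
branching points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .graph_init import SkeletonGraph, edges_to_logits
from .io_formats import PointCloud
from .sfs_mst import is_tree

__all__ = [
    "MetricsReport",
    "sample_skeleton_points",
    "chamfer_distance",
    "simplify_graph",
    "metrics_report",
]


def sample_skeleton_points(graph: SkeletonGraph, spacing: float) -> PointCloud:
    """Uniform points along every edge at the given spacing (meters).

    Each edge of length L yields ceil(L / spacing) + 1 evenly spaced points
    including both endpoints; nodes shared by several edges appear once.
    Isolated nodes contribute their position.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    pts = [graph.positions]
    for i, j in graph.edges():
        a, b = graph.positions[i], graph.positions[j]
        length = float(np.linalg.norm(b - a))
        n_seg = max(int(np.ceil(length / spacing)), 1)
        t = np.linspace(0.0, 1.0, n_seg + 1)[1:-1]  # interior only
        if len(t):
            pts.append(a[None, :] + t[:, None] * (b - a)[None, :])
    return PointCloud(points=np.vstack(pts))


def chamfer_distance(p_pred: PointCloud | np.ndarray, p_gt: PointCloud | np.ndarray,
                     mode: str = "squared") -> float:
    """Bidirectional Chamfer distance between two point clouds.

    ``mode='squared'`` (default): sum of the two directional means of squared
    nearest-neighbor distances. ``mode='linear'``: the same with plain
    distances.
    """
    a = p_pred.points if isinstance(p_pred, PointCloud) else np.asarray(p_pred)
    b = p_gt.points if isinstance(p_gt, PointCloud) else np.asarray(p_gt)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("chamfer_distance requires non-empty clouds")
    d_ab, _ = cKDTree(b).query(a)
    d_ba, _ = cKDTree(a).query(b)
    if mode == "squared":
        return float((d_ab ** 2).mean() + (d_ba ** 2).mean())
    if mode == "linear":
        return float(d_ab.mean() + d_ba.mean())
    raise ValueError(f"unknown chamfer mode {mode!r}")


def simplify_graph(graph: SkeletonGraph) -> SkeletonGraph:
    """Contract every degree-2 node, retaining endpoints and branch points.

    Simplification iteratively merges the two edges incident to a degree-2
    node. A cycle consisting solely of degree-2 nodes cannot be simplified
    and raises (it flags non-tree input); other non-tree inputs emit a
    warning and are simplified where possible.
    """
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_nodes))
    g.add_edges_from(graph.edges())
    if graph.n_nodes and not is_tree(graph):
        warnings.warn("simplify_graph: input is not a tree", stacklevel=2)
    changed = True
    while changed:
        changed = False
        for node in list(g.nodes):
            if g.degree(node) != 2:
                continue
            u, v = list(g.neighbors(node))
            if u == v or g.has_edge(u, v):
                continue  # contraction would create a multi-edge / self-loop
            g.remove_node(node)
            g.add_edge(u, v)
            changed = True
    if any(g.degree(n) == 2 for n in g.nodes):
        raise ValueError("cannot simplify: cycle of degree-2 nodes")
    keep = sorted(g.nodes)
    remap = {old: new for new, old in enumerate(keep)}
    edges = [(remap[a], remap[b]) for a, b in g.edges]
    return SkeletonGraph(
        positions=graph.positions[keep],
        radii=graph.radii[keep],
        adjacency_logits=edges_to_logits(len(keep), edges),
    )


@dataclass
class MetricsReport:
    """Prediction-vs-ground-truth comparison for one tree."""

    chamfer: float  # squared-distance units (m^2) by default
    chamfer_linear: float  # plain distance (m)
    delta_nodes: int
    delta_edges: int
    pred_is_tree: bool
    spacing: float

    def to_dict(self) -> dict:
        return {
            "chamfer": self.chamfer,
            "chamfer_linear": self.chamfer_linear,
            "delta_nodes": self.delta_nodes,
            "delta_edges": self.delta_edges,
            "pred_is_tree": self.pred_is_tree,
            "spacing": self.spacing,
        }


def metrics_report(pred: SkeletonGraph, gt: SkeletonGraph,
                   spacing: float = 0.001) -> MetricsReport:
    """Chamfer distance on sampled skeletons, node/edge count deltas on
    simplified graphs, and the tree check for the prediction."""
    p_pred = sample_skeleton_points(pred, spacing)
    p_gt = sample_skeleton_points(gt, spacing)
    cd = chamfer_distance(p_pred, p_gt, mode="squared")
    cd_lin = chamfer_distance(p_pred, p_gt, mode="linear")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sp = simplify_graph(pred)
        sg = simplify_graph(gt)
    return MetricsReport(
        chamfer=cd,
        chamfer_linear=cd_lin,
        delta_nodes=abs(sp.n_nodes - sg.n_nodes),
        delta_edges=abs(len(sp.edges()) - len(sg.edges())),
        pred_is_tree=is_tree(pred),
        spacing=spacing,
    )
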