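"""Initial skeleton graph from filtered point clouds.

The pipeline: filter the raw (MVS + densified) cloud by multi-view mask
consistency, remove outliers, cluster the survivors with K-means into K nodes
(centroid position + median local radius), connect them with a Euclidean
minimum spanning tree, and parameterize the edge set as a symmetric matrix of
adjacency logits so the topology itself becomes an optimizable quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from .io_formats import BinaryMask, CameraView, PointCloud, RunConfig

__all__ = [
    "SkeletonGraph",
    "edges_to_logits",
    "mask_consistency_filter",
    "remove_outliers",
    "cluster_nodes",
    "build_mst_edges",
    "init_adjacency",
    "default_node_count",
    "initialize_graph",
]


def edges_to_logits(k: int, edges: Sequence[tuple[int, int]], eps: float = 1e-6) -> np.ndarray:
    """Symmetric K x K logit matrix: logit(1-eps) on edges, logit(eps) off."""
    if not (0.0 < eps < 0.5):
        raise ValueError("eps must lie in (0, 0.5)")
    lo = float(np.log(eps / (1.0 - eps)))
    hi = -lo
    logits = np.full((k, k), lo, dtype=np.float64)
    for i, j in edges:
        if not (0 <= i < k and 0 <= j < k):
            raise IndexError(f"edge ({i}, {j}) out of range for {k} nodes")
        logits[i, j] = hi
        logits[j, i] = hi
    np.fill_diagonal(logits, 0.0)
    return logits


# alias for the operation name used at the module surface
def init_adjacency(edges: Sequence[tuple[int, int]], k: int, eps: float = 1e-6) -> np.ndarray:
    return edges_to_logits(k, edges, eps=eps)


@dataclass
class SkeletonGraph:
    """Tree skeleton: node positions (K, 3), branch radii (K,), and a
    symmetric matrix of adjacency logits whose sigmoid is the probability
    that an edge exists. The diagonal is ignored (kept at zero)."""

    positions: np.ndarray
    radii: np.ndarray
    adjacency_logits: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=np.float64).reshape(-1)
        self.adjacency_logits = np.asarray(self.adjacency_logits, dtype=np.float64)
        k = len(self.positions)
        if self.radii.shape != (k,):
            raise ValueError("radii length must match node count")
        if self.adjacency_logits.shape != (k, k):
            raise ValueError("adjacency_logits must be K x K")
        if not np.allclose(self.adjacency_logits, self.adjacency_logits.T):
            raise ValueError("adjacency_logits must be symmetric")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        np.fill_diagonal(self.adjacency_logits, 0.0)

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    def adjacency_probabilities(self) -> np.ndarray:
        from scipy.special import expit

        a = expit(self.adjacency_logits)
        np.fill_diagonal(a, 0.0)
        return a

    def edges(self, threshold: float = 0.5) -> list[tuple[int, int]]:
        """Upper-triangular pairs whose edge probability exceeds threshold."""
        a = self.adjacency_probabilities()
        ii, jj = np.where(np.triu(a, 1) > threshold)
        return list(zip(ii.tolist(), jj.tolist()))

    def copy(self) -> "SkeletonGraph":
        return SkeletonGraph(self.positions.copy(), self.radii.copy(),
                             self.adjacency_logits.copy())

    def bbox_diagonal(self) -> float:
        if self.n_nodes < 2:
            return 1.0
        span = self.positions.max(axis=0) - self.positions.min(axis=0)
        return float(np.linalg.norm(span)) or 1.0


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def mask_consistency_filter(cloud: PointCloud, views: Sequence[CameraView],
                            masks: Sequence[BinaryMask], n_min: int = 3,
                            z_near: float = 0.01) -> PointCloud:
    """Keep points whose projection lands on >= n_min foreground masks.

    A view only counts if the point is in front of the camera (z > z_near)
    and projects inside the image bounds onto a foreground pixel.
    """
    if not views:
        raise ValueError("mask_consistency_filter requires at least one view")
    if len(views) != len(masks):
        raise ValueError("views and masks must align")
    if n_min < 1:
        raise ValueError("n_min must be >= 1")
    pts = cloud.points
    if len(pts) == 0:
        return PointCloud(points=pts)
    votes = np.zeros(len(pts), dtype=np.int64)
    for view, mask in zip(views, masks):
        uv, z = view.project(pts)
        col = np.floor(uv[:, 0]).astype(np.int64)
        row = np.floor(uv[:, 1]).astype(np.int64)
        ok = (z > z_near) & (col >= 0) & (col < view.width) & (row >= 0) & (row < view.height)
        hit = np.zeros(len(pts), dtype=bool)
        hit[ok] = mask.grid[row[ok], col[ok]]
        votes += hit
    return PointCloud(points=pts[votes >= n_min])


def remove_outliers(cloud: PointCloud, radius_r: float | None = None,
                    min_neighbors: int = 5, sor_k: int = 20,
                    sor_std: float = 2.0) -> PointCloud:
    """Radius-based then statistical outlier removal.

    ``radius_r`` defaults to twice the median nearest-neighbor distance.
    The statistical stage drops points whose mean distance to their sor_k
    nearest neighbors exceeds the global mean by more than sor_std standard
    deviations.
    """
    pts = cloud.points
    if len(pts) == 0:
        raise ValueError("remove_outliers: empty cloud")
    tree = cKDTree(pts)
    if radius_r is None:
        nn_d, _ = tree.query(pts, k=min(2, len(pts)))
        radius_r = 2.0 * float(np.median(nn_d[:, -1])) if len(pts) > 1 else 1.0
    counts = np.array([len(idx) - 1 for idx in tree.query_ball_point(pts, radius_r)])
    pts = pts[counts >= min_neighbors]
    if len(pts) == 0:
        raise ValueError(
            "radius filter removed every point; relax radius_r/min_neighbors")
    k = min(sor_k + 1, len(pts))
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=k)
    mean_d = d[:, 1:].mean(axis=1) if k > 1 else np.zeros(len(pts))
    keep = mean_d <= mean_d.mean() + sor_std * mean_d.std()
    pts = pts[keep]
    if len(pts) == 0:
        raise ValueError("statistical filter removed every point; relax sor_std")
    return PointCloud(points=pts)


# ---------------------------------------------------------------------------
# clustering and MST
# ---------------------------------------------------------------------------

def default_node_count(n_points: int) -> int:
    """Node budget tied to cloud density: clamp(round(n/200), 16, 256)."""
    return int(np.clip(round(n_points / 200), 16, 256))


def cluster_nodes(cloud: PointCloud, k: int, seed: int = 0,
                  r_min_init: float = 0.005) -> tuple[np.ndarray, np.ndarray]:
    """K-means cluster centroids and per-cluster median local radius.

    Cluster members of a branch spread mostly *along* the branch, so the
    local radius is measured as the median distance to the cluster's first
    principal axis through the centroid (the local cylinder radius).
    Clusters too small for a stable axis (< 3 points) fall back to the
    median distance to the centroid. Radii are floored at ``r_min_init``
    (meters) so degenerate clusters still carry a usable branch radius.
    """
    pts = cloud.points
    if k > len(pts):
        raise ValueError(f"k={k} exceeds point count {len(pts)}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=300,
                random_state=seed)
    labels = km.fit_predict(pts)
    centers = km.cluster_centers_.astype(np.float64)
    radii = np.empty(k, dtype=np.float64)
    for i in range(k):
        members = pts[labels == i]
        if len(members) == 0:  # sklearn relocates empty clusters; guard anyway
            radii[i] = r_min_init
            continue
        d = members - centers[i]
        if len(members) >= 3:
            # distance to the first principal axis through the centroid
            _, _, vt = np.linalg.svd(d, full_matrices=False)
            axis = vt[0]
            perp = d - np.outer(d @ axis, axis)
            radii[i] = np.median(np.linalg.norm(perp, axis=1))
        else:
            radii[i] = np.median(np.linalg.norm(d, axis=1))
    return centers, np.maximum(radii, r_min_init)


def build_mst_edges(positions: np.ndarray) -> list[tuple[int, int]]:
    """Euclidean minimum spanning tree over the complete node graph.

    Delegates to Kruskal with deterministic (weight, i, j) tie-breaking.
    """
    from .sfs_mst import hard_mst

    positions = np.asarray(positions, dtype=float)
    k = len(positions)
    if k <= 1:
        return []
    diff = positions[:, None, :] - positions[None, :, :]
    w = np.sqrt((diff ** 2).sum(axis=2))
    mask = hard_mst(w)
    ii, jj = np.where(np.triu(mask, 1))
    return list(zip(ii.tolist(), jj.tolist()))


def initialize_graph(cloud: PointCloud, views: Sequence[CameraView],
                     masks: Sequence[BinaryMask], config: RunConfig | None = None,
                     cloud_gs: PointCloud | None = None) -> SkeletonGraph:
    """Full initialization: merge clouds, filter, cluster, MST, logits."""
    config = config or RunConfig()
    pts = cloud.points
    if cloud_gs is not None and len(cloud_gs):
        pts = np.vstack([pts, cloud_gs.points])
    merged = PointCloud(points=pts)
    filtered = mask_consistency_filter(merged, views, masks,
                                       n_min=min(config.n_min, len(views)),
                                       z_near=config.z_near)
    cleaned = remove_outliers(filtered, radius_r=config.outlier_radius,
                              min_neighbors=config.outlier_min_neighbors,
                              sor_k=config.sor_k, sor_std=config.sor_std)
    k = config.kmeans_k or default_node_count(len(cleaned))
    k = min(k, len(cleaned))
    centers, radii = cluster_nodes(cleaned, k, seed=config.seed,
                                   r_min_init=config.r_min_init)
    edges = build_mst_edges(centers)
    logits = edges_to_logits(k, edges, eps=config.eps)
    return SkeletonGraph(positions=centers, radii=radii, adjacency_logits=logits)
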