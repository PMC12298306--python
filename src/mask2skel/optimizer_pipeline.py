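"""End-to-end refinement loop: render, project to a tree, score, step.

Per iteration the loop (1) projects the soft adjacency onto its
maximum-probability spanning tree, (2) samples splats on the soft edge
support (probability above a floor, union the MST edges) and on the MST
edges, (3) renders both silhouettes for a deterministic cyclic batch of
views, (4) evaluates the silhouette and geometry losses, and (5) takes an
Adam step on three parameter groups: node positions, log-radii (so radii
stay positive) and adjacency logits. The state with the best total loss is
returned; finalization snaps the adjacency to the hard MST, which makes
every output a valid tree by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

from .graph_init import SkeletonGraph
from .io_formats import BinaryMask, CameraView, RunConfig
from .losses import build_omega, geometry_loss, silhouette_loss
from .sfs_mst import sfs_project
from .splat_renderer import SplatSet, render_backward, render_silhouette, sample_edge_gaussians

__all__ = ["OptimizationState", "optimize_graph", "finalize_tree"]

_LOGIT_CLAMP = None  # set per config eps


@dataclass
class OptimizationState:
    """Mutable optimizer view of the graph plus bookkeeping."""

    graph: SkeletonGraph
    iteration: int = 0
    history: dict = field(default_factory=lambda: {
        "total": [], "l_gs": [], "l_mst": [], "rep": [], "edge_short": [],
        "angle": [], "mid": [], "radius": []})
    seed: int = 0

    @property
    def log_radii(self) -> np.ndarray:
        return np.log(self.graph.radii)


class _Adam:
    def __init__(self, shape, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.t = 0

    def step(self, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * grad
        self.v = self.b2 * self.v + (1 - self.b2) * grad ** 2
        mh = self.m / (1 - self.b1 ** self.t)
        vh = self.v / (1 - self.b2 ** self.t)
        return self.lr * mh / (np.sqrt(vh) + self.eps)


def _splat_grads_to_graph(splats: SplatSet, grads, k: int):
    """Chain splat-level gradients to node positions, radii and per-edge
    opacity. Splat m at fraction t on edge (i, j) contributes (1-t) to node i
    and t to node j for both center and scale."""
    d_pos = np.zeros((k, 3))
    d_rad = np.zeros(k)
    n_edges = len(splats.edge_nodes)
    d_op_edge = np.zeros(n_edges)
    if len(splats) == 0:
        return d_pos, d_rad, d_op_edge
    ni = splats.edge_nodes[splats.edge_index, 0]
    nj = splats.edge_nodes[splats.edge_index, 1]
    t = splats.frac
    np.add.at(d_pos, ni, (1.0 - t)[:, None] * grads.d_centers)
    np.add.at(d_pos, nj, t[:, None] * grads.d_centers)
    np.add.at(d_rad, ni, (1.0 - t) * grads.d_scales)
    np.add.at(d_rad, nj, t * grads.d_scales)
    np.add.at(d_op_edge, splats.edge_index, grads.d_opacities)
    return d_pos, d_rad, d_op_edge


def optimize_graph(init: SkeletonGraph, views: Sequence[CameraView],
                   masks: Sequence[BinaryMask], config: RunConfig | None = None,
                   iterations: int | None = None):
    """Refine an initial skeleton graph against multi-view silhouettes.

    Returns (refined SkeletonGraph at the best total loss, OptimizationState
    with per-component loss history). Deterministic given the config.
    """
    config = config or RunConfig()
    n_iter = config.iterations if iterations is None else iterations
    if len(views) < 2:
        raise ValueError("optimization requires at least two views")
    if len(views) != len(masks):
        raise ValueError("views and masks must align")
    state = OptimizationState(graph=init.copy(), seed=config.seed)
    if n_iter == 0:
        return init.copy(), state

    k = init.n_nodes
    diag = init.bbox_diagonal()
    positions = init.positions.copy()
    log_radii = np.log(init.radii.copy())
    logits = init.adjacency_logits.copy()
    clamp = float(np.log((1 - config.eps) / config.eps))
    # nodes may not leave the observed volume: the initial graph lies inside
    # the multi-view visual hull, so its padded bounding box bounds the scene
    box_lo = init.positions.min(axis=0) - 0.1 * diag
    box_hi = init.positions.max(axis=0) + 0.1 * diag

    adam_pos = _Adam((k, 3), config.lr_positions * diag)
    adam_rad = _Adam((k,), config.lr_log_radii)
    # exponential position-lr decay: coarse alignment early, sub-pixel
    # settling late
    pos_decay = config.lr_position_decay ** (1.0 / max(n_iter, 1))

    n_views = len(views)
    batch = min(config.view_batch, n_views)
    mask_grids = [m.grid.astype(np.float64) for m in masks]

    best = {"loss": np.inf, "positions": positions.copy(),
            "log_radii": log_radii.copy(), "logits": logits.copy()}

    for it in range(n_iter):
        graph = SkeletonGraph(positions=positions, radii=np.exp(log_radii),
                              adjacency_logits=logits)
        probs = graph.adjacency_probabilities()
        ii, jj = np.where(np.triu(probs, 1) > config.prob_floor)
        if config.use_sfs:
            proj = sfs_project(logits, positions, weight_mode=config.mst_weight_mode)
            mst_edges = proj.edges()
        else:  # ablation: no in-loop tree projection; regularize soft edges
            mst_edges = graph.edges()
        soft_edges = sorted(set(zip(ii.tolist(), jj.tolist())) | set(mst_edges))
        share = not config.use_sfs

        # The soft rendering carries the adjacency evidence (opacity = edge
        # probability); the MST rendering supervises the geometry of the
        # current best tree and is rendered with fully opaque edges
        # (straight-through through the hard mask), so that a partially
        # suppressed edge cannot drag its endpoints around via a dim,
        # under-covering silhouette.
        splats_soft = sample_edge_gaussians(graph, config.n_per_edge, soft_edges)
        if share:
            splats_mst = splats_soft
        else:
            splats_mst = sample_edge_gaussians(
                graph, config.n_per_edge, mst_edges,
                opacity_override=None if not config.use_sfs else 1.0 - config.eps)

        view_ids = [(it * batch + b) % n_views for b in range(batch)]
        l_gs_sum = l_mst_sum = 0.0
        d_pos = np.zeros((k, 3))
        d_rad = np.zeros(k)
        d_logit_edge_soft = np.zeros(len(splats_soft.edge_nodes))
        d_logit_edge_mst = np.zeros(len(splats_mst.edge_nodes))
        live_views = 0
        for vi in view_ids:
            view, m = views[vi], mask_grids[vi]
            r_soft = render_silhouette(splats_soft, view, config)
            r_mst = r_soft if share else render_silhouette(splats_mst, view, config)
            omega = build_omega(m, np.maximum(r_soft.alpha, r_mst.alpha),
                                config.omega_dilate_frac, config.omega_alpha_thresh)
            if not omega.any():
                continue
            live_views += 1
            l_gs, l_mst, _, d_a, d_a_mst = silhouette_loss(
                r_soft.alpha, r_mst.alpha, m, omega,
                config.lambda_gs, config.lambda_mst)
            l_gs_sum += l_gs
            l_mst_sum += l_mst
            if share:
                g = render_backward(r_soft.cache,
                                    config.lambda_gs * d_a + config.lambda_mst * d_a_mst)
                dp, dr, dov = _splat_grads_to_graph(splats_soft, g, k)
                d_pos += dp
                d_rad += dr
                d_logit_edge_soft += dov
            else:
                g1 = render_backward(r_soft.cache, config.lambda_gs * d_a)
                dp, dr, dov = _splat_grads_to_graph(splats_soft, g1, k)
                d_pos += dp
                d_rad += dr
                d_logit_edge_soft += dov
                g2 = render_backward(r_mst.cache, config.lambda_mst * d_a_mst)
                dp, dr, dov = _splat_grads_to_graph(splats_mst, g2, k)
                d_pos += dp
                d_rad += dr
                d_logit_edge_mst += dov
        if live_views == 0:
            raise ValueError("empty Omega in every view of the batch: "
                             "masks and renderings are disjoint")
        inv = 1.0 / live_views
        l_gs_mean = l_gs_sum * inv
        l_mst_mean = l_mst_sum * inv
        d_pos *= inv
        d_rad *= inv
        d_logit_edge_soft *= inv
        d_logit_edge_mst *= inv

        geo = geometry_loss(positions, np.exp(log_radii), mst_edges, config)
        total = (config.lambda_gs * l_gs_mean + config.lambda_mst * l_mst_mean
                 + geo.value)
        if not np.isfinite(total):
            raise RuntimeError(
                f"non-finite loss at iteration {it}; state: "
                f"|pos|max={np.abs(positions).max():.3g}, "
                f"|logit|max={np.abs(logits).max():.3g}")

        # assemble parameter-group gradients
        radii = np.exp(log_radii)
        grad_pos = d_pos + geo.d_positions
        grad_log_rad = (d_rad + geo.d_radii) * radii  # chain r = exp(rho)
        # Adjacency uses a straight-through estimator: near the saturated
        # initialization the sigmoid derivative is ~eps and would freeze the
        # topology (and magnitude-normalized updates would suppress weakly
        # and strongly contradicted edges at the same speed), so the opacity
        # gradient acts on the logit directly via plain gradient descent —
        # suppression speed is then proportional to the silhouette evidence
        # against an edge. The median opacity gradient over the sampled
        # edges is subtracted first: splats rendered for sub-pixel-thin
        # branches spill a Gaussian skirt over background in *every* edge
        # alike, a common-mode artifact of the renderer rather than
        # edge-existence evidence; only the differential part — edges
        # contradicted more than is typical for this scene — encodes
        # connectivity.
        grad_logits = np.zeros((k, k))
        sampled = np.zeros((k, k), dtype=bool)
        if len(splats_soft.edge_nodes) and d_logit_edge_soft.any():
            en = splats_soft.edge_nodes
            grad_logits[en[:, 0], en[:, 1]] += d_logit_edge_soft
            grad_logits[en[:, 1], en[:, 0]] += d_logit_edge_soft
            sampled[en[:, 0], en[:, 1]] = True
            sampled[en[:, 1], en[:, 0]] = True
        if sampled.any():
            grad_logits[sampled] -= np.median(grad_logits[sampled])

        positions = np.clip(positions - adam_pos.step(grad_pos), box_lo, box_hi)
        adam_pos.lr *= pos_decay
        log_radii = log_radii - adam_rad.step(grad_log_rad)
        logits = logits - config.lr_logits * grad_logits
        logits = 0.5 * (logits + logits.T)
        logits = np.clip(logits, -clamp, clamp)
        np.fill_diagonal(logits, 0.0)

        state.history["total"].append(total)
        state.history["l_gs"].append(l_gs_mean)
        state.history["l_mst"].append(l_mst_mean)
        for name in ("rep", "edge_short", "angle", "mid", "radius"):
            state.history[name].append(geo.components[name])
        state.iteration = it + 1
        if total < best["loss"]:
            best = {"loss": total, "positions": positions.copy(),
                    "log_radii": log_radii.copy(), "logits": logits.copy()}

    refined = SkeletonGraph(positions=best["positions"],
                            radii=np.exp(best["log_radii"]),
                            adjacency_logits=best["logits"])
    state.graph = refined
    return refined, state


def finalize_tree(graph: SkeletonGraph, config: RunConfig | None = None) -> SkeletonGraph:
    """Snap the soft adjacency to its hard MST: retained edges get
    logit(1 - eps), all others logit(eps). The output always satisfies the
    connected-acyclic tree check."""
    config = config or RunConfig()
    proj = sfs_project(graph.adjacency_logits, graph.positions,
                       weight_mode=config.mst_weight_mode)
    hi = float(np.log((1 - config.eps) / config.eps))
    logits = np.where(proj.edge_mask, hi, -hi)
    np.fill_diagonal(logits, 0.0)
    return SkeletonGraph(positions=graph.positions.copy(),
                         radii=graph.radii.copy(), adjacency_logits=logits)
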