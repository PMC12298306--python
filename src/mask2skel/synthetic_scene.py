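"""Procedural test scenes: turtle-generated 3D trees with known skeletons,
camera rings, rendered ground-truth silhouettes, and corrupted point clouds
that emulate the failure modes of image-based reconstruction on thin
branches (surface noise, missing branch fragments, floating outliers).

Two regimes are covered by one parametric generator: ``curvature=0`` gives
straight, uniformly branching trees a few meters tall (rewriting-grammar
style), while ``curvature>0`` subdivides and bends segments to produce
larger, organically curved trees with pronounced trunk-to-tip taper.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .graph_init import SkeletonGraph, edges_to_logits
from .io_formats import BinaryMask, CameraView, PointCloud, RunConfig
from .splat_renderer import render_silhouette, sample_edge_gaussians

__all__ = [
    "SceneBundle",
    "generate_lsystem_tree",
    "make_camera_ring",
    "render_gt_masks",
    "corrupt_point_cloud",
    "corrupt_masks",
    "make_scene",
]


# ---------------------------------------------------------------------------
# tree generation
# ---------------------------------------------------------------------------

def _perp_unit(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random unit vector perpendicular to v."""
    while True:
        r = rng.normal(size=3)
        p = r - (r @ v) * v
        n = np.linalg.norm(p)
        if n > 1e-9:
            return p / n


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1 - c)


def generate_lsystem_tree(depth: int = 4, branch_prob: float = 0.8,
                          branch_angle_deg: float = 30.0,
                          length_decay: float = 0.75,
                          radius_decay: float = 0.7,
                          curvature: float = 0.0,
                          seed: int = 0,
                          trunk_length: float = 1.5,
                          trunk_radius: float = 0.04,
                          min_radius: float = 0.003,
                          eps: float = 1e-6) -> SkeletonGraph:
    """Stochastic recursive branching interpreted by a 3D turtle.

    Each generation grows a segment and then either bifurcates (probability
    ``branch_prob``, both children pitched ~``branch_angle_deg`` away from
    the parent direction at opposed azimuths) or continues with a single
    jittered child. Segment lengths shrink by ``length_decay`` and radii by
    ``radius_decay`` per generation. ``curvature > 0`` splits every segment
    into three sub-segments bent by Gaussian angles of that scale (radians),
    producing organic, curved branches. Deterministic in ``seed``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not (0.0 < length_decay <= 1.0 and 0.0 < radius_decay <= 1.0):
        raise ValueError("decay factors must lie in (0, 1]")
    if not (0.0 <= branch_prob <= 1.0):
        raise ValueError("branch_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    positions = [np.zeros(3)]
    radii = [trunk_radius]
    edges: list[tuple[int, int]] = []
    angle = np.deg2rad(branch_angle_deg)

    def add_segment(start_idx: int, direction: np.ndarray, length: float,
                    r_start: float, r_end: float) -> int:
        """Grow one segment (possibly subdivided when curved); returns the
        index of its end node."""
        n_sub = 3 if curvature > 0 else 1
        idx = start_idx
        d = direction.copy()
        for s in range(n_sub):
            if curvature > 0:
                axis = _perp_unit(d, rng)
                d = _rotate(d, axis, rng.normal(0.0, curvature))
                d /= np.linalg.norm(d)
            frac = (s + 1) / n_sub
            pos = positions[idx] + d * (length / n_sub)
            rad = max(r_start + frac * (r_end - r_start), min_radius)
            positions.append(pos)
            radii.append(rad)
            new_idx = len(positions) - 1
            edges.append((idx, new_idx))
            idx = new_idx
        return idx

    def grow(node_idx: int, direction: np.ndarray, length: float,
             radius: float, gen: int) -> None:
        r_end = max(radius * radius_decay, min_radius)
        end_idx = add_segment(node_idx, direction, length, radius, r_end)
        if gen + 1 >= depth:
            return
        if rng.random() < branch_prob:
            axis = _perp_unit(direction, rng)
            spin = rng.uniform(0.0, np.pi)
            for sgn in (1.0, -1.0):
                a = _rotate(axis, direction, spin)
                jitter = rng.normal(0.0, 0.15 * angle)
                child = _rotate(direction, a, sgn * (angle + jitter))
                child /= np.linalg.norm(child)
                grow(end_idx, child, length * length_decay, r_end, gen + 1)
        else:
            axis = _perp_unit(direction, rng)
            child = _rotate(direction, axis, rng.normal(0.0, 0.3 * angle))
            child /= np.linalg.norm(child)
            grow(end_idx, child, length * length_decay, r_end, gen + 1)

    grow(0, np.array([0.0, 0.0, 1.0]), trunk_length, trunk_radius, 0)
    k = len(positions)
    logits = edges_to_logits(k, edges, eps=eps)
    return SkeletonGraph(positions=np.array(positions), radii=np.array(radii),
                         adjacency_logits=logits)


# ---------------------------------------------------------------------------
# cameras
# ---------------------------------------------------------------------------

def _look_at(center: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """World->camera rotation and translation for a camera at ``center``
    looking at ``target`` (world up = +z; image x right, y down)."""
    f = target - center
    f = f / np.linalg.norm(f)
    up = np.array([0.0, 0.0, 1.0])
    if abs(f @ up) > 0.999:
        up = np.array([0.0, 1.0, 0.0])
    x = np.cross(f, up)
    x /= np.linalg.norm(x)
    y = np.cross(f, x)
    R = np.stack([x, y, f])
    t = -R @ center
    return R, t


def make_camera_ring(n_views: int, ring_radius: float, height: float,
                     arc_deg: float = 360.0,
                     target: np.ndarray | Sequence[float] = (0.0, 0.0, 0.0),
                     intrinsics: tuple = (200.0, 200.0, 64.0, 64.0, 128, 128)) -> list[CameraView]:
    """Cameras evenly spaced on a horizontal arc, all looking at ``target``.

    A full ring (arc 360) spaces centers by arc/n; a partial arc (sidewalk
    capture regime) spreads them over [0, arc].
    """
    if n_views < 2:
        raise ValueError("n_views must be >= 2")
    target = np.asarray(target, dtype=float)
    fx, fy, cx, cy, w, h = intrinsics
    if arc_deg >= 360.0:
        angles = np.deg2rad(360.0 * np.arange(n_views) / n_views)
    else:
        angles = np.deg2rad(arc_deg * np.arange(n_views) / (n_views - 1))
    views = []
    for i, a in enumerate(angles):
        center = np.array([target[0] + ring_radius * np.cos(a),
                           target[1] + ring_radius * np.sin(a), height])
        R, t = _look_at(center, target)
        views.append(CameraView(fx=fx, fy=fy, cx=cx, cy=cy, width=int(w),
                                height=int(h), rotation=R, translation=t,
                                view_id=f"{i:03d}"))
    return views


# ---------------------------------------------------------------------------
# ground-truth silhouettes
# ---------------------------------------------------------------------------

def render_gt_masks(gt_graph: SkeletonGraph, views: Sequence[CameraView],
                    threshold: float = 0.5, config: RunConfig | None = None,
                    n_dense: int = 128) -> list[BinaryMask]:
    """Binary silhouettes of the ground-truth skeleton: the graph is rendered
    with fully opaque edges (opacity 1 - eps) and dense per-edge sampling,
    then thresholded."""
    config = config or RunConfig()
    splats = sample_edge_gaussians(gt_graph, n_dense, gt_graph.edges(),
                                   opacity_override=1.0 - config.eps)
    masks = []
    any_fg = False
    for view in views:
        r = render_silhouette(splats, view, config, with_cache=False)
        grid = r.alpha > threshold
        any_fg |= bool(grid.any())
        masks.append(BinaryMask(grid=grid, view_id=view.view_id))
    if not any_fg:
        raise ValueError("ground-truth graph renders empty in every view "
                         "(outside all camera frusta?)")
    return masks


# ---------------------------------------------------------------------------
# corruption
# ---------------------------------------------------------------------------

def corrupt_point_cloud(gt_graph: SkeletonGraph, points_per_meter: float = 400.0,
                        noise_sd: float = 0.01, fragment_drop_frac: float = 0.2,
                        outlier_frac: float = 0.05, seed: int = 0) -> PointCloud:
    """Reconstruction-like cloud: branch-surface samples with Gaussian noise,
    whole contiguous spans of skeleton deleted (fragmentation), and uniform
    outliers in a 1.5x bounding box. Outlier count is ``outlier_frac`` of the
    pre-drop surface sample count, so a fully fragmented cloud still contains
    its outliers. Deterministic in ``seed``."""
    for name, frac in (("fragment_drop_frac", fragment_drop_frac),
                       ("outlier_frac", outlier_frac)):
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    edges = gt_graph.edges()
    pos, rad = gt_graph.positions, gt_graph.radii
    lengths = np.array([np.linalg.norm(pos[j] - pos[i]) for i, j in edges])
    total_len = lengths.sum()
    samples = []
    sample_edge = []
    sample_t = []
    for e, (i, j) in enumerate(edges):
        n = max(int(round(points_per_meter * lengths[e])), 1)
        t = rng.uniform(0.0, 1.0, n)
        axis = pos[j] - pos[i]
        axis_u = axis / (lengths[e] or 1.0)
        r_t = rad[i] + t * (rad[j] - rad[i])
        perp = np.array([_perp_unit(axis_u, rng) for _ in range(n)])
        p = pos[i][None, :] + t[:, None] * axis[None, :] + r_t[:, None] * perp
        samples.append(p)
        sample_edge.append(np.full(n, e))
        sample_t.append(t)
    pts = np.vstack(samples)
    edge_id = np.concatenate(sample_edge)
    t_all = np.concatenate(sample_t)
    n_sampled = len(pts)
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, pts.shape)

    # drop whole contiguous spans (full edges, plus one partial interval)
    keep = np.ones(n_sampled, dtype=bool)
    target = fragment_drop_frac * total_len
    if target > 0:
        order = rng.permutation(len(edges))
        dropped = 0.0
        for e in order:
            if dropped >= target:
                break
            remaining = target - dropped
            if lengths[e] <= remaining:
                keep[edge_id == e] = False
                dropped += lengths[e]
            else:
                span = remaining / lengths[e]
                t0 = rng.uniform(0.0, 1.0 - span)
                sel = (edge_id == e) & (t_all >= t0) & (t_all <= t0 + span)
                keep[sel] = False
                dropped += remaining
    pts = pts[keep]

    n_out = int(round(outlier_frac * n_sampled))
    if n_out > 0:
        lo = pos.min(axis=0)
        hi = pos.max(axis=0)
        mid = (lo + hi) / 2
        half = np.maximum((hi - lo) / 2, 1e-3) * 1.5
        outliers = rng.uniform(mid - half, mid + half, size=(n_out, 3))
        pts = np.vstack([pts, outliers]) if len(pts) else outliers
    return PointCloud(points=pts)


def corrupt_masks(masks: Sequence[BinaryMask], erode_frac_views: float = 0.0,
                  erode_px: int = 1, seed: int = 0) -> list[BinaryMask]:
    """Erode the masks of a seeded random subset of views by ``erode_px``
    pixels (3x3 structuring element applied iteratively), emulating views
    whose segmentation lost thin branches."""
    if not (0.0 <= erode_frac_views <= 1.0):
        raise ValueError("erode_frac_views must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(masks)
    n_affected = int(round(erode_frac_views * n))
    affected = set(rng.choice(n, size=n_affected, replace=False).tolist())
    out = []
    for i, m in enumerate(masks):
        if i in affected and erode_px > 0:
            grid = ndimage.binary_erosion(m.grid, structure=np.ones((3, 3), bool),
                                          iterations=erode_px, border_value=0)
            out.append(BinaryMask(grid=grid, view_id=m.view_id))
        else:
            out.append(BinaryMask(grid=m.grid.copy(), view_id=m.view_id))
    return out


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

@dataclass
class SceneBundle:
    """A complete reproducible fixture: ground-truth skeleton, camera ring,
    ground-truth silhouettes, and a corrupted initialization cloud."""

    gt_graph: SkeletonGraph
    views: list[CameraView]
    gt_masks: list[BinaryMask]
    corrupted_cloud: PointCloud
    seed: int


_MODE_PRESETS = {
    # straight, uniformly branching, a few meters tall
    "straight": dict(depth=4, branch_prob=0.85, branch_angle_deg=30.0,
                     length_decay=0.75, radius_decay=0.7, curvature=0.0,
                     trunk_length=1.4, trunk_radius=0.05),
    # curved, organically bending, strongly tapering, up to ~15-20 m
    "curved": dict(depth=4, branch_prob=0.85, branch_angle_deg=35.0,
                   length_decay=0.8, radius_decay=0.55, curvature=0.18,
                   trunk_length=5.0, trunk_radius=0.3),
}


def make_scene(mode: str = "straight", n_views: int = 12, resolution: int = 128,
               seed: int = 0, arc_deg: float = 360.0,
               noise_sd: float | None = None, fragment_drop_frac: float = 0.2,
               outlier_frac: float = 0.05, points_per_meter: float | None = None,
               config: RunConfig | None = None) -> SceneBundle:
    """Build a full synthetic scene in one of two regimes.

    Cameras form a ring (radius ~1.2x the skeleton bounding-box diagonal,
    at mid-height) with focal length chosen so the tree fills most of the
    frame. Noise and sampling density default to scale-aware values: surface
    noise 1 cm (straight) / 4 cm (curved).
    """
    if mode not in _MODE_PRESETS:
        raise ValueError(f"mode must be one of {sorted(_MODE_PRESETS)}")
    config = config or RunConfig()
    gt = generate_lsystem_tree(seed=seed, eps=config.eps, **_MODE_PRESETS[mode])
    lo = gt.positions.min(axis=0)
    hi = gt.positions.max(axis=0)
    target = (lo + hi) / 2
    diag = float(np.linalg.norm(hi - lo))
    ring_radius = 1.2 * diag
    f = 0.85 * resolution * ring_radius / diag
    views = make_camera_ring(
        n_views, ring_radius, height=target[2], arc_deg=arc_deg, target=target,
        intrinsics=(f, f, resolution / 2, resolution / 2, resolution, resolution))
    gt_masks = render_gt_masks(gt, views, config=config)
    if noise_sd is None:
        noise_sd = 0.01 if mode == "straight" else 0.04
    if points_per_meter is None:
        points_per_meter = 400.0 if mode == "straight" else 100.0
    cloud = corrupt_point_cloud(gt, points_per_meter=points_per_meter,
                                noise_sd=noise_sd,
                                fragment_drop_frac=fragment_drop_frac,
                                outlier_frac=outlier_frac, seed=seed)
    return SceneBundle(gt_graph=gt, views=views, gt_masks=gt_masks,
                       corrupted_cloud=cloud, seed=seed)
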