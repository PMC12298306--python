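"""Differentiable silhouette rendering of a skeleton graph.

Each graph edge is expanded into a row of isotropic 3D Gaussians whose
centers and standard deviations interpolate the endpoint positions and radii,
and whose common opacity is the edge's adjacency probability. A pinhole
camera projects every Gaussian to an image-plane mean and (first-order)
isotropic std, and pixels composite opacities order-independently:

    alpha(x) = 1 - prod_g (1 - o_g * G_g(x)),   G_g(x) = exp(-d^2 / (2 s^2)).

Gradients of any scalar image loss with respect to splat centers, scales and
opacities are computed analytically (see ``_raster``) and chained back to
node positions, radii and adjacency logits by the optimizer.

An alternative per-splat response ``alpha = 1 - exp(-sum o_g G_g)`` is
available as ``alpha_variant='exponential'``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from . import _raster
from .graph_init import SkeletonGraph
from .io_formats import CameraView, RunConfig

__all__ = [
    "SplatSet",
    "RenderedSilhouette",
    "SplatGrads",
    "sample_edge_gaussians",
    "project_gaussian",
    "render_silhouette",
    "gradient_check",
]


@dataclass
class SplatSet:
    """Edge-sampled isotropic Gaussians. All splats of one edge share that
    edge's opacity; rotation and color are fixed constants and not stored."""

    centers: np.ndarray  # (M, 3) m
    scales: np.ndarray  # (M,) isotropic std, m
    opacities: np.ndarray  # (M,) in (0, 1)
    edge_index: np.ndarray  # (M,) index into the sampled edge list
    edge_nodes: np.ndarray  # (E, 2) node ids per sampled edge
    frac: np.ndarray  # (M,) interpolation fraction along the edge

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=np.float64))
        self.scales = np.asarray(self.scales, dtype=np.float64).reshape(-1)
        self.opacities = np.asarray(self.opacities, dtype=np.float64).reshape(-1)
        if np.any(self.scales <= 0) and len(self.scales):
            raise ValueError("splat scales must be positive")
        if len(self.opacities) and (np.any(self.opacities <= 0) or np.any(self.opacities > 1)):
            raise ValueError("opacities must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.scales)


@dataclass
class RenderedSilhouette:
    alpha: np.ndarray  # (H, W) in [0, 1]
    view_id: str
    cache: "RenderCache | None" = None


@dataclass
class RenderCache:
    """Everything backward needs: per-splat projected quantities and the
    per-pixel transmittance product."""

    view: CameraView
    config: RunConfig
    n_splats: int
    valid_idx: np.ndarray  # (Mv,) indices into the splat set, canonical order
    cam_xyz: np.ndarray  # (Mv, 3)
    mean2d: np.ndarray  # (Mv, 2)
    std2d: np.ndarray  # (Mv,)
    sigma_clamped: np.ndarray  # (Mv,) bool
    opacities: np.ndarray  # (Mv,)
    scales: np.ndarray  # (Mv,)
    prod: np.ndarray  # (H, W) transmittance = 1 - alpha


@dataclass
class SplatGrads:
    d_centers: np.ndarray  # (M, 3)
    d_scales: np.ndarray  # (M,)
    d_opacities: np.ndarray  # (M,)


def sample_edge_gaussians(graph: SkeletonGraph, n_per_edge: int,
                          edge_set: list[tuple[int, int]],
                          opacity_override: float | None = None) -> SplatSet:
    """Expand edges into n_per_edge + 1 splats each, at fractions n/N along
    the segment, with linearly interpolated radii as isotropic scales.

    Opacities come from the graph's adjacency probabilities unless
    ``opacity_override`` pins them (used for ground-truth mask rendering).
    """
    if n_per_edge < 1:
        raise ValueError("n_per_edge must be >= 1")
    e = len(edge_set)
    if e == 0:
        return SplatSet(centers=np.zeros((0, 3)), scales=np.zeros(0),
                        opacities=np.zeros(0), edge_index=np.zeros(0, dtype=int),
                        edge_nodes=np.zeros((0, 2), dtype=int), frac=np.zeros(0))
    edge_nodes = np.asarray(edge_set, dtype=int).reshape(e, 2)
    t = np.linspace(0.0, 1.0, n_per_edge + 1)  # (S,)
    ci = graph.positions[edge_nodes[:, 0]]  # (E, 3)
    cj = graph.positions[edge_nodes[:, 1]]
    ri = graph.radii[edge_nodes[:, 0]]
    rj = graph.radii[edge_nodes[:, 1]]
    centers = ci[:, None, :] + t[None, :, None] * (cj - ci)[:, None, :]
    scales = ri[:, None] + t[None, :] * (rj - ri)[:, None]
    if opacity_override is not None:
        op_edge = np.full(e, float(opacity_override))
    else:
        op_edge = expit(graph.adjacency_logits[edge_nodes[:, 0], edge_nodes[:, 1]])
    s = len(t)
    return SplatSet(
        centers=centers.reshape(-1, 3),
        scales=scales.reshape(-1),
        opacities=np.repeat(op_edge, s),
        edge_index=np.repeat(np.arange(e), s),
        edge_nodes=edge_nodes,
        frac=np.tile(t, e),
    )


def project_gaussian(centers: np.ndarray, scales: np.ndarray, view: CameraView,
                     config: RunConfig | None = None):
    """Project 3D isotropic Gaussians into the image plane.

    Returns (mean2d (M,2) px, std2d (M,) px, depth (M,), culled (M,) bool).
    The image-plane std is first-order pinhole scaling ``max(fx,fy)*s/z``
    plus a sub-pixel blur floor, clamped to ``sigma_max_px``; splats with
    depth <= z_near are flagged culled (not an error).
    """
    config = config or RunConfig()
    c = np.atleast_2d(np.asarray(centers, dtype=np.float64))
    s = np.asarray(scales, dtype=np.float64).reshape(-1)
    cam = c @ view.rotation.T + view.translation
    z = cam[:, 2]
    culled = z <= config.z_near
    zsafe = np.where(culled, 1.0, z)
    u = view.fx * cam[:, 0] / zsafe + view.cx
    v = view.fy * cam[:, 1] / zsafe + view.cy
    fm = max(view.fx, view.fy)
    sigma = fm * s / zsafe + config.blur_floor_px
    sigma = np.minimum(sigma, config.sigma_max_px)
    return np.stack([u, v], axis=1), sigma, z, culled


def render_silhouette(splats: SplatSet, view: CameraView,
                      config: RunConfig | None = None,
                      with_cache: bool = True) -> RenderedSilhouette:
    """Composite the splat set into a soft silhouette for one view."""
    config = config or RunConfig()
    h, w = view.height, view.width
    variant = (_raster.VARIANT_EXPONENTIAL if config.alpha_variant == "exponential"
               else _raster.VARIANT_PRODUCT)
    acc = np.zeros((h, w), dtype=np.float64)
    if len(splats) == 0:
        alpha = np.zeros((h, w))
        cache = RenderCache(view, config, 0, np.zeros(0, dtype=int),
                            np.zeros((0, 3)), np.zeros((0, 2)), np.zeros(0),
                            np.zeros(0, dtype=bool), np.zeros(0), np.zeros(0),
                            np.ones((h, w)))
        return RenderedSilhouette(alpha=alpha, view_id=view.view_id,
                                  cache=cache if with_cache else None)
    mean2d, sigma, z, culled = project_gaussian(splats.centers, splats.scales,
                                                view, config)
    r = config.cutoff_sigma * sigma
    on_image = ((mean2d[:, 0] + r >= 0) & (mean2d[:, 0] - r <= w) &
                (mean2d[:, 1] + r >= 0) & (mean2d[:, 1] - r <= h))
    valid = np.flatnonzero(~culled & on_image)
    # canonical processing order: per-pixel accumulation then does not
    # depend on the order splats were supplied in (permutation-invariant
    # rendering, bit for bit)
    order = np.lexsort((splats.opacities[valid], sigma[valid],
                        mean2d[valid, 0], mean2d[valid, 1]))
    vidx = valid[order]
    mx = np.ascontiguousarray(mean2d[vidx, 0])
    my = np.ascontiguousarray(mean2d[vidx, 1])
    sp = np.ascontiguousarray(sigma[vidx])
    op = np.ascontiguousarray(splats.opacities[vidx])
    _raster.splat_forward(mx, my, sp, op, acc, config.cutoff_sigma, variant)
    prod = np.exp(acc)
    alpha = 1.0 - prod
    cam = splats.centers @ view.rotation.T + view.translation
    fm = max(view.fx, view.fy)
    clamped = (fm * splats.scales / np.where(z <= config.z_near, 1.0, z)
               + config.blur_floor_px) > config.sigma_max_px
    cache = RenderCache(
        view=view, config=config, n_splats=len(splats), valid_idx=vidx,
        cam_xyz=cam[vidx], mean2d=np.stack([mx, my], axis=1), std2d=sp,
        sigma_clamped=clamped[vidx], opacities=op,
        scales=splats.scales[vidx], prod=prod,
    ) if with_cache else None
    return RenderedSilhouette(alpha=alpha, view_id=view.view_id, cache=cache)


def render_backward(cache: RenderCache, d_alpha: np.ndarray) -> SplatGrads:
    """Chain dL/dalpha back to 3D splat centers, scales and opacities."""
    cfg = cache.config
    variant = (_raster.VARIANT_EXPONENTIAL if cfg.alpha_variant == "exponential"
               else _raster.VARIANT_PRODUCT)
    m = cache.n_splats
    d_centers = np.zeros((m, 3))
    d_scales = np.zeros(m)
    d_opacities = np.zeros(m)
    mv = len(cache.std2d)
    if mv == 0:
        return SplatGrads(d_centers, d_scales, d_opacities)
    dmx = np.zeros(mv)
    dmy = np.zeros(mv)
    dsp = np.zeros(mv)
    dop = np.zeros(mv)
    _raster.splat_backward(
        np.ascontiguousarray(cache.mean2d[:, 0]),
        np.ascontiguousarray(cache.mean2d[:, 1]),
        cache.std2d, cache.opacities, cache.prod,
        np.ascontiguousarray(d_alpha, dtype=np.float64),
        cfg.cutoff_sigma, variant, dmx, dmy, dsp, dop)
    view = cache.view
    x, y, z = cache.cam_xyz[:, 0], cache.cam_xyz[:, 1], cache.cam_xyz[:, 2]
    fm = max(view.fx, view.fy)
    live = ~cache.sigma_clamped
    dX = dmx * view.fx / z
    dY = dmy * view.fy / z
    dZ = (-dmx * view.fx * x / z ** 2 - dmy * view.fy * y / z ** 2
          - np.where(live, dsp * fm * cache.scales / z ** 2, 0.0))
    d_cam = np.stack([dX, dY, dZ], axis=1)
    d_centers[cache.valid_idx] = d_cam @ view.rotation
    d_scales[cache.valid_idx] = np.where(live, dsp * fm / z, 0.0)
    d_opacities[cache.valid_idx] = dop
    return SplatGrads(d_centers, d_scales, d_opacities)


# ---------------------------------------------------------------------------
# finite-difference validation of the analytic gradients
# ---------------------------------------------------------------------------

def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def gradient_check(splats: SplatSet, view: CameraView, target: np.ndarray,
                   config: RunConfig | None = None, h: float = 1e-4) -> float:
    """Compare analytic gradients of an L1 image loss against central finite
    differences for all three parameter groups (centers, scales, opacity
    logits). Returns the maximum relative error across groups, where each
    group's error is ||g_analytic - g_fd||_inf / max(||g_fd||_inf, 1e-10).
    Intended for small scenes (<= ~16 splats, <= 64 x 64 images)."""
    config = config or RunConfig()
    target = np.asarray(target, dtype=np.float64)

    def loss_of(sp: SplatSet) -> float:
        r = render_silhouette(sp, view, config, with_cache=False)
        return float(np.abs(r.alpha - target).mean())

    rendered = render_silhouette(splats, view, config)
    d_alpha = np.sign(rendered.alpha - target) / target.size
    grads = render_backward(rendered.cache, d_alpha)
    o = splats.opacities
    d_logits = grads.d_opacities * o * (1.0 - o)

    def fd_group(get, setv, shape) -> np.ndarray:
        out = np.zeros(shape)
        base = get().copy()
        for idx in np.ndindex(shape):
            step = h * (1.0 + abs(base[idx]))
            pert = base.copy()
            pert[idx] = base[idx] + step
            setv(pert)
            lp = loss_of(splats)
            pert[idx] = base[idx] - step
            setv(pert)
            lm = loss_of(splats)
            out[idx] = (lp - lm) / (2 * step)
        setv(base)
        return out

    errs = []

    def rel(ga, gf):
        return np.max(np.abs(ga - gf)) / max(np.max(np.abs(gf)), 1e-10)

    fd_c = fd_group(lambda: splats.centers,
                    lambda v: setattr(splats, "centers", v),
                    splats.centers.shape)
    errs.append(rel(grads.d_centers, fd_c))
    fd_s = fd_group(lambda: splats.scales,
                    lambda v: setattr(splats, "scales", v),
                    splats.scales.shape)
    errs.append(rel(grads.d_scales, fd_s))

    logits = _logit(o)

    def set_logits(v):
        splats.opacities = expit(v)

    base_logits = logits.copy()
    fd_l = np.zeros_like(logits)
    for i in range(len(logits)):
        step = h * (1.0 + abs(base_logits[i]))
        v = base_logits.copy()
        v[i] += step
        set_logits(v)
        lp = loss_of(splats)
        v[i] = base_logits[i] - step
        set_logits(v)
        lm = loss_of(splats)
        fd_l[i] = (lp - lm) / (2 * step)
    set_logits(base_logits)
    errs.append(rel(d_logits, fd_l))
    return float(max(errs))
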