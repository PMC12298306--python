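"""Silhouette supervision and geometry regularizers, with analytic gradients.

The silhouette term is an L1 difference between rendered soft masks and the
binary supervision masks, evaluated over a foreground-relevant pixel set
Omega (dilated mask union rendered coverage) and applied twice: once to the
full soft graph rendering (weight lambda_gs) and once to the MST-projected
rendering (weight lambda_mst).

Five geometry terms discourage physically implausible skeletons:

* repulsion          — Gaussian kernel on close node pairs,
* edge-length        — Gaussian kernel on short edges (suppresses trivial links),
* angle fold         — softplus(cos theta - cos theta_min) on consecutive-edge
                       triples, penalizing sharp back-and-forth turns,
* midpoint direction — softplus(d_max - ||m1 - m2||) on near-collinear edge
                       pairs whose midpoints crowd together (gate: direction
                       cosine > tau_dir),
* radius floor       — softplus(r_min - r_i) per node.

Every function returns (value, gradients); gradients are plain numpy arrays
consumed by the optimizer's Adam step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .io_formats import RunConfig

__all__ = [
    "softplus",
    "build_omega",
    "silhouette_loss",
    "repulsion_loss",
    "edge_length_loss",
    "angle_fold_loss",
    "midpoint_direction_loss",
    "radius_floor_loss",
    "geometry_loss",
    "total_loss_value",
]


def softplus(x):
    return np.logaddexp(0.0, x)


# ---------------------------------------------------------------------------
# silhouette
# ---------------------------------------------------------------------------

def build_omega(mask: np.ndarray, alpha: np.ndarray,
                dilate_frac: float = 0.05, alpha_thresh: float = 0.01) -> np.ndarray:
    """Foreground-relevant pixel set for one view: the supervision mask
    dilated by ``dilate_frac`` of the image width, union pixels the current
    rendering covers (alpha > alpha_thresh). Recomputed every iteration and
    treated as a non-differentiable selection."""
    rho = max(int(round(dilate_frac * mask.shape[1])), 1)
    st = np.ones((2 * rho + 1, 2 * rho + 1), dtype=bool)
    dilated = ndimage.binary_dilation(mask.astype(bool), structure=st)
    return dilated | (alpha > alpha_thresh)


def silhouette_loss(alpha: np.ndarray, alpha_mst: np.ndarray, mask: np.ndarray,
                    omega: np.ndarray, lambda_gs: float = 0.1,
                    lambda_mst: float = 1.0):
    """L1 silhouette losses over Omega for the soft and MST renderings.

    Returns (l_gs, l_mst, weighted_sum, d_alpha, d_alpha_mst) where the
    gradient arrays are the derivatives of the *unweighted* per-term means.
    """
    omega = np.asarray(omega, dtype=bool)
    n = int(omega.sum())
    if n == 0:
        raise ValueError("empty Omega: mask and rendering are disjoint")
    m = np.asarray(mask, dtype=np.float64)
    r_gs = np.where(omega, alpha - m, 0.0)
    r_mst = np.where(omega, alpha_mst - m, 0.0)
    l_gs = float(np.abs(r_gs).sum() / n)
    l_mst = float(np.abs(r_mst).sum() / n)
    d_alpha = np.sign(r_gs) / n
    d_alpha_mst = np.sign(r_mst) / n
    return l_gs, l_mst, lambda_gs * l_gs + lambda_mst * l_mst, d_alpha, d_alpha_mst


# ---------------------------------------------------------------------------
# geometry regularizers
# ---------------------------------------------------------------------------

def repulsion_loss(positions: np.ndarray, sigma_rep: float = 0.02):
    """sum_{i<j} exp(-||ci - cj||^2 / sigma^2) and its position gradient."""
    c = np.asarray(positions, dtype=np.float64)
    k = len(c)
    grad = np.zeros_like(c)
    if k < 2:
        return 0.0, grad
    diff = c[:, None, :] - c[None, :, :]  # (K, K, 3)
    d2 = (diff ** 2).sum(axis=2)
    kern = np.exp(-d2 / sigma_rep ** 2)
    np.fill_diagonal(kern, 0.0)
    value = float(kern.sum() / 2.0)
    # d/dci of exp(-d2/s^2) = kern * (-2 (ci-cj) / s^2); full sum over j
    grad = (-2.0 / sigma_rep ** 2) * (kern[:, :, None] * diff).sum(axis=1)
    return value, grad


def edge_length_loss(positions: np.ndarray, edges, sigma_edge: float = 0.02):
    """sum_{(i,j) in E} exp(-||ci - cj||^2 / sigma^2)."""
    c = np.asarray(positions, dtype=np.float64)
    grad = np.zeros_like(c)
    if not len(edges):
        return 0.0, grad
    e = np.asarray(edges, dtype=int)
    diff = c[e[:, 0]] - c[e[:, 1]]
    d2 = (diff ** 2).sum(axis=1)
    kern = np.exp(-d2 / sigma_edge ** 2)
    coeff = (-2.0 / sigma_edge ** 2) * kern
    np.add.at(grad, e[:, 0], coeff[:, None] * diff)
    np.add.at(grad, e[:, 1], -coeff[:, None] * diff)
    return float(kern.sum()), grad


def _edge_triples(edges, k: int) -> list[tuple[int, int, int]]:
    """Unordered triples (i, j, k), i < k, with both (i,j) and (j,k) edges."""
    nbrs: list[list[int]] = [[] for _ in range(k)]
    for a, b in edges:
        nbrs[a].append(b)
        nbrs[b].append(a)
    triples = []
    for j in range(k):
        ns = sorted(nbrs[j])
        for x in range(len(ns)):
            for y in range(x + 1, len(ns)):
                triples.append((ns[x], j, ns[y]))
    return triples


def angle_fold_loss(positions: np.ndarray, edges, theta_min_deg: float = 20.0,
                    k: int | None = None):
    """softplus(cos theta_ijk - cos theta_min) over consecutive-edge triples.

    theta is the angle at the pivot j between (ci - cj) and (ck - cj); a
    straight chain (theta = 180 deg) is barely penalized, a fold-back
    (theta -> 0) strongly. Triples containing a zero-length edge are skipped.
    """
    c = np.asarray(positions, dtype=np.float64)
    k = k if k is not None else len(c)
    grad = np.zeros_like(c)
    cos_min = np.cos(np.deg2rad(theta_min_deg))
    total = 0.0
    for i, j, kk in _edge_triples(edges, k):
        v1 = c[i] - c[j]
        v2 = c[kk] - c[j]
        n1 = np.linalg.norm(v1)
        n2 = np.linalg.norm(v2)
        if n1 == 0.0 or n2 == 0.0:
            continue
        cos_t = float(v1 @ v2 / (n1 * n2))
        total += float(softplus(cos_t - cos_min))
        s = float(expit(cos_t - cos_min))  # d softplus
        dv1 = v2 / (n1 * n2) - cos_t * v1 / n1 ** 2
        dv2 = v1 / (n1 * n2) - cos_t * v2 / n2 ** 2
        grad[i] += s * dv1
        grad[kk] += s * dv2
        grad[j] -= s * (dv1 + dv2)
    return total, grad


def midpoint_direction_loss(positions: np.ndarray, edges, tau_dir: float = 0.90,
                            d_max: float = 0.02, k: int | None = None,
                            variant: str = "prose"):
    """Penalty on directionally aligned consecutive edges whose midpoints
    crowd together. The gate keeps pairs whose direction cosine between
    (cj - ci) and (ck - cj) exceeds tau_dir; the gate itself carries no
    gradient. ``variant='prose'`` penalizes close midpoints,
    softplus(d_max - ||m1 - m2||); ``variant='printed'`` the reverse sign.
    """
    c = np.asarray(positions, dtype=np.float64)
    k = k if k is not None else len(c)
    grad = np.zeros_like(c)
    sign = 1.0 if variant == "printed" else -1.0
    total = 0.0
    for i, j, kk in _edge_triples(edges, k):
        u1 = c[j] - c[i]
        u2 = c[kk] - c[j]
        n1 = np.linalg.norm(u1)
        n2 = np.linalg.norm(u2)
        if n1 == 0.0 or n2 == 0.0:
            continue
        if u1 @ u2 / (n1 * n2) <= tau_dir:
            continue
        # m1 - m2 = (ci - ck) / 2
        dvec = (c[i] - c[kk]) / 2.0
        d = float(np.linalg.norm(dvec))
        arg = (d - d_max) if variant == "printed" else (d_max - d)
        total += float(softplus(arg))
        if d > 0.0:
            s = float(expit(arg)) * sign
            dd = s * dvec / (2.0 * d)
            grad[i] += dd
            grad[kk] -= dd
    return total, grad


def radius_floor_loss(radii: np.ndarray, r_min: float = 0.01):
    """sum_i softplus(r_min - r_i) over nodes, keeping radii from collapsing."""
    r = np.asarray(radii, dtype=np.float64)
    value = float(softplus(r_min - r).sum())
    grad = -expit(r_min - r)
    return value, grad


@dataclass
class GeometryLossResult:
    value: float  # weighted sum
    components: dict
    d_positions: np.ndarray
    d_radii: np.ndarray


def geometry_loss(positions: np.ndarray, radii: np.ndarray, edges,
                  config: RunConfig) -> GeometryLossResult:
    """Weighted geometry regularizer and its gradients w.r.t. positions and
    radii, evaluated on the given (hard MST) edge set."""
    k = len(positions)
    l_rep, g_rep = repulsion_loss(positions, config.sigma_rep)
    l_edge, g_edge = edge_length_loss(positions, edges, config.sigma_edge)
    l_ang, g_ang = angle_fold_loss(positions, edges, config.theta_min_deg, k)
    l_mid, g_mid = midpoint_direction_loss(positions, edges, config.tau_dir,
                                           config.d_max, k,
                                           variant=config.midpoint_variant)
    l_rad, g_rad = radius_floor_loss(radii, config.r_min)
    value = (config.lambda_rep * l_rep + config.lambda_edge_short * l_edge
             + config.lambda_angle * l_ang + config.lambda_mid * l_mid
             + config.lambda_radius * l_rad)
    d_pos = (config.lambda_rep * g_rep + config.lambda_edge_short * g_edge
             + config.lambda_angle * g_ang + config.lambda_mid * g_mid)
    d_rad = config.lambda_radius * g_rad
    return GeometryLossResult(
        value=float(value),
        components={"rep": l_rep, "edge_short": l_edge, "angle": l_ang,
                    "mid": l_mid, "radius": l_rad},
        d_positions=d_pos, d_radii=d_rad)


def total_loss_value(l_gs: float, l_mst: float, geometry: dict,
                     config: RunConfig) -> float:
    """Scalar total: lambda_gs*L_GS + lambda_mst*L_MST + weighted geometry."""
    return (config.lambda_gs * l_gs + config.lambda_mst * l_mst
            + config.lambda_rep * geometry.get("rep", 0.0)
            + config.lambda_edge_short * geometry.get("edge_short", 0.0)
            + config.lambda_angle * geometry.get("angle", 0.0)
            + config.lambda_mid * geometry.get("mid", 0.0)
            + config.lambda_radius * geometry.get("radius", 0.0))
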