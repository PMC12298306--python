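"""Readers and writers for every external format the pipeline touches.

Conventions (stated once, used everywhere):

* World units are meters; the world up axis is +z.
* A camera looks down +z in its own frame; pixel x grows right, pixel y grows
  down; pixel indices are 0-based and the center of pixel (i, j) lies at
  continuous coordinate (i + 0.5, j + 0.5).
* Extrinsics map world to camera: ``x_cam = R @ x_world + t``.
"""

from __future__ import annotations

import dataclasses
import glob
import json
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import trimesh
import yaml
from imageio.v3 import imread, imwrite
from scipy.spatial.transform import Rotation

__all__ = [
    "CameraView",
    "BinaryMask",
    "PointCloud",
    "RunConfig",
    "read_masks",
    "write_mask",
    "read_cameras",
    "write_cameras_json",
    "read_ply",
    "write_ply",
    "read_skeleton",
    "write_skeleton",
    "write_skeleton_obj",
]

_ORTHO_TOL = 1e-6


@dataclass(frozen=True)
class CameraView:
    """Pinhole camera: intrinsics in pixels, world->camera extrinsics."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    rotation: np.ndarray  # (3, 3) world -> camera
    translation: np.ndarray  # (3,)
    view_id: str = "0"

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-5) or np.linalg.det(R) < 0:
            raise ValueError(f"rotation for view {self.view_id} is not a proper rotation")

    def camera_center(self) -> np.ndarray:
        """World-space position of the optical center (-R^T t)."""
        return -self.rotation.T @ self.translation

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project (N, 3) world points; returns ((N, 2) pixel coords, (N,) depth)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        cam = p @ self.rotation.T + self.translation
        z = cam[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            u = self.fx * cam[:, 0] / z + self.cx
            v = self.fy * cam[:, 1] / z + self.cy
        return np.stack([u, v], axis=1), z


@dataclass
class BinaryMask:
    """Per-view binary silhouette; ``grid`` is (height, width) bool."""

    grid: np.ndarray
    view_id: str = "0"
    warning: str | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass
class PointCloud:
    """Unordered 3D points in meters."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if pts.size and not np.all(np.isfinite(pts)):
            raise ValueError("point cloud contains non-finite coordinates")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class RunConfig:
    """All pipeline hyper-parameters with their defaults.

    Loss weights and geometry thresholds default to the fixed experimental
    values (lambda_gs=0.1, lambda_mst=1.0, all geometry weights 0.05,
    sigma_rep = sigma_edge = 2 cm, theta_min = 20 deg, tau_dir = 0.90,
    d_max = 2 cm, r_min = 1 cm, adjacency eps = 1e-6, 64 splats per edge).
    """

    # silhouette loss
    lambda_gs: float = 0.1
    lambda_mst: float = 1.0
    # geometry regularizers
    lambda_rep: float = 0.05
    lambda_edge_short: float = 0.05
    lambda_angle: float = 0.05
    lambda_mid: float = 0.05
    lambda_radius: float = 0.05
    sigma_rep: float = 0.02  # m
    sigma_edge: float = 0.02  # m
    theta_min_deg: float = 20.0
    tau_dir: float = 0.90
    d_max: float = 0.02  # m
    r_min: float = 0.01  # m
    midpoint_variant: str = "prose"  # "prose" (penalize close) | "printed"
    # adjacency parameterization
    eps: float = 1e-6
    mst_weight_mode: str = "neglog"  # "neglog" | "euclidean"
    use_sfs: bool = True  # False disables the in-loop tree projection (ablation)
    # splatting / rendering
    n_per_edge: int = 64
    blur_floor_px: float = 0.3
    cutoff_sigma: float = 3.0
    sigma_max_px: float = 32.0
    z_near: float = 0.01  # m
    alpha_variant: str = "product"  # "product" | "exponential"
    # initialization
    n_min: int = 3
    kmeans_k: int | None = None  # None -> clamp(round(n/200), 16, 256)
    r_min_init: float = 0.005  # m, floor for cluster median radius
    outlier_radius: float | None = None  # None -> 2x median NN distance
    outlier_min_neighbors: int = 5
    sor_k: int = 20
    sor_std: float = 2.0
    # optimization
    iterations: int = 2000
    lr_positions: float = 2e-3  # x scene bbox diagonal
    lr_position_decay: float = 1.0  # final/initial position lr over the run
    lr_log_radii: float = 5e-3
    # straight-through SGD step on adjacency logits; scaled so that an edge
    # whose splats consistently overpaint background (opacity gradient of
    # order 1e-3 per iteration) is suppressed within a few hundred iterations
    lr_logits: float = 200.0
    view_batch: int = 4
    prob_floor: float = 0.01
    omega_dilate_frac: float = 0.05
    omega_alpha_thresh: float = 0.01
    seed: int = 0
    # evaluation
    chamfer_mode: str = "squared"  # "squared" | "linear"
    sample_spacing: float = 0.001  # m

    def __post_init__(self) -> None:
        if not (0.0 < self.eps < 0.5):
            raise ValueError("eps must lie in (0, 0.5)")
        if self.n_per_edge < 1:
            raise ValueError("n_per_edge must be >= 1")
        for name in ("lambda_gs", "lambda_mst", "lambda_rep", "lambda_edge_short",
                     "lambda_angle", "lambda_mid", "lambda_radius"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.theta_min_deg < 90.0):
            raise ValueError("theta_min_deg must lie in (0, 90)")
        if not (-1.0 < self.tau_dir < 1.0):
            raise ValueError("tau_dir must lie in (-1, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | os.PathLike) -> None:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        with open(path, "w") as fh:
            fh.write(text)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def _natural_key(s: str) -> list:
    return [int(tok) if tok.isdigit() else tok for tok in re.split(r"(\d+)", s)]


def read_masks(path_pattern: str, cameras: Sequence[CameraView] | None = None) -> list[BinaryMask]:
    """Read binary PNG masks matching a glob pattern, sorted by view id.

    Pixels > 127 (any channel averaged) map to foreground. The stem of each
    file name is its view id. If ``cameras`` is given, each mask's shape is
    checked against the camera with the same view id.
    """
    paths = sorted(glob.glob(path_pattern), key=_natural_key)
    if not paths:
        raise FileNotFoundError(f"no mask files match {path_pattern!r}")
    cams = {c.view_id: c for c in (cameras or [])}
    masks = []
    for p in paths:
        vid = os.path.splitext(os.path.basename(p))[0]
        img = imread(p)
        if img.ndim == 3:
            img = img[..., :3].mean(axis=2)
        grid = img > 127
        if vid in cams:
            cam = cams[vid]
            if grid.shape != (cam.height, cam.width):
                raise ValueError(
                    f"mask {p} has shape {grid.shape}, camera {vid} expects "
                    f"({cam.height}, {cam.width})")
        masks.append(BinaryMask(grid=grid, view_id=vid))
    return masks


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    imwrite(path, (mask.grid.astype(np.uint8) * 255))


# ---------------------------------------------------------------------------
# cameras
# ---------------------------------------------------------------------------

def _camera_to_dict(cam: CameraView) -> dict:
    return {
        "view_id": cam.view_id,
        "fx": cam.fx, "fy": cam.fy, "cx": cam.cx, "cy": cam.cy,
        "width": cam.width, "height": cam.height,
        "rotation": cam.rotation.tolist(),
        "translation": cam.translation.tolist(),
    }


def write_cameras_json(cameras: Iterable[CameraView], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump({"cameras": [_camera_to_dict(c) for c in cameras]}, fh, indent=1)


def quaternion_to_rotation(qw: float, qx: float, qy: float, qz: float) -> np.ndarray:
    """Rotation matrix from a (w, x, y, z) unit quaternion (COLMAP order)."""
    return Rotation.from_quat([qx, qy, qz, qw]).as_matrix()


def _read_cameras_json(path: str) -> list[CameraView]:
    with open(path) as fh:
        data = json.load(fh)
    cams = []
    for d in data["cameras"]:
        cams.append(CameraView(
            fx=d["fx"], fy=d["fy"], cx=d["cx"], cy=d["cy"],
            width=int(d["width"]), height=int(d["height"]),
            rotation=np.array(d["rotation"], dtype=float),
            translation=np.array(d["translation"], dtype=float),
            view_id=str(d["view_id"]),
        ))
    return cams


def _read_cameras_colmap(path: str) -> list[CameraView]:
    """Read COLMAP text model: ``path`` is a directory containing
    cameras.txt and images.txt (PINHOLE or SIMPLE_PINHOLE models)."""
    cam_file = os.path.join(path, "cameras.txt")
    img_file = os.path.join(path, "images.txt")
    intr: dict[int, tuple] = {}
    with open(cam_file) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            cam_id, model = int(parts[0]), parts[1]
            w, h = int(parts[2]), int(parts[3])
            params = [float(x) for x in parts[4:]]
            if model == "PINHOLE":
                fx, fy, cx, cy = params[:4]
            elif model == "SIMPLE_PINHOLE":
                fx = fy = params[0]
                cx, cy = params[1], params[2]
            else:
                raise ValueError(f"unsupported COLMAP camera model {model!r}")
            intr[cam_id] = (fx, fy, cx, cy, w, h)
    cams = []
    with open(img_file) as fh:
        lines = [l.strip() for l in fh if l.strip() and not l.startswith("#")]
    # images.txt alternates: pose line, 2D-point line (may be empty and absent)
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        qw, qx, qy, qz = (float(x) for x in parts[1:5])
        t = np.array([float(x) for x in parts[5:8]])
        cam_id = int(parts[8])
        name = parts[9] if len(parts) > 9 else parts[0]
        R = quaternion_to_rotation(qw, qx, qy, qz)
        if not np.allclose(R @ R.T, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError(f"non-orthonormal rotation for image {name}")
        fx, fy, cx, cy, w, h = intr[cam_id]
        cams.append(CameraView(fx=fx, fy=fy, cx=cx, cy=cy, width=w, height=h,
                               rotation=R, translation=t,
                               view_id=os.path.splitext(name)[0]))
        i += 2  # skip the POINTS2D line
    cams.sort(key=lambda c: _natural_key(c.view_id))
    return cams


def read_cameras(path: str | os.PathLike, dialect: str = "json") -> list[CameraView]:
    """Read cameras from JSON (``dialect='json'``) or a COLMAP text model
    directory (``dialect='colmap_text'``)."""
    if dialect == "json":
        return _read_cameras_json(str(path))
    if dialect == "colmap_text":
        return _read_cameras_colmap(str(path))
    raise ValueError(f"unknown camera dialect {dialect!r}")


# ---------------------------------------------------------------------------
# point clouds (PLY)
# ---------------------------------------------------------------------------

def read_ply(path: str | os.PathLike) -> PointCloud:
    """Read x/y/z vertex positions from an ASCII or binary-little-endian PLY."""
    # handle vertex-count-0 files that trimesh rejects
    with open(path, "rb") as fh:
        header = fh.read(2048).decode("latin-1", errors="ignore")
    m = re.search(r"element vertex (\d+)", header)
    if m is None:
        raise ValueError(f"{path}: PLY file without a vertex element")
    if int(m.group(1)) == 0:
        return PointCloud(points=np.zeros((0, 3)))
    if not re.search(r"property \S+ x", header):
        raise ValueError(f"{path}: PLY vertex element lacks x/y/z properties")
    loaded = trimesh.load(str(path), process=False)
    verts = np.asarray(loaded.vertices, dtype=np.float64)
    return PointCloud(points=verts)


def write_ply(cloud: PointCloud, path: str | os.PathLike, binary: bool = True) -> None:
    """Write a point cloud as PLY (float32 vertices, bit-stable round trip)."""
    pts = np.asarray(cloud.points, dtype=np.float32)
    if binary:
        body = pts.astype("<f4").tobytes()
        header = (
            "ply\nformat binary_little_endian 1.0\n"
            f"element vertex {len(pts)}\n"
            "property float x\nproperty float y\nproperty float z\n"
            "end_header\n"
        )
        with open(path, "wb") as fh:
            fh.write(header.encode("ascii"))
            fh.write(body)
    else:
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(pts)}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            fh.write("end_header\n")
            for x, y, z in pts:
                fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")


# ---------------------------------------------------------------------------
# skeleton graphs (JSON interchange + OBJ export)
# ---------------------------------------------------------------------------

def write_skeleton(graph, path: str | os.PathLike, include_logits: bool = True) -> None:
    """Serialize a SkeletonGraph to JSON: nodes (id, xyz, radius), edge list,
    and optionally the dense adjacency-logit matrix."""
    doc = {
        "nodes": [
            {"id": i, "xyz": graph.positions[i].tolist(),
             "radius": float(graph.radii[i])}
            for i in range(graph.n_nodes)
        ],
        "edges": [[int(i), int(j)] for i, j in graph.edges()],
    }
    if include_logits and graph.adjacency_logits is not None:
        doc["adjacency_logits"] = np.asarray(graph.adjacency_logits).tolist()
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_skeleton(path: str | os.PathLike):
    from .graph_init import SkeletonGraph, edges_to_logits

    with open(path) as fh:
        doc = json.load(fh)
    ids = [n["id"] for n in doc["nodes"]]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate node ids")
    order = np.argsort(ids)
    nodes = [doc["nodes"][i] for i in order]
    positions = np.array([n["xyz"] for n in nodes], dtype=float)
    radii = np.array([n["radius"] for n in nodes], dtype=float)
    remap = {ids[i]: rank for rank, i in enumerate(order)}
    edges = [(remap[i], remap[j]) for i, j in doc.get("edges", [])]
    if "adjacency_logits" in doc:
        logits = np.array(doc["adjacency_logits"], dtype=float)
    else:
        logits = edges_to_logits(len(nodes), edges)
    return SkeletonGraph(positions=positions, radii=radii, adjacency_logits=logits)


def write_skeleton_obj(graph, path: str | os.PathLike) -> None:
    """Secondary OBJ-line export (v/l records) for quick viewing."""
    with open(path, "w") as fh:
        for p in graph.positions:
            fh.write(f"v {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        for i, j in graph.edges():
            fh.write(f"l {i + 1} {j + 1}\n")
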