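"""Metric-scale phenotyping: 2D-3D leaf instance alignment, area, inclination.

Given a completed point cloud in world coordinates, a calibrated pinhole
camera, and per-leaf binary instance masks, the pipeline projects every
3-D point into the image, matches projected pixels against each mask by
intersection-over-union, assigns points to the best-matching leaf, and
derives per-leaf area (plane-projected triangulation) and inclination
(angle between the best-fit-plane normal and the vertical axis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay

from .cloud import PointCloud, RigidTransform

__all__ = [
    "CameraModel",
    "InstanceMask",
    "camera_to_world",
    "world_to_camera",
    "project_pinhole",
    "mask_iou",
    "extract_leaf_clusters",
    "leaf_area",
    "leaf_inclination",
]

DEFAULT_TAU_IOU = 0.87


@dataclass
class CameraModel:
    """Pinhole camera: intrinsics K (3x3), extrinsics [R|t], image size."""

    intrinsics: np.ndarray
    extrinsics: RigidTransform
    height: int
    width: int

    def __post_init__(self) -> None:
        self.intrinsics = np.asarray(self.intrinsics, dtype=np.float64).reshape(3, 3)
        fx, fy = self.intrinsics[0, 0], self.intrinsics[1, 1]
        cx, cy = self.intrinsics[0, 2], self.intrinsics[1, 2]
        if fx <= 0 or fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= cx <= self.width and 0 <= cy <= self.height):
            raise ValueError("principal point must lie inside the image")


@dataclass
class InstanceMask:
    """Binary leaf-instance raster M_k in {0,1}^(H x W)."""

    pixels: np.ndarray
    instance_id: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be a 2-D raster")


def camera_to_world(p_c: np.ndarray, t: RigidTransform) -> np.ndarray:
    """p_w = R p_c + t."""
    return t.apply(np.asarray(p_c, dtype=np.float64))


def world_to_camera(p_w: np.ndarray, t: RigidTransform) -> np.ndarray:
    return t.inverse().apply(np.asarray(p_w, dtype=np.float64))


def project_pinhole(p_w: np.ndarray, cam: CameraModel) -> tuple[np.ndarray, np.ndarray]:
    """Project world points to pixel coordinates (u, v) with validity flags.

    Homogeneous projection [u v 1]^T ~ K [R|t] [X Y Z 1]^T with perspective
    division; a point is invalid when its camera-frame depth is <= 0 or its
    pixel falls outside the frame.
    """
    pts = np.atleast_2d(np.asarray(p_w, dtype=np.float64))
    p_cam = cam.extrinsics.apply(pts)
    z = p_cam[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        proj = (cam.intrinsics @ p_cam.T).T
        uv = proj[:, :2] / proj[:, 2:3]
    valid = (
        (z > 0)
        & np.isfinite(uv).all(axis=1)
        & (uv[:, 0] >= 0) & (uv[:, 0] < cam.width)
        & (uv[:, 1] >= 0) & (uv[:, 1] < cam.height)
    )
    return uv, valid


def _pixel_set(uv: np.ndarray, valid: np.ndarray, H: int, W: int) -> set[tuple[int, int]]:
    vv = np.rint(uv[valid]).astype(np.int64)
    vv[:, 0] = np.clip(vv[:, 0], 0, W - 1)
    vv[:, 1] = np.clip(vv[:, 1], 0, H - 1)
    return {(int(v), int(u)) for u, v in vv}


def mask_iou(mask: InstanceMask, projected_pixels: set[tuple[int, int]]) -> float:
    """Intersection-over-union between a mask's on-pixels and a pixel set."""
    on = {(int(r), int(c)) for r, c in zip(*np.nonzero(mask.pixels))}
    union = on | projected_pixels
    if not union:
        return 0.0
    return len(on & projected_pixels) / len(union)


def extract_leaf_clusters(
    cloud: PointCloud,
    masks: list[InstanceMask],
    cam: CameraModel,
    tau_iou: float = DEFAULT_TAU_IOU,
) -> list[tuple[InstanceMask, PointCloud]]:
    """Per-leaf 3-D clusters via 2D-3D IOU matching.

    For each mask with IOU >= tau against the projected cloud, collect the
    points whose valid projection lands on an on-pixel; a point claimed by
    several passing masks goes to the one with the highest IOU.  Returns
    ``(mask, cluster)`` pairs; empty (with a warning) when no mask passes.
    """
    if not 0 < tau_iou <= 1:
        raise ValueError("tau_iou must be in (0, 1]")
    uv, valid = project_pinhole(cloud.points, cam)
    proj_pixels = _pixel_set(uv, valid, cam.height, cam.width)
    ious = [mask_iou(m, proj_pixels) for m in masks]
    passing = [i for i, v in enumerate(ious) if v >= tau_iou]
    if not passing:
        import warnings

        warnings.warn("no instance mask reached the IOU threshold", stacklevel=2)
        return []
    cols = np.clip(np.rint(uv[:, 0]).astype(np.int64), 0, cam.width - 1)
    rows = np.clip(np.rint(uv[:, 1]).astype(np.int64), 0, cam.height - 1)
    owner = np.full(len(cloud), -1, dtype=np.int64)
    best = np.full(len(cloud), -np.inf)
    for i in sorted(passing, key=lambda i: ious[i]):  # highest IOU claims last
        hits = valid & masks[i].pixels[rows, cols]
        claim = hits & (ious[i] >= best)
        owner[claim] = i
        best[claim] = ious[i]
    out = []
    for i in passing:
        idx = np.flatnonzero(owner == i)
        if len(idx):
            out.append((masks[i], cloud.select(idx)))
    return out


def _best_fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(normal, in-plane basis 2x3) of the least-squares plane through points."""
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] < 1e-12 * max(evals[2], 1e-300):
        raise ValueError("points are collinear; no unique plane")
    return evecs[:, 0], evecs[:, 1:].T


def leaf_area(leaf: PointCloud, edge_factor: float = 5.0) -> float:
    """Surface area from a plane-projected triangulation of the leaf points.

    Points are projected onto the best-fit plane, triangulated there
    (Delaunay), lifted back to 3-D, and the triangle areas are summed.
    Triangles with an edge longer than ``edge_factor`` times the median
    triangulation edge are dropped to avoid bridging separate lobes.
    """
    if len(leaf) < 3:
        raise ValueError("leaf_area needs at least 3 points")
    _, basis = _best_fit_plane(leaf.points)
    uv = (leaf.points - leaf.points.mean(axis=0)) @ basis.T
    tri = Delaunay(uv)
    pts = leaf.points
    simplices = tri.simplices
    a = pts[simplices[:, 0]]
    b = pts[simplices[:, 1]]
    c = pts[simplices[:, 2]]
    edges = np.stack([
        np.linalg.norm(b - a, axis=1),
        np.linalg.norm(c - b, axis=1),
        np.linalg.norm(a - c, axis=1),
    ])
    keep = edges.max(axis=0) <= edge_factor * float(np.median(edges))
    cross = np.cross(b - a, c - a)
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    return float(areas[keep].sum())


def leaf_inclination(leaf: PointCloud) -> float:
    """Angle (degrees, folded to [0, 90]) between the leaf normal and vertical.

    The leaf normal is the smallest principal component of the point
    covariance; a horizontal leaf has inclination 0, a vertical one 90.
    """
    if len(leaf) < 3:
        raise ValueError("leaf_inclination needs at least 3 points")
    normal, _ = _best_fit_plane(leaf.points)
    cosang = abs(float(normal @ np.array([0.0, 0.0, 1.0]))) / np.linalg.norm(normal)
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
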