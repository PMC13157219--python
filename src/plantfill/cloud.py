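"""Point-cloud data model, sampling, normalization and rigid transforms.

The :class:`PointCloud` container is deliberately minimal: an ``(N, 3)``
float array of coordinates, an optional parallel integer label vector
(organ / cluster ids), and a coordinate-frame tag.  Everything downstream
(clustering, occlusion simulation, the completion network, phenotyping)
consumes this one type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "PointCloud",
    "RigidTransform",
    "NormalizationState",
    "apply_rigid",
    "centroid",
    "ifps_indices",
    "ifps_downsample",
    "normalize",
    "denormalize",
    "pca_normal",
    "rotate_z",
]

FRAMES = ("camera", "world", "normalized")


@dataclass
class PointCloud:
    """An unordered set of N 3-D points with optional per-point labels.

    Parameters
    ----------
    points : (N, 3) array of finite coordinates, N >= 1.
    labels : optional (N,) integer array of organ / cluster ids.
    frame : one of ``{"camera", "world", "normalized"}``.
    """

    points: np.ndarray
    labels: Optional[np.ndarray] = None
    frame: str = "world"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got {self.points.shape}")
        if self.points.shape[0] < 1:
            raise ValueError("a PointCloud needs at least one point")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points contain non-finite coordinates")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (self.points.shape[0],):
                raise ValueError(
                    f"labels must have length N={self.points.shape[0]}, "
                    f"got shape {self.labels.shape}"
                )
        if self.frame not in FRAMES:
            raise ValueError(f"frame must be one of {FRAMES}, got {self.frame!r}")

    def __len__(self) -> int:
        return self.points.shape[0]

    def select(self, indices: np.ndarray) -> "PointCloud":
        """Sub-cloud at ``indices`` (labels carried along)."""
        idx = np.asarray(indices)
        labels = None if self.labels is None else self.labels[idx]
        return PointCloud(self.points[idx], labels=labels, frame=self.frame)

    def with_points(self, points: np.ndarray) -> "PointCloud":
        """Same metadata, new coordinates (shape must be preserved per-label)."""
        labels = self.labels
        if labels is not None and len(labels) != len(points):
            labels = None
        return PointCloud(np.asarray(points, dtype=np.float64), labels=labels, frame=self.frame)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points.min(axis=0), self.points.max(axis=0)

    def bbox_diagonal(self) -> float:
        lo, hi = self.bounding_box()
        return float(np.linalg.norm(hi - lo))


@dataclass
class RigidTransform:
    """A proper rigid motion p -> R p + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise ValueError("rotation determinant must be +1 (proper rotation)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)


@dataclass
class NormalizationState:
    """Per-axis bounding box used by the [-1, 1] normalization map."""

    m_min: np.ndarray
    m_max: np.ndarray

    def __post_init__(self) -> None:
        self.m_min = np.asarray(self.m_min, dtype=np.float64).reshape(3)
        self.m_max = np.asarray(self.m_max, dtype=np.float64).reshape(3)
        if np.any(self.m_max < self.m_min):
            raise ValueError("m_max must be >= m_min componentwise")
        if not np.any(self.m_max > self.m_min):
            raise ValueError("at least one axis must have positive extent")


def apply_rigid(cloud: PointCloud, t: RigidTransform) -> PointCloud:
    """Apply a rigid motion to every point; pairwise distances are preserved."""
    return cloud.with_points(t.apply(cloud.points))


def centroid(cloud: PointCloud) -> np.ndarray:
    """Arithmetic mean of all points."""
    return cloud.points.mean(axis=0)


def ifps_indices(points: np.ndarray, m: int, seed: int = 0, start: Optional[int] = None) -> np.ndarray:
    """Iterative farthest point sampling: indices of an m-point subset.

    The first point is a seeded uniform choice among the inputs (or ``start``);
    every subsequent point maximizes its distance to the already-selected set.
    Ties go to the lowest index (argmax convention).
    """
    pts = np.asarray(points, dtype=np.float64)
    n = pts.shape[0]
    if not 1 <= m <= n:
        raise ValueError(f"m must satisfy 1 <= m <= N={n}, got {m}")
    if start is None:
        start = int(np.random.default_rng(seed).integers(n))
    chosen = np.empty(m, dtype=np.int64)
    chosen[0] = start
    dist = np.linalg.norm(pts - pts[start], axis=1)
    dist[start] = -1.0  # chosen indices are never re-selected, even at distance 0
    for i in range(1, m):
        nxt = int(np.argmax(dist))
        chosen[i] = nxt
        np.minimum(dist, np.linalg.norm(pts - pts[nxt], axis=1), out=dist)
        dist[nxt] = -1.0
    return chosen


def ifps_downsample(cloud: PointCloud, m: int, seed: int = 0) -> PointCloud:
    """IFPS subset of the cloud with exactly m points."""
    return cloud.select(ifps_indices(cloud.points, m, seed=seed))


def normalize(cloud: PointCloud, isotropic: bool = False) -> tuple[PointCloud, NormalizationState]:
    """Map the cloud's bounding box into [-1, 1] per axis.

    The default map is anisotropic (each axis scaled independently); with
    ``isotropic=True`` a single scale (the largest axis extent) is used so
    the aspect ratio is preserved.
    """
    m_min = cloud.points.min(axis=0)
    m_max = cloud.points.max(axis=0)
    extent = m_max - m_min
    for axis, name in enumerate("xyz"):
        if extent[axis] <= 0:
            raise ValueError(f"degenerate axis {name!r}: m_max == m_min")
    if isotropic:
        half = extent.max() / 2.0
        center = (m_min + m_max) / 2.0
        m_min = center - half
        m_max = center + half
        extent = m_max - m_min
    pts = 2.0 * (cloud.points - m_min) / extent - 1.0
    out = PointCloud(pts, labels=cloud.labels, frame="normalized")
    return out, NormalizationState(m_min, m_max)


def denormalize(cloud: PointCloud, state: NormalizationState) -> PointCloud:
    """Invert :func:`normalize`: p <- (p + 1)/2 * (m_max - m_min) + m_min."""
    if state is None:
        raise ValueError("denormalize requires the NormalizationState from normalize()")
    if cloud.frame != "normalized":
        raise ValueError("denormalize expects a cloud in the 'normalized' frame")
    pts = (cloud.points + 1.0) / 2.0 * (state.m_max - state.m_min) + state.m_min
    return PointCloud(pts, labels=cloud.labels, frame="world")


def pca_normal(cloud: PointCloud, index: int, k: int = 16) -> np.ndarray:
    """Unit surface normal at one point from its k-nearest-neighborhood PCA.

    The normal is the covariance eigenvector with the smallest eigenvalue.
    Sign convention: positive z component; if z ~ 0, positive x.
    """
    n = len(cloud)
    if k < 3:
        raise ValueError("k must be >= 3 for a PCA normal")
    if k > n:
        raise ValueError(f"k={k} exceeds cloud size N={n}")
    tree = cKDTree(cloud.points)
    _, idx = tree.query(cloud.points[index], k=k)
    nbhd = cloud.points[np.atleast_1d(idx)]
    cov = np.cov(nbhd.T)
    evals, evecs = np.linalg.eigh(cov)
    normal = evecs[:, 0]
    normal = normal / np.linalg.norm(normal)
    if normal[2] < -1e-12 or (abs(normal[2]) <= 1e-12 and normal[0] < 0):
        normal = -normal
    return normal


def rotate_z(cloud: PointCloud, angle_deg: float) -> PointCloud:
    """Rigid rotation about the z-axis through the origin."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return apply_rigid(cloud, RigidTransform(rot, np.zeros(3)))
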