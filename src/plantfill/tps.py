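"""Radial-tangential thin-plate-spline deformation and non-rigid augmentation.

The deformation of a point x is

    y = sum_i W_i [alpha * psi_r(x, x_i) + beta * psi_t(x, x_i, n_i)] + A x + b

with the classical TPS radial basis psi_r(r) = r^2 log r and a tangential
(angular) basis psi_t = cos(angle between x - x_i and the control normal
n_i).  alpha/beta weight the two bases; with beta = 0 this is classical
3-D TPS, with alpha = beta = 0 it is affine.  Control normals come from
local PCA.  Fitting solves the interpolation system with the standard TPS
side conditions (W orthogonal to the affine monomials) plus a small ridge
on the basis block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cloud import PointCloud, ifps_indices, pca_normal
from .clustering import hierarchical_cluster

__all__ = [
    "TPSTransform",
    "tps_basis_radial",
    "tps_basis_tangential",
    "tps_transform",
    "fit_tps",
    "augment",
    "cluster_with_assignment",
]

RIDGE = 1e-8


@dataclass
class TPSTransform:
    control_points: np.ndarray  # (C, 3)
    weights: np.ndarray  # (C, 3)
    affine: np.ndarray  # (3, 3)
    offset: np.ndarray  # (3,)
    alpha: float
    beta: float
    normals: np.ndarray  # (C, 3) unit vectors

    def __post_init__(self) -> None:
        self.control_points = np.atleast_2d(np.asarray(self.control_points, dtype=np.float64))
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=np.float64))
        self.affine = np.asarray(self.affine, dtype=np.float64).reshape(3, 3)
        self.offset = np.asarray(self.offset, dtype=np.float64).reshape(3)
        self.normals = np.atleast_2d(np.asarray(self.normals, dtype=np.float64))
        if self.alpha < 0 or self.beta < 0 or self.alpha + self.beta <= 0:
            raise ValueError("alpha, beta must be nonnegative with alpha + beta > 0")
        if self.weights.shape != self.control_points.shape:
            raise ValueError("weights must be one 3-vector per control point")
        if self.normals.shape != self.control_points.shape:
            raise ValueError("normals must be one unit 3-vector per control point")
        norms = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("control normals must be unit length")


def tps_basis_radial(x: np.ndarray, xi: np.ndarray) -> np.ndarray:
    """psi_r = r^2 log r with r = ||x - xi||, continuously 0 at r = 0."""
    x = np.asarray(x, dtype=np.float64)
    xi = np.asarray(xi, dtype=np.float64)
    r = np.linalg.norm(np.atleast_2d(x) - np.atleast_2d(xi), axis=-1)
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = r[nz] ** 2 * np.log(r[nz])
    return out if out.shape != (1,) else float(out[0])


def tps_basis_tangential(x: np.ndarray, xi: np.ndarray, n: np.ndarray) -> np.ndarray:
    """psi_t = cos(angle between x - xi and n); 0 at x = xi.  Bounded in [-1, 1]."""
    n = np.asarray(n, dtype=np.float64)
    if not np.allclose(np.linalg.norm(n, axis=-1), 1.0, atol=1e-6):
        raise ValueError("tangential basis requires a unit normal")
    d = np.atleast_2d(np.asarray(x, dtype=np.float64)) - np.atleast_2d(np.asarray(xi, dtype=np.float64))
    r = np.linalg.norm(d, axis=-1)
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = (d[nz] @ np.asarray(n, dtype=np.float64).reshape(3)) / r[nz]
    return out if out.shape != (1,) else float(out[0])


def _basis_matrix(points: np.ndarray, t_controls: np.ndarray, t_normals: np.ndarray,
                  alpha: float, beta: float) -> np.ndarray:
    """K[a, i] = alpha * psi_r(p_a, x_i) + beta * psi_t(p_a, x_i, n_i)."""
    diff = points[:, None, :] - t_controls[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        psi_r = np.where(r > 0, r**2 * np.log(np.where(r > 0, r, 1.0)), 0.0)
        psi_t = np.where(r > 0, np.einsum("aij,ij->ai", diff, t_normals) / np.where(r > 0, r, 1.0), 0.0)
    return alpha * psi_r + beta * psi_t


def tps_transform(cloud: PointCloud, t: TPSTransform) -> PointCloud:
    """Apply the radial-tangential TPS pointwise."""
    k = _basis_matrix(cloud.points, t.control_points, t.normals, t.alpha, t.beta)
    y = k @ t.weights + cloud.points @ t.affine.T + t.offset
    return cloud.with_points(y)


def fit_tps(
    source_controls: np.ndarray,
    target_controls: np.ndarray,
    alpha: float = 0.7,
    beta: float = 0.3,
    normals: np.ndarray | None = None,
) -> TPSTransform:
    """Solve the TPS interpolation system mapping sources onto targets.

    Requires >= 4 non-coplanar controls for a unique affine part.  The
    linear system is the basis matrix plus an affine block, with side
    conditions P^T W = 0, and a 1e-8 ridge on the basis block for
    conditioning.
    """
    src = np.atleast_2d(np.asarray(source_controls, dtype=np.float64))
    tgt = np.atleast_2d(np.asarray(target_controls, dtype=np.float64))
    if src.shape != tgt.shape:
        raise ValueError("source and target control lists must have equal shapes")
    c = src.shape[0]
    if c < 4:
        raise ValueError("TPS fitting needs at least 4 control points")
    if normals is None:
        # default normals: radial directions from the control centroid (unit),
        # with a fixed fallback for controls at the centroid itself
        d = src - src.mean(axis=0)
        nrm = np.linalg.norm(d, axis=1, keepdims=True)
        normals = np.where(nrm > 1e-12, d / np.maximum(nrm, 1e-12), [0.0, 0.0, 1.0])
    normals = np.atleast_2d(np.asarray(normals, dtype=np.float64))

    K = _basis_matrix(src, src, normals, alpha, beta) + RIDGE * np.eye(c)
    P = np.hstack([np.ones((c, 1)), src])  # (C, 4)
    A_sys = np.zeros((c + 4, c + 4))
    A_sys[:c, :c] = K
    A_sys[:c, c:] = P
    A_sys[c:, :c] = P.T
    rhs = np.zeros((c + 4, 3))
    rhs[:c] = tgt
    try:
        sol = np.linalg.solve(A_sys, rhs)
    except np.linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(A_sys, rhs, rcond=None)
    resid = np.linalg.norm(A_sys @ sol - rhs)
    if not np.isfinite(sol).all() or resid > 1e-3 * max(1.0, np.abs(tgt).max()):
        raise np.linalg.LinAlgError(
            f"TPS system is singular beyond ridge tolerance (residual {resid:.3g})"
        )
    W = sol[:c]
    b = sol[c]
    A = sol[c + 1:].T  # rows of sol are x/y/z monomial coefficients
    return TPSTransform(src, W, A, b, alpha, beta, normals)


def cluster_with_assignment(cloud: PointCloud, k: int, seed: int = 0,
                            max_exact: int = 600) -> np.ndarray:
    """Cluster labels for a cloud of any size.

    Clouds up to ``max_exact`` points are clustered exactly; larger clouds
    are clustered on an IFPS subsample and the remaining points assigned to
    the nearest cluster centroid.
    """
    n = len(cloud)
    if n <= max_exact:
        return hierarchical_cluster(cloud, k).labels
    sub_idx = ifps_indices(cloud.points, max_exact, seed=seed)
    sub = hierarchical_cluster(cloud.select(sub_idx), k)
    d = np.linalg.norm(cloud.points[:, None, :] - sub.centroids[None, :, :], axis=-1)
    return np.argmin(d, axis=1).astype(np.int64)


def augment(
    cloud: PointCloud,
    k: int = 8,
    n_variants: int = 1,
    max_displacement: float = 0.05,
    seed: int = 0,
    alpha: float = 0.7,
    beta: float = 0.3,
    n_controls: int = 12,
    normal_k: int = 16,
) -> list[PointCloud]:
    """Generate non-rigid variants of a plant cloud.

    For each variant the cloud is clustered into ``k`` groups, a random
    non-stem cluster is selected (the stem is taken to be the cluster whose
    centroid has the lowest height), ``n_controls`` control points are
    IFPS-sampled inside it and displaced by random vectors of norm at most
    ``max_displacement`` x bounding-box diagonal, and the fitted TPS is
    applied to that cluster only.  All other points are bit-identical to
    the input, and the output has the same N.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if k < 2:
        raise ValueError("k must be >= 2 (cannot distinguish stem from leaf regions)")
    rng = np.random.default_rng(seed)
    diag = cloud.bbox_diagonal()
    out: list[PointCloud] = []
    for _ in range(n_variants):
        if max_displacement == 0:
            out.append(PointCloud(cloud.points.copy(), labels=cloud.labels, frame=cloud.frame))
            continue
        labels = cluster_with_assignment(cloud, k, seed=int(rng.integers(2**31)))
        cz = np.array([cloud.points[labels == c][:, 2].mean() for c in range(k)])
        stem_cluster = int(np.argmin(cz))
        candidates = [c for c in range(k) if c != stem_cluster and np.any(labels == c)]
        target_cluster = int(rng.choice(candidates))
        mask = labels == target_cluster
        part = cloud.select(np.flatnonzero(mask))
        n_c = min(n_controls, len(part))
        ctrl_idx = ifps_indices(part.points, n_c, seed=int(rng.integers(2**31)))
        controls = part.points[ctrl_idx]
        normals = np.stack([
            pca_normal(part, int(i), k=min(normal_k, len(part))) for i in ctrl_idx
        ])
        direction = rng.normal(size=controls.shape)
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        magnitude = rng.uniform(0.0, max_displacement * diag, size=(len(controls), 1))
        targets = controls + direction * magnitude
        t = fit_tps(controls, targets, alpha=alpha, beta=beta, normals=normals)
        new_pts = cloud.points.copy()
        new_pts[mask] = tps_transform(part, t).points
        out.append(PointCloud(new_pts, labels=cloud.labels, frame=cloud.frame))
    return out
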