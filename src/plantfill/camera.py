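"""Virtual-camera occlusion simulation and silhouette rendering.

A virtual viewpoint on a sphere around the cloud defines an orthographic
projection plane through the cloud centroid (plane normal = centroid -
viewpoint).  From one viewpoint we can

* render a binary silhouette, stamping a density-aware disc at every
  projected point (DARE: radius r = ceil(eta * A / M) where A is the
  visible-pixel count of a probe render and M the projected point count),
* split the cloud into visible / missing subsets with a per-pixel z-buffer,
* mask predicted points against ground-truth silhouettes (a point survives
  only if its projection lands on an on-pixel in every view).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cloud import PointCloud, centroid, ifps_indices

__all__ = [
    "VirtualCamera",
    "SilhouetteImage",
    "ViewPartition",
    "camera_for_viewpoint",
    "sample_viewpoints",
    "project_point",
    "plane_uv",
    "dare_radius",
    "render_silhouette",
    "partition_visibility",
    "silhouette_mask",
]

DEFAULT_IMG = 256
DEFAULT_RADIUS_FACTOR = 2.4
DEFAULT_ETA = 1.0
PROBE_RADIUS = 3


@dataclass
class VirtualCamera:
    p_view: np.ndarray
    p_cen: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.p_view = np.asarray(self.p_view, dtype=np.float64).reshape(3)
        self.p_cen = np.asarray(self.p_cen, dtype=np.float64).reshape(3)
        if not np.isclose(np.linalg.norm(self.p_view - self.p_cen), self.radius, atol=1e-6):
            raise ValueError("viewpoint must lie on the view sphere: ||p_view - p_cen|| == radius")
        n_hat = self.normal / np.linalg.norm(self.normal)
        up = np.array([0.0, 0.0, 1.0])
        u = np.cross(up, n_hat)
        if np.linalg.norm(u) < 1e-6:
            up = np.array([0.0, 1.0, 0.0])
            u = np.cross(up, n_hat)
        self.basis_u = u / np.linalg.norm(u)
        self.basis_v = np.cross(n_hat, self.basis_u)
        self.n_hat = n_hat

    @property
    def normal(self) -> np.ndarray:
        """Projection-plane normal n = p_cen - p_view."""
        return self.p_cen - self.p_view


def camera_for_viewpoint(p_view: np.ndarray, p_cen: np.ndarray) -> VirtualCamera:
    p_view = np.asarray(p_view, dtype=np.float64)
    p_cen = np.asarray(p_cen, dtype=np.float64)
    return VirtualCamera(p_view, p_cen, float(np.linalg.norm(p_view - p_cen)))


@dataclass
class SilhouetteImage:
    pixels: np.ndarray  # (H, W) bool
    camera: VirtualCamera
    pixel_radius: int
    scale: float  # world units per pixel

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixels must be a non-empty 2-D raster")
        if self.pixel_radius <= 0:
            raise ValueError("pixel_radius must be positive")


@dataclass
class ViewPartition:
    visible: PointCloud
    missing: PointCloud
    camera: VirtualCamera
    visible_indices: np.ndarray
    missing_indices: np.ndarray
    raw_occluded: int = 0  # z-buffer occluded count before resizing to missing_size


def sample_viewpoints(
    cloud: PointCloud,
    n_views: int,
    radius_factor: float = DEFAULT_RADIUS_FACTOR,
    seed: int = 0,
) -> list[VirtualCamera]:
    """Seeded uniform viewpoints on a sphere around the cloud centroid.

    The sphere radius is ``radius_factor`` times the largest axis extent of
    the cloud; factors <= 0.5 would put the camera inside the bounding
    sphere and are rejected.
    """
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    if radius_factor <= 0.5:
        raise ValueError("radius_factor must exceed 0.5 (camera inside the cloud)")
    cen = centroid(cloud)
    lo, hi = cloud.bounding_box()
    radius = radius_factor * float((hi - lo).max())
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(n_views, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return [VirtualCamera(cen + radius * d, cen, radius) for d in dirs]


def project_point(p: np.ndarray, camera: VirtualCamera) -> np.ndarray:
    """Orthogonal projection of p onto the camera's plane through p_cen."""
    p = np.asarray(p, dtype=np.float64)
    n = camera.normal
    return p - np.outer((np.atleast_2d(p) - camera.p_cen) @ n / (n @ n), n).reshape(p.shape)


def _uv_depth(points: np.ndarray, camera: VirtualCamera) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """In-plane (u, v) coordinates and signed depth for an (N, 3) array."""
    rel = np.atleast_2d(points) - camera.p_cen
    return rel @ camera.basis_u, rel @ camera.basis_v, rel @ camera.n_hat


def plane_uv(
    p: np.ndarray,
    camera: VirtualCamera,
    H: int,
    W: int,
    scale: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pixel coordinates (row, col), signed depth, and in-frame flags.

    Pixels use a top-left origin with row = -v; the cloud center maps to
    (H/2, W/2).  Depth is the signed distance along the viewing direction;
    negative is toward the camera.  Out-of-frame pixels are flagged, not
    clamped.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    u, v, depth = _uv_depth(p, camera)
    col = np.rint(W / 2 + u / scale).astype(np.int64)
    row = np.rint(H / 2 - v / scale).astype(np.int64)
    in_frame = (row >= 0) & (row < H) & (col >= 0) & (col < W)
    return row, col, depth, in_frame


def auto_scale(cloud: PointCloud, camera: VirtualCamera, H: int, W: int,
               fill: float = 0.8) -> float:
    """World-units-per-pixel that fits the projected cloud into the frame."""
    u, v, _ = _uv_depth(cloud.points, camera)
    extent = max(u.max() - u.min(), v.max() - v.min(), 1e-12)
    return float(extent / (fill * min(H, W)))


def dare_radius(m_points: int, visible_pixels: int, eta: float = DEFAULT_ETA) -> int:
    """Density-aware pixel radius: r = ceil(eta / d) with density d = M / A."""
    if m_points < 1 or visible_pixels < 1:
        raise ValueError("point and pixel counts must be >= 1")
    if eta <= 0:
        raise ValueError("eta must be positive")
    return max(1, int(np.ceil(eta * visible_pixels / m_points)))


def _disc_offsets(r: int) -> tuple[np.ndarray, np.ndarray]:
    dr, dc = np.mgrid[-r:r + 1, -r:r + 1]
    keep = dr**2 + dc**2 <= r**2
    return dr[keep], dc[keep]


def _stamp(rows: np.ndarray, cols: np.ndarray, H: int, W: int, r: int) -> np.ndarray:
    img = np.zeros((H, W), dtype=bool)
    dr, dc = _disc_offsets(r)
    rr = (rows[:, None] + dr[None, :]).ravel()
    cc = (cols[:, None] + dc[None, :]).ravel()
    ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
    img[rr[ok], cc[ok]] = True
    return img


def render_silhouette(
    cloud: PointCloud,
    camera: VirtualCamera,
    H: int = DEFAULT_IMG,
    W: int = DEFAULT_IMG,
    eta: float = DEFAULT_ETA,
    scale: float | None = None,
) -> SilhouetteImage:
    """Two-pass density-aware silhouette render.

    Pass 1 stamps a generous probe disc to estimate the visible-pixel count
    A; pass 2 stamps discs of radius ``dare_radius(M, A, eta)``.
    """
    if scale is None:
        scale = auto_scale(cloud, camera, H, W)
    row, col, _, in_frame = plane_uv(cloud.points, camera, H, W, scale)
    if not np.any(in_frame):
        raise ValueError("all points project out of frame; increase scale or image size")
    rows, cols = row[in_frame], col[in_frame]
    m = int(in_frame.sum())
    probe = _stamp(rows, cols, H, W, PROBE_RADIUS)
    r = dare_radius(m, int(probe.sum()), eta)
    pixels = _stamp(rows, cols, H, W, r)
    return SilhouetteImage(pixels=pixels, camera=camera, pixel_radius=r, scale=scale)


def partition_visibility(
    cloud: PointCloud,
    camera: VirtualCamera,
    missing_size: int,
    H: int = DEFAULT_IMG,
    W: int = DEFAULT_IMG,
    depth_tol: float | None = None,
    scale: float | None = None,
    seed: int = 0,
) -> ViewPartition:
    """Split a cloud into visible and missing subsets under one viewpoint.

    Per-pixel z-buffer: within a pixel the point nearest the camera is
    visible, and points deeper than it by more than ``depth_tol`` (default
    1% of the bounding-box diagonal) are occluded.  The occluded set is
    then resized to exactly ``missing_size``: IFPS-reduced if larger,
    topped up with the deepest remaining points (farthest along the
    viewing direction, i.e. the far side of the cloud) if smaller.  The
    result is a disjoint cover of the input.
    """
    n = len(cloud)
    if missing_size >= n:
        raise ValueError(f"missing_size must be < N={n}")
    if depth_tol is None:
        depth_tol = 0.01 * cloud.bbox_diagonal()
    if scale is None:
        scale = auto_scale(cloud, camera, H, W)
    row, col, depth, in_frame = plane_uv(cloud.points, camera, H, W, scale)
    # out-of-frame points cannot be occluded by anything; treat as visible
    pix = row * W + col
    front = np.full(H * W, np.inf)
    np.minimum.at(front, pix[in_frame], depth[in_frame])
    margin = np.zeros(n)
    margin[in_frame] = depth[in_frame] - front[pix[in_frame]]
    occluded = margin > depth_tol
    n_raw = int(occluded.sum())

    occ_idx = np.flatnonzero(occluded)
    if len(occ_idx) > missing_size:
        keep = ifps_indices(cloud.points[occ_idx], missing_size, seed=seed)
        occ_idx = occ_idx[keep]
    elif len(occ_idx) < missing_size:
        vis_idx = np.flatnonzero(~occluded)
        order = vis_idx[np.argsort(-depth[vis_idx], kind="stable")]
        extra = order[: missing_size - len(occ_idx)]
        occ_idx = np.concatenate([occ_idx, extra])
    occ_idx = np.sort(occ_idx)
    vis_mask = np.ones(n, dtype=bool)
    vis_mask[occ_idx] = False
    vis_idx = np.flatnonzero(vis_mask)
    return ViewPartition(
        visible=cloud.select(vis_idx),
        missing=cloud.select(occ_idx),
        camera=camera,
        visible_indices=vis_idx,
        missing_indices=occ_idx,
        raw_occluded=n_raw,
    )


def silhouette_mask(pred: PointCloud, gt_silhouettes: list[SilhouetteImage]) -> np.ndarray:
    """Boolean keep-mask over predicted points.

    A predicted point is kept iff its projection lands on an on-pixel in
    *every* ground-truth silhouette; points projecting out of frame are
    dropped.
    """
    if not gt_silhouettes:
        raise ValueError("silhouette_mask requires at least one silhouette")
    keep = np.ones(len(pred), dtype=bool)
    for sil in gt_silhouettes:
        h, w = sil.pixels.shape
        row, col, _, in_frame = plane_uv(pred.points, sil.camera, h, w, sil.scale)
        on = np.zeros(len(pred), dtype=bool)
        on[in_frame] = sil.pixels[row[in_frame], col[in_frame]]
        keep &= on
    return keep
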