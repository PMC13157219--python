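"""Differentiable soft silhouette rendering.

The hard DARE renderer (``plantfill.camera.render_silhouette``) is a
binary rasterization and carries no gradient.  For the generator's
silhouette-adversarial term we instead splat each projected point as an
isotropic Gaussian of width ``sigma_px`` pixels and squash the
accumulated intensity with tanh; the resulting image is differentiable
with respect to the 3-D point coordinates.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["soft_silhouette"]


def soft_silhouette(
    points: Tensor,
    camera,
    H: int,
    W: int,
    scale: float,
    sigma_px: float = 1.5,
) -> Tensor:
    """Render an (H, W) soft silhouette of an (M, 3) point Tensor.

    Returns tanh(sum of Gaussian splats), values in [0, 1).  The backward
    pass routes pixel gradients to the point coordinates through the
    splat kernel and the orthographic projection.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    pts = points.data
    rel = pts - camera.p_cen
    u = rel @ camera.basis_u
    v = rel @ camera.basis_v
    col_f = W / 2 + u / scale
    row_f = H / 2 - v / scale

    win = int(np.ceil(3 * sigma_px))
    dr, dc = np.mgrid[-win:win + 1, -win:win + 1]
    dr, dc = dr.ravel(), dc.ravel()
    pr = np.rint(row_f).astype(np.int64)[:, None] + dr[None, :]
    pc = np.rint(col_f).astype(np.int64)[:, None] + dc[None, :]
    contrib = np.exp(
        -((pr - row_f[:, None]) ** 2 + (pc - col_f[:, None]) ** 2) / (2 * sigma_px**2)
    )
    ok = (pr >= 0) & (pr < H) & (pc >= 0) & (pc < W)
    raw = np.zeros((H, W))
    np.add.at(raw, (pr[ok], pc[ok]), contrib[ok])
    out = Tensor(raw, _prev=(points,))

    def bwd(g):
        if not points.requires_grad:
            return
        gvals = np.where(ok, g[np.clip(pr, 0, H - 1), np.clip(pc, 0, W - 1)], 0.0)
        common = gvals * contrib / sigma_px**2
        d_row = (common * (pr - row_f[:, None])).sum(axis=1)
        d_col = (common * (pc - col_f[:, None])).sum(axis=1)
        du = d_col / scale
        dv = -d_row / scale
        gp = np.outer(du, camera.basis_u) + np.outer(dv, camera.basis_v)
        points._accum(gp)

    out._backward = bwd
    return out.tanh()
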