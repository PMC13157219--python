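"""Differentiable training losses for the completion GAN.

The total objective is L = lambda_com * L_com + lambda_dis * L_dis +
lambda_sil * L_sil, where L_com is a three-scale Chamfer completion loss
(ground truths at the secondary and primary resolutions come from one and
two rounds of farthest point sampling of the detail-resolution ground
truth), and the adversarial terms use standard non-saturating GAN binary
cross-entropy for both discriminators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .camera import SilhouetteImage, render_silhouette
from .nn import Tensor, concat, soft_silhouette
from .networks import MultiScalePrediction, geometric_ifps

__all__ = [
    "LossWeights",
    "chamfer_t",
    "completion_loss",
    "discriminator_loss",
    "generator_adversarial",
    "silhouette_loss",
    "total_loss",
]

EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """Objective weights; at least one lambda must be positive."""

    lambda_com: float = 1.0
    lambda_dis: float = 0.05
    lambda_sil: float = 0.05
    alpha_mid: float = 0.5
    beta_coarse: float = 0.25

    def __post_init__(self) -> None:
        if min(self.lambda_com, self.lambda_dis, self.lambda_sil,
               self.alpha_mid, self.beta_coarse) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.lambda_com + self.lambda_dis + self.lambda_sil <= 0:
            raise ValueError("at least one lambda must be positive")


def chamfer_t(a: Tensor, b) -> Tensor:
    """Differentiable symmetric Chamfer distance, batch-averaged.

    ``a``: Tensor (B, Na, 3) or (Na, 3); ``b``: array/Tensor broadcastable
    to (B, Nb, 3).  Returns a scalar Tensor (mean over the batch).
    """
    b = b if isinstance(b, Tensor) else Tensor(np.asarray(b, dtype=np.float64))
    if a.ndim == 2:
        a = a.reshape(1, *a.shape)
    if b.ndim == 2:
        b = b.reshape(1, *b.shape)
    diff = a.reshape(a.shape[0], a.shape[1], 1, 3) - b.reshape(b.shape[0], 1, b.shape[1], 3)
    sq = (diff * diff).sum(axis=3)
    d_ab = sq.amin(axis=2).mean(axis=1)  # (B,)
    d_ba = sq.amin(axis=1).mean(axis=1)
    return (d_ab + d_ba).mean()


def completion_loss(
    pred: MultiScalePrediction,
    gt_detail: np.ndarray,
    weights: LossWeights = LossWeights(),
) -> tuple[Tensor, dict[str, float]]:
    """Three-scale Chamfer loss against IFPS-reduced ground truths.

    gt_detail: (B, M, 3).  The secondary/primary ground truths are one and
    two farthest-point-sampling halvings of gt_detail (deterministic
    geometric start, so the loss is reproducible).
    """
    gt = np.asarray(gt_detail, dtype=np.float64)
    if gt.ndim == 2:
        gt = gt[None]
    b, m, _ = gt.shape
    det, sec, pri = pred.detail, pred.secondary, pred.primary
    if det.ndim == 2:
        det, sec, pri = (t.reshape(1, *t.shape) for t in (det, sec, pri))
    if det.shape[1] > m:
        raise ValueError("ground truth must have at least as many points as the detail scale")
    m_sec = sec.shape[1]
    m_pri = pri.shape[1]
    gt1 = np.stack([g[geometric_ifps(g, m_sec)] for g in gt])
    gt2 = np.stack([g1[geometric_ifps(g1, m_pri)] for g1 in gt1])
    d1 = chamfer_t(det, gt)
    d2 = chamfer_t(sec, gt1)
    d3 = chamfer_t(pri, gt2)
    loss = d1 + weights.alpha_mid * d2 + weights.beta_coarse * d3
    terms = {
        "cd_detail": float(d1.data),
        "cd_secondary": float(d2.data),
        "cd_primary": float(d3.data),
    }
    return loss, terms


def _safe_scores(scores: Tensor) -> Tensor:
    if np.any(scores.data <= 0) or np.any(scores.data >= 1):
        warnings.warn("discriminator scores outside (0, 1); clipping at 1e-7", stacklevel=3)
    return scores.clip_min(EPS)


def discriminator_loss(real_scores: Tensor, fake_scores: Tensor) -> Tensor:
    """Binary cross-entropy discriminator objective.

    mean(-log D(real) - log(1 - D(fake))); at the 0.5/0.5 fixed point this
    is 2 log 2 per pair, and it tends to 0 for a perfect discriminator.
    """
    real = _safe_scores(real_scores)
    one_minus_fake = _safe_scores(1.0 - fake_scores)
    return (-(real.log()) - one_minus_fake.log()).mean()


def generator_adversarial(fake_scores: Tensor) -> Tensor:
    """Non-saturating generator term: mean(-log D(fake))."""
    return (-_safe_scores(fake_scores).log()).mean()


def silhouette_loss(
    pred_points: Tensor,
    gt_points: np.ndarray,
    cameras: list,
    disc,
    H: int,
    W: int,
    scales: list[float] | None = None,
    sigma_px: float = 1.5,
) -> tuple[Tensor, Tensor]:
    """Per-view adversarial silhouette terms, averaged over N_proj views.

    Renders the (masked) predicted cloud softly and the ground-truth cloud
    hard for every camera, scores both with the silhouette discriminator,
    and returns ``(generator_term, discriminator_term)``.  The generator
    term backpropagates to the predicted point coordinates through the
    soft renderer.
    """
    if not cameras:
        raise ValueError("silhouette_loss requires at least one camera")
    from .cloud import PointCloud

    fake_imgs = []
    real_imgs = []
    for j, cam in enumerate(cameras):
        scale = None if scales is None else scales[j]
        gt_sil = render_silhouette(PointCloud(gt_points), cam, H, W, scale=scale)
        real_imgs.append(gt_sil.pixels.astype(np.float64))
        fake_imgs.append(soft_silhouette(pred_points, cam, H, W, gt_sil.scale, sigma_px))
    fake = concat([img.reshape(1, 1, H, W) for img in fake_imgs], axis=0)
    real = Tensor(np.stack(real_imgs)[:, None, :, :])
    fake_scores = disc(fake)
    real_scores = disc(real)
    gen_term = generator_adversarial(fake_scores)
    disc_term = discriminator_loss(real_scores, fake_scores.detach().clip_min(EPS))
    return gen_term, disc_term


def total_loss(l_com, l_dis, l_sil, weights: LossWeights = LossWeights()):
    """Weighted sum lambda_com * L_com + lambda_dis * L_dis + lambda_sil * L_sil."""
    return (
        weights.lambda_com * l_com
        + weights.lambda_dis * l_dis
        + weights.lambda_sil * l_sil
    )
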