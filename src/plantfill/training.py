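"""Alternating adversarial training, evaluation, and single-view completion.

One training item is a (plant, viewpoint) pair: the normalized complete
cloud is split by the virtual camera into a fixed-size visible input and
the ground-truth missing region, and the complete cloud's multi-view
silhouettes provide both the consistency mask and the silhouette
discriminator's reference images.  Per iteration the two discriminators
are updated first on real vs. generated (masked) samples, then the
encoder + generator are updated with the combined multi-resolution
completion loss and adversarial feedback.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .camera import (
    partition_visibility,
    render_silhouette,
    sample_viewpoints,
    silhouette_mask,
)
from .cloud import PointCloud, ifps_indices, normalize, denormalize, rotate_z
from .losses import (
    LossWeights,
    chamfer_t,
    completion_loss,
    discriminator_loss,
    generator_adversarial,
    total_loss,
)
from .metrics import MetricReport, chamfer, ema_smooth, metric_report, DEFAULT_TAU
from .networks import MSDDGModel, NetConfig, desk_config, geometric_ifps
from .nn import AdamW, StepLR, Tensor, concat, soft_silhouette
from .synthetic import DatasetIndex, load_sample

__all__ = [
    "TrainConfig",
    "TrainLog",
    "TrainingItem",
    "desk_train_config",
    "build_items",
    "train",
    "evaluate",
    "baseline_visible_ifps",
    "complete",
    "rotation_robustness",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (defaults follow the full-scale protocol)."""

    learning_rate: float = 5e-4
    weight_decay: float = 1e-4
    batch_size: int = 16
    iterations: int = 1000
    scheduler_step: int = 50
    scheduler_gamma: float = 0.5
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    n_partition_views: int = 5
    n_sil_views: int = 10
    cloud_size: int = 2048
    net: NetConfig = field(default_factory=NetConfig)
    optimizer: str = "adamw"  # "adamw" (decoupled decay) or "adam"
    betas: tuple[float, float] = (0.9, 0.999)
    ema_alpha: float = 0.2
    checkpoint_every: int = 0  # 0 = only final
    sigma_px: float = 1.5

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.iterations < 1:
            raise ValueError("rates and sizes must be positive")
        if self.optimizer not in ("adamw", "adam"):
            raise ValueError("optimizer must be 'adamw' or 'adam'")
        if self.net.M >= self.cloud_size:
            raise ValueError("missing size M must be smaller than cloud_size")

    @property
    def visible_size(self) -> int:
        return self.cloud_size - self.net.M


def desk_train_config(seed: int = 0, iterations: int = 200) -> TrainConfig:
    """CPU-scale preset: quartered widths, M = 128, 384-point clouds.

    The loss weighting is chamfer-dominant (small adversarial weights) so
    the short run stays in the supervised-convergence regime; the
    full-scale defaults in :class:`LossWeights` keep the larger
    adversarial weights.
    """
    return TrainConfig(
        learning_rate=2e-3,
        iterations=iterations,
        scheduler_step=100,
        seed=seed,
        weights=LossWeights(lambda_com=1.0, lambda_dis=0.01, lambda_sil=0.01),
        n_partition_views=5,
        n_sil_views=3,
        cloud_size=384,
        net=desk_config(M=128, seed=seed),
    )


def load_config(path: str | Path) -> TrainConfig:
    """Build a TrainConfig from a YAML file.

    Top-level keys map to TrainConfig fields; the nested ``net`` and
    ``weights`` mappings build NetConfig / LossWeights.  Omitted keys keep
    their defaults.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = dict(raw)
    if "net" in kwargs:
        net = {k: tuple(v) if isinstance(v, list) else v for k, v in kwargs["net"].items()}
        kwargs["net"] = NetConfig(**net)
    if "weights" in kwargs:
        kwargs["weights"] = LossWeights(**kwargs["weights"])
    return TrainConfig(**kwargs)


@dataclass
class TrainingItem:
    """One (plant, viewpoint) training pair in normalized coordinates."""

    visible: np.ndarray  # (V, 3)
    missing: np.ndarray  # (M, 3)
    species: str
    sil_cameras: list
    sil_images: list  # hard SilhouetteImage of the complete cloud, per view
    soft_real: np.ndarray  # (n_views, H, W) soft renders of the complete cloud


@dataclass
class TrainLog:
    """Per-iteration raw losses; EMA series derive from them via ema_smooth."""

    l_com: list[float] = field(default_factory=list)
    l_dis: list[float] = field(default_factory=list)
    l_sil: list[float] = field(default_factory=list)
    l_total: list[float] = field(default_factory=list)
    checkpoints: list[str] = field(default_factory=list)
    ema_alpha: float = 0.2

    def ema(self, series: str) -> np.ndarray:
        return ema_smooth(getattr(self, series), alpha=self.ema_alpha)


def _prepare_sample(cloud: PointCloud, species: str, config: TrainConfig,
                    rng: np.random.Generator) -> list[TrainingItem]:
    """Normalize, downsample, partition under several views, render silhouettes."""
    sub = cloud.select(ifps_indices(cloud.points, config.cloud_size, seed=int(rng.integers(2**31))))
    norm, _ = normalize(sub)
    H = W = config.net.sil_img
    sil_cams = sample_viewpoints(norm, config.n_sil_views, seed=int(rng.integers(2**31)))
    sils = [render_silhouette(norm, cam, H, W) for cam in sil_cams]
    soft_real = np.stack([
        soft_silhouette(Tensor(norm.points), cam, H, W, sil.scale, config.sigma_px).data
        for cam, sil in zip(sil_cams, sils)
    ])
    part_cams = sample_viewpoints(norm, config.n_partition_views,
                                  seed=int(rng.integers(2**31)))
    items = []
    for cam in part_cams:
        part = partition_visibility(norm, cam, config.net.M,
                                    H=H, W=W, seed=int(rng.integers(2**31)))
        items.append(TrainingItem(
            visible=part.visible.points,
            missing=part.missing.points,
            species=species,
            sil_cameras=sil_cams,
            sil_images=sils,
            soft_real=soft_real,
        ))
    return items


def build_items(index: DatasetIndex, config: TrainConfig, split: str,
                limit: Optional[int] = None) -> list[TrainingItem]:
    """Materialize (plant, view) training items for one dataset split."""
    rng = np.random.default_rng(config.seed + {"train": 0, "test": 1, "val": 2}[split])
    entries = index.split(split)
    if limit is not None:
        entries = entries[:limit]
    items: list[TrainingItem] = []
    for entry in entries:
        items.extend(_prepare_sample(load_sample(entry), entry["species"], config, rng))
    if not items:
        raise ValueError(f"dataset split {split!r} is empty")
    return items


def _keep_masks(pred_detail: np.ndarray, batch: Sequence[TrainingItem]) -> np.ndarray:
    """(B, M, 1) silhouette-consistency keep masks for a predicted batch."""
    masks = []
    for points, item in zip(pred_detail, batch):
        keep = silhouette_mask(PointCloud(points), item.sil_images)
        masks.append(keep[:, None].astype(np.float64))
    return np.stack(masks)


def train(
    items: Sequence[TrainingItem],
    config: TrainConfig,
    checkpoint_dir: Optional[str | Path] = None,
) -> tuple[MSDDGModel, TrainLog]:
    """Alternating adversarial training on prepared items.

    Per iteration: (1) both discriminators are updated to separate real
    from generated (masked) samples; (2) encoder + generator are updated
    with the weighted completion + adversarial objective.  Raises on a
    non-finite loss with the iteration index.
    """
    if not items:
        raise ValueError("training requires a non-empty item list")
    rng = np.random.default_rng(config.seed)
    model = MSDDGModel(config.net)
    model.train()
    decoupled = config.optimizer == "adamw"
    g_opt = AdamW(model.encoder.parameters() + model.generator.parameters(),
                  lr=config.learning_rate, betas=config.betas,
                  weight_decay=config.weight_decay, decoupled=decoupled)
    d_opt = AdamW(model.spatial_disc.parameters() + model.sil_disc.parameters(),
                  lr=config.learning_rate, betas=config.betas,
                  weight_decay=config.weight_decay, decoupled=decoupled)
    sched = StepLR(g_opt, step_size=config.scheduler_step, gamma=config.scheduler_gamma)
    log = TrainLog(ema_alpha=config.ema_alpha)
    H = W = config.net.sil_img

    for it in range(config.iterations):
        batch_idx = rng.choice(len(items), size=min(config.batch_size, len(items)),
                               replace=len(items) < config.batch_size)
        batch = [items[i] for i in batch_idx]
        vis = np.stack([b.visible for b in batch])
        gt = np.stack([b.missing for b in batch])

        # ---- generator forward (shared for both phases)
        pred = model.generator(model.encoder(vis))
        masks = _keep_masks(pred.detail.data, batch)
        masked_fake = pred.detail.data * masks

        # ---- phase 1: discriminator updates (generator frozen)
        d_opt.zero_grad()
        real_s = model.spatial_disc(Tensor(gt))
        fake_s = model.spatial_disc(Tensor(masked_fake))
        l_d_spatial = discriminator_loss(real_s, fake_s)

        fake_imgs, real_imgs = [], []
        for points, item in zip(masked_fake, batch):
            j = int(rng.integers(len(item.sil_cameras)))
            cam, sil = item.sil_cameras[j], item.sil_images[j]
            fake_imgs.append(
                soft_silhouette(Tensor(points), cam, H, W, sil.scale, config.sigma_px).data
            )
            real_imgs.append(item.soft_real[j])
        real_sil = model.sil_disc(Tensor(np.stack(real_imgs)[:, None]))
        fake_sil = model.sil_disc(Tensor(np.stack(fake_imgs)[:, None]))
        l_d_sil = discriminator_loss(real_sil, fake_sil)
        (l_d_spatial + l_d_sil).backward()
        d_opt.step()

        # ---- phase 2: encoder + generator update
        g_opt.zero_grad()
        l_com, _ = completion_loss(pred, gt, config.weights)
        mask_t = Tensor(masks)
        masked_pred = pred.detail * mask_t
        l_adv_dis = generator_adversarial(model.spatial_disc(masked_pred))
        sil_terms = []
        for i, item in enumerate(batch):
            j = int(rng.integers(len(item.sil_cameras)))
            cam, sil = item.sil_cameras[j], item.sil_images[j]
            img = soft_silhouette(masked_pred[i], cam, H, W, sil.scale, config.sigma_px)
            sil_terms.append(img.reshape(1, 1, H, W))
        l_adv_sil = generator_adversarial(model.sil_disc(concat(sil_terms, axis=0)))
        loss = total_loss(l_com, l_adv_dis, l_adv_sil, config.weights)
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"non-finite loss at iteration {it}")
        loss.backward()
        g_opt.step()
        sched.step()

        log.l_com.append(float(l_com.data))
        log.l_dis.append(float(l_d_spatial.data))
        log.l_sil.append(float(l_d_sil.data))
        log.l_total.append(float(loss.data))
        if (checkpoint_dir is not None and config.checkpoint_every
                and (it + 1) % config.checkpoint_every == 0):
            path = Path(checkpoint_dir) / f"ckpt_{it + 1:06d}.npz"
            model.save(path)
            log.checkpoints.append(str(path))

    if checkpoint_dir is not None:
        path = Path(checkpoint_dir) / "ckpt_final.npz"
        Path(checkpoint_dir).mkdir(parents=True, exist_ok=True)
        model.save(path)
        log.checkpoints.append(str(path))
    return model, log


def evaluate(model: MSDDGModel, items: Sequence[TrainingItem],
             tau: float = DEFAULT_TAU) -> dict:
    """Per-item metrics of predicted vs. ground-truth missing regions.

    Returns ``{"per_item": [...], "per_species": {...}, "mean": {...}}``
    with dCD / dUCD / dHD / F1 aggregated per species and overall.
    """
    model.eval()
    reports: list[tuple[str, MetricReport]] = []
    for item in items:
        pred = model.predict(item.visible).detail.data[0]
        reports.append((item.species, metric_report(pred, item.missing, tau)))
    model.train()
    return _aggregate(reports)


def baseline_visible_ifps(items: Sequence[TrainingItem],
                          m: int, tau: float = DEFAULT_TAU) -> dict:
    """Reference predictor: m IFPS points of the visible cloud."""
    reports = []
    for item in items:
        pred = item.visible[geometric_ifps(item.visible, m)]
        reports.append((item.species, metric_report(pred, item.missing, tau)))
    return _aggregate(reports)


def _aggregate(reports: list[tuple[str, MetricReport]]) -> dict:
    def summarize(rs: list[MetricReport]) -> dict:
        return {
            "dCD": float(np.mean([r.d_cd for r in rs])),
            "dUCD": float(np.mean([r.d_ucd for r in rs])),
            "dHD": float(np.mean([r.d_hd for r in rs])),
            "F1": float(np.mean([r.f1 for r in rs])),
            "n": len(rs),
        }

    species = sorted({s for s, _ in reports})
    return {
        "per_item": [r for _, r in reports],
        "per_species": {s: summarize([r for sp, r in reports if sp == s]) for s in species},
        "mean": summarize([r for _, r in reports]),
    }


def report_csv(report: dict) -> str:
    """Render an evaluation report as CSV, one row per species plus the mean.

    The unidirectional-Chamfer and Hausdorff columns are both emitted and
    labeled explicitly (published tables sometimes conflate the two under
    one header).
    """
    lines = ["group,dCD,dUCD,dHD,F1,n"]
    rows = dict(report["per_species"])
    rows["average"] = report["mean"]
    for name, r in rows.items():
        lines.append(f"{name},{r['dCD']:.6g},{r['dUCD']:.6g},{r['dHD']:.6g},"
                     f"{r['F1']:.6g},{r['n']}")
    return "\n".join(lines) + "\n"


def complete(model: MSDDGModel, incomplete: PointCloud,
             input_size: Optional[int] = None, seed: int = 0) -> PointCloud:
    """Single-view completion: returns input ∪ M predicted points.

    The incomplete cloud is normalized to [-1, 1], IFPS-downsampled to the
    network's fixed input size, passed through encoder + generator, and
    the predicted detail points are denormalized back with the stored
    state.  The output contains the original points bit-identically,
    followed by the M predictions (N_out = N_in + M).
    """
    n = len(incomplete)
    if input_size is None:
        input_size = 2048 - model.config.M  # full-scale preprocessing convention
    norm, state = normalize(incomplete)
    if n >= input_size:
        sub = norm.points[ifps_indices(norm.points, input_size, seed=seed)]
    else:  # pad by cycling points to reach the fixed input size
        reps = np.resize(np.arange(n), input_size)
        sub = norm.points[reps]
    model.eval()
    pred_norm = model.predict(sub).detail.data[0]
    model.train()
    pred_world = denormalize(PointCloud(pred_norm, frame="normalized"), state)
    return PointCloud(np.vstack([incomplete.points, pred_world.points]))


def rotation_robustness(model: MSDDGModel, items: Sequence[TrainingItem],
                        angles: Sequence[float] = (30.0, 60.0, 90.0)) -> dict:
    """Completion accuracy under z-rotations of the (normalized) input.

    For each angle the visible cloud is rotated, the missing region is
    predicted, the prediction is rotated back, and the Chamfer distance to
    the unrotated ground truth is compared with the unrotated baseline.
    Returns per-angle mean CD, the baseline CD, and the deltas.
    """
    model.eval()
    base = []
    per_angle = {float(a): [] for a in angles}
    for item in items:
        pred0 = model.predict(item.visible).detail.data[0]
        base.append(chamfer(pred0, item.missing))
        for a in angles:
            vis_rot = rotate_z(PointCloud(item.visible, frame="normalized"), a)
            pred = model.predict(vis_rot.points).detail.data[0]
            pred_back = rotate_z(PointCloud(pred, frame="normalized"), -a)
            per_angle[float(a)].append(chamfer(pred_back.points, item.missing))
    model.train()
    baseline = float(np.mean(base))
    out = {"baseline_cd": baseline, "angles": {}}
    for a, vals in per_angle.items():
        cd = float(np.mean(vals))
        out["angles"][a] = {"cd": cd, "delta": cd - baseline}
    return out
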