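"""Completion-network architecture: encoder, generator, dual discriminators.

* ``CMLP``: a shared per-point MLP with widths [64, 128, 256, 512, 1024]
  whose last four layer outputs are each globally max-pooled over points
  and concatenated, giving a 1920-dimensional combined feature.
* ``MultiResolutionEncoder`` (MRE): three parallel CMLPs fed with farthest
  point samplings of the input at resolutions N, N/2 and N/4, concatenated
  and mapped through a final MLP back to the 1920-dimensional latent V.
* ``MultiScaleGenerator`` (MSPG): four chained fully connected layers
  (1024 / 512 / 256 / 128); the two coarsest feed a primary point set of
  M/4 points, the middle layer expands it to a secondary set of M/2 via
  skip-connected per-point offsets, and the widest layer refines to the
  detail set of M points.  All outputs are tanh-squashed into [-1, 1].
* ``SpatialDiscriminator`` / ``SilhouetteDiscriminator``: a shared
  [1->64, 64->128, 128->256] channel progression in the dual-discriminator
  heads, scoring 3-D point sets and 2-D silhouettes respectively with a
  sigmoid output in (0, 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cloud import ifps_indices
from .nn import AdamW, BatchNorm, Conv2d, Linear, Module, Tensor, concat

__all__ = [
    "NetConfig",
    "desk_config",
    "MultiScalePrediction",
    "CMLP",
    "MultiResolutionEncoder",
    "MultiScaleGenerator",
    "SpatialDiscriminator",
    "SilhouetteDiscriminator",
    "MSDDGModel",
    "geometric_ifps",
]


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters.

    ``cmlp_widths`` are the per-point layer widths; the last ``n_pooled``
    of them are max-pooled and concatenated, so the latent dimension is
    their sum (1920 for the default widths).  ``mre_scales`` are the IFPS
    divisor factors for the three parallel encoder branches.  ``M`` is the
    generator's detail-resolution output size; secondary and primary are
    M/2 and M/4.
    """

    cmlp_widths: tuple[int, ...] = (64, 128, 256, 512, 1024)
    n_pooled: int = 4
    mre_scales: tuple[int, ...] = (1, 2, 4)
    mspg_fc_dims: tuple[int, ...] = (1024, 512, 256, 128)
    disc_channels: tuple[int, ...] = (64, 128, 256)
    M: int = 512
    sil_img: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M % 4 != 0:
            raise ValueError("M must be divisible by 4 (three output scales)")
        if len(self.mspg_fc_dims) != 4:
            raise ValueError("mspg_fc_dims must list four layer widths")
        if list(self.disc_channels) != sorted(set(self.disc_channels)):
            raise ValueError("disc_channels must be strictly increasing")

    @property
    def latent_dim(self) -> int:
        return sum(self.cmlp_widths[-self.n_pooled:])


def desk_config(M: int = 128, seed: int = 0) -> NetConfig:
    """CPU-scale preset: channel widths quartered throughout."""
    return NetConfig(
        cmlp_widths=(16, 32, 64, 128, 256),
        mspg_fc_dims=(256, 128, 64, 32),
        disc_channels=(16, 32, 64),
        M=M,
        sil_img=64,
        seed=seed,
    )


@dataclass
class MultiScalePrediction:
    """Generator output at three resolutions (Tensors of shape (B, n, 3))."""

    primary: Tensor
    secondary: Tensor
    detail: Tensor

    def detail_clouds(self) -> np.ndarray:
        return self.detail.data


def geometric_ifps(points: np.ndarray, m: int) -> np.ndarray:
    """Permutation-invariant IFPS: start at the point farthest from the centroid."""
    start = int(np.argmax(np.linalg.norm(points - points.mean(axis=0), axis=1)))
    return ifps_indices(points, m, start=start)


class _PointBlock(Module):
    """Linear -> BatchNorm -> ReLU applied per point."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.lin = Linear(n_in, n_out, rng)
        self.bn = BatchNorm(n_out)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.lin(x)).relu()


class CMLP(Module):
    """Combined MLP: per-point layers with the last four max-pooled and concatenated."""

    def __init__(self, config: NetConfig, rng: np.random.Generator):
        super().__init__()
        widths = config.cmlp_widths
        self.n_pooled = config.n_pooled
        dims = [3, *widths]
        self.blocks = [_PointBlock(dims[i], dims[i + 1], rng) for i in range(len(widths))]

    def forward(self, x: Tensor) -> Tensor:
        """(B, N, 3) -> (B, latent_dim)."""
        pooled = []
        h = x
        for i, block in enumerate(self.blocks):
            h = block(h)
            if i >= len(self.blocks) - self.n_pooled:
                pooled.append(h.amax(axis=1))
        return concat(pooled, axis=-1)


class MultiResolutionEncoder(Module):
    """Three parallel CMLPs on multi-resolution IFPS inputs -> latent V."""

    def __init__(self, config: NetConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.branches = [CMLP(config, rng) for _ in config.mre_scales]
        L = config.latent_dim
        self.fuse1 = Linear(L * len(config.mre_scales), L, rng)
        self.fuse_bn = BatchNorm(L)
        self.fuse2 = Linear(L, L, rng)

    def forward(self, points: np.ndarray) -> Tensor:
        """points: (B, N, 3) array or Tensor -> latent (B, latent_dim)."""
        x = points if isinstance(points, Tensor) else Tensor(points)
        if not np.all(np.isfinite(x.data)):
            raise ValueError("encoder input contains non-finite coordinates")
        b, n, _ = x.shape
        if n < max(self.config.mre_scales):
            raise ValueError(f"input has {n} points; need at least {max(self.config.mre_scales)}")
        feats = []
        for divisor, branch in zip(self.config.mre_scales, self.branches):
            m = n // divisor
            if divisor == 1:
                sub = x
            else:
                idx = np.stack([geometric_ifps(x.data[i], m) for i in range(b)])
                sub = x[np.arange(b)[:, None], idx]
            feats.append(branch(sub))
        fused = self.fuse_bn(self.fuse1(concat(feats, axis=-1))).relu()
        return self.fuse2(fused)


class MultiScaleGenerator(Module):
    """Coarse-to-fine point decoder with skip-connected per-point offsets."""

    def __init__(self, config: NetConfig, rng: np.random.Generator):
        super().__init__()
        self.M = config.M
        d1, d2, d3, d4 = config.mspg_fc_dims
        L = config.latent_dim
        self.fc1 = Linear(L, d1, rng)
        self.fc2 = Linear(d1, d2, rng)
        self.fc3 = Linear(d2, d3, rng)
        self.fc4 = Linear(d3, d4, rng)
        self.head_primary = Linear(d3 + d4, (self.M // 4) * 3, rng)
        self.head_secondary = Linear(d2, (self.M // 2) * 3, rng)
        self.head_detail = Linear(d1, self.M * 3, rng)

    def forward(self, v: Tensor) -> MultiScalePrediction:
        # no normalization in the decoder chain: batch statistics fight the
        # coordinate-regression objective
        if not np.all(np.isfinite(v.data)):
            raise ValueError("generator input latent contains non-finite values")
        b = v.shape[0]
        l1 = self.fc1(v).relu()
        l2 = self.fc2(l1).relu()
        l3 = self.fc3(l2).relu()
        l4 = self.fc4(l3).relu()
        primary = self.head_primary(concat([l3, l4], axis=-1)).reshape(b, self.M // 4, 3).tanh()
        off_sec = self.head_secondary(l2).reshape(b, self.M // 2, 3)
        secondary = (primary.repeat(2, axis=1) + off_sec).tanh()
        off_det = self.head_detail(l1).reshape(b, self.M, 3)
        detail = (secondary.repeat(2, axis=1) + off_det).tanh()
        return MultiScalePrediction(primary=primary, secondary=secondary, detail=detail)


class SpatialDiscriminator(Module):
    """Scores the 3-D plausibility of a fixed-size point set, output in (0, 1)."""

    def __init__(self, config: NetConfig, rng: np.random.Generator):
        super().__init__()
        self.M = config.M
        c = config.disc_channels
        dims = [3, *c]
        self.blocks = [_PointBlock(dims[i], dims[i + 1], rng) for i in range(len(c))]
        self.head1 = Linear(sum(c), 128, rng)
        self.head2 = Linear(128, 1, rng)

    def forward(self, x) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.shape[1] != self.M:
            raise ValueError(f"spatial discriminator expects {self.M} points, got {x.shape[1]}")
        pooled = []
        h = x
        for block in self.blocks:
            h = block(h)
            pooled.append(h.amax(axis=1))
        feat = concat(pooled, axis=-1)
        return self.head2(self.head1(feat).relu()).sigmoid()


class SilhouetteDiscriminator(Module):
    """Scores the realism of binary/soft silhouette rasters, output in (0, 1)."""

    def __init__(self, config: NetConfig, rng: np.random.Generator):
        super().__init__()
        self.img = config.sil_img
        c = config.disc_channels
        dims = [1, *c]
        self.convs = [Conv2d(dims[i], dims[i + 1], 3, rng, stride=2) for i in range(len(c))]
        self.bns = [BatchNorm(ch, axis_last=False) for ch in c]
        self.head1 = Linear(c[-1], 64, rng)
        self.head2 = Linear(64, 1, rng)

    def forward(self, x) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.ndim == 3:
            x = x.reshape(x.shape[0], 1, x.shape[1], x.shape[2])
        if x.shape[2] != self.img or x.shape[3] != self.img:
            raise ValueError(f"silhouette discriminator expects {self.img}x{self.img} rasters")
        h = x
        for conv, bn in zip(self.convs, self.bns):
            h = bn(conv(h).relu())
        feat = h.amax(axis=3).amax(axis=2)
        return self.head2(self.head1(feat).relu()).sigmoid()


class MSDDGModel:
    """The full network bundle: encoder, generator and the two discriminators."""

    def __init__(self, config: NetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.encoder = MultiResolutionEncoder(config, rng)
        self.generator = MultiScaleGenerator(config, rng)
        self.spatial_disc = SpatialDiscriminator(config, rng)
        self.sil_disc = SilhouetteDiscriminator(config, rng)

    def modules(self) -> dict[str, Module]:
        return {
            "encoder": self.encoder,
            "generator": self.generator,
            "spatial_disc": self.spatial_disc,
            "sil_disc": self.sil_disc,
        }

    def train(self) -> None:
        for m in self.modules().values():
            m.train()

    def eval(self) -> None:
        for m in self.modules().values():
            m.eval()

    def predict(self, visible: np.ndarray) -> MultiScalePrediction:
        """Forward encoder + generator on a (B, N, 3) or (N, 3) visible cloud."""
        pts = np.asarray(visible, dtype=np.float64)
        if pts.ndim == 2:
            pts = pts[None]
        return self.generator(self.encoder(pts))

    def save(self, path: str | Path) -> None:
        """Single-archive checkpoint: all module weights plus the config as JSON."""
        state: dict[str, np.ndarray] = {}
        for name, module in self.modules().items():
            state.update(module.state_dict(prefix=name + "/"))
        cfg = json.dumps(vars(self.config) | {"__class__": "NetConfig"}, default=list)
        np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8), **state)

    @classmethod
    def load(cls, path: str | Path) -> "MSDDGModel":
        with np.load(path) as archive:
            cfg_raw = json.loads(bytes(archive["__config__"]).decode())
            cfg_raw.pop("__class__", None)
            cfg = NetConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in cfg_raw.items()})
            model = cls(cfg)
            state = {k: archive[k] for k in archive.files if k != "__config__"}
        for name, module in model.modules().items():
            prefix = name + "/"
            module.load_state_dict(
                {k[len(prefix):]: v for k, v in state.items() if k.startswith(prefix)},
            )
        return model
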