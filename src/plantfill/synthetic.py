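"""Seedable generator of synthetic plant point clouds.

Emulates juvenile row-crop plants (a stem plus several curved leaves) at
the fidelity the completion pipeline needs: thin curved sheets attached to
a roughly vertical stem, organ labels, > 5000 points per plant, and four
species-like templates that differ in leaf shape, aspect and droop.  The
leaf surface is a quadratic-Bezier-bent ellipse patch; the ``curvature``
parameter bends it along the midrib.  No botanical fidelity is claimed.

Labels: 0 = stem, i = i-th leaf (1-based).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .cloud import PointCloud
from .io import save_cloud

__all__ = [
    "SPECIES_TEMPLATES",
    "PlantSpec",
    "DatasetIndex",
    "generate_plant",
    "leaf_surface",
    "generate_dataset",
]

# template -> (width profile name, leaf aspect, base droop, elevation slope)
SPECIES_TEMPLATES = {
    "sunflower_like": ("heart", 0.85, 0.55, 0.60),
    "pumpkin_like": ("heart", 1.10, 0.75, 0.45),
    "eggplant_like": ("oval", 0.70, 0.50, 0.55),
    "luffa_like": ("lobed", 0.95, 0.85, 0.50),
}

_GOLDEN_ANGLE_DEG = 137.5


@dataclass(frozen=True)
class PlantSpec:
    """Generation parameters for one synthetic plant.

    ``points_total`` must be >= 5000 (complete clouds in this pipeline are
    dense; downstream preprocessing downsamples them).  ``n_leaves`` is
    capped at 50, the most complex canopy the method targets.
    """

    species_template: str = "sunflower_like"
    n_leaves: int = 5
    stem_height: float = 1.0
    leaf_scale: float = 0.45
    curvature: float = 0.5
    points_total: int = 6000
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.species_template not in SPECIES_TEMPLATES:
            raise ValueError(
                f"unknown species_template {self.species_template!r}; "
                f"expected one of {sorted(SPECIES_TEMPLATES)}"
            )
        if not 1 <= self.n_leaves <= 50:
            raise ValueError("n_leaves must be in [1, 50]")
        if self.points_total < 5000:
            raise ValueError("points_total must be >= 5000")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.stem_height <= 0 or self.leaf_scale <= 0:
            raise ValueError("stem_height and leaf_scale must be positive")


def _width_profile(name: str, u: np.ndarray) -> np.ndarray:
    if name == "heart":
        return np.sin(np.pi * np.power(u, 0.7))
    if name == "oval":
        return np.sin(np.pi * u)
    if name == "lobed":
        return np.sin(np.pi * u) * (1.0 + 0.25 * np.sin(3.0 * np.pi * u))
    raise ValueError(name)


def _leaf_frame(spec: PlantSpec, leaf_idx: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Attachment point and in-plane basis (midrib, side) for leaf ``leaf_idx`` (1-based)."""
    shape, _, _, _ = SPECIES_TEMPLATES[spec.species_template]
    n = spec.n_leaves
    # attachment fraction along the stem, spread over the upper portion
    frac = 0.30 + 0.65 * (leaf_idx - 0.5) / n
    attach = _stem_centerline(spec, np.array([frac]))[0]
    azim = np.deg2rad(_GOLDEN_ANGLE_DEG * (leaf_idx - 1))
    e_mid = np.array([np.cos(azim), np.sin(azim), 0.0])
    e_side = np.array([-np.sin(azim), np.cos(azim), 0.0])
    return attach, e_mid, e_side


def leaf_surface(spec: PlantSpec, leaf_idx: int, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Evaluate the parametric leaf surface S(u, v).

    ``u`` in [0, 1] runs base-to-tip along the midrib; ``v`` in [-1, 1] runs
    across the blade.  The midrib rises with a template-specific slope and
    droops quadratically with ``curvature``; the blade has a shallow
    cross-sectional arch so it is not a flat sheet.
    """
    shape, aspect, droop, slope = SPECIES_TEMPLATES[spec.species_template]
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    attach, e_mid, e_side = _leaf_frame(spec, leaf_idx)
    L = spec.leaf_scale
    e_up = np.array([0.0, 0.0, 1.0])
    w = _width_profile(shape, u)
    mid = (
        attach[None, :]
        + np.outer(L * u, e_mid)
        + np.outer(L * (slope * u - droop * spec.curvature * u**2), e_up)
    )
    blade = np.outer(v * 0.35 * aspect * L * w, e_side)
    arch = np.outer(0.12 * L * w * (1.0 - v**2), e_up)
    return mid + blade + arch


def _stem_centerline(spec: PlantSpec, s: np.ndarray) -> np.ndarray:
    """Bent-cylinder centerline; ``s`` in [0, 1] is height fraction."""
    bend = 0.06 * spec.curvature * spec.stem_height
    return np.stack(
        [bend * s**2, np.zeros_like(s), spec.stem_height * s], axis=1
    )


def generate_plant(spec: PlantSpec, return_params: bool = False) -> PointCloud:
    """Sample a labeled plant point cloud; deterministic for a fixed seed.

    Point budget: ~30% of ``points_total`` on the stem, the rest split
    evenly across leaves with any remainder going to the stem.  With
    ``return_params=True`` the per-leaf (u, v) parameter draws are also
    returned, which lets tests measure exact surface residuals.
    """
    rng = np.random.default_rng(spec.seed)
    n_stem = int(0.30 * spec.points_total)
    per_leaf = (spec.points_total - n_stem) // spec.n_leaves
    n_stem = spec.points_total - per_leaf * spec.n_leaves  # remainder -> stem

    pts_parts: list[np.ndarray] = []
    lbl_parts: list[np.ndarray] = []
    params: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    s = rng.uniform(0.0, 1.0, n_stem)
    theta = rng.uniform(0.0, 2.0 * np.pi, n_stem)
    radius = 0.02 * spec.stem_height * (1.0 - 0.4 * s)
    center = _stem_centerline(spec, s)
    stem = center + np.stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.zeros(n_stem)], axis=1
    )
    pts_parts.append(stem)
    lbl_parts.append(np.zeros(n_stem, dtype=np.int64))

    for leaf in range(1, spec.n_leaves + 1):
        u = rng.uniform(0.04, 1.0, per_leaf)
        v = rng.uniform(-1.0, 1.0, per_leaf)
        pts_parts.append(leaf_surface(spec, leaf, u, v))
        lbl_parts.append(np.full(per_leaf, leaf, dtype=np.int64))
        params[leaf] = (u, v)

    pts = np.concatenate(pts_parts)
    if spec.noise_sd > 0:
        pts = pts + rng.normal(0.0, spec.noise_sd, pts.shape)
    cloud = PointCloud(pts, labels=np.concatenate(lbl_parts))
    if return_params:
        return cloud, params
    return cloud


@dataclass
class DatasetIndex:
    """Index of generated samples and their train/test/validation split.

    Each sample entry carries the species tag, the fully resolved
    :class:`PlantSpec` (so the cloud can be regenerated on demand), the
    split tag, and the cloud path when the dataset was written to disk.
    """

    samples: list[dict] = field(default_factory=list)
    split_ratio: tuple[float, float, float] = (0.7, 0.2, 0.1)

    def split(self, tag: str) -> list[dict]:
        return [s for s in self.samples if s["split"] == tag]

    def split_sizes(self) -> dict[str, int]:
        return {tag: len(self.split(tag)) for tag in ("train", "test", "val")}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "split_ratio": list(self.split_ratio),
            "samples": [
                {**s, "spec": vars(s["spec"]) if isinstance(s["spec"], PlantSpec) else s["spec"]}
                for s in self.samples
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DatasetIndex":
        payload = json.loads(Path(path).read_text())
        samples = []
        for s in payload["samples"]:
            s = dict(s)
            s["spec"] = PlantSpec(**s["spec"])
            samples.append(s)
        return cls(samples=samples, split_ratio=tuple(payload["split_ratio"]))


def generate_dataset(
    counts: dict[str, int],
    split_ratio: Sequence[float] = (0.7, 0.2, 0.1),
    seed: int = 0,
    out_dir: Optional[str | Path] = None,
    base_spec: Optional[PlantSpec] = None,
) -> DatasetIndex:
    """Build a mixed-species dataset index with a seeded 7:2:1-style split.

    ``counts`` maps species template -> number of samples.  Samples from all
    species are shuffled jointly before splitting, so later mini-batches mix
    species.  Split sizes are floor-based on the shuffled list with the
    remainder assigned to training.  With ``out_dir`` set, clouds are written
    as NPY plus a JSON index; otherwise the index is virtual and clouds are
    regenerated on demand from their specs.
    """
    ratio = np.asarray(split_ratio, dtype=np.float64)
    if np.any(ratio < 0) or ratio.sum() <= 0:
        raise ValueError("split_ratio entries must be nonnegative with a positive sum")
    if not np.isclose(ratio.sum(), 1.0):
        import warnings

        warnings.warn("split_ratio does not sum to 1; normalizing", stacklevel=2)
        ratio = ratio / ratio.sum()

    rng = np.random.default_rng(seed)
    base = base_spec or PlantSpec()
    entries = []
    # stratified split: floor-based per species with remainders to training,
    # so every split keeps the global species proportions
    for species in sorted(counts):
        n = counts[species]
        if n < 1:
            raise ValueError(f"count for {species!r} must be >= 1")
        species_entries = []
        for _ in range(n):
            spec = replace(
                base,
                species_template=species,
                n_leaves=int(rng.integers(3, 9)),
                stem_height=float(base.stem_height * rng.uniform(0.8, 1.2)),
                leaf_scale=float(base.leaf_scale * rng.uniform(0.8, 1.2)),
                curvature=float(np.clip(base.curvature * rng.uniform(0.6, 1.4), 0.0, 1.5)),
                seed=int(rng.integers(2**31)),
            )
            species_entries.append({"species": species, "spec": spec})
        n_test = int(np.floor(ratio[1] * n))
        n_val = int(np.floor(ratio[2] * n))
        n_train = n - n_test - n_val
        tags = ["train"] * n_train + ["test"] * n_test + ["val"] * n_val
        for entry, tag in zip(species_entries, tags):
            entry["split"] = tag
            entry["path"] = None
        entries.extend(species_entries)
    # joint shuffle so later mini-batches mix species
    order = rng.permutation(len(entries))
    entries = [entries[i] for i in order]

    index = DatasetIndex(samples=entries, split_ratio=tuple(ratio))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, entry in enumerate(index.samples):
            path = out_dir / f"plant_{i:05d}.npy"
            save_cloud(generate_plant(entry["spec"]), path)
            entry["path"] = str(path)
        index.to_json(out_dir / "index.json")
    return index


def load_sample(entry: dict) -> PointCloud:
    """Materialize one index entry (from disk if written, else regenerated)."""
    if entry.get("path"):
        from .io import load_cloud

        return load_cloud(entry["path"])
    return generate_plant(entry["spec"])
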