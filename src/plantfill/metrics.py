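"""Completion-quality metrics and the EMA loss smoother.

All four metrics operate on raw coordinate sets (the training pipeline
feeds them normalized [-1, 1] coordinates, so reported values are in
normalized units):

* ``chamfer`` -- symmetric mean of *squared* nearest-neighbor distances,
* ``ucd``     -- one-directional mean nearest-neighbor distance,
* ``hausdorff`` -- max over both directions of the largest nearest-neighbor
  distance,
* ``f1_score`` -- harmonic mean of precision/recall under a matching
  threshold tau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "MetricReport",
    "chamfer",
    "ucd",
    "hausdorff",
    "f1_score",
    "metric_report",
    "ema_smooth",
    "DEFAULT_TAU",
]

DEFAULT_TAU = 0.03  # F1 matching threshold in normalized coordinates


@dataclass
class MetricReport:
    """dCD / dUCD / dHD / F1(tau) for one predicted-vs-reference pair."""

    d_cd: float
    d_ucd: float
    d_hd: float
    f1: float
    precision: float
    recall: float
    tau: float

    def as_dict(self) -> dict:
        return {
            "dCD": self.d_cd,
            "dUCD": self.d_ucd,
            "dHD": self.d_hd,
            "F1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
            "tau": self.tau,
        }


def _as_set(a) -> np.ndarray:
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    if a.size == 0:
        raise ValueError("metric requires a non-empty point set")
    return a


def _nn_dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each point of a to its nearest neighbor in b."""
    d, _ = cKDTree(b).query(a, k=1)
    return d


def chamfer(a, b) -> float:
    """Symmetric Chamfer distance: sum of both mean-of-min squared distances."""
    a, b = _as_set(a), _as_set(b)
    return float((_nn_dist(a, b) ** 2).mean() + (_nn_dist(b, a) ** 2).mean())


def ucd(a, b) -> float:
    """Unidirectional Chamfer distance: mean nearest distance from a to b."""
    a, b = _as_set(a), _as_set(b)
    return float(_nn_dist(a, b).mean())


def hausdorff(a, b) -> float:
    """Symmetric Hausdorff distance (max of both directed sup-inf distances)."""
    a, b = _as_set(a), _as_set(b)
    return float(max(_nn_dist(a, b).max(), _nn_dist(b, a).max()))


def f1_score(pred, gt, tau: float = DEFAULT_TAU) -> tuple[float, float, float]:
    """(precision, recall, f1) under matching threshold tau.

    Precision: fraction of predicted points whose nearest ground-truth
    neighbor is within tau.  Recall: fraction of ground-truth points whose
    nearest predicted neighbor is within tau.  F1 is 0 when P + R = 0.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    pred, gt = _as_set(pred), _as_set(gt)
    precision = float((_nn_dist(pred, gt) < tau).mean())
    recall = float((_nn_dist(gt, pred) < tau).mean())
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def metric_report(pred, gt, tau: float = DEFAULT_TAU) -> MetricReport:
    precision, recall, f1 = f1_score(pred, gt, tau)
    return MetricReport(
        d_cd=chamfer(pred, gt),
        d_ucd=ucd(pred, gt),
        d_hd=hausdorff(pred, gt),
        f1=f1,
        precision=precision,
        recall=recall,
        tau=tau,
    )


def ema_smooth(series, alpha: float = 0.2) -> np.ndarray:
    """Exponential moving average EMA_t = alpha * EMA_{t-1} + (1 - alpha) * x_t.

    EMA_0 = x_0.  alpha defaults to 0.2, which suppresses the adversarial
    high-frequency oscillations while preserving the convergence trend.
    """
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    series = np.asarray(series, dtype=np.float64)
    if series.size == 0:
        raise ValueError("series must be non-empty")
    out = np.empty_like(series)
    out[0] = series[0]
    for t in range(1, len(series)):
        out[t] = alpha * out[t - 1] + (1 - alpha) * series[t]
    return out
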