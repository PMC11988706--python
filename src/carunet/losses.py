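"""Segmentation losses and evaluation metrics.

The loss family is the compound

    L_total = alpha * L_Dice + beta * L_BCE + gamma * L_Focal

with non-negative weights (the ablation grid uses 0/1 weights, i.e. equal
contribution for every enabled term).  The losses operate on soft
probability maps during training and are differentiable through the
package's autodiff tensors; plain numpy arrays are accepted too and yield a
float.

Metrics are the six standard ones — accuracy, Dice, IoU, recall, precision,
specificity — computed from the per-image confusion matrix after
thresholding the probability map at 0.5.  Per image, IoU and Dice satisfy
IoU = Dice / (2 - Dice).  Reports aggregate per-image means by default; a
pooled mode accumulates one global confusion matrix instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import autograd as ag
from .autograd import Tensor
from .errors import ConfigurationError, ShapeError

__all__ = [
    "LossConfig", "MetricReport", "dice_loss", "bce_loss", "focal_loss",
    "compound_loss", "segmentation_metrics", "METRIC_COLUMNS",
]

METRIC_COLUMNS = ("accuracy", "dice", "iou", "recall", "precision", "specificity")


@dataclass(frozen=True)
class LossConfig:
    """Weights and settings of the compound loss.

    ``alpha``, ``beta``, ``gamma`` weight the Dice, binary cross-entropy and
    focal terms.  ``focal_gamma``/``focal_alpha`` are the focal modulation
    exponent and class weight (named to avoid colliding with the compound
    weights).
    """

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    dice_epsilon: float = 1e-6
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    clip: float = 1e-7

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ConfigurationError("alpha/beta/gamma: weights must be non-negative")
        if self.alpha == self.beta == self.gamma == 0:
            raise ConfigurationError("alpha/beta/gamma: at least one weight must be > 0")
        if self.dice_epsilon <= 0:
            raise ConfigurationError(f"dice_epsilon: must be > 0, got {self.dice_epsilon}")
        if self.focal_gamma < 0:
            raise ConfigurationError(f"focal_gamma: must be >= 0, got {self.focal_gamma}")
        if not 0 < self.clip < 0.5:
            raise ConfigurationError(f"clip: must be in (0, 0.5), got {self.clip}")

    @classmethod
    def named(cls, name: str) -> "LossConfig":
        """A loss combination by name, e.g. ``"dice"`` or ``"bce+dice"``."""
        parts = set(name.lower().replace(" ", "").split("+"))
        unknown = parts - {"dice", "bce", "focal"}
        if unknown:
            raise ConfigurationError(f"loss: unknown components {sorted(unknown)}")
        return cls(alpha=float("dice" in parts), beta=float("bce" in parts),
                   gamma=float("focal" in parts))


def _pair(p, g):
    tp = p if isinstance(p, Tensor) else Tensor(np.asarray(p, dtype=np.float64))
    gd = np.asarray(g.data if isinstance(g, Tensor) else g, dtype=tp.data.dtype)
    if tp.data.shape != gd.shape:
        raise ShapeError(f"prediction {tp.data.shape} and mask {gd.shape} differ")
    return tp, gd, isinstance(p, Tensor)


def _ret(t: Tensor, was_tensor: bool):
    return t if was_tensor else float(t.data)


def dice_loss(p, g, eps: float = 1e-6):
    """Soft Dice loss ``1 - (2*sum(PG)+eps) / (sum(P)+sum(G)+eps)``."""
    tp, gd, wt = _pair(p, g)
    inter = ag.reduce_sum(ag.mul(tp, gd))
    denom = ag.add(ag.reduce_sum(tp), float(gd.sum()))
    out = ag.sub(1.0, ag.div(ag.add(ag.mul(inter, 2.0), eps), ag.add(denom, eps)))
    return _ret(out, wt)


def bce_loss(p, g, clip: float = 1e-7):
    """Pixel-mean binary cross-entropy with probability clipping."""
    tp, gd, wt = _pair(p, g)
    pc = ag.clip(tp, clip, 1.0 - clip)
    ll = ag.add(ag.mul(ag.log(pc), gd),
                ag.mul(ag.log(ag.sub(1.0, pc)), 1.0 - gd))
    out = ag.neg(ag.reduce_mean(ll))
    return _ret(out, wt)


def focal_loss(p, g, focal_gamma: float = 2.0, focal_alpha: float = 0.25,
               clip: float = 1e-7):
    """Pixel-mean focal loss ``-alpha_f (1-p_t)^gamma_f log(p_t)``.

    ``p_t`` is the predicted probability of the true class; with
    ``focal_gamma=0, focal_alpha=1`` this reduces exactly to the BCE loss.
    """
    if focal_gamma < 0:
        raise ConfigurationError(f"focal_gamma: must be >= 0, got {focal_gamma}")
    tp, gd, wt = _pair(p, g)
    pt = ag.add(ag.mul(tp, gd), ag.mul(ag.sub(1.0, tp), 1.0 - gd))
    pt = ag.clip(pt, clip, 1.0 - clip)
    mod = ag.power(ag.sub(1.0, pt), focal_gamma) if focal_gamma else 1.0
    out = ag.neg(ag.reduce_mean(ag.mul(ag.mul(mod, ag.log(pt)), focal_alpha)))
    return _ret(out, wt)


def compound_loss(p, g, cfg: LossConfig):
    """Weighted sum of the enabled loss components."""
    if not isinstance(cfg, LossConfig):
        raise ConfigurationError("cfg: expected a LossConfig")
    tp, _, wt = _pair(p, g)
    total = None
    if cfg.alpha:
        total = ag.mul(dice_loss(tp, g, cfg.dice_epsilon), cfg.alpha)
    if cfg.beta:
        term = ag.mul(bce_loss(tp, g, cfg.clip), cfg.beta)
        total = term if total is None else ag.add(total, term)
    if cfg.gamma:
        term = ag.mul(focal_loss(tp, g, cfg.focal_gamma, cfg.focal_alpha, cfg.clip),
                      cfg.gamma)
        total = term if total is None else ag.add(total, term)
    return _ret(total, wt)


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------

def _safe_ratio(num: float, den: float, gt_empty_agrees: bool) -> float:
    if den > 0:
        return num / den
    return 1.0 if gt_empty_agrees else 0.0


def _metrics_from_counts(tp: float, fp: float, fn: float, tn: float) -> dict:
    n = tp + fp + fn + tn
    return {
        "accuracy": (tp + tn) / n if n else 1.0,
        "dice": _safe_ratio(2 * tp, 2 * tp + fp + fn, fp == fn == 0),
        "iou": _safe_ratio(tp, tp + fp + fn, fp == fn == 0),
        "recall": _safe_ratio(tp, tp + fn, fp == 0),
        "precision": _safe_ratio(tp, tp + fp, fn == 0),
        "specificity": _safe_ratio(tn, tn + fp, fn == 0),
    }


@dataclass(frozen=True)
class MetricReport:
    """Per-image metric table plus its aggregate.

    ``aggregation`` records whether the summary row is the per-image mean
    (``"image_mean"``) or derives from one pooled confusion matrix
    (``"pooled"``).
    """

    per_image: pd.DataFrame
    aggregation: str = "image_mean"
    pooled_counts: tuple[float, float, float, float] | None = None

    @property
    def mean(self) -> pd.Series:
        if self.aggregation == "pooled":
            return pd.Series(_metrics_from_counts(*self.pooled_counts))
        return self.per_image[list(METRIC_COLUMNS)].mean()

    def as_percent(self) -> pd.Series:
        """Aggregate metrics as percentages rounded to two decimals."""
        return (self.mean * 100).round(2)

    def to_csv(self, path) -> None:
        df = (self.per_image.set_index("id")[list(METRIC_COLUMNS)] * 100).round(2)
        df.loc["mean"] = self.as_percent()
        df.to_csv(path)

    def to_json(self, path) -> None:
        payload = {
            "aggregation": self.aggregation,
            "mean": {k: round(float(v), 2) for k, v in self.as_percent().items()},
            "per_image": {
                row["id"]: {k: round(float(row[k]) * 100, 2) for k in METRIC_COLUMNS}
                for _, row in self.per_image.iterrows()
            },
        }
        import json
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def segmentation_metrics(p, g, threshold: float = 0.5, ids=None,
                         pooled: bool = False) -> MetricReport:
    """Confusion-matrix metrics of a probability map against a binary mask.

    Accepts a single image (H, W) or a stack (N, H, W); trailing singleton
    channel axes are squeezed.  ``pooled=True`` aggregates one global
    confusion matrix instead of averaging per-image metrics.
    """
    pa = np.asarray(p.data if isinstance(p, Tensor) else p, dtype=np.float64)
    ga = np.asarray(g.data if isinstance(g, Tensor) else g, dtype=np.float64)
    if pa.ndim >= 3 and pa.shape[-1] == 1:
        pa, ga = pa[..., 0], ga[..., 0]
    if pa.shape != ga.shape:
        raise ShapeError(f"prediction {pa.shape} and mask {ga.shape} differ")
    if pa.ndim == 2:
        pa, ga = pa[None], ga[None]
    if ids is None:
        ids = [f"img_{i:04d}" for i in range(pa.shape[0])]
    rows = []
    totals = np.zeros(4)
    for i in range(pa.shape[0]):
        pred = pa[i] >= threshold
        gt = ga[i] >= 0.5
        tp = float(np.sum(pred & gt))
        fp = float(np.sum(pred & ~gt))
        fn = float(np.sum(~pred & gt))
        tn = float(np.sum(~pred & ~gt))
        totals += (tp, fp, fn, tn)
        rows.append({"id": ids[i], **_metrics_from_counts(tp, fp, fn, tn)})
    return MetricReport(per_image=pd.DataFrame(rows),
                        aggregation="pooled" if pooled else "image_mean",
                        pooled_counts=tuple(totals))
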