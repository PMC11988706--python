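"""Training harness: seeded trainer, k-fold cross-validation, ablation grid
and the Mann-Whitney U comparison.

The training regimen follows the published recipe: Adam with initial
learning rate 1e-3, batch size 32, 50 epochs, Dice loss, and a
reduce-on-plateau schedule that multiplies the learning rate by 0.1 when the
validation loss has not improved for 5 epochs; the checkpoint with minimal
validation loss is kept.  Every run is a pure function of (config, seed,
data): batch order, weight initialization and augmentation jitter all derive
from the seed.

Leakage discipline: sources are split before augmentation and only training
sources are augmented, so derived images never cross their source's split;
cross-validation folds are disjoint by construction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .autograd import Adam, Module, RMSprop, SGD
from .data import ImagePair
from .errors import ConfigurationError, DivergenceError
from .losses import LossConfig, MetricReport, compound_loss, segmentation_metrics
from .models import ModelConfig, build_model

__all__ = [
    "TrainConfig", "FoldResult", "train", "evaluate", "kfold_cv",
    "mann_whitney_u", "run_ablation_grid", "LOSS_GRID", "OPTIMIZERS",
    "VARIANTS",
]

OPTIMIZERS = ("adam", "rmsprop", "sgd")

#: The seven 0/1 loss-weight combinations of the loss-function ablation.
LOSS_GRID = ("bce", "dice", "focal", "bce+dice", "bce+focal", "dice+focal",
             "bce+dice+focal")

#: Ablation variants I-V: architecture plus activation function.
VARIANTS: dict[str, tuple[str, str]] = {
    "unet": ("unet", "relu"),
    "res_unet": ("res_unet", "leaky_relu"),
    "res_unet_attn": ("res_unet_attn", "leaky_relu"),
    "proposed_relu": ("proposed", "relu"),
    "proposed": ("proposed", "leaky_relu"),
}


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (defaults follow the published regimen)."""

    optimizer: str = "adam"
    initial_lr: float = 0.001
    batch_size: int = 32
    epochs: int = 50
    lr_reduce_factor: float = 0.1
    lr_patience: int = 5
    loss: LossConfig = field(default_factory=lambda: LossConfig(1.0, 0.0, 0.0))
    seed: int = 0

    def __post_init__(self):
        if self.optimizer not in OPTIMIZERS:
            raise ConfigurationError(
                f"optimizer: unknown {self.optimizer!r}, expected one of {OPTIMIZERS}")
        if self.batch_size < 1:
            raise ConfigurationError(f"batch_size: must be >= 1, got {self.batch_size}")
        if not 0 < self.lr_reduce_factor < 1:
            raise ConfigurationError(
                f"lr_reduce_factor: must be in (0, 1), got {self.lr_reduce_factor}")
        if self.epochs < 1:
            raise ConfigurationError(f"epochs: must be >= 1, got {self.epochs}")
        if self.initial_lr <= 0:
            raise ConfigurationError(f"initial_lr: must be > 0, got {self.initial_lr}")


@dataclass(frozen=True)
class FoldResult:
    """Evaluation of one cross-validation fold."""

    fold: int
    report: MetricReport
    per_image_dice: tuple[float, ...]


def _make_optimizer(model: Module, cfg: TrainConfig):
    params = model.parameters()
    if cfg.optimizer == "adam":
        return Adam(params, lr=cfg.initial_lr)
    if cfg.optimizer == "rmsprop":
        return RMSprop(params, lr=cfg.initial_lr)
    return SGD(params, lr=cfg.initial_lr, momentum=0.9)


def _stack(pairs: list[ImagePair]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([np.asarray(p.image, dtype=np.float32) for p in pairs])[..., None]
    y = np.stack([np.asarray(p.mask, dtype=np.float32) for p in pairs])[..., None]
    return x, y


def _epoch_loss(model: Module, x: np.ndarray, y: np.ndarray, loss_cfg: LossConfig,
                batch_size: int) -> float:
    """Mean loss over a dataset in eval mode (no gradients)."""
    model.eval()
    total, count = 0.0, 0
    for i in range(0, len(x), batch_size):
        xb, yb = x[i:i + batch_size], y[i:i + batch_size]
        pred = model(xb)
        total += float(compound_loss(pred, yb, loss_cfg).data) * len(xb)
        count += len(xb)
    return total / count


def train(model: Module, train_set: list[ImagePair], val_set: list[ImagePair],
          cfg: TrainConfig, log=None):
    """Train ``model``; returns ``(best_state, history)``.

    ``best_state`` is the ``state_dict`` snapshot at the epoch with minimal
    validation loss; ``history`` is a DataFrame with columns epoch,
    train_loss, val_loss, lr.  Raises :class:`DivergenceError` if the loss
    becomes non-finite.
    """
    if not train_set or not val_set:
        raise ConfigurationError("train/val sets must be non-empty")
    rng = np.random.default_rng([cfg.seed, 0xA])
    xt, yt = _stack(train_set)
    xv, yv = _stack(val_set)
    opt = _make_optimizer(model, cfg)
    history = []
    best_val = math.inf
    best_state = None
    since_improve = 0
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(xt))
        running, seen = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            pred = model(xt[idx])
            loss = compound_loss(pred, yt[idx], cfg.loss)
            value = float(loss.data)
            if not math.isfinite(value):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            model.zero_grad()
            loss.backward(np.ones_like(loss.data))
            opt.step()
            running += value * len(idx)
            seen += len(idx)
        train_loss = running / seen
        val_loss = _epoch_loss(model, xv, yv, cfg.loss, cfg.batch_size)
        if not math.isfinite(val_loss):
            raise DivergenceError(f"non-finite validation loss at epoch {epoch}")
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss, "lr": opt.lr})
        if log:
            print(f"epoch {epoch:3d}  train {train_loss:.4f}  val {val_loss:.4f}  "
                  f"lr {opt.lr:.2e}", file=log)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.lr_patience:
                opt.lr *= cfg.lr_reduce_factor
                since_improve = 0
    return best_state, pd.DataFrame(history)


def evaluate(model: Module, test_set: list[ImagePair], threshold: float = 0.5,
             batch_size: int = 8, pooled: bool = False) -> MetricReport:
    """Deterministic evaluation: forward in eval mode, binarize at the
    threshold, per-image metrics plus their mean."""
    if not test_set:
        raise ConfigurationError("test set must be non-empty")
    model.eval()
    x, y = _stack(test_set)
    preds = []
    for i in range(0, len(x), batch_size):
        preds.append(model(x[i:i + batch_size]).data)
    p = np.concatenate(preds, axis=0)
    return segmentation_metrics(p, y, threshold=threshold,
                                ids=[q.id for q in test_set], pooled=pooled)


def predict(model: Module, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Probability maps for a stack of images (N, H, W) or (N, H, W, 1)."""
    model.eval()
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 3:
        x = x[..., None]
    out = [model(x[i:i + batch_size]).data[..., 0] for i in range(0, len(x), batch_size)]
    return np.concatenate(out, axis=0)


# --------------------------------------------------------------------------
# Cross-validation
# --------------------------------------------------------------------------

def kfold_cv(dataset: list[ImagePair], model_config: ModelConfig,
             cfg: TrainConfig, k: int = 5, log=None):
    """k-fold cross-validation: seeded partition into near-equal folds, each
    fold held out once; returns ``(fold_results, summary)`` where the
    summary has a mean and a sample-standard-deviation row per metric."""
    if k < 2:
        raise ConfigurationError(f"k: need at least 2 folds, got {k}")
    if k > len(dataset):
        raise ConfigurationError(
            f"k: {k} folds exceed dataset size {len(dataset)}")
    rng = np.random.default_rng([cfg.seed, 0xF])
    order = rng.permutation(len(dataset))
    folds = [sorted(order[i::k].tolist()) for i in range(k)]
    results: list[FoldResult] = []
    for fold_idx, test_idx in enumerate(folds):
        test_ids = set(test_idx)
        train_pairs = [dataset[i] for i in range(len(dataset)) if i not in test_ids]
        test_pairs = [dataset[i] for i in test_idx]
        model = build_model(model_config, seed=cfg.seed + fold_idx)
        best_state, _ = train(model, train_pairs, test_pairs,
                              replace(cfg, seed=cfg.seed + fold_idx), log=log)
        model.load_state_dict(best_state)
        report = evaluate(model, test_pairs)
        results.append(FoldResult(
            fold=fold_idx, report=report,
            per_image_dice=tuple(report.per_image["dice"].tolist())))
    table = pd.DataFrame([r.report.mean for r in results])
    summary = pd.DataFrame({"mean": table.mean(), "std": table.std(ddof=1)}).T
    return results, summary


# --------------------------------------------------------------------------
# Mann-Whitney U
# --------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    ``U`` counts pairs ``a_i > b_j`` plus half the ties.  For ``n*m <= 64``
    the p-value is exact: all C(n+m, n) assignments of the pooled sample are
    enumerated and the p-value is the fraction with ``|U - nm/2|`` at least
    as large as observed.  Larger samples use the normal approximation with
    tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise ConfigurationError("samples must be non-empty")
    n, m = a.size, b.size
    u_obs = _u_statistic(a, b)
    centre = n * m / 2.0
    if n * m <= 64:
        pooled = np.concatenate([a, b])
        dev_obs = abs(u_obs - centre)
        hits = total = 0
        for pick in itertools.combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(pick)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - centre) >= dev_obs - 1e-12:
                hits += 1
        return u_obs, hits / total
    # normal approximation with tie correction
    pooled = np.concatenate([a, b])
    nm = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum())) / (nm * (nm - 1))
    sigma2 = n * m / 12.0 * ((nm + 1) - tie_term)
    if sigma2 <= 0:
        return u_obs, 1.0
    z = (abs(u_obs - centre) - 0.5) / math.sqrt(sigma2)
    p = min(1.0, max(2.0 * (1.0 - norm.cdf(max(z, 0.0))), np.nextafter(0, 1)))
    return u_obs, p


# --------------------------------------------------------------------------
# Ablation grid
# --------------------------------------------------------------------------

def run_ablation_grid(train_set: list[ImagePair], val_set: list[ImagePair],
                      test_set: list[ImagePair], variants: list[str],
                      losses: list[str], optimizers: list[str],
                      cfg: TrainConfig, model_config_fn, reference: str | None = None,
                      log=None):
    """Train/evaluate every (variant, loss, optimizer) cell from scratch.

    ``model_config_fn(arch, activation)`` supplies the architecture config
    for a variant.  Returns ``(results, pvalues)``: a metric table with one
    row per cell (percentages), and a Mann-Whitney p-value matrix comparing
    each non-reference variant's per-image accuracy/Dice/IoU against the
    reference variant (default: the last variant listed).
    """
    for v in variants:
        if v not in VARIANTS:
            raise ConfigurationError(f"variant: unknown {v!r}, expected one of "
                                     f"{sorted(VARIANTS)}")
    for o in optimizers:
        if o not in OPTIMIZERS:
            raise ConfigurationError(f"optimizer: unknown {o!r}")
    loss_cfgs = {name: LossConfig.named(name) for name in losses}
    reference = reference if reference is not None else variants[-1]

    rows = []
    per_image: dict[tuple[str, str, str], pd.DataFrame] = {}
    for idx, (v, lname, opt) in enumerate(
            itertools.product(variants, losses, optimizers)):
        arch, activation = VARIANTS[v]
        mcfg = model_config_fn(arch, activation)
        cell_seed = (cfg.seed * 1009 + idx) % (2**31)
        cell_cfg = replace(cfg, optimizer=opt, loss=loss_cfgs[lname], seed=cell_seed)
        model = build_model(mcfg, seed=cell_seed)
        best_state, _ = train(model, train_set, val_set, cell_cfg, log=log)
        model.load_state_dict(best_state)
        report = evaluate(model, test_set)
        per_image[(v, lname, opt)] = report.per_image
        rows.append({"variant": v, "loss": lname, "optimizer": opt,
                     **report.as_percent().to_dict()})
    results = pd.DataFrame(rows)

    # p-value matrix against the reference variant (first grid cell of each)
    pvals = []
    if reference in variants:
        ref_key = next(k for k in per_image if k[0] == reference)
        ref = per_image[ref_key]
        for v in variants:
            if v == reference:
                continue
            key = next(k for k in per_image if k[0] == v)
            cur = per_image[key]
            row = {"variant": v}
            for metric in ("accuracy", "dice", "iou"):
                _, p = mann_whitney_u(ref[metric].to_numpy(), cur[metric].to_numpy())
                row[f"p_{metric}"] = p
            pvals.append(row)
    return results, pd.DataFrame(pvals)
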