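"""Training protocol: stratified splits, class-weighted loss, AdamW + cosine.

The protocol mirrors common practice for imbalanced histopathology
classification: a stratified 7:1:2 train/val/test split computed per class,
class-balanced batch sampling plus inverse-frequency class weights in the
cross-entropy loss, AdamW with a cosine-annealed learning rate and global
gradient-norm clipping, and checkpoint selection by validation F1.

`shortcut_experiment` is the behavioural probe for stain-bias suppression: it
trains the full model and an SDA-ablated twin on identical synthetic data in
which stain domain and label are confounded during training but independent
at test time, so the test-accuracy gap measures reliance on the colour
shortcut.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

from .metrics import evaluate
from .model import ModelConfig, OsccClassifier
from .nn import AdamW, SGD, Tensor, clip_grad_norm, cosine_lr, cross_entropy

__all__ = [
    "TrainConfig",
    "TrainResult",
    "stratified_split",
    "class_weights",
    "prepare_images",
    "train",
    "shortcut_experiment",
    "shortcut_benchmark_config",
]

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults follow the reference configuration."""

    input_side: int = 224
    batch_size: int = 32
    epochs: int = 200
    optimizer: str = "adamw"
    lr: float = 1e-4
    weight_decay: float = 1e-2
    schedule: str = "cosine"
    clip_norm: float = 1.0
    seed: int = 42
    mixed_precision: bool = False  # accepted for config compatibility; fp64 math
    selection_metric: str = "f1"
    normalize_mean: tuple[float, float, float] = (0.5, 0.5, 0.5)
    normalize_std: tuple[float, float, float] = (0.5, 0.5, 0.5)

    def __post_init__(self):
        for name in ("input_side", "batch_size", "epochs", "lr", "weight_decay",
                     "clip_norm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @classmethod
    def from_file(cls, path: str) -> "TrainConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("normalize_mean", "normalize_std"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class TrainResult:
    model: OsccClassifier
    best_epoch: int
    best_state: dict
    history: pd.DataFrame


def stratified_split(labels, ratios=(0.7, 0.1, 0.2), seed: int = 42) -> np.ndarray:
    """Per-class 7:1:2-style split; returns an array of 'train'/'val'/'test' tags.

    Within each class: |train| = round(r0*n), |val| = round(r1*n), and the
    remainder goes to test (half-up rounding).  Shuffling within each class is
    driven by `seed`, so the assignment is deterministic.
    """
    labels = np.asarray(labels)
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    rng = np.random.default_rng(seed)
    tags = np.empty(len(labels), dtype=object)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 3:
            raise ValueError(f"class {cls!r} has fewer than 3 samples")
        rng.shuffle(idx)
        n = len(idx)
        n_train = int(np.floor(ratios[0] * n + 0.5))
        n_val = int(np.floor(ratios[1] * n + 0.5))
        tags[idx[:n_train]] = "train"
        tags[idx[n_train : n_train + n_val]] = "val"
        tags[idx[n_train + n_val :]] = "test"
    return tags


def class_weights(train_labels) -> np.ndarray:
    """Balanced inverse-frequency weights: w_c = n_train / (2 * n_c)."""
    labels = np.asarray(train_labels)
    n = len(labels)
    counts = np.array([np.sum(labels == 0), np.sum(labels == 1)], dtype=float)
    if (counts == 0).any():
        raise ValueError("both classes must be present in the training set")
    return n / (2.0 * counts)


def prepare_images(images: np.ndarray, config: TrainConfig) -> np.ndarray:
    """Channel standardisation of an image stack in [0, 1]."""
    mean = np.asarray(config.normalize_mean)
    std = np.asarray(config.normalize_std)
    return (np.asarray(images, dtype=np.float64) - mean) / std


def _balanced_batches(labels: np.ndarray, batch_size: int, n_batches: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Class-balanced batch sampling (the stratified sampling strategy):
    each batch draws half its slots from each class, with replacement for the
    minority class."""
    pools = [np.flatnonzero(labels == c) for c in (0, 1)]
    half = batch_size // 2
    batches = []
    for _ in range(n_batches):
        parts = [rng.choice(pool, size=half, replace=len(pool) < half)
                 for pool in pools]
        batch = np.concatenate(parts)
        rng.shuffle(batch)
        batches.append(batch)
    return batches


def _make_optimizer(config: TrainConfig, params):
    name = config.optimizer.lower()
    if name == "adamw":
        return AdamW(params, lr=config.lr, weight_decay=config.weight_decay)
    if name == "sgd":
        return SGD(params, lr=config.lr, momentum=0.9,
                   weight_decay=config.weight_decay)
    raise ValueError(f"unknown optimizer {config.optimizer!r}")


def train(model: OsccClassifier, images: np.ndarray, labels: np.ndarray,
          splits: np.ndarray, config: TrainConfig) -> TrainResult:
    """Train `model`; returns the checkpoint maximising validation F1.

    `images` must already be normalised (see :func:`prepare_images`).
    Per-epoch train/val losses and validation metrics are returned as the
    history frame; on completion the model carries the best checkpoint.
    """
    labels = np.asarray(labels, dtype=int)
    splits = np.asarray(splits)
    train_idx = np.flatnonzero(splits == "train")
    val_idx = np.flatnonzero(splits == "val")
    if len(val_idx) == 0:
        raise ValueError("validation split is empty")
    weights = class_weights(labels[train_idx])
    params = model.parameters()
    opt = _make_optimizer(config, params)
    rng = np.random.default_rng(config.seed)
    n_batches = max(1, int(np.ceil(len(train_idx) / config.batch_size)))

    history_rows = []
    best = (-np.inf, -1, None)  # (selection metric, epoch, state)
    for epoch in range(config.epochs):
        if config.schedule == "cosine":
            opt.lr = cosine_lr(config.lr, epoch, config.epochs)
        epoch_losses = []
        for batch in _balanced_batches(labels[train_idx], config.batch_size,
                                       n_batches, rng):
            idx = train_idx[batch]
            probs = model(Tensor(images[idx]))
            loss = cross_entropy(probs, labels[idx], weights)
            loss_val = float(loss.numpy())
            if not np.isfinite(loss_val):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss_val}"
                )
            model.zero_grad()
            loss.backward()
            clip_grad_norm(params, config.clip_norm)
            opt.step()
            epoch_losses.append(loss_val)

        val_scores = model.predict_proba(images[val_idx])[:, 1]
        val_loss = float(cross_entropy(
            Tensor(np.stack([1 - val_scores, val_scores], axis=1)),
            labels[val_idx], weights,
        ).numpy())
        report = evaluate(labels[val_idx], val_scores)
        sel = getattr(report, config.selection_metric)
        sel = -np.inf if sel is None else sel
        history_rows.append({
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": val_loss,
            "val_acc": report.acc,
            "val_f1": report.f1,
            "val_auc": report.auc,
        })
        if sel > best[0]:
            best = (sel, epoch, copy.deepcopy(model.state_dict()))
        logger.debug("epoch %d: train_loss=%.4f val_f1=%s", epoch,
                     history_rows[-1]["train_loss"], report.f1)

    if best[2] is not None:
        model.load_state_dict(best[2])
    return TrainResult(model=model, best_epoch=best[1], best_state=best[2],
                       history=pd.DataFrame(history_rows))


# ---------------------------------------------------------------------------
# Synthetic shortcut benchmark
# ---------------------------------------------------------------------------

def shortcut_benchmark_config() -> tuple[dict, TrainConfig, ModelConfig]:
    """Fixed study conditions for the stain-shortcut benchmark.

    ~400 images per run: 320 at 64x64 for train+val (split 87.5/12.5) and a
    fresh 80-image deconfounded test set; training confound rho = 0.9;
    desk-scale model (stride-8 mini backbone, 32 channels, head dim 32,
    window 4 on the 8x8 token grid); 12 epochs of AdamW at 1e-3.
    """
    from .synthetic import SyntheticDatasetSpec

    data = {
        "train_spec": SyntheticDatasetSpec(
            n_per_class=(160, 160), image_side=64, confound=0.9,
            split_ratios=(0.875, 0.125, 0.0),
        ),
        "test_n_per_class": (40, 40),
    }
    train_cfg = TrainConfig(input_side=64, batch_size=32, epochs=12, lr=1e-3)
    model_cfg = ModelConfig(backbone_channels=(16, 32, 32), head_dim=32,
                            head_depth=2, sda_window=4)
    return data, train_cfg, model_cfg


def shortcut_experiment(
    seeds,
    train_confound: float = 0.9,
    arms: tuple[str, ...] = ("full", "no_sda"),
    train_spec=None,
    train_config: TrainConfig | None = None,
    model_config: ModelConfig | None = None,
    test_n_per_class: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Train matched model pairs on stain-confounded data; test deconfounded.

    For each seed, one synthetic dataset is generated with label-domain
    confound `train_confound` and every arm is trained on *identical* images;
    the test set uses the same morphology but domain independent of label
    (rho = 0).  Returns one row per (seed, arm) with test metrics.
    """
    from .synthetic import generate_dataset, shifted_test_set

    data, default_train_cfg, default_model_cfg = shortcut_benchmark_config()
    spec = train_spec if train_spec is not None else data["train_spec"]
    spec = replace(spec, confound=train_confound)
    tcfg = train_config or default_train_cfg
    mcfg = model_config or default_model_cfg
    test_n = test_n_per_class or data["test_n_per_class"]

    rows = []
    for seed in seeds:
        seed = int(seed)
        seed_spec = replace(spec, seed=seed)
        images, manifest = generate_dataset(seed_spec)
        test_images, test_manifest = shifted_test_set(
            seed_spec, mode="decorrelate", n_per_class=test_n
        )
        x = prepare_images(images, tcfg)
        x_test = prepare_images(test_images, tcfg)
        y = manifest["label"].to_numpy()
        y_test = test_manifest["label"].to_numpy()
        splits = manifest["split"].to_numpy()
        for arm in arms:
            arm_cfg = replace(mcfg, use_sda=(arm != "no_sda"), seed=seed)
            arm_tcfg = replace(tcfg, seed=seed)
            model = OsccClassifier(arm_cfg)
            result = train(model, x, y, splits, arm_tcfg)
            scores = result.model.predict_proba(x_test)[:, 1]
            report = evaluate(y_test, scores)
            rows.append({
                "seed": seed,
                "arm": arm,
                "train_confound": train_confound,
                "best_epoch": result.best_epoch,
                "test_acc": report.acc,
                "test_f1": report.f1,
                "test_auc": report.auc,
            })
            logger.info("seed %d arm %s: test acc %.2f", seed, arm, report.acc)
    return pd.DataFrame(rows)
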