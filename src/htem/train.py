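"""Training and evaluation loops, plus the protocol drivers
(one-vs-rest imbalance, noise robustness, ablation grids).

Defaults mirror the reference protocol: Adam at learning rate 0.002,
batch size 32, 100 epochs, 224 x 224 inputs, cross-entropy on the
pre-softmax scores.  Model selection keeps the weights of the best
validation-accuracy epoch when a validation split exists.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from . import nn
from .datakit import (LabelledDataset, NoiseSpec, make_imbalanced_versions,
                      preprocess_batch)
from .metrics import (EvalReport, RankedScores, average_precision,
                      confusion_matrix, mean_ap)
from .model import HTEM, HTEMConfig, make_variant


@dataclass
class TrainConfig:
    learning_rate: float = 0.002
    batch_size: int = 32
    epochs: int = 100
    image_side: int = 224
    optimizer: str = "adam"                 # or "sgd"
    loss: str = "cross_entropy"
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("learning_rate > 0, batch_size >= 1, epochs >= 0 required")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.loss != "cross_entropy":
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class History:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    epoch_seconds: list[float] = field(default_factory=list)

    def to_csv(self) -> str:
        lines = ["epoch,train_loss,train_accuracy,val_loss,val_accuracy,seconds"]
        for i in range(len(self.train_loss)):
            vl = self.val_loss[i] if i < len(self.val_loss) else ""
            va = self.val_accuracy[i] if i < len(self.val_accuracy) else ""
            lines.append(f"{i},{self.train_loss[i]},{self.train_accuracy[i]},"
                         f"{vl},{va},{self.epoch_seconds[i]}")
        return "\n".join(lines)


def _forward_batched(model: HTEM, images: np.ndarray, batch_size: int) -> np.ndarray:
    """Score a stack of images without building gradient tape state."""
    outs = []
    for start in range(0, len(images), batch_size):
        outs.append(model.forward(images[start:start + batch_size]).data)
    return np.concatenate(outs, axis=0)


def train(model: HTEM, ds: LabelledDataset, cfg: TrainConfig,
          verbose: bool = False) -> tuple[HTEM, History]:
    """Mini-batch optimization of ``model`` on the dataset's train split.

    Batches are reshuffled each epoch with a seeded generator; when a
    ``val`` split exists the best-validation-accuracy weights are restored
    into the returned model at the end.
    """
    if model.cfg.image_size != cfg.image_side:
        raise ValueError(f"model expects {model.cfg.image_size}px input but "
                         f"training config says {cfg.image_side}px")
    train_ds = ds.subset("train")
    if len(train_ds) == 0:
        raise ValueError("dataset has no train split")
    val_ds = ds.subset("val")

    x_train, y_train = preprocess_batch(train_ds, cfg.image_side)
    x_val, y_val = (preprocess_batch(val_ds, cfg.image_side)
                    if len(val_ds) else (None, None))

    params = model.parameters()
    if cfg.optimizer == "adam":
        opt = nn.Adam(params, lr=cfg.learning_rate)
    else:
        opt = nn.SGD(params, lr=cfg.learning_rate)

    rng = np.random.default_rng(cfg.seed)
    history = History()
    best_val, best_state = -1.0, None

    for epoch in range(cfg.epochs):
        tic = time.time()
        model.train()
        order = rng.permutation(len(x_train))
        losses, correct = [], 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            model.zero_grad()
            logits = model.forward(x_train[idx])
            loss = ad.cross_entropy(logits, y_train[idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((np.argmax(logits.data, axis=1) == y_train[idx]).sum())
        history.train_loss.append(float(np.mean(losses)))
        history.train_accuracy.append(correct / len(x_train))

        if x_val is not None:
            model.eval()
            logits = _forward_batched(model, x_val, cfg.batch_size)
            vloss = float(ad.cross_entropy(ad.Tensor(logits), y_val).data)
            vacc = float((np.argmax(logits, axis=1) == y_val).mean())
            history.val_loss.append(vloss)
            history.val_accuracy.append(vacc)
            if vacc > best_val:
                best_val = vacc
                best_state = model.state_dict()
        history.epoch_seconds.append(time.time() - tic)
        if verbose:
            msg = (f"epoch {epoch:3d} loss {history.train_loss[-1]:.4f} "
                   f"acc {history.train_accuracy[-1]:.3f}")
            if x_val is not None:
                msg += f" val_acc {history.val_accuracy[-1]:.3f}"
            print(msg)

    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history


def evaluate(model: HTEM, ds: LabelledDataset, split: str = "test",
             noise: NoiseSpec | None = None, batch_size: int = 32) -> EvalReport:
    """Deterministic evaluation of one split (no augmentation at eval time).

    When ``noise`` is given it is applied to each image, on the [0,1]
    scale, before preprocessing, with seeds derived from the spec.
    """
    sub = ds.subset(split) if split else ds
    if len(sub) == 0:
        raise ValueError(f"split {split!r} is empty")
    model.eval()
    x, y = preprocess_batch(sub, model.cfg.image_size, noise=noise)
    logits = _forward_batched(model, x, batch_size)
    preds = np.argmax(logits, axis=1)
    cm = confusion_matrix(y, preds, model.cfg.num_classes,
                          class_names=list(ds.class_names))
    return EvalReport(cm)


def run_imbalanced_protocol(ds: LabelledDataset, model_cfg: HTEMConfig,
                            cfg: TrainConfig,
                            verbose: bool = False) -> tuple[list[float], float]:
    """One-vs-rest AP protocol: train a fresh binary model per class.

    Each class in turn is relabelled positive against all others, a model
    with two output classes is trained on the resulting imbalanced dataset,
    and AP is computed from the positive-class scores on the validation
    split (falling back to test, then train).  Returns (APs, mAP).
    """
    if len(ds.class_names) < 2:
        raise ValueError("need at least 2 classes")
    versions = make_imbalanced_versions(ds)
    aps = []
    for k, binary_ds in enumerate(versions):
        bin_cfg = replace(model_cfg, num_classes=2)
        model = HTEM(bin_cfg, seed=cfg.seed + k)
        model, _ = train(model, binary_ds, cfg)
        eval_split = next(s for s in ("val", "test", "train")
                          if len(binary_ds.subset(s)))
        sub = binary_ds.subset(eval_split)
        x, y = preprocess_batch(sub, model.cfg.image_size)
        scores = _forward_batched(model, x, cfg.batch_size)[:, 1]
        aps.append(average_precision(RankedScores(scores, y)))
        if verbose:
            print(f"dataset {k + 1}: AP {aps[-1]:.4f}")
    return aps, mean_ap(aps)


def run_ablation(ds: LabelledDataset, model_cfg: HTEMConfig, cfg: TrainConfig,
                 grid: list[dict] | None = None,
                 verbose: bool = False) -> list[dict]:
    """Train one variant per grid cell with identical seed and data.

    The default grid is the four-cell attention x feed-forward table:
    both baselines, CPSA only, LFFN only, and the full model.
    """
    if grid is None:
        grid = [
            {"name": "none", "attention": "mha", "ffn": "ffn"},
            {"name": "cpsa_only", "attention": "cpsa", "ffn": "ffn"},
            {"name": "lffn_only", "attention": "mha", "ffn": "lffn"},
            {"name": "full", "attention": "cpsa", "ffn": "lffn"},
        ]
    rows = []
    for cell in grid:
        cell = dict(cell)
        name = cell.pop("name", str(cell))
        model = make_variant(model_cfg, seed=cfg.seed, **cell)
        model, history = train(model, ds, cfg)
        eval_split = next(s for s in ("test", "val", "train") if len(ds.subset(s)))
        report = evaluate(model, ds, split=eval_split, batch_size=cfg.batch_size)
        rows.append({"name": name, **cell, "accuracy": report.accuracy,
                     "final_train_loss": history.train_loss[-1] if history.train_loss else None})
        if verbose:
            print(f"{name}: accuracy {report.accuracy:.4f}")
    return rows
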