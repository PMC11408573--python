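"""Training harness for the two-class nodule classifier.

Follows the model/results idiom: :class:`NoduleClassifier` is built from the
training data (plus either a static validation set or an MCCV schedule) and a
:class:`TrainingConfig`; ``fit()`` returns a :class:`TrainingResults` holding
the fitted network, the per-epoch history (train/validation accuracy,
learning-rate trace) and a ``summary()`` table.

Training details: Adam on class-weighted softmax cross-entropy, per-epoch
shuffling, and a reduce-on-plateau rule — the learning rate is multiplied by
``plateau_factor`` (default 0.1) whenever validation accuracy fails to
improve on its best value for ``plateau_patience`` consecutive epochs.
Everything is a pure function of the config seed on a fixed platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._net import SmallConvNet, softmax
from .splitting import MccvSchedule

__all__ = ["TrainingConfig", "NoduleClassifier", "TrainingResults",
           "SmallConvNet", "train", "evaluate_accuracy", "CLASS_NAMES"]

CLASS_NAMES = ("benign", "malignant")


class TrainingError(ValueError):
    """The training request is invalid (single-class data, empty val...)."""


@dataclass
class TrainingConfig:
    """Hyper-parameters of one training run.

    Defaults are the desk-scale study settings: Adam at learning rate 1e-3
    (the largest rate at which this layer-normed network trains stably from
    random init), batch size 32, 50 epochs, with the plateau rule cutting
    the learning rate to one tenth after 15 epochs without validation
    improvement (strict improvement over the best value so far, tolerance
    1e-4; the long patience keeps the rule from strangling late
    memorization, which the leakage study must leave possible).
    """

    learning_rate: float = 1e-3
    batch_size: int = 32
    n_epochs: int = 50
    optimizer: str = "adam"
    plateau_factor: float = 0.1
    plateau_patience: int = 15
    plateau_min_delta: float = 1e-4
    seed: int = 0
    mccv: bool = False
    conv_channels: tuple[int, int, int] = (12, 16, 32)
    hidden_units: int = 24
    class_weighting: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise TrainingError("learning_rate must be > 0")
        if not 0 < self.plateau_factor < 1:
            raise TrainingError("plateau_factor must be in (0, 1)")
        if self.batch_size < 1 or self.n_epochs < 1:
            raise TrainingError("batch_size and n_epochs must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_channels"] = list(self.conv_channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        d = dict(d)
        if "conv_channels" in d:
            d["conv_channels"] = tuple(d["conv_channels"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainingConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))


class _Adam:
    def __init__(self, params: dict[str, np.ndarray],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] -= lr * (self.m[k] / bias1) / (
                np.sqrt(self.v[k] / bias2) + self.eps)


def _as_label_array(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "US":
        lut = {name: i for i, name in enumerate(CLASS_NAMES)}
        try:
            arr = np.array([lut[str(v)] for v in arr])
        except KeyError as exc:
            raise TrainingError(f"unknown class label {exc.args[0]!r}") from exc
    return arr.astype(np.int64)


@dataclass
class TrainingResults:
    """Outcome of :meth:`NoduleClassifier.fit`."""

    model: SmallConvNet
    history: pd.DataFrame       # epoch, train_acc, val_acc, lr, train_loss
    config: TrainingConfig

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return self.model.forward_batch(images)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=1)

    def accuracy(self, images: np.ndarray, labels: Sequence) -> float:
        return evaluate_accuracy(self.model, images, labels)

    @property
    def final_train_accuracy(self) -> float:
        return float(self.history["train_acc"].iloc[-1])

    @property
    def final_val_accuracy(self) -> float:
        return float(self.history["val_acc"].iloc[-1])

    def summary(self) -> str:
        h = self.history
        lines = [
            "Nodule classifier training results",
            "=" * 42,
            f"epochs:              {len(h)}",
            f"final train acc:     {h['train_acc'].iloc[-1]:.4f}",
            f"final val acc:       {h['val_acc'].iloc[-1]:.4f}",
            f"best val acc:        {h['val_acc'].max():.4f}",
            f"final learning rate: {h['lr'].iloc[-1]:.2e}",
            f"lr plateau steps:    {int((h['lr'].diff() < 0).sum())}",
            f"mccv validation:     {self.config.mccv}",
        ]
        return "\n".join(lines)

    def save_history(self, path: str | Path) -> None:
        self.history.to_csv(path, index=False)


class NoduleClassifier:
    """Two-class CNN classifier bound to its training data.

    Parameters
    ----------
    images, labels
        Training pool: (N, H, W) grayscale array in [0, 1] and N labels
        (0/1 ints or "benign"/"malignant" strings).
    validation
        Static ``(images, labels)`` validation set.  Mutually exclusive with
        ``mccv_schedule``.
    mccv_schedule
        An :class:`~leakaudit.splitting.MccvSchedule`; then ``patient_ids``
        must give each pool image's patient and the train/validation
        assignment is re-drawn from the schedule at every epoch.
    """

    def __init__(self, images: np.ndarray, labels: Sequence,
                 *, validation: tuple[np.ndarray, Sequence] | None = None,
                 mccv_schedule: MccvSchedule | None = None,
                 patient_ids: Sequence[str] | None = None,
                 config: TrainingConfig | None = None):
        self.config = config or TrainingConfig()
        self.images = np.asarray(images, dtype=np.float32)
        self.labels = _as_label_array(labels)
        if self.images.shape[0] != self.labels.shape[0]:
            raise TrainingError("images and labels length mismatch")
        if (validation is None) == (mccv_schedule is None):
            raise TrainingError(
                "provide exactly one of validation=(images, labels) or "
                "mccv_schedule=...")
        self.mccv_schedule = mccv_schedule
        if mccv_schedule is not None:
            if patient_ids is None:
                raise TrainingError("mccv_schedule requires patient_ids")
            self.patient_ids = np.asarray(patient_ids)
            if self.patient_ids.shape[0] != self.images.shape[0]:
                raise TrainingError("patient_ids length mismatch")
            self.val_images = self.val_labels = None
        else:
            self.patient_ids = None
            v_imgs, v_labels = validation
            self.val_images = np.asarray(v_imgs, dtype=np.float32)
            self.val_labels = _as_label_array(v_labels)
            if self.val_images.shape[0] == 0:
                raise TrainingError("validation set is empty")
        if np.unique(self.labels).size < 2:
            raise TrainingError("training pool contains a single class; "
                                "both classes are required")

    # ------------------------------------------------------------------ fit

    def _epoch_partition(self, epoch: int) -> tuple[np.ndarray, np.ndarray]:
        """Indices of (train, validation) images for this epoch."""
        if self.mccv_schedule is None:
            return np.arange(self.images.shape[0]), None
        assign = self.mccv_schedule.epoch_assignments[
            epoch % self.mccv_schedule.n_epochs]
        part = np.array([assign.get(p, "train") for p in self.patient_ids])
        tr = np.flatnonzero(part == "train")
        va = np.flatnonzero(part == "validation")
        if va.size == 0:
            raise TrainingError(f"MCCV epoch {epoch}: empty validation set")
        if np.unique(self.labels[tr]).size < 2:
            raise TrainingError(f"MCCV epoch {epoch}: single-class train set")
        return tr, va

    def fit(self) -> TrainingResults:
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xC1A]))
        net = SmallConvNet(conv_channels=cfg.conv_channels,
                           hidden_units=cfg.hidden_units,
                           seed=int(np.random.SeedSequence(
                               [cfg.seed, 0x117]).generate_state(1)[0]))
        if cfg.class_weighting:
            counts = np.bincount(self.labels, minlength=2).astype(np.float64)
            weights = counts.sum() / (2.0 * np.maximum(counts, 1))
        else:
            weights = np.ones(2)
        opt = _Adam(net.params)
        lr = cfg.learning_rate
        best_val = -np.inf
        wait = 0
        rows = []
        for epoch in range(cfg.n_epochs):
            tr_idx, va_idx = self._epoch_partition(epoch)
            order = rng.permutation(tr_idx)
            n_correct = 0
            loss_sum = 0.0
            weight_sum = 0.0
            for start in range(0, order.size, cfg.batch_size):
                batch = order[start:start + cfg.batch_size]
                x = net._as_batch(self.images[batch])
                y = self.labels[batch]
                logits, caches = net._forward_full(x)
                probs = softmax(logits)
                w = weights[y].astype(np.float32)
                p_true = np.clip(probs[np.arange(y.size), y], 1e-12, None)
                loss_sum += float(-(w * np.log(p_true)).sum())
                weight_sum += float(w.sum())
                n_correct += int((logits.argmax(axis=1) == y).sum())
                dlogits = probs.astype(np.float32)
                dlogits[np.arange(y.size), y] -= 1.0
                dlogits *= (w / w.sum())[:, None]
                grads = net._backward(dlogits, caches)
                opt.step(net.params, grads, lr)
            train_acc = n_correct / order.size
            if self.mccv_schedule is None:
                val_x, val_y = self.val_images, self.val_labels
            else:
                val_x, val_y = self.images[va_idx], self.labels[va_idx]
            val_acc = evaluate_accuracy(net, val_x, val_y)
            rows.append({"epoch": epoch, "train_acc": train_acc,
                         "val_acc": val_acc, "lr": lr,
                         "train_loss": loss_sum / max(weight_sum, 1e-12)})
            if val_acc > best_val + cfg.plateau_min_delta:
                best_val = val_acc
                wait = 0
            else:
                wait += 1
                if wait >= cfg.plateau_patience:
                    lr *= cfg.plateau_factor
                    wait = 0
        history = pd.DataFrame(rows)
        return TrainingResults(model=net, history=history, config=cfg)


def train(train_images: np.ndarray, train_labels: Sequence,
          validation: tuple[np.ndarray, Sequence] | MccvSchedule,
          config: TrainingConfig | None = None,
          patient_ids: Sequence[str] | None = None) -> TrainingResults:
    """Train a model under either a static validation set or MCCV.

    Convenience wrapper around :class:`NoduleClassifier`; ``validation`` is a
    ``(images, labels)`` pair or an :class:`~leakaudit.splitting.MccvSchedule`
    (the latter requires ``patient_ids`` aligned with ``train_images``).
    """
    if isinstance(validation, MccvSchedule):
        model = NoduleClassifier(train_images, train_labels,
                                 mccv_schedule=validation,
                                 patient_ids=patient_ids, config=config)
    else:
        model = NoduleClassifier(train_images, train_labels,
                                 validation=validation, config=config)
    return model.fit()


def evaluate_accuracy(model: SmallConvNet | TrainingResults,
                      images: np.ndarray, labels: Sequence) -> float:
    """Fraction of images whose argmax-probability prediction is correct."""
    if isinstance(model, TrainingResults):
        model = model.model
    labels = _as_label_array(labels)
    if labels.size == 0:
        raise TrainingError("evaluation set is empty")
    probs = model.forward_batch(np.asarray(images, dtype=np.float32))
    return float((probs.argmax(axis=1) == labels).mean())
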