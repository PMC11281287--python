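"""Model optimisation: Adam with binary cross-entropy, mini-batches of 32,
step learning-rate decay, L2 weight decay, early stopping on validation loss,
and flip/crop augmentation.

Training samples are 64×64 tiles; each pass applies a random horizontal and/or
vertical flip (probability 0.5 each — top-down plant imagery has no preferred
orientation) followed by a uniform-random 50×50 crop. Evaluation uses a
deterministic centre crop and no flips. The model returned by :func:`fit` is
the one with the lowest validation loss seen during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import Sample
from .model import WaterDeficitClassifier
from .nn import Adam, Tensor, bce_mean


@dataclass
class TrainConfig:
    """Optimisation hyperparameters (defaults follow the training recipe:
    Adam at 1e-3, batch 32, at most 200 epochs with 50-epoch patience,
    learning rate ×0.1 every 15 epochs, weight decay 5e-4, 64→50 crop)."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 50
    lr_step: int = 15
    lr_factor: float = 0.1
    weight_decay: float = 5e-4
    crop_to: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "batch_size", "max_epochs", "patience",
                     "lr_step", "lr_factor", "weight_decay", "crop_to"):
            if getattr(self, name) < 0 or getattr(self, name) == 0 and \
                    name not in ("weight_decay",):
                raise ValueError(f"{name} must be positive")

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate during 1-indexed ``epoch``: decayed by ``lr_factor``
        every ``lr_step`` epochs (epoch 16 under defaults runs at 1e-4)."""
        return self.learning_rate * self.lr_factor ** ((epoch - 1) // self.lr_step)


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    learning_rate: list = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        """1-indexed epoch with the lowest validation loss."""
        return int(np.argmin(self.val_loss)) + 1

    def __len__(self) -> int:
        return len(self.train_loss)


def _sample_array(s) -> np.ndarray:
    return s.data if isinstance(s, Sample) else np.asarray(s)


def augment(h: np.ndarray, mode: str = "train",
            rng: np.random.Generator | None = None, crop_to: int = 50) -> np.ndarray:
    """Flip-and-crop augmentation on one (C, H, W) sample.

    ``train``: random H/V flips (p = 0.5 each) then a uniform-random
    ``crop_to``×``crop_to`` crop. ``eval``: deterministic centre crop only.
    """
    h = np.asarray(h)
    if h.ndim != 3:
        raise ValueError(f"sample must be rank-3 (C,H,W), got {h.shape}")
    c, hh, ww = h.shape
    if hh < crop_to or ww < crop_to:
        raise ValueError(f"spatial size {(hh, ww)} smaller than crop {crop_to}")
    if mode == "train":
        if rng is None:
            raise ValueError("train-mode augmentation needs an rng")
        if rng.random() < 0.5:
            h = h[:, ::-1, :]
        if rng.random() < 0.5:
            h = h[:, :, ::-1]
        r = int(rng.integers(0, hh - crop_to + 1))
        cpos = int(rng.integers(0, ww - crop_to + 1))
    elif mode == "eval":
        r = (hh - crop_to) // 2
        cpos = (ww - crop_to) // 2
    else:
        raise ValueError(f"unknown augmentation mode {mode!r}")
    return np.ascontiguousarray(h[:, r:r + crop_to, cpos:cpos + crop_to])


def bce_loss(p, y) -> float:
    """Mean binary cross-entropy of probabilities against {0,1} labels
    (probabilities clamped at 1e-7)."""
    p = np.atleast_1d(np.asarray(p, dtype=np.float64))
    y = np.atleast_1d(np.asarray(y, dtype=np.float64))
    pc = np.clip(p, 1e-7, 1 - 1e-7)
    return float(-(y * np.log(pc) + (1 - y) * np.log(1 - pc)).mean())


def _labels(samples) -> np.ndarray:
    return np.array([s.label for s in samples], dtype=np.float32)


def evaluate_loss(model: WaterDeficitClassifier, samples, crop_to: int = 50,
                  batch_size: int = 64) -> float:
    """Inference-mode (centre-crop) mean BCE over a sample list."""
    losses, ns = [], []
    for i in range(0, len(samples), batch_size):
        chunk = samples[i:i + batch_size]
        batch = np.stack([augment(_sample_array(s), "eval", crop_to=crop_to)
                          for s in chunk])
        p = model.predict_proba(batch)
        losses.append(bce_loss(p, _labels(chunk)) * len(chunk))
        ns.append(len(chunk))
    return float(np.sum(losses) / np.sum(ns))


def predict_scores(model: WaterDeficitClassifier, samples, crop_to: int = 50,
                   batch_size: int = 64) -> np.ndarray:
    """Inference-mode probabilities for a list of samples."""
    out = []
    for i in range(0, len(samples), batch_size):
        batch = np.stack([augment(_sample_array(s), "eval", crop_to=crop_to)
                          for s in samples[i:i + batch_size]])
        out.append(model.predict_proba(batch))
    return np.concatenate(out) if out else np.empty(0)


def fit(model: WaterDeficitClassifier, train_set, val_set,
        cfg: TrainConfig | None = None, restore_best: bool = True
        ) -> tuple[WaterDeficitClassifier, TrainHistory]:
    """Train in place and return ``(model_at_best_val_loss, history)``.

    With ``restore_best=False`` the model keeps its final-epoch parameters
    instead of the best-validation snapshot (useful when the quantity of
    interest — e.g. the attention weights — accumulates over the whole run).

    Stops at the earlier of ``max_epochs`` and ``patience`` consecutive epochs
    without a strict validation-loss improvement. One master seed fans out to
    named sub-seeds for shuffling and augmentation; parameter initialisation
    is owned by the model's own seed.
    """
    cfg = cfg or TrainConfig()
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    labels = _labels(train_set)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    ss = np.random.SeedSequence(cfg.seed).spawn(2)
    shuffle_rng = np.random.default_rng(ss[0])
    aug_rng = np.random.default_rng(ss[1])
    opt = Adam(model.parameters(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    history = TrainHistory()
    best_state, best_val, stale = None, np.inf, 0
    for epoch in range(1, cfg.max_epochs + 1):
        opt.lr = cfg.lr_at_epoch(epoch)
        order = shuffle_rng.permutation(len(train_set))
        epoch_losses, epoch_ns = [], []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            batch = np.stack([
                augment(_sample_array(train_set[j]), "train", aug_rng, cfg.crop_to)
                for j in idx])
            p = model(Tensor(batch), train=True)
            loss = bce_mean(p, labels[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data) * len(idx))
            epoch_ns.append(len(idx))
        train_loss = float(np.sum(epoch_losses) / np.sum(epoch_ns))
        val_loss = evaluate_loss(model, val_set, crop_to=cfg.crop_to)
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        history.learning_rate.append(opt.lr)
        if val_loss < best_val:
            best_val, stale = val_loss, 0
            best_state = model.state_dict()
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    if restore_best and best_state is not None:
        model.load_state_dict(best_state)
    return model, history
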