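"""Training strategy and evaluation for the patch-transformer.

The split is chronological: the first 80 % of the (deterministically
ordered) data trains the model and the remainder validates it, grouped at
source-trial granularity so overlapping windows of one recording never
straddle the split.  Training is Adam on the cross-entropy of the logits,
with a multiplicative per-epoch learning-rate decay lr_e = lr0 * decay^e;
the checkpoint of the epoch with minimal validation loss is kept.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .autodiff import softmax_cross_entropy
from .datasets import FALL, DatasetManifest
from .metrics import ConfusionMatrix, MetricsReport, compute_metrics
from .network import (ModelConfig, PatchTransformer, count_params,
                      estimate_flops)
from .preprocessing import PatchSequence, WindowConfig, build_patch_sequences

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "EpochRecord",
    "chronological_split",
    "Adam",
    "train",
    "evaluate",
    "run_window_ablation",
]


@dataclass
class TrainConfig:
    """Optimisation settings.

    Defaults are the smartphone-scale recipe (batch 32, decay 0.95); the
    waist-unit-scale recipe uses batch 16 and decay 0.98
    (:meth:`sisfall_scale`).  The learning rate at epoch e is
    lr0 * lr_decay**e.
    """

    batch_size: int = 32
    epochs: int = 50
    lr0: float = 1e-3
    lr_decay: float = 0.95
    split_fraction: float = 0.8
    select_on: str = "val"   # epoch selection: "val" or "train" loss
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie strictly in (0, 1)")
        if not 0.0 < self.lr_decay <= 1.0:
            raise ValueError("lr_decay must lie in (0, 1]")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.select_on not in ("val", "train"):
            raise ValueError("select_on must be 'val' or 'train'")

    @classmethod
    def sisfall_scale(cls, **kw) -> "TrainConfig":
        kw.setdefault("batch_size", 16)
        kw.setdefault("lr_decay", 0.98)
        return cls(**kw)


@dataclass
class EpochRecord:
    epoch: int
    lr: float
    train_loss: float
    val_loss: float
    val_metrics: MetricsReport


@dataclass
class TrainHistory:
    records: list[EpochRecord]
    best_epoch: int
    best_state: dict[str, np.ndarray]

    @property
    def val_losses(self) -> np.ndarray:
        return np.array([r.val_loss for r in self.records])

    @property
    def train_losses(self) -> np.ndarray:
        return np.array([r.train_loss for r in self.records])


def chronological_split(sequences: list[PatchSequence], fraction: float,
                        by_trial: bool = True
                        ) -> tuple[list[PatchSequence], list[PatchSequence]]:
    """First-``fraction`` / remainder split of an ordered sample list.

    With ``by_trial`` (default) the split boundary falls between source
    recordings: the first floor(fraction * G) of the G distinct source
    trials train, so no recording contributes windows to both sides.
    """
    if not sequences:
        raise ValueError("cannot split an empty sample list")
    if by_trial:
        groups: list[str] = []
        for s in sequences:
            key = s.source_trial.group_key()
            if not groups or groups[-1] != key:
                if key in groups:
                    raise ValueError("sequences are not grouped by source trial")
                groups.append(key)
        n_train_groups = int(fraction * len(groups))
        if n_train_groups == 0 or n_train_groups == len(groups):
            raise ValueError(
                f"fraction {fraction} leaves an empty side for {len(groups)} trials"
            )
        train_keys = set(groups[:n_train_groups])
        train = [s for s in sequences if s.source_trial.group_key() in train_keys]
        test = [s for s in sequences if s.source_trial.group_key() not in train_keys]
    else:
        cut = int(fraction * len(sequences))
        if cut == 0 or cut == len(sequences):
            raise ValueError(f"fraction {fraction} leaves an empty side")
        train, test = sequences[:cut], sequences[cut:]
    return train, test


class Adam:
    """Adam optimiser over a parameter list."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _stack(sequences: list[PatchSequence]) -> tuple[np.ndarray, np.ndarray]:
    blocks = np.stack([s.blocks for s in sequences])
    labels = np.array([1 if s.label == FALL else 0 for s in sequences])
    return blocks, labels


def _dataset_loss(model: PatchTransformer, blocks: np.ndarray,
                  labels: np.ndarray, batch: int = 256) -> float:
    total, n = 0.0, blocks.shape[0]
    for i in range(0, n, batch):
        xb, yb = blocks[i:i + batch], labels[i:i + batch]
        loss = softmax_cross_entropy(model.forward(xb), yb)
        total += float(loss.data) * len(yb)
    return total / n


def train(model: PatchTransformer, train_set: list[PatchSequence],
          val_set: list[PatchSequence], cfg: TrainConfig) -> TrainHistory:
    """Fit the network; returns per-epoch records and the best checkpoint.

    Fully reproducible: batch order is drawn from a generator seeded by
    ``cfg.seed`` and all arithmetic is deterministic float64.
    """
    if not train_set or not val_set:
        raise ValueError("training and validation sets must be non-empty")
    xb_train, y_train = _stack(train_set)
    xb_val, y_val = _stack(val_set)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr0)

    records: list[EpochRecord] = []
    best_loss, best_epoch, best_state = np.inf, -1, model.state_dict()
    n = xb_train.shape[0]
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr0 * cfg.lr_decay**epoch
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            logits = model.forward(xb_train[idx])
            loss = softmax_cross_entropy(logits, y_train[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} (loss={loss.data})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        val_loss = _dataset_loss(model, xb_val, y_val)
        cm = evaluate(model, val_set)
        records.append(EpochRecord(
            epoch=epoch, lr=opt.lr, train_loss=epoch_loss / n,
            val_loss=val_loss, val_metrics=compute_metrics(cm)))
        selected = val_loss if cfg.select_on == "val" else epoch_loss / n
        if selected < best_loss:
            best_loss, best_epoch = selected, epoch
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return TrainHistory(records=records, best_epoch=best_epoch,
                        best_state=best_state)


def evaluate(model: PatchTransformer, test_set: list[PatchSequence],
             batch: int = 256) -> ConfusionMatrix:
    """Argmax predictions tallied against the fall/no-fall truth."""
    if not test_set:
        raise ValueError("test set is empty")
    blocks, labels = _stack(test_set)
    preds = np.concatenate([
        model.predict(blocks[i:i + batch]) for i in range(0, len(labels), batch)
    ])
    tp = int(((preds == 1) & (labels == 1)).sum())
    fn = int(((preds == 0) & (labels == 1)).sum())
    fp = int(((preds == 1) & (labels == 0)).sum())
    tn = int(((preds == 0) & (labels == 0)).sum())
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def run_window_ablation(manifest: DatasetManifest, window_seconds: list[float],
                        target_seconds: float, fs: float,
                        model_kwargs: dict | None = None,
                        train_cfg: TrainConfig | None = None,
                        stride_fraction: float = 0.5) -> list[dict]:
    """Train and evaluate one model per window size; one report row each.

    Each row carries the evaluation metrics, the exact parameter count, the
    multiply-add estimate, and the mean per-sample inference time.
    """
    train_cfg = train_cfg or TrainConfig()
    model_kwargs = dict(model_kwargs or {})
    rows: list[dict] = []
    for w in window_seconds:
        cfg = WindowConfig(window_seconds=w, stride_seconds=w * stride_fraction, fs=fs)
        sequences = build_patch_sequences(manifest, cfg, target_seconds)
        train_set, test_set = chronological_split(sequences, train_cfg.split_fraction)
        channels = sequences[0].C
        mcfg = ModelConfig(channels=channels, patch_side=cfg.n,
                           seq_len=sequences[0].N, seed=train_cfg.seed,
                           **model_kwargs)
        model = PatchTransformer(mcfg)
        train(model, train_set, test_set, train_cfg)
        cm = evaluate(model, test_set)
        report = compute_metrics(cm)
        t0 = time.perf_counter()
        for s in test_set[:32]:
            model.predict(s.blocks[None])
        per_sample = (time.perf_counter() - t0) / min(32, len(test_set))
        rows.append({
            "window_seconds": w,
            **report.as_dict(),
            "params": count_params(model),
            "flops": estimate_flops(model),
            "test_time_s": per_sample,
        })
    return rows
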