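"""High-level model/results interface for fall detection.

:class:`FallDetector` is constructed from data (patch sequences, or a raw
trial manifest via :meth:`FallDetector.from_manifest`) plus the network and
training settings; :meth:`FallDetector.fit` runs the training strategy and
returns a :class:`FallDetectorResults` carrying the fitted network, the
per-epoch history, evaluation helpers and a ``summary()`` table.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .datasets import DatasetManifest
from .metrics import ConfusionMatrix, MetricsReport, compute_metrics
from .network import (ModelConfig, PatchTransformer, count_params,
                      estimate_flops)
from .preprocessing import PatchSequence, WindowConfig, build_patch_sequences
from .training import TrainConfig, TrainHistory, chronological_split, evaluate, train

__all__ = ["FallDetector", "FallDetectorResults"]


class FallDetector:
    """A patch-transformer fall-vs-ADL classifier bound to its data.

    Parameters
    ----------
    train_sequences, val_sequences
        Labelled :class:`~ptnfall.preprocessing.PatchSequence` lists.  The
        validation set drives learning-rate-independent epoch selection and
        is the default evaluation set of the results object.
    model_config, train_config
        Architecture and optimisation settings; both have working defaults
        derived from the data shapes when omitted.
    """

    def __init__(self, train_sequences: list[PatchSequence],
                 val_sequences: list[PatchSequence],
                 model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None):
        if not train_sequences or not val_sequences:
            raise ValueError("both sequence sets must be non-empty")
        shapes = {s.blocks.shape[1:] for s in train_sequences + val_sequences}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent patch-sequence shapes: {sorted(shapes)}")
        (n_seq, n, _, c) = train_sequences[0].blocks.shape
        self.train_sequences = train_sequences
        self.val_sequences = val_sequences
        self.train_config = train_config or TrainConfig()
        self.model_config = model_config or ModelConfig(
            channels=c, patch_side=n, seq_len=n_seq, seed=self.train_config.seed)
        self.network = PatchTransformer(self.model_config)

    @classmethod
    def from_manifest(cls, manifest: DatasetManifest, window_config: WindowConfig,
                      target_seconds: float,
                      model_config: ModelConfig | None = None,
                      train_config: TrainConfig | None = None) -> "FallDetector":
        """Preprocess a trial manifest and split it chronologically."""
        train_config = train_config or TrainConfig()
        sequences = build_patch_sequences(manifest, window_config, target_seconds)
        train_set, val_set = chronological_split(
            sequences, train_config.split_fraction)
        return cls(train_set, val_set, model_config=model_config,
                   train_config=train_config)

    def fit(self) -> "FallDetectorResults":
        """Train per the configured strategy; weights end at the best epoch."""
        history = train(self.network, self.train_sequences,
                        self.val_sequences, self.train_config)
        return FallDetectorResults(self, history)


class FallDetectorResults:
    """Fit results: history, diagnostics, prediction and reporting."""

    def __init__(self, model: FallDetector, history: TrainHistory):
        self.model = model
        self.network = model.network
        self.history = history
        self.best_epoch = history.best_epoch
        self.confusion_matrix: ConfusionMatrix = evaluate(
            self.network, model.val_sequences)
        self.metrics: MetricsReport = compute_metrics(self.confusion_matrix)

    # -- prediction -----------------------------------------------------------

    def predict(self, sequences: list[PatchSequence]) -> np.ndarray:
        blocks = np.stack([s.blocks for s in sequences])
        return self.network.predict(blocks)

    def predict_proba(self, sequences: list[PatchSequence]) -> np.ndarray:
        blocks = np.stack([s.blocks for s in sequences])
        return self.network.predict_proba(blocks)

    def evaluate(self, sequences: list[PatchSequence]) -> ConfusionMatrix:
        return evaluate(self.network, sequences)

    # -- reporting ------------------------------------------------------------

    def history_frame(self) -> pd.DataFrame:
        rows = [{
            "epoch": r.epoch, "lr": r.lr, "train_loss": r.train_loss,
            "val_loss": r.val_loss, **{f"val_{k}": v
                                       for k, v in r.val_metrics.as_dict().items()},
        } for r in self.history.records]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        cfg, tcfg = self.model.model_config, self.model.train_config
        cm, m = self.confusion_matrix, self.metrics
        buf = io.StringIO()
        w = buf.write
        w("Patch-Transformer Fall Detection Results\n")
        w("=" * 58 + "\n")
        w(f"{'channels (C)':<28}{cfg.channels:>10}\n")
        w(f"{'token width (D = C^2)':<28}{cfg.d_model:>10}\n")
        w(f"{'attention heads (h)':<28}{cfg.heads:>10}\n")
        w(f"{'encoder layers (L)':<28}{cfg.layers:>10}\n")
        w(f"{'patch side (n)':<28}{cfg.patch_side:>10}\n")
        w(f"{'tokens per sample (N)':<28}{cfg.seq_len:>10}\n")
        w(f"{'local features (conv)':<28}{str(cfg.local_features):>10}\n")
        w(f"{'parameters':<28}{count_params(self.network):>10}\n")
        w(f"{'multiply-adds / sample':<28}{estimate_flops(self.network):>10}\n")
        w("-" * 58 + "\n")
        w(f"{'train samples':<28}{len(self.model.train_sequences):>10}\n")
        w(f"{'validation samples':<28}{len(self.model.val_sequences):>10}\n")
        w(f"{'epochs (best)':<28}{f'{tcfg.epochs} ({self.best_epoch})':>10}\n")
        w(f"{'batch size / lr0 / decay':<28}"
          f"{f'{tcfg.batch_size} / {tcfg.lr0:g} / {tcfg.lr_decay:g}':>10}\n")
        w("-" * 58 + "\n")
        w("validation confusion matrix (rows: actual fall, no-fall)\n")
        w(f"    TP={cm.tp:<6} FN={cm.fn:<6}\n    FP={cm.fp:<6} TN={cm.tn:<6}\n")
        w("-" * 58 + "\n")
        for name, value in m.as_dict().items():
            w(f"{name.capitalize():<28}{value:>9.2f}%\n")
        return buf.getvalue()

    def plot_history(self, ax=None):
        """Train/validation loss curves with the selected epoch marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.history_frame()
        ax.plot(frame["epoch"], frame["train_loss"], label="train loss")
        ax.plot(frame["epoch"], frame["val_loss"], label="validation loss")
        ax.axvline(self.best_epoch, color="grey", ls="--", lw=1,
                   label=f"best epoch ({self.best_epoch})")
        ax.set_xlabel("epoch")
        ax.set_ylabel("cross-entropy loss")
        ax.legend()
        return ax
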