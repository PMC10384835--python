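"""Segmentation of recordings into fixed-size patch sequences.

The pipeline normalises every trial to a common duration (long ADL
recordings are split into equal subsegments; fall recordings, captured with
extra lead-in/lead-out, are resampled), cuts each uniformised trial into
overlapping sliding windows of W samples with stride S < W, and reshapes
each window into an n x n x C patch with n = floor(sqrt(W)), keeping the
first n^2 samples in row-major time order.  Channels from multiple sensors
are concatenated in fixed sensor order, so C is the merged channel count and
the token width downstream is D = C^2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .datasets import ADL, FALL, DatasetManifest, Trial

__all__ = [
    "WindowConfig",
    "PatchSequence",
    "uniformize_duration",
    "sliding_windows",
    "patchify",
    "unpatchify",
    "concat_sensors",
    "build_patch_sequences",
    "TrialTooShortError",
    "WindowConfigError",
]

logger = logging.getLogger(__name__)


class WindowConfigError(ValueError):
    """Invalid window/stride combination."""


class TrialTooShortError(ValueError):
    """Trial shorter than the requested duration or window."""


@dataclass
class WindowConfig:
    """Sliding-window geometry.

    ``window_seconds`` and ``stride_seconds`` are durations; the derived
    sample counts are W = window_seconds * fs and S = stride_seconds * fs,
    with the hard constraint 0 < S < W (overlapping windows).  ``n`` is the
    patch side, the largest integer with n^2 <= W.
    """

    window_seconds: float
    stride_seconds: float
    fs: float
    W: int = field(init=False)
    S: int = field(init=False)
    n: int = field(init=False)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise WindowConfigError("sampling rate must be positive")
        self.W = int(round(self.window_seconds * self.fs))
        self.S = int(round(self.stride_seconds * self.fs))
        self.n = math.isqrt(self.W)
        if self.W < 1 or self.n < 1:
            raise WindowConfigError("window must contain at least one sample")
        if not 0 < self.S < self.W:
            raise WindowConfigError(
                f"stride S={self.S} must satisfy 0 < S < W={self.W}: "
                "overlapping windows require a step smaller than the window"
            )

    def n_windows(self, n_samples: int) -> int:
        if n_samples < self.W:
            raise TrialTooShortError(
                f"trial of {n_samples} samples is shorter than one window "
                f"({self.W} samples)"
            )
        return (n_samples - self.W) // self.S + 1


@dataclass
class PatchSequence:
    """One uniformised trial as a sequence of N patch blocks (N, n, n, C)."""

    blocks: np.ndarray
    label: str
    source_trial: Trial

    def __post_init__(self) -> None:
        self.blocks = np.asarray(self.blocks, dtype=np.float64)
        if self.blocks.ndim != 4 or self.blocks.shape[0] < 1:
            raise ValueError("blocks must be a non-empty (N, n, n, C) array")

    @property
    def N(self) -> int:
        return self.blocks.shape[0]

    @property
    def C(self) -> int:
        return self.blocks.shape[3]


def uniformize_duration(trial: Trial, target_seconds: float) -> list[Trial]:
    """Normalise one trial to the target duration.

    ADL trials longer than the target are split into floor(duration/target)
    consecutive equal subsegments (trailing remainder dropped); fall trials
    are linearly resampled onto a uniform grid of target_seconds * fs
    samples; trials already at the target pass through unchanged.
    """
    target = int(round(target_seconds * trial.fs))
    n = trial.n_samples
    if n == target:
        return [trial]
    if n < target:
        raise TrialTooShortError(
            f"trial {trial.group_key()} ({n} samples) is shorter than the "
            f"target of {target} samples"
        )
    if trial.label == FALL:
        old_t = np.arange(n, dtype=np.float64)
        new_t = np.linspace(0.0, n - 1, target)
        data = np.column_stack([
            np.interp(new_t, old_t, trial.data[:, c]) for c in range(trial.data.shape[1])
        ])
        return [Trial(data, trial.fs, trial.label, trial.activity_code,
                      trial.subject_id, trial.trial_id, trial.sensor_layout)]
    k = n // target
    segments = []
    for i in range(k):
        seg = trial.data[i * target:(i + 1) * target]
        segments.append(Trial(seg, trial.fs, trial.label, trial.activity_code,
                              trial.subject_id, f"{trial.trial_id}#{i}",
                              trial.sensor_layout))
    return segments


def sliding_windows(trial: Trial, cfg: WindowConfig) -> list[np.ndarray]:
    """Overlapping W x C windows starting at 0, S, 2S, ...; trailing samples
    that do not fill a window are dropped."""
    n = cfg.n_windows(trial.n_samples)
    return [trial.data[i * cfg.S:i * cfg.S + cfg.W] for i in range(n)]


def patchify(window: np.ndarray, cfg: WindowConfig) -> np.ndarray:
    """Reshape the first n^2 rows of a W x C window into an n x n x C grid,
    row-major in time."""
    window = np.asarray(window)
    n = cfg.n
    if window.shape[0] < n * n:
        raise ValueError(f"window of {window.shape[0]} rows cannot fill {n}x{n}")
    kept = window[:n * n]
    return kept.reshape(n, n, window.shape[1])


def unpatchify(block: np.ndarray) -> np.ndarray:
    """Invert :func:`patchify` on the kept samples: (n, n, C) -> (n^2, C)."""
    n = block.shape[0]
    return block.reshape(n * n, block.shape[2])


def concat_sensors(per_sensor_blocks: list[np.ndarray]) -> np.ndarray:
    """Channel-axis concatenation of per-sensor n x n x c_i blocks in fixed
    sensor order; all blocks must share the patch side n."""
    sides = {b.shape[:2] for b in per_sensor_blocks}
    if len(sides) != 1:
        raise ValueError(f"mismatched patch sides across sensors: {sorted(sides)}")
    return np.concatenate(per_sensor_blocks, axis=2)


def _patchify_window(window: np.ndarray, cfg: WindowConfig,
                     layout: tuple[tuple[str, int], ...]) -> np.ndarray:
    """Patchify each sensor's channel block, then concatenate (fixed order)."""
    blocks, start = [], 0
    for _, count in layout:
        blocks.append(patchify(window[:, start:start + count], cfg))
        start += count
    return concat_sensors(blocks)


def build_patch_sequences(manifest: DatasetManifest, cfg: WindowConfig,
                          target_seconds: float) -> list[PatchSequence]:
    """uniformize -> window -> patchify -> concat for a whole manifest.

    One :class:`PatchSequence` per uniformised trial, label inherited.
    Trials shorter than the target duration are discarded with a warning.
    """
    if cfg.n * cfg.n != cfg.W:
        logger.info(
            "window of W=%d samples is not square; keeping the first %d "
            "samples of each window (n=%d)", cfg.W, cfg.n**2, cfg.n)
    sequences = []
    for trial in manifest:
        try:
            uniform = uniformize_duration(trial, target_seconds)
        except TrialTooShortError:
            logger.warning("discarding trial %s: shorter than %.3g s",
                           trial.group_key(), target_seconds)
            continue
        for t in uniform:
            windows = sliding_windows(t, cfg)
            blocks = np.stack([
                _patchify_window(w, cfg, t.sensor_layout) for w in windows
            ])
            sequences.append(PatchSequence(blocks, t.label, t))
    return sequences
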