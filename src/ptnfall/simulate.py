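"""Synthetic wearable-IMU trials: falls, daily activities, and confounders.

The generator is phenomenological: it synthesises the acceleration-magnitude
profile each activity class imprints on a waist-worn IMU and distributes it
over the three axes through a slowly varying orientation vector, rather than
simulating rigid-body dynamics.  Falls follow the canonical signature - a
free-fall dip of the magnitude toward 0 g, a sharp impact spike of several g
lasting well under 0.3 s, then near-motionless rest at 1 g.  ADLs are
gravity plus periodic gait (walk/jog), stillness, or smooth postural
transitions (sit/lie).  A configurable fraction of ADLs are *confounders*:
abrupt sit/lie events whose transient peak crosses the threshold a naive
magnitude detector would use, the classic failure mode of threshold-based
fall detection, while still lacking the free-fall dip.

Gyroscope channels (when the layout has them) are low-amplitude smoothed
noise during normal activity with a burst during the fall phase; a second
accelerometer is a rescaled copy of the first with independent noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import uniform_filter1d

from .datasets import (ADL, FALL, SISFALL_LAYOUT, UNIMIB_LAYOUT,
                       DatasetManifest, Trial)

__all__ = ["SimConfig", "gen_adl", "gen_fall", "gen_dataset", "threshold_baseline"]

ADL_KINDS = ("walk", "jog", "sit", "lie", "still")
CONFOUNDER_KINDS = ("sit", "lie")

# dataset-style activity codes (underscore-free: they embed in file names)
ADL_CODES = {"walk": "D01", "jog": "D02", "sit": "D03", "lie": "D04",
             "still": "D05"}


@dataclass
class SimConfig:
    """Study conditions of the simulator.

    Defaults emulate smartphone-accelerometer-scale recordings: 3 s trials
    at 50 Hz with a single 3-axis accelerometer.  ``sisfall_scale`` switches
    to the 200 Hz, 9-channel waist-unit layout with 12 s ADL / 15 s fall
    trials.  Amplitudes are in g, durations in seconds.
    """

    fs: float = 50.0
    duration: float = 3.0
    sensor_layout: tuple[tuple[str, int], ...] = UNIMIB_LAYOUT
    noise_sd: float = 0.04

    # fall template
    dip_depth: float = 0.2          # magnitude floor during free fall
    dip_duration: float = 0.35
    impact_peak: tuple[float, float] = (3.5, 5.5)   # drawn uniformly
    impact_width: float = 0.06      # Gaussian sigma of the spike
    rest_level: float = 1.0
    rest_noise_sd: float = 0.01

    # ADL templates
    gait_freq: tuple[float, float] = (1.5, 3.0)     # Hz, walk..jog
    gait_amplitude: float = 0.3
    transition_peak: tuple[float, float] = (2.0, 3.5)  # confounder transient
    transition_width: float = 0.12

    confounder_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.confounder_fraction <= 1.0:
            raise ValueError("confounder_fraction must lie in [0, 1]")
        if self.duration < self.dip_duration + 0.5:
            raise ValueError("duration too short to contain a fall event")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    @classmethod
    def sisfall_scale(cls, **kw) -> "SimConfig":
        kw.setdefault("fs", 200.0)
        kw.setdefault("duration", 12.0)
        kw.setdefault("sensor_layout", SISFALL_LAYOUT)
        return cls(**kw)


# ---------------------------------------------------------------------------
# building blocks


def _orientation(n: int, rng: np.random.Generator, tilt_sd: float = 0.05) -> np.ndarray:
    """A slowly varying unit vector near the vertical axis, shape (n, 3)."""
    base = np.array([0.0, 0.0, 1.0])
    wobble = rng.normal(0.0, tilt_sd, (n, 3))
    wobble = uniform_filter1d(wobble, size=max(3, n // 10), axis=0)
    v = base + wobble
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _accel_from_magnitude(mag: np.ndarray, orient: np.ndarray,
                          noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    acc = mag[:, None] * orient
    return acc + rng.normal(0.0, noise_sd, acc.shape)


def _gyro(n: int, rng: np.random.Generator, base_sd: float,
          burst: slice | None = None, burst_amp: float = 0.0) -> np.ndarray:
    """Angular-rate channels: smoothed noise, optionally with an event burst."""
    g = rng.normal(0.0, base_sd, (n, 3))
    g = uniform_filter1d(g, size=5, axis=0)
    if burst is not None:
        idx = np.arange(n)[burst]
        envelope = np.hanning(len(idx))
        g[burst] += (envelope[:, None]
                     * rng.normal(0.0, burst_amp, (len(idx), 3)))
    return g


def _assemble(acc: np.ndarray, gyro_fn, cfg: SimConfig,
              rng: np.random.Generator) -> np.ndarray:
    """Fill the configured sensor layout from the primary accelerometer."""
    channels = []
    for name, count in cfg.sensor_layout:
        if name.startswith("acc") and not channels:
            channels.append(acc)
        elif name.startswith("acc"):
            channels.append(acc * 0.98 + rng.normal(0.0, cfg.noise_sd, acc.shape))
        elif name.startswith("gyro"):
            channels.append(gyro_fn(rng))
        else:
            raise ValueError(f"unknown sensor {name!r} in layout")
    return np.hstack(channels)


def _make_trial(data: np.ndarray, cfg: SimConfig, label: str, activity: str,
                index: int) -> Trial:
    return Trial(
        data=data,
        fs=cfg.fs,
        label=label,
        activity_code=activity,
        subject_id="SY01",
        trial_id=f"R{index:04d}",
        sensor_layout=cfg.sensor_layout,
    )


# ---------------------------------------------------------------------------
# generators


def gen_adl(kind: str, cfg: SimConfig, seed: int | None = None,
            index: int = 0) -> Trial:
    """One activity-of-daily-living trial of the requested kind."""
    if kind not in ADL_KINDS:
        raise ValueError(f"unknown ADL kind {kind!r}; choose from {ADL_KINDS}")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs

    if kind == "still":
        mag = np.ones(n)
        orient = _orientation(n, rng, tilt_sd=0.01)
        acc = _accel_from_magnitude(mag, orient, cfg.noise_sd, rng)
        gyro = lambda r: _gyro(n, r, 0.5)
    elif kind in ("walk", "jog"):
        lo, hi = cfg.gait_freq
        f = rng.uniform(lo, (lo + hi) / 2) if kind == "walk" else rng.uniform((lo + hi) / 2, hi)
        phase = rng.uniform(0, 2 * np.pi)
        mag = 1.0 + cfg.gait_amplitude * np.sin(2 * np.pi * f * t + phase)
        orient = _orientation(n, rng)
        acc = _accel_from_magnitude(mag, orient, cfg.noise_sd, rng)
        gyro = lambda r: _gyro(n, r, 5.0)
    else:  # sit / lie: smooth postural transition with a bounded transient
        t0 = rng.uniform(0.3 * cfg.duration, 0.6 * cfg.duration)
        peak = rng.uniform(*cfg.transition_peak)
        width = cfg.transition_width
        bump = (peak - 1.0) * np.exp(-0.5 * ((t - t0) / width) ** 2)
        settle = 1.0 / (1.0 + np.exp(-(t - t0) / 0.1))  # sigmoid level-off
        mag = 1.0 + bump + 0.05 * settle * np.sin(2 * np.pi * 0.5 * t)
        orient = _orientation(n, rng)
        if kind == "lie":  # reorientation: vertical axis rotates toward horizontal
            mix = settle[:, None]
            target = np.array([0.7, 0.1, 0.7])
            orient = (1 - mix) * orient + mix * target
            orient /= np.linalg.norm(orient, axis=1, keepdims=True)
        acc = _accel_from_magnitude(mag, orient, cfg.noise_sd, rng)
        burst = slice(max(0, int((t0 - 0.3) * cfg.fs)), int((t0 + 0.3) * cfg.fs))
        gyro = lambda r: _gyro(n, r, 5.0, burst=burst, burst_amp=60.0)

    data = _assemble(acc, gyro, cfg, rng)
    return _make_trial(data, cfg, ADL, ADL_CODES[kind], index)


def gen_fall(cfg: SimConfig, seed: int | None = None, index: int = 0) -> Trial:
    """One fall trial: pre-fall gait, free-fall dip, impact spike, rest."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs

    event_len = cfg.dip_duration + 0.25  # dip + impact/settling margin
    latest = cfg.duration - event_len - 0.3
    if latest <= 0.1:
        raise ValueError("fall event does not fit in the configured duration")
    t_dip = rng.uniform(0.1, latest)          # free-fall onset
    t_impact = t_dip + cfg.dip_duration       # impact instant
    peak = rng.uniform(*cfg.impact_peak)

    # magnitude profile, piecewise
    f = rng.uniform(*cfg.gait_freq)
    mag = 1.0 + cfg.gait_amplitude * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    dip = (t >= t_dip) & (t < t_impact)
    ramp = (t[dip] - t_dip) / cfg.dip_duration
    mag[dip] = 1.0 + (cfg.dip_depth - 1.0) * np.minimum(1.0, 3.0 * ramp)
    spike = (peak - cfg.rest_level) * np.exp(-0.5 * ((t - t_impact) / cfg.impact_width) ** 2)
    after = t >= t_impact
    mag[after] = cfg.rest_level
    mag = np.where(after | ~dip, mag + spike, mag)

    orient = _orientation(n, rng)
    mix = 1.0 / (1.0 + np.exp(-(t - t_impact) / 0.08))[:, None]  # body topples
    target = np.array([0.8, 0.2, 0.55])
    orient = (1 - mix) * orient + mix * target
    orient /= np.linalg.norm(orient, axis=1, keepdims=True)

    noise = np.where(t >= t_impact + 0.3, cfg.rest_noise_sd, cfg.noise_sd)
    acc = mag[:, None] * orient + rng.normal(0.0, 1.0, (n, 3)) * noise[:, None]

    burst = slice(int(t_dip * cfg.fs), int(min(cfg.duration, t_impact + 0.2) * cfg.fs))
    gyro = lambda r: _gyro(n, r, 5.0, burst=burst, burst_amp=200.0)
    data = _assemble(acc, gyro, cfg, rng)
    return _make_trial(data, cfg, FALL, "F01", index)


def gen_dataset(n_falls: int, n_adls: int, cfg: SimConfig) -> DatasetManifest:
    """A labelled manifest with exact class counts.

    Per-trial seeds derive from the master seed, so the manifest is fully
    reproducible.  A ``confounder_fraction`` share of the ADLs (rounded) are
    abrupt sit/lie transitions; the rest cycle through walk/jog/still.
    """
    if n_falls < 0 or n_adls < 0:
        raise ValueError("counts must be non-negative")
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(n_falls + n_adls + 1)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in children]
    mix_rng = np.random.default_rng(seeds[-1])

    n_conf = int(round(cfg.confounder_fraction * n_adls))
    kinds = ["fall"] * n_falls
    kinds += [CONFOUNDER_KINDS[i % 2] for i in range(n_conf)]
    kinds += [("walk", "jog", "still")[i % 3] for i in range(n_adls - n_conf)]
    # interleave classes deterministically, as a recording campaign would mix
    # activities in time; a purely class-blocked order would make any
    # chronological train/test split single-class
    mix_rng.shuffle(kinds)
    trials: list[Trial] = []
    for i, kind in enumerate(kinds):
        if kind == "fall":
            trials.append(gen_fall(cfg, seed=seeds[i], index=i))
        else:
            trials.append(gen_adl(kind, cfg, seed=seeds[i], index=i))
    return DatasetManifest(trials, source="synthetic")


def threshold_baseline(trial: Trial, threshold: float = 2.5) -> str:
    """Classic magnitude-threshold detector: fall iff the peak acceleration
    vector magnitude of the primary accelerometer exceeds ``threshold`` g."""
    acc = None
    for name, _ in trial.sensor_layout:
        if name.startswith("acc"):
            acc = trial.sensor_channels(name)
            break
    if acc is None:
        raise ValueError("trial has no accelerometer channels")
    mag = np.linalg.norm(acc, axis=1)
    return FALL if float(mag.max()) > threshold else ADL
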