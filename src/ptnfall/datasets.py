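"""Readers and writers for wearable-IMU fall/ADL recordings.

Two on-disk dialects are supported:

* **sisfall** - one plain-text ``.txt`` file per trial, one comma-separated
  row of 9 integer ADC counts per 200 Hz sample (waist-worn unit: a wide-range
  accelerometer, a gyroscope and a second accelerometer, x/y/z each).  The
  file name ``<activity>_<subject>_<trial>.txt`` encodes the activity code
  (prefix ``D`` = ADL, ``F`` = fall), subject and trial.
* **unimib** - MATLAB ``.mat`` arrays of pre-windowed 3-axis smartphone
  accelerometer samples at 50 Hz (``acc_data``: one row per window, the three
  axes concatenated) with an integer label vector (``acc_labels``: 1-9 = ADL
  classes, 10-17 = fall classes).

Both are mapped onto a single :class:`Trial` container holding data in
physical units (acceleration in g, angular velocity in deg/s).
"""

from __future__ import annotations

import glob
import os
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.io import loadmat, savemat

__all__ = [
    "FALL",
    "ADL",
    "Trial",
    "DatasetManifest",
    "AdcSpec",
    "SISFALL_ADC",
    "IDENTITY_ADC",
    "read_sisfall_trial",
    "read_sisfall_dataset",
    "read_unimib_dataset",
    "write_fixture_dataset",
]

FALL = "fall"
ADL = "adl"

SISFALL_FS = 200.0
UNIMIB_FS = 50.0

SISFALL_LAYOUT = (("acc1", 3), ("gyro", 3), ("acc2", 3))
UNIMIB_LAYOUT = (("acc", 3),)


class TrialParseError(ValueError):
    """A recording file violates its dialect's layout."""


class LabelingError(ValueError):
    """An activity code cannot be mapped to fall/ADL."""


@dataclass
class Trial:
    """One labelled multichannel sensor recording.

    ``data`` is time x channels in physical units; ``sensor_layout`` is the
    ordered (sensor name, channel count) decomposition of the channel axis.
    """

    data: np.ndarray
    fs: float
    label: str
    activity_code: str
    subject_id: str
    trial_id: str
    sensor_layout: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        expected = sum(c for _, c in self.sensor_layout)
        if self.data.ndim != 2 or self.data.shape[0] < 1:
            raise ValueError("trial data must be a non-empty time x channels array")
        if self.data.shape[1] != expected:
            raise ValueError(
                f"channel count {self.data.shape[1]} does not match the sensor "
                f"layout total {expected}"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.label not in (FALL, ADL):
            raise LabelingError(f"label must be '{FALL}' or '{ADL}', got {self.label!r}")
        if not np.isfinite(self.data).all():
            raise ValueError("trial data contains NaN or Inf")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def sensor_channels(self, name: str) -> np.ndarray:
        """The channel block of one named sensor."""
        start = 0
        for sensor, count in self.sensor_layout:
            if sensor == name:
                return self.data[:, start:start + count]
            start += count
        raise KeyError(name)

    def group_key(self) -> str:
        """Identity of the source recording, ignoring subsegment suffixes."""
        return f"{self.activity_code}_{self.subject_id}_{self.trial_id.split('#')[0]}"


@dataclass
class DatasetManifest:
    """An ordered collection of trials from one source."""

    trials: list[Trial]
    source: str = "synthetic"

    @property
    def counts_by_label(self) -> dict[str, int]:
        counts = {FALL: 0, ADL: 0}
        for t in self.trials:
            counts[t.label] += 1
        return counts

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)


# ---------------------------------------------------------------------------
# ADC conversion


@dataclass(frozen=True)
class AdcSpec:
    """Linear ADC-count -> physical-unit maps, one (range, resolution) pair
    per sensor: value = (2 * range / 2**resolution) * raw."""

    sensors: tuple[tuple[str, float, int], ...]

    def scale(self, sensor: str) -> float:
        for name, rng, bits in self.sensors:
            if name == sensor:
                return 2.0 * rng / float(2**bits)
        raise KeyError(sensor)


# Sensor specs of the SisFall acquisition unit: ADXL345 (+-16 g, 13 bit),
# ITG3200 (+-2000 deg/s, 16 bit), MMA8451Q (+-8 g, 14 bit).
SISFALL_ADC = AdcSpec((("acc1", 16.0, 13), ("gyro", 2000.0, 16), ("acc2", 8.0, 14)))

# Unit-scale conversion, convenient for fixtures and round-trip tests.
IDENTITY_ADC = AdcSpec((("acc1", 0.5, 0), ("gyro", 0.5, 0), ("acc2", 0.5, 0)))

_SISFALL_NAME = re.compile(r"^([DF])([^_]*)_([^_]+)_([^_.]+)\.txt$")


def _parse_sisfall_name(filename: str) -> tuple[str, str, str, str]:
    m = _SISFALL_NAME.match(os.path.basename(filename))
    if not m:
        raise LabelingError(
            f"cannot parse activity/subject/trial from file name {filename!r}"
        )
    prefix, rest, subject, trial = m.groups()
    label = FALL if prefix == "F" else ADL
    return label, prefix + rest, subject, trial


def read_sisfall_trial(path: str, adc_spec: AdcSpec = SISFALL_ADC,
                       fs: float = SISFALL_FS) -> Trial:
    """Read one SisFall-dialect text trial into physical units."""
    label, activity, subject, trial_id = _parse_sisfall_name(path)
    rows: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip().rstrip(";")
            if not line:
                continue
            fields = [f.strip() for f in line.split(",")]
            if len(fields) != 9:
                raise TrialParseError(
                    f"{path}:{lineno}: expected 9 comma-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                rows.append([int(f) for f in fields])
            except ValueError as exc:
                raise TrialParseError(f"{path}:{lineno}: non-integer field") from exc
    if not rows:
        raise TrialParseError(f"{path}: empty trial file")
    raw = np.array(rows, dtype=np.float64)
    scales = np.concatenate([
        np.full(count, adc_spec.scale(name)) for name, count in SISFALL_LAYOUT
    ])
    return Trial(
        data=raw * scales,
        fs=fs,
        label=label,
        activity_code=activity,
        subject_id=subject,
        trial_id=trial_id,
        sensor_layout=SISFALL_LAYOUT,
    )


def read_sisfall_dataset(path: str, adc_spec: AdcSpec = SISFALL_ADC,
                         fs: float = SISFALL_FS) -> DatasetManifest:
    """Read every ``.txt`` trial under a directory, file-name sorted."""
    files = sorted(glob.glob(os.path.join(path, "*.txt")))
    trials = [read_sisfall_trial(f, adc_spec, fs) for f in files]
    return DatasetManifest(trials, source="sisfall")


def read_unimib_dataset(path: str) -> DatasetManifest:
    """Read a UniMiB-dialect directory (acc_data.mat + acc_labels.mat).

    Every stored window becomes one 50 Hz, 3-channel :class:`Trial`; the 17
    fine activity labels collapse to ADL (1-9) vs fall (10-17).
    """
    data_file = os.path.join(path, "acc_data.mat")
    labels_file = os.path.join(path, "acc_labels.mat")
    for f in (data_file, labels_file):
        if not os.path.exists(f):
            raise FileNotFoundError(f"missing UniMiB array file: {f}")
    data = np.atleast_2d(loadmat(data_file)["acc_data"]).astype(np.float64)
    labels = np.asarray(loadmat(labels_file)["acc_labels"]).ravel().astype(int)
    if data.shape[0] != labels.shape[0]:
        raise TrialParseError(
            f"{path}: {data.shape[0]} windows but {labels.shape[0]} labels"
        )
    if data.shape[1] % 3 != 0:
        raise TrialParseError(
            f"{path}: row length {data.shape[1]} is not divisible by 3 axes"
        )
    t = data.shape[1] // 3
    trials = []
    for i, (row, code) in enumerate(zip(data, labels)):
        if not 1 <= code <= 17:
            raise LabelingError(f"{path}: window {i}: unknown class code {code}")
        label = ADL if code <= 9 else FALL
        window = row.reshape(3, t).T  # axes stored concatenated x|y|z
        trials.append(Trial(
            data=window,
            fs=UNIMIB_FS,
            label=label,
            activity_code=f"U{code:02d}",
            subject_id="NA",
            trial_id=f"W{i:05d}",
            sensor_layout=UNIMIB_LAYOUT,
        ))
    return DatasetManifest(trials, source="unimib")


# ---------------------------------------------------------------------------
# fixture writer


def write_fixture_dataset(manifest: DatasetManifest, path: str, dialect: str,
                          adc_spec: AdcSpec = SISFALL_ADC) -> list[str]:
    """Write a manifest to disk in a reader-compatible dialect.

    Round-tripping through the matching reader reproduces the data to ADC
    quantisation (sisfall) or exactly (unimib), and labels exactly.
    """
    os.makedirs(path, exist_ok=True)
    if dialect == "sisfall":
        return _write_sisfall(manifest, path, adc_spec)
    if dialect == "unimib":
        return _write_unimib(manifest, path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _write_sisfall(manifest: DatasetManifest, path: str, adc_spec: AdcSpec) -> list[str]:
    scales = np.concatenate([
        np.full(count, adc_spec.scale(name)) for name, count in SISFALL_LAYOUT
    ])
    written = []
    for trial in manifest:
        if trial.data.shape[1] != 9:
            raise ValueError(
                f"sisfall dialect requires 9 channels, trial "
                f"{trial.group_key()} has {trial.data.shape[1]}"
            )
        raw = np.rint(trial.data / scales).astype(np.int64)
        name = f"{trial.activity_code}_{trial.subject_id}_{trial.trial_id}.txt"
        fpath = os.path.join(path, name)
        with open(fpath, "w") as fh:
            for row in raw:
                fh.write(",".join(str(v) for v in row) + ";\n")
        written.append(fpath)
    return written


def _write_unimib(manifest: DatasetManifest, path: str) -> list[str]:
    lengths = {t.n_samples for t in manifest}
    if len(lengths) > 1:
        raise ValueError("unimib dialect requires equal-length windows")
    rows, labels = [], []
    for trial in manifest:
        if trial.data.shape[1] != 3:
            raise ValueError(
                f"unimib dialect requires 3 channels, trial "
                f"{trial.group_key()} has {trial.data.shape[1]}"
            )
        rows.append(trial.data.T.reshape(-1))  # concatenate axes x|y|z
        code = int(trial.activity_code[1:]) if trial.activity_code.startswith("U") \
            else (10 if trial.label == FALL else 1)
        labels.append(code)
    data_file = os.path.join(path, "acc_data.mat")
    labels_file = os.path.join(path, "acc_labels.mat")
    savemat(data_file, {"acc_data": np.vstack(rows)})
    savemat(labels_file, {"acc_labels": np.array(labels, dtype=np.int64)})
    return [data_file, labels_file]
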