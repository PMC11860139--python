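"""Reading, harmonizing and windowing 6-channel smartphone IMU recordings.

A recording carries three accelerometer axes (m/s^2) and three gyroscope axes
(rad/s) in the fixed channel order ``ax, ay, az, gx, gy, gz``.  Heterogeneous
corpora are harmonized to 100 Hz and cut into non-overlapping 2-second windows
of shape (200, 6) — the unit every classifier downstream consumes.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

#: canonical channel order for every (n, 6) sample block
CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz")

#: recognized source labels
LABELS = ("gait", "autowalker1", "autowalker2")

#: multi-class map — genuine gait is class 0, one class per auto-walker geometry
MULTICLASS_MAP = {"gait": 0, "autowalker1": 1, "autowalker2": 2}

#: binary map — genuine = 1 (positive class), any auto-walker = 0
BINARY_MAP = {"gait": 1, "autowalker1": 0, "autowalker2": 0}

WINDOW_LEN = 200
TARGET_RATE = 100.0

G_TO_MS2 = 9.80665
DEG_TO_RAD = np.pi / 180.0


class DialectError(ValueError):
    """Raised when a column-mapping config does not match the file."""


class ParseError(ValueError):
    """Raised for a malformed cell or a non-monotone timestamp, naming the row."""


@dataclass
class GaitRecording:
    """A variable-length 6-channel IMU time series.

    samples : (n, 6) float array in canonical channel order and units
    rate : sampling frequency in Hz
    source_label : one of ``gait``, ``autowalker1``, ``autowalker2``
    subject_id : opaque subject or device identifier
    timestamps : optional strictly-increasing sample times in seconds
    """

    samples: np.ndarray
    rate: float
    source_label: str
    subject_id: str
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 6 or len(self.samples) == 0:
            raise ValueError("samples must be a non-empty (n, 6) array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if self.source_label not in LABELS:
            raise ValueError(f"unknown source_label {self.source_label!r}")
        if self.timestamps is not None:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if len(self.timestamps) != len(self.samples):
                raise ValueError("timestamps must align with samples")
            if np.any(np.diff(self.timestamps) <= 0):
                raise ValueError("timestamps must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return (len(self.samples) - 1) / self.rate


@dataclass
class Window:
    """A fixed (200, 6) segment — two seconds at 100 Hz; the classification unit."""

    values: np.ndarray
    label: str
    origin: tuple[str, int] = ("", 0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (WINDOW_LEN, 6):
            raise ValueError(f"window must be ({WINDOW_LEN}, 6), got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("window values must be finite")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class LabeledDataset:
    """A stack of windows with labels, group ids and split/section assignment.

    windows : (n, 200, 6) array
    labels : (n,) source labels (strings from ``LABELS``)
    groups : (n,) subject or phone identifier per window
    split : (n,) one of ``train``, ``test``, ``unseen``
    section : (n,) evaluation section tag — ``seen`` for the train/test pool,
        ``unseen_subject`` / ``unseen_phone`` for generalization sets and
        ``overtime`` for sessions recorded after a time gap
    """

    windows: np.ndarray
    labels: np.ndarray
    groups: np.ndarray
    split: np.ndarray
    section: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.groups = np.asarray(self.groups, dtype=object)
        self.split = np.asarray(self.split, dtype=object)
        if self.section is None:
            self.section = np.full(len(self.labels), "seen", dtype=object)
        self.section = np.asarray(self.section, dtype=object)
        n = len(self.windows)
        if self.windows.shape[1:] != (WINDOW_LEN, 6):
            raise ValueError("windows must be (n, 200, 6)")
        for name, arr in (("labels", self.labels), ("groups", self.groups),
                          ("split", self.split), ("section", self.section)):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} windows")
        bad = set(self.split) - {"train", "test", "unseen"}
        if bad:
            raise ValueError(f"invalid split values {bad}")

    def __len__(self) -> int:
        return len(self.windows)

    def multiclass_labels(self) -> np.ndarray:
        return np.array([MULTICLASS_MAP[l] for l in self.labels], dtype=int)

    def binary_labels(self) -> np.ndarray:
        """Genuine gait = 1 (positive), auto-walker = 0."""
        return np.array([BINARY_MAP[l] for l in self.labels], dtype=int)

    def subset(self, mask: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(self.windows[mask], self.labels[mask],
                              self.groups[mask], self.split[mask], self.section[mask])

    def in_split(self, split: str) -> "LabeledDataset":
        return self.subset(self.split == split)

    def in_section(self, section: str) -> "LabeledDataset":
        return self.subset(self.section == section)

    def to_hdf5(self, path) -> None:
        str_dt = h5py.string_dtype()
        with h5py.File(path, "w") as f:
            f.create_dataset("windows", data=self.windows, compression="gzip")
            for name in ("labels", "groups", "split", "section"):
                f.create_dataset(name, data=[str(v) for v in getattr(self, name)],
                                 dtype=str_dt)

    @classmethod
    def from_hdf5(cls, path) -> "LabeledDataset":
        with h5py.File(path, "r") as f:
            return cls(
                windows=f["windows"][...],
                labels=f["labels"].asstr()[...],
                groups=f["groups"].asstr()[...],
                split=f["split"].asstr()[...],
                section=f["section"].asstr()[...],
            )


def concat_datasets(parts: Sequence[LabeledDataset]) -> LabeledDataset:
    if not parts:
        raise ValueError("no datasets to concatenate")
    return LabeledDataset(
        np.concatenate([p.windows for p in parts]),
        np.concatenate([p.labels for p in parts]),
        np.concatenate([p.groups for p in parts]),
        np.concatenate([p.split for p in parts]),
        np.concatenate([p.section for p in parts]),
    )


def aggregate_shape(per_corpus_counts: Iterable[int],
                    window_len: int = WINDOW_LEN, n_channels: int = 6) -> tuple[int, int, int]:
    """Combined array shape when per-corpus window stacks are concatenated.

    Bookkeeping helper: feeding the per-corpus window counts of a multi-corpus
    training pool returns the shape of the pooled (n, 200, 6) tensor.
    """
    return (int(sum(per_corpus_counts)), window_len, n_channels)


def read_recording(path, dialect: Mapping) -> GaitRecording:
    """Read a delimited-text IMU recording using a column-mapping dialect.

    The dialect maps the six canonical channels to file columns and declares
    units and provenance::

        {"columns": {"ax": "accX", ..., "gz": "gyrZ"},
         "timestamp": "time",            # optional column name
         "accel_in_g": False,            # convert g -> m/s^2
         "gyro_in_deg": False,           # convert deg/s -> rad/s
         "label": "gait", "subject_id": "s01",
         "rate": 100.0}                  # optional; else inferred from timestamps

    Recordings shorter than one window are returned with a warning.
    """
    try:
        colmap = dict(dialect["columns"])
    except KeyError as e:
        raise DialectError("dialect must provide a 'columns' mapping") from e
    missing = [ch for ch in CHANNELS if ch not in colmap]
    if missing:
        raise DialectError(f"dialect missing channel columns: {missing}")

    sep = dialect.get("sep", ",")
    df = pd.read_csv(path, sep=sep)
    wanted = [colmap[ch] for ch in CHANNELS]
    ts_col = dialect.get("timestamp")
    if ts_col:
        wanted = wanted + [ts_col]
    absent = [c for c in wanted if c not in df.columns]
    if absent:
        raise DialectError(f"file {path} lacks columns {absent}; has {list(df.columns)}")

    numeric = df[wanted].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(f"non-numeric cell at data row {row} in {path}")

    samples = numeric[[colmap[ch] for ch in CHANNELS]].to_numpy(dtype=float)
    if dialect.get("accel_in_g"):
        samples[:, :3] *= G_TO_MS2
    if dialect.get("gyro_in_deg"):
        samples[:, 3:] *= DEG_TO_RAD

    timestamps = None
    rate = dialect.get("rate")
    if ts_col:
        timestamps = numeric[ts_col].to_numpy(dtype=float)
        diffs = np.diff(timestamps)
        nonmono = np.flatnonzero(diffs <= 0)
        if nonmono.size:
            raise ParseError(
                f"timestamp column not strictly increasing at row {int(nonmono[0]) + 1} in {path}")
        if rate is None:
            rate = infer_sampling_rate(timestamps)
    if rate is None:
        raise DialectError("dialect must give 'rate' or a 'timestamp' column")

    if len(samples) < WINDOW_LEN:
        warnings.warn(f"recording {path} has only {len(samples)} samples (< {WINDOW_LEN}); "
                      "it will yield no windows", stacklevel=2)
    return GaitRecording(samples, float(rate), dialect.get("label", "gait"),
                         str(dialect.get("subject_id", "unknown")), timestamps)


def infer_sampling_rate(timestamps: Sequence[float]) -> int:
    """Sampling rate in integer Hz from timestamps, via the median interval.

    The median of successive differences is robust to occasional dropped
    samples, so a single long gap does not bias the estimate.
    """
    ts = np.asarray(timestamps, dtype=float)
    if ts.ndim != 1 or len(ts) < 3:
        raise ValueError("need at least 3 timestamps")
    diffs = np.diff(ts)
    if np.any(diffs <= 0):
        raise ValueError("timestamps must be strictly increasing")
    return int(round(1.0 / float(np.median(diffs))))


def resample(recording: GaitRecording, target_rate: float = TARGET_RATE) -> GaitRecording:
    """Linearly interpolate every channel onto a uniform grid at ``target_rate``.

    The output spans the original duration; when the rates already match the
    samples are returned unchanged.  Linear interpolation is adequate here
    because harmonization only ever upsamples (50 -> 100 Hz).
    """
    if not target_rate > 0:
        raise ValueError("target_rate must be positive")
    if target_rate == recording.rate:
        return GaitRecording(recording.samples.copy(), recording.rate,
                             recording.source_label, recording.subject_id)
    n = len(recording.samples)
    duration = (n - 1) / recording.rate
    t_old = np.arange(n) / recording.rate
    n_new = int(np.floor(duration * target_rate)) + 1
    t_new = np.arange(n_new) / target_rate
    out = np.column_stack([np.interp(t_new, t_old, recording.samples[:, c]) for c in range(6)])
    return GaitRecording(out, float(target_rate), recording.source_label, recording.subject_id)


def segment(recording: GaitRecording, window_len: int = WINDOW_LEN,
            stride: int | None = None) -> list[Window]:
    """Cut a 100 Hz recording into consecutive fixed-length windows.

    Non-overlapping by default (stride = window_len); the trailing remainder
    shorter than one window is dropped, so an n-sample recording yields
    floor(n / window_len) windows.  A too-short recording yields an empty list.
    """
    if abs(recording.rate - TARGET_RATE) > 1e-9:
        raise ValueError(f"segment expects a {TARGET_RATE:g} Hz recording "
                         f"(got {recording.rate:g} Hz); resample first")
    if stride is None:
        stride = window_len
    if window_len <= 0 or stride <= 0:
        raise ValueError("window_len and stride must be positive")
    out: list[Window] = []
    n = len(recording.samples)
    for start in range(0, n - window_len + 1, stride):
        out.append(Window(recording.samples[start:start + window_len],
                          recording.source_label, (recording.subject_id, start)))
    return out


def _group_rng(seed: int, group: str) -> np.random.Generator:
    # stable per-group stream: the assignment of one subject never depends on
    # which other subjects are present
    return np.random.default_rng([seed, zlib.crc32(group.encode())])


def split_by_ratio(groups: Sequence[str], ratio: float = 0.8, seed: int = 0,
                   unseen_groups: Iterable[str] = ()) -> np.ndarray:
    """Assign each window to train/test/unseen, splitting within each group.

    Every subject (or device) keeps ``floor(ratio * n)`` of its windows for
    training and the rest for testing, so the split never pools across
    subjects.  Groups listed in ``unseen_groups`` contribute all their windows
    to the unseen split.  Deterministic under ``seed``.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    groups = np.asarray(groups, dtype=object)
    unseen = set(unseen_groups)
    out = np.empty(len(groups), dtype=object)
    for g in sorted(set(groups)):
        idx = np.flatnonzero(groups == g)
        if idx.size == 0:
            warnings.warn(f"empty group {g!r} skipped", stacklevel=2)
            continue
        if g in unseen:
            out[idx] = "unseen"
            continue
        perm = _group_rng(seed, str(g)).permutation(idx.size)
        n_train = int(np.floor(ratio * idx.size))
        out[idx[perm[:n_train]]] = "train"
        out[idx[perm[n_train:]]] = "test"
    return out


def windows_to_dataset(windows: Sequence[Window], split: Sequence[str] | None = None,
                       section: Sequence[str] | None = None) -> LabeledDataset:
    """Stack Window objects into an array-backed LabeledDataset."""
    if not windows:
        raise ValueError("no windows")
    values = np.stack([w.values for w in windows])
    labels = np.array([w.label for w in windows], dtype=object)
    groups = np.array([w.origin[0] for w in windows], dtype=object)
    if split is None:
        split = np.full(len(windows), "train", dtype=object)
    return LabeledDataset(values, labels, groups, np.asarray(split, dtype=object),
                          None if section is None else np.asarray(section, dtype=object))
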