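"""Hand-crafted window features separating human gait from mechanical rocking.

Each of the six channels of a (200, 6) window contributes 29 features — 19
statistical summaries and 10 peak-structure values — for 174 in total.  The
statistical block captures amplitude, spread, shape and signal complexity;
the peak block captures the timing and height pattern of the three tallest
local maxima, where human gait shows cycle-to-cycle variability that a
rocking device lacks.

Frozen conventions (documented because several quantities admit variants):

* variance / standard deviation are population-normalized (divide by n);
* ``iav`` is the sum of |x| and ``mav`` its mean, so ``iav = 200 * mav``;
* skewness is ``m3 / m2**1.5`` and kurtosis is excess (``m4 / m2**2 - 3``);
  both are defined as 0 for a zero-variance signal;
* the four moving-average summaries are the mean of the signal (or of |x|)
  smoothed with a width-5 unweighted or width-5 triangular kernel;
* the four entropies are: Shannon entropy of a 16-bin amplitude histogram,
  normalized spectral entropy of the DC-free power spectrum, sample entropy
  (m=2, r=0.2*sd), and normalized permutation entropy (order 3, delay 1);
  each is defined as 0 for a degenerate (constant) signal;
* a peak is a strict local maximum; for a plateau the first sample of the
  plateau is the index; height ties are broken toward the earlier index;
  missing peak slots are the sentinel (index -1, height 0) and differences
  involving a sentinel are 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sp_signal
from sklearn.ensemble import RandomForestClassifier

from .signals_io import CHANNELS, WINDOW_LEN, LabeledDataset, Window

SMA_WIDTH = 5
HIST_BINS = 16
SAMPEN_M = 2
SAMPEN_R_FACTOR = 0.2
PERMEN_ORDER = 3

STAT_NAMES = (
    "iav", "mav", "variance", "rms", "sd", "mean", "mad",
    "sma_simple", "sma_advanced", "sma_abs_simple", "sma_abs_advanced",
    "skewness", "kurtosis", "iqr", "energy",
    "entropy_hist", "entropy_spectral", "entropy_sample", "entropy_perm",
)

PEAK_NAMES = (
    "peak1_idx", "peak1_height", "peak2_idx", "peak2_height",
    "peak3_idx", "peak3_height",
    "peak_idx_diff21", "peak_height_diff21", "peak_idx_diff32", "peak_height_diff32",
)

#: canonical 174 feature names, channel-major: all 29 of ax, then ay, ... gz
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{ch}_{name}" for ch in CHANNELS for name in STAT_NAMES + PEAK_NAMES
)

N_FEATURES = len(FEATURE_NAMES)  # 29 * 6 = 174

_EPS = 1e-12


@dataclass
class PeakSet:
    """Indices and heights of the three tallest local maxima, ordered by index.

    Missing slots hold the sentinel index -1 / height 0.
    """

    indices: np.ndarray  # (3,) int
    heights: np.ndarray  # (3,) float

    @property
    def n_peaks(self) -> int:
        return int(np.sum(self.indices >= 0))

    def to_features(self) -> np.ndarray:
        x1, x2, x3 = self.indices
        y1, y2, y3 = self.heights
        d21 = (x2 - x1, y2 - y1) if x1 >= 0 and x2 >= 0 else (0, 0.0)
        d32 = (x3 - x2, y3 - y2) if x2 >= 0 and x3 >= 0 else (0, 0.0)
        return np.array([x1, y1, x2, y2, x3, y3, d21[0], d21[1], d32[0], d32[1]],
                        dtype=float)


@dataclass
class FeatureVector:
    """The 174-value representation of one window, name-aligned and ordered."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features, got {self.values.shape}")


def _moving_average_mean(x: np.ndarray, weights: np.ndarray) -> float:
    smoothed = np.convolve(x, weights / weights.sum(), mode="valid")
    return float(np.mean(smoothed))


def _hist_entropy(x: np.ndarray) -> float:
    if np.ptp(x) < _EPS:
        return 0.0
    counts, _ = np.histogram(x, bins=HIST_BINS)
    p = counts[counts > 0] / len(x)
    return float(-np.sum(p * np.log(p)))


def _spectral_entropy(x: np.ndarray) -> float:
    power = np.abs(np.fft.rfft(x)) ** 2
    power = power[1:]  # drop DC so a constant offset carries no information
    total = power.sum()
    if total < _EPS:
        return 0.0
    p = power / total
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)) / np.log(len(power)))


def _sample_entropy(x: np.ndarray, m: int = SAMPEN_M, r_factor: float = SAMPEN_R_FACTOR) -> float:
    sd = float(np.std(x))
    if sd < _EPS:
        return 0.0
    r = r_factor * sd

    def count_matches(order: int) -> int:
        templ = sliding_window_view(x, order)
        # Chebyshev distance between all template pairs, i < j
        d = np.abs(templ[:, None, :] - templ[None, :, :]).max(axis=2)
        within = d <= r
        n = len(templ)
        return int((within.sum() - n) // 2)

    b = count_matches(m)
    a = count_matches(m + 1)
    if a == 0 or b == 0:
        return 0.0
    return float(-np.log(a / b))


def _permutation_entropy(x: np.ndarray, order: int = PERMEN_ORDER) -> float:
    if np.ptp(x) < _EPS:
        return 0.0
    windows = sliding_window_view(x, order)
    # ordinal pattern of each window; stable argsort resolves ties by position
    ranks = np.argsort(windows, axis=1, kind="stable")
    codes = ranks @ (order ** np.arange(order))
    _, counts = np.unique(codes, return_counts=True)
    p = counts / len(codes)
    return float(-np.sum(p * np.log(p)) / np.log(math.factorial(order)))


def channel_statistics(x: np.ndarray) -> np.ndarray:
    """The 19 statistical features of one 200-sample channel (see module docs)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or not np.all(np.isfinite(x)):
        raise ValueError("channel must be a finite 1-D array")
    n = len(x)
    absx = np.abs(x)
    iav = float(absx.sum())
    mav = iav / n
    mean = float(x.mean())
    centered = x - mean
    m2 = float(np.mean(centered ** 2))
    variance = m2
    sd = float(np.sqrt(variance))
    energy = float(np.sum(x ** 2))
    rms = float(np.sqrt(energy / n))
    mad = float(np.median(np.abs(x - np.median(x))))
    box = np.ones(SMA_WIDTH)
    tri = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
    sma_simple = _moving_average_mean(x, box)
    sma_advanced = _moving_average_mean(x, tri)
    sma_abs_simple = _moving_average_mean(absx, box)
    sma_abs_advanced = _moving_average_mean(absx, tri)
    if m2 < _EPS:
        skewness = 0.0
        kurtosis = 0.0
    else:
        skewness = float(np.mean(centered ** 3) / m2 ** 1.5)
        kurtosis = float(np.mean(centered ** 4) / m2 ** 2 - 3.0)
    q1, q3 = np.percentile(x, [25, 75])
    iqr = float(q3 - q1)
    return np.array([
        iav, mav, variance, rms, sd, mean, mad,
        sma_simple, sma_advanced, sma_abs_simple, sma_abs_advanced,
        skewness, kurtosis, iqr, energy,
        _hist_entropy(x), _spectral_entropy(x), _sample_entropy(x),
        _permutation_entropy(x),
    ])


def find_peaks(x: np.ndarray) -> PeakSet:
    """Locate the three tallest local maxima of a channel, reordered by index.

    Strict local maxima only; a plateau counts once, at its first sample.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or not np.all(np.isfinite(x)):
        raise ValueError("channel must be a finite 1-D array")
    locs, props = sp_signal.find_peaks(x, plateau_size=1)
    if locs.size and "left_edges" in props:
        locs = props["left_edges"]
    heights = x[locs] if locs.size else np.empty(0)
    # tallest three; stable sort on -height keeps the earlier index on ties
    order = np.argsort(-heights, kind="stable")[:3]
    chosen = np.sort(locs[order])
    indices = np.full(3, -1, dtype=int)
    peak_heights = np.zeros(3)
    indices[: len(chosen)] = chosen
    peak_heights[: len(chosen)] = x[chosen]
    return PeakSet(indices, peak_heights)


def extract_features(window: Window | np.ndarray) -> FeatureVector:
    """The full 174-value feature vector of one (200, 6) window.

    Channel-major layout: the 19 statistics then the 10 peak values of ``ax``,
    then of ``ay``, ..., then of ``gz``.
    """
    values = window.values if isinstance(window, Window) else np.asarray(window, dtype=float)
    if values.shape != (WINDOW_LEN, 6):
        raise ValueError(f"expected a ({WINDOW_LEN}, 6) window, got {values.shape}")
    blocks = []
    for c in range(6):
        channel = values[:, c]
        blocks.append(channel_statistics(channel))
        blocks.append(find_peaks(channel).to_features())
    return FeatureVector(np.concatenate(blocks))


def feature_matrix(dataset: LabeledDataset | np.ndarray) -> pd.DataFrame:
    """Feature vectors for every window, as a DataFrame with canonical columns."""
    windows = dataset.windows if isinstance(dataset, LabeledDataset) else np.asarray(dataset)
    rows = np.stack([extract_features(w).values for w in windows])
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES))


def rank_features(features, labels: Sequence, seed: int = 0,
                  n_estimators: int = 200) -> list[tuple[str, float]]:
    """Rank features by mean impurity-based importance of a random forest.

    Returns (name, importance) pairs sorted by decreasing importance; the
    importances sum to 1.  Deterministic under ``seed``.
    """
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = list(FEATURE_NAMES) if X.shape[1] == N_FEATURES else [
            f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes to rank features")
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    rf.fit(X, y)
    imp = rf.feature_importances_
    order = np.argsort(-imp, kind="stable")
    return [(names[i], float(imp[i])) for i in order]
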