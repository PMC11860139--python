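"""Independent direct-formula oracles used to cross-check the package.

Every function here is written straight from the definition of the quantity
(loops, explicit DFT, scipy.stats reference routines) and deliberately shares
no code with the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def stat_features_oracle(x: np.ndarray) -> dict[str, float]:
    """The 19 statistical channel features, each from its textbook definition."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    mean = math.fsum(x) / n
    var = math.fsum((v - mean) ** 2 for v in x) / n
    energy = math.fsum(v * v for v in x)
    out = {
        "iav": math.fsum(abs(v) for v in x),
        "mav": math.fsum(abs(v) for v in x) / n,
        "variance": var,
        "rms": math.sqrt(energy / n),
        "sd": math.sqrt(var),
        "mean": mean,
        "mad": float(stats.median_abs_deviation(x)),
        "sma_simple": _sma_oracle(x, np.ones(5) / 5),
        "sma_advanced": _sma_oracle(x, np.array([1, 2, 3, 2, 1]) / 9),
        "sma_abs_simple": _sma_oracle(np.abs(x), np.ones(5) / 5),
        "sma_abs_advanced": _sma_oracle(np.abs(x), np.array([1, 2, 3, 2, 1]) / 9),
        "skewness": float(stats.skew(x, bias=True)) if var > 1e-12 else 0.0,
        "kurtosis": float(stats.kurtosis(x, bias=True)) if var > 1e-12 else 0.0,
        "iqr": float(stats.iqr(x)),
        "energy": energy,
        "entropy_hist": _hist_entropy_oracle(x),
        "entropy_spectral": _spectral_entropy_oracle(x),
        "entropy_sample": _sample_entropy_oracle(x),
        "entropy_perm": _perm_entropy_oracle(x),
    }
    return out


def _sma_oracle(x: np.ndarray, w: np.ndarray) -> float:
    k = len(w)
    vals = [math.fsum(w[j] * x[i + j] for j in range(k)) for i in range(len(x) - k + 1)]
    return math.fsum(vals) / len(vals)


def _hist_entropy_oracle(x: np.ndarray) -> float:
    if np.ptp(x) < 1e-12:
        return 0.0
    counts, _ = np.histogram(x, bins=16)
    return float(stats.entropy(counts))  # scipy normalizes and uses natural log


def _spectral_entropy_oracle(x: np.ndarray) -> float:
    n = len(x)
    k = np.arange(1, n // 2 + 1)  # positive frequencies, DC excluded
    j = np.arange(n)
    dft = np.exp(-2j * np.pi * np.outer(k, j) / n) @ x  # explicit DFT matrix
    power = np.abs(dft) ** 2
    if power.sum() < 1e-12:
        return 0.0
    p = power / power.sum()
    return float(stats.entropy(p) / math.log(len(power)))


def _sample_entropy_oracle(x: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    sd = float(np.std(x))
    if sd < 1e-12:
        return 0.0
    r = r_factor * sd

    def matches(order: int) -> int:
        n_t = len(x) - order + 1
        count = 0
        for i in range(n_t):
            ti = x[i:i + order]
            for j in range(i + 1, n_t):
                if np.max(np.abs(ti - x[j:j + order])) <= r:
                    count += 1
        return count

    b = matches(m)
    a = matches(m + 1)
    if a == 0 or b == 0:
        return 0.0
    return -math.log(a / b)


def _perm_entropy_oracle(x: np.ndarray, order: int = 3) -> float:
    if np.ptp(x) < 1e-12:
        return 0.0
    counts: dict[tuple, int] = {}
    for i in range(len(x) - order + 1):
        pattern = tuple(np.argsort(x[i:i + order], kind="stable"))
        counts[pattern] = counts.get(pattern, 0) + 1
    total = sum(counts.values())
    h = -math.fsum(c / total * math.log(c / total) for c in counts.values())
    return h / math.log(math.factorial(order))


def local_maxima_oracle(x: np.ndarray) -> list[tuple[int, float]]:
    """All interior local maxima by brute-force scan; plateaus at first sample."""
    x = np.asarray(x, dtype=float)
    peaks = []
    i = 1
    n = len(x)
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] < x[i]:
                peaks.append((i, float(x[i])))
            i = j + 1
        else:
            i += 1
    return peaks


def top3_peaks_oracle(x: np.ndarray) -> tuple[list[int], list[float]]:
    """Indices/heights of the three tallest maxima, re-ordered by index."""
    peaks = local_maxima_oracle(x)
    peaks.sort(key=lambda p: (-p[1], p[0]))
    chosen = sorted(peaks[:3])
    idx = [p[0] for p in chosen] + [-1] * (3 - len(chosen))
    hts = [p[1] for p in chosen] + [0.0] * (3 - len(chosen))
    return idx, hts


def fnr_fpr_oracle(scores, labels, thresholds):
    """FNR/FPR at each threshold by explicit counting."""
    fnr, fpr = [], []
    for t in thresholds:
        aw = [s for s, y in zip(scores, labels) if y == 0]
        gen = [s for s, y in zip(scores, labels) if y == 1]
        fnr.append(sum(1 for s in aw if s > t) / len(aw))
        fpr.append(sum(1 for s in gen if s <= t) / len(gen))
    return np.array(fnr), np.array(fpr)
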