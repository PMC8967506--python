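"""Gray-level histograms, exponential smoothing, peaks, and the
maximum-entropy (Kapur) threshold.

The segmentation pipeline separates the dark blood pool from bright
myocardium by the gray level t* that maximizes the sum of the Shannon
entropies of the two classes obtained by splitting the 256-bin histogram at
t. Within each class the bin masses are renormalized to probabilities
k_i = g(i) / sum_class g(j) and the class entropy is -sum k_i ln k_i (natural
log; 0 ln 0 := 0). A class entropy is maximal, ln m, exactly when its m
nonzero bins carry equal mass.

An exponentially smoothed histogram Y(a) = (1-beta) Y(a-1) + beta H(a) is
used only for locating histogram peaks (the raw counts fluctuate strongly at
neighbouring gray levels); the threshold itself is always computed on the raw
integer histogram.

Conventions fixed here for reproducibility:

* the split at t puts gray levels [0, t] in class 1 and [t+1, 255] in
  class 2, so candidate thresholds run from the first nonzero bin to one
  below the last nonzero bin (splits leaving a class empty are excluded from
  the search, not scored as zero);
* ties are broken by the smallest maximizing t.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateInputError, InvalidThresholdError, ParameterError
from .image_io import BinaryMask, GrayImage

__all__ = [
    "Histogram",
    "NormalizedHistogram",
    "SmoothedHistogram",
    "ThresholdResult",
    "compute_histogram",
    "normalize_histogram",
    "smooth_histogram",
    "find_peaks",
    "class_entropies",
    "max_entropy_threshold",
    "histogram_to_csv",
]

N_BINS = 256


@dataclass(frozen=True)
class Histogram:
    """256-bin gray-level counts g(i) and their total."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (N_BINS,):
            raise ParameterError(f"histogram needs exactly {N_BINS} bins, got {c.shape}")
        if (c < 0).any():
            raise ParameterError("negative histogram count")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class NormalizedHistogram:
    """Bin probabilities k(i), summing to 1."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=np.float64)
        if p.shape != (N_BINS,):
            raise ParameterError(f"expected {N_BINS} probabilities, got {p.shape}")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
            raise ParameterError("probabilities must be non-negative and sum to 1")
        object.__setattr__(self, "probs", p)


@dataclass(frozen=True)
class SmoothedHistogram:
    """Exponentially smoothed bin values Y(a) with smoothing constant beta."""

    values: np.ndarray
    beta: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (N_BINS,):
            raise ParameterError(f"expected {N_BINS} values, got {v.shape}")
        if not (0.0 < self.beta <= 1.0):
            raise ParameterError(f"beta must lie in (0, 1], got {self.beta}")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ThresholdResult:
    """Maximum-entropy threshold with its diagnostic entropy curve.

    Attributes
    ----------
    threshold : int
        The maximizing gray level t*; class 1 is [0, t*], class 2 is
        [t*+1, 255].
    entropy_curve : np.ndarray
        D(t) = H1(t) + H2(t) in nats for every t (NaN where a class would
        be empty).
    d1, d2 : float
        The two class entropies at t*.
    """

    threshold: int
    entropy_curve: np.ndarray
    d1: float
    d2: float


def compute_histogram(image: GrayImage, roi: BinaryMask | None = None) -> Histogram:
    """Count pixels per gray level, optionally restricted to a region mask."""
    px = image.pixels
    if roi is not None:
        if roi.shape != image.shape:
            raise ParameterError("ROI mask shape differs from image shape")
        px = px[roi.pixels]
    return Histogram(np.bincount(px.ravel(), minlength=N_BINS))


def normalize_histogram(hist: Histogram) -> NormalizedHistogram:
    """Convert counts to probabilities k(i) = g(i) / total."""
    total = hist.total
    if total == 0:
        raise DegenerateInputError("empty histogram cannot be normalized")
    return NormalizedHistogram(hist.counts / total)


def smooth_histogram(
    hist: Histogram, beta: float, y0: float | None = None
) -> SmoothedHistogram:
    """Exponentially smooth the counts: Y(a) = (1-beta) Y(a-1) + beta H(a).

    ``y0`` seeds the recurrence as Y(-1); it defaults to counts[0], so the
    first smoothed value equals the first raw count.
    """
    if not (0.0 < beta <= 1.0):
        raise ParameterError(f"beta must lie in (0, 1], got {beta}")
    counts = hist.counts.astype(np.float64)
    prev = float(counts[0]) if y0 is None else float(y0)
    values = np.empty(N_BINS)
    for a in range(N_BINS):
        prev = (1.0 - beta) * prev + beta * counts[a]
        values[a] = prev
    return SmoothedHistogram(values, beta)


def find_peaks(smoothed: SmoothedHistogram, min_separation: int = 1) -> list[int]:
    """Locate histogram peaks, greedily pruned to a minimum separation.

    A peak is a bin (or the leftmost bin of a plateau) strictly greater than
    its neighbours; the array edges are treated as having virtual -inf
    neighbours, so a monotone run ending at an edge yields an edge peak.
    Returns peak bins ordered by descending smoothed value; a candidate
    within ``min_separation`` bins of an already accepted (higher) peak is
    dropped.
    """
    if min_separation < 1:
        raise ParameterError("min_separation must be >= 1")
    v = smoothed.values
    candidates: list[int] = []
    i = 0
    while i < N_BINS:
        j = i
        while j + 1 < N_BINS and v[j + 1] == v[i]:
            j += 1
        left = v[i - 1] if i > 0 else -np.inf
        right = v[j + 1] if j + 1 < N_BINS else -np.inf
        if v[i] > left and v[i] > right:
            candidates.append(i)  # leftmost bin of the plateau
        i = j + 1
    candidates.sort(key=lambda b: (-v[b], b))
    peaks: list[int] = []
    for b in candidates:
        if all(abs(b - p) >= min_separation for p in peaks):
            peaks.append(b)
    return peaks


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy (nats) of a renormalized nonzero count vector."""
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def class_entropies(hist: Histogram, t: int) -> tuple[float, float]:
    """Entropies of the two classes split at gray level t.

    Class 1 covers bins [0, t], class 2 covers [t+1, 255]; each is
    renormalized internally. Raises :class:`InvalidThresholdError` if either
    class has zero mass, so callers can exclude (not score) such splits.
    """
    if not (0 <= t <= N_BINS - 1):
        raise ParameterError(f"threshold must lie in [0, 255], got {t}")
    lo = hist.counts[: t + 1]
    hi = hist.counts[t + 1 :]
    if lo.sum() == 0 or hi.sum() == 0:
        raise InvalidThresholdError(f"split at {t} leaves an empty class")
    return _entropy(lo), _entropy(hi)


def max_entropy_threshold(hist: Histogram) -> ThresholdResult:
    """Exhaustive maximum-entropy threshold search over all valid splits.

    Evaluates D(t) = H1(t) + H2(t) for every t that leaves both classes
    nonempty and returns the smallest maximizing t. Requires at least two
    distinct nonzero gray levels.
    """
    counts = hist.counts.astype(np.float64)
    nonzero = np.flatnonzero(counts)
    if nonzero.size < 2:
        raise DegenerateInputError(
            "threshold search needs >= 2 distinct nonzero gray levels"
        )
    # Vectorized Kapur: class entropy from cumulative sums of c and c*ln c.
    clogc = np.where(counts > 0, counts * np.log(np.maximum(counts, 1e-300)), 0.0)
    c1 = np.cumsum(counts)
    s1 = np.cumsum(clogc)
    total, stotal = c1[-1], s1[-1]
    c2 = total - c1
    s2 = stotal - s1
    with np.errstate(divide="ignore", invalid="ignore"):
        h1 = np.log(c1) - s1 / c1
        h2 = np.log(c2) - s2 / c2
    curve = np.full(N_BINS, np.nan)
    valid = (c1 > 0) & (c2 > 0)
    curve[valid] = h1[valid] + h2[valid]
    # Tiny negative values from cancellation are clamped to exact zero.
    curve[valid] = np.maximum(curve[valid], 0.0)
    t_star = int(np.nanargmax(curve))
    d1, d2 = class_entropies(hist, t_star)
    return ThresholdResult(threshold=t_star, entropy_curve=curve, d1=d1, d2=d2)


def histogram_to_csv(hist: Histogram, path: str | Path) -> None:
    """Write the histogram as a 256-row ``bin,count`` CSV for inspection."""
    rows = "\n".join(f"{i},{c}" for i, c in enumerate(hist.counts))
    Path(path).write_text("bin,count\n" + rows + "\n")
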