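"""Pain volatility: the statistic, 1-D clustering, threshold and labels.

Pain volatility for a severity series :math:`R = \\langle R_1, \\dots, R_n
\\rangle` is the mean absolute successive difference

.. math:: V(R) = \\frac{1}{n-1} \\sum_{i=2}^{n} |R_i - R_{i-1}|,

taken over consecutive reports in record order, regardless of the elapsed
time between them.  Unlike the standard deviation of the ratings, V is
sensitive to the *order* of the series: a steady upward trend has a large SD
but a small V, while a saw-tooth pattern scores high on both.

Users are split into low/high volatility classes by pooling every user's
predictor-window and outcome-window scores (two values per user), running
1-D k-means with k=2, and taking the midpoint of the gap between the two
clusters as the threshold.  A score strictly greater than the threshold is
labelled *high*; a score equal to the threshold is *low*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "VolatilitySeries",
    "VolatilityClassification",
    "KMeans1DResult",
    "StabilityResult",
    "compute_volatility",
    "compute_sd",
    "kmeans_1d",
    "derive_threshold",
    "classify_scores",
    "subsample_stability",
]


@dataclass(frozen=True)
class VolatilitySeries:
    """An ordered severity-rating series for one user and window."""

    user_id: str
    role: str  # "predictor" | "outcome"
    ratings: tuple[int, ...]

    def __post_init__(self) -> None:
        for r in self.ratings:
            if not 0 <= r <= 10:
                raise ValueError(f"rating {r} outside [0, 10]")

    @property
    def n(self) -> int:
        return len(self.ratings)


def _as_ratings(series) -> np.ndarray:
    ratings = series.ratings if isinstance(series, VolatilitySeries) else series
    arr = np.asarray(ratings, dtype=float)
    if arr.ndim != 1:
        raise ValueError("ratings must be one-dimensional")
    return arr


def compute_volatility(series: VolatilitySeries | Sequence[int]) -> float:
    """Mean absolute change between consecutive ratings, divisor n - 1."""
    arr = _as_ratings(series)
    if arr.size < 2:
        raise ValueError("volatility requires at least 2 ratings")
    return float(np.abs(np.diff(arr)).sum() / (arr.size - 1))


def compute_sd(series: VolatilitySeries | Sequence[int]) -> float:
    """Sample standard deviation of the ratings (divisor n - 1)."""
    arr = _as_ratings(series)
    if arr.size < 2:
        raise ValueError("SD requires at least 2 ratings")
    return float(np.std(arr, ddof=1))


@dataclass(frozen=True)
class KMeans1DResult:
    """Lloyd's-algorithm output on scalar data, clusters sorted by mean."""

    assignments: np.ndarray  # cluster index per value, 0 = lowest mean
    means: np.ndarray
    sse: float


def kmeans_1d(
    values: Sequence[float],
    k: int = 2,
    seed: int | None = None,
    n_restarts: int = 25,
) -> KMeans1DResult:
    """Lloyd's k-means on scalar values with deterministic + random restarts.

    Each restart runs Lloyd iterations (assign to nearest mean, update
    means) until membership stabilises; the restart with the lowest
    within-cluster sum of squares wins.  Restarts are seeded two ways:
    deterministically from the segment means of sorted-order splits (for
    k=2, every split when n <= 512, evenly thinned above — a restart
    started at a split's own means can only improve on it, so covering the
    splits makes reaching the sorted-split optimum certain rather than
    merely likely on weakly separated data), plus ``n_restarts`` random
    draws of k distinct data values.  Clusters are relabelled in
    increasing order of mean.

    Raises ``ValueError`` when all values are identical (degenerate: no
    gap exists to threshold on) or when there are fewer values than
    clusters.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < k:
        raise ValueError(f"need at least {k} values")
    uniq = np.unique(x)
    if uniq.size < 2:
        raise ValueError("degenerate clustering: all values identical")
    if uniq.size < k:
        raise ValueError(f"only {uniq.size} distinct values for k={k}")
    rng = np.random.default_rng(seed)
    inits: list[np.ndarray] = []
    if k == 2:
        xs = np.sort(x)
        csum = np.cumsum(xs)
        total = csum[-1]
        splits = np.arange(1, x.size)
        if splits.size > 512:
            splits = splits[np.linspace(0, splits.size - 1, 512).astype(int)]
        for i in splits:
            inits.append(
                np.array([csum[i - 1] / i, (total - csum[i - 1]) / (x.size - i)])
            )
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for restart in range(len(inits) + n_restarts):
        if restart < len(inits):
            means = inits[restart]
        else:
            means = rng.choice(uniq, size=k, replace=False).astype(float)
        assign = np.full(x.size, -1)
        for _ in range(300):
            new_assign = np.abs(x[:, None] - means[None, :]).argmin(axis=1)
            if np.array_equal(new_assign, assign):
                break
            assign = new_assign
            for j in range(k):
                members = x[assign == j]
                # re-seed an emptied cluster from a random distinct value
                means[j] = members.mean() if members.size else rng.choice(uniq)
        sse = float(((x - means[assign]) ** 2).sum())
        if best is None or sse < best[0] - 1e-12:
            best = (sse, assign.copy(), means.copy())
    sse, assign, means = best
    order = np.argsort(means)
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return KMeans1DResult(relabel[assign], means[order], sse)


def _gap_threshold(x: np.ndarray, assignments: np.ndarray) -> float:
    """Midpoint between the top of the low cluster and the bottom of the high."""
    low_max = float(x[assignments == 0].max())
    high_min = float(x[assignments == 1].min())
    return (low_max + high_min) / 2.0


@dataclass(frozen=True)
class VolatilityClassification:
    """A volatility threshold plus per-window low/high labels."""

    threshold: float
    predictor_labels: dict[str, str]
    outcome_labels: dict[str, str]
    cluster_assignments: np.ndarray

    def label(self, score: float) -> str:
        return "high" if score > self.threshold else "low"


def classify_scores(scores: Mapping[str, float], threshold: float) -> dict[str, str]:
    """Label each score: strictly above the threshold is high, else low."""
    return {
        uid: ("high" if s > threshold else "low") for uid, s in scores.items()
    }


def derive_threshold(
    predictor_scores: Mapping[str, float],
    outcome_scores: Mapping[str, float],
    seed: int | None = None,
) -> VolatilityClassification:
    """Cluster the pooled predictor+outcome scores and derive the threshold.

    Every user contributes two values, one per window.  The pooled scores
    are split by 1-D 2-means; the threshold is the midpoint of the gap
    between the clusters, and each window's labels come from applying the
    threshold to that window's scores.
    """
    if not predictor_scores or not outcome_scores:
        raise ValueError("both score collections must be non-empty")
    pooled = np.concatenate(
        [
            np.fromiter(predictor_scores.values(), dtype=float),
            np.fromiter(outcome_scores.values(), dtype=float),
        ]
    )
    result = kmeans_1d(pooled, k=2, seed=seed)
    threshold = _gap_threshold(pooled, result.assignments)
    return VolatilityClassification(
        threshold=threshold,
        predictor_labels=classify_scores(predictor_scores, threshold),
        outcome_labels=classify_scores(outcome_scores, threshold),
        cluster_assignments=result.assignments,
    )


@dataclass(frozen=True)
class StabilityResult:
    """Thresholds from repeated half-sample re-clustering."""

    thresholds: tuple[float, ...]

    @property
    def max_spread(self) -> float:
        if len(self.thresholds) < 2:
            return 0.0
        return float(max(self.thresholds) - min(self.thresholds))


def subsample_stability(
    pooled_scores: Sequence[float],
    n_repeats: int = 4,
    fraction: float = 0.5,
    seed: int | None = None,
) -> StabilityResult:
    """Re-derive the threshold on random half-size subsamples.

    Draws ``n_repeats`` subsamples of ``fraction`` of the pooled scores
    without replacement, re-clusters each and records the resulting
    threshold.  A small spread across repeats indicates the low/high split
    is a property of the score distribution, not of any particular sample.
    """
    x = np.asarray(pooled_scores, dtype=float)
    if n_repeats and x.size < 4:
        raise ValueError("need at least 4 pooled scores")
    rng = np.random.default_rng(seed)
    thresholds = []
    for _ in range(n_repeats):
        idx = rng.choice(x.size, size=max(2, int(fraction * x.size)), replace=False)
        sub = x[idx]
        result = kmeans_1d(sub, k=2, seed=int(rng.integers(2**31)))
        thresholds.append(_gap_threshold(sub, result.assignments))
    return StabilityResult(tuple(thresholds))
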