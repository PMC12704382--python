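"""Temporal Dynamics Clustering (TDC) of fluorescence time series.

Each detrended series is summarized by moments of its sorted absolute
first-order differences |Δy_t| = |y_t - y_{t-1}|: a quantile index

    u = (T-1)^(2/3) / ln(ln(T-1)),    I_q = 1 - u / (T-1)

(T the series length) splits the differences into a *main* section (values at
or below the empirical I_q quantile: moderate frame-to-frame variation) and a
*tail* section (values above it: extreme variation events).  The features
(μ_main, σ_main, μ_tail) feed k-means clustering with the cluster count
selected by the highest silhouette score at the minimal number of clusters.

The features scale linearly with the series (no normalization), so series
must share comparable intensity units.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

logger = logging.getLogger("tipflux")

KMEANS_RESTARTS = 50


class SeriesTooShortError(ValueError):
    def __init__(self, T: int, minimum: int):
        super().__init__(f"series length {T} too short for TDC; minimal admissible length is {minimum}")
        self.minimum = minimum


@dataclass(frozen=True)
class TdcFeatures:
    """Main/tail variability summary of one series."""

    T: int
    u: float
    I_q: float
    mu_main: float
    sigma_main: float
    mu_tail: float

    def as_vector(self) -> np.ndarray:
        return np.array([self.mu_main, self.sigma_main, self.mu_tail])


@dataclass
class ClusterResult:
    k: int
    labels: np.ndarray
    silhouette: float
    per_k_scores: dict


def tail_size_u(T: int) -> float:
    """Tail-size parameter u = (T-1)^(2/3) / ln(ln(T-1))."""
    if T < 4:
        raise SeriesTooShortError(T, min_admissible_length())
    return (T - 1) ** (2.0 / 3.0) / math.log(math.log(T - 1))


def quantile_index(T: int) -> float:
    """Quantile index I_q = 1 - u/(T-1) splitting main from tail."""
    u = tail_size_u(T)
    if u >= T - 1:
        raise SeriesTooShortError(T, min_admissible_length())
    return 1.0 - u / (T - 1)


def min_admissible_length(limit: int = 1000) -> int:
    """Smallest series length for which the I_q split is well defined."""
    for T in range(4, limit):
        if (T - 1) ** (2.0 / 3.0) / math.log(math.log(T - 1)) < T - 1:
            return T
    raise RuntimeError("no admissible length found")


def first_order_abs_diff(series: np.ndarray) -> np.ndarray:
    """|y_t - y_{t-1}| for consecutive frames; NaN gaps are dropped pairwise."""
    y = np.asarray(series, float)
    if y.size < 2:
        raise ValueError("series must have at least 2 points")
    d = np.abs(np.diff(y))
    n_gaps = int(np.isnan(d).sum())
    if n_gaps:
        logger.warning("first-order differences: %d gaps from missing values dropped", n_gaps)
        d = d[np.isfinite(d)]
    return d


def tdc_features(series: np.ndarray, T: int | None = None) -> TdcFeatures:
    """Compute (μ_main, σ_main, μ_tail) for one series.

    ``T`` defaults to the series length; the I_q quantile uses linear
    interpolation between order statistics and "above I_q" is strict.  With an
    empty tail (heavy ties at the maximum) μ_tail falls back to the maximal
    difference, so μ_tail ≥ μ_main always holds.
    """
    y = np.asarray(series, float)
    if T is None:
        T = y.size
    iq = quantile_index(T)
    diffs = first_order_abs_diff(y)
    q = float(np.quantile(diffs, iq))
    main = diffs[diffs <= q]
    tail = diffs[diffs > q]
    mu_tail = float(tail.mean()) if tail.size else float(diffs.max())
    sigma_main = float(main.std(ddof=1)) if main.size > 1 else 0.0
    return TdcFeatures(T, tail_size_u(T), iq, float(main.mean()), sigma_main, mu_tail)


def cluster_features(
    features,
    k_range=None,
    seed: int = 0,
    n_init: int = KMEANS_RESTARTS,
    standardize: bool = False,
) -> ClusterResult:
    """k-means over feature vectors with silhouette-based selection of k.

    ``features`` is a list of :class:`TdcFeatures` or an (N, 3) array.  For
    each k in ``k_range`` (default 2..N-1) k-means is run with ``n_init``
    seeded restarts; the selected k maximizes the silhouette score, ties
    broken toward fewer clusters.  Features are used raw (unstandardized) by
    default; set ``standardize`` to z-score them first.
    """
    X = np.asarray(
        [f.as_vector() if isinstance(f, TdcFeatures) else np.asarray(f, float) for f in features]
    )
    N = len(X)
    if N < 3:
        raise ValueError("need at least 3 series to cluster")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate input: all feature vectors identical")
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0)
    if k_range is None:
        k_range = range(2, N)
    per_k: dict[int, tuple] = {}
    for k in k_range:
        if not 2 <= k <= N - 1:
            continue
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        score = float(silhouette_score(X, km.labels_))
        per_k[k] = (score, km.labels_)
    if not per_k:
        raise ValueError("empty k range")
    best_score = max(s for s, _ in per_k.values())
    best_k = min(k for k, (s, _) in per_k.items() if s >= best_score - 1e-12)
    score, labels = per_k[best_k]
    logger.info("TDC clustering: selected k=%d (silhouette %.3f)", best_k, score)
    return ClusterResult(best_k, labels, score, {k: s for k, (s, _) in per_k.items()})
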