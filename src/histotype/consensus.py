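"""Consensus clustering for cluster-count stability (CDF / delta-area).

For each k, samples are repeatedly subsampled and clustered with k-means
whose centers are initialized from a k-cut of average-linkage hierarchical
clustering under (1 - Pearson) distance; this hybrid makes every resample
deterministic given its subsample while honoring both correlation-based
agglomeration and k-means refinement. The consensus matrix entry (i, j) is
the fraction of co-sampled resamples in which i and j co-clustered; CDFs of
its off-diagonal entries and their area gains across k locate the smallest
stable cluster count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import average, fcluster, leaves_list
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .exceptions import (
    ConfigurationError,
    DegenerateItemError,
    InsufficientRangeError,
)
from .io import ExpressionMatrix

CDF_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class ConsensusResult:
    k: int
    consensus: np.ndarray        # samples x samples, diag 1, entries in [0,1]
    never_cosampled: np.ndarray  # boolean mask of undefined pairs
    cdf: np.ndarray              # ECDF of off-diagonal entries on CDF_GRID
    area: float
    delta_area: float
    assignments: np.ndarray


def _pearson_distance(rows: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(rows)
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    d = 1.0 - r
    return np.clip((d + d.T) / 2.0, 0.0, None)


def _init_centers(sub: np.ndarray, k: int) -> np.ndarray:
    """k-means centers from a k-cut of average-linkage (1 - Pearson) tree."""
    d = _pearson_distance(sub)
    labels = fcluster(average(squareform(d, checks=False)), k,
                      criterion="maxclust")
    centers = []
    for lab in np.unique(labels):
        centers.append(sub[labels == lab].mean(axis=0))
    while len(centers) < k:           # degenerate cut: pad with farthest point
        centers.append(sub[np.argmax(d.sum(axis=1))])
    return np.asarray(centers[:k])


def consensus_cluster(X: ExpressionMatrix, k_range=range(2, 8),
                      resamples: int = 250, subsample_frac: float = 0.8,
                      seed: int = 0) -> list:
    """Consensus matrices, CDFs and delta-areas for each cluster count."""
    k_range = sorted(set(int(k) for k in k_range))
    if any(k < 2 for k in k_range):
        raise ConfigurationError("cluster counts must be >= 2")
    if resamples < 2:
        raise ConfigurationError("need >= 2 resamples")
    if not 0.0 < subsample_frac <= 1.0:
        raise ConfigurationError("subsample_frac must be in (0, 1]")
    n = X.n_samples
    if n < max(k_range) + 2:
        raise ConfigurationError(
            f"{n} samples cannot support k = {max(k_range)}")
    m = max(int(round(subsample_frac * n)), max(k_range))

    # z-score genes; samples become rows
    sd = X.values.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    Z = ((X.values - X.values.mean(axis=1, keepdims=True)) / sd[:, None]).T

    rng = np.random.default_rng(seed)
    results = []
    prev_area = 0.0
    for k in k_range:
        co_cluster = np.zeros((n, n))
        co_sample = np.zeros((n, n))
        for _ in range(resamples):
            idx = np.sort(rng.choice(n, m, replace=False)) \
                if m < n else np.arange(n)
            sub = Z[idx]
            km = KMeans(n_clusters=k, init=_init_centers(sub, k), n_init=1,
                        max_iter=300)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                labels = km.fit_predict(sub)
            same = labels[:, None] == labels[None, :]
            co_cluster[np.ix_(idx, idx)] += same
            co_sample[np.ix_(idx, idx)] += 1.0
        never = co_sample == 0
        with np.errstate(invalid="ignore"):
            M = np.where(never, 0.0, co_cluster / np.maximum(co_sample, 1.0))
        np.fill_diagonal(M, 1.0)
        np.fill_diagonal(never, False)

        iu = np.triu_indices(n, k=1)
        vals = M[iu][~never[iu]]
        cdf = np.searchsorted(np.sort(vals), CDF_GRID, side="right") / vals.size
        area = float(np.trapezoid(cdf, CDF_GRID))
        delta = area if not results else area - prev_area
        prev_area = area

        link = average(squareform(np.clip(1.0 - M, 0.0, None), checks=False))
        assignments = fcluster(link, k, criterion="maxclust")
        results.append(ConsensusResult(
            k=k, consensus=M, never_cosampled=never, cdf=cdf, area=area,
            delta_area=float(delta), assignments=assignments))
    return results


def select_stable_k(results: list, threshold: float = 0.1) -> int:
    """Smallest k whose successor adds little CDF area.

    Returns the smallest k with delta_area(k+1) < threshold * area(k); if
    every increment stays above the threshold there is no plateau and the
    largest k is returned with a warning.
    """
    if len(results) < 3:
        raise InsufficientRangeError("need at least 3 consecutive k values")
    ks = [r.k for r in results]
    if ks != list(range(ks[0], ks[0] + len(ks))):
        raise ConfigurationError("results must cover consecutive k")
    for prev, nxt in zip(results[:-1], results[1:]):
        if nxt.delta_area < threshold * prev.area:
            return prev.k
    warnings.warn("no CDF plateau found; returning the largest k",
                  UserWarning, stacklevel=2)
    return results[-1].k


def hierarchical_cluster(X: ExpressionMatrix, axis: str = "samples"):
    """Average-linkage tree under 1 - uncentered correlation distance.

    Returns the scipy linkage matrix and the deterministic leaf ordering.
    """
    if axis == "samples":
        rows = X.values.T
        ids = X.sample_ids
    elif axis == "genes":
        rows = X.values
        ids = X.gene_ids
    else:
        raise ConfigurationError(f"axis must be 'genes' or 'samples', not {axis!r}")
    if rows.shape[0] < 2:
        raise ConfigurationError("need >= 2 items to cluster")
    norms = np.linalg.norm(rows, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise DegenerateItemError(
            f"zero-norm rows: {[ids[i] for i in zero[:10]]}")
    sim = (rows @ rows.T) / np.outer(norms, norms)
    d = np.clip(1.0 - sim, 0.0, None)
    np.fill_diagonal(d, 0.0)
    link = average(squareform((d + d.T) / 2.0, checks=False))
    return link, leaves_list(link)
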