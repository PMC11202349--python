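"""Classical single-pass imputers used as comparison methods.

All four operate on the original measurement scale, preserve observed cells
exactly, and return a dense ``d x n`` matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import MaskedSeries

__all__ = ["KnnConfig", "impute_zero", "impute_mean", "impute_last",
           "impute_knn"]


@dataclass
class KnnConfig:
    """K-nearest-neighbour imputation settings.

    Neighbours are other timesteps (rows as samples); the distance is the
    Euclidean distance over mutually observed features normalized by the
    co-observed count, and contributions are inverse-distance weighted.
    """

    k: int = 5

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")


def impute_zero(series: MaskedSeries) -> np.ndarray:
    """Fill missing cells with 0."""
    return series.values * series.mask


def _feature_means(series: MaskedSeries) -> np.ndarray:
    obs_counts = series.mask.sum(axis=1)
    sums = (series.values * series.mask).sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(obs_counts > 0, sums / np.maximum(obs_counts, 1), 0.0)
    return means


def impute_mean(series: MaskedSeries, means: np.ndarray | None = None,
                ) -> np.ndarray:
    """Fill missing cells with the per-feature mean of observed values.

    ``means`` may be supplied externally (e.g. computed on a training split
    to avoid test leakage).
    """
    if means is None:
        means = _feature_means(series)
    out = series.values.copy()
    miss = series.mask == 0.0
    out[miss] = np.broadcast_to(means[:, None], out.shape)[miss]
    return out


def impute_last(series: MaskedSeries) -> np.ndarray:
    """Last observation carried forward per feature.

    A leading run of missing values (no prior observation) falls back to the
    feature mean.
    """
    means = _feature_means(series)
    out = series.values.copy()
    for j in range(series.n_features):
        last = None
        for i in range(series.n_steps):
            if series.mask[j, i] == 1.0:
                last = out[j, i]
            else:
                out[j, i] = last if last is not None else means[j]
    return out


def impute_knn(series: MaskedSeries, config: KnnConfig | None = None,
               ) -> np.ndarray:
    """Inverse-distance-weighted k-nearest-timestep imputation.

    For a missing cell ``(j, i)``, candidate timesteps are those observing
    feature ``j`` and sharing at least one co-observed feature with timestep
    ``i``; among them the ``k`` nearest by co-observation-normalized masked
    Euclidean distance contribute an inverse-distance weighted mean.  A zero
    distance makes the neighbour's value copied exactly.  With no candidate
    at all the cell falls back to the feature mean.
    """
    config = config or KnnConfig()
    V, M = series.values, series.mask
    d, n = V.shape
    means = _feature_means(series)
    out = V.copy()

    # pairwise masked distances between timestep vectors
    co = M.T @ M                                   # co-observed counts (n, n)
    diff_sq = np.zeros((n, n))
    for j in range(d):
        obs_j = M[j] == 1.0
        dj = np.subtract.outer(V[j], V[j]) ** 2
        dj *= np.outer(obs_j, obs_j)
        diff_sq += dj
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.sqrt(diff_sq / np.maximum(co, 1))
    dist[co == 0] = np.inf
    np.fill_diagonal(dist, np.inf)

    for j in range(d):
        for i in np.nonzero(M[j] == 0.0)[0]:
            cand = np.nonzero((M[j] == 1.0) & np.isfinite(dist[i]))[0]
            if cand.size == 0:
                out[j, i] = means[j]
                continue
            order = cand[np.argsort(dist[i, cand], kind="stable")]
            nearest = order[: config.k]
            dd = dist[i, nearest]
            if np.any(dd == 0.0):
                out[j, i] = V[j, nearest[dd == 0.0]].mean()
            else:
                w = 1.0 / dd
                out[j, i] = float((w * V[j, nearest]).sum() / w.sum())
    return out
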