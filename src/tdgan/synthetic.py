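"""Synthetic EHR-like benchmark: correlated multivariate series with
controlled missingness and full ground truth.

Each record emulates a patient's physiological indicator extract: ``d``
features sampled at irregular timestamps, temporally autocorrelated (latent
AR(1) per feature), correlated across features (linear mixing), and offset
so true values stay bounded away from zero (MAPE remains defined).  Two
corruption mechanisms are provided: cell-level MCAR deletion, and the
record-level "secondary missing" protocol in which whole complete records,
chosen by a normally distributed index, are deleted until a target missing
rate is reached.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import HeldOutSet, MaskedSeries

__all__ = ["SyntheticConfig", "generate_truth", "apply_mcar",
           "corrupt_dataset", "apply_secondary_missing"]


@dataclass
class SyntheticConfig:
    """Generator settings.

    ``phi`` is the AR(1) coefficient of the per-feature latent process;
    ``mixing`` in [0, 1) blends each feature with the cross-feature average;
    offsets ``offset_base + offset_step * j`` keep true values well away
    from zero (enforced with a floor at ``value_floor``); timestamps advance
    by ``1 ± jitter`` per step.
    """

    d: int = 5
    n: int = 100
    records: int = 50
    phi: float = 0.8
    mixing: float = 0.3
    noise_sd: float = 1.0
    offset_base: float = 10.0
    offset_step: float = 2.0
    value_floor: float = 0.5
    jitter: float = 0.3
    missing_rate: float = 0.3
    seed: int = 1024

    def __post_init__(self):
        if not -1.0 < self.phi < 1.0:
            raise ValueError("phi must lie in (-1, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.mixing < 1.0:
            raise ValueError("mixing must lie in [0, 1)")


def generate_truth(config: SyntheticConfig) -> list:
    """Fully observed records (mask all ones), reproducible per seed."""
    rng = np.random.default_rng(config.seed)
    offsets = config.offset_base + config.offset_step * np.arange(config.d)
    mix_mat = ((1.0 - config.mixing) * np.eye(config.d)
               + config.mixing / config.d * np.ones((config.d, config.d)))
    stat_sd = config.noise_sd / np.sqrt(1.0 - config.phi ** 2) \
        if config.noise_sd > 0 else 0.0
    records = []
    for _ in range(config.records):
        latent = np.zeros((config.d, config.n))
        latent[:, 0] = rng.normal(0.0, stat_sd, size=config.d) \
            if stat_sd > 0 else 0.0
        eps = rng.normal(0.0, config.noise_sd, size=(config.d, config.n)) \
            if config.noise_sd > 0 else np.zeros((config.d, config.n))
        for i in range(1, config.n):
            latent[:, i] = config.phi * latent[:, i - 1] + eps[:, i]
        values = offsets[:, None] + mix_mat @ latent
        # keep truths bounded away from zero so MAPE stays defined
        small = np.abs(values) < config.value_floor
        values[small] = np.sign(values[small] + 1e-12) * config.value_floor
        gaps = rng.uniform(1.0 - config.jitter, 1.0 + config.jitter,
                           size=config.n)
        times = np.concatenate([[0.0], np.cumsum(gaps[1:])])
        records.append(MaskedSeries(values, np.ones_like(values), times))
    return records


def apply_mcar(series: MaskedSeries, p: float, seed: int,
               record_index: int = 0) -> tuple:
    """Hide each currently observed cell independently with probability p.

    Returns the corrupted record and the held-out set carrying the ground
    truth of every hidden cell.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError("p must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    hide = (rng.random(series.values.shape) < p) & (series.mask == 1.0)
    cells = [(record_index, int(j), int(i)) for j, i in zip(*np.nonzero(hide))]
    truth = series.values[hide]
    mask = series.mask.copy()
    mask[hide] = 0.0
    corrupted = MaskedSeries(series.values * mask, mask, series.times.copy(),
                             list(series.feature_names))
    return corrupted, HeldOutSet(cells, truth)


def corrupt_dataset(records: list, p: float, seed: int) -> tuple:
    """MCAR-corrupt every record; pools the held-out cells into one set."""
    rng = np.random.default_rng(seed)
    corrupted, cells, truth = [], [], []
    for ridx, rec in enumerate(records):
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        c, h = apply_mcar(rec, p, sub_seed, record_index=ridx)
        corrupted.append(c)
        cells.extend(h.cells)
        truth.append(h.truth)
    truth = np.concatenate(truth) if truth else np.empty(0)
    return corrupted, HeldOutSet(cells, truth)


def _is_complete(rec: MaskedSeries) -> bool:
    return bool((rec.mask == 1.0).all())


def apply_secondary_missing(records: list, target_rate: float, seed: int,
                            ) -> tuple:
    """Delete whole complete records until the target missing rate is hit.

    Record indices are drawn as ``round(N(R/2, R/6))`` clipped to range; a
    drawn index pointing at an already-incomplete record advances to the
    next index (cyclically) until a complete record is found.  Stops with a
    warning when the target is unreachable.  Returns the corrupted dataset
    and the held-out set of the deleted records' cells.
    """
    rng = np.random.default_rng(seed)
    R = len(records)
    out = [r.copy() for r in records]
    total_cells = sum(r.mask.size for r in out)
    missing = sum((r.mask == 0.0).sum() for r in out)
    cells, truth = [], []

    def rate():
        return missing / total_cells

    while rate() < target_rate:
        if not any(_is_complete(r) for r in out):
            warnings.warn("no complete records left; achieved missing rate "
                          f"{rate():.3f} < target {target_rate:.3f}")
            break
        idx = int(round(rng.normal(R / 2.0, R / 6.0)))
        idx = int(np.clip(idx, 0, R - 1))
        for step in range(R):
            cand = (idx + step) % R
            if _is_complete(out[cand]):
                rec = out[cand]
                for j in range(rec.n_features):
                    for i in range(rec.n_steps):
                        cells.append((cand, j, i))
                truth.append(rec.values.flatten())
                out[cand] = MaskedSeries(
                    np.zeros_like(rec.values), np.zeros_like(rec.mask),
                    rec.times.copy(), list(rec.feature_names))
                missing += rec.mask.size
                break
    truth = np.concatenate(truth) if truth else np.empty(0)
    return out, HeldOutSet(cells, truth)
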