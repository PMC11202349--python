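"""Core containers for sparse multivariate clinical time series.

A record is a ``d x n`` matrix of physiological measurements (``d`` features,
``n`` timestamps) in which most cells may be missing.  Missingness is carried
explicitly as a binary mask; the value matrix stores the placeholder ``0.0``
at missing cells so every array is dense and finite.  Alongside the mask, a
per-feature time-interval matrix records the elapsed time since each feature
was last observed, which downstream decay models consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MaskedSeries",
    "DeltaMatrix",
    "NormalizationState",
    "HeldOutSet",
    "build_mask",
    "compute_delta",
    "normalize",
    "denormalize",
    "split_records",
    "read_series",
    "write_series",
]

PLACEHOLDER = 0.0


@dataclass
class MaskedSeries:
    """A ``d x n`` multivariate series with explicit missingness.

    Parameters
    ----------
    values : ndarray of shape (d, n)
        Observed measurements; missing cells hold the placeholder ``0.0``.
    mask : ndarray of shape (d, n)
        ``1.0`` where the cell was observed, ``0.0`` where it is missing.
    times : ndarray of shape (n,)
        Strictly increasing timestamps in one consistent (arbitrary) unit.
    feature_names : list of str
        Length-``d`` labels, one per row of ``values``.
    """

    values: np.ndarray
    mask: np.ndarray
    times: np.ndarray
    feature_names: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a d x n matrix")
        d, n = self.values.shape
        if self.mask.shape != (d, n):
            raise ValueError("mask shape must match values shape")
        if self.times.shape != (n,):
            raise ValueError("times must have one entry per timestep")
        if not np.isin(self.mask, (0.0, 1.0)).all():
            raise ValueError("mask entries must be 0 or 1")
        if not np.isfinite(self.values).all():
            raise ValueError("values must be finite (missing cells are 0.0)")
        if n > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(d)]
        if len(self.feature_names) != d:
            raise ValueError("feature_names length must equal d")
        # enforce the placeholder convention
        self.values = self.values * self.mask

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "MaskedSeries":
        return MaskedSeries(
            self.values.copy(), self.mask.copy(), self.times.copy(),
            list(self.feature_names),
        )


@dataclass
class DeltaMatrix:
    """Per-feature elapsed time since the last observation (``d x n``)."""

    delta: np.ndarray

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=float)
        if np.any(self.delta < 0):
            raise ValueError("delta entries must be nonnegative")


@dataclass
class NormalizationState:
    """Per-feature affine map between the data scale and ``[lo, hi]``.

    Observed per-feature minima/maxima define the map; a constant feature
    (min == max) maps to the interval midpoint.
    """

    vmin: np.ndarray
    vmax: np.ndarray
    lo: float = -1.0
    hi: float = 1.0

    def forward(self, values: np.ndarray) -> np.ndarray:
        vmin = self.vmin[:, None]
        vmax = self.vmax[:, None]
        span = vmax - vmin
        mid = 0.5 * (self.lo + self.hi)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.lo + (values - vmin) * (self.hi - self.lo) / span
        return np.where(span == 0, mid, out)

    def inverse(self, values: np.ndarray) -> np.ndarray:
        vmin = self.vmin[:, None]
        vmax = self.vmax[:, None]
        span = vmax - vmin
        out = vmin + (values - self.lo) * span / (self.hi - self.lo)
        return np.where(span == 0, vmin, out)


@dataclass
class HeldOutSet:
    """Cells hidden from a record for evaluation, with their ground truth.

    ``cells`` is a list of ``(record_index, feature_index, time_index)``
    triples; ``truth`` the original values at those cells.  ``predicted`` is
    filled in after imputation.
    """

    cells: list
    truth: np.ndarray
    predicted: np.ndarray | None = None

    def __post_init__(self):
        self.truth = np.asarray(self.truth, dtype=float)
        if len(self.cells) != len(self.truth):
            raise ValueError("one truth value per held-out cell")

    def __len__(self) -> int:
        return len(self.cells)

    def gather(self, imputed: dict[int, np.ndarray] | list) -> np.ndarray:
        """Collect predictions at the held-out cells from imputed matrices."""
        if isinstance(imputed, (list, tuple)):
            imputed = dict(enumerate(imputed))
        pred = np.array([imputed[r][j, i] for (r, j, i) in self.cells])
        self.predicted = pred
        return pred


def build_mask(raw_table: pd.DataFrame, time_column: str = "time") -> MaskedSeries:
    """Convert a wide table with empty cells into a :class:`MaskedSeries`.

    The table has one timestamp column and ``d`` feature columns; an empty
    (NaN) cell means missing.  Raises on non-numeric feature cells and on
    duplicate timestamps.
    """
    if time_column not in raw_table.columns:
        raise ValueError(f"table must contain a '{time_column}' column")
    times = pd.to_numeric(raw_table[time_column], errors="raise").to_numpy(float)
    if len(np.unique(times)) != len(times):
        raise ValueError("duplicate timestamps in time column")
    order = np.argsort(times, kind="stable")
    feat_cols = [c for c in raw_table.columns if c != time_column]
    if not feat_cols:
        raise ValueError("table must contain at least one feature column")
    d, n = len(feat_cols), len(times)
    values = np.zeros((d, n))
    mask = np.zeros((d, n))
    for j, col in enumerate(feat_cols):
        try:
            numeric = pd.to_numeric(raw_table[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = raw_table[col][pd.to_numeric(raw_table[col], errors="coerce").isna()
                                 & raw_table[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"non-numeric cell in column '{col}' at row {row}") from exc
        col_vals = numeric.to_numpy(float)[order]
        observed = np.isfinite(col_vals)
        mask[j, observed] = 1.0
        values[j, observed] = col_vals[observed]
    return MaskedSeries(values, mask, times[order], feat_cols)


def compute_delta(series: MaskedSeries) -> DeltaMatrix:
    """Elapsed time since each feature's last observation.

    The first column is 0.  For later steps the interval either restarts at
    ``t_i - t_{i-1}`` (previous step observed) or accumulates the previous
    interval (previous step missing); equivalently, ``delta[j, i]`` is
    ``t_i`` minus the timestamp of feature ``j``'s most recent observation
    before step ``i`` (falling back to ``t_0`` when there is none).
    """
    d, n = series.values.shape
    delta = np.zeros((d, n))
    t = series.times
    for i in range(1, n):
        gap = t[i] - t[i - 1]
        prev_obs = series.mask[:, i - 1] == 1.0
        delta[:, i] = np.where(prev_obs, gap, delta[:, i - 1] + gap)
    return DeltaMatrix(delta)


def normalize(series: MaskedSeries, lo: float = -1.0, hi: float = 1.0,
              ) -> tuple[MaskedSeries, NormalizationState]:
    """Map observed entries per feature affinely onto ``[lo, hi]``.

    Missing cells keep the placeholder 0.  A feature with a single distinct
    observed value maps to the interval midpoint.  Features with no observed
    value at all are treated as constant at 0.
    """
    obs = series.mask == 1.0
    d = series.n_features
    vmin = np.empty(d)
    vmax = np.empty(d)
    for j in range(d):
        if obs[j].any():
            vmin[j] = series.values[j, obs[j]].min()
            vmax[j] = series.values[j, obs[j]].max()
        else:
            vmin[j] = vmax[j] = 0.0
    state = NormalizationState(vmin, vmax, lo, hi)
    scaled = state.forward(series.values) * series.mask
    out = MaskedSeries(scaled, series.mask.copy(), series.times.copy(),
                       list(series.feature_names))
    return out, state


def denormalize(values: np.ndarray, state: NormalizationState) -> np.ndarray:
    """Inverse of :func:`normalize` applied to a dense matrix."""
    return state.inverse(values)


def split_records(dataset: list, ratio: float = 0.7, seed: int = 1024,
                  ) -> tuple[list, list]:
    """Random train/test partition of records at the given train fraction.

    Disjoint and exhaustive; the train size is ``round(ratio * len(dataset))``
    so a 10-record dataset at 0.7 yields a 7/3 split. Reproducible per seed.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    if len(dataset) < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dataset))
    n_train = int(round(ratio * len(dataset)))
    n_train = min(max(n_train, 1), len(dataset) - 1)
    train_idx = sorted(order[:n_train])
    test_idx = sorted(order[n_train:])
    return [dataset[i] for i in train_idx], [dataset[i] for i in test_idx]


def write_series(series: MaskedSeries, path) -> None:
    """Write a record as a wide CSV: ``time`` column first, empty cell = missing."""
    df = pd.DataFrame({"time": series.times})
    for j, name in enumerate(series.feature_names):
        col = series.values[j].astype(object).copy()
        col[series.mask[j] == 0.0] = np.nan
        df[name] = col
    df.to_csv(path, index=False, na_rep="")


def read_series(path, time_column: str = "time") -> MaskedSeries:
    """Read a wide CSV written by :func:`write_series`.

    Both the empty string and the literal ``NaN`` are read as missing;
    trailing blank lines are ignored.
    """
    df = pd.read_csv(path, skip_blank_lines=True)
    if time_column not in df.columns:
        raise ValueError(f"file {path} lacks a '{time_column}' column")
    return build_mask(df, time_column=time_column)
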