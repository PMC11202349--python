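"""Masked evaluation criteria for imputation: RMSE, MAPE and pairwise AUC.

Errors are always computed on the held-out (artificially removed) cells only,
on the original measurement scale — never on the normalized model scale.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata

__all__ = ["LabeledScores", "EvalReport", "rmse", "mape", "auc",
           "evaluate_heldout"]


@dataclass
class LabeledScores:
    """Classifier scores split into positive- and negative-class sets."""

    positives: np.ndarray
    negatives: np.ndarray

    def __post_init__(self):
        self.positives = np.asarray(self.positives, dtype=float)
        self.negatives = np.asarray(self.negatives, dtype=float)


@dataclass
class EvalReport:
    """Held-out imputation errors on the original scale."""

    rmse: float
    mape: float
    n_cells: int
    auc: float | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["auc"] is None:
            d.pop("auc")
        return d


def rmse(y: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean squared error between ground truth and predictions."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape or y.size == 0:
        raise ValueError("y and y_pred must be equal-length and non-empty")
    return float(np.sqrt(np.mean((y - y_pred) ** 2)))


def mape(y: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean absolute percentage error, as a percentage.

    Undefined when any ground-truth value is 0; callers must exclude
    zero-truth cells before evaluating.
    """
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape or y.size == 0:
        raise ValueError("y and y_pred must be equal-length and non-empty")
    if np.any(y == 0):
        raise ValueError(
            "MAPE is undefined for zero ground-truth values; "
            "exclude zero-truth cells before evaluating")
    return float(100.0 * np.mean(np.abs((y - y_pred) / y)))


def auc(scores: LabeledScores) -> float:
    """Probability that a random positive outscores a random negative.

    Pairwise (Mann-Whitney) normalization over ``|D+| * |D-|`` pairs with
    ties counted 0.5, computed via midranks.
    """
    pos, neg = scores.positives, scores.negatives
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def evaluate_heldout(heldout, imputed, compute_auc: bool = False,
                     auc_labels=None) -> EvalReport:
    """Score imputed matrices against a held-out cell set.

    Parameters
    ----------
    heldout : HeldOutSet
        Hidden cells with their ground truth (original scale).
    imputed : dict or list of ndarray
        Per-record dense imputed matrices, original scale.
    compute_auc, auc_labels
        When requested, ``auc_labels`` (one binary label per held-out cell)
        splits the predictions into score classes for the AUC.
    """
    pred = heldout.gather(imputed)
    truth = heldout.truth
    report_auc = None
    if compute_auc:
        labels = np.asarray(auc_labels, dtype=int)
        report_auc = auc(LabeledScores(pred[labels == 1], pred[labels == 0]))
    return EvalReport(
        rmse=rmse(truth, pred),
        mape=mape(truth, pred),
        n_cells=len(heldout),
        auc=report_auc,
    )
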