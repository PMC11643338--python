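"""Evaluation metrics: label incoherence index, RMSE splits, MCC.

The Label Incoherence Index (LII) quantifies how well an embedding
respects the activity labels: for each point, take its k nearest
neighbors under cosine distance (excluding the point itself), average
the absolute label differences, then average over all points.  Lower
LII means a more label-coherent space; an embedding learned with
AC-awareness should score lower than one trained on regression loss
alone, and both lower than the raw structural space.

Regression performance is reported as RMSE over the full test set and,
separately, over the molecules flagged as activity-cliff compounds
(RMSE_cliff); pair classification is scored with the Matthews
correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.metrics import matthews_corrcoef

__all__ = [
    "LIIConfig",
    "EvaluationReport",
    "lii",
    "rmse",
    "rmse_split",
    "mcc",
    "paired_t_test",
]


@dataclass
class LIIConfig:
    """Neighbor count for the LII; the distance is always cosine."""

    k: int = 5

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be a positive integer")


@dataclass
class EvaluationReport:
    rmse_all: float
    rmse_cliff: Optional[float] = None
    mcc: Optional[float] = None
    lii: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "rmse_all": self.rmse_all,
            "rmse_cliff": self.rmse_cliff,
            "mcc": self.mcc,
            "lii": self.lii,
        }


def lii(embeddings, labels, k: int = 5) -> float:
    """Label Incoherence Index of an embedding.

    Cosine k-nearest neighbors per point (self excluded; distance ties
    broken by lower index), mean absolute label difference to those
    neighbors, averaged over all points.
    """
    x = np.asarray(embeddings, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64).ravel()
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("embeddings must be [n, d] with one label per row")
    n = x.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n, got k={k}, n={n}")
    norms = np.linalg.norm(x, axis=1)
    if (norms == 0).any():
        raise ValueError("zero-norm embedding rows make cosine distance undefined")
    xn = x / norms[:, None]
    dist = 1.0 - xn @ xn.T
    np.fill_diagonal(dist, np.inf)  # exclude self
    # stable argsort breaks distance ties by lower index
    neighbor_idx = np.argsort(dist, axis=1, kind="stable")[:, :k]
    return float(np.abs(y[neighbor_idx] - y[:, None]).mean())


def rmse(predictions, labels) -> float:
    """Root-mean-square error."""
    pred = np.asarray(predictions, dtype=np.float64).ravel()
    lab = np.asarray(labels, dtype=np.float64).ravel()
    if pred.shape != lab.shape:
        raise ValueError("predictions and labels must have matching lengths")
    if pred.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((pred - lab) ** 2)))


def rmse_split(predictions, labels, cliff_flags):
    """Overall RMSE and RMSE over the cliff-flagged subset.

    Returns ``(rmse_all, rmse_cliff)``; ``rmse_cliff`` is None when no
    record is flagged.
    """
    flags = np.asarray(cliff_flags, dtype=bool).ravel()
    pred = np.asarray(predictions, dtype=np.float64).ravel()
    lab = np.asarray(labels, dtype=np.float64).ravel()
    if not (pred.shape == lab.shape == flags.shape):
        raise ValueError("all inputs must have matching lengths")
    overall = rmse(pred, lab)
    cliff = rmse(pred[flags], lab[flags]) if flags.any() else None
    return overall, cliff


def mcc(predicted_labels, true_labels) -> float:
    """Matthews correlation coefficient; 0 by convention when a
    confusion-matrix margin is empty."""
    pred = np.asarray(predicted_labels).ravel().astype(int)
    true = np.asarray(true_labels).ravel().astype(int)
    if pred.shape != true.shape:
        raise ValueError("matched lengths required")
    if len(np.unique(true)) < 2:
        raise ValueError("both classes must be present in the true labels")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(matthews_corrcoef(true, pred))


def paired_t_test(a, b, alternative: str = "two-sided"):
    """Plain paired t-test on matched score vectors; returns (t, p)."""
    res = stats.ttest_rel(np.asarray(a, float), np.asarray(b, float), alternative=alternative)
    return float(res.statistic), float(res.pvalue)
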