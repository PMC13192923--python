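"""Masked evaluation metrics for continuous and binary outcomes.

Continuous: RMSE, MAE, R^2 = 1 - SS_res/SS_tot, Pearson r.  Binary:
AUROC (Mann-Whitney convention, ties count one half), AUPRC in the
average-precision step convention, and the Brier score.  Every metric is
computed only over positions flagged valid (observed and labeled); a
constant truth vector makes r (and AUROC/AUPRC for single-class truth)
undefined, reported as NaN with a warning rather than an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    average_precision_score,
    brier_score_loss,
    mean_absolute_error,
    mean_squared_error,
    r2_score,
    roc_auc_score,
)

__all__ = ["regression_metrics", "classification_metrics", "MetricReport", "reports_to_csv"]


@dataclass
class MetricReport:
    """One evaluation row: outcome x model x seed."""

    outcome: str
    model: str
    seed: int
    metrics: dict
    n_positions: int
    event_prevalence: float | None = None

    def to_row(self) -> dict:
        row = {
            "outcome": self.outcome,
            "model": self.model,
            "seed": self.seed,
            "n_positions": self.n_positions,
            "event_prevalence": self.event_prevalence,
        }
        row.update(self.metrics)
        return row


def _select(y_true: np.ndarray, y_pred: np.ndarray, valid: np.ndarray | None):
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if valid is not None:
        v = np.asarray(valid).astype(bool).ravel()
        y_true, y_pred = y_true[v], y_pred[v]
    return y_true, y_pred


def regression_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, valid: np.ndarray | None = None
) -> dict[str, float]:
    """RMSE, MAE, R^2, Pearson r over valid positions."""
    yt, yp = _select(y_true, y_pred, valid)
    if yt.size < 2:
        raise ValueError("need at least 2 valid positions for regression metrics")
    out = {
        "rmse": float(np.sqrt(mean_squared_error(yt, yp))),
        "mae": float(mean_absolute_error(yt, yp)),
        "r2": float(r2_score(yt, yp)),
    }
    if np.std(yt) == 0 or np.std(yp) == 0:
        warnings.warn("constant vector: Pearson r undefined, reported as NaN", stacklevel=2)
        out["pearson_r"] = float("nan")
    else:
        out["pearson_r"] = float(stats.pearsonr(yt, yp).statistic)
    return out


def classification_metrics(
    y_true: np.ndarray, scores: np.ndarray, valid: np.ndarray | None = None
) -> dict[str, float]:
    """AUROC, AUPRC (average precision), Brier over valid positions.

    Single-class truth leaves AUROC/AUPRC undefined (NaN, with warning);
    the Brier score is still computed.
    """
    yt, sc = _select(y_true, scores, valid)
    if yt.size < 1:
        raise ValueError("need at least 1 valid position")
    if np.any((sc < 0) | (sc > 1)):
        raise ValueError("scores must lie in [0, 1]")
    out: dict[str, float] = {"brier": float(brier_score_loss(yt, sc))}
    if len(np.unique(yt)) < 2:
        warnings.warn(
            "single-class truth: AUROC/AUPRC undefined, reported as NaN", stacklevel=2
        )
        out["auroc"] = float("nan")
        out["auprc"] = float("nan")
    else:
        out["auroc"] = float(roc_auc_score(yt, sc))
        out["auprc"] = float(average_precision_score(yt, sc))
    out["prevalence"] = float(np.mean(yt)) if set(np.unique(yt)) <= {0.0, 1.0} else float("nan")
    return out


def per_subject_last(
    y: np.ndarray, scores: np.ndarray, valid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Reduce (subject, period) arrays to one value per subject.

    Keeps each subject's last valid period — the alternative to the default
    per-period evaluation of discrete-time outcomes, summarizing whether the
    subject ever experienced the event by end of follow-up.  Subjects with
    no valid period are dropped.
    """
    y = np.asarray(y, dtype=float)
    scores = np.asarray(scores, dtype=float)
    valid = np.asarray(valid).astype(bool)
    if y.ndim != 2:
        raise ValueError("expected (n_subjects, n_periods) arrays")
    keep, ys, ss = [], [], []
    for i in range(y.shape[0]):
        idx = np.nonzero(valid[i])[0]
        if idx.size:
            keep.append(i)
            ys.append(y[i, idx[-1]])
            ss.append(scores[i, idx[-1]])
    return np.asarray(ys), np.asarray(ss)


def reports_to_csv(reports: list[MetricReport], path) -> pd.DataFrame:
    """Write tidy metric rows (one per outcome x model x seed) to CSV."""
    df = pd.DataFrame([r.to_row() for r in reports])
    df.to_csv(path, index=False)
    return df
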