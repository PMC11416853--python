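"""Single-feature ROC discrimination between two classes.

For each numeric feature the module reports the Mann-Whitney AUC (the
probability that a positive-class value exceeds a negative-class value,
ties half-credited) and the best single-threshold accuracy: the maximum
fraction of samples classified correctly by thresholding the feature,
maximized over all candidate thresholds and both orientations
(greater-is-positive and lesser-is-positive).  A feature is flagged
"discriminative" when that accuracy exceeds a configurable cutoff
(default 0.80, the conventional acceptability level for a binary
classification).

Best-threshold accuracy is the only reading that makes a per-feature
accuracy well-defined without a pre-committed threshold; the choice is
recorded in the report metadata.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

ACCEPTABILITY_CUTOFF = 0.80

GREATER = "greater_is_positive"
LESSER = "lesser_is_positive"


@dataclass(frozen=True)
class ROCResult:
    """Per-feature discrimination summary."""

    feature_name: str
    auc: float
    orientation: str
    best_threshold: float
    best_accuracy: float
    n_pos: int
    n_neg: int
    discriminative: bool


def _as_array(scores: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} score list is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} scores contain non-finite values")
    return arr


def auc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """Mann-Whitney AUC: fraction of (pos, neg) pairs with pos > neg,
    ties counted 0.5.

    Computed from midranks via exact rational arithmetic, so the
    complement identity auc(pos, neg) + auc(neg, pos) == 1 holds exactly
    in floating point.
    """
    pos = _as_array(pos_scores, "positive")
    neg = _as_array(neg_scores, "negative")
    ranks = rankdata(np.concatenate([pos, neg]))
    # midranks are half-integers: represent 2*U exactly as an integer
    two_r = np.rint(2.0 * ranks[: pos.size]).astype(np.int64).sum()
    two_u = int(two_r) - pos.size * (pos.size + 1)
    return float(Fraction(two_u, 2 * pos.size * neg.size))


def best_threshold_accuracy(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> tuple[float, float, str]:
    """Maximum single-threshold accuracy over both orientations.

    Candidate thresholds are the midpoints of consecutive sorted unique
    values plus -inf/+inf; a sample on the positive side is ``score >
    threshold`` under greater-is-positive and ``score < threshold``
    under lesser-is-positive.  Ties in accuracy are broken toward the
    lowest threshold, greater-is-positive first.

    Returns (threshold, accuracy, orientation).
    """
    pos = _as_array(pos_scores, "positive")
    neg = _as_array(neg_scores, "negative")
    n = pos.size + neg.size
    uniq = np.unique(np.concatenate([pos, neg]))
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate([[-np.inf], mids, [np.inf]])
    # correct under greater_is_positive: pos > t plus neg <= t
    pos_gt = pos.size - np.searchsorted(np.sort(pos), candidates, side="right")
    neg_le = np.searchsorted(np.sort(neg), candidates, side="right")
    acc_greater = (pos_gt + neg_le) / n
    # lesser_is_positive: pos < t plus neg >= t
    acc_lesser = (
        np.searchsorted(np.sort(pos), candidates, side="left")
        + neg.size - np.searchsorted(np.sort(neg), candidates, side="left")
    ) / n
    best_g = int(np.argmax(acc_greater))  # argmax takes the first (lowest) threshold
    best_l = int(np.argmax(acc_lesser))
    if acc_greater[best_g] >= acc_lesser[best_l]:
        return float(candidates[best_g]), float(acc_greater[best_g]), GREATER
    return float(candidates[best_l]), float(acc_lesser[best_l]), LESSER


def feature_roc(
    feature_name: str,
    pos_scores: Sequence[float],
    neg_scores: Sequence[float],
    accuracy_cutoff: float = ACCEPTABILITY_CUTOFF,
) -> ROCResult:
    threshold, accuracy, orientation = best_threshold_accuracy(pos_scores, neg_scores)
    return ROCResult(
        feature_name=feature_name,
        auc=auc(pos_scores, neg_scores),
        orientation=orientation,
        best_threshold=threshold,
        best_accuracy=accuracy,
        n_pos=len(pos_scores),
        n_neg=len(neg_scores),
        discriminative=accuracy > accuracy_cutoff,
    )


def feature_table_roc(
    matrix: pd.DataFrame,
    positive_label: str | None = None,
    accuracy_cutoff: float = ACCEPTABILITY_CUTOFF,
    label_column: str = "label",
    id_column: str = "id",
) -> list[ROCResult]:
    """One ROCResult per numeric feature column of a labeled table.

    The table needs an id column, a two-class label column and numeric
    feature columns (a descriptor table, a PseAAC matrix, or any
    user-supplied table of the same shape).  ``positive_label`` defaults
    to the first label in table order; the orientation maximization
    makes the results symmetric in that choice.
    """
    if label_column not in matrix.columns:
        raise ValueError(f"no {label_column!r} column in feature table")
    labels = matrix[label_column]
    classes = list(dict.fromkeys(labels))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if positive_label is None:
        positive_label = classes[0]
    elif positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} not in {classes}")
    is_pos = (labels == positive_label).to_numpy()
    results = []
    for col in matrix.columns:
        if col in (label_column, id_column):
            continue
        values = matrix[col]
        if not pd.api.types.is_numeric_dtype(values):
            continue
        arr = values.to_numpy(dtype=float)
        results.append(
            feature_roc(col, arr[is_pos], arr[~is_pos], accuracy_cutoff=accuracy_cutoff)
        )
    return results


def roc_report_frame(results: Sequence[ROCResult]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in results])


def write_roc_report(
    results: Sequence[ROCResult],
    tsv_path: str | Path | None = None,
    json_path: str | Path | None = None,
    accuracy_cutoff: float = ACCEPTABILITY_CUTOFF,
) -> None:
    frame = roc_report_frame(results)
    if tsv_path is not None:
        frame.to_csv(tsv_path, sep="\t", index=False, float_format="%.10g")
    if json_path is not None:
        payload = {
            "accuracy_definition": "best single-threshold accuracy over both orientations",
            "accuracy_cutoff": accuracy_cutoff,
            "features": [asdict(r) for r in results],
        }
        Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def plot_roc_curve(
    pos_scores: Sequence[float], neg_scores: Sequence[float], ax=None, label: str | None = None
):
    """Empirical ROC curve for one feature (greater-is-positive scores)."""
    import matplotlib.pyplot as plt

    pos = _as_array(pos_scores, "positive")
    neg = _as_array(neg_scores, "negative")
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    tpr = [(pos >= t).mean() for t in thresholds] + [1.0]
    fpr = [(neg >= t).mean() for t in thresholds] + [1.0]
    if ax is None:
        _, ax = plt.subplots()
    ax.plot([0.0] + fpr, [0.0] + tpr, drawstyle="steps-post", label=label)
    ax.plot([0, 1], [0, 1], linestyle=":", color="grey")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    if label:
        ax.legend()
    return ax
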