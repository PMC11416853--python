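"""Cross-validated two-class classification with four classifier families.

The four families mirror a common protein-classification toolbox:

* **OET-KNN** (evidence-theoretic k-nearest neighbor): each of the k
  nearest training neighbors of a test point contributes a
  Dempster-Shafer basic belief assignment — mass ``alpha *
  exp(-gamma_q * d^2)`` on its own class q, the remainder on the full
  frame of discernment — and the k assignments are fused with
  Dempster's rule; the class with the larger combined belief wins.
* **Covariance discriminant**: class-conditional Gaussians with
  per-class covariance (a quadratic discriminant), ridge-regularized
  for collinear feature columns.
* **SVM** and **random forest**: standard implementations from
  scikit-learn, seeded.

Evaluation is stratified k-fold cross-validation with pooled confusion
counts and the usual binary metrics

    ACC = (TP+TN)/(TP+TN+FP+FN)
    MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    Sn  = TP/(TP+FN)
    Sp  = TN/(TN+FP)

plus the fold-wise AUC mean and standard deviation.  MCC is defined as
0 when any marginal factor under the radical is 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .roc_stats import auc as mann_whitney_auc

CLASSIFIER_NAMES = ("oet_knn", "covariance_discriminant", "svm", "random_forest")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


def metrics(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """(acc, mcc, sn, sp) from confusion counts.

    Sn/Sp are NaN when their denominator is empty (no positives / no
    negatives evaluated); MCC is 0 when a marginal factor is 0.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    n = counts.total
    if n == 0:
        raise ValueError("no evaluated instances")
    acc = (tp + tn) / n
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    sn = tp / (tp + fn) if (tp + fn) else float("nan")
    sp = tn / (tn + fp) if (tn + fp) else float("nan")
    return acc, mcc, sn, sp


# ---------------------------------------------------------------------------
# OET-KNN

def _dempster_combine_two_class(masses: np.ndarray) -> np.ndarray:
    """Fuse k mass functions over the frame {pos, neg}.

    ``masses`` has rows (m_pos, m_neg, m_theta).  For singleton-or-frame
    assignments Dempster's rule reduces to products of "not the other
    class": unnormalized bel(pos) = prod(m_pos + m_theta) - prod(m_theta).
    Returns the normalized (bel_pos, bel_neg, bel_theta).
    """
    prod_theta = float(np.prod(masses[:, 2]))
    not_neg = float(np.prod(masses[:, 0] + masses[:, 2]))
    not_pos = float(np.prod(masses[:, 1] + masses[:, 2]))
    pos = not_neg - prod_theta
    neg = not_pos - prod_theta
    norm = pos + neg + prod_theta  # 1 - conflict
    if norm <= 0:  # total conflict: fall back to vacuous belief
        return np.array([0.0, 0.0, 1.0])
    return np.array([pos / norm, neg / norm, prod_theta / norm])


class OETKNNClassifier:
    """Evidence-theoretic k-nearest-neighbor classifier (two classes).

    gamma_q defaults to 1 / (mean squared within-class pairwise distance
    of class q on the training data), a published heuristic that adapts
    the evidence decay to each class's spread.
    """

    def __init__(self, k: int = 5, alpha: float = 0.95,
                 gamma: dict | None = None):
        if not 0 < alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {alpha}")
        self.k = k
        self.alpha = alpha
        self.gamma_override = gamma
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OETKNNClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.k > X.shape[0]:
            raise ValueError(f"k={self.k} exceeds training size {X.shape[0]}")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(f"need two classes, got {self.classes_}")
        self._X = X
        self._y_idx = np.searchsorted(self.classes_, y)
        self.gamma_ = {}
        for ci, cls in enumerate(self.classes_):
            if self.gamma_override is not None and cls in self.gamma_override:
                self.gamma_[ci] = float(self.gamma_override[cls])
                continue
            pts = X[self._y_idx == ci]
            if pts.shape[0] < 2:
                self.gamma_[ci] = 1.0
                continue
            d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
            mean_d2 = d2[np.triu_indices(pts.shape[0], k=1)].mean()
            self.gamma_[ci] = 1.0 / mean_d2 if mean_d2 > 0 else 1.0
        return self

    def _beliefs(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], 3))
        d2_all = (
            np.sum(X**2, axis=1)[:, None]
            - 2.0 * X @ self._X.T
            + np.sum(self._X**2, axis=1)[None, :]
        )
        np.maximum(d2_all, 0.0, out=d2_all)
        for i in range(X.shape[0]):
            # stable argsort breaks distance ties by training-row index
            nn = np.argsort(d2_all[i], kind="stable")[: self.k]
            masses = np.zeros((self.k, 3))
            for j, t in enumerate(nn):
                ci = self._y_idx[t]
                m = self.alpha * math.exp(-self.gamma_[ci] * d2_all[i, t])
                masses[j, ci] = m
                masses[j, 2] = 1.0 - m
            out[i] = _dempster_combine_two_class(masses)
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        bel = self._beliefs(X)
        # argmax over the two singleton beliefs; ties -> lower class index
        return self.classes_[(bel[:, 1] > bel[:, 0]).astype(int)]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Pignistic probability of the second class (classes_[1])."""
        bel = self._beliefs(X)
        return bel[:, 1] + 0.5 * bel[:, 2]


# ---------------------------------------------------------------------------
# Covariance discriminant

class CovarianceDiscriminant:
    """Quadratic discriminant: per-class Gaussian with ridge-stabilized
    covariance.  Score of class c for point x:

        -(x-mu_c)' Sigma_c^{-1} (x-mu_c) - log|Sigma_c| + 2 log prior_c

    Ridge default 1e-6 * trace(Sigma)/dim keeps collinear feature
    columns (e.g. PseAAC components, which sum to 1) invertible.
    """

    def __init__(self, ridge: float | None = None):
        self.ridge = ridge
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CovarianceDiscriminant":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        dim = X.shape[1]
        self._means, self._prec, self._logdet, self._logprior = [], [], [], []
        for cls in self.classes_:
            pts = X[y == cls]
            if pts.shape[0] < 2:
                raise ValueError(f"class {cls!r} has fewer than 2 training instances")
            mu = pts.mean(axis=0)
            cov = np.cov(pts, rowvar=False)
            ridge = self.ridge
            if ridge is None:
                ridge = 1e-6 * np.trace(cov) / dim
            cov = cov + ridge * np.eye(dim)
            sign, logdet = np.linalg.slogdet(cov)
            if sign <= 0:
                raise np.linalg.LinAlgError("covariance not positive definite")
            self._means.append(mu)
            self._prec.append(np.linalg.inv(cov))
            self._logdet.append(logdet)
            self._logprior.append(math.log(pts.shape[0] / X.shape[0]))
        return self

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], self.classes_.size))
        for ci in range(self.classes_.size):
            d = X - self._means[ci]
            maha = np.einsum("ij,jk,ik->i", d, self._prec[ci], d)
            out[:, ci] = -maha - self._logdet[ci] + 2.0 * self._logprior[ci]
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.scores(X), axis=1)]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        s = self.scores(X)
        return s[:, 1] - s[:, 0]


# ---------------------------------------------------------------------------
# Cross-validation driver

#: Which classifiers see standardized features (train-fold mean/sd).
_STANDARDIZE = {"oet_knn": True, "covariance_discriminant": False,
                "svm": True, "random_forest": False}


@dataclass(frozen=True)
class ClassifierSpec:
    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(f"unknown classifier {self.name!r}; choose from {CLASSIFIER_NAMES}")


def _build(spec: ClassifierSpec, seed: int):
    p = dict(spec.params)
    if spec.name == "oet_knn":
        return OETKNNClassifier(**p)
    if spec.name == "covariance_discriminant":
        return CovarianceDiscriminant(**p)
    if spec.name == "svm":
        p.setdefault("kernel", "rbf")
        p.setdefault("C", 1.0)
        return SVC(random_state=seed, **p)
    p.setdefault("n_estimators", 200)
    return RandomForestClassifier(random_state=seed, **p)


def _decision_scores(model, X: np.ndarray, positive) -> np.ndarray:
    if isinstance(model, (OETKNNClassifier, CovarianceDiscriminant)):
        s = model.decision_scores(X)
        return s if model.classes_[1] == positive else -s
    if isinstance(model, SVC):
        s = model.decision_function(X)
        return s if model.classes_[1] == positive else -s
    proba = model.predict_proba(X)
    col = int(np.where(model.classes_ == positive)[0][0])
    return proba[:, col]


@dataclass(frozen=True)
class EvaluationReport:
    """Pooled cross-validation result for one classifier."""

    classifier_name: str
    params: dict
    acc: float
    mcc: float
    sn: float
    sp: float
    auc_mean: float
    auc_sd: float
    pooled_counts: ConfusionCounts
    fold_counts: tuple[ConfusionCounts, ...]
    positive_label: str
    cv_scheme: str
    seed: int

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def cross_validate(
    matrix: pd.DataFrame,
    spec: ClassifierSpec,
    folds: int = 5,
    seed: int = 17,
    positive_label: str | None = None,
    jackknife: bool = False,
    label_column: str = "label",
    id_column: str = "id",
) -> EvaluationReport:
    """Stratified k-fold evaluation of one classifier on a feature table.

    ``matrix`` is the TSV-shaped frame produced by the descriptor or
    PseAAC stages (id, label, numeric columns).  ``jackknife=True``
    switches to leave-one-out (fold AUCs are then undefined and
    reported as NaN).  Deterministic given data, spec and seed.
    """
    feature_cols = [
        c for c in matrix.columns
        if c not in (label_column, id_column)
        and pd.api.types.is_numeric_dtype(matrix[c])
    ]
    if not feature_cols:
        raise ValueError("no numeric feature columns")
    X = matrix[feature_cols].to_numpy(dtype=float)
    y = matrix[label_column].to_numpy()
    classes = list(dict.fromkeys(matrix[label_column]))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if positive_label is None:
        positive_label = classes[0]
    class_counts = pd.Series(y).value_counts()
    n_folds = len(y) if jackknife else folds
    if not jackknife:
        if folds < 2:
            raise ValueError("folds must be >= 2")
        if class_counts.min() < folds:
            raise ValueError(
                f"smallest class has {class_counts.min()} members, fewer than {folds} folds"
            )

    standardize = _STANDARDIZE[spec.name]
    fold_counts: list[ConfusionCounts] = []
    fold_aucs: list[float] = []

    if jackknife:
        splits = [
            (np.delete(np.arange(len(y)), i), np.array([i])) for i in range(len(y))
        ]
    else:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(skf.split(X, y))

    for train_idx, test_idx in splits:
        X_tr, X_te = X[train_idx], X[test_idx]
        y_tr, y_te = y[train_idx], y[test_idx]
        if len(set(y_tr)) < 2:
            raise ValueError("degenerate single-class training fold")
        if standardize:
            mu = X_tr.mean(axis=0)
            sd = X_tr.std(axis=0)
            sd[sd == 0] = 1.0
            X_tr = (X_tr - mu) / sd
            X_te = (X_te - mu) / sd
        model = _build(spec, seed).fit(X_tr, y_tr)
        pred = model.predict(X_te)
        is_pos = y_te == positive_label
        pred_pos = pred == positive_label
        fold_counts.append(ConfusionCounts(
            tp=int(np.sum(is_pos & pred_pos)),
            tn=int(np.sum(~is_pos & ~pred_pos)),
            fp=int(np.sum(~is_pos & pred_pos)),
            fn=int(np.sum(is_pos & ~pred_pos)),
        ))
        if not jackknife and is_pos.any() and (~is_pos).any():
            scores = _decision_scores(model, X_te, positive_label)
            fold_aucs.append(mann_whitney_auc(scores[is_pos], scores[~is_pos]))

    pooled = ConfusionCounts()
    for c in fold_counts:
        pooled = pooled + c
    acc, mcc, sn, sp = metrics(pooled)
    auc_arr = np.array(fold_aucs) if fold_aucs else np.array([float("nan")])
    return EvaluationReport(
        classifier_name=spec.name,
        params=dict(spec.params),
        acc=acc, mcc=mcc, sn=sn, sp=sp,
        auc_mean=float(np.mean(auc_arr)),
        auc_sd=float(np.std(auc_arr, ddof=1)) if auc_arr.size > 1 else 0.0,
        pooled_counts=pooled,
        fold_counts=tuple(fold_counts),
        positive_label=str(positive_label),
        cv_scheme="jackknife" if jackknife else f"stratified {folds}-fold, shuffled",
        seed=seed,
    )


def evaluate_classifiers(
    matrix: pd.DataFrame,
    specs: Sequence[ClassifierSpec] | None = None,
    folds: int = 5,
    seed: int = 17,
    positive_label: str | None = None,
    jackknife: bool = False,
) -> list[EvaluationReport]:
    """Run the four default classifiers (or a custom list) on one matrix."""
    if specs is None:
        specs = [ClassifierSpec(name) for name in CLASSIFIER_NAMES]
    return [
        cross_validate(matrix, s, folds=folds, seed=seed,
                       positive_label=positive_label, jackknife=jackknife)
        for s in specs
    ]


def report_frame(reports: Sequence[EvaluationReport]) -> pd.DataFrame:
    """Tabular summary: one row per classifier with ACC/MCC/AUC/Sn/Sp."""
    return pd.DataFrame([
        {
            "classifier": r.classifier_name,
            "acc": r.acc, "mcc": r.mcc,
            "auc_mean": r.auc_mean, "auc_sd": r.auc_sd,
            "sn": r.sn, "sp": r.sp,
        }
        for r in reports
    ])


def write_reports(
    reports: Sequence[EvaluationReport],
    tsv_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> None:
    if tsv_path is not None:
        report_frame(reports).to_csv(tsv_path, sep="\t", index=False, float_format="%.10g")
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps([r.to_dict() for r in reports], indent=2, sort_keys=True) + "\n"
        )
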