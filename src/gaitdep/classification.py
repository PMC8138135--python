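"""Diagnostic classification: linear SVM, backward feature selection, CV.

The case/control recognition stage trains a linear-kernel support vector
machine on each of the seven nonempty combinations of the three feature
banks and reports stratified 10-fold cross-validated sensitivity (recall of
cases), specificity (recall of controls) and AUC, averaged across folds,
plus a pooled out-of-fold ROC curve for plotting.  Sequential backward
selection (SBS) optionally prunes features first: starting from the full
set it greedily removes the feature whose removal best preserves mean CV
accuracy, stopping when every removal would reduce it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ClassifierReport",
    "train_svm",
    "sbs_select",
    "crossval_evaluate",
    "run_block_combinations",
    "BLOCK_COMBINATIONS",
]

BLOCKS = ("spatiotemporal", "time", "frequency")
BLOCK_COMBINATIONS: tuple[tuple[str, ...], ...] = tuple(
    combo for r in (1, 2, 3) for combo in combinations(BLOCKS, r)
)


@dataclass
class ClassifierReport:
    """Cross-validated performance of one feature-block combination."""

    block_combination: tuple[str, ...]
    fold_sensitivity: np.ndarray
    fold_specificity: np.ndarray
    fold_auc: np.ndarray
    roc_points: np.ndarray                  # (m, 2) pooled (FPR, TPR)
    selected_features: list[str] = field(default_factory=list)
    seed: int = 0

    @property
    def sensitivity(self) -> float:
        return float(np.mean(self.fold_sensitivity))

    @property
    def specificity(self) -> float:
        return float(np.mean(self.fold_specificity))

    @property
    def auc(self) -> float:
        return float(np.mean(self.fold_auc))

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "blocks": "+".join(self.block_combination),
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "auc": self.auc,
            }
        )


def _svm_pipeline(C: float = 1.0) -> Pipeline:
    return Pipeline(
        [("scale", StandardScaler()), ("svm", SVC(kernel="linear", C=C))]
    )


def train_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> SVC:
    """Fit a linear-kernel SVM on (already standardized) features."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    model = SVC(kernel="linear", C=C)
    model.fit(np.asarray(X, dtype=float), y)
    return model


def _cv_accuracy(X: np.ndarray, y: np.ndarray, k: int, seed: int, C: float) -> float:
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return float(np.mean(cross_val_score(_svm_pipeline(C), X, y, cv=cv)))


def sbs_select(X: pd.DataFrame, y: np.ndarray, evaluator=None,
               k: int = 10, seed: int = 0, C: float = 1.0) -> list[str]:
    """Sequential backward selection of feature columns.

    Greedy elimination: at each step the feature whose removal maximizes the
    evaluator (default: mean stratified k-fold CV accuracy of the linear
    SVM with within-fold standardization) is dropped, provided the evaluator
    does not fall below its current value — ties favor the smaller set.
    Selection stops when every candidate removal would lower the evaluator
    or a single feature remains.
    """
    if X.shape[1] < 2:
        raise ValueError("SBS needs at least 2 features")
    if evaluator is None:
        evaluator = lambda Xs, ys: _cv_accuracy(Xs, ys, k, seed, C)  # noqa: E731
    y = np.asarray(y)
    current = list(X.columns)
    score = evaluator(X[current].to_numpy(), y)
    while len(current) > 1:
        best_score, best_feature = -np.inf, None
        for f in current:
            trial = [c for c in current if c != f]
            s = evaluator(X[trial].to_numpy(), y)
            if s > best_score:
                best_score, best_feature = s, f
        if best_score >= score:
            current.remove(best_feature)
            score = best_score
        else:
            break
    return current


def crossval_evaluate(X: pd.DataFrame | np.ndarray, y: np.ndarray, k: int = 10,
                      seed: int = 0, C: float = 1.0,
                      block_combination: tuple[str, ...] = (),
                      selected_features: list[str] | None = None) -> ClassifierReport:
    """Stratified k-fold CV of the linear SVM with per-fold standardization.

    Sensitivity treats label 1 (case) as positive; AUC uses the SVM decision
    scores with midrank tie handling; the pooled out-of-fold scores provide
    the ROC points for plotting.
    """
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(y) < k:
        raise ValueError(f"need at least k={k} samples")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError("each class needs at least k members for stratified CV")
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    sens, spec, aucs = [], [], []
    pooled_scores = np.empty(len(y))
    for train_idx, test_idx in cv.split(Xa, y):
        pipe = _svm_pipeline(C)
        pipe.fit(Xa[train_idx], y[train_idx])
        pred = pipe.predict(Xa[test_idx])
        scores = pipe.decision_function(Xa[test_idx])
        yt = y[test_idx]
        tp = int(np.sum((pred == 1) & (yt == 1)))
        fn = int(np.sum((pred == 0) & (yt == 1)))
        tn = int(np.sum((pred == 0) & (yt == 0)))
        fp = int(np.sum((pred == 1) & (yt == 0)))
        sens.append(tp / (tp + fn))
        spec.append(tn / (tn + fp))
        aucs.append(roc_auc_score(yt, scores))
        pooled_scores[test_idx] = scores
    fpr, tpr, _ = roc_curve(y, pooled_scores)
    return ClassifierReport(
        block_combination=tuple(block_combination),
        fold_sensitivity=np.array(sens),
        fold_specificity=np.array(spec),
        fold_auc=np.array(aucs),
        roc_points=np.column_stack([fpr, tpr]),
        selected_features=list(selected_features or []),
        seed=seed,
    )


def run_block_combinations(features_by_block: dict[str, pd.DataFrame],
                           y: np.ndarray, k: int = 10, seed: int = 0,
                           C: float = 1.0,
                           feature_selection: str = "sbs") -> list[ClassifierReport]:
    """Evaluate all seven nonempty feature-bank combinations.

    Every combination uses the identical fold assignment (same seed and
    labels) so the reports are directly comparable.  ``feature_selection``
    is ``"sbs"`` (backward selection before CV, on the pooled data) or
    ``"none"``; SBS over the full signal-feature banks is expensive, so
    large studies typically run with ``"none"``.
    """
    if set(features_by_block) != set(BLOCKS):
        raise ValueError(f"features_by_block must have keys {BLOCKS}")
    if feature_selection not in ("sbs", "none"):
        raise ValueError("feature_selection must be 'sbs' or 'none'")
    y = np.asarray(y, dtype=int)
    reports = []
    for combo in BLOCK_COMBINATIONS:
        X = pd.concat([features_by_block[b] for b in combo], axis=1)
        if feature_selection == "sbs" and X.shape[1] >= 2:
            kept = sbs_select(X, y, k=k, seed=seed, C=C)
            X = X[kept]
        else:
            kept = list(X.columns)
        reports.append(
            crossval_evaluate(X, y, k=k, seed=seed, C=C,
                              block_combination=combo, selected_features=kept)
        )
    return reports
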