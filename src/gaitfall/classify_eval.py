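"""MLP training, stratified 10-fold evaluation and model selection.

The classifier is a single-hidden-layer perceptron (ReLU activation,
stochastic-gradient solver, L2 alpha 1e-4, at most 200 epochs) whose hidden
size is swept from 10 to 200 in steps of 10. Evaluation is stratified
10-fold cross-validation with fold-aware min-max scaling (fit on the
training folds only); the out-of-fold predictions of all folds are pooled
into a single confusion matrix, from which accuracy, sensitivity (faller
recall) and specificity (non-faller recall) are computed. AUC comes from
the pooled out-of-fold scores.

Model selection over a (K, N, hidden) grid is lexicographic: highest
accuracy, then highest sensitivity, then fewest features N, then fewest
hidden units, then smallest K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .errors import CohortInvalidError, TrainingFailedError, UndefinedMetricError
from .feature_table import FeatureMatrix, fit_minmax

HIDDEN_SWEEP_DEFAULT = tuple(range(10, 201, 10))
N_FOLDS_DEFAULT = 10
SCORE_THRESHOLD = 0.5


@dataclass
class MLPConfig:
    """Hyper-parameters of the perceptron; unlisted ones follow the
    scikit-learn defaults."""

    hidden_units: int = 50
    l2_alpha: float = 1e-4
    max_epochs: int = 200
    seed: int = 0
    activation: str = "relu"
    solver: str = "sgd"

    def validate(self) -> None:
        if self.hidden_units < 1 or self.l2_alpha <= 0 or self.max_epochs < 1:
            raise CohortInvalidError(f"invalid MLP config: {self}")


@dataclass
class ConfusionMatrix:
    """Pooled out-of-fold counts; positive class = faller."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class EvaluationReport:
    """Pooled cross-validation outcome for one (K, N, hidden) configuration."""

    cm: ConfusionMatrix
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    hidden_units: int
    K: int | None = None
    N: int | None = None
    seed: int = 0
    fold_assignment: np.ndarray | None = None
    failed_folds: list[int] = field(default_factory=list)

    def as_row(self) -> dict:
        return {
            "K": self.K,
            "N": self.N,
            "hidden_units": self.hidden_units,
            "AUC": self.auc,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "TP": self.cm.tp,
            "FN": self.cm.fn,
            "FP": self.cm.fp,
            "TN": self.cm.tn,
        }


def compute_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) from pooled counts."""
    if min(cm.tp, cm.fn, cm.fp, cm.tn) < 0 or cm.total == 0:
        raise UndefinedMetricError("confusion counts must be nonnegative, total > 0")
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise UndefinedMetricError("a class has no evaluated subjects")
    accuracy = (cm.tp + cm.tn) / cm.total
    sensitivity = cm.tp / (cm.tp + cm.fn)
    specificity = cm.tn / (cm.tn + cm.fp)
    return accuracy, sensitivity, specificity


def stratified_folds(
    labels: np.ndarray, n_folds: int = N_FOLDS_DEFAULT, seed: int = 0
) -> np.ndarray:
    """Fold index per subject; folds are class-balanced and seed-deterministic.

    If the smaller class has fewer members than ``n_folds`` the fold count is
    reduced to that class size, with a warning.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise CohortInvalidError("stratified folds need both classes present")
    smallest = int(counts.min())
    if smallest < n_folds:
        warnings.warn(
            f"reducing folds from {n_folds} to {smallest} (smallest class size)",
            stacklevel=2,
        )
        n_folds = smallest
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(y.size, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((y.size, 1)), y)):
        assignment[test_idx] = fold
    return assignment


class _MLPScorer:
    """Trained perceptron exposing a continuous faller score and 0.5-threshold class."""

    def __init__(self, model: MLPClassifier):
        self._model = model

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        return self._model.predict_proba(np.asarray(X, dtype=float))[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.score_samples(X) >= SCORE_THRESHOLD).astype(int)


def train_mlp(X: np.ndarray, y: np.ndarray, cfg: MLPConfig) -> _MLPScorer:
    """Fit the perceptron on (scaled) features; deterministic given cfg.seed."""
    cfg.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise TrainingFailedError("training set has a single class")
    if X.size == 0 or np.all(np.ptp(X, axis=0) == 0):
        raise TrainingFailedError("all feature columns are constant")
    model = MLPClassifier(
        hidden_layer_sizes=(cfg.hidden_units,),
        activation=cfg.activation,
        solver=cfg.solver,
        alpha=cfg.l2_alpha,
        max_iter=cfg.max_epochs,
        random_state=cfg.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return _MLPScorer(model)


def cross_validate(
    X: pd.DataFrame,
    y: np.ndarray,
    cfg: MLPConfig,
    seed: int = 0,
    n_folds: int = N_FOLDS_DEFAULT,
    scale: bool = True,
    trainer=train_mlp,
) -> EvaluationReport:
    """Stratified k-fold CV with pooled out-of-fold confusion counts.

    Scaling parameters are fit on the training folds and applied to the test
    fold. Folds whose training fails are recorded in ``failed_folds`` and
    their subjects left out of the pooled counts. ``trainer`` is the pluggable
    scorer factory (default: the MLP); it must return an object with
    ``score_samples``.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=int)
    assignment = stratified_folds(y, n_folds=n_folds, seed=seed)
    scores = np.full(y.size, np.nan)
    preds = np.full(y.size, -1)
    failed: list[int] = []
    for fold in np.unique(assignment):
        test = assignment == fold
        train = ~test
        Xtr, Xte = X.iloc[train], X.iloc[test]
        if scale:
            params = fit_minmax(Xtr)
            Xtr, Xte = params.transform(Xtr), params.transform(Xte)
        fold_seed = (cfg.seed * 1000003 + int(fold)) % (2**31)
        try:
            scorer = trainer(
                Xtr.to_numpy(), y[train], replace(cfg, seed=fold_seed)
            )
        except TrainingFailedError:
            failed.append(int(fold))
            continue
        scores[test] = scorer.score_samples(Xte.to_numpy())
        preds[test] = (scores[test] >= SCORE_THRESHOLD).astype(int)
    evaluated = preds >= 0
    cm = ConfusionMatrix(
        tp=int(np.sum((y == 1) & (preds == 1))),
        fn=int(np.sum((y == 1) & evaluated & (preds == 0))),
        fp=int(np.sum((y == 0) & (preds == 1))),
        tn=int(np.sum((y == 0) & evaluated & (preds == 0))),
    )
    accuracy, sensitivity, specificity = compute_metrics(cm)
    pooled = evaluated & np.isfinite(scores)
    if np.unique(y[pooled]).size == 2 and np.ptp(scores[pooled]) > 0:
        auc = float(roc_auc_score(y[pooled], scores[pooled]))
    else:
        auc = 0.5
    return EvaluationReport(
        cm=cm,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        auc=auc,
        hidden_units=cfg.hidden_units,
        seed=seed,
        fold_assignment=assignment,
        failed_folds=failed,
    )


def model_select(reports: list[EvaluationReport]) -> EvaluationReport:
    """Lexicographic: max accuracy, max sensitivity, min N, min hidden, min K."""
    if not reports:
        raise CohortInvalidError("model_select needs a nonempty grid")
    return min(
        reports,
        key=lambda r: (
            -r.accuracy,
            -r.sensitivity,
            r.N if r.N is not None else 0,
            r.hidden_units,
            r.K if r.K is not None else 0,
        ),
    )


def make_mlp_eval_fn(
    matrix: FeatureMatrix,
    hidden_sweep=HIDDEN_SWEEP_DEFAULT,
    n_folds: int = N_FOLDS_DEFAULT,
    seed: int = 0,
):
    """Evaluation callback for the selection sweep.

    For one feature subset, cross-validates every hidden size in the sweep
    and returns the best report by (accuracy, sensitivity, fewest hidden
    units); per-cell MLP seeds are derived from the global seed and the cell
    coordinates so results do not depend on execution order.
    """
    y = matrix.y()

    def eval_fn(names: list[str], K: int, N: int) -> EvaluationReport:
        sub = matrix.X[names]
        best: EvaluationReport | None = None
        for h in hidden_sweep:
            cell_seed = (seed * 7919 + K * 101 + N) % (2**31)
            cfg = MLPConfig(hidden_units=h, seed=cell_seed)
            report = cross_validate(sub, y, cfg, seed=seed, n_folds=n_folds)
            report.K, report.N = K, N
            if best is None or (-report.accuracy, -report.sensitivity, report.hidden_units) < (
                -best.accuracy,
                -best.sensitivity,
                best.hidden_units,
            ):
                best = report
        return best

    return eval_fn
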