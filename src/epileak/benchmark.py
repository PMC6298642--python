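"""Train/test benchmark harness, metrics, and analytic baselines.

The harness fits a classifier per cross-validation fold and records *both*
training-fold and held-out metrics (precision, recall, F1, AUROC, AUPRC).
Comparing the two across fold schemes is the core diagnostic: a large
train-test gap at high model capacity signals memorization, and a test
score that collapses when folds are made leakage-free was never
generalization in the first place.

Analytic baselines anchor "random" performance under class imbalance: a
classifier predicting every pair positive has precision equal to the
prevalence p and recall 1, hence F1 = 2p / (1 + p) — 1/11 at a 1:20
positive:negative ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.ensemble import (
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import (
    average_precision_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC

from .cv_schemes import CVPartition
from .ep_data import EPDataset, EPDataError, feature_subset

__all__ = [
    "ModelSpec",
    "Metrics",
    "BenchmarkResult",
    "f1_score",
    "all_positive_f1",
    "compute_metrics",
    "evaluate",
    "parameter_scan",
]

FAMILIES = ("gradient_boosting", "random_forest", "rbf_svm", "linear_svm")

METRIC_NAMES = ("precision", "recall", "f1", "auroc", "auprc")


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus the hyperparameters varied in the scans.

    ``n_trees`` applies to the tree ensembles (default 4000 for gradient
    boosting, the capacity at which published EP classifiers reached their
    headline scores).  ``C`` weights misclassification error and ``gamma``
    sets the RBF kernel scale for the SVM families; ``gamma=None`` means
    the 1/n_features default.  ``tree_method='hist'`` uses histogram-based
    gradient boosting; ``'exact'`` uses the classical implementation.
    All other hyperparameters stay at scikit-learn's documented defaults.
    """

    family: str
    n_trees: int = 4000
    C: float = 1.0
    gamma: Optional[float] = None
    tree_method: str = "hist"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise EPDataError(f"unknown model family {self.family!r}")
        if self.n_trees < 1:
            raise EPDataError("n_trees must be >= 1")
        if self.C <= 0:
            raise EPDataError("C must be > 0")
        if self.gamma is not None and self.gamma <= 0:
            raise EPDataError("gamma must be > 0")
        if self.tree_method not in ("hist", "exact"):
            raise EPDataError("tree_method must be 'hist' or 'exact'")

    @property
    def needs_scaling(self) -> bool:
        return self.family in ("rbf_svm", "linear_svm")

    def label(self) -> str:
        if self.family in ("gradient_boosting", "random_forest"):
            return f"{self.family}(n_trees={self.n_trees})"
        gamma = "1/n_features" if self.gamma is None else f"{self.gamma:g}"
        if self.family == "rbf_svm":
            return f"rbf_svm(C={self.C:g}, gamma={gamma})"
        return f"linear_svm(C={self.C:g})"


@dataclass(frozen=True)
class Metrics:
    """Threshold metrics plus ranking metrics for one model on one split.

    ``auroc`` and ``auprc`` are NaN when the split contains a single
    class, in which case ranking quality is undefined.
    """

    precision: float
    recall: float
    f1: float
    auroc: float
    auprc: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def f1_score(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0 <= p <= 1 and 0 <= r <= 1):
        raise EPDataError(f"precision and recall must be in [0, 1], got {p}, {r}")
    if p + r == 0:
        return 0.0
    return 2 * p * r / (p + r)


def all_positive_f1(pos_fraction: float) -> float:
    """F1 of predicting every pair positive at the given prevalence.

    Precision equals the prevalence, recall is 1, so
    F1 = 2p / (1 + p); at p = 1/21 (a 1:20 ratio) this is 1/11 — the
    floor against which test performance should be judged.
    """
    if not (0 < pos_fraction <= 1):
        raise EPDataError(f"pos_fraction must be in (0, 1], got {pos_fraction}")
    return 2 * pos_fraction / (1 + pos_fraction)


def compute_metrics(
    labels: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> Metrics:
    """Score a set of predictions against binary labels.

    Precision/recall/F1 come from thresholding the scores at
    ``threshold``; AUROC and AUPRC come from the score ranking with tied
    scores averaged.  Single-class label sets yield NaN ranking metrics.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1 or y.size == 0:
        raise EPDataError("labels and scores must be equal-length 1-D, non-empty")
    pred = (s >= threshold).astype(int)
    p = precision_score(y, pred, zero_division=0)
    r = recall_score(y, pred, zero_division=0)
    if y.min() == y.max():
        auroc = auprc = float("nan")
    else:
        auroc = roc_auc_score(y, s)
        auprc = average_precision_score(y, s)
    return Metrics(float(p), float(r), f1_score(p, r), float(auroc), float(auprc))


def build_estimator(spec: ModelSpec, n_features: int, seed: int):
    """Instantiate the scikit-learn estimator for a model spec."""
    if spec.family == "gradient_boosting":
        if spec.tree_method == "hist":
            return HistGradientBoostingClassifier(
                max_iter=spec.n_trees, early_stopping=False, random_state=seed
            )
        return GradientBoostingClassifier(n_estimators=spec.n_trees, random_state=seed)
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=spec.n_trees, random_state=seed, n_jobs=1
        )
    gamma = spec.gamma if spec.gamma is not None else 1.0 / n_features
    if spec.family == "rbf_svm":
        return SVC(kernel="rbf", C=spec.C, gamma=gamma, random_state=seed)
    return LinearSVC(C=spec.C, random_state=seed)


def _positive_scores(model, X: np.ndarray) -> np.ndarray:
    """Positive-class score in [0, 1] for any supported estimator.

    Tree ensembles expose predicted probabilities directly; SVM decision
    values are squashed through a logistic so that a decision value of 0
    maps to 0.5 and the 0.5 threshold reproduces the SVM's own class
    prediction while preserving the ranking.
    """
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return expit(model.decision_function(X))


@dataclass
class BenchmarkResult:
    """Per-fold train/test metrics plus pooled test metrics per config.

    ``table`` holds one row per (scheme, blocks, model, fold) with
    ``train_*`` and ``test_*`` metric columns; ``pooled`` holds one row
    per configuration with test metrics computed on the concatenated
    held-out predictions of all folds.
    """

    table: pd.DataFrame
    pooled: pd.DataFrame

    def mean_test(self, metric: str = "f1") -> float:
        """Mean of a test metric over folds (NaN folds ignored)."""
        return float(np.nanmean(self.table[f"test_{metric}"]))

    def mean_train(self, metric: str = "f1") -> float:
        return float(np.nanmean(self.table[f"train_{metric}"]))

    def summary(self) -> pd.DataFrame:
        """Fold-averaged train/test metrics per configuration."""
        keys = ["scheme", "blocks", "model"]
        cols = [f"{split}_{m}" for split in ("train", "test") for m in METRIC_NAMES]
        return self.table.groupby(keys, sort=False)[cols].mean().reset_index()

    @staticmethod
    def concat(results: Iterable["BenchmarkResult"]) -> "BenchmarkResult":
        results = list(results)
        return BenchmarkResult(
            pd.concat([r.table for r in results], ignore_index=True),
            pd.concat([r.pooled for r in results], ignore_index=True),
        )


def evaluate(
    dataset: EPDataset,
    partition: CVPartition,
    blocks: Iterable[str],
    spec: ModelSpec,
    run_seed: int = 0,
    threshold: float = 0.5,
) -> BenchmarkResult:
    """Cross-validated train/test evaluation of one model configuration.

    For each fold the model is fit on the remaining folds, then scored on
    both the training folds and the held-out fold.  SVM families see
    features standardized with training-fold statistics only; tree
    families consume raw features.  Per-fold model seeds derive
    deterministically from ``run_seed``.

    Folds whose held-out part contains a single class get NaN ranking
    metrics and a warning, and the run continues.
    """
    if partition.n_pairs != dataset.n_pairs:
        raise EPDataError("partition does not cover the dataset")
    blocks = sorted(set(blocks))
    ft = feature_subset(dataset, blocks)
    X = ft.values
    y = dataset.labels
    blocks_label = "".join(b for b in ("E", "P", "W") if b in blocks)

    rows = []
    all_test_scores = np.empty(dataset.n_pairs)
    for fold in range(partition.k):
        tr = partition.train_indices(fold)
        te = partition.test_indices(fold)
        X_tr, X_te = X[tr], X[te]
        if spec.needs_scaling:
            scaler = StandardScaler().fit(X_tr)
            X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
        model = build_estimator(
            spec, ft.n_features, seed=(run_seed * 100_003 + fold) % (2**31)
        )
        model.fit(X_tr, y[tr])
        s_tr = _positive_scores(model, X_tr)
        s_te = _positive_scores(model, X_te)
        all_test_scores[te] = s_te
        if y[te].min() == y[te].max():
            warnings.warn(
                f"fold {fold} held-out set has a single class; its ranking "
                "metrics are undefined",
                stacklevel=2,
            )
        rows.append(
            {
                "scheme": partition.scheme,
                "blocks": blocks_label,
                "model": spec.label(),
                "fold": fold,
                "n_train": len(tr),
                "n_test": len(te),
                **{f"train_{m}": v for m, v in compute_metrics(y[tr], s_tr, threshold).as_dict().items()},
                **{f"test_{m}": v for m, v in compute_metrics(y[te], s_te, threshold).as_dict().items()},
            }
        )
    pooled = compute_metrics(y, all_test_scores, threshold)
    pooled_row = pd.DataFrame(
        [
            {
                "scheme": partition.scheme,
                "blocks": blocks_label,
                "model": spec.label(),
                **{f"test_{m}": v for m, v in pooled.as_dict().items()},
            }
        ]
    )
    return BenchmarkResult(pd.DataFrame(rows), pooled_row)


def parameter_scan(
    dataset: EPDataset,
    partitions: Sequence[CVPartition],
    grid: Sequence[tuple[Iterable[str], ModelSpec]],
    run_seed: int = 0,
) -> BenchmarkResult:
    """Evaluate a grid of (feature blocks, model) configs over partitions.

    Results are simply concatenated; each cell is an independent
    `evaluate` run, so execution order cannot affect the numbers.
    """
    if not grid:
        raise EPDataError("grid must be non-empty")
    results = [
        evaluate(dataset, part, blocks, spec, run_seed=run_seed)
        for part in partitions
        for blocks, spec in grid
    ]
    return BenchmarkResult.concat(results)
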