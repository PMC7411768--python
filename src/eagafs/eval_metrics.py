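"""Evaluation harness: clamped MLP classification, metrics, CV, model comparison.

The selected attribute subset is judged with a multilayer perceptron whose
weights are projected into [-0.5, 0.5] after every training epoch — a
simple capacity control against overfitting on small clinical tables.
Reports carry accuracy, precision, recall, F-score (all in percent),
latency (model build time + prediction time) and the raw confusion counts.

Two fitted models can be compared with a one-sided pooled two-proportion
z-test on their correct-classification counts: with y1 and y2 correct out
of m samples each, a1 = y1/m, a2 = y2/m, a = (y1+y2)/(2m),

    S = (a1 - a2) / sqrt(2 * a * (1 - a) / m),

and the null "both models are equally accurate" is rejected in favour of
model 2 when S < -z_(1-alpha) (1.645 at alpha = 0.05).  Everything is on
the proportion scale.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import confusion_matrix
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .dataset_io import FoldPlan, SplitPlan, TabularDataset, split_train_test
from .wrapper_fitness import design_matrix, subset_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierSpec",
    "ClampedMLP",
    "EvalReport",
    "ComparisonTest",
    "train_mlp",
    "compute_metrics",
    "evaluate_split",
    "cross_validate",
    "compare_models",
    "sweep",
]


@dataclass
class ClassifierSpec:
    """MLP configuration.

    ``hidden_layers=None`` uses one hidden layer of ceil((attributes + 2)/2)
    units.  ``max_weight_magnitude`` is the post-epoch projection bound on
    every weight and bias.
    """

    hidden_layers: tuple[int, ...] | None = None
    max_weight_magnitude: float = 0.5
    epochs: int = 100
    learning_seed: int = 0
    learning_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.max_weight_magnitude <= 0:
            raise ValueError("max_weight_magnitude must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be positive")


class ClampedMLP:
    """MLP trained one epoch at a time with weights clipped after each epoch.

    Inputs are standardized internally.  Training is deterministic for a
    fixed ``learning_seed`` (fixed epoch budget; non-convergence is not an
    error).
    """

    def __init__(self, spec: ClassifierSpec):
        self.spec = spec
        self._scaler: StandardScaler | None = None
        self._mlp: MLPClassifier | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ClampedMLP":
        spec = self.spec
        hidden = spec.hidden_layers
        if hidden is None:
            hidden = (int(np.ceil((X.shape[1] + 2) / 2)),)
        self._scaler = StandardScaler().fit(X)
        Xs = self._scaler.transform(X)
        self._mlp = MLPClassifier(
            hidden_layer_sizes=hidden,
            solver="sgd",
            learning_rate_init=spec.learning_rate,
            momentum=0.9,
            random_state=spec.learning_seed,
            max_iter=1,
            warm_start=False,
        )
        classes = np.unique(y)
        bound = spec.max_weight_magnitude
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(spec.epochs):
                self._mlp.partial_fit(Xs, y, classes=classes)
                for w in self._mlp.coefs_:
                    np.clip(w, -bound, bound, out=w)
                for b in self._mlp.intercepts_:
                    np.clip(b, -bound, bound, out=b)
        return self

    @property
    def weights(self) -> list[np.ndarray]:
        if self._mlp is None:
            raise RuntimeError("model is not fitted")
        return list(self._mlp.coefs_) + list(self._mlp.intercepts_)

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._mlp is None or self._scaler is None:
            raise RuntimeError("model is not fitted")
        return self._mlp.predict(self._scaler.transform(X))


def train_mlp(train: TabularDataset, spec: ClassifierSpec | None = None) -> ClampedMLP:
    """Fit a weight-clamped MLP on a dataset (both classes required)."""
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training data must contain both classes")
    spec = spec or ClassifierSpec()
    return ClampedMLP(spec).fit(design_matrix(train), train.labels)


@dataclass
class EvalReport:
    """Classification report; rates in percent, latency in seconds."""

    accuracy: float
    precision: float
    recall: float
    f_score: float
    latency_seconds: float
    confusion: tuple[int, int, int, int]  # (tp, fp, fn, tn)
    flags: list[str] = field(default_factory=list)
    per_fold: list["EvalReport"] | None = None

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f_score,
            "latency_seconds": self.latency_seconds,
            "confusion": {"tp": self.confusion[0], "fp": self.confusion[1],
                          "fn": self.confusion[2], "tn": self.confusion[3]},
            "flags": self.flags,
        }
        if self.per_fold is not None:
            d["per_fold"] = [f.to_dict() for f in self.per_fold]
        return d


def compute_metrics(
    confusion: tuple[int, int, int, int], latency_seconds: float = 0.0
) -> EvalReport:
    """Accuracy / precision / recall / F-score (percent) from (tp, fp, fn, tn).

    Zero-denominator ratios are reported as 0 with an explanatory flag.
    """
    tp, fp, fn, tn = confusion
    total = tp + fp + fn + tn
    if total < 1:
        raise ValueError("confusion counts must sum to at least 1")
    flags: list[str] = []
    accuracy = 100.0 * (tp + tn) / total
    if tp + fp:
        precision = 100.0 * tp / (tp + fp)
    else:
        precision, flags = 0.0, flags + ["precision undefined (no positive predictions)"]
    if tp + fn:
        recall = 100.0 * tp / (tp + fn)
    else:
        recall, flags = 0.0, flags + ["recall undefined (no positive instances)"]
    if precision + recall:
        f_score = 2 * precision * recall / (precision + recall)
    else:
        f_score, flags = 0.0, flags + ["f-score undefined (precision + recall = 0)"]
    return EvalReport(
        accuracy=accuracy, precision=precision, recall=recall, f_score=f_score,
        latency_seconds=latency_seconds, confusion=(tp, fp, fn, tn), flags=flags,
    )


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    cm = confusion_matrix(y_true, y_pred, labels=[0, 1])
    tn, fp, fn, tp = cm.ravel()
    return int(tp), int(fp), int(fn), int(tn)


def evaluate_split(
    ds: TabularDataset,
    chromosome: Sequence[int],
    spec: ClassifierSpec | None = None,
    split: SplitPlan | None = None,
    model=None,
) -> EvalReport:
    """Train on the split's train share, report on its test share.

    ``model`` may override the classifier with any fit/predict object (e.g.
    a stub); latency = model build time + prediction time.
    """
    sub = subset_dataset(ds, chromosome)
    if split is None:
        split = split_train_test(sub, 0.6, seed=0)
    X = design_matrix(sub)
    y = sub.labels
    tr, te = split.train_indices, split.test_indices
    t0 = time.perf_counter()
    if model is None:
        spec = spec or ClassifierSpec()
        model = ClampedMLP(spec).fit(X[tr], y[tr])
    else:
        model.fit(X[tr], y[tr])
    t1 = time.perf_counter()
    pred = model.predict(X[te])
    t2 = time.perf_counter()
    return compute_metrics(_confusion(y[te], pred), (t1 - t0) + (t2 - t1))


def cross_validate(
    ds: TabularDataset,
    chromosome: Sequence[int],
    spec: ClassifierSpec | None = None,
    folds: FoldPlan | None = None,
    model_factory=None,
) -> EvalReport:
    """k-fold cross-validation of the chromosome's subset.

    Each fold in turn is the test set while the others train the model; the
    summary report is the arithmetic mean of the per-fold rates (summed
    confusion, summed latency).  Folds whose training share lacks a class
    are skipped with a warning and flagged in the report.
    """
    sub = subset_dataset(ds, chromosome)
    if folds is None:
        raise ValueError("a FoldPlan is required")
    X = design_matrix(sub)
    y = sub.labels
    reports: list[EvalReport] = []
    flags: list[str] = []
    for i, test_idx in enumerate(folds.folds):
        train_idx = np.setdiff1d(np.arange(sub.n_rows), test_idx)
        if len(np.unique(y[train_idx])) < 2 or not len(test_idx):
            warnings.warn(f"fold {i} skipped: training share lacks a class",
                          stacklevel=2)
            flags.append(f"fold {i} skipped (single-class training share)")
            continue
        t0 = time.perf_counter()
        if model_factory is None:
            model = ClampedMLP(spec or ClassifierSpec()).fit(X[train_idx], y[train_idx])
        else:
            model = model_factory()
            model.fit(X[train_idx], y[train_idx])
        t1 = time.perf_counter()
        pred = model.predict(X[test_idx])
        t2 = time.perf_counter()
        reports.append(
            compute_metrics(_confusion(y[test_idx], pred), (t1 - t0) + (t2 - t1))
        )
    if not reports:
        raise ValueError("every fold was skipped; cannot summarize")
    tp = sum(r.confusion[0] for r in reports)
    fp = sum(r.confusion[1] for r in reports)
    fn = sum(r.confusion[2] for r in reports)
    tn = sum(r.confusion[3] for r in reports)
    mean = compute_metrics((tp, fp, fn, tn),
                           sum(r.latency_seconds for r in reports))
    # Summary rates are fold means (the protocol's arithmetic-mean rule),
    # while the confusion holds the summed counts for audit.
    mean.accuracy = float(np.mean([r.accuracy for r in reports]))
    mean.precision = float(np.mean([r.precision for r in reports]))
    mean.recall = float(np.mean([r.recall for r in reports]))
    if mean.precision + mean.recall:
        mean.f_score = (2 * mean.precision * mean.recall
                        / (mean.precision + mean.recall))
    else:
        mean.f_score = 0.0
    mean.flags.extend(flags)
    mean.per_fold = reports
    return mean


@dataclass
class ComparisonTest:
    """Result of the pooled two-proportion accuracy comparison."""

    y1: int
    y2: int
    m: int
    a1_bar: float
    a2_bar: float
    a_bar: float
    s: float
    s_alpha: float
    alpha: float
    decision: str  # "reject_null" | "retain_null" | "undefined"


def compare_models(y1: int, y2: int, m: int, alpha: float = 0.05) -> ComparisonTest:
    """One-sided pooled z-test of "model 2 is more accurate than model 1".

    The statistic is antisymmetric in (y1, y2) and zero when they agree;
    it is undefined (decision "undefined") when the pooled accuracy is 0
    or 1, since the variance vanishes.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    if not (0 <= y1 <= m and 0 <= y2 <= m):
        raise ValueError("correct counts must lie in [0, m]")
    a1, a2 = y1 / m, y2 / m
    a = (y1 + y2) / (2 * m)
    s_alpha = float(norm.ppf(1 - alpha))
    if a in (0.0, 1.0):
        return ComparisonTest(y1, y2, m, a1, a2, a, float("nan"), s_alpha, alpha,
                              "undefined")
    s = (a1 - a2) / np.sqrt(2 * a * (1 - a) / m)
    decision = "reject_null" if s < -s_alpha else "retain_null"
    return ComparisonTest(y1, y2, m, a1, a2, a, float(s), s_alpha, alpha, decision)


def sweep(
    ds: TabularDataset,
    configs: Sequence,
    spec: ClassifierSpec | None = None,
    sample_sizes: Sequence[int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Variant x sample-size comparison table.

    For every run configuration and sample size: subsample the rows
    (seeded), run the selector, evaluate the selected attributes with the
    MLP on a stratified 60/40 split, and emit one row of accuracy /
    precision / recall / F-score / latency.
    """
    from .ga_engine import run as _run  # local import avoids a cycle

    if not len(configs):
        raise ValueError("config grid must be non-empty")
    sizes = list(sample_sizes) if sample_sizes else [ds.n_rows]
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        size = min(size, ds.n_rows)
        idx = np.sort(rng.choice(ds.n_rows, size=size, replace=False))
        sample = TabularDataset(
            schema=list(ds.schema),
            X=ds.X.iloc[idx].reset_index(drop=True),
            labels=ds.labels[idx],
            relation=ds.relation,
            class_name=ds.class_name,
            class_tokens=ds.class_tokens,
        )
        for cfg in configs:
            result = _run(sample, cfg)
            mask = [1 if nm in result.selected_attributes else 0
                    for nm in sample.attribute_names]
            split = split_train_test(sample, 0.6, seed=seed)
            report = evaluate_split(sample, mask, spec=spec, split=split)
            rows.append(
                {
                    "sample_size": size,
                    "variant": cfg.variant,
                    "n_selected": sum(mask),
                    "accuracy": report.accuracy,
                    "precision": report.precision,
                    "recall": report.recall,
                    "f_score": report.f_score,
                    "latency_seconds": report.latency_seconds,
                }
            )
    return pd.DataFrame(rows)
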