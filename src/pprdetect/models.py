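"""Classifiers, detection metrics and the statistical comparison protocol.

Two model families are evaluated for window-level PPR detection:

* ``knn`` — two-class K-nearest neighbours (Euclidean, majority vote); the
  ROC score of a window is the fraction of its K neighbours labelled PPR;
  K is swept over {3, 5, 7, 9, 11, 13, 15}.
* ``nn`` — a one-hidden-dense-layer neural network (ReLU hidden units,
  probabilistic output, cross-entropy loss, Adam, <= 200 epochs with early
  stopping on a 10% validation split); the hidden width is swept over
  {10, 20, 30, 40, 50}.

Evaluation reports confusion counts at the 0.5 score threshold and

    ACC  = (TP + TN) / Ndata
    SENS = TP / (TP + FN)
    SPEC = TN / (TN + FP)

plus the ROC curve (threshold sweep) and its trapezoidal AUC.  Configurations
are compared on their across-repetition sensitivity samples with the
Shapiro normality test and the Levene homogeneity test; when neither rejects,
a one-way ANOVA at alpha = 0.05 decides whether the configurations perform
identically, otherwise the report abstains explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier

__all__ = [
    "KNN_GRID",
    "NN_GRID",
    "ModelConfig",
    "Classifier",
    "train",
    "EvalReport",
    "evaluate",
    "anova_oneway",
    "ComparisonReport",
    "compare_configurations",
    "summarize",
]

KNN_GRID: tuple[int, ...] = (3, 5, 7, 9, 11, 13, 15)
NN_GRID: tuple[int, ...] = (10, 20, 30, 40, 50)


@dataclass(frozen=True)
class ModelConfig:
    """One point of the model grid.

    ``param`` is K (number of neighbours) for ``family="knn"`` and the hidden
    width for ``family="nn"``.
    """

    family: str  # "knn" | "nn"
    param: int
    rng_seed: int | None = None
    max_epochs: int = 200

    def __post_init__(self) -> None:
        if self.family not in ("knn", "nn"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.param < 1:
            raise ValueError("param must be >= 1")

    @property
    def label(self) -> str:
        return f"{self.family}:{self.param}"


@dataclass
class Classifier:
    """A fitted model exposing a PPR score in [0, 1] per window."""

    config: ModelConfig
    _impl: object

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        proba = self._impl.predict_proba(np.asarray(X, dtype=float))
        # column of the positive (PPR = 1) class
        classes = list(self._impl.classes_)
        return proba[:, classes.index(1)]

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_scores(X) >= threshold).astype(int)


def train(X: np.ndarray, y: np.ndarray, cfg: ModelConfig) -> Classifier:
    """Fit one configuration on a training fold.

    ``y`` uses 1 for PPR and 0 for non-PPR.  KNN stores the fold and votes
    among the K Euclidean-nearest points (distance ties resolved by index
    order); the network is deterministic under ``cfg.rng_seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y lengths differ")
    if cfg.family == "knn":
        if cfg.param >= X.shape[0]:
            raise ValueError(
                f"K = {cfg.param} must be smaller than the training size {X.shape[0]}"
            )
        impl = KNeighborsClassifier(n_neighbors=cfg.param, metric="euclidean")
    else:
        impl = MLPClassifier(
            hidden_layer_sizes=(cfg.param,),
            activation="relu",
            solver="adam",
            max_iter=cfg.max_epochs,
            early_stopping=True,
            validation_fraction=0.1,
            n_iter_no_change=20,
            learning_rate_init=0.01,
            random_state=cfg.rng_seed,
        )
    impl.fit(X, y)
    return Classifier(config=cfg, _impl=impl)


@dataclass
class EvalReport:
    """Confusion counts, ACC/SENS/SPEC, ROC points and AUC on one test set.

    ``sens``/``spec`` are NaN (with ``degenerate`` set) when the test set
    lacks positives or negatives, never a silent 0.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    sens: float
    spec: float
    auc: float
    roc_points: np.ndarray  # (n_thresholds, 2) columns (FPR, TPR)
    degenerate: bool = False

    @property
    def n_data(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


def evaluate(
    clf: Classifier | None,
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
    *,
    scores: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    threshold: float = 0.5,
) -> EvalReport:
    """Evaluate a classifier (or precomputed scores) on a labelled test set.

    Either pass ``clf, X, y`` or ``scores=..., labels=...``.  Confusion counts
    use ``score >= threshold``; the ROC curve sweeps the score threshold and
    AUC is its trapezoidal integral.
    """
    if scores is None:
        if clf is None or X is None or y is None:
            raise ValueError("pass (clf, X, y) or (scores, labels)")
        scores = clf.predict_scores(X)
        labels = np.asarray(y, dtype=int)
    else:
        labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty test set")

    preds = (scores >= threshold).astype(int)
    tp = int(np.sum((preds == 1) & (labels == 1)))
    tn = int(np.sum((preds == 0) & (labels == 0)))
    fp = int(np.sum((preds == 1) & (labels == 0)))
    fn = int(np.sum((preds == 0) & (labels == 1)))
    n = tp + tn + fp + fn
    n_pos, n_neg = tp + fn, tn + fp

    acc = (tp + tn) / n
    sens = tp / n_pos if n_pos else math.nan
    spec = tn / n_neg if n_neg else math.nan

    if n_pos and n_neg:
        fpr, tpr, _ = roc_curve(labels, scores)
        auc_val = float(_trapezoid_auc(fpr, tpr))
        roc = np.column_stack([fpr, tpr])
    else:
        auc_val = math.nan
        roc = np.empty((0, 2))

    return EvalReport(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        acc=acc,
        sens=sens,
        spec=spec,
        auc=auc_val,
        roc_points=roc,
        degenerate=not (n_pos and n_neg),
    )


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way ANOVA F statistic and p-value across the groups."""
    stat, p = spstats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(stat), float(p)


@dataclass
class ComparisonReport:
    """Outcome of the Shapiro / Levene / ANOVA protocol over configurations.

    ``reject`` is ``True``/``False`` only when the ANOVA preconditions held
    (no Shapiro or Levene rejection); otherwise ``abstained`` is set and
    ``reject`` is ``None``.
    """

    sens_by_config: dict[str, np.ndarray]
    shapiro_p: dict[str, float]
    levene_p: float
    anova_f: float | None
    anova_p: float | None
    alpha: float
    reject: bool | None
    abstained: bool
    notes: list[str] = field(default_factory=list)


def compare_configurations(
    sens_by_config: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> ComparisonReport:
    """Compare per-configuration sensitivity samples across repetitions.

    Runs the Shapiro normality test per configuration and the Levene
    homogeneity test across configurations; when neither rejects at ``alpha``,
    a one-way ANOVA decides whether all configurations share a population.
    Constant groups make Shapiro inapplicable; they are flagged and the report
    abstains.

    Raises
    ------
    ValueError
        With fewer than 2 configurations or fewer than 3 samples in a group.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in sens_by_config.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 configurations to compare")
    for name, g in groups.items():
        if g.size < 3:
            raise ValueError(f"configuration {name!r} has {g.size} samples; need >= 3")

    notes: list[str] = []
    shapiro_p: dict[str, float] = {}
    degenerate = False
    for name, g in groups.items():
        if np.ptp(g) == 0.0:
            shapiro_p[name] = math.nan
            notes.append(f"group {name!r} is constant; Shapiro inapplicable")
            degenerate = True
        else:
            shapiro_p[name] = float(spstats.shapiro(g).pvalue)

    levene_p = float(spstats.levene(*groups.values()).pvalue) if not degenerate else math.nan

    normal_ok = (not degenerate) and all(p > alpha for p in shapiro_p.values())
    homogeneous_ok = (not degenerate) and levene_p > alpha
    if normal_ok and homogeneous_ok:
        f_stat, p = anova_oneway(list(groups.values()))
        return ComparisonReport(
            sens_by_config=groups,
            shapiro_p=shapiro_p,
            levene_p=levene_p,
            anova_f=f_stat,
            anova_p=p,
            alpha=alpha,
            reject=bool(p < alpha),
            abstained=False,
            notes=notes,
        )
    if not degenerate:
        if not normal_ok:
            notes.append("Shapiro rejected normality for at least one group")
        if not homogeneous_ok:
            notes.append("Levene rejected homogeneity of variances")
    return ComparisonReport(
        sens_by_config=groups,
        shapiro_p=shapiro_p,
        levene_p=levene_p,
        anova_f=None,
        anova_p=None,
        alpha=alpha,
        reject=None,
        abstained=True,
        notes=notes,
    )


def summarize(metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean / median / std of ACC, SENS, SPEC per configuration and test set.

    ``metrics`` is a long table with one row per (configuration, test set,
    repetition) carrying columns ``family, param, test_set, acc, sens, spec``
    (as produced by the experiment runner).  Returns a table indexed by
    (family, param, test_set) with a (metric, statistic) column hierarchy.
    """
    if metrics.empty:
        raise ValueError("metrics table is empty")
    keys = [k for k in ("family", "param", "test_set") if k in metrics.columns]
    agg = metrics.groupby(keys)[["acc", "sens", "spec"]].agg(
        ["mean", "median", "std"]
    )
    return agg.fillna({c: 0.0 for c in agg.columns if c[1] == "std"})
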