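"""End-to-end experiment runner: recordings -> windows -> folds -> metrics.

``run_experiment`` wires the whole pipeline together: average-montage
re-referencing, Fz windowing/labelling, per-repetition balanced splits (with
segment-recombination augmentation of the training minority class and the
test-side synthetic top-up), per-fold [0,1] scaling + 95%-variance PCA, model
training over a configuration grid, and Test 1 / Test 2 evaluation.  With
``augment=False`` the identical pipeline runs without the augmentation stage —
the training fold is then the imbalanced 500 real PPR + 3000 non-PPR sample —
which is the control arm for measuring what augmentation buys.

The result object holds a long per-repetition metrics table and offers the
summary, the Shapiro/Levene/ANOVA comparison, and pooled ROC points (scores
pooled over repetitions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .augmentation import DAParams
from .features import extract_features, fit_scaler_pca, preprocess_window
from .models import (
    Classifier,
    ComparisonReport,
    EvalReport,
    ModelConfig,
    compare_configurations,
    evaluate,
    summarize,
    train,
)
from .splitting import SplitResult, SplitSpec, make_repetitions
from .synthetic import AnnotatedRecording
from .windowing import PPR, LabeledWindow, slide_windows
from .features import apply_average_montage

__all__ = ["ExperimentResult", "run_experiment", "windows_from_recordings"]


def windows_from_recordings(
    recordings: Sequence[AnnotatedRecording],
    channel: str = "Fz",
) -> list[LabeledWindow]:
    """Montage-reference each recording and slice it into labelled Fz windows.

    The average montage needs all channels, so it is applied at the recording
    level; windows then carry only the analysis channel.  (Recombination acts
    per channel, so augmenting single-channel windows is equivalent to
    augmenting all 19 and selecting the channel afterwards.)
    """
    windows: list[LabeledWindow] = []
    for rec in recordings:
        referenced = apply_average_montage(rec)
        windows.extend(slide_windows(referenced, channels=[channel]))
    return windows


def _feature_matrix(
    windows: Sequence[LabeledWindow],
    cache: dict[str, np.ndarray],
    fs: float,
) -> np.ndarray:
    rows = []
    for w in windows:
        feats = cache.get(w.window_id)
        if feats is None:
            feats = extract_features(preprocess_window(w, fs=fs), fs=fs)
            if w.provenance == "real":
                cache[w.window_id] = feats
        rows.append(feats)
    return np.asarray(rows)


def _labels(windows: Sequence[LabeledWindow]) -> np.ndarray:
    return np.fromiter((1 if w.label == PPR else 0 for w in windows), dtype=int)


@dataclass
class ExperimentResult:
    """Per-repetition detection metrics with summary and comparison views."""

    metrics: pd.DataFrame  # long: family, param, test_set, rep, acc, sens, spec, auc, tp...
    pooled_scores: dict[tuple[str, int, str], tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )
    splits: list[SplitResult] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return summarize(self.metrics)

    def comparison(self, family: str, test_set: str = "test1") -> ComparisonReport:
        """Shapiro/Levene/ANOVA over a family's grid on one test set."""
        sub = self.metrics[
            (self.metrics["family"] == family) & (self.metrics["test_set"] == test_set)
        ]
        sens = {
            f"{family}:{p}": g["sens"].to_numpy()
            for p, g in sub.groupby("param", sort=True)
        }
        return compare_configurations(sens)

    def pooled_roc(self, family: str, param: int, test_set: str = "test1") -> EvalReport:
        """Evaluation on scores pooled across repetitions (global ROC)."""
        scores, labels = self.pooled_scores[(family, param, test_set)]
        return evaluate(None, scores=scores, labels=labels)


def run_experiment(
    recordings: Sequence[AnnotatedRecording] | None = None,
    windows: Sequence[LabeledWindow] | None = None,
    configs: Sequence[ModelConfig] = (ModelConfig("knn", 3), ModelConfig("nn", 10)),
    spec: SplitSpec | None = None,
    da_params: DAParams | None = None,
    n_reps: int = 5,
    seed: int | None = 0,
    augment: bool = True,
    channel: str = "Fz",
    fs: float = 500.0,
    mode: str = "random",
    feature_cache: dict[str, np.ndarray] | None = None,
) -> ExperimentResult:
    """Run the full detection experiment.

    Pass either ``recordings`` (windowed internally on ``channel``) or a
    prebuilt ``windows`` list.  For every repetition: build the split, fit
    scaler + PCA on the training fold's features only, train each
    configuration, and evaluate on Test 1 and Test 2.  With ``augment=False``
    synthetic windows are dropped from the training fold (test sets are
    unchanged), isolating the augmentation stage's effect.  A ``feature_cache``
    dict (window_id -> feature vector, real windows only) may be shared across
    calls to avoid refeaturizing the same windows.

    Returns an :class:`ExperimentResult`; everything is deterministic under
    ``seed``.
    """
    if windows is None:
        if recordings is None:
            raise ValueError("pass recordings or windows")
        windows = windows_from_recordings(recordings, channel=channel)
    spec = spec or SplitSpec()
    da_params = da_params or DAParams()

    splits = make_repetitions(
        windows, spec, n_reps=n_reps, seed=seed, da_params=da_params, mode=mode
    )

    cache: dict[str, np.ndarray] = feature_cache if feature_cache is not None else {}
    records: list[dict] = []
    pooled: dict[tuple[str, int, str], list[tuple[np.ndarray, np.ndarray]]] = {}

    for rep, split in enumerate(splits):
        train_windows = (
            split.train
            if augment
            else [w for w in split.train if w.provenance == "real"]
        )
        X_train = _feature_matrix(train_windows, cache, fs)
        y_train = _labels(train_windows)
        t = fit_scaler_pca(X_train)
        Z_train = t.transform(X_train)

        test_sets = {"test1": split.test1, "test2": split.test2}
        Z_tests = {}
        y_tests = {}
        for name, tw in test_sets.items():
            Xt = _feature_matrix(tw, cache, fs)
            Z_tests[name] = t.transform(Xt)
            y_tests[name] = _labels(tw)

        for cfg in configs:
            cfg_rep = ModelConfig(
                cfg.family,
                cfg.param,
                rng_seed=(cfg.rng_seed if cfg.rng_seed is not None else 0) + rep,
                max_epochs=cfg.max_epochs,
            )
            clf = train(Z_train, y_train, cfg_rep)
            for name in test_sets:
                scores = clf.predict_scores(Z_tests[name])
                report = evaluate(None, scores=scores, labels=y_tests[name])
                records.append(
                    {
                        "family": cfg.family,
                        "param": cfg.param,
                        "test_set": name,
                        "rep": rep,
                        "augmented": augment,
                        "acc": report.acc,
                        "sens": report.sens,
                        "spec": report.spec,
                        "auc": report.auc,
                        "tp": report.tp,
                        "tn": report.tn,
                        "fp": report.fp,
                        "fn": report.fn,
                    }
                )
                pooled.setdefault((cfg.family, cfg.param, name), []).append(
                    (scores, y_tests[name])
                )

    pooled_scores = {
        key: (
            np.concatenate([s for s, _ in chunks]),
            np.concatenate([l for _, l in chunks]),
        )
        for key, chunks in pooled.items()
    }
    return ExperimentResult(
        metrics=pd.DataFrame(records), pooled_scores=pooled_scores, splits=splits
    )
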