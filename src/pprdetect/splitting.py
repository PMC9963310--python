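"""Balanced training folds and dual test sets for imbalanced PPR windows.

One repetition of the cross-validation scheme:

1. sample ``n_train_nonppr`` non-PPR and ``n_train_real_ppr`` real PPR windows
   without replacement from the dataset (3000 and 500 by default);
2. recombine ``n_train_synth_ppr`` synthetic PPR windows (2500) from the
   selected real PPR windows, balanced over the four positional cases;
3. the training fold is their union — 6000 windows, exactly 50/50;
4. Test 1 is everything left: all remaining real PPR and non-PPR windows;
5. further synthetic PPR windows are recombined *from Test 1's real PPR
   windows only* until the test-side PPR count reaches ``test_ppr_total``
   (3000); Test 2 is Test 1 plus those windows.

Across repetitions the pools are re-drawn independently ("sub-sampling with
replacement" across folds: a non-PPR window may serve in several repetitions'
training folds, but never in both train and test of the same repetition).
Restricting the test-side synthetic parents to Test 1 keeps the two sides
leakage-free, which is assertable through every synthetic window's recorded
parent identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .augmentation import DAParams, SyntheticWindow, augment_balanced, group_by_case
from .windowing import NON_PPR, PPR, LabeledWindow

__all__ = ["SplitSpec", "SplitResult", "make_split", "make_repetitions"]


@dataclass(frozen=True)
class SplitSpec:
    """Composition of one repetition's training fold and test sets.

    The defaults reproduce the reference construction: 3000 non-PPR + 500 real
    PPR + 2500 synthetic PPR in training (perfect 50/50 balance) and a test-side
    synthetic top-up to 3000 PPR windows in Test 2.
    """

    n_train_nonppr: int = 3000
    n_train_real_ppr: int = 500
    n_train_synth_ppr: int = 2500
    test_ppr_total: int = 3000
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_train_nonppr, self.n_train_real_ppr, self.n_train_synth_ppr) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_train_real_ppr + self.n_train_synth_ppr != self.n_train_nonppr:
            raise ValueError(
                "real + synthetic PPR must equal non-PPR for a balanced fold "
                f"({self.n_train_real_ppr} + {self.n_train_synth_ppr} != "
                f"{self.n_train_nonppr})"
            )


@dataclass
class SplitResult:
    """One repetition's training fold plus Test 1 / Test 2 and their census.

    ``test1`` holds only real windows; ``test2`` is ``test1`` plus test-side
    synthetic PPR windows.  ``composition`` counts windows per (role, label,
    provenance).
    """

    train: list[LabeledWindow]
    test1: list[LabeledWindow]
    test2: list[LabeledWindow]
    composition: dict[tuple[str, str, str], int] = field(default_factory=dict)

    def composition_frame(self) -> pd.DataFrame:
        rows = [
            {"role": r, "label": l, "provenance": p, "count": c}
            for (r, l, p), c in sorted(self.composition.items())
        ]
        return pd.DataFrame(rows)


def _census(windows: Sequence[LabeledWindow], role: str) -> dict:
    out: dict[tuple[str, str, str], int] = {}
    for w in windows:
        key = (role, w.label, w.provenance)
        out[key] = out.get(key, 0) + 1
    return out


def make_split(
    dataset: Sequence[LabeledWindow],
    spec: SplitSpec | None = None,
    da_params: DAParams | None = None,
    rng: np.random.Generator | None = None,
) -> SplitResult:
    """Build one repetition's balanced training fold and the two test sets.

    ``dataset`` must contain only real windows.  Sampling is without
    replacement within the repetition.  Raises ``ValueError`` naming the
    deficient class or case when pools are too small (including when Test 1
    retains no real PPR windows to parent the test-side synthetic ones).
    """
    spec = spec or SplitSpec()
    da_params = da_params or DAParams()
    rng = rng if rng is not None else np.random.default_rng(spec.rng_seed)

    if any(w.provenance != "real" for w in dataset):
        raise ValueError("dataset passed to make_split must contain only real windows")
    ppr_idx = [i for i, w in enumerate(dataset) if w.label == PPR]
    non_idx = [i for i, w in enumerate(dataset) if w.label == NON_PPR]
    if len(non_idx) < spec.n_train_nonppr:
        raise ValueError(
            f"insufficient non-PPR pool: {len(non_idx)} < {spec.n_train_nonppr}"
        )
    if len(ppr_idx) < spec.n_train_real_ppr:
        raise ValueError(
            f"insufficient real-PPR pool: {len(ppr_idx)} < {spec.n_train_real_ppr}"
        )

    sel_non = rng.choice(len(non_idx), size=spec.n_train_nonppr, replace=False)
    sel_ppr = rng.choice(len(ppr_idx), size=spec.n_train_real_ppr, replace=False)
    train_non = [dataset[non_idx[i]] for i in sel_non]
    train_ppr = [dataset[ppr_idx[i]] for i in sel_ppr]

    train_synth = augment_balanced(
        train_ppr, spec.n_train_synth_ppr, da_params, rng=rng, id_prefix="synth:train"
    )
    train = train_non + train_ppr + train_synth

    sel_non_set = {non_idx[i] for i in sel_non}
    sel_ppr_set = {ppr_idx[i] for i in sel_ppr}
    test1 = [
        w
        for i, w in enumerate(dataset)
        if i not in sel_non_set and i not in sel_ppr_set
    ]

    test_real_ppr = [w for w in test1 if w.label == PPR]
    n_needed = max(spec.test_ppr_total - len(test_real_ppr), 0)
    if n_needed > 0:
        if not test_real_ppr:
            raise ValueError(
                "Test 1 retains no real PPR windows to parent test-side "
                "synthetic windows"
            )
        test_synth = augment_balanced(
            test_real_ppr, n_needed, da_params, rng=rng, id_prefix="synth:test"
        )
    else:
        test_synth = []
    test2 = test1 + test_synth

    composition = {
        **_census(train, "train"),
        **_census(test1, "test1"),
        **_census(test2, "test2"),
    }
    return SplitResult(train=train, test1=test1, test2=test2, composition=composition)


def make_repetitions(
    dataset: Sequence[LabeledWindow],
    spec: SplitSpec | None = None,
    n_reps: int = 10,
    seed: int | None = None,
    da_params: DAParams | None = None,
    mode: str = "random",
) -> list[SplitResult]:
    """Independent repetitions of :func:`make_split`.

    ``mode="random"`` (default) re-draws both pools independently per
    repetition.  ``mode="holdout"`` additionally excludes one recording's
    windows from the training pools in turn (repetition i holds out the i-th
    distinct recording; its windows all land in the test sets), requiring
    ``n_reps <= number of recordings``.

    Per-repetition randomness comes from ``default_rng([seed, rep])`` — a
    documented counter scheme, so runs with equal seeds select identical
    windows.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if mode not in ("random", "holdout"):
        raise ValueError(f"unknown mode {mode!r}")
    spec = spec or SplitSpec()
    base = seed if seed is not None else 0

    recordings = sorted({w.recording_id for w in dataset})
    if mode == "holdout" and n_reps > len(recordings):
        raise ValueError(
            f"holdout mode needs n_reps <= {len(recordings)} recordings"
        )

    results = []
    for rep in range(n_reps):
        rng = np.random.default_rng([base, rep])
        if mode == "holdout":
            held = recordings[rep]
            pool = [w for w in dataset if w.recording_id != held]
            held_windows = [w for w in dataset if w.recording_id == held]
            res = make_split(pool, spec, da_params, rng=rng)
            res.test1 = res.test1 + held_windows
            res.test2 = res.test2 + held_windows
            res.composition = {
                **_census(res.train, "train"),
                **_census(res.test1, "test1"),
                **_census(res.test2, "test2"),
            }
        else:
            res = make_split(dataset, spec, da_params, rng=rng)
        results.append(res)
    return results
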