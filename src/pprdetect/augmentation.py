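"""Segment-recombination data augmentation for PPR windows.

A synthetic PPR window C is built from two real parent windows A and B of the
same positional case by alternating fixed-length segments: with n cut-points
the window splits into n+1 equal segments, and C takes segment 0 from A,
segment 1 from B, segment 2 from A, and so on.  At each cut-point x a 5-sample
convex interpolation smooths the transition between the left parent L and
right parent R:

    C(x-2) = L(x-2)
    C(x-1) = 0.75 L(x-1) + 0.25 R(x-1)
    C(x)   = 0.50 L(x)   + 0.50 R(x)
    C(x+1) = 0.25 L(x+1) + 0.75 R(x+1)
    C(x+2) = R(x+2)

(The outermost two rows restate what alternation already guarantees; they are
kept for fidelity to the scheme's definition.)  The same cut-points are applied
to every channel so that cross-channel coherence is preserved.  Because all
weights are convex, every sample of C lies between the parents' values at that
sample, and recombining a window with itself returns it unchanged.

Augmentation is balanced over the four positional cases: the requested total is
split equally (remainder to the first cases in the fixed order onset, offset,
middle, whole), and each child draws two distinct parents uniformly at random
from its case pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.signal import periodogram

from .windowing import CASES, PPR, LabeledWindow

__all__ = [
    "DAParams",
    "SyntheticWindow",
    "cut_points",
    "recombine",
    "smooth_cutpoint",
    "augment_balanced",
    "group_by_case",
    "SpectralSimilarity",
    "spectral_similarity",
]


@dataclass(frozen=True)
class DAParams:
    """Parameters of the recombination operator.

    ``n_cutpoints`` cut-points divide the window into ``n_cutpoints + 1`` equal
    segments (the window length must be divisible by that count; 500 samples
    with the default n=3 gives cut-points at samples 125, 250, 375).
    ``smoothing_halfwidth`` is fixed at 2 samples by the interpolation scheme.
    """

    n_cutpoints: int = 3
    smoothing_halfwidth: int = 2
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cutpoints < 0:
            raise ValueError("n_cutpoints must be >= 0")
        if self.smoothing_halfwidth != 2:
            raise ValueError("the interpolation scheme fixes smoothing_halfwidth at 2")


@dataclass
class SyntheticWindow(LabeledWindow):
    """A recombined PPR window; records the identifiers of its two parents."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.provenance != "synthetic" or self.parent_ids is None:
            raise ValueError("SyntheticWindow requires provenance='synthetic' and parent_ids")


def cut_points(length: int, n_cutpoints: int) -> list[int]:
    """Cut-point sample indices k*L/(n+1), k = 1..n."""
    n_seg = n_cutpoints + 1
    if length % n_seg != 0:
        raise ValueError(
            f"window length {length} not divisible into {n_seg} equal segments"
        )
    seg = length // n_seg
    return [k * seg for k in range(1, n_cutpoints + 1)]


def smooth_cutpoint(
    C: np.ndarray, A: np.ndarray, B: np.ndarray, x: int
) -> np.ndarray:
    """Apply the 5-sample convex interpolation at cut-point ``x`` in place.

    Assumes the segment left of ``x`` came from ``A`` and the segment right of
    ``x`` from ``B`` (pass the arrays swapped for the mirrored orientation).
    Arrays are ``(channels, length)``; all channels are smoothed with the same
    weights.  Returns ``C``.
    """
    length = C.shape[-1]
    if x - 2 < 0 or x + 2 >= length:
        raise ValueError(f"cut-point {x} closer than 2 samples to a window edge")
    C[..., x - 2] = A[..., x - 2]
    C[..., x - 1] = 0.75 * A[..., x - 1] + 0.25 * B[..., x - 1]
    C[..., x] = 0.5 * A[..., x] + 0.5 * B[..., x]
    C[..., x + 1] = 0.25 * A[..., x + 1] + 0.75 * B[..., x + 1]
    C[..., x + 2] = B[..., x + 2]
    return C


def recombine(
    parent_a: LabeledWindow,
    parent_b: LabeledWindow,
    params: DAParams | None = None,
    window_id: str | None = None,
) -> SyntheticWindow:
    """Recombine two same-case PPR windows into a synthetic child.

    Segment k (half-open, equal length) is copied from ``parent_a`` when k is
    even and from ``parent_b`` when k is odd; the interpolation of
    :func:`smooth_cutpoint` is then applied at every cut-point, with the parent
    roles alternating to match the adjacent segments.

    Raises
    ------
    ValueError
        If the parents differ in shape or case, or are not PPR windows.
    """
    params = params or DAParams()
    A, B = parent_a.data, parent_b.data
    if A.shape != B.shape:
        raise ValueError("parents must have identical shapes")
    if parent_a.label != PPR or parent_b.label != PPR:
        raise ValueError("both parents must be PPR windows")
    if parent_a.ppr_case != parent_b.ppr_case:
        raise ValueError(
            f"parents must share a case (got {parent_a.ppr_case!r} vs "
            f"{parent_b.ppr_case!r})"
        )
    length = A.shape[-1]
    cuts = cut_points(length, params.n_cutpoints)
    seg = length // (params.n_cutpoints + 1)

    C = np.empty_like(A, dtype=float)
    for k in range(params.n_cutpoints + 1):
        src = A if k % 2 == 0 else B
        C[..., k * seg : (k + 1) * seg] = src[..., k * seg : (k + 1) * seg]
    for i, x in enumerate(cuts):
        left, right = (A, B) if i % 2 == 0 else (B, A)
        smooth_cutpoint(C, left, right, x)

    return SyntheticWindow(
        data=C,
        label=PPR,
        ppr_case=parent_a.ppr_case,
        provenance="synthetic",
        recording_id="synthetic",
        start_sample=-1,
        window_id=window_id or f"synth:{parent_a.window_id}+{parent_b.window_id}",
        channel_names=parent_a.channel_names,
        parent_ids=(parent_a.window_id, parent_b.window_id),
    )


def group_by_case(windows: Iterable[LabeledWindow]) -> dict[str, list[LabeledWindow]]:
    """Group PPR windows by positional case (fixed case order, non-PPR ignored)."""
    groups: dict[str, list[LabeledWindow]] = {c: [] for c in CASES}
    for w in windows:
        if w.label == PPR:
            groups[w.ppr_case].append(w)
    return groups


def _case_quotas(total_new: int) -> dict[str, int]:
    base, rem = divmod(total_new, len(CASES))
    return {c: base + (1 if i < rem else 0) for i, c in enumerate(CASES)}


def augment_balanced(
    pool: Mapping[str, Sequence[LabeledWindow]] | Iterable[LabeledWindow],
    total_new: int,
    params: DAParams | None = None,
    rng: np.random.Generator | None = None,
    id_prefix: str = "synth",
) -> list[SyntheticWindow]:
    """Generate ``total_new`` synthetic PPR windows, balanced across cases.

    ``pool`` is either a mapping case -> windows or a flat iterable of PPR
    windows (grouped internally).  The total is split equally over the four
    cases; when not divisible by 4 the remainder goes to the first cases in the
    order onset, offset, middle, whole.  Each child draws two distinct parents
    uniformly at random from its case pool (pairs may repeat across children).
    Reproducible under ``params.rng_seed`` (or an explicitly passed ``rng``).

    Raises
    ------
    ValueError
        If a case with a non-zero quota has fewer than two parent windows.
    """
    params = params or DAParams()
    if total_new < 0:
        raise ValueError("total_new must be >= 0")
    if total_new == 0:
        return []
    groups = pool if isinstance(pool, Mapping) else group_by_case(pool)
    rng = rng if rng is not None else np.random.default_rng(params.rng_seed)

    out: list[SyntheticWindow] = []
    quotas = _case_quotas(total_new)
    for case in CASES:
        quota = quotas[case]
        members = list(groups.get(case, ()))
        if quota == 0:
            continue
        if len(members) < 2:
            raise ValueError(
                f"case {case!r} has {len(members)} parent window(s); "
                "at least 2 are required for recombination"
            )
        for j in range(quota):
            ia, ib = rng.choice(len(members), size=2, replace=False)
            child = recombine(
                members[ia],
                members[ib],
                params,
                window_id=f"{id_prefix}:{case}:{j}",
            )
            out.append(child)
    return out


@dataclass(frozen=True)
class SpectralSimilarity:
    """Band-wise power comparison between a child window and its parents' mean.

    Powers are integrated over 1-Hz bands spanning 1-50 Hz from channel-averaged
    periodograms.  ``ratio`` is child power over parent-mean power per band
    (NaN where the parent power is zero).  This is a diagnostic report, not a
    filter: the recombination operator is used unconditionally.
    """

    band_edges: np.ndarray  # (n_bands + 1,)
    parent_power: np.ndarray  # (n_bands,)
    child_power: np.ndarray  # (n_bands,)

    @property
    def ratio(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.child_power / self.parent_power

    @property
    def max_abs_log2_ratio(self) -> float:
        r = self.ratio
        r = r[np.isfinite(r) & (r > 0)]
        if r.size == 0:
            return 0.0
        return float(np.max(np.abs(np.log2(r))))


def _band_power(
    data: np.ndarray, fs: float, edges: np.ndarray
) -> np.ndarray:
    f, p = periodogram(data, fs=fs, axis=-1)
    if data.ndim == 2:
        p = p.mean(axis=0)
    power = np.empty(len(edges) - 1)
    for i in range(len(edges) - 1):
        mask = (f >= edges[i]) & (f < edges[i + 1])
        power[i] = p[mask].sum()
    return power


def spectral_similarity(
    parent_a: LabeledWindow,
    parent_b: LabeledWindow,
    child: LabeledWindow,
    fs: float = 500.0,
    f_lo: float = 1.0,
    f_hi: float = 50.0,
) -> SpectralSimilarity:
    """Compare child band powers (1-50 Hz) with the mean of its parents'."""
    if not (parent_a.data.shape == parent_b.data.shape == child.data.shape):
        raise ValueError("parents and child must share a shape")
    edges = np.arange(f_lo, f_hi + 1.0)
    pa = _band_power(parent_a.data, fs, edges)
    pb = _band_power(parent_b.data, fs, edges)
    pc = _band_power(child.data, fs, edges)
    return SpectralSimilarity(
        band_edges=edges, parent_power=0.5 * (pa + pb), child_power=pc
    )
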