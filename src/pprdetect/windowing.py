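"""Sliding-window segmentation and PPR labelling of annotated EEG.

Recordings are cut into 1-second windows with 90% overlap (step 50 samples at
500 Hz).  A window is labelled ``PPR`` iff it shares at least one sample with a
ground-truth PPR interval (half-open coordinates throughout).  PPR windows are
further assigned one of four positional cases describing where the discharge
sits relative to the window:

``onset``
    the window contains the start of a discharge that continues past it,
``offset``
    the window contains the end of a discharge that began before it,
``middle``
    the discharge spans the whole window,
``whole``
    the discharge lies entirely inside the window.

The case drives the augmentation stage: synthetic windows are only recombined
from parents of the same case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic import AnnotatedRecording, PPRInterval

__all__ = [
    "PPR",
    "NON_PPR",
    "CASES",
    "LabeledWindow",
    "slide_windows",
    "label_window",
    "classify_ppr_case",
    "n_windows",
    "windows_to_manifest",
]

PPR = "PPR"
NON_PPR = "nonPPR"

#: Fixed case order used wherever a deterministic ordering over cases is needed.
CASES = ("onset", "offset", "middle", "whole")


@dataclass
class LabeledWindow:
    """A fixed-length multichannel EEG slice with its label and provenance.

    ``data`` has shape ``(n_channels, length)``; for real windows it is a view
    into the parent recording's signal.  ``ppr_case`` is ``"none"`` iff the
    label is ``nonPPR``; synthetic (augmented) windows are always ``PPR``.
    """

    data: np.ndarray
    label: str
    ppr_case: str
    provenance: str  # "real" | "synthetic"
    recording_id: str
    start_sample: int
    window_id: str
    channel_names: tuple[str, ...] | None = None
    parent_ids: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if (self.ppr_case == "none") != (self.label == NON_PPR):
            raise ValueError("ppr_case == 'none' must hold iff label == nonPPR")
        if self.provenance == "synthetic" and self.label != PPR:
            raise ValueError("synthetic windows must be labelled PPR")

    @property
    def length(self) -> int:
        return self.data.shape[1]


def label_window(
    start: int, length: int, intervals: Sequence[PPRInterval]
) -> str:
    """Label the half-open window ``[start, start+length)``.

    ``PPR`` iff the window shares at least one sample with any interval.
    """
    end = start + length
    for iv in intervals:
        if iv.start_sample < end and iv.end_sample > start:
            return PPR
    return NON_PPR


def _dominant_interval(
    start: int, length: int, intervals: Sequence[PPRInterval]
) -> PPRInterval:
    """The intersecting interval with the largest overlap; ties -> earlier."""
    end = start + length
    best: PPRInterval | None = None
    best_overlap = -1
    for iv in intervals:  # intervals are sorted, so ties resolve to the earlier one
        overlap = min(end, iv.end_sample) - max(start, iv.start_sample)
        if overlap > 0 and overlap > best_overlap:
            best, best_overlap = iv, overlap
    if best is None:
        raise ValueError("classify_ppr_case called on a window with no PPR overlap")
    return best


def classify_ppr_case(
    start: int, length: int, intervals: Sequence[PPRInterval]
) -> str:
    """Positional case of a PPR window relative to its dominant interval.

    With interval ``[s, e)`` and window ``[start, start+length)``:
    ``whole`` if the interval is contained in the window, ``onset`` if only its
    start is, ``offset`` if only its end is, ``middle`` if the interval covers
    the window entirely.
    """
    iv = _dominant_interval(start, length, intervals)
    end = start + length
    starts_inside = iv.start_sample >= start
    ends_inside = iv.end_sample <= end
    if starts_inside and ends_inside:
        return "whole"
    if starts_inside:
        return "onset"
    if ends_inside:
        return "offset"
    return "middle"


def n_windows(n_samples: int, length: int = 500, step: int = 50) -> int:
    """Number of full windows in an ``n_samples`` recording: floor((N-L)/step)+1."""
    if n_samples < length:
        return 0
    return (n_samples - length) // step + 1


def slide_windows(
    rec: AnnotatedRecording,
    window_s: float = 1.0,
    overlap: float = 0.9,
    channels: Sequence[str] | None = None,
) -> list[LabeledWindow]:
    """Slice a recording into labelled fixed-length windows.

    Windows start at multiples of ``step = window_s * (1 - overlap) * rate``
    (50 samples with the defaults at 500 Hz); trailing samples that do not fill
    a full window are discarded.  Window data are views into the recording's
    signal.  ``channels`` optionally restricts the windows to a channel subset
    (e.g. ``["Fz"]``).

    Raises
    ------
    ValueError
        If the recording is shorter than one window.
    """
    fs = rec.sampling_rate
    length = int(round(window_s * fs))
    step = int(round(window_s * (1.0 - overlap) * fs))
    if step < 1:
        raise ValueError("overlap too large: step would be < 1 sample")
    if rec.n_samples < length:
        raise ValueError(
            f"recording has {rec.n_samples} samples, shorter than one "
            f"{length}-sample window"
        )
    if channels is None:
        sig = rec.signal
        names = rec.channel_names
    else:
        idx = [rec.channel_names.index(c) for c in channels]
        sig = rec.signal[idx]
        names = tuple(channels)

    windows: list[LabeledWindow] = []
    for start in range(0, rec.n_samples - length + 1, step):
        label = label_window(start, length, rec.intervals)
        case = (
            classify_ppr_case(start, length, rec.intervals)
            if label == PPR
            else "none"
        )
        windows.append(
            LabeledWindow(
                data=sig[:, start : start + length],
                label=label,
                ppr_case=case,
                provenance="real",
                recording_id=rec.recording_id,
                start_sample=start,
                window_id=f"{rec.recording_id}:{start}",
                channel_names=names,
            )
        )
    return windows


def windows_to_manifest(windows: Iterable[LabeledWindow]) -> pd.DataFrame:
    """Manifest table of a window collection (one row per window)."""
    rows = [
        {
            "window_id": w.window_id,
            "recording_id": w.recording_id,
            "start_sample": w.start_sample,
            "label": w.label,
            "ppr_case": w.ppr_case,
            "provenance": w.provenance,
            "parent_a": w.parent_ids[0] if w.parent_ids else "",
            "parent_b": w.parent_ids[1] if w.parent_ids else "",
        }
        for w in windows
    ]
    return pd.DataFrame(rows)
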