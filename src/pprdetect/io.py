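"""Recording and window-store I/O.

Two interchange formats for annotated recordings:

* a documented columnar text format — ``<id>_signals.csv`` with one column per
  channel (header = channel labels, one row per sample, nominal microvolts)
  plus a sidecar ``<id>_annotations.csv`` with columns
  ``recording_id,start_sample,end_sample`` (0-based, half-open);
* EDF — one recording per ``.edf`` file written by a minimal built-in writer
  (16-bit, one data record per second), with the same sidecar CSV carrying the
  PPR intervals.  Reading EDF uses :mod:`mne` when available.

Window stores persist a window collection as a compressed ``.npz`` of stacked
window data plus a ``manifest.csv`` (window_id, recording_id, start_sample,
label, ppr_case, provenance, parents).
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .windowing import LabeledWindow, windows_to_manifest
from .synthetic import AnnotatedRecording, PPRInterval

__all__ = [
    "write_recording_csv",
    "read_recording_csv",
    "write_annotations_csv",
    "read_annotations_csv",
    "write_edf",
    "read_edf",
    "save_windows",
    "load_windows",
]


def write_annotations_csv(rec: AnnotatedRecording, path: str | Path) -> None:
    pd.DataFrame(
        {
            "recording_id": [rec.recording_id] * len(rec.intervals),
            "start_sample": [iv.start_sample for iv in rec.intervals],
            "end_sample": [iv.end_sample for iv in rec.intervals],
        }
    ).to_csv(path, index=False)


def read_annotations_csv(path: str | Path) -> list[PPRInterval]:
    df = pd.read_csv(path)
    return [
        PPRInterval(int(r.start_sample), int(r.end_sample)) for r in df.itertuples()
    ]


def write_recording_csv(rec: AnnotatedRecording, out_dir: str | Path) -> Path:
    """Write ``<id>_signals.csv`` + ``<id>_annotations.csv``; returns the signal path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sig_path = out_dir / f"{rec.recording_id}_signals.csv"
    df = pd.DataFrame(rec.signal.T, columns=list(rec.channel_names))
    df.insert(0, "sampling_rate", rec.sampling_rate)
    df.to_csv(sig_path, index=False)
    write_annotations_csv(rec, out_dir / f"{rec.recording_id}_annotations.csv")
    return sig_path


def read_recording_csv(
    signals_path: str | Path, annotations_path: str | Path | None = None
) -> AnnotatedRecording:
    signals_path = Path(signals_path)
    df = pd.read_csv(signals_path)
    fs = float(df.pop("sampling_rate").iloc[0])
    recording_id = signals_path.stem.removesuffix("_signals")
    if annotations_path is None:
        candidate = signals_path.with_name(f"{recording_id}_annotations.csv")
        annotations_path = candidate if candidate.exists() else None
    intervals = (
        read_annotations_csv(annotations_path) if annotations_path is not None else []
    )
    return AnnotatedRecording(
        signal=df.to_numpy().T,
        channel_names=tuple(df.columns),
        sampling_rate=fs,
        intervals=tuple(intervals),
        recording_id=recording_id,
    )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: AnnotatedRecording, path: str | Path) -> Path:
    """Write a recording as a plain EDF file (16-bit, 1-second data records).

    The signal is truncated to a whole number of seconds (EDF data records are
    fixed-duration).  Physical scaling spans the per-channel data range, so
    amplitudes round-trip to within 16-bit quantisation.  Annotations go in a
    sidecar CSV next to the file.
    """
    path = Path(path)
    fs = rec.sampling_rate
    spr = int(round(fs))  # samples per record (1 s records)
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one 1-second EDF record")
    ns = rec.n_channels
    data = rec.signal[:, : n_records * spr]

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    same = phys_max - phys_min == 0
    phys_max = np.where(same, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.round((data - phys_min[:, None]) * scale[:, None] + dig_min),
        dig_min,
        dig_max,
    ).astype("<i2")

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),  # patient id (anonymous)
            _edf_field(f"Startdate X X X X {rec.recording_id}", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(str(256 * (ns + 1)), 8),
            _edf_field("", 44),
            _edf_field(str(n_records), 8),
            _edf_field("1", 8),  # record duration, seconds
            _edf_field(str(ns), 4),
        ]
    )
    per_signal = b"".join(
        [
            b"".join(_edf_field(name, 16) for name in rec.channel_names),
            b"".join(_edf_field("AgAgCl electrode", 80) for _ in range(ns)),
            b"".join(_edf_field("uV", 8) for _ in range(ns)),
            b"".join(_edf_field(f"{phys_min[i]:.5g}", 8) for i in range(ns)),
            b"".join(_edf_field(f"{phys_max[i]:.5g}", 8) for i in range(ns)),
            b"".join(_edf_field(str(dig_min), 8) for _ in range(ns)),
            b"".join(_edf_field(str(dig_max), 8) for _ in range(ns)),
            b"".join(_edf_field("", 80) for _ in range(ns)),
            b"".join(_edf_field(str(spr), 8) for _ in range(ns)),
            b"".join(_edf_field("", 32) for _ in range(ns)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())  # channel-major within the record

    write_annotations_csv(rec, path.with_suffix(".annotations.csv"))
    return path


def read_edf(
    path: str | Path, annotations_path: str | Path | None = None
) -> AnnotatedRecording:
    """Read an EDF recording via mne (optional dependency) plus the sidecar CSV."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the optional dependency mne") from exc
    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # mne returns volts
    if annotations_path is None:
        candidate = path.with_suffix(".annotations.csv")
        annotations_path = candidate if candidate.exists() else None
    intervals = (
        read_annotations_csv(annotations_path) if annotations_path is not None else []
    )
    return AnnotatedRecording(
        signal=signal,
        channel_names=tuple(raw.ch_names),
        sampling_rate=float(raw.info["sfreq"]),
        intervals=tuple(intervals),
        recording_id=path.stem,
    )


# ---------------------------------------------------------------------------
# window store
# ---------------------------------------------------------------------------

def save_windows(windows: Sequence[LabeledWindow], out_dir: str | Path) -> Path:
    """Persist windows as ``windows.npz`` + ``manifest.csv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = windows_to_manifest(windows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    data = np.stack([w.data for w in windows]) if windows else np.empty((0, 0, 0))
    names = windows[0].channel_names if windows and windows[0].channel_names else ()
    np.savez_compressed(
        out_dir / "windows.npz", data=data, channel_names=np.array(names, dtype=str)
    )
    return out_dir


def load_windows(store_dir: str | Path) -> list[LabeledWindow]:
    store_dir = Path(store_dir)
    manifest = pd.read_csv(store_dir / "manifest.csv", keep_default_na=False)
    archive = np.load(store_dir / "windows.npz", allow_pickle=False)
    data = archive["data"]
    names = tuple(archive["channel_names"].tolist()) or None
    windows = []
    for i, row in enumerate(manifest.itertuples()):
        parents = (
            (str(row.parent_a), str(row.parent_b))
            if str(row.parent_a)
            else None
        )
        windows.append(
            LabeledWindow(
                data=data[i],
                label=str(row.label),
                ppr_case=str(row.ppr_case),
                provenance=str(row.provenance),
                recording_id=str(row.recording_id),
                start_sample=int(row.start_sample),
                window_id=str(row.window_id),
                channel_names=names,
                parent_ids=parents,
            )
        )
    return windows
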