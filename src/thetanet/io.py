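"""Reading and writing EEG recordings and tabular task files.

Continuous EEG is exchanged either as a delimited numeric matrix (CSV/TSV,
header row = channel labels, one row per sample — the portable, lossless
dialect) or as EDF (European Data Format, 16-bit). EDF files are read with
MNE; writing uses a small built-in EDF writer so that synthetic cohorts can
be exported without extra dependencies.

Event tables (``events.tsv``: trial, phase, onset_sample, duration_samples)
and behavior tables (``behavior.tsv``: trial, correct, rt_ms) are plain
tab-separated files handled with pandas.
"""

from __future__ import annotations

import io as _io
import struct
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import normalize_label

__all__ = [
    "Recording",
    "load_recording",
    "write_recording_delimited",
    "write_recording_edf",
    "read_events",
    "write_events",
    "read_behavior",
    "write_behavior",
]

EVENT_COLUMNS = ["trial", "phase", "onset_sample", "duration_samples"]
BEHAVIOR_COLUMNS = ["trial", "correct", "rt_ms"]
TASK_PHASES = ("cue", "encoding", "maintenance", "retrieval")


@dataclass(frozen=True)
class Recording:
    """A continuous multichannel EEG recording.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : tuple of str
        One label per row of ``data``, canonical montage spelling.
    subject_id : str
        Identifier carried through the pipeline.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    subject_id: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        labels = tuple(normalize_label(c) for c in self.channel_labels)
        object.__setattr__(self, "channel_labels", labels)
        if data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(labels) != data.shape[0]:
            raise ValueError(
                f"{len(labels)} labels for {data.shape[0]} data rows"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.isfinite(data).all():
            raise ValueError("data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "Recording":
        return replace(self, data=data)

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(normalize_label(label))
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def load_recording(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
    subject_id: str | None = None,
    expected_channels: list[str] | None = None,
) -> Recording:
    """Load a recording from an EDF or delimited file.

    Parameters
    ----------
    path : path
        Input file. ``format`` is inferred from the suffix when omitted
        (``.edf`` vs ``.csv``/``.tsv``).
    fs : float, optional
        Required for delimited input (the matrix carries no rate); ignored
        for EDF, which stores it in the header.
    expected_channels : list of str, optional
        When given, the loaded channel set must match (after label
        normalization) or a descriptive error is raised.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        rec = _read_edf(path, subject_id=subject_id)
    elif format == "delimited":
        if fs is None:
            raise ValueError("fs is required for delimited input")
        frame = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
        rec = Recording(
            data=frame.to_numpy(dtype=float).T,
            fs=fs,
            channel_labels=tuple(str(c) for c in frame.columns),
            subject_id=subject_id or path.stem,
        )
    else:
        raise ValueError(f"unknown format {format!r}")
    if expected_channels is not None:
        expected = [normalize_label(c) for c in expected_channels]
        if list(rec.channel_labels) != expected:
            raise ValueError(
                f"channel mismatch in {path.name}: expected {expected}, "
                f"found {list(rec.channel_labels)}"
            )
    return rec


def write_recording_delimited(rec: Recording, path: str | Path) -> None:
    """Write a recording as a delimited matrix (lossless round trip)."""
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w", newline="\n") as fh:
        fh.write(sep.join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.17g", delimiter=sep, newline="\n")


# --------------------------------------------------------------------------
# EDF
# --------------------------------------------------------------------------

def _read_edf(path: Path, subject_id: str | None = None) -> Recording:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE returns volts for EEG channels
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        subject_id=subject_id or path.stem,
    )


def write_recording_edf(rec: Recording, path: str | Path) -> None:
    """Write a recording as a 16-bit EDF file.

    Each channel is scaled to its own physical range, so the round-trip
    error is bounded by one 16-bit quantization step of the channel's
    peak-to-peak amplitude. The signal is padded with zeros to a whole
    number of 1-second data records.
    """
    if rec.fs != int(rec.fs):
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(rec.fs)
    k = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / fs))
    padded = np.zeros((k, n_records * fs))
    padded[:, : rec.n_samples] = rec.data

    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    flat = pmax - pmin <= 0
    pmax[flat] = pmin[flat] + 1.0
    dmin, dmax = -32768, 32767
    gain = (pmax - pmin) / (dmax - dmin)
    digital = np.round((padded - pmin[:, None]) / gain[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = _io.BytesIO()
    header.write(pad("0", 8))  # version
    header.write(pad(rec.subject_id or "X", 80))  # patient id
    header.write(pad("synthetic", 80))  # recording id
    header.write(pad("01.01.00", 8))
    header.write(pad("00.00.00", 8))
    header.write(pad(str(256 * (1 + k)), 8))
    header.write(pad("", 44))
    header.write(pad(str(n_records), 8))
    header.write(pad("1", 8))  # record duration, seconds
    header.write(pad(str(k), 4))
    for label in rec.channel_labels:
        header.write(pad(f"EEG {label}", 16))
    for _ in range(k):
        header.write(pad("synthetic", 80))  # transducer
    for _ in range(k):
        header.write(pad("uV", 8))
    for v in pmin:
        header.write(pad(f"{v:.8g}"[:8], 8))
    for v in pmax:
        header.write(pad(f"{v:.8g}"[:8], 8))
    header.write(pad(str(dmin), 8) * k)
    header.write(pad(str(dmax), 8) * k)
    for _ in range(k):
        header.write(pad("", 80))  # prefiltering
    header.write(pad(str(fs), 8) * k)
    header.write(pad("", 32) * k)  # reserved

    with open(path, "wb") as fh:
        fh.write(header.getvalue())
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())


# --------------------------------------------------------------------------
# Tabular files
# --------------------------------------------------------------------------

def read_events(path: str | Path) -> pd.DataFrame:
    """Read an events table; validates columns and ordering invariants."""
    events = pd.read_csv(path, sep="\t")
    return validate_events(events)


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"events table missing columns {sorted(missing)}")
    events = events[EVENT_COLUMNS].copy()
    for col in ("trial", "onset_sample", "duration_samples"):
        events[col] = events[col].astype(int)
    for trial, grp in events.groupby("trial"):
        if not grp["onset_sample"].is_monotonic_increasing:
            raise ValueError(f"onsets not non-decreasing within trial {trial}")
    return events


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    validate_events(events).to_csv(path, sep="\t", index=False)


def read_behavior(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(BEHAVIOR_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"behavior table missing columns {sorted(missing)}")
    table = table[BEHAVIOR_COLUMNS].copy()
    table["correct"] = table["correct"].astype(bool)
    return table


def write_behavior(table: pd.DataFrame, path: str | Path) -> None:
    table[BEHAVIOR_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )
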