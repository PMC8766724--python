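"""Preprocessing chain for continuous EEG.

The chain mirrors standard clinical-EEG practice: low-pass at 100 Hz,
notch at 49-51 Hz (European mains), re-reference to the common average,
and baseline-drift removal. All filters are 4th-order Butterworth applied
forward-backward (``filtfilt``), i.e. zero-phase, so epoch timing is not
shifted. Artifact removal (ocular/myogenic) is a no-op hook here: the
synthetic cohorts carry no artifacts, and real-data users can plug their
own callable into the pipeline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .io import Recording

__all__ = [
    "EpochSet",
    "lowpass_filter",
    "notch_filter",
    "common_average_reference",
    "remove_drift",
    "extract_epochs",
    "preprocess_recording",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EpochSet:
    """Equal-length task epochs: trials x channels x samples."""

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    phase: str
    trial_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        data = np.ascontiguousarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "trial_ids", tuple(int(t) for t in self.trial_ids))
        if data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trials, channels, samples)")
        if data.shape[0] != len(self.trial_ids):
            raise ValueError("one trial id per epoch required")
        if len(set(self.trial_ids)) != len(self.trial_ids):
            raise ValueError("trial ids must be unique")
        if data.shape[1] != len(self.channel_labels):
            raise ValueError("one label per channel row required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def _filtfilt(rec: Recording, b: np.ndarray, a: np.ndarray) -> Recording:
    return rec.with_data(signal.filtfilt(b, a, rec.data, axis=-1))


def lowpass_filter(rec: Recording, cutoff: float = 100.0, order: int = 4) -> Recording:
    """Zero-phase Butterworth low-pass."""
    if not 0 < cutoff < rec.fs / 2:
        raise ValueError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist={rec.fs / 2} Hz)"
        )
    b, a = signal.butter(order, cutoff, btype="low", fs=rec.fs)
    return _filtfilt(rec, b, a)


def notch_filter(
    rec: Recording, band: tuple[float, float] = (49.0, 51.0), order: int = 4
) -> Recording:
    """Zero-phase Butterworth band-stop (mains notch)."""
    low, high = band
    if not 0 < low < high < rec.fs / 2:
        raise ValueError(f"invalid stop band {band} for fs={rec.fs}")
    b, a = signal.butter(order, (low, high), btype="bandstop", fs=rec.fs)
    return _filtfilt(rec, b, a)


def common_average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous mean across channels from every channel."""
    if rec.n_channels < 2:
        raise ValueError("common average reference needs >= 2 channels")
    return rec.with_data(rec.data - rec.data.mean(axis=0, keepdims=True))


def remove_drift(
    rec: Recording,
    method: str = "linear_detrend",
    cutoff: float | None = None,
    order: int = 4,
) -> Recording:
    """Remove slow baseline drift.

    ``linear_detrend`` subtracts the per-channel least-squares line;
    ``highpass`` applies a zero-phase Butterworth high-pass at ``cutoff``
    (default 0.05 Hz, the lower delta edge).
    """
    if method == "linear_detrend":
        n = rec.n_samples
        t = np.arange(n) - (n - 1) / 2.0
        slope = (rec.data @ t) / (t @ t)
        out = rec.data - rec.data.mean(axis=-1, keepdims=True)
        out -= slope[:, None] * t
        return rec.with_data(out)
    if method == "highpass":
        cutoff = 0.05 if cutoff is None else cutoff
        if not 0 < cutoff < rec.fs / 2:
            raise ValueError(f"highpass cutoff {cutoff} Hz invalid for fs={rec.fs}")
        b, a = signal.butter(order, cutoff, btype="high", fs=rec.fs)
        return _filtfilt(rec, b, a)
    raise ValueError(f"unknown drift-removal method {method!r}")


def extract_epochs(rec: Recording, events: pd.DataFrame, phase: str) -> EpochSet:
    """Cut equal-length epochs for one task phase.

    Sample indexing is 0-based and half-open: an event at onset ``o`` with
    duration ``d`` yields samples ``o .. o+d-1``. All epochs of a phase
    must share one duration (the generator guarantees this; real event
    tables are validated). A phase absent from the table yields an empty
    EpochSet with a warning rather than an error.
    """
    rows = events[events["phase"] == phase]
    if rows.empty:
        warnings.warn(f"no events with phase {phase!r}; returning empty EpochSet")
        return EpochSet(
            data=np.zeros((0, rec.n_channels, 0)),
            fs=rec.fs,
            channel_labels=rec.channel_labels,
            phase=phase,
            trial_ids=(),
        )
    durations = rows["duration_samples"].unique()
    if len(durations) != 1:
        raise ValueError(
            f"phase {phase!r} has mixed durations {sorted(durations)}; "
            "epochs must be equal length"
        )
    dur = int(durations[0])
    out_of_bounds = rows[rows["onset_sample"] + dur > rec.n_samples]
    if not out_of_bounds.empty:
        raise ValueError(
            "epochs exceed recording bounds for trials "
            f"{sorted(out_of_bounds['trial'].tolist())}"
        )
    epochs = np.stack(
        [rec.data[:, o : o + dur] for o in rows["onset_sample"].to_numpy()]
    )
    return EpochSet(
        data=epochs,
        fs=rec.fs,
        channel_labels=rec.channel_labels,
        phase=phase,
        trial_ids=tuple(rows["trial"].tolist()),
    )


def preprocess_recording(
    rec: Recording,
    lowpass_cutoff: float = 100.0,
    notch_band: tuple[float, float] = (49.0, 51.0),
    drift_method: str = "linear_detrend",
    drift_cutoff: float | None = None,
    artifact_hook=None,
) -> Recording:
    """Apply the full chain: low-pass, notch, CAR, drift removal.

    Filters above Nyquist are skipped with a log message (relevant when
    running the smoke profile at reduced sampling rates). ``artifact_hook``,
    when given, is called last with the Recording and must return one.
    """
    steps = []
    if lowpass_cutoff < rec.fs / 2:
        steps.append(f"lowpass@{lowpass_cutoff:g}Hz")
    if notch_band[1] < rec.fs / 2:
        steps.append(f"notch@{notch_band[0]:g}-{notch_band[1]:g}Hz")
    steps += ["common_average_reference", f"drift:{drift_method}"]
    if artifact_hook is not None:
        steps.append("artifact_hook")
    logger.info("preprocessing chain for %s: %s", rec.subject_id, " -> ".join(steps))
    if lowpass_cutoff < rec.fs / 2:
        rec = lowpass_filter(rec, lowpass_cutoff)
    else:
        logger.info(
            "skipping low-pass at %g Hz (Nyquist %g Hz)", lowpass_cutoff, rec.fs / 2
        )
    if notch_band[1] < rec.fs / 2:
        rec = notch_filter(rec, notch_band)
    else:
        logger.info("skipping notch %s (Nyquist %g Hz)", notch_band, rec.fs / 2)
    rec = common_average_reference(rec)
    rec = remove_drift(rec, method=drift_method, cutoff=drift_cutoff)
    if artifact_hook is not None:
        rec = artifact_hook(rec)
    return rec
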