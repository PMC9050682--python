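"""Preprocessing chain: band-pass filter, average reference, downsample, epoch.

The chain runs in exactly this order.  Filtering uses a zero-phase
Hamming-windowed FIR band-pass (0.1–100 Hz by default) with the transition
bandwidth conventions of established EEG software.  Epochs span -100 to
800 ms around every presentation onset at the downsampled 250 Hz rate (226
timepoints).  No baseline correction is applied: with 200–400 ms between
onsets, the pre-stimulus window contains the previous stimulus' response,
so subtracting it would inject structured signal.  For the same reason
successive epochs share samples by design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import mne
import numpy as np
import pandas as pd
from scipy.signal import filtfilt, firwin

from .synth import ContinuousRecording, ParticipantSimulation
from .design import GROUP1_ORIENTATIONS, GROUP2_ORIENTATIONS

logger = logging.getLogger(__name__)

EPOCH_TMIN_MS: float = -100.0
EPOCH_TMAX_MS: float = 800.0
TARGET_RATE_HZ: int = 250


def filter_continuous(
    rec: ContinuousRecording, l_freq: float = 0.1, h_freq: float = 100.0
) -> ContinuousRecording:
    """Zero-phase Hamming-window FIR band-pass; length preserved."""
    sr = rec.sampling_rate_hz
    if sr <= 200:
        raise ValueError("sampling rate must exceed 200 Hz before filtering")
    if h_freq >= sr / 2:
        raise ValueError("low-pass cutoff must be below the Nyquist frequency")
    out = mne.filter.filter_data(
        rec.data,
        sr,
        l_freq,
        h_freq,
        fir_window="hamming",
        fir_design="firwin",
        phase="zero",
        verbose="error",
    )
    return replace(rec, data=out)


def rereference_average(rec: ContinuousRecording) -> ContinuousRecording:
    """Re-reference to the average of all channels (idempotent)."""
    if rec.data.shape[0] < 2:
        raise ValueError("average reference requires at least 2 channels")
    return replace(rec, data=rec.data - rec.data.mean(axis=0, keepdims=True))


def downsample(
    rec: ContinuousRecording, target_hz: int = TARGET_RATE_HZ
) -> ContinuousRecording:
    """Anti-aliased decimation by an integer factor.

    A zero-phase 101-tap Hamming FIR low-pass at 80% of the new Nyquist
    precedes sample picking; event onsets are re-expressed in new sample
    indices.
    """
    sr = rec.sampling_rate_hz
    if sr % target_hz != 0:
        raise ValueError(
            f"sampling rate {sr} is not an integer multiple of {target_hz}"
        )
    q = sr // target_hz
    if q == 1:
        return rec
    h = firwin(101, 0.8 * (target_hz / 2), fs=sr, window="hamming")
    smoothed = filtfilt(h, [1.0], rec.data, axis=-1)
    events = rec.events.copy()
    events["onset_sample"] = (
        (events["onset_sample"] / q).round().astype(int)
    )
    return replace(
        rec, data=smoothed[:, ::q], sampling_rate_hz=target_hz, events=events
    )


@dataclass
class EpochSet:
    """Epoched data (trials x channels x timepoints) with per-trial metadata.

    `metadata` carries the events-table fields plus `analysis_group` (1 for
    cued orientations 22.5/112.5, 2 for 67.5/157.5; only analysable trials
    are labelled).
    """

    data: np.ndarray
    times_ms: np.ndarray
    sampling_rate_hz: int
    metadata: pd.DataFrame

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def _assign_analysis_group(meta: pd.DataFrame) -> pd.Series:
    group = pd.Series(pd.NA, index=meta.index, dtype="Int64")
    analysable = meta["analysable"] == 1
    group[analysable & meta["cued_orientation"].isin(GROUP1_ORIENTATIONS)] = 1
    group[analysable & meta["cued_orientation"].isin(GROUP2_ORIENTATIONS)] = 2
    return group


def epoch(
    rec: ContinuousRecording,
    tmin_ms: float = EPOCH_TMIN_MS,
    tmax_ms: float = EPOCH_TMAX_MS,
) -> EpochSet:
    """Cut one epoch per presentation; windows outside the recording are
    dropped with a logged warning."""
    sr = rec.sampling_rate_hz
    i0 = int(round(tmin_ms * sr / 1000.0))
    i1 = int(round(tmax_ms * sr / 1000.0))
    onsets = rec.events["onset_sample"].to_numpy()
    ok = (onsets + i0 >= 0) & (onsets + i1 < rec.n_samples)
    if not ok.all():
        logger.warning(
            "dropping %d epoch(s) whose window exceeds the recording",
            int((~ok).sum()),
        )
    kept = np.flatnonzero(ok)
    data = np.stack(
        [rec.data[:, onsets[i] + i0 : onsets[i] + i1 + 1] for i in kept]
    )
    meta = rec.events.iloc[kept].reset_index(drop=True)
    meta["analysis_group"] = _assign_analysis_group(meta)
    times_ms = np.arange(i0, i1 + 1) * (1000.0 / sr)
    return EpochSet(
        data=data, times_ms=times_ms, sampling_rate_hz=sr, metadata=meta
    )


def concat_epochs(epoch_sets: list[EpochSet]) -> EpochSet:
    """Stack epoch sets sharing a time axis (e.g. one per sequence)."""
    first = epoch_sets[0]
    for es in epoch_sets[1:]:
        if not np.array_equal(es.times_ms, first.times_ms):
            raise ValueError("epoch sets have mismatched time axes")
    return EpochSet(
        data=np.concatenate([es.data for es in epoch_sets], axis=0),
        times_ms=first.times_ms,
        sampling_rate_hz=first.sampling_rate_hz,
        metadata=pd.concat(
            [es.metadata for es in epoch_sets], ignore_index=True
        ),
    )


def preprocess_recording(
    rec: ContinuousRecording,
    l_freq: float = 0.1,
    h_freq: float = 100.0,
    target_hz: int = TARGET_RATE_HZ,
) -> EpochSet:
    """Full chain on one recording: filter -> re-reference -> downsample -> epoch."""
    return epoch(
        downsample(
            rereference_average(filter_continuous(rec, l_freq, h_freq)),
            target_hz,
        )
    )


def preprocess_participant(
    sim: ParticipantSimulation,
    l_freq: float = 0.1,
    h_freq: float = 100.0,
    target_hz: int = TARGET_RATE_HZ,
) -> EpochSet:
    """Preprocess every sequence of a simulated participant and concatenate."""
    return concat_epochs(
        [
            preprocess_recording(rec, l_freq, h_freq, target_hz)
            for rec in sim.recordings()
        ]
    )
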