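"""Bandpass filtering, middle-segment extraction and fixed-length epoching.

The acquisition protocol records one minute per task; only the middle 40 s are
analysed (subjects take a few seconds to settle into the task and fade near the
end), after a 0.5-40 Hz digital bandpass. Each retained series is cut into
non-overlapping 1024-sample (2 s at 512 Hz) epochs, each treated as one
classification sample: 20 epochs per series, 160 per group for the study
geometry of 4 subjects x 2 tasks.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sp_signal

from .simulate import Recording

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class EpochSet:
    """Epoch tensor (n_epochs x n_channels x epoch_len) with group labels.

    ``provenance[i]`` records (subject_id, task_id, epoch_index) for epoch i.
    """

    epochs: np.ndarray
    fs: float
    montage: Tuple[str, ...]
    labels: np.ndarray
    provenance: List[Tuple[str, str, int]]

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (n_epochs, n_channels, epoch_len)")
        if self.epochs.shape[0] != len(self.labels):
            raise ValueError("labels length must equal number of epochs")
        if self.epochs.shape[1] != len(self.montage):
            raise ValueError("channel axis must match montage length")
        if self.epochs.size and not np.all(np.isfinite(self.epochs)):
            raise ValueError("epochs contain non-finite values")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def epoch_len(self) -> int:
        return self.epochs.shape[2]


def bandpass(recording: Recording, low: float = 0.5, high: float = 40.0) -> Recording:
    """Zero-phase 4th-order Butterworth bandpass, applied per channel.

    Forward-backward filtering keeps the channels time-aligned: any phase
    distortion would corrupt the interregional correlations downstream.
    """
    nyq = recording.fs / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(f"band edges must satisfy 0 < {low} < {high} < fs/2 = {nyq}")
    sos = sp_signal.butter(4, (low, high), btype="bandpass", fs=recording.fs, output="sos")
    filtered = sp_signal.sosfiltfilt(sos, recording.data, axis=1)
    return dataclasses.replace(recording, data=np.ascontiguousarray(filtered))


def extract_middle(recording: Recording, keep_s: float) -> Recording:
    """Keep the centred ``keep_s`` seconds (e.g. t = 10..50 s of a 60 s series)."""
    keep = int(round(keep_s * recording.fs))
    n = recording.n_samples
    if keep > n:
        raise ValueError(f"cannot keep {keep} samples from a {n}-sample recording")
    start = (n - keep) // 2
    return dataclasses.replace(recording, data=recording.data[:, start:start + keep].copy())


def epoch_series(recording: Recording, epoch_len: int = 1024) -> EpochSet:
    """Cut into consecutive non-overlapping epochs; remainder samples dropped."""
    if epoch_len < 2:
        raise ValueError("epoch_len must be >= 2")
    n_epochs = recording.n_samples // epoch_len
    if n_epochs == 0:
        warnings.warn(
            f"recording {recording.subject_id}/{recording.task_id} shorter than one "
            f"epoch ({recording.n_samples} < {epoch_len}); empty EpochSet",
            stacklevel=2,
        )
    usable = recording.data[:, : n_epochs * epoch_len]
    # (channels, n_epochs, epoch_len) -> (n_epochs, channels, epoch_len)
    epochs = usable.reshape(recording.data.shape[0], n_epochs, epoch_len).transpose(1, 0, 2)
    return EpochSet(
        epochs=np.ascontiguousarray(epochs),
        fs=recording.fs,
        montage=tuple(recording.montage),
        labels=np.full(n_epochs, recording.group, dtype=int),
        provenance=[(recording.subject_id, recording.task_id, i) for i in range(n_epochs)],
    )


def reject_epochs(epochset: EpochSet, k_sd: float = 6.0) -> EpochSet:
    """Amplitude-threshold artifact rejection (reproducible stand-in for manual
    visual screening): drop any epoch in which some channel exceeds ``k_sd``
    times that channel's dataset-wide standard deviation. Default off in the
    pipeline."""
    if epochset.n_epochs == 0:
        return epochset
    ch_sd = epochset.epochs.std(axis=(0, 2), keepdims=True)
    bad = np.any(np.abs(epochset.epochs) > k_sd * ch_sd, axis=(1, 2))
    if bad.any():
        logger.info("rejecting %d/%d epochs above %.1f channel SD", bad.sum(),
                    epochset.n_epochs, k_sd)
    keep = ~bad
    return EpochSet(
        epochs=epochset.epochs[keep],
        fs=epochset.fs,
        montage=epochset.montage,
        labels=epochset.labels[keep],
        provenance=[p for p, ok in zip(epochset.provenance, keep) if ok],
    )


def assemble_dataset(
    recordings: Sequence[Recording],
    low: float = 0.5,
    high: float = 40.0,
    keep_s: Optional[float] = 40.0,
    epoch_len: int = 1024,
    reject_k_sd: Optional[float] = None,
) -> EpochSet:
    """bandpass -> extract_middle -> epoch_series over all recordings, stacked.

    Recordings are canonically ordered (group, subject, task) before epoching,
    so the epoch order is independent of input order. All recordings must share
    sampling rate and montage.
    """
    if not recordings:
        raise ValueError("no recordings given")
    fs = recordings[0].fs
    montage = tuple(recordings[0].montage)
    for r in recordings:
        if r.fs != fs:
            raise ValueError(f"sampling-rate mismatch: {r.fs} vs {fs}")
        if tuple(r.montage) != montage:
            raise ValueError(f"montage mismatch in {r.subject_id}/{r.task_id}")

    ordered = sorted(recordings, key=lambda r: (r.group, r.subject_id, r.task_id))
    parts: List[EpochSet] = []
    for rec in ordered:
        rec = bandpass(rec, low, high)
        if keep_s is not None:
            rec = extract_middle(rec, keep_s)
        parts.append(epoch_series(rec, epoch_len))

    out = EpochSet(
        epochs=np.concatenate([p.epochs for p in parts]) if parts else np.empty((0, len(montage), epoch_len)),
        fs=fs,
        montage=montage,
        labels=np.concatenate([p.labels for p in parts]),
        provenance=[pv for p in parts for pv in p.provenance],
    )
    if reject_k_sd is not None:
        out = reject_epochs(out, reject_k_sd)
    return out
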