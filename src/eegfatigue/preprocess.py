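"""Resting/VR EEG preprocessing: re-reference, high-pass, epoching, notch, flags.

The pipeline mirrors a standard resting-state spectral workflow: common-average
re-reference, zero-phase 1.5 Hz high-pass, segmentation into 2 s epochs with a
500 ms moving window, a 50 Hz notch applied after segmentation, and automated
threshold-based artifact flagging.  Flags feed reporting (per-epoch fractions
of clean channels); they never alter the data, because the downstream models
are deliberately evaluated on artifactual signals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synth import ContinuousEEG, Segment

__all__ = ["EpochSet", "preprocess_continuous", "epoch_and_notch", "flag_artifacts"]

logger = logging.getLogger(__name__)


@dataclass
class EpochSet:
    """Epoched EEG: (epochs, channels, samples) plus per-epoch metadata."""

    data: np.ndarray                 # (n_epochs, n_channels, n_samples), uV
    rate: float
    epoch_onsets: np.ndarray         # s from recording start
    epoch_length: float              # s
    step: float                      # s
    labels: np.ndarray               # per-epoch segment kind (str array)
    channel_labels: tuple[str, ...]
    channel_flags: np.ndarray = None  # (n_epochs, n_channels) bool
    clean_fraction: np.ndarray = None  # per-epoch fraction of unflagged channels

    def __post_init__(self) -> None:
        if self.channel_flags is None:
            self.channel_flags = np.zeros(self.data.shape[:2], dtype=bool)
        if self.clean_fraction is None:
            self.clean_fraction = 1.0 - self.channel_flags.mean(axis=1)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def select(self, idx) -> "EpochSet":
        """Subset of epochs (boolean mask or index array)."""
        idx = np.asarray(idx)
        return EpochSet(self.data[idx], self.rate, self.epoch_onsets[idx],
                        self.epoch_length, self.step, self.labels[idx],
                        self.channel_labels, self.channel_flags[idx],
                        self.clean_fraction[idx])


def preprocess_continuous(eeg: ContinuousEEG, highpass_hz: float = 1.5,
                          order: int = 4) -> ContinuousEEG:
    """Common-average re-reference followed by a zero-phase Butterworth high-pass.

    Raises on single-channel input (the common average is undefined there).
    """
    if eeg.n_channels < 2:
        raise ValueError("common-average re-reference requires >= 2 channels")
    sig = eeg.signal - eeg.signal.mean(axis=0, keepdims=True)
    sos = sps.butter(order, highpass_hz, btype="highpass", fs=eeg.rate, output="sos")
    sig = sps.sosfiltfilt(sos, sig, axis=-1)
    # filtering a zero-mean-across-channels signal preserves the zero mean,
    # but enforce it exactly against accumulation of rounding error
    sig -= sig.mean(axis=0, keepdims=True)
    return ContinuousEEG(sig, eeg.rate, tuple(eeg.channel_labels), list(eeg.annotations))


def epoch_and_notch(eeg: ContinuousEEG, segments: list[Segment],
                    epoch_length: float = 2.0, step: float = 0.5,
                    notch_hz: float = 50.0, notch_q: float = 30.0) -> EpochSet:
    """Cut 2 s epochs with a 0.5 s step per segment, then notch-filter each epoch.

    Epoch windows are half-open ``[onset, onset + epoch_length)``; partial
    trailing windows are discarded.  Segments shorter than one epoch yield no
    epochs and log a warning.  The 50 Hz notch (zero-phase IIR) is applied per
    epoch, i.e. after segmentation.
    """
    rate = eeg.rate
    ns = int(round(epoch_length * rate))
    if abs(epoch_length * rate - ns) > 1e-9:
        raise ValueError("epoch_length times rate must be an integer sample count")
    step_ns = int(round(step * rate))

    data, onsets, labels = [], [], []
    for seg in segments:
        i0 = int(round(seg.onset * rate))
        i1 = int(round(seg.end * rate))
        n_ep = (i1 - i0 - ns) // step_ns + 1 if i1 - i0 >= ns else 0
        if n_ep == 0:
            logger.warning("segment %s shorter than one epoch; skipped", seg.kind)
            continue
        for k in range(n_ep):
            start = i0 + k * step_ns
            data.append(eeg.signal[:, start:start + ns])
            onsets.append(start / rate)
            labels.append(seg.kind)
    if not data:
        arr = np.empty((0, eeg.n_channels, ns))
    else:
        arr = np.stack(data)
        if notch_hz and notch_hz < rate / 2:
            b, a = sps.iirnotch(notch_hz, notch_q, fs=rate)
            arr = sps.filtfilt(b, a, arr, axis=-1)
    return EpochSet(arr, rate, np.array(onsets, dtype=float), epoch_length, step,
                    np.array(labels, dtype=object), tuple(eeg.channel_labels))


def flag_artifacts(epochs: EpochSet, amp_threshold: float = 100.0,
                   grad_threshold: float = 50.0) -> EpochSet:
    """Threshold-based artifact flagging per epoch and channel.

    A channel is flagged within an epoch when its absolute amplitude exceeds
    ``amp_threshold`` (uV) or any sample-to-sample step exceeds
    ``grad_threshold`` (uV/sample).  Returns a new :class:`EpochSet` with
    updated flags and clean fractions; the data are untouched.
    """
    if amp_threshold <= 0 or grad_threshold <= 0:
        raise ValueError("thresholds must be positive")
    amp = np.abs(epochs.data).max(axis=-1) > amp_threshold
    grad = np.abs(np.diff(epochs.data, axis=-1)).max(axis=-1) > grad_threshold
    flags = amp | grad
    return EpochSet(epochs.data, epochs.rate, epochs.epoch_onsets,
                    epochs.epoch_length, epochs.step, epochs.labels,
                    epochs.channel_labels, flags, 1.0 - flags.mean(axis=1))
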