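"""Band-pass filtering, resampling, epoching, and artifact rejection.

The analysis chain mirrors a standard resting-state workflow: a zero-phase
1–60 Hz band-pass, optional downsampling to the 200 Hz rate at which scale
τ corresponds to τ·5 ms, segmentation into fixed-length non-overlapping
epochs, and an automated amplitude-threshold epoch rejection standing in
for manual artifact exclusion.

Zero-phase (forward-backward Butterworth) filtering is used because only
offline analysis is performed; no attempt is made to replicate causal
acquisition hardware filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .io import EEGRecording

__all__ = ["EpochSet", "bandpass", "resample", "segment", "reject_epochs"]

#: Minimum coarse-grained length at the largest scale for SampEn with m=2.
_MIN_COARSE_LEN = 4


@dataclass
class EpochSet:
    """Fixed-length artifact-free epochs for one subject.

    Attributes
    ----------
    epochs : ndarray, shape (n_epochs, n_channels, n_samples)
        Kept epochs, µV.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Channel labels in canonical montage order.
    epoch_len : float
        Epoch length in seconds.
    kept, rejected : list of int
        Partition of the original epoch indices.
    subject_id : str
    """

    epochs: np.ndarray
    fs: float
    labels: list[str]
    epoch_len: float
    kept: list[int] = field(default_factory=list)
    rejected: list[int] = field(default_factory=list)
    subject_id: str = ""

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def usable(self) -> bool:
        """False when every epoch was rejected; such subjects are flagged."""
        return self.n_epochs >= 1


def bandpass(rec: EEGRecording, lo: float = 1.0, hi: float = 60.0, order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass, applied per channel.

    Parameters
    ----------
    lo, hi : float
        Pass-band edges in Hz; must satisfy 0 < lo < hi < fs/2.
    order : int
        Butterworth order (effective roll-off doubles under filtfilt).
    """
    nyq = rec.fs / 2.0
    if not (0 < lo < hi):
        raise ValueError(f"need 0 < lo < hi, got lo={lo}, hi={hi}")
    if hi >= nyq:
        raise ValueError(f"high edge {hi} Hz must be below Nyquist {nyq} Hz")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return EEGRecording(out, rec.fs, list(rec.labels), rec.subject_id, dict(rec.meta))


def resample(rec: EEGRecording, target_fs: float) -> EEGRecording:
    """Polyphase downsampling to ``target_fs``; upsampling is refused.

    Downsampling 500 → 200 Hz makes coarse-graining scale τ correspond to
    a τ·5 ms time window.
    """
    if target_fs > rec.fs:
        raise ValueError(f"upsampling {rec.fs} -> {target_fs} Hz not supported")
    if target_fs == rec.fs:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return EEGRecording(out, target_fs, list(rec.labels), rec.subject_id, dict(rec.meta))


def segment(rec: EEGRecording, epoch_len: float, max_scale: int = 40) -> EpochSet:
    """Cut a recording into consecutive non-overlapping fixed-length epochs.

    The trailing remainder shorter than ``epoch_len`` is dropped.  The epoch
    must be long enough that the coarse-grained series at ``max_scale``
    still supports m=2 sample entropy (floor(n/max_scale) >= 4).
    """
    n_per = int(round(epoch_len * rec.fs))
    if n_per // max_scale < _MIN_COARSE_LEN:
        raise ValueError(
            f"epoch of {n_per} samples too short for scale {max_scale} "
            f"(need >= {max_scale * _MIN_COARSE_LEN})"
        )
    n_ep = rec.n_samples // n_per
    if n_ep < 1:
        raise ValueError("recording shorter than one epoch")
    ep = rec.data[:, : n_ep * n_per].reshape(rec.n_channels, n_ep, n_per)
    ep = np.ascontiguousarray(np.swapaxes(ep, 0, 1))
    return EpochSet(
        epochs=ep,
        fs=rec.fs,
        labels=list(rec.labels),
        epoch_len=epoch_len,
        kept=list(range(n_ep)),
        rejected=[],
        subject_id=rec.subject_id,
    )


def reject_epochs(es: EpochSet, amp_thresh: float = 100.0) -> EpochSet:
    """Drop epochs whose absolute peak on any channel exceeds ``amp_thresh`` µV.

    An automated surrogate for manual artifact (blink/movement/EMG)
    exclusion; 100 µV is the common clinical convention.  If every epoch is
    rejected the returned set is flagged unusable rather than silently empty.
    """
    if not amp_thresh > 0:
        raise ValueError(f"amplitude threshold must be positive, got {amp_thresh}")
    peaks = np.abs(es.epochs).max(axis=(1, 2))
    keep_mask = peaks <= amp_thresh
    kept = [es.kept[i] for i in range(es.n_epochs) if keep_mask[i]]
    rejected = sorted(
        set(es.rejected) | {es.kept[i] for i in range(es.n_epochs) if not keep_mask[i]}
    )
    if not kept:
        warnings.warn(
            f"subject {es.subject_id!r}: all {es.n_epochs} epochs exceed "
            f"{amp_thresh} µV; subject flagged unusable"
        )
    return EpochSet(
        epochs=es.epochs[keep_mask],
        fs=es.fs,
        labels=list(es.labels),
        epoch_len=es.epoch_len,
        kept=kept,
        rejected=rejected,
        subject_id=es.subject_id,
    )
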