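"""Preprocessing chain: re-reference, downsample, low-pass, epoch, reject, cap.

All filters are zero-phase FIR so that evoked-potential latencies are not
biased; downsampling is polyphase with built-in anti-aliasing and events are
re-indexed to the nearest new sample.  Artefact rejection is a deterministic
peak-to-peak criterion standing in for visual inspection.
"""

from __future__ import annotations

import logging
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import EpochSet, Event, Recording

__all__ = [
    "rereference_common_average",
    "downsample",
    "lowpass",
    "epoch",
    "reject_trials",
    "cap_trials",
]

logger = logging.getLogger(__name__)


def rereference_common_average(rec: Recording) -> Recording:
    """Subtract the instantaneous mean across channels from every channel."""
    if rec.n_channels < 2:
        raise ValueError("common-average reference needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy(data=data)


def downsample(rec: Recording, target_fs: float) -> Recording:
    """Anti-alias filter and decimate to ``target_fs``; re-index events."""
    if target_fs > rec.fs:
        raise ValueError(f"target fs {target_fs} above original {rec.fs}")
    if target_fs == rec.fs:
        return rec.copy()
    ratio = Fraction(target_fs / rec.fs).limit_denominator(1000)
    data = signal.resample_poly(rec.data, ratio.numerator, ratio.denominator, axis=1)
    scale = target_fs / rec.fs
    last = data.shape[1] - 1
    events = [Event(min(int(round(e.sample * scale)), last), e.label)
              for e in rec.events]
    return rec.copy(data=data, fs=target_fs, events=events)


def lowpass(rec: Recording, cutoff: float) -> Recording:
    """Zero-phase FIR low-pass with stopband edge at 1.25x the cutoff."""
    nyq = rec.fs / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz at or above Nyquist {nyq} Hz")
    transition = 0.25 * cutoff
    # Hamming-window FIR: ~53 dB single-pass, doubled by forward-backward filtering
    numtaps = int(np.ceil(3.3 * rec.fs / transition)) | 1
    taps = signal.firwin(numtaps, cutoff + transition / 2.0, fs=rec.fs)
    data = signal.filtfilt(taps, [1.0], rec.data, axis=1,
                           padlen=min(3 * numtaps, rec.n_samples - 1))
    return rec.copy(data=data)


def epoch(rec: Recording, trigger_label: str, window: tuple[float, float]) -> EpochSet:
    """Cut one trial per matching event; edge-overlapping trials are dropped."""
    a, b = window
    if a >= b:
        raise ValueError("window start must precede window end")
    samples = rec.event_samples(trigger_label)
    if len(samples) == 0:
        raise ValueError(f"no events labelled {trigger_label!r}")
    start_off = int(round(a * rec.fs))
    n_samp = int(round((b - a) * rec.fs))
    starts = samples + start_off
    ok = (starts >= 0) & (starts + n_samp <= rec.n_samples)
    n_dropped = int(np.sum(~ok))
    if n_dropped:
        logger.info("epoch: dropped %d/%d trials overlapping the recording edge",
                    n_dropped, len(samples))
    if not np.any(ok):
        raise ValueError("all requested epochs fall outside the recording")
    data = np.stack([rec.data[:, s:s + n_samp] for s in starts[ok]])
    return EpochSet(data=data, fs=rec.fs, t0_offset=start_off / rec.fs,
                    trigger_label=trigger_label,
                    trial_ids=np.flatnonzero(ok))


def reject_trials(epochs: EpochSet, amp_threshold: float) -> EpochSet:
    """Drop trials whose peak-to-peak amplitude exceeds ``amp_threshold`` uV."""
    if amp_threshold <= 0:
        raise ValueError("amplitude threshold must be > 0")
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)   # (trials, channels)
    keep = np.all(ptp <= amp_threshold, axis=1)
    if not np.any(keep):
        raise ValueError("artefact rejection removed every trial")
    n_rej = int(np.sum(~keep))
    if n_rej:
        logger.info("reject_trials: removed %d/%d trials", n_rej, epochs.n_trials)
    return epochs.subset(keep)


def cap_trials(epochs: EpochSet, n: int) -> EpochSet:
    """Keep the first ``n`` trials in temporal order."""
    if n < 1:
        raise ValueError("trial cap must be >= 1")
    if n > epochs.n_trials:
        raise ValueError(f"requested {n} trials but only {epochs.n_trials} available")
    return epochs.subset(np.arange(n))
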