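"""Comparison of retroprojected solutions against the original EEG.

After a decomposition (blind or semi-blind) has been retroprojected to
channel space, these routines quantify what the extraction captured: the
electrode under the voltage-field maximum at the P100 latency, the averaged
VEP there, the residual ("discrepancy") left in the data, the per-channel
reactivity of evoked activity, and the discrepancy index

    DI = sum_i Rbar_i(residual)^2 / sum_i Rbar_i(EEG)^2

with Rbar = R / (delta2 + delta1 + 1) the window-length-normalised evoked
reactivity.  DI is 0 for a perfect extraction (no evoked content left in the
residual) and 1 for a null extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import EpochSet
from .fss import TemporalConstraintSpec, _temporal_r_from_ea, evoked_activity

__all__ = [
    "DiscrepancyResult",
    "select_electrode",
    "compute_vep",
    "discrepancy",
    "reactivity",
    "discrepancy_index",
]

logger = logging.getLogger(__name__)


@dataclass
class DiscrepancyResult:
    residual: np.ndarray                 # channels x samples, EEG - retroprojection
    reactivity_residual: np.ndarray      # Rbar per channel, residual
    reactivity_eeg: np.ndarray           # Rbar per channel, original EEG
    di: float


def select_electrode(retroprojection: np.ndarray, events: np.ndarray, fs: float,
                     t_k: int, window: tuple[float, float] = (-0.100, 0.250)
                     ) -> int:
    """Channel with the largest |averaged retroprojected potential| at ``t_k``.

    Ties are broken by the lowest channel index (logged).  An all-zero
    voltage field is rejected.
    """
    start_off = int(round(window[0] * fs))
    col = t_k - start_off
    ea = np.stack([
        evoked_activity(ch, events, fs, window)[0] for ch in retroprojection
    ])
    field = np.abs(ea[:, col])
    if np.all(field == 0):
        raise ValueError("all-zero voltage field at the P100 latency")
    best = int(np.argmax(field))
    if np.sum(field == field[best]) > 1:
        logger.info("select_electrode: tie broken by lowest channel index (%d)", best)
    return best


def compute_vep(epochs: EpochSet, channel: int) -> tuple[np.ndarray, np.ndarray]:
    """Across-trial mean and +-1 SD envelope at one electrode.

    The baseline (-100..0 ms) mean is subtracted from every trial first.
    """
    if epochs.n_trials < 2:
        raise ValueError("need at least 2 trials")
    if not (0 <= channel < epochs.n_channels):
        raise ValueError(f"invalid channel {channel}")
    x = epochs.channel(channel)
    base = (epochs.times >= -0.100) & (epochs.times < 0.0)
    x = x - x[:, base].mean(axis=1, keepdims=True)
    return x.mean(axis=0), x.std(axis=0)


def discrepancy(eeg: np.ndarray, retroprojection: np.ndarray) -> np.ndarray:
    """Elementwise difference between the EEG and a retroprojection (exact)."""
    eeg = np.asarray(eeg)
    retroprojection = np.asarray(retroprojection)
    if eeg.shape != retroprojection.shape:
        raise ValueError(f"shape mismatch {eeg.shape} vs {retroprojection.shape}")
    return eeg - retroprojection


def reactivity(data: np.ndarray, events: np.ndarray,
               spec: TemporalConstraintSpec) -> np.ndarray:
    """Per-channel reactivity Rbar = R / (delta2 + delta1 + 1).

    R is the evoked-activity score evaluated on each channel's own evoked
    trace with the channel's own polarity convention, so Rbar is
    magnitude-like; the normalisation makes it invariant to widening the
    window over a constant-amplitude plateau.
    """
    width = spec.delta1 + spec.delta2 + 1
    out = np.empty(data.shape[0])
    for i, ch in enumerate(np.atleast_2d(data)):
        ea, times = evoked_activity(ch, events, spec.fs, spec.epoch_window,
                                    spec.baseline_window)
        out[i] = _temporal_r_from_ea(ea, times, spec) / width
    return out


def discrepancy_index(eeg: np.ndarray, retroprojection: np.ndarray,
                      events: np.ndarray, spec: TemporalConstraintSpec
                      ) -> DiscrepancyResult:
    """DI over all channels; 0 = perfect extraction, 1 = null extraction."""
    residual = discrepancy(eeg, retroprojection)
    r_res = reactivity(residual, events, spec)
    r_eeg = reactivity(eeg, events, spec)
    denom = np.sum(r_eeg**2)
    if denom == 0:
        raise ValueError("no evoked reactivity in the raw data")
    di = float(np.sum(r_res**2) / denom)
    return DiscrepancyResult(residual=residual, reactivity_residual=r_res,
                             reactivity_eeg=r_eeg, di=di)
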