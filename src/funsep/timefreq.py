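"""Event-related spectral perturbation and single-trial analyses.

The short-time transform is a Hann-tapered moving FFT (default 256 samples,
step 32).  ERSP maps are the dB change of across-trial mean power relative to
the mean baseline power per frequency; significance is assessed pointwise with
a bootstrap null built by drawing random baseline latency windows per trial.
The module also separates evoked from induced activity by regressing a scaled
across-trial template out of every trial, averages maps into canonical
frequency bands, orders trials by normalised rectified-area scores, renders
ERP images, and contrasts the first and fourth quartiles of ordered trials
with a permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EpochSet

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "ERSPResult",
    "PerTrialTF",
    "TrialOrder",
    "QuartileResult",
    "per_trial_tf",
    "ersp_single_trial",
    "ersp_of_average",
    "regress_evoked",
    "band_average",
    "order_trials",
    "erp_image",
    "quartile_compare",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    range: tuple[float, float]


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("alpha", (8.0, 13.0)),
    BandDefinition("beta", (14.0, 30.0)),
    BandDefinition("low_gamma", (31.0, 60.0)),
    BandDefinition("high_gamma", (61.0, 90.0)),
)

# Default windows (s) for the two trial-scoring modes; per-subject values are
# configurable because peak latency varies across individuals.
VEP_WINDOW = (0.065, 0.145)
P100_WINDOW = (0.080, 0.120)


@dataclass
class PerTrialTF:
    """Per-trial short-time power at one channel."""

    power: np.ndarray     # (n_trials, n_freqs, n_times)
    freqs: np.ndarray     # Hz
    times: np.ndarray     # s, window centres relative to the trigger
    fs: float


@dataclass
class ERSPResult:
    freqs: np.ndarray
    times: np.ndarray
    dB_map: np.ndarray            # (n_freqs, n_times) mean change from baseline
    sig_mask: np.ndarray          # boolean, same shape, pointwise at level alpha
    baseline_mask: np.ndarray     # boolean over times marking baseline columns
    n_boot: int
    alpha: float


@dataclass
class TrialOrder:
    order: np.ndarray     # permutation of trial positions, ascending score
    scores: np.ndarray    # per-trial normalised rectified area, original order
    window: tuple[float, float]
    mode: str


@dataclass
class QuartileResult:
    q1_mean: np.ndarray
    q4_mean: np.ndarray
    q1_sd: np.ndarray
    q4_sd: np.ndarray
    diff: np.ndarray              # Q4 - Q1 trace
    statistic: float              # time-mean of diff over the test window
    p_value: float                # two-sided permutation p
    n_perm: int = 0


# ---------------------------------------------------------------------------
# Short-time transform
# ---------------------------------------------------------------------------

def _stft_power(x: np.ndarray, win: int, step: int) -> np.ndarray:
    """Hann-tapered moving-window power; x is (..., n_samples)."""
    frames = np.lib.stride_tricks.sliding_window_view(x, win, axis=-1)[..., ::step, :]
    taper = np.hanning(win)
    spec = np.fft.rfft(frames * taper, axis=-1)
    power = (np.abs(spec) ** 2) / (taper @ taper)
    return np.moveaxis(power, -1, -2)      # (..., n_freqs, n_times)


def per_trial_tf(epochs: EpochSet, channel: int = 0, win_samples: int = 256,
                 step: int = 32) -> PerTrialTF:
    if win_samples > epochs.n_samples:
        raise ValueError("window longer than epoch")
    x = epochs.channel(channel)
    power = _stft_power(x, win_samples, step)
    freqs = np.fft.rfftfreq(win_samples, 1.0 / epochs.fs)
    n_times = power.shape[-1]
    centers = (np.arange(n_times) * step + win_samples / 2.0) / epochs.fs
    times = epochs.t0_offset + centers
    return PerTrialTF(power=power, freqs=freqs, times=times, fs=epochs.fs)


def _baseline_mask(times: np.ndarray, baseline_window: tuple[float, float] | None
                   ) -> np.ndarray:
    if baseline_window is None:
        mask = times < 0
    else:
        a, b = baseline_window
        mask = (times >= a) & (times < b)
    if not np.any(mask):
        raise ValueError("baseline shorter than one analysis window")
    return mask


# ---------------------------------------------------------------------------
# ERSP with bootstrap significance
# ---------------------------------------------------------------------------

def _ersp_from_power(power: np.ndarray, freqs: np.ndarray, times: np.ndarray,
                     baseline_mask: np.ndarray, n_boot: int, alpha: float,
                     rng: np.random.Generator) -> ERSPResult:
    n_trials = power.shape[0]
    base_cols = np.flatnonzero(baseline_mask)
    base_ref = power[:, :, base_cols].mean(axis=(0, 2))      # (n_freqs,)
    mean_power = power.mean(axis=0)                          # (n_freqs, n_times)
    db_map = 10.0 * np.log10(mean_power / base_ref[:, None])

    # Null distribution per frequency: across-trial mean power with each
    # trial contributing one randomly drawn baseline latency window.
    draws = rng.choice(base_cols, size=(n_boot, n_trials))
    null = power[np.arange(n_trials)[None, :], :, draws].mean(axis=1)   # (n_boot, n_freqs)
    null_db = 10.0 * np.log10(null / base_ref[None, :])

    # Rank-based two-sided pointwise test: a pixel is significant when its
    # rank among the null draws yields p = 2*min(p_up, p_lo) <= alpha.
    greater = (null_db[:, :, None] >= db_map[None, :, :]).sum(axis=0)
    lesser = (null_db[:, :, None] <= db_map[None, :, :]).sum(axis=0)
    p_up = (1.0 + greater) / (n_boot + 1.0)
    p_lo = (1.0 + lesser) / (n_boot + 1.0)
    p = 2.0 * np.minimum(p_up, p_lo)
    return ERSPResult(freqs=freqs, times=times, dB_map=db_map,
                      sig_mask=p <= alpha, baseline_mask=baseline_mask,
                      n_boot=n_boot, alpha=alpha)


def ersp_single_trial(epochs: EpochSet, channel: int = 0, win_samples: int = 256,
                      step: int = 32, baseline_window: tuple[float, float] | None = None,
                      n_boot: int = 200, alpha: float = 0.01,
                      rng: np.random.Generator | None = None) -> ERSPResult:
    """ERSP of single-trial power, averaged across trials, with bootstrap mask."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for a usable null")
    rng = np.random.default_rng(0) if rng is None else rng
    tf = per_trial_tf(epochs, channel, win_samples, step)
    mask = _baseline_mask(tf.times, baseline_window)
    return _ersp_from_power(tf.power, tf.freqs, tf.times, mask, n_boot, alpha, rng)


def ersp_of_average(epochs: EpochSet, channel: int = 0, win_samples: int = 256,
                    step: int = 32, baseline_window: tuple[float, float] | None = None,
                    n_boot: int = 200, alpha: float = 0.01,
                    rng: np.random.Generator | None = None) -> ERSPResult:
    """ERSP of the trial-averaged waveform; keeps only the evoked part."""
    avg = epochs.data.mean(axis=0, keepdims=True)
    avg_set = EpochSet(data=avg, fs=epochs.fs, t0_offset=epochs.t0_offset,
                       trigger_label=epochs.trigger_label, trial_ids=np.array([0]))
    return ersp_single_trial(avg_set, channel, win_samples, step,
                             baseline_window, n_boot, alpha, rng)


# ---------------------------------------------------------------------------
# Evoked / induced separation
# ---------------------------------------------------------------------------

def regress_evoked(epochs: EpochSet) -> EpochSet:
    """Subtract a per-trial least-squares scaled copy of the evoked template.

    For each channel the template is the across-trial mean; each trial keeps
    its induced (non-phase-locked) activity while the optimally weighted
    evoked contribution is removed.
    """
    if epochs.n_trials < 2:
        raise ValueError("need at least 2 trials to estimate the template")
    template = epochs.data.mean(axis=0)                       # (channels, samples)
    energy = np.sum(template**2, axis=1)                      # per channel
    if np.any(energy == 0):
        raise ValueError("zero-variance template on some channel")
    beta = np.einsum("tcs,cs->tc", epochs.data, template) / energy
    residual = epochs.data - beta[:, :, None] * template[None, :, :]
    return EpochSet(data=residual, fs=epochs.fs, t0_offset=epochs.t0_offset,
                    trigger_label=epochs.trigger_label, trial_ids=epochs.trial_ids)


# ---------------------------------------------------------------------------
# Band averaging
# ---------------------------------------------------------------------------

def band_average(tf: PerTrialTF, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
                 baseline_window: tuple[float, float] = (-0.1, 0.0)
                 ) -> dict[str, np.ndarray]:
    """Per-trial per-band dB time courses, referenced to the baseline interval.

    Power is averaged over each band's frequency rows, converted to dB, and
    the across-trial mean over baseline columns subtracted (a common
    reference per band, as in standard ERSP practice, so between-trial
    contrasts are preserved).
    """
    base_mask = _baseline_mask(tf.times, baseline_window)
    out: dict[str, np.ndarray] = {}
    for band in bands:
        lo, hi = band.range
        fmask = (tf.freqs >= lo) & (tf.freqs <= hi)
        if not np.any(fmask):
            raise ValueError(f"band {band.name} outside the frequency axis")
        band_power = tf.power[:, fmask, :].mean(axis=1)       # (trials, times)
        db = 10.0 * np.log10(band_power)
        db -= db[:, base_mask].mean()
        out[band.name] = db
    return out


# ---------------------------------------------------------------------------
# Trial ordering, ERP images, quartiles
# ---------------------------------------------------------------------------

def order_trials(epochs: EpochSet, channel: int = 0, mode: str = "VEP",
                 window: tuple[float, float] | None = None) -> TrialOrder:
    """Ascending order of trials by normalised rectified area in a window.

    ``mode='VEP'`` scores the whole evoked complex (default 65-145 ms);
    ``mode='P100'`` scores the principal peak alone (default 80-120 ms).
    The score is the mean absolute amplitude over the window, so it is
    invariant to widening the window over constant signal.
    """
    if mode not in ("VEP", "P100"):
        raise ValueError("mode must be 'VEP' or 'P100'")
    if window is None:
        window = VEP_WINDOW if mode == "VEP" else P100_WINDOW
    times = epochs.times
    sel = (times >= window[0]) & (times <= window[1])
    if not np.any(sel):
        raise ValueError("scoring window is empty for this epoch geometry")
    scores = np.mean(np.abs(epochs.channel(channel)[:, sel]), axis=1)
    return TrialOrder(order=np.argsort(scores, kind="stable"), scores=scores,
                      window=window, mode=mode)


def erp_image(epochs: EpochSet, order: TrialOrder, channel: int = 0,
              smooth_width: int = 1) -> np.ndarray:
    """Trials x time matrix with rows sorted by the trial order.

    ``smooth_width`` > 1 applies a boxcar average across adjacent sorted
    trials (a visual aid; it must stay below the number of trials).
    """
    if smooth_width >= epochs.n_trials:
        raise ValueError("smooth_width must be smaller than the trial count")
    img = epochs.channel(channel)[order.order]
    if smooth_width > 1:
        kernel = np.ones(smooth_width) / smooth_width
        img = np.apply_along_axis(
            lambda col: np.convolve(col, kernel, mode="same"), 0, img)
    return img


def quartile_compare(band_trace: np.ndarray, order: TrialOrder,
                     n_perm: int = 1000, rng: np.random.Generator | None = None,
                     stat_window_mask: np.ndarray | None = None) -> QuartileResult:
    """First vs fourth quartile of ordered trials, with a permutation test.

    ``band_trace`` is (trials, times) in original trial order.  The test
    statistic is the time-mean of the Q4 - Q1 difference (optionally over a
    sub-window); the null shuffles trial labels.
    """
    n_trials = band_trace.shape[0]
    if n_trials < 8:
        raise ValueError("need at least 8 trials for quartile comparison")
    rng = np.random.default_rng(0) if rng is None else rng
    q = n_trials // 4
    lo_idx, hi_idx = order.order[:q], order.order[-q:]
    mask = (np.ones(band_trace.shape[1], dtype=bool)
            if stat_window_mask is None else stat_window_mask)

    q1_mean = band_trace[lo_idx].mean(axis=0)
    q4_mean = band_trace[hi_idx].mean(axis=0)
    diff = q4_mean - q1_mean
    stat = float(diff[mask].mean())

    trial_means = band_trace[:, mask].mean(axis=1)
    perm_stats = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n_trials)
        perm_stats[b] = trial_means[perm[-q:]].mean() - trial_means[perm[:q]].mean()
    p = (1.0 + np.sum(np.abs(perm_stats) >= abs(stat))) / (n_perm + 1.0)

    return QuartileResult(
        q1_mean=q1_mean, q4_mean=q4_mean,
        q1_sd=band_trace[lo_idx].std(axis=0), q4_sd=band_trace[hi_idx].std(axis=0),
        diff=diff, statistic=stat, p_value=float(p), n_perm=n_perm)
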