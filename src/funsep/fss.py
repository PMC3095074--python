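"""Functional source separation: semi-blind extraction of a single source.

A single unit-norm weight vector w is sought in PCA-whitened space so that
the source y(t) = w^T z(t) maximises the contrast

    F = J + lambda * R

where J is the log-cosh negentropy approximation used in ICA and R is a
functional constraint: either the event-locked evoked-activity score around
the P100 peak (temporal constraint) or the normalised stimulus-minus-rest
band power difference (spectral constraint, 30-90 Hz by default).  Because R
need not be differentiable, F is optimised by simulated annealing on the unit
sphere (geometric cooling, Gaussian perturbations scaled with temperature,
Metropolis acceptance, multiple restarts) followed by a greedy refinement at
small step size.  The extracted source is mapped back to channel space by a
least-squares mixing column, and its rank-1 retroprojection reconstructs its
scalp contribution.

Both constraints admit fast closed forms in w: epoch averaging is linear, so
the temporal score is a signed sum of a precomputed evoked matrix projected
onto w; Welch band power is quadratic, so the spectral score is a ratio of
two quadratic forms built from band-summed cross-spectral matrices.  The
generic single-timecourse evaluators below are the reference definitions; the
annealer's fast path is tested against them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import EpochSet
from .ica import whiten_reduce

__all__ = [
    "TemporalConstraintSpec",
    "SpectralConstraintSpec",
    "AnnealingConfig",
    "FunctionalSource",
    "evoked_activity",
    "fit_temporal_spec",
    "constraint_temporal",
    "constraint_spectral",
    "negentropy_j",
    "fss_extract",
    "retroproject_fs",
]

logger = logging.getLogger(__name__)

# E[log cosh(X)] for X ~ N(0, 1); reference value of the negentropy contrast.
_GAUSS_LOGCOSH = 0.374567207491438


def _logcosh(y: np.ndarray) -> np.ndarray:
    # overflow-safe log cosh
    a = np.abs(y)
    return a + np.log1p(np.exp(-2.0 * a)) - np.log(2.0)


@dataclass
class TemporalConstraintSpec:
    """P100-peak evoked-activity constraint.

    ``t_k`` is the peak sample index relative to the trigger; ``delta1`` and
    ``delta2`` are the sample distances from the peak to the 50%-amplitude
    points before and after it.  The reference channel is the original EEG
    channel with the maximal evoked potential inside the search window.
    """

    t_k: int
    delta1: int
    delta2: int
    fs: float
    reference_channel: int
    baseline_window: tuple[float, float] = (-0.100, 0.0)
    search_window: tuple[float, float] = (0.080, 0.120)
    epoch_window: tuple[float, float] = (-0.100, 0.250)

    def __post_init__(self) -> None:
        lo = int(round(self.search_window[0] * self.fs))
        hi = int(round(self.search_window[1] * self.fs))
        if not (lo <= self.t_k <= hi):
            raise ValueError("t_k must lie inside the search window")
        if self.delta1 < 0 or self.delta2 < 0:
            raise ValueError("half-width offsets must be >= 0")
        if self.baseline_window[1] > 0:
            raise ValueError("baseline must precede the trigger")


@dataclass
class SpectralConstraintSpec:
    """Stimulus-vs-rest band power constraint (gamma band by default)."""

    band: tuple[float, float] = (30.0, 90.0)
    stim_window: tuple[float, float] = (0.0, 5.0)
    rest_window: tuple[float, float] = (-5.0, 0.0)
    nperseg: int = 256
    noverlap: int = 128

    def __post_init__(self) -> None:
        if self.band[0] >= self.band[1]:
            raise ValueError("band must be a non-empty range")
        if not (self.rest_window[1] <= self.stim_window[0]
                or self.stim_window[1] <= self.rest_window[0]):
            raise ValueError("stimulus and rest windows must be disjoint")


@dataclass
class AnnealingConfig:
    """Simulated-annealing schedule for the FSS contrast.

    ``initial_temperature=None`` (default) sets the temperature adaptively to
    a fraction of the objective spread over random probe directions, so the
    schedule is invariant to the scale of lambda * R.
    """

    n_iterations: int = 1000
    initial_temperature: float | None = None
    cooling_factor: float = 0.993
    perturbation_scale: float = 0.4
    perturbation_floor: float = 0.02
    n_restarts: int = 6
    n_refine: int = 400
    refine_scale: float = 0.1          # decays geometrically to refine_scale_end
    refine_scale_end: float = 0.003
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.cooling_factor < 1.0):
            raise ValueError("cooling factor must lie in (0, 1)")
        for name in ("n_iterations", "n_restarts"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class FunctionalSource:
    timecourse: np.ndarray          # (n_samples,), unit variance
    mixing_column: np.ndarray       # (n_channels,)
    weights: np.ndarray             # unit-norm vector in whitened space
    constraint_value: float         # R of the returned source
    negentropy: float               # J of the returned source
    objective_trace: np.ndarray     # best-so-far F per annealing step
    spec: TemporalConstraintSpec | SpectralConstraintSpec
    lam: float
    improved_over_random: bool = True


# ---------------------------------------------------------------------------
# Reference (single-timecourse) constraint evaluators
# ---------------------------------------------------------------------------

def _epoch_1d(x: np.ndarray, events: np.ndarray, fs: float,
              window: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Event-locked segments of a 1-D signal; returns (segments, times)."""
    start_off = int(round(window[0] * fs))
    n_samp = int(round((window[1] - window[0]) * fs))
    starts = np.asarray(events, dtype=int) + start_off
    ok = (starts >= 0) & (starts + n_samp <= len(x))
    if not np.any(ok):
        raise ValueError("no event window fits inside the data")
    segs = np.stack([x[s:s + n_samp] for s in starts[ok]])
    times = (start_off + np.arange(n_samp)) / fs
    return segs, times


def evoked_activity(x: np.ndarray, events: np.ndarray, fs: float,
                    window: tuple[float, float] = (-0.100, 0.250),
                    baseline_window: tuple[float, float] = (-0.100, 0.0)
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Event-locked average of a source time course, baseline-referenced.

    Returns ``(ea, times)`` where ``ea`` is the pointwise mean across epochs
    with the mean over the baseline window subtracted.
    """
    if len(np.atleast_1d(events)) == 0:
        raise ValueError("need at least one event")
    segs, times = _epoch_1d(np.asarray(x, dtype=float), events, fs, window)
    ea = segs.mean(axis=0)
    base = (times >= baseline_window[0]) & (times < baseline_window[1])
    if not np.any(base):
        raise ValueError("baseline window outside the epoch")
    return ea - ea[base].mean(), times


def fit_temporal_spec(epochs: EpochSet,
                      search_window: tuple[float, float] = (0.080, 0.120),
                      baseline_window: tuple[float, float] = (-0.100, 0.0)
                      ) -> TemporalConstraintSpec:
    """Locate the P100 on the maximal original EEG channel.

    The reference channel is the one with the largest absolute evoked value
    inside the search window; ``t_k`` is its peak sample and the two
    half-width offsets run to the first samples where the evoked trace falls
    below 50% of the peak.
    """
    times = epochs.times
    if times[0] > baseline_window[0] or times[-1] < search_window[1] + 0.05:
        raise ValueError("epochs must cover the baseline and the post-peak flank")
    ea = epochs.data.mean(axis=0)                            # (channels, samples)
    base = (times >= baseline_window[0]) & (times < baseline_window[1])
    ea = ea - ea[:, base].mean(axis=1, keepdims=True)
    sel = (times >= search_window[0]) & (times <= search_window[1])
    win_idx = np.flatnonzero(sel)
    peak_per_ch = np.abs(ea[:, win_idx]).max(axis=1)
    ch = int(np.argmax(peak_per_ch))
    trace = ea[ch]
    k_local = int(np.argmax(np.abs(trace[win_idx])))
    k = int(win_idx[k_local])
    peak = trace[k]
    if peak == 0 or np.allclose(trace, trace[0]):
        raise ValueError("no peak found: evoked response is flat")
    signed = trace * np.sign(peak)
    half = 0.5 * abs(peak)
    d1 = 0
    while k - d1 - 1 >= 0 and signed[k - d1 - 1] >= half:
        d1 += 1
    d2 = 0
    while k + d2 + 1 < len(signed) and signed[k + d2 + 1] >= half:
        d2 += 1
    t_k = int(round(k + times[0] * epochs.fs))               # samples post-trigger
    return TemporalConstraintSpec(t_k=t_k, delta1=d1, delta2=d2, fs=epochs.fs,
                                  reference_channel=ch,
                                  baseline_window=baseline_window,
                                  search_window=search_window,
                                  epoch_window=(baseline_window[0],
                                                max(0.250, (t_k + d2) / epochs.fs + 0.05)))


def _temporal_r_from_ea(ea: np.ndarray, times: np.ndarray,
                        spec: TemporalConstraintSpec) -> float:
    idx = np.round(times * spec.fs).astype(int)
    peak_mask = (idx >= spec.t_k - spec.delta1) & (idx <= spec.t_k + spec.delta2)
    base_mask = ((times >= spec.baseline_window[0])
                 & (times < spec.baseline_window[1]))
    if not np.any(peak_mask):
        raise ValueError("peak window outside the epoch")
    peak_sum = ea[peak_mask].sum()
    sign = 1.0 if peak_sum >= 0 else -1.0   # polarity: peak-window sum positive
    return float(sign * peak_sum - sign * ea[base_mask].sum())


def constraint_temporal(x: np.ndarray, events: np.ndarray,
                        spec: TemporalConstraintSpec) -> float:
    """Evoked-activity score: signed sum over the peak window minus baseline sum.

    The source polarity is chosen so the peak-window sum is positive before
    evaluation; the score is linear in the source scale.
    """
    ea, times = evoked_activity(x, events, spec.fs, spec.epoch_window,
                                spec.baseline_window)
    return _temporal_r_from_ea(ea, times, spec)


def constraint_spectral(x: np.ndarray, block_events: np.ndarray, fs: float,
                        spec: SpectralConstraintSpec) -> float:
    """Normalised stimulus-minus-rest band power of a source time course.

    Welch PSDs (Hann taper, ``nperseg`` samples, 50% overlap) are averaged
    across block windows; R = (sum_band P_stim - sum_band P_rest) /
    sum_band P_rest.
    """
    x = np.asarray(x, dtype=float)
    block_events = np.atleast_1d(block_events)
    stim_segs, _ = _epoch_1d(x, block_events, fs, spec.stim_window)
    rest_segs, _ = _epoch_1d(x, block_events, fs, spec.rest_window)
    freqs, p_stim = signal.welch(stim_segs, fs, window="hann",
                                 nperseg=spec.nperseg, noverlap=spec.noverlap)
    _, p_rest = signal.welch(rest_segs, fs, window="hann",
                             nperseg=spec.nperseg, noverlap=spec.noverlap)
    mask = (freqs >= spec.band[0]) & (freqs <= spec.band[1])
    stim = p_stim.mean(axis=0)[mask].sum()
    rest = p_rest.mean(axis=0)[mask].sum()
    if rest <= 0:
        raise ValueError("rest-band power is zero")
    return float((stim - rest) / rest)


def negentropy_j(x: np.ndarray) -> float:
    """Log-cosh negentropy approximation, evaluated on the standardised signal.

    J = (E[log cosh y] - E[log cosh nu])^2 with nu standard normal; J >= 0,
    ~0 for Gaussian input, larger for super-Gaussian input, and invariant to
    sign flips.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input must be finite")
    std = x.std()
    if std == 0:
        raise ValueError("constant input has undefined negentropy")
    y = (x - x.mean()) / std
    return float((np.mean(_logcosh(y)) - _GAUSS_LOGCOSH) ** 2)


# ---------------------------------------------------------------------------
# Fast objective in whitened space
# ---------------------------------------------------------------------------

class _TemporalObjective:
    """R(w) = signed sums of w @ M with M the whitened evoked matrix."""

    def __init__(self, z: np.ndarray, events: np.ndarray,
                 spec: TemporalConstraintSpec):
        window = spec.epoch_window
        fs = spec.fs
        start_off = int(round(window[0] * fs))
        n_samp = int(round((window[1] - window[0]) * fs))
        starts = np.asarray(events, dtype=int) + start_off
        ok = (starts >= 0) & (starts + n_samp <= z.shape[1])
        segs = np.stack([z[:, s:s + n_samp] for s in starts[ok]])
        m = segs.mean(axis=0)                       # (k, n_samp)
        times = (start_off + np.arange(n_samp)) / fs
        base = (times >= spec.baseline_window[0]) & (times < spec.baseline_window[1])
        m = m - m[:, base].mean(axis=1, keepdims=True)
        idx = np.round(times * fs).astype(int)
        peak = (idx >= spec.t_k - spec.delta1) & (idx <= spec.t_k + spec.delta2)
        self.peak_vec = m[:, peak].sum(axis=1)      # (k,)
        self.base_vec = m[:, base].sum(axis=1)

    def __call__(self, w: np.ndarray) -> float:
        p = w @ self.peak_vec
        sign = 1.0 if p >= 0 else -1.0
        return sign * p - sign * (w @ self.base_vec)


class _SpectralObjective:
    """R(w) = (w C_stim w - w C_rest w) / (w C_rest w)."""

    def __init__(self, z: np.ndarray, block_events: np.ndarray, fs: float,
                 spec: SpectralConstraintSpec):
        self.c_stim = _band_csd(z, block_events, fs, spec, spec.stim_window)
        self.c_rest = _band_csd(z, block_events, fs, spec, spec.rest_window)

    def __call__(self, w: np.ndarray) -> float:
        rest = w @ self.c_rest @ w
        return float((w @ self.c_stim @ w - rest) / rest)


def _band_csd(z: np.ndarray, events: np.ndarray, fs: float,
              spec: SpectralConstraintSpec,
              window: tuple[float, float]) -> np.ndarray:
    """Band-summed cross-spectral matrix over Welch segments of event windows."""
    start_off = int(round(window[0] * fs))
    n_samp = int(round((window[1] - window[0]) * fs))
    step = spec.nperseg - spec.noverlap
    taper = np.hanning(spec.nperseg)
    freqs = np.fft.rfftfreq(spec.nperseg, 1.0 / fs)
    fmask = (freqs >= spec.band[0]) & (freqs <= spec.band[1])
    acc = np.zeros((z.shape[0], z.shape[0]))
    n_segs = 0
    for ev in np.atleast_1d(events):
        s0 = ev + start_off
        if s0 < 0 or s0 + n_samp > z.shape[1]:
            continue
        seg = z[:, s0:s0 + n_samp]
        frames = np.lib.stride_tricks.sliding_window_view(
            seg, spec.nperseg, axis=1)[:, ::step, :]
        spec_f = np.fft.rfft(frames * taper, axis=-1)[:, :, fmask]
        acc += np.einsum("isf,jsf->ij", spec_f, np.conj(spec_f)).real
        n_segs += frames.shape[1]
    if n_segs == 0:
        raise ValueError("no full block window inside the data")
    return acc / n_segs


# ---------------------------------------------------------------------------
# Simulated annealing
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _anneal(objective, k: int, cfg: AnnealingConfig,
            rng: np.random.Generator) -> tuple[np.ndarray, float, np.ndarray, float]:
    """Best weight vector over restarts; returns (w, F, trace, F_at_init)."""
    if cfg.initial_temperature is None:
        probes = [objective(_unit(rng.standard_normal(k))) for _ in range(20)]
        t0 = 0.2 * (max(probes) - min(probes)) + 1e-12
    else:
        t0 = cfg.initial_temperature
    best_w = None
    best_f = -np.inf
    best_trace = None
    init_f = -np.inf
    for _ in range(cfg.n_restarts):
        w = _unit(rng.standard_normal(k))
        f = objective(w)
        init_f = max(init_f, f)
        run_best_w, run_best_f = w, f
        trace = np.empty(cfg.n_iterations + cfg.n_refine)
        temp = t0
        for i in range(cfg.n_iterations):
            scale = max(cfg.perturbation_floor,
                        cfg.perturbation_scale * temp / t0)
            cand = _unit(w + scale * rng.standard_normal(k))
            f_cand = objective(cand)
            if f_cand >= f or rng.random() < np.exp((f_cand - f) / temp):
                w, f = cand, f_cand
                if f > run_best_f:
                    run_best_w, run_best_f = w, f
            temp *= cfg.cooling_factor
            trace[i] = run_best_f
        # greedy refinement from the best point, step size decaying geometrically
        w, f = run_best_w, run_best_f
        decay = (cfg.refine_scale_end / cfg.refine_scale) ** (1.0 / max(1, cfg.n_refine))
        scale = cfg.refine_scale
        for i in range(cfg.n_refine):
            cand = _unit(w + scale * rng.standard_normal(k))
            f_cand = objective(cand)
            if f_cand > f:
                w, f = cand, f_cand
            scale *= decay
            trace[cfg.n_iterations + i] = f
        if f > best_f:
            best_w, best_f, best_trace = w, f, trace
    return best_w, best_f, best_trace, init_f


def fss_extract(data: np.ndarray, spec, events: np.ndarray,
                lam: float = 1000.0, anneal: AnnealingConfig | None = None,
                fs: float | None = None, var_threshold: float = 0.99,
                j_subsample: int = 4) -> FunctionalSource:
    """Extract the functional source maximising F = J + lambda R.

    Parameters
    ----------
    data : (n_channels, n_samples) continuous preprocessed EEG, uV.
    spec : TemporalConstraintSpec or SpectralConstraintSpec.
    events : reversal samples (temporal) or block-onset samples (spectral).
    lam : constraint weight; 1000 by default, 0 reduces to a pure
        single-component negentropy maximiser.
    fs : sampling rate; required for a spectral spec (the temporal spec
        carries its own).
    var_threshold : variance fraction for the internal whitening.
    j_subsample : evaluate J on every ``j_subsample``-th sample during the
        search (the final report always uses the full source).
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    anneal = AnnealingConfig() if anneal is None else anneal
    rng = np.random.default_rng(anneal.seed)
    white = whiten_reduce(np.asarray(data, dtype=float), var_threshold)
    z = white.z
    k = white.n_components

    if isinstance(spec, TemporalConstraintSpec):
        r_of_w = _TemporalObjective(z, events, spec)
        fs_used = spec.fs
    elif isinstance(spec, SpectralConstraintSpec):
        if fs is None:
            raise ValueError("fs is required with a spectral constraint")
        r_of_w = _SpectralObjective(z, events, fs, spec)
        fs_used = fs
    else:
        raise TypeError(f"unsupported constraint spec {type(spec)!r}")

    z_sub = z[:, ::j_subsample]

    def objective(w: np.ndarray) -> float:
        y = w @ z_sub
        j = (np.mean(_logcosh(y)) - _GAUSS_LOGCOSH) ** 2
        return j + lam * r_of_w(w)

    w, f_best, trace, f_init = _anneal(objective, k, anneal, rng)
    if f_best <= f_init:
        warnings.warn("annealing did not improve over random initialisation",
                      RuntimeWarning, stacklevel=2)

    y = w @ z
    y = y / y.std()
    centered = data - data.mean(axis=1, keepdims=True)
    mixing_column = centered @ y / (y @ y)

    if isinstance(spec, TemporalConstraintSpec):
        r_final = constraint_temporal(y, events, spec)
    else:
        r_final = constraint_spectral(y, events, fs_used, spec)
    return FunctionalSource(
        timecourse=y, mixing_column=mixing_column, weights=w,
        constraint_value=float(r_final), negentropy=negentropy_j(y),
        objective_trace=trace, spec=spec, lam=lam,
        improved_over_random=bool(f_best > f_init))


def retroproject_fs(source: FunctionalSource) -> np.ndarray:
    """Rank-1 scalp contribution of the functional source."""
    return np.outer(source.mixing_column, source.timecourse)
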