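"""Synthetic event-related EEG with planted, fully known sources.

The generator emulates a checkerboard-reversal session: stimulation blocks of
``block_dur`` seconds with reversals at ``reversal_rate`` Hz, separated by
``gap_dur`` seconds of rest.  It plants

* a *visual* source with a dipole-like occipital topography carrying a
  P100-like biphasic wave after every reversal, a phase-locked (evoked) gamma
  burst in the first ~200 ms, and non-phase-locked (induced) gamma bursts
  throughout each reversal interval;
* an *alpha* source (8-13 Hz) that desynchronises during stimulation;
* a stationary broadband *background* source;
* per-channel 1/f noise plus a small white sensor-noise floor.

With ``shared_topography=True`` the evoked wave and the gamma activity live in
one source with one mixing column (the single-generator scenario); with
``False`` the induced gamma is split into a second source whose column is
orthogonalised against the visual column.  Per-reversal VEP amplitude can be
coupled to per-reversal induced gamma power through ``coupling_c``.

Everything is derived from a single integer seed, so two runs with equal
configuration are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import signal

from .containers import Event, Recording

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_montage",
    "simulate",
    "spectral_content_check",
]


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Parameters of the simulated checkerboard session.

    Amplitudes are in microvolts.  ``noise_snr`` is the ratio of the mean
    single-trial P100 RMS (over the wave's support, at the channel where the
    visual column peaks) to the RMS of the spatially unstructured noise floor
    (1/f plus sensor white noise) on that channel.  Structured brain
    background (alpha, broadband source) comes on top of that floor, so raw
    single-trial traces remain far noisier than the floor alone.
    """

    n_channels: int = 32
    fs: float = 512.0
    n_blocks: int = 20
    block_dur: float = 5.0
    gap_dur: float = 10.0
    reversal_rate: float = 2.0
    p100_latency: float = 0.100       # s
    p100_width: float = 0.050         # FWHM of the Gaussian envelope, s
    vep_amp_mean: float = 6.0         # uV, peak of the mean P100 at source level
    vep_amp_cv: float = 0.3           # trial-amplitude coefficient of variation
    gamma_freq: float = 45.0          # Hz
    gamma_amp_mean: float = 0.2       # uV, induced-burst envelope peak at mean trial
    evoked_gamma_frac: float = 0.4    # fraction of gamma power that is phase-locked
    coupling_c: float = 0.5           # VEP-amplitude -> induced-gamma-power coupling
    alpha_amp: float = 2.0            # uV RMS of the alpha source at rest
    alpha_desync_frac: float = 0.5    # power drop of alpha during blocks
    background_amp: float = 1.5       # uV RMS of the stationary broadband source
    shared_topography: bool = True
    noise_snr: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("need at least one block")
        for name in ("block_dur", "gap_dur", "reversal_rate", "fs",
                     "p100_latency", "p100_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        n_rev = self.reversal_rate * self.block_dur
        if abs(n_rev - round(n_rev)) > 1e-9:
            raise ValueError("reversal_rate * block_dur must be an integer")
        if not (0.0 <= self.evoked_gamma_frac <= 1.0):
            raise ValueError("evoked_gamma_frac must lie in [0, 1]")
        if not (0.0 <= self.alpha_desync_frac <= 1.0):
            raise ValueError("alpha_desync_frac must lie in [0, 1]")
        if self.noise_snr <= 0:
            raise ValueError("noise_snr must be > 0 (zero-noise-SNR is degenerate)")

    @property
    def reversals_per_block(self) -> int:
        return int(round(self.reversal_rate * self.block_dur))

    @property
    def n_reversals(self) -> int:
        return self.n_blocks * self.reversals_per_block


@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline is never shown."""

    true_sources: np.ndarray          # (n_sources, n_samples), unit structure in uV
    true_mixing: np.ndarray           # (n_channels, n_sources), unit-norm columns
    source_names: list[str]
    trial_vep_amp: np.ndarray         # per-reversal P100 peak amplitude, uV
    trial_gamma_power: np.ndarray     # per-reversal induced gamma power (uV^2 scale)
    event_table: list[Event]
    extras: dict[str, Any] = field(default_factory=dict)

    def source(self, name: str) -> np.ndarray:
        return self.true_sources[self.source_names.index(name)]

    def mixing_column(self, name: str) -> np.ndarray:
        return self.true_mixing[:, self.source_names.index(name)]


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

_ROWS: list[tuple[str, float]] = [
    ("Fp", 0.92), ("AF", 0.78), ("AFF", 0.68), ("F", 0.57), ("FFC", 0.46),
    ("FC", 0.35), ("FCC", 0.24), ("C", 0.12), ("CCP", 0.01), ("CP", -0.10),
    ("CPP", -0.22), ("P", -0.34), ("PPO", -0.45), ("PO", -0.57), ("POO", -0.68),
    ("O", -0.78), ("OI", -0.86), ("I", -0.93),
]

_OCCIPITAL_PREFIXES = ("POO", "O", "OI", "I")


def _full_label_grid() -> tuple[list[str], np.ndarray]:
    labels: list[str] = []
    pos: list[tuple[float, float]] = []
    for prefix, y in _ROWS:
        half_width = 0.95 * np.sqrt(max(1e-6, 1.0 - y * y))
        entries: list[tuple[str, float]] = [(f"{prefix}z", 0.0)]
        for num in range(1, 9):
            k = (num + 1) // 2            # distance rank from the midline
            side = -1.0 if num % 2 == 1 else 1.0
            x_unit = side * k / 4.5
            entries.append((f"{prefix}{num}", x_unit))
            entries.append((f"{prefix}{num}h", x_unit - side * 0.5 / 4.5))
        for name, x_unit in entries:
            labels.append(name)
            pos.append((x_unit * half_width, y))
    return labels, np.array(pos)


def make_montage(n_channels: int) -> tuple[list[str], np.ndarray]:
    """Unique 10-5-style labels with 2-D positions on the unit disc.

    Channels are drawn evenly from an anterior-to-posterior grid so that any
    montage spans the whole scalp, including an occipital group.
    """
    if not (8 <= n_channels <= 256):
        raise ValueError("n_channels must lie in [8, 256]")
    labels, pos = _full_label_grid()
    idx = np.round(np.linspace(0, len(labels) - 1, n_channels)).astype(int)
    if len(np.unique(idx)) != n_channels:   # pragma: no cover - guarded by grid size
        raise RuntimeError("montage sampling produced duplicate channels")
    return [labels[i] for i in idx], pos[idx]


def _rbf_column(pos: np.ndarray, center: tuple[float, float], width: float) -> np.ndarray:
    d2 = np.sum((pos - np.asarray(center)) ** 2, axis=1)
    col = np.exp(-d2 / (2.0 * width**2))
    return col / np.linalg.norm(col)


# ---------------------------------------------------------------------------
# Waveform building blocks
# ---------------------------------------------------------------------------

def _p100_template(cfg: SimulationConfig) -> np.ndarray:
    """One-cycle, Gaussian-windowed biphasic wave peaking at ``p100_latency``.

    Returned on a window of +-2 envelope FWHM around the peak; peak value 1.
    """
    sigma = cfg.p100_width / 2.355
    half = 2.0 * cfg.p100_width
    t = np.arange(-half, half + 0.5 / cfg.fs, 1.0 / cfg.fs)
    f_c = 1.0 / (2.0 * cfg.p100_width)    # one half-cycle per FWHM -> biphasic lobes
    wave = np.exp(-t**2 / (2 * sigma**2)) * np.cos(2 * np.pi * f_c * t)
    return wave / wave.max()


def _gamma_burst(cfg: SimulationConfig, dur: float, center_frac: float,
                 phase: float) -> np.ndarray:
    """Hann-enveloped oscillation at ``gamma_freq`` over ``dur`` seconds."""
    n = int(round(dur * cfg.fs))
    t = np.arange(n) / cfg.fs
    env = np.hanning(n)
    return env * np.cos(2 * np.pi * cfg.gamma_freq * (t - center_frac * dur) + phase)


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float) -> np.ndarray:
    """Per-channel independent 1/f-amplitude noise, unit RMS per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    scale = np.ones_like(freqs)
    nonzero = freqs > 1.0                   # flat below 1 Hz, 1/f above
    scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    shaped = np.fft.irfft(np.fft.rfft(white, axis=1) * scale, n=n_samples, axis=1)
    shaped /= shaped.std(axis=1, keepdims=True)
    return shaped


def _narrowband_noise(rng: np.random.Generator, n_samples: int, fs: float,
                      lo: float, hi: float) -> np.ndarray:
    """Band-limited Gaussian noise with unit RMS."""
    white = rng.standard_normal(n_samples)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    return x / x.std()


def _waxing_envelope(rng: np.random.Generator, n_samples: int, fs: float,
                     timescale: float = 1.0, depth: float = 0.6) -> np.ndarray:
    """Slow positive amplitude modulation (waxing/waning), unit mean square.

    Rhythms in real EEG come and go on a ~second timescale, which also makes
    their amplitude distribution super-Gaussian — without this, a simulated
    rhythm is an (ICA-unidentifiable) Gaussian process.
    """
    slow = _narrowband_noise(rng, n_samples, fs, 1.0 / (4 * timescale),
                             1.0 / timescale)
    env = 1.0 + depth * slow
    env = np.clip(env, 0.05, None)
    return env / np.sqrt(np.mean(env**2))


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def simulate(cfg: SimulationConfig) -> tuple[Recording, GroundTruth]:
    """Generate a continuous recording and its ground truth.

    The recording is ``n_blocks * (block_dur + gap_dur)`` seconds long; each
    block is preceded by its rest gap, so rest epochs (-5..0 s) are always
    available before a block onset.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    n_samples = int(round(cfg.n_blocks * (cfg.block_dur + cfg.gap_dur) * fs))
    labels, pos = make_montage(cfg.n_channels)

    # -- events -------------------------------------------------------------
    period = cfg.block_dur + cfg.gap_dur
    rev_interval = 1.0 / cfg.reversal_rate
    block_onsets = np.array(
        [int(round((b * period + cfg.gap_dur) * fs)) for b in range(cfg.n_blocks)]
    )
    reversal_samples = np.concatenate([
        onset + np.round(np.arange(cfg.reversals_per_block) * rev_interval * fs).astype(int)
        for onset in block_onsets
    ])
    events = ([Event(int(s), "block_onset") for s in block_onsets]
              + [Event(int(s), "reversal") for s in reversal_samples])
    events.sort(key=lambda e: (e.sample, e.label != "block_onset"))

    # -- per-trial amplitudes and powers -------------------------------------
    n_rev = cfg.n_reversals
    vep_amp = cfg.vep_amp_mean * np.maximum(
        0.1, 1.0 + cfg.vep_amp_cv * rng.standard_normal(n_rev))
    indep = np.maximum(0.1, 1.0 + cfg.vep_amp_cv * rng.standard_normal(n_rev))
    c = cfg.coupling_c
    gamma_rel = (1.0 - c) * indep + c * (vep_amp / cfg.vep_amp_mean)
    trial_gamma_power = cfg.gamma_amp_mean**2 * gamma_rel

    # -- phase-locked parts: P100 train and evoked gamma bursts ---------------
    template = _p100_template(cfg)
    half_len = (len(template) - 1) // 2
    peak_shift = int(round(cfg.p100_latency * fs))
    p100_train = np.zeros(n_samples)
    evoked_gamma = np.zeros(n_samples)
    # evoked/induced split: amplitudes scale as sqrt of the power fractions
    ev_scale = cfg.gamma_amp_mean * np.sqrt(cfg.evoked_gamma_frac)
    ind_scale = cfg.gamma_amp_mean * np.sqrt(1.0 - cfg.evoked_gamma_frac)
    ev_burst = _gamma_burst(cfg, 0.18, 0.5, phase=0.0)  # locked burst, ~20-200 ms
    ev_burst_start = int(round(0.02 * fs))
    for k, s in enumerate(reversal_samples):
        start = s + peak_shift - half_len
        sl = slice(max(0, start), min(n_samples, start + len(template)))
        tl = slice(sl.start - start, sl.start - start + (sl.stop - sl.start))
        p100_train[sl] += vep_amp[k] * template[tl]
        bs = s + ev_burst_start
        sl = slice(max(0, bs), min(n_samples, bs + len(ev_burst)))
        tl = slice(sl.start - bs, sl.start - bs + (sl.stop - sl.start))
        evoked_gamma[sl] += ev_scale * (vep_amp[k] / cfg.vep_amp_mean) * ev_burst[tl]

    # -- induced gamma: random-phase bursts spanning each reversal interval ---
    induced = np.zeros(n_samples)
    ind_len = int(round(rev_interval * fs))
    for k, s in enumerate(reversal_samples):
        phase = rng.uniform(0, 2 * np.pi)
        burst = _gamma_burst(cfg, rev_interval, 0.5, phase=phase)
        sl = slice(max(0, s), min(n_samples, s + ind_len))
        tl = slice(sl.start - s, sl.start - s + (sl.stop - sl.start))
        induced[sl] += ind_scale * np.sqrt(gamma_rel[k]) * burst[tl]

    # -- alpha source with block desynchronisation ----------------------------
    # The rhythm rides on broadband 1/f activity of the same population, as in
    # real EEG, so no spatial direction is free of wideband noise.
    alpha_base = _narrowband_noise(rng, n_samples, fs, 8.0, 13.0)
    block_mask = np.zeros(n_samples)
    for onset in block_onsets:
        block_mask[onset:onset + int(round(cfg.block_dur * fs))] = 1.0
    alpha_env = np.where(block_mask > 0, np.sqrt(1.0 - cfg.alpha_desync_frac), 1.0)
    alpha_broadband = 0.4 * cfg.alpha_amp * _pink_noise(rng, 1, n_samples, fs)[0]
    alpha_wax = _waxing_envelope(rng, n_samples, fs, timescale=1.0)
    alpha = cfg.alpha_amp * alpha_base * alpha_env * alpha_wax + alpha_broadband

    # -- stationary broadband background source -------------------------------
    background = (cfg.background_amp * _pink_noise(rng, 1, n_samples, fs)[0]
                  * _waxing_envelope(rng, n_samples, fs, timescale=2.0))

    # -- mixing ---------------------------------------------------------------
    col_visual = _rbf_column(pos, (0.0, -0.78), 0.25)
    col_alpha = _rbf_column(pos, (0.45, -0.40), 0.30)
    col_bg = _rbf_column(pos, (0.0, 0.35), 0.50)

    if cfg.shared_topography:
        # one generator carries the wave and all gamma activity
        evoked = p100_train + evoked_gamma
        sources = np.vstack([evoked + induced, alpha, background])
        names = ["visual", "alpha", "background"]
        mixing = np.column_stack([col_visual, col_alpha, col_bg])
        vep_idx = gamma_idx = 0
    else:
        # distinct generators: the wave on one column, all gamma (evoked and
        # induced) on an orthogonal one.  The gamma field is centred away
        # from the occipital wave generator; with strongly overlapping
        # spatial filters the band-ratio contrast can trade signal purity
        # for rest-noise cancellation between the two directions.
        evoked = p100_train
        col_gamma = _rbf_column(pos, (-0.30, 0.50), 0.30)
        col_gamma = col_gamma - (col_gamma @ col_visual) * col_visual
        col_gamma /= np.linalg.norm(col_gamma)
        sources = np.vstack([p100_train, evoked_gamma + induced, alpha, background])
        names = ["vep", "gamma", "alpha", "background"]
        mixing = np.column_stack([col_visual, col_gamma, col_alpha, col_bg])
        vep_idx, gamma_idx = 0, 1

    clean = mixing @ sources

    # -- unstructured noise floor, calibrated from noise_snr ------------------
    peak_ch = int(np.argmax(np.abs(col_visual)))
    support = np.abs(template) > 0.05
    p100_rms = np.abs(col_visual[peak_ch]) * cfg.vep_amp_mean * np.sqrt(
        np.mean(template[support] ** 2))
    sigma_total = p100_rms / cfg.noise_snr
    sigma_pink = sigma_total / np.sqrt(1.0 + 0.3**2)
    sigma_white = 0.3 * sigma_pink
    noise = (sigma_pink * _pink_noise(rng, cfg.n_channels, n_samples, fs)
             + sigma_white * rng.standard_normal((cfg.n_channels, n_samples)))

    recording = Recording(data=clean + noise, fs=fs, channel_labels=labels,
                          channel_pos=pos, events=events)
    gt = GroundTruth(
        true_sources=sources,
        true_mixing=mixing,
        source_names=names,
        trial_vep_amp=vep_amp,
        trial_gamma_power=trial_gamma_power,
        event_table=events,
        extras={
            "evoked_trace": evoked,
            "induced_trace": induced,
            "sensor_noise": noise,
            "peak_channel": peak_ch,
            "vep_source_idx": vep_idx,
            "gamma_source_idx": gamma_idx,
            "alpha_source_idx": names.index("alpha"),
            "background_source_idx": names.index("background"),
            "p100_template": template,
            "noise_sigma": sigma_total,
        },
    )
    return recording, gt


# ---------------------------------------------------------------------------
# Oracle utilities
# ---------------------------------------------------------------------------

def _segments(x: np.ndarray, starts: np.ndarray, length: int) -> np.ndarray:
    return np.stack([x[s:s + length] for s in starts])


def spectral_content_check(gt: GroundTruth, band: tuple[float, float],
                           cfg: SimulationConfig) -> dict[str, float]:
    """Stimulus/rest band-power ratio per true source, by direct periodogram.

    Independent of the pipeline's PSD machinery: each block's stimulation and
    rest windows are transformed separately and band power summed.  A ratio
    > 1 marks a source with planted stimulus-related band power, < 1 marks
    desynchronisation, ~1 a stationary source.
    """
    lo, hi = band
    if not (0 < lo < hi <= cfg.fs / 2):
        raise ValueError("band must be non-empty and below Nyquist")
    fs = cfg.fs
    onsets = np.array([e.sample for e in gt.event_table if e.label == "block_onset"])
    stim_len = int(round(cfg.block_dur * fs))
    rest_len = min(stim_len, int(round(cfg.gap_dur * fs)))
    out: dict[str, float] = {}
    freqs = np.fft.rfftfreq(stim_len, 1.0 / fs)
    mask = (freqs >= lo) & (freqs <= hi)
    for name, src in zip(gt.source_names, gt.true_sources):
        stim = _segments(src, onsets, stim_len)
        rest = _segments(src, onsets - rest_len, rest_len)
        # per-sample power so unequal stim/rest durations compare fairly
        p_stim = np.mean(np.abs(np.fft.rfft(stim, n=stim_len, axis=1))**2,
                         axis=0) / stim_len
        p_rest = np.mean(np.abs(np.fft.rfft(rest, n=stim_len, axis=1))**2,
                         axis=0) / rest_len
        rest_power = np.sum(p_rest[mask])
        # a source that is silent at rest has unbounded stimulus/rest ratio
        with np.errstate(divide="ignore"):
            out[name] = float(np.sum(p_stim[mask]) / rest_power)
    return out
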