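"""Blind decomposition: PCA reduction, FastICA, gamma screening, retroprojection.

The mixing model is x(t) = A s(t) with m channels and n <= m sources; the
demixing system IC(t) = W x(t) estimates the sources up to permutation, sign
and scale.  Dimensionality is reduced by plain PCA variance ranking to the
smallest component count whose cumulative explained variance reaches the
threshold (default 95%).  Estimation uses the FastICA fixed-point algorithm
with the log-cosh negentropy contrast and symmetric decorrelation.
Components of interest are then screened by their stimulus-versus-rest
gamma-band power change, and selected components are mapped back to channel
space by summing their rank-1 retroprojections.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .containers import EpochSet
from .timefreq import per_trial_tf

__all__ = [
    "Whitening",
    "Decomposition",
    "ComponentScreen",
    "whiten_reduce",
    "fastica",
    "screen_components",
    "retroproject",
]

logger = logging.getLogger(__name__)


@dataclass
class Whitening:
    """PCA basis retaining the top-k variance directions, unit-variance output."""

    z: np.ndarray                  # (k, n_samples) decorrelated, unit variance
    basis: np.ndarray              # (m, k) orthonormal PCA directions
    eigvals: np.ndarray            # top-k covariance eigenvalues
    mean: np.ndarray               # per-channel mean removed before projection
    retained_variance: float       # fraction of total variance kept
    n_components: int

    def project(self, data: np.ndarray) -> np.ndarray:
        centered = data - self.mean[:, None]
        return (self.basis.T @ centered) / np.sqrt(self.eigvals)[:, None]

    def unproject(self, z: np.ndarray) -> np.ndarray:
        """Back to (centered) channel space."""
        return self.basis @ (z * np.sqrt(self.eigvals)[:, None])


@dataclass
class Decomposition:
    sources: np.ndarray            # (k, n_samples), unit variance
    mixing: np.ndarray             # (m, k), channel-space estimate of A
    demixing: np.ndarray           # (k, m), W acting on centered data
    whitening: Whitening
    seed: int

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]

    @property
    def retained_variance(self) -> float:
        return self.whitening.retained_variance


@dataclass
class ComponentScreen:
    selected_ids: np.ndarray       # indices of components with increased gamma
    gamma_gain_db: np.ndarray      # per-component task - rest band change, dB
    p_values: np.ndarray
    band: tuple[float, float]
    alpha: float


def whiten_reduce(data: np.ndarray, var_threshold: float = 0.95) -> Whitening:
    """PCA to the smallest k with cumulative explained variance >= threshold."""
    if not (0.0 < var_threshold <= 1.0):
        raise ValueError("var_threshold must lie in (0, 1]")
    m, n = data.shape
    if n <= m:
        raise ValueError("need more samples than channels")
    mean = data.mean(axis=1)
    centered = data - mean[:, None]
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    eigvals = s**2 / n
    total = eigvals.sum()
    rank = int(np.sum(eigvals > eigvals[0] * 1e-12))
    if var_threshold >= 1.0 and rank < m:
        raise ValueError("rank-deficient data cannot reach 100% explained variance")
    cumfrac = np.cumsum(eigvals) / total
    k = int(np.searchsorted(cumfrac, var_threshold - 1e-12) + 1)
    k = min(k, rank)
    basis = u[:, :k]
    z = (basis.T @ centered) / np.sqrt(eigvals[:k])[:, None]
    return Whitening(z=z, basis=basis, eigvals=eigvals[:k], mean=mean,
                     retained_variance=float(cumfrac[k - 1]), n_components=k)


def fastica(white: Whitening, seed: int = 0, max_restarts: int = 3,
            max_iter: int = 500) -> Decomposition:
    """FastICA (log-cosh, symmetric) on whitened data; deterministic per seed.

    Non-convergent runs are logged and restarted with a derived seed up to
    ``max_restarts`` times before raising.
    """
    last_warning = None
    for attempt in range(max_restarts):
        run_seed = seed + 1000003 * attempt
        est = FastICA(n_components=white.n_components, whiten=False,
                      fun="logcosh", algorithm="parallel", max_iter=max_iter,
                      random_state=run_seed)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            est.fit(white.z.T)
            converged = not any(issubclass(w.category, ConvergenceWarning)
                                for w in caught)
        if converged:
            break
        last_warning = caught[-1]
        logger.warning("fastica: attempt %d did not converge, retrying", attempt + 1)
    else:
        raise RuntimeError(
            f"FastICA failed to converge in {max_restarts} restarts "
            f"(last: {last_warning.message if last_warning else 'unknown'})")

    rotation = est.components_                       # (k, k), approx orthogonal
    sources = rotation @ white.z
    std = sources.std(axis=1)
    sources /= std[:, None]
    # channel-space mixing/demixing through the PCA basis, absorbing the
    # unit-variance rescaling of the sources
    scale = np.sqrt(white.eigvals)
    mixing = white.basis @ (scale[:, None] * np.linalg.pinv(rotation)) * std[None, :]
    demixing = (rotation @ (white.basis / scale[None, :]).T) / std[:, None]
    # sign convention: largest-|entry| of each mixing column positive
    for j in range(mixing.shape[1]):
        if mixing[np.argmax(np.abs(mixing[:, j])), j] < 0:
            mixing[:, j] *= -1.0
            sources[j] *= -1.0
            demixing[j] *= -1.0
    return Decomposition(sources=sources, mixing=mixing, demixing=demixing,
                         whitening=white, seed=seed)


def component_epochs(dec: Decomposition, block_epochs: EpochSet,
                     component: int) -> EpochSet:
    """Project channel-space epochs onto one component's time course."""
    w = dec.demixing[component]
    centered = block_epochs.data - dec.whitening.mean[None, :, None]
    traces = np.einsum("c,tcs->ts", w, centered)[:, None, :]
    return EpochSet(data=traces, fs=block_epochs.fs, t0_offset=block_epochs.t0_offset,
                    trigger_label=block_epochs.trigger_label,
                    trial_ids=block_epochs.trial_ids)


def screen_components(dec: Decomposition, block_epochs: EpochSet,
                      band: tuple[float, float] = (30.0, 90.0),
                      alpha: float = 0.01, n_boot: int = 500,
                      win_samples: int = 256, step: int = 32,
                      rng: np.random.Generator | None = None) -> ComponentScreen:
    """Select components whose gamma power rises from rest to stimulation.

    Per component, each block trial contributes the difference between its
    mean band power (dB) during the task half and during the rest half of the
    epoch.  Significance of the across-trial mean difference is assessed by a
    sign-flip randomisation test, which is exactly calibrated under the
    stationary null.  An empty selection is returned with a warning rather
    than an error.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    k = dec.n_components
    gains = np.empty(k)
    pvals = np.empty(k)
    flips = rng.choice([-1.0, 1.0], size=(n_boot, block_epochs.n_trials))
    for comp in range(k):
        cep = component_epochs(dec, block_epochs, comp)
        tf = per_trial_tf(cep, 0, win_samples, step)
        fmask = (tf.freqs >= band[0]) & (tf.freqs <= band[1])
        task = tf.times > 0
        rest = tf.times <= 0
        if not (np.any(task) and np.any(rest)):
            raise ValueError("block epochs must span both rest and task halves")
        band_db = 10.0 * np.log10(tf.power[:, fmask, :].mean(axis=1))
        d = band_db[:, task].mean(axis=1) - band_db[:, rest].mean(axis=1)
        observed = d.mean()
        null = (flips * d[None, :]).mean(axis=1)
        gains[comp] = observed
        pvals[comp] = (1.0 + np.sum(null >= observed)) / (n_boot + 1.0)
    selected = np.flatnonzero((pvals <= alpha) & (gains > 0))
    if selected.size == 0:
        warnings.warn("no component shows a significant gamma increase",
                      RuntimeWarning, stacklevel=2)
    return ComponentScreen(selected_ids=selected, gamma_gain_db=gains,
                           p_values=pvals, band=band, alpha=alpha)


def retroproject(dec: Decomposition, ids) -> np.ndarray:
    """Sum of rank-1 source contributions A_k IC_k in channel space.

    Retroprojecting every component reproduces the PCA-retained part of the
    (centered) data.
    """
    ids = np.atleast_1d(np.asarray(ids, dtype=int))
    if ids.size == 0:
        raise ValueError("ids must be non-empty")
    if np.any((ids < 0) | (ids >= dec.n_components)):
        raise ValueError("invalid component id")
    return dec.mixing[:, ids] @ dec.sources[ids]
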