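"""Shared fixtures: simulated sessions and their preprocessed/extracted forms.

Expensive artifacts (full 20-block simulations, FSS extractions) are
session-scoped and shared between unit and acceptance tests.  All randomness
is seeded, so the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

import funsep
from funsep import fss, preprocess

REVERSAL_WINDOW = (-0.6, 0.5)
BLOCK_WINDOW = (-5.0, 5.0)


def preprocess_chain(rec):
    """The standard chain at native 512 Hz: re-reference then low-pass 100 Hz."""
    return preprocess.lowpass(preprocess.rereference_common_average(rec), 100.0)


@pytest.fixture(scope="session")
def default_sim():
    """Default shared-topography session: 20 blocks, 200 reversals."""
    cfg = funsep.SimulationConfig(seed=7)
    rec, gt = funsep.simulate(cfg)
    return cfg, rec, gt


@pytest.fixture(scope="session")
def default_prep(default_sim):
    _, rec, gt = default_sim
    clean = preprocess_chain(rec)
    rev = preprocess.epoch(clean, "reversal", REVERSAL_WINDOW)
    blocks = preprocess.epoch(clean, "block_onset", BLOCK_WINDOW)
    return clean, rev, blocks


@pytest.fixture(scope="session")
def small_sim():
    """Cheap 4-block session for unit tests."""
    cfg = funsep.SimulationConfig(n_blocks=4, seed=3)
    rec, gt = funsep.simulate(cfg)
    return cfg, rec, gt


@pytest.fixture(scope="session")
def temporal_spec(default_prep):
    _, rev, _ = default_prep
    return fss.fit_temporal_spec(rev)


@pytest.fixture(scope="session")
def fss_shared(default_prep, temporal_spec):
    """Both constrained extractions on the shared-topography fixture."""
    clean, _, _ = default_prep
    fs_p100 = fss.fss_extract(
        clean.data, temporal_spec, clean.event_samples("reversal"),
        anneal=fss.AnnealingConfig(seed=17))
    fs_gamma = fss.fss_extract(
        clean.data, fss.SpectralConstraintSpec(), clean.event_samples("block_onset"),
        anneal=fss.AnnealingConfig(seed=27), fs=clean.fs)
    return fs_p100, fs_gamma


@pytest.fixture(scope="session")
def decoupled_sim():
    """Distinct orthogonal topographies, zero VEP-gamma coupling.

    The null scenario plants a gamma generator with no phase-locked part
    (any evoked gamma tied to the trial amplitude would itself couple the
    two sources) and makes it strong enough to be extractable on its own.
    """
    cfg = funsep.SimulationConfig(seed=7, shared_topography=False, coupling_c=0.0,
                                  evoked_gamma_frac=0.0, gamma_amp_mean=1.0)
    rec, gt = funsep.simulate(cfg)
    return cfg, rec, gt


@pytest.fixture(scope="session")
def fss_decoupled(decoupled_sim):
    _, rec, _ = decoupled_sim
    clean = preprocess_chain(rec)
    rev = preprocess.epoch(clean, "reversal", REVERSAL_WINDOW)
    tspec = fss.fit_temporal_spec(rev)
    fs_p100 = fss.fss_extract(
        clean.data, tspec, clean.event_samples("reversal"),
        anneal=fss.AnnealingConfig(seed=17))
    fs_gamma = fss.fss_extract(
        clean.data, fss.SpectralConstraintSpec(), clean.event_samples("block_onset"),
        anneal=fss.AnnealingConfig(seed=27), fs=clean.fs)
    return fs_p100, fs_gamma


def corr(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
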