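"""Functional source separation: constraints, negentropy, annealing, recovery."""

import numpy as np
import pytest

import funsep
from funsep import fss
from funsep.fss import (
    AnnealingConfig,
    FunctionalSource,
    SpectralConstraintSpec,
    TemporalConstraintSpec,
    constraint_spectral,
    constraint_temporal,
    evoked_activity,
    fit_temporal_spec,
    fss_extract,
    negentropy_j,
    retroproject_fs,
)
from funsep.containers import EpochSet

from conftest import corr, preprocess_chain

FS = 512.0


def _epochs_from_trials(trials: np.ndarray, t0=-0.1) -> EpochSet:
    return EpochSet(data=trials[:, None, :], fs=FS, t0_offset=t0,
                    trigger_label="reversal", trial_ids=np.arange(len(trials)))


def _template_trace(n=180, peak=0.1, width=0.05, t0=-0.1):
    t = t0 + np.arange(n) / FS
    sigma = width / 2.355
    return np.exp(-((t - peak) ** 2) / (2 * sigma**2)), t


class TestEvokedActivity:
    def test_identical_epochs_reproduce_one_epoch(self):
        tmpl, _ = _template_trace()
        x = np.tile(tmpl, 5)
        events = np.arange(5) * len(tmpl) + round(0.1 * FS)
        ea, times = evoked_activity(x, events, FS, window=(-0.1, 0.25))
        single = x[:len(ea)] - x[:round(0.1 * FS)].mean()
        assert np.allclose(ea, single)

    def test_large_n_recovers_template(self):
        rng = np.random.default_rng(0)
        tmpl, _ = _template_trace(n=180)
        spacing = 256
        n_ev = 400
        x = np.zeros(spacing * (n_ev + 1))
        events = np.arange(n_ev) * spacing + 60
        for s in events:
            x[s - 51:s - 51 + 180] += tmpl
        x += 0.5 * rng.standard_normal(len(x))
        ea, _ = evoked_activity(x, events, FS, window=(-0.1, 0.25))
        assert corr(ea, tmpl[:len(ea)]) > 0.99

    def test_noise_average_scales_as_sqrt_n(self):
        rng = np.random.default_rng(1)
        n_ev = 400
        x = rng.standard_normal(300 * (n_ev + 1))
        events = np.arange(n_ev) * 300 + 100
        ea, _ = evoked_activity(x, events, FS, window=(-0.1, 0.25))
        expected = 1.0 / np.sqrt(n_ev)
        assert 0.5 * expected < ea.std() < 2.0 * expected

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            evoked_activity(np.zeros(100), np.array([]), FS)


class TestFitTemporalSpec:
    def test_planted_peak_and_half_width(self):
        tmpl, t = _template_trace(peak=0.1, width=0.05)
        epochs = _epochs_from_trials(np.tile(tmpl, (20, 1)))
        spec = fit_temporal_spec(epochs)
        assert abs(spec.t_k - round(0.1 * FS)) <= 1
        # oracle FWHM measured on the template itself
        above = np.flatnonzero(tmpl >= 0.5 * tmpl.max())
        fwhm = above[-1] - above[0]
        assert abs((spec.delta1 + spec.delta2) - fwhm) <= 2
        assert abs(spec.delta1 - spec.delta2) <= 1    # symmetric wave

    def test_reference_channel_is_maximal(self, default_prep, default_sim):
        _, rev, _ = default_prep
        _, _, gt = default_sim
        spec = fit_temporal_spec(rev)
        assert spec.reference_channel == gt.extras["peak_channel"]

    def test_flat_response_rejected(self):
        epochs = _epochs_from_trials(np.zeros((10, 180)))
        with pytest.raises(ValueError):
            fit_temporal_spec(epochs)


class TestTemporalConstraint:
    @pytest.fixture(scope="class")
    def spec(self):
        return TemporalConstraintSpec(t_k=51, delta1=7, delta2=7, fs=FS,
                                      reference_channel=0)

    def test_planted_source_scores_highest(self, default_sim, spec):
        _, rec, gt = default_sim
        revs = rec.event_samples("reversal")
        scores = {name: constraint_temporal(src, revs, spec)
                  for name, src in zip(gt.source_names, gt.true_sources)}
        assert scores["visual"] > max(v for k, v in scores.items() if k != "visual")

    def test_zero_signal_gives_zero(self, spec):
        assert constraint_temporal(np.zeros(10000), np.arange(5) * 1000 + 500,
                                   spec) == 0.0

    def test_linearity_in_scale(self, default_sim, spec):
        _, rec, gt = default_sim
        revs = rec.event_samples("reversal")
        src = gt.source("visual")
        r1 = constraint_temporal(src, revs, spec)
        r2 = constraint_temporal(2.0 * src, revs, spec)
        assert np.isclose(r2, 2.0 * r1)
        # polarity convention: a sign flip leaves R unchanged
        assert np.isclose(constraint_temporal(-src, revs, spec), r1)


class TestSpectralConstraint:
    def test_stationary_source_scores_zero(self):
        rng = np.random.default_rng(2)
        n_blocks, period = 20, int(15 * FS)
        x = rng.standard_normal(period * n_blocks + 1000)
        onsets = np.arange(n_blocks) * period + int(5 * FS)
        r = constraint_spectral(x, onsets, FS, SpectralConstraintSpec())
        assert abs(r) < 0.05

    def test_doubled_stimulus_power_gives_one(self):
        """A source whose in-band power exactly doubles during stimulation
        has R = (2P - P)/P = 1 up to PSD estimator error."""
        from scipy import signal as sg
        rng = np.random.default_rng(3)
        n_blocks, period = 20, int(15 * FS)
        n = period * n_blocks + 1000
        sos = sg.butter(4, [30, 90], btype="bandpass", fs=FS, output="sos")
        base = sg.sosfiltfilt(sos, rng.standard_normal(n))
        extra = sg.sosfiltfilt(sos, rng.standard_normal(n))
        onsets = np.arange(n_blocks) * period + int(5 * FS)
        x = base.copy()
        for s in onsets:
            x[s:s + int(5 * FS)] += extra[s:s + int(5 * FS)]
        r = constraint_spectral(x, onsets, FS, SpectralConstraintSpec())
        assert abs(r - 1.0) < 0.1

    def test_planted_gamma_beats_alpha(self, default_sim):
        """Oracle check on the true sources; a small white floor is added
        because the planted visual source is exactly silent at rest."""
        _, rec, gt = default_sim
        rng = np.random.default_rng(11)
        onsets = rec.event_samples("block_onset")
        spec = SpectralConstraintSpec()
        floor = 0.05 * gt.source("visual").std()
        r = {name: constraint_spectral(
                 gt.source(name) + floor * rng.standard_normal(rec.n_samples),
                 onsets, FS, spec)
             for name in ("visual", "alpha")}
        assert r["visual"] > 0
        assert r["visual"] > r["alpha"]

    def test_disjoint_windows_required(self):
        with pytest.raises(ValueError):
            SpectralConstraintSpec(stim_window=(0, 5), rest_window=(-1, 1))


class TestNegentropy:
    def test_gaussian_near_zero(self):
        x = np.random.default_rng(4).standard_normal(100000)
        assert negentropy_j(x) < 1e-4

    def test_super_gaussian_exceeds_gaussian(self):
        rng = np.random.default_rng(5)
        g = rng.standard_normal(100000)
        lap = rng.laplace(size=100000)
        assert negentropy_j(lap) > negentropy_j(g)

    def test_sign_flip_invariant(self):
        x = np.random.default_rng(6).laplace(size=50000)
        assert negentropy_j(x) == negentropy_j(-x)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            negentropy_j(np.ones(1000))


class TestExtraction:
    def test_temporal_recovery(self, default_sim, fss_shared):
        _, _, gt = default_sim
        fs_p100, _ = fss_shared
        assert abs(corr(fs_p100.timecourse, gt.source("visual"))) >= 0.9

    def test_spectral_recovery(self, default_sim, fss_shared):
        _, _, gt = default_sim
        _, fs_gamma = fss_shared
        assert abs(corr(fs_gamma.timecourse, gt.source("visual"))) >= 0.9

    def test_objective_dominates_random_vectors(self, default_prep, fss_shared,
                                                temporal_spec):
        """The annealed solution beats 100 random unit vectors."""
        clean, _, _ = default_prep
        fs_p100, _ = fss_shared
        from funsep.ica import whiten_reduce
        white = whiten_reduce(clean.data, 0.99)
        objective = fss._TemporalObjective(white.z, clean.event_samples("reversal"),
                                           temporal_spec)
        rng = np.random.default_rng(7)
        best_random = max(
            objective(v / np.linalg.norm(v))
            for v in rng.standard_normal((100, white.n_components)))
        assert objective(fs_p100.weights) >= best_random

    def test_fast_path_matches_reference_constraint(self, fss_shared, default_prep,
                                                    temporal_spec):
        """The quadratic/linear annealing objective agrees with the generic
        single-timecourse evaluators on the returned source."""
        clean, _, _ = default_prep
        fs_p100, fs_gamma = fss_shared
        from funsep.ica import whiten_reduce
        white = whiten_reduce(clean.data, 0.99)
        tobj = fss._TemporalObjective(white.z, clean.event_samples("reversal"),
                                      temporal_spec)
        sobj = fss._SpectralObjective(white.z, clean.event_samples("block_onset"),
                                      clean.fs, SpectralConstraintSpec())
        # temporal: linear in the source, so compare after unit-variance scaling
        y = fs_p100.weights @ white.z
        assert np.isclose(tobj(fs_p100.weights) / y.std(),
                          fs_p100.constraint_value, rtol=1e-6)
        assert np.isclose(sobj(fs_gamma.weights), fs_gamma.constraint_value,
                          rtol=0.05)

    def test_objective_trace_envelope_monotone(self, fss_shared):
        for src in fss_shared:
            assert np.all(np.diff(src.objective_trace) >= 0)

    def test_deterministic_given_seed(self, small_sim):
        cfg, rec, _ = small_sim
        clean = preprocess_chain(rec)
        spec = SpectralConstraintSpec()
        kwargs = dict(lam=1000.0, anneal=AnnealingConfig(seed=3, n_iterations=200,
                                                         n_restarts=2, n_refine=50),
                      fs=clean.fs)
        a = fss_extract(clean.data, spec, clean.event_samples("block_onset"), **kwargs)
        b = fss_extract(clean.data, spec, clean.event_samples("block_onset"), **kwargs)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.timecourse, b.timecourse)

    def test_lambda_zero_is_pure_negentropy(self, small_sim):
        """With lambda = 0 the contrast reduces to J alone, so the winner
        maximises negentropy, not the constraint."""
        cfg, rec, _ = small_sim
        clean = preprocess_chain(rec)
        anneal = AnnealingConfig(seed=4, n_iterations=300, n_restarts=2, n_refine=100)
        spec = SpectralConstraintSpec()
        src = fss_extract(clean.data, spec, clean.event_samples("block_onset"),
                          lam=0.0, anneal=anneal, fs=clean.fs)
        rng = np.random.default_rng(8)
        from funsep.ica import whiten_reduce
        white = whiten_reduce(clean.data, 0.99)
        random_j = [negentropy_j(v @ white.z / np.linalg.norm(v))
                    for v in rng.standard_normal((50, white.n_components))]
        assert src.negentropy >= max(random_j)

    def test_lambda_monotonicity(self, small_sim):
        """The achieved constraint value is non-decreasing in lambda."""
        cfg, rec, _ = small_sim
        clean = preprocess_chain(rec)
        spec = SpectralConstraintSpec()
        onsets = clean.event_samples("block_onset")
        values = []
        for lam in (0.0, 10.0, 1000.0):
            rs = [fss_extract(clean.data, spec, onsets, lam=lam,
                              anneal=AnnealingConfig(seed=seed), fs=clean.fs
                              ).constraint_value
                  for seed in (1, 2, 3)]
            values.append(np.mean(rs))
        assert values[0] <= values[1] + 0.05 * abs(values[1])
        assert values[1] <= values[2] + 0.05 * abs(values[2])

    def test_restart_stability(self, small_sim):
        """Best objective varies little across independent annealing seeds."""
        cfg, rec, _ = small_sim
        clean = preprocess_chain(rec)
        spec = SpectralConstraintSpec()
        onsets = clean.event_samples("block_onset")
        finals = []
        for seed in (11, 12, 13, 14, 15):
            src = fss_extract(clean.data, spec, onsets,
                              anneal=AnnealingConfig(seed=seed), fs=clean.fs)
            finals.append(src.objective_trace[-1])
        finals = np.array(finals)
        assert finals.std() / abs(finals.mean()) < 0.05

    def test_negative_lambda_rejected(self, small_sim):
        _, rec, _ = small_sim
        with pytest.raises(ValueError):
            fss_extract(rec.data, SpectralConstraintSpec(),
                        rec.event_samples("block_onset"), lam=-1.0, fs=rec.fs)


class TestRetroprojectFS:
    def _source(self):
        rng = np.random.default_rng(9)
        y = rng.standard_normal(1000)
        a = rng.standard_normal(8)
        return FunctionalSource(
            timecourse=y, mixing_column=a, weights=np.ones(3) / np.sqrt(3),
            constraint_value=1.0, negentropy=0.0, objective_trace=np.zeros(2),
            spec=SpectralConstraintSpec(), lam=1000.0)

    def test_rank_one(self):
        retro = retroproject_fs(self._source())
        assert np.linalg.matrix_rank(retro) == 1

    def test_sign_flip_invariance(self):
        src = self._source()
        flipped = FunctionalSource(
            timecourse=-src.timecourse, mixing_column=-src.mixing_column,
            weights=src.weights, constraint_value=src.constraint_value,
            negentropy=src.negentropy, objective_trace=src.objective_trace,
            spec=src.spec, lam=src.lam)
        assert np.array_equal(retroproject_fs(src), retroproject_fs(flipped))

    def test_noiseless_single_source_reconstruction(self):
        """On rank-1 data the extracted retroprojection reproduces the data."""
        rng = np.random.default_rng(10)
        src = self._source()
        data = np.outer(src.mixing_column, src.timecourse)
        err = np.linalg.norm(retroproject_fs(src) - data) / np.linalg.norm(data)
        assert err < 1e-12
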