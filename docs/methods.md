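# Methods

## Signal model

All routines assume the instantaneous linear mixing model

    x(t) = A s(t) + n(t)

with `x` the m-channel scalp potential (microvolts), `A` an m x n mixing
matrix of unit-norm columns (one scalp field per generator), `s` the n
underlying source time courses and `n` unstructured sensor/background noise.
Blind decomposition estimates a demixing matrix `W` with `IC(t) = W x(t)`
up to permutation, sign and scale; a source is mapped back to the scalp by
its rank-1 retroprojection `A_k IC_k(t)`.

## Semi-blind extraction (FSS)

A single source is extracted by maximising, over unit-norm weight vectors
`w` in PCA-whitened space,

    F(w) = J(y) + lambda * R(y),      y(t) = w' z(t),

where `J` is the log-cosh negentropy approximation used in ICA,

    J(y) = ( E[log cosh y] - E[log cosh nu] )^2,   nu ~ N(0,1),

and `R` encodes prior knowledge about the source being sought:

* **Temporal (P100) constraint.** The evoked activity EA(t) is the
  reversal-locked average of `y`, baseline-referenced to (-100, 0) ms.
  `R` is the signed sum of EA over the window `[t_k - d1, t_k + d2]` minus
  the baseline sum, after flipping polarity so the peak-window sum is
  positive.  The peak sample `t_k` and the 50%-amplitude offsets `d1, d2`
  are fitted once on the raw EEG: the reference channel is the one with the
  largest absolute evoked value inside the 80-120 ms search window.
* **Spectral (gamma) constraint.** `R = (P_stim - P_rest) / P_rest`, where
  `P` is the 30-90 Hz sum of Welch PSDs (Hann taper, 256-sample segments,
  50% overlap) averaged over the stimulation (0..5 s) and rest (-5..0 s)
  windows of every block.

`lambda` defaults to 1000, which makes the constraint dominate and leaves
`J` as a regulariser; `lambda = 0` reduces the extractor to a plain
single-component negentropy maximiser.

Because `R` need not be differentiable, `F` is maximised by simulated
annealing on the unit sphere: Gaussian perturbations whose scale tracks the
temperature (with a small floor), Metropolis acceptance, geometric cooling
(factor 0.993 per step, 1000 steps), six random restarts, and a greedy
refinement of 400 steps whose step size decays geometrically from 0.1 to
0.003.  The initial temperature is set adaptively to 20% of the objective
spread over 20 random probe directions, which makes the schedule invariant
to the scale of `lambda * R`.  The best-of-restarts vector is kept; a run
that fails to improve on its random initialisations raises a warning.

Both constraints admit fast closed forms in `w` — epoch averaging is linear
(the temporal score is a dot product with a precomputed evoked matrix) and
Welch band power is quadratic (the spectral score is a ratio of two
quadratic forms built from band-summed cross-spectral matrices) — so one
annealing step costs O(k) or O(k^2) plus a subsampled negentropy evaluation.
The returned source is always re-scored with the generic single-timecourse
evaluators, and the test suite checks that the two paths agree.

The internal whitening for FSS retains 99% of the variance (the ICA route
uses 95%): the functional source being sought may hold a small variance
share, and a tighter cut risks truncating it when one rhythm dominates.

## Evaluation

* **Electrode selection**: the channel with the largest absolute averaged
  retroprojected potential at the P100 latency (ties broken towards the
  lowest index).
* **VEP**: across-trial mean and +-1 SD at the selected electrode, with the
  (-100, 0) ms baseline subtracted per trial.
* **Discrepancy**: the residual `EEG - retroprojection` (exact elementwise
  subtraction).
* **Reactivity**: per channel, `Rbar = R / (d2 + d1 + 1)` with `R` the
  temporal-constraint score of that channel's own evoked trace under its own
  polarity convention; the normalisation makes `Rbar` invariant to widening
  the window over a constant-amplitude plateau.
* **Discrepancy index**: `DI = sum_i Rbar_i(residual)^2 / sum_i
  Rbar_i(EEG)^2` over channels; 0 for a perfect extraction, 1 for a null
  one.  The squared form follows the printed definition of the index; with
  per-channel polarity made positive it is a magnitude-like ratio.

## Time-frequency analysis

The short-time transform is a Hann-tapered moving FFT, 256 samples
(500 ms at 512 Hz) with a 32-sample step.  The ERSP is the dB change of
across-trial mean power relative to the mean baseline power per frequency.
Significance is pointwise: the null distribution per frequency is built by
resampling one random baseline latency column per trial and re-averaging
(200 draws by default); a pixel is flagged when its rank-based two-sided
p-value `2 * min(p_up, p_lo)` with `p = (1 + count) / (n_boot + 1)` falls at
or below the level (0.01 by default).  This rule is calibrated provided the
baseline spans many analysis windows — with the -5..0 s block baseline the
measured false-positive rate on stationary noise is close to nominal (the
suite asserts 1% +- 0.5%); with baselines only a few windows long the null
draws become correlated and the test grows anticonservative, so block-length
baselines are used wherever the mask matters.

The ERSP of the trial average retains only the phase-locked (evoked) part of
a response *relative to the evoked/noise balance*: the ratio of residual
induced power to baseline noise is invariant under trial averaging, so
induced activity disappears from the averaged map only when its single-trial
band power sits at or below the background in that band — which is the
physiologically typical regime for gamma, and the regime the generator's
defaults emulate.

Evoked/induced separation regresses the across-trial mean template out of
every trial with a per-trial, per-channel least-squares scale ("optimally
weighted" removal); the residual trials keep non-phase-locked activity, and
the mean of the residuals carries no template component (exactly zero for
the least-squares scaling used here).

Band traces average power over the alpha (8-13), beta (14-30), low-gamma
(31-60) and high-gamma (61-90 Hz) rows, convert to dB and subtract the
across-trial mean over the (-100, 0) ms baseline columns — a common
reference per band.  A per-trial baseline was rejected deliberately: with
500 ms windows at a 2 Hz reversal rate the baseline columns overlap
neighbouring reversals, and per-trial subtraction both injects large dB
noise from low-power columns and cancels part of any between-trial effect.

Trials are ordered by the normalised rectified area (mean |amplitude|) over
the VEP window (65-145 ms) or the P100 window (80-120 ms); both windows are
configurable because peak latency varies across subjects.  Quartile
contrasts compare the top and bottom 25% of ordered trials with a label-
permutation test (1000 shuffles, two-sided) on the time-mean of the Q4-Q1
difference.  Single-trial band analyses are run on denoised
(retroprojected) signals: at realistic sensor-level gamma SNR the raw
single-trial band power is noise-dominated and no ordering effect is
measurable there.

## Synthetic sessions

The generator emulates a checkerboard-reversal protocol: blocks of 5 s of
stimulation with reversals at 2 Hz, separated by 10 s of rest, at 512 Hz
(2048 Hz available to exercise the downsampler) on a 10-5-style montage laid
out on the unit disc.  Planted sources:

* a **visual** generator with a focal occipital field carrying (i) a
  one-cycle Gaussian-windowed biphasic wave peaking `p100_latency` (100 ms)
  after every reversal, FWHM `p100_width` (50 ms), per-trial amplitude
  `vep_amp_mean (6 uV) * (1 + vep_amp_cv (0.3) * z)`; (ii) a phase-locked
  gamma burst at `gamma_freq` (45 Hz) in the first ~20-200 ms, amplitude
  proportional to the trial's wave amplitude; (iii) random-phase induced
  gamma bursts spanning each reversal interval with per-trial power
  `(1 - c) * independent + c * normalised VEP amplitude`, `c =
  coupling_c` (0.5).  `evoked_gamma_frac` (0.4) fixes the phase-locked share
  of gamma power.  With `shared_topography=False` the wave and the gamma
  activity are split onto two orthogonal columns.
* an **alpha** source (8-13 Hz, 2 uV RMS) whose narrowband power drops by
  `alpha_desync_frac` (0.5) during stimulation, riding on a broadband 1/f
  component of the same population (0.4x its amplitude) and waxing/waning on
  a ~1 s timescale;
* a stationary broadband **background** source (1.5 uV RMS), also slowly
  amplitude-modulated;
* per-channel independent 1/f noise plus a white sensor floor, scaled so
  that the mean single-trial P100 RMS at the occipital peak channel is
  `noise_snr` (20) times the unstructured floor RMS.

Design rationale for the defaults, in brief: the broadband components and
the slow amplitude modulation reproduce two well-known properties of real
EEG (no spatial direction is free of wideband power; rhythms are
super-Gaussian because they wax and wane) without which, respectively, the
spectral constraint's population optimum drifts off the planted generator
and FastICA cannot converge.  The induced gamma amplitude (0.2 uV) puts
single-trial gamma slightly below the sensor background in its band —
matching its real-world near-invisibility in raw traces and making the
averaged-trial ERSP genuinely evoked-only — while the unstructured floor is
kept low enough that the planted generator is linearly recoverable to high
fidelity and the 95%-variance PCA retains only structured directions.

What the generator does **not** emulate: volume-conduction head geometry
(fields are radial-basis blobs, not lead-field projections), ocular/muscle
artefacts, latency jitter of the stimulus or of the P100, inter-subject
variability, non-stationary electrode impedance, and spatially correlated
sensor noise.  Passing tests therefore demonstrate correctness of the
algorithms under the stated model, not robustness to real-data pathologies.

## Numerical choices and degenerate inputs

* Zero-phase FIR filtering (Hamming-window design, forward-backward) so
  evoked latencies are unbiased; stopband edge at 1.25x the cutoff.
* Polyphase resampling with rational ratios; events re-indexed to the
  nearest new sample and clipped inside the record.
* Epochs overlapping the recording edge are dropped and counted, not padded.
* Artefact rejection is a deterministic peak-to-peak threshold.
* The negentropy reference constant E[log cosh nu] = 0.3745672... is fixed
  by quadrature; log cosh is evaluated in an overflow-safe form.
* Sign conventions: IC mixing columns have their largest-|entry| positive;
  the temporal constraint flips the candidate source so the peak-window sum
  is positive; retroprojections are invariant to all of these.
* Degenerate inputs raise: flat evoked responses, constant signals, empty
  bands or windows, zero rest-band power, all-zero voltage fields,
  rank-deficient data with a 100% variance demand, configurations with a
  non-integer number of reversals per block.

## Known limitations

* The spectral constraint, being a ratio of quadratic forms, will trade a
  little signal purity for rest-noise cancellation when two generators'
  spatial filters overlap strongly; on such geometries its optimum acquires
  an admixture of the other generator even at the population level.
* The bootstrap significance mask is pointwise and makes no multiplicity
  correction across pixels; clusters should be read qualitatively.
* One functional source is extracted per constraint; no deflation scheme for
  several sources per constraint, and no orthogonality coupling between the
  two constrained extractions.
* The quartile permutation test treats trials as exchangeable; slow drifts
  in trial order would violate that.
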