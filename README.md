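# funsep

Blind and semi-blind source separation for event-related EEG, built around
**functional source separation (FSS)**: extracting a single neural generator
by maximising a contrast that combines statistical independence with prior
physiological knowledge.

## The problem

The EEG measured at the scalp is a linear mixture of many generators,

    x(t) = A s(t) + n(t),

so the activity of one population of interest — say, the generator of the
visual evoked potential's P100 peak, or of the stimulus-driven gamma-band
(30–90 Hz) response — is hidden inside every channel.  Independent component
analysis (ICA) unmixes blindly, but leaves the user to pick components.  FSS
instead extracts exactly one source `y = w'x` by maximising

    F = J + λ·R,     λ = 1000,

where `J` is the negentropy index used in ICA and `R` is a *functional
constraint*: either the event-locked evoked activity around the P100 peak
(temporal constraint) or the normalised stimulus-minus-rest gamma band power
(spectral constraint).  Because `R` need not be differentiable, `F` is
maximised by simulated annealing on the unit sphere in whitened space.
Comparing the sources obtained under the two constraints asks a scientific
question directly: are the evoked potential and the gamma response generated
by the same neuronal population?

The package is aimed at electrophysiologists who want a reproducible,
scriptable version of this analysis chain, and ships a synthetic-session
generator with fully known ground truth so that every stage can be validated
by parameter recovery:

* `funsep.synth` — checkerboard-session simulator (blocks, reversals, a
  planted P100+gamma generator, desynchronising alpha, 1/f background).
* `funsep.preprocess` — common-average reference, polyphase downsampling,
  zero-phase low-pass, epoching, peak-to-peak artefact rejection, trial cap.
* `funsep.ica` — PCA reduction to ≥95% explained variance, FastICA,
  gamma-screening of components, retroprojection.
* `funsep.fss` — the temporal and spectral constraints, negentropy,
  simulated annealing, single-source extraction and retroprojection.
* `funsep.evaluate` — electrode selection at the voltage-field maximum, VEP
  averaging, discrepancy, reactivity and the discrepancy index (DI).
* `funsep.timefreq` — event-related spectral perturbation (ERSP) with
  bootstrap significance, evoked/induced separation by template regression,
  band averaging, ERP images, trial ordering and quartile contrasts.
* `funsep.cli` — a `funsep` command orchestrating simulate → preprocess →
  ICA/FSS → evaluate → time-frequency into a run directory with tables,
  figures and a manifest.

## Worked example

```python
import numpy as np
import funsep
from funsep import fss, preprocess

cfg = funsep.SimulationConfig(seed=7)            # 20 blocks, 200 reversals, 32 ch
rec, truth = funsep.simulate(cfg)

clean = preprocess.lowpass(preprocess.rereference_common_average(rec), 100.0)
epochs = preprocess.epoch(clean, "reversal", (-0.6, 0.5))

tspec = fss.fit_temporal_spec(epochs)            # locate the P100 on the raw EEG
fs_p100 = fss.fss_extract(clean.data, tspec, clean.event_samples("reversal"),
                          anneal=fss.AnnealingConfig(seed=17))
fs_gamma = fss.fss_extract(clean.data, fss.SpectralConstraintSpec(),
                           clean.event_samples("block_onset"),
                           anneal=fss.AnnealingConfig(seed=27), fs=clean.fs)

visual = truth.source("visual")
print(f"P100 peak: {tspec.t_k / clean.fs * 1000:.1f} ms on "
      f"{clean.channel_labels[tspec.reference_channel]}")
print(f"temporal-constraint recovery r = "
      f"{abs(np.corrcoef(fs_p100.timecourse, visual)[0, 1]):.3f}")
print(f"spectral-constraint recovery r = "
      f"{abs(np.corrcoef(fs_gamma.timecourse, visual)[0, 1]):.3f}")
print(f"agreement between the two extractions r = "
      f"{abs(np.corrcoef(fs_p100.timecourse, fs_gamma.timecourse)[0, 1]):.3f}")
print(f"spectral constraint R (gamma stim/rest gain) = "
      f"{fs_gamma.constraint_value:.2f}")
```

Output:

```
P100 peak: 99.6 ms on O1
temporal-constraint recovery r = 0.990
spectral-constraint recovery r = 0.991
agreement between the two extractions r = 0.998
spectral constraint R (gamma stim/rest gain) = 2.82
```

The planted session couples the wave and the gamma activity in one
occipital generator; both constraints — one knowing only *when* the evoked
wave peaks, the other only *which band* gains power during stimulation —
recover that generator (r ≈ 0.99 against the ground-truth time course) and
agree with each other (r ≈ 0.998).  The fitted P100 latency (99.6 ms at an
occipital electrode) matches the planted 100 ms, and the extracted source's
gamma power roughly triples during stimulation (R ≈ 2.8).

The same chain runs from the shell:

```bash
funsep all --out runs/demo --seed 7
funsep report --run-dir runs/demo
```

which writes epoch containers, extraction results, a per-method summary
table (selected electrode, P100 latency, discrepancy index), quartile
statistics and PNG figures into `runs/demo/`.

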