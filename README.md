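# uffclamp

Simulation and analysis of **ultrafast force-clamp (UFFC)** single-molecule
optical-trap experiments on myosin.  In a UFFC experiment an actin filament
suspended between two trapped beads (a "three-bead dumbbell") is dragged at
constant force (1.5–4.5 pN) past a surface-bound myosin; when the motor
binds, the filament motion arrests within ~50 µs, and the myosin
**working stroke** — a 5–10 nm lever-arm displacement — is resolved within
a millisecond of binding.  The central scientific question this toolchain
addresses is the ordering of the earliest force-generating events: does the
working stroke precede or follow the release of inorganic phosphate (Pi)
from the actomyosin active site?

The package is a library for researchers who simulate or re-analyze such
recordings.  It covers the full chain:

- **Kinetic engine** — mechanochemical schemes as continuous-time Markov
  chains with Bell-model force-dependent rates, *k(F) = k₀·exp(F·d/kT)*,
  simulated by the first-reaction Gillespie rule; shipped presets for the
  *stroke-first* ordering (stroke → Pi release, rebinding enables
  reversals) and the competing *Pi-first* ordering.
- **Instrument simulator** — 250 kHz dual-trap traces: triangle-wave
  filament motion at *v = F/γ*, Poisson attachments, exponential arrest and
  2 pN/nm series-elastic stretch, per-state lever-arm displacements,
  measurement noise, instrumental drift, and the 2 ms feedback pauses used
  for baseline probing — plus a ground-truth event channel.
- **Drift-and-slope correction (DSC)** — zero-force baselines from the
  feedback pauses, removal of slow drift and the position-proportional
  deflector force error.
- **Event detection** — Gaussian-smoothed velocity thresholding with
  empirical false-event control (≤1%), analytic filter-delay correction,
  per-force deadtimes and binding-time uncertainties (σ_t), and deadtime /
  σ_t calibration against injected arrests.
- **Dwell-time inference** — deadtime-truncated 1–3 exponential-mixture
  maximum likelihood with equal-molecule weighting, nested
  log-likelihood-ratio model selection (p < 0.05), deadtime-corrected
  amplitudes and molecule-level bootstrap confidence intervals:

      f(t) = Σᵢ aᵢ kᵢ e^(−kᵢ t) / Σⱼ aⱼ e^(−kⱼ t_d),   t ≥ t_d.

- **Ensemble averaging** — time-forward averages of event displacements
  with the σ_t extension rule and equal-molecule weighting; quantification
  of stroke amplitude, stroke rate (single-exponential rise, amplitude
  fixed at 1), the post-stroke "dip" attributed to stroke reversals, and
  total displacement.
- **Model comparison** — predicted ensembles under both orderings at 0 vs
  10 mM Pi with paired seeds; the discriminating signatures are the dip
  growth/delay and total-displacement loss (stroke-first) versus a
  Pi-slowed stroke rate (Pi-first).

## Worked example

`examples/` contains one short script per capability.  Fitting a
deadtime-truncated duration mixture (`examples/03_fit_dwell_times.py`):

```
$ python examples/03_fit_dwell_times.py
n = 2000 events >= 0.5 ms deadtime, 6 molecules
selected 2 components (LLR p-values: {'1->2': 4.374829256236037e-305, '2->3': 1.0})
  k0 =   1077.5 s^-1  [68% CI 1033-1127]   A_obs = 0.225   A_corrected = 0.331
  k1 =     10.1 s^-1  [68% CI 10-10]   A_obs = 0.775   A_corrected = 0.669
truth: rates (1000.0, 10.0), corrected amplitudes (0.3, 0.7)
```

The observed fast fraction (0.23) is depressed because most sub-millisecond
events fall below the 0.5 ms deadtime; the deadtime-corrected amplitudes
re-inflate it toward the generating 0.30/0.70 split, and both rates come
back within a few percent.  The other examples simulate a trace with ground truth
(`01`), auto-select detection parameters and measure binding-time accuracy
(`02`), build and quantify a working-stroke ensemble average (`04`), and
run the stroke-first vs Pi-first comparison (`05`).

A thin CLI wraps the same functions for shell use
(`uffc simulate | preprocess | detect | fitdur | ensemble | quantify |
compare | demo`); `uffc demo --seed 1 --out run/` executes the whole
pipeline end to end and writes a manifest with the seed, config hash and
artifact hashes.

## Layout

```
src/uffclamp/     io, kinetics, simulate, dsc, detect, dwell,
                  ensemble, compare, pipeline, cli
tests/            pytest suite (unit, property, acceptance)
examples/         one narrative script per capability
docs/methods.md   models, defaults, calibrations, limitations
```
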