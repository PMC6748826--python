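"""Deadtime-corrected exponential-mixture MLE of attachment durations.

Draws durations from a known two-component mixture, truncates them at an
experimental deadtime, fits 1-3 components with nested model selection, and
prints rates, observed and deadtime-corrected amplitudes with bootstrap
confidence intervals.
"""

import numpy as np

from uffclamp.dwell import DwellSample, bootstrap_ci, select_model

rng = np.random.default_rng(11)
true_amps, true_rates, deadtime = (0.3, 0.7), (1000.0, 10.0), 0.5e-3

samples = []
while len(samples) < 2000:
    comp = rng.random(4000) < true_amps[0]
    t = np.where(comp, rng.exponential(1 / true_rates[0], 4000), rng.exponential(1 / true_rates[1], 4000))
    samples.extend(t[t >= deadtime].tolist())
durations = np.array(samples[:2000])
molecules = np.arange(len(durations)) % 6  # six molecules, weighted equally

sample = DwellSample(durations, molecules, deadtime)
fit = select_model(sample, rng_seed=0)
bootstrap_ci(sample, fit, n_boot=200, levels=(0.68,), rng_seed=1)

print(f"n = {sample.n_events} events >= {deadtime*1e3:.1f} ms deadtime, "
      f"{sample.n_molecules} molecules")
print(f"selected {fit.n_components} components (LLR p-values: {fit.llr_pvalues})")
for i, (k, a_obs, a_corr) in enumerate(
    zip(fit.rates, fit.amplitudes_observed, fit.amplitudes_corrected)
):
    lo, hi = fit.ci[f"k{i}"][0.68]
    print(f"  k{i} = {k:8.1f} s^-1  [68% CI {lo:.0f}-{hi:.0f}]   "
          f"A_obs = {a_obs:.3f}   A_corrected = {a_corr:.3f}")
print(f"truth: rates {true_rates}, corrected amplitudes {true_amps}")
# The observed fast fraction is depressed (~0.21) because most 1 ms-scale
# events fall below the deadtime; the corrected amplitudes re-inflate it
# back to the generating 0.30/0.70 split.
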