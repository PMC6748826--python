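"""Ensemble-average working-stroke displacements and quantify the stroke.

Runs the data pipeline at 3 pN hindering load: simulate, detect, average
the long (>15 ms) hindering events with the extension rule, and quantify
stroke amplitude, stroke rate, dip, and total displacement.
"""

import dataclasses

import numpy as np
import pandas as pd

from uffclamp import (
    DetectionConfig,
    InstrumentConfig,
    detect_events,
    ensemble_from_segments,
    extract_event_segments,
    fit_stroke_rate,
    preset_scheme,
    quantify_stroke,
    simulate_trace,
)
from uffclamp.simulate import MechanicsConfig

force = 3.0
cfg = dataclasses.replace(DetectionConfig(), threshold_fraction=0.5)
scheme = preset_scheme("stroke_first")
instrument = InstrumentConfig(applied_force=force)

segments, kept = [], []
for mol in range(4):
    trace, _ = simulate_trace(
        scheme, instrument, MechanicsConfig(), 60.0, 5.0, rng_seed=100 + mol,
        molecule_id=f"mol{mol}", trace_id=f"t{mol}",
    )
    events = detect_events(trace, cfg, force=force)
    hindering = events[events.direction == "hindering"]
    s, k, _ = extract_event_segments(hindering, trace)
    segments.append(s)
    kept.append(k)
    del trace  # traces are large; keep only the event segments

segments = np.concatenate(segments)
kept = pd.concat(kept, ignore_index=True)
grid = (np.arange(segments.shape[1]) - 250) * 4e-6

long_sel = kept.duration_s >= 0.015
avg = ensemble_from_segments(
    segments[long_sel.to_numpy()], kept[long_sel], grid, force_pN=force, min_duration_s=0.015
)
q = quantify_stroke(avg)
k_stroke, (lo, hi) = fit_stroke_rate(avg, q)

print(f"{avg.n_events} events >15 ms from {avg.n_molecules} molecules at {force} pN")
print(f"initial stroke: {q.initial_displacement_nm:.2f} nm reached by "
      f"t_init = {q.t_init_s*1e3:.2f} ms, rate {k_stroke:.0f} s^-1 (95% CI {lo:.0f}-{hi:.0f})")
print(f"dip: {q.dip_amplitude_nm:.2f} nm at +{q.dip_time_s*1e3:.1f} ms after t_init")
print(f"total displacement: {q.total_displacement_nm:.2f} nm")
# The ~4.5 nm measured step is the 6 nm lever-arm stroke minus the 1.5 nm
# series-elastic stretch at 3 pN / 2 pN/nm; the small dip reflects
# occasional stroke reversals even without added phosphate.
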