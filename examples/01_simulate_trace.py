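"""Simulate a short ultrafast-force-clamp recording with ground truth.

Builds the stroke-first myosin scheme, simulates 20 s of dual-trap data at
3 pN with attachments at 2 s^-1, adds instrumental drift and feedback
pauses, and prints what the ground-truth channel knows about each event.
"""

import numpy as np

from uffclamp import InstrumentConfig, preset_scheme, simulate_trace
from uffclamp.simulate import DriftModel, MechanicsConfig, apply_drift_and_pauses

scheme = preset_scheme("stroke_first")
instrument = InstrumentConfig(applied_force=3.0)
trace, truth = simulate_trace(
    scheme, instrument, MechanicsConfig(), duration_s=20.0, attachment_rate=2.0, rng_seed=7
)
trace, truth = apply_drift_and_pauses(trace, DriftModel(), rng_seed=8, truth=truth)

print(f"{trace.n_samples} samples at {1/trace.dt/1e3:.0f} kHz "
      f"({trace.pause_flag.mean():.0%} of time in feedback pauses)")
print(f"{len(truth)} attachments; unbound speed {instrument.unbound_speed/1e3:.1f} nm/ms")
for ev in truth[:8]:
    stroke = "no stroke" if ev.detached_prestroke else f"stroke at +{(ev.stroke_time_s-ev.start_s)*1e3:.2f} ms"
    print(f"  t={ev.start_s:7.3f} s  {ev.duration_s*1e3:8.2f} ms  {ev.direction:9s}  {stroke}")
durs = np.array([e.duration_s for e in truth])
print(f"median duration {np.median(durs)*1e3:.2f} ms; "
      f"{np.mean([e.detached_prestroke for e in truth]):.0%} detached before the stroke")
# Durations span sub-ms (pre-stroke detachments) to seconds (full ATPase
# cycles); hindering events arrest the filament against the 3 pN load.
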