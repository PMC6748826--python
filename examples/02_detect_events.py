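"""Detect binding events by velocity thresholding and check them against truth.

Simulates a myosin-free trace to auto-select the smoothing width and
velocity threshold (false events <= 1% of the expected event count), then
detects attachments on a trace with binding and reports detection
efficiency and binding-time accuracy against the ground truth.
"""

import numpy as np

from uffclamp import (
    DEADTIME_TABLE,
    DetectionConfig,
    InstrumentConfig,
    detect_events,
    preset_scheme,
    select_detection_params,
    simulate_trace,
)
from uffclamp.simulate import MechanicsConfig

force = 3.0
instrument = InstrumentConfig(applied_force=force)
mech = MechanicsConfig()
scheme = preset_scheme("stroke_first")

free, _ = simulate_trace(scheme, instrument, mech, 30.0, 0.0, rng_seed=1)
cfg = select_detection_params(free, DetectionConfig(), expected_event_count=30, force=force)
print(f"selected smoothing {cfg.gaussian_sigma_s*1e6:.0f} us, "
      f"threshold {cfg.threshold_fraction:.2f} x unbound speed")

trace, truth = simulate_trace(scheme, instrument, mech, 60.0, 3.0, rng_seed=2)
events = detect_events(trace, cfg, force=force)
dead = DEADTIME_TABLE[force]
detectable = [e for e in truth if e.duration_s >= 2 * dead and not e.truncated]
det_s, det_e = events.start_s.to_numpy(), events.end_s.to_numpy()
errors = []
for e in detectable:
    hits = np.flatnonzero((det_e > e.start_s) & (det_s < e.end_s))
    if len(hits) == 1:
        errors.append(det_s[hits[0]] - e.start_s)
errors = np.array(errors)

print(f"{len(events)} events detected (deadtime {dead*1e3:.2f} ms); "
      f"{len(errors)}/{len(detectable)} well-resolved truth events matched")
print(f"binding-time error: mean {errors.mean()*1e6:+.0f} us, RMS {np.sqrt((errors**2).mean())*1e6:.0f} us")
print(events.head(5).round(5).to_string(index=False))
# Events >= 2x the deadtime are found essentially always; start times are
# localized to a few hundred microseconds at 3 pN, the sigma_t scale that
# also sets the ensemble extension point.
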