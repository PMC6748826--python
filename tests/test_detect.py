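import dataclasses

import numpy as np
import pytest

from uffclamp import (
    DetectionConfig,
    InstrumentConfig,
    Trace,
    ValidationError,
    calibrate_deadtime_sigma,
    detect_events,
    select_threshold,
    simulate_trace,
    smoothed_velocity,
)
from uffclamp.detect import (
    DEADTIME_TABLE,
    DetectionError,
    _delay_shift,
    count_false_events,
    unbound_speed_estimate,
)
from uffclamp.simulate import MechanicsConfig

from conftest import single_exit_scheme


def _arrest_trace(v=66667.0, t0=0.02, t1=0.04, total=0.06, dt=4e-6, noise=0.0, seed=0):
    """Constant-velocity motion with one rigid arrest in [t0, t1)."""
    rng = np.random.default_rng(seed)
    n = int(round(total / dt))
    t = np.arange(n) * dt
    x = np.where(t < t0, v * t, np.where(t < t1, v * t0, v * t0 + v * (t - t1)))
    if noise:
        x = x + rng.normal(0, noise, n)
    return Trace(
        dt=dt,
        trap_pos_lead=x,
        trap_pos_trail=x - 500.0,
        force_lead=np.full(n, 3.0),
        force_trail=np.full(n, 4.5),
        pause_flag=np.zeros(n, dtype=bool),
        meta=InstrumentConfig(applied_force=3.0),
    )


class TestSmoothedVelocity:
    def test_constant_velocity_recovered(self):
        tr = _arrest_trace(t0=1.0, t1=1.0)  # no arrest
        v, valid = smoothed_velocity(tr, 4e-4)
        assert valid.all()
        mid = slice(2000, -2000)
        np.testing.assert_allclose(v[mid], 66667.0, rtol=3e-3)

    def test_step_stop_crosses_half_velocity_at_t0(self):
        tr = _arrest_trace()
        v, _ = smoothed_velocity(tr, 4e-4)
        # symmetric kernel: the v/2 crossing sits at the stop time
        below = np.flatnonzero(v < 0.5 * 66667.0)
        t_cross = below[below > 1000][0] * tr.dt
        assert t_cross == pytest.approx(0.02, abs=2e-5)

    def test_analytic_delay_at_other_thresholds(self):
        tr = _arrest_trace()
        v, _ = smoothed_velocity(tr, 4e-4)
        theta = 0.25
        below = np.flatnonzero(v < theta * 66667.0)
        t_cross = below[below > 1000][0] * tr.dt
        assert t_cross - 0.02 == pytest.approx(_delay_shift(4e-4, theta), abs=2e-5)

    def test_too_small_sigma_rejected(self):
        tr = _arrest_trace()
        with pytest.raises(ValidationError):
            smoothed_velocity(tr, 1e-6)

    def test_zero_mean_noise_velocity(self):
        rng = np.random.default_rng(3)
        n = 100_000
        x = rng.normal(0, 1.0, n)
        tr = Trace(
            dt=4e-6,
            trap_pos_lead=x,
            trap_pos_trail=x,
            force_lead=np.zeros(n),
            force_trail=np.zeros(n),
            pause_flag=np.zeros(n, dtype=bool),
        )
        v, _ = smoothed_velocity(tr, 4e-4)
        assert abs(v.mean()) < 3 * v.std() / np.sqrt(n / 200)


class TestThresholdSelection:
    def test_noise_free_tie_break_is_half(self, quiet_instrument, quiet_mechanics):
        tr, _ = simulate_trace(
            single_exit_scheme(), quiet_instrument, quiet_mechanics, 2.0, 0.0, rng_seed=1
        )
        theta = select_threshold(tr, DetectionConfig(), expected_event_count=50, force=3.0)
        assert theta == pytest.approx(0.5)

    def test_more_noise_never_raises_threshold(self, default_mechanics):
        thetas = []
        for ou in (2.0, 8.0):
            inst = InstrumentConfig(applied_force=3.0, ou_noise_sd=ou)
            tr, _ = simulate_trace(
                single_exit_scheme(), inst, default_mechanics, 10.0, 0.0, rng_seed=4
            )
            try:
                thetas.append(
                    select_threshold(tr, DetectionConfig(), expected_event_count=20, force=3.0)
                )
            except DetectionError:
                thetas.append(0.0)  # advice to smooth more counts as a decrease
        assert thetas[1] <= thetas[0]

    def test_missing_threshold_is_error(self):
        tr = _arrest_trace()
        with pytest.raises(DetectionError, match="threshold"):
            detect_events(tr, DetectionConfig(), force=3.0)


class TestDetectEvents:
    def test_noise_free_single_arrest_recovered(self):
        tr = _arrest_trace()
        cfg = dataclasses.replace(DetectionConfig(), threshold_fraction=0.5)
        events = detect_events(tr, cfg, force=3.0)
        assert len(events) == 1
        assert events.start_s.iloc[0] == pytest.approx(0.02, abs=4e-4)
        assert events.end_s.iloc[0] == pytest.approx(0.04, abs=4e-4)
        assert events.direction.iloc[0] == "assisting"  # moving along the stroke

    def test_translation_invariance(self):
        cfg = dataclasses.replace(DetectionConfig(), threshold_fraction=0.5)
        a = detect_events(_arrest_trace(t0=0.02, t1=0.04), cfg, force=3.0)
        b = detect_events(_arrest_trace(t0=0.025, t1=0.045), cfg, force=3.0)
        assert b.start_s.iloc[0] - a.start_s.iloc[0] == pytest.approx(0.005, abs=1e-5)
        assert b.end_s.iloc[0] - a.end_s.iloc[0] == pytest.approx(0.005, abs=1e-5)

    def test_sub_deadtime_event_excluded(self):
        # a 1 ms arrest at 1.5 pN falls below the 2.7 ms deadtime
        tr = _arrest_trace(v=33333.0, t0=0.02, t1=0.021)
        cfg = dataclasses.replace(DetectionConfig(), threshold_fraction=0.5)
        assert len(detect_events(tr, cfg, force=1.5)) == 0
        assert len(detect_events(tr, cfg, force=4.5)) == 1

    def test_boundary_spans_discarded(self):
        tr = _arrest_trace(t0=0.0, t1=0.02)  # arrest abuts the trace start
        cfg = dataclasses.replace(DetectionConfig(), threshold_fraction=0.5)
        assert len(detect_events(tr, cfg, force=3.0)) == 0

    def test_no_false_events_on_quiet_binding_free_trace(self, default_mechanics):
        inst = InstrumentConfig(applied_force=3.0)
        tr, _ = simulate_trace(
            single_exit_scheme(), inst, default_mechanics, 10.0, 0.0, rng_seed=6
        )
        assert count_false_events(tr, DetectionConfig(), 0.5, force=3.0) == 0


class TestDeadtimeCalibration:
    def test_deadtimes_near_published_and_monotone(self):
        cfg = dataclasses.replace(DetectionConfig(), threshold_fraction=0.5)
        out = {}
        for force in (1.5, 4.5):
            inst = InstrumentConfig(applied_force=force)
            dead, sig = calibrate_deadtime_sigma(
                inst, force, cfg, rng_seed=42, n_trials=60, n_grid=10
            )
            out[force] = (dead, sig)
        # calibrated against the published per-force deadtimes
        assert 0.35 * 2.7e-3 < out[1.5][0] < 1.6 * 2.7e-3
        assert 0.35 * 0.5e-3 < out[4.5][0] < 1.6 * 0.5e-3
        assert out[4.5][0] < out[1.5][0]
        assert out[4.5][1] < out[1.5][1]  # binding-time uncertainty shrinks with force

    def test_noise_free_floor_is_kernel_limited(self, quiet_instrument):
        cfg = dataclasses.replace(DetectionConfig(), threshold_fraction=0.5)
        dead, _ = calibrate_deadtime_sigma(
            quiet_instrument, 3.0, cfg, rng_seed=1, n_trials=30, n_grid=12
        )
        sigma_s = cfg.sigma_for(3.0)
        assert dead <= 2.5 * sigma_s


def test_deadtime_table_monotone_nonincreasing():
    forces = sorted(DEADTIME_TABLE)
    vals = [DEADTIME_TABLE[f] for f in forces]
    assert all(b <= a for a, b in zip(vals, vals[1:]))
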