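"""Synthetic ultrafast-force-clamp trace generator.

Turns kinetic state paths into realistic dual-trap force-clamp recordings:
triangle-wave filament motion at the clamped force (reversing each time the
trap traverses the set excursion), Poisson attachment while unbound,
exponential arrest and series-elastic stretch on binding, per-state lever-arm
displacements with per-interaction Gaussian jitter, measurement noise, and an
optional drift/feedback-pause stage, plus a ground-truth event channel.

Brownian dynamics are not integrated.  Position noise is white Gaussian plus
an optional low-pass (Ornstein-Uhlenbeck) component that emulates the slow
Brownian wander of the dumbbell under feedback; the downstream analysis
operates on smoothed velocities, for which these two scales are what matter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .io import GroundTruthEvent, InstrumentConfig, Trace, ValidationError
from .kinetics import KineticScheme, simulate_state_path

#: Sampling interval, s (250 kHz acquisition).
DEFAULT_DT = 4e-6

#: Fixed lead/trail trap separation used in synthetic traces, nm.
_TRAIL_OFFSET = 500.0


@dataclass
class MechanicsConfig:
    """Mechanical coupling of myosin to the clamped dumbbell.

    link_stiffness: series stiffness of the myosin, pN/nm (stretch on binding
    is ``applied_force / link_stiffness``).  position_jitter_sd: per-interaction
    Gaussian jitter of each state's position value, nm.  arrest_timescale:
    exponential time constant of motion arrest at binding, s.
    """

    link_stiffness: float = 2.0
    position_jitter_sd: float = 0.1
    arrest_timescale: float = 5e-5

    def __post_init__(self) -> None:
        if self.link_stiffness <= 0 or self.arrest_timescale <= 0:
            raise ValidationError("mechanics parameters must be positive")
        if self.position_jitter_sd < 0:
            raise ValidationError("position_jitter_sd must be >= 0")


@dataclass
class DriftModel:
    """Slow instrumental force drift, position-dependent force error, and
    periodic feedback pauses.

    slope_pN_per_s: drift rate of the zero-force baseline (0.25-2 pN/hour is
    the emulated instrumental range).  eod_slope_pN_per_nm: position-
    proportional force error of the deflector.  offset_pN: constant baseline
    offset.  Pauses freeze the trap for ``pause_duration_s`` at each excursion
    endpoint (top and bottom alternating, twice per ~``pause_period_s`` at the
    default 3 pN kinematics).
    """

    slope_pN_per_s: float = 1.0 / 3600.0
    eod_slope_pN_per_nm: float = 0.002
    offset_pN: float = 0.0
    pause_period_s: float = 0.010
    pause_duration_s: float = 0.002

    def __post_init__(self) -> None:
        if not self.pause_duration_s < self.pause_period_s:
            raise ValidationError("pause_duration_s must be < pause_period_s")


def _triangle(x0: float, dir0: int, v: float, half: float, tau: np.ndarray):
    """Closed-form triangle wave: position/direction at times ``tau`` for a
    trap at ``x0`` moving in ``dir0`` at speed ``v`` between ``+-half``."""
    u0 = dir0 * x0
    w = (u0 + half + v * tau) % (4.0 * half)
    ascending = w <= 2.0 * half
    u = np.where(ascending, w - half, 3.0 * half - w)
    d = np.where(ascending, dir0, -dir0)
    return dir0 * u, d.astype(np.int8)


def _ou_noise(n: int, sd: float, tau_s: float, dt: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0 or n == 0:
        return np.zeros(n)
    a = np.exp(-dt / tau_s)
    w = rng.standard_normal(n) * (sd * np.sqrt(1.0 - a * a))
    w[0] = rng.standard_normal() * sd  # stationary start
    return lfilter([1.0], [1.0, -a], w)


def _path_levels(path, scheme: KineticScheme, jitter_sd: float, rng: np.random.Generator):
    """Per-state displacement levels (nm) contributed by the lever arm,
    including the per-interaction jitter draw for each occupied state.
    Positions are absolute contributions relative to the unbound baseline,
    so binding into a displaced state paints that displacement."""
    pos = np.array([scheme.state(s).position_nm for s in path.states])
    jit = rng.normal(0.0, jitter_sd, len(pos)) if jitter_sd > 0 else np.zeros(len(pos))
    return pos + jit


def simulate_trace(
    scheme: KineticScheme,
    instrument: InstrumentConfig,
    mechanics: MechanicsConfig,
    duration_s: float,
    attachment_rate: float,
    rng_seed,
    molecule_id: str = "mol0",
    trace_id: str = "trace0",
    dt: float = DEFAULT_DT,
    polarity: int = 1,
) -> tuple[Trace, list[GroundTruthEvent]]:
    """Simulate one force-clamp trace plus its ground-truth event list.

    While unbound the trap moves at ``applied_force / drag_coefficient``,
    reversing at each excursion endpoint; attachments start as a Poisson
    process at ``attachment_rate``.  On binding the position relaxes
    exponentially (``arrest_timescale``) to the series-elastic stretch
    ``applied_force / link_stiffness`` continued in the direction of motion,
    and each occupied state adds its (jittered) position value along the
    stroke direction.  Events beginning under motion opposite the stroke
    polarity are hindering-loaded.  Bit-reproducible for a fixed seed.
    """
    if duration_s < 0.1:
        raise ValidationError("duration_s must be >= 0.1 s")
    if attachment_rate < 0:
        raise ValidationError("attachment_rate must be >= 0")
    rng = np.random.default_rng(rng_seed)
    n = int(round(duration_s / dt))
    half = instrument.excursion / 2.0
    v = instrument.unbound_speed
    stretch = instrument.applied_force / mechanics.link_stiffness

    x = np.empty(n)
    fdir = np.empty(n, dtype=np.int8)
    truth: list[GroundTruthEvent] = []

    idx = 0
    x0, dir0 = 0.0, 1
    while idx < n:
        wait = rng.exponential(1.0 / attachment_rate) if attachment_rate > 0 else np.inf
        n_seg = n - idx if not np.isfinite(wait) else min(n - idx, max(1, int(np.ceil(wait / dt))))
        tau = np.arange(n_seg) * dt
        seg_x, seg_d = _triangle(x0, dir0, v, half, tau)
        x[idx : idx + n_seg] = seg_x
        fdir[idx : idx + n_seg] = seg_d
        # state at the first sample after the segment
        nx, nd = _triangle(x0, dir0, v, half, np.array([n_seg * dt]))
        x0, dir0 = float(nx[0]), int(nd[0])
        idx += n_seg
        if idx >= n:
            break

        # binding at sample `idx`
        d_bind = dir0
        hindering = d_bind != polarity
        f_signed = instrument.applied_force if hindering else -instrument.applied_force
        path = simulate_state_path(scheme, f_signed, rng)
        levels = _path_levels(path, scheme, mechanics.position_jitter_sd, rng)
        T = path.duration_s
        n_ev = min(n - idx, max(1, int(np.ceil(T / dt))))
        tau = np.arange(n_ev) * dt
        entry = np.asarray(path.entry_times[1:])  # times of leaving each state
        state_i = np.searchsorted(entry, tau, side="right")
        ev_x = (
            x0
            + d_bind * stretch * (1.0 - np.exp(-tau / mechanics.arrest_timescale))
            + polarity * levels[state_i]
        )
        x[idx : idx + n_ev] = ev_x
        fdir[idx : idx + n_ev] = d_bind

        t_b = idx * dt
        stroke_t = path.stroke_time()
        truth.append(
            GroundTruthEvent(
                start_s=t_b,
                end_s=t_b + T,
                state_path=[(s, t_b + t) for s, t in zip(path.states, path.entry_times)],
                stroke_time_s=None if stroke_t is None else t_b + stroke_t,
                detached_prestroke=stroke_t is None,
                direction="hindering" if hindering else "assisting",
                force_pN=f_signed,
                truncated=idx + n_ev >= n or (t_b + T) > duration_s,
            )
        )
        x0 = float(np.clip(ev_x[-1], -half + 1e-9, half - 1e-9))
        idx += n_ev

    if instrument.noise_sd > 0:
        x = x + rng.normal(0.0, instrument.noise_sd, n)
    if instrument.ou_noise_sd > 0:
        x = x + _ou_noise(n, instrument.ou_noise_sd, instrument.ou_tau_s, dt, rng)

    force_lead = fdir * instrument.applied_force
    if instrument.force_noise_sd > 0:
        force_lead = force_lead + rng.normal(0.0, instrument.force_noise_sd, n)
        force_trail = instrument.pretension + rng.normal(0.0, instrument.force_noise_sd, n)
    else:
        force_lead = force_lead.astype(float)
        force_trail = np.full(n, instrument.pretension)

    trace = Trace(
        dt=dt,
        trap_pos_lead=x,
        trap_pos_trail=x - _TRAIL_OFFSET,
        force_lead=force_lead,
        force_trail=force_trail,
        pause_flag=np.zeros(n, dtype=bool),
        meta=instrument,
        molecule_id=molecule_id,
        trace_id=trace_id,
        polarity=polarity,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# Drift and feedback pauses
# ---------------------------------------------------------------------------


def _endpoint_triggers(x: np.ndarray, half: float, margin: float = 8.0) -> np.ndarray:
    """Sample indices where the trap first reaches the top/bottom of the
    excursion (alternating), which is when the feedback pauses."""
    top = x > half - margin
    bot = x < -half + margin
    top_edges = np.flatnonzero(top & ~np.roll(top, 1))
    bot_edges = np.flatnonzero(bot & ~np.roll(bot, 1))
    top_edges = top_edges[top_edges > 0]
    bot_edges = bot_edges[bot_edges > 0]
    merged = sorted(
        [(i, 1) for i in top_edges] + [(i, -1) for i in bot_edges]
    )
    out = []
    last_side = 0
    for i, side in merged:
        if side != last_side:
            out.append(i)
            last_side = side
    return np.asarray(out, dtype=np.int64)


def apply_drift_and_pauses(
    trace: Trace,
    drift: DriftModel,
    rng_seed,
    truth: Sequence[GroundTruthEvent] | None = None,
    insert_pauses: bool = True,
):
    """Add instrumental drift, deflector-slope force error, and feedback pauses.

    The recorded force gains a baseline ``offset + slope*t + eod_slope*(x -
    x_bottom)``.  When ``insert_pauses`` is set, a 2 ms pause (trap frozen,
    applied force off) is inserted each time the trap reaches the top or the
    bottom of the excursion; subsequent samples shift later in time and the
    trace is re-truncated to its original length.  If ``truth`` is given the
    ground-truth event times are shifted accordingly and the shifted list is
    returned alongside the trace.
    """
    if trace.pause_flag.any():
        raise ValidationError("trace already contains pause blocks")
    rng = np.random.default_rng(rng_seed)
    n = trace.n_samples
    dt = trace.dt
    half = trace.meta.excursion / 2.0
    x = trace.trap_pos_lead
    f_lead = trace.force_lead
    f_trail = trace.force_trail
    pause = np.zeros(n, dtype=bool)

    if insert_pauses:
        triggers = _endpoint_triggers(x, half)
        n_pause = int(round(drift.pause_duration_s / dt))
        segs_x, segs_f, segs_ft, segs_p = [], [], [], []
        prev = 0
        for r in triggers:
            segs_x.append(x[prev : r + 1])
            segs_f.append(f_lead[prev : r + 1])
            segs_ft.append(f_trail[prev : r + 1])
            segs_p.append(np.zeros(r + 1 - prev, dtype=bool))
            # frozen trap; applied force off during the pause
            segs_x.append(np.full(n_pause, x[r]))
            segs_f.append(rng.normal(0.0, trace.meta.force_noise_sd, n_pause))
            segs_ft.append(
                trace.meta.pretension + rng.normal(0.0, trace.meta.force_noise_sd, n_pause)
            )
            segs_p.append(np.ones(n_pause, dtype=bool))
            prev = r + 1
        segs_x.append(x[prev:])
        segs_f.append(f_lead[prev:])
        segs_ft.append(f_trail[prev:])
        segs_p.append(np.zeros(n - prev, dtype=bool))
        x = np.concatenate(segs_x)[:n]
        f_lead = np.concatenate(segs_f)[:n]
        f_trail = np.concatenate(segs_ft)[:n]
        pause = np.concatenate(segs_p)[:n]
        if truth is not None:
            trig_t = triggers * dt
            shifted = []
            for ev in truth:
                shift = drift.pause_duration_s * np.searchsorted(trig_t, ev.start_s)
                if ev.start_s + shift >= n * dt:
                    continue
                shifted.append(
                    GroundTruthEvent(
                        start_s=ev.start_s + shift,
                        end_s=ev.end_s + shift,
                        state_path=[(s, t + shift) for s, t in ev.state_path],
                        stroke_time_s=None if ev.stroke_time_s is None else ev.stroke_time_s + shift,
                        detached_prestroke=ev.detached_prestroke,
                        direction=ev.direction,
                        force_pN=ev.force_pN,
                        truncated=ev.truncated or ev.end_s + shift > n * dt,
                    )
                )
            truth = shifted

    t = np.arange(n) * dt
    baseline = drift.offset_pN + drift.slope_pN_per_s * t + drift.eod_slope_pN_per_nm * (x + half)
    out = Trace(
        dt=dt,
        trap_pos_lead=x,
        trap_pos_trail=x - _TRAIL_OFFSET,
        force_lead=f_lead + baseline,
        force_trail=f_trail,
        pause_flag=pause,
        meta=trace.meta,
        molecule_id=trace.molecule_id,
        trace_id=trace.trace_id,
        polarity=trace.polarity,
    )
    return (out, list(truth)) if truth is not None else out
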