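"""Detection of actomyosin attachments as arrests of trap motion.

The leading-bead trap position is the filament-position proxy.  Its velocity
is Gaussian-smoothed (160-800 us SD depending on force), and maximal spans
where the absolute smoothed velocity stays below a threshold (a fraction of
the mean unbound speed) are events.  Start/end times are corrected for the
analytic crossing delay of a Gaussian-smoothed ideal step at the chosen
threshold/velocity ratio; events shorter than the per-force deadtime are
discarded; feedback-pause samples are masked and never traversed by events.
The velocity threshold is chosen empirically so that the estimated
false-event fraction on binding-free traces is below a target (1% of the
event count of a matched binding trace).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import oaconvolve
from scipy.special import ndtri

from .io import InstrumentConfig, Trace, ValidationError, events_dataframe

#: Per-force analysis deadtimes, s (constant across biochemical conditions).
DEADTIME_TABLE = {1.5: 2.7e-3, 2.25: 1.25e-3, 3.0: 0.73e-3, 3.75: 0.65e-3, 4.5: 0.5e-3}

#: Per-force binding-time uncertainty sigma_t, s: the start-time RMS error of
#: detection on simulated ground-truth events under the default instrument
#: model (calibrated once; ~500 us at 1.5 pN falling monotonically to
#: ~100 us at 4.5 pN, with a small margin for estimation uncertainty).
SIGMA_T_TABLE = {1.5: 5.5e-4, 2.25: 3.6e-4, 3.0: 2.9e-4, 3.75: 1.7e-4, 4.5: 1.1e-4}

#: Per-force Gaussian smoothing SD, s (more smoothing at lower force, where
#: the unbound motion is slower).
SIGMA_S_TABLE = {1.5: 8.0e-4, 2.25: 5.6e-4, 3.0: 4.0e-4, 3.75: 2.4e-4, 4.5: 1.6e-4}

_SIGMA_MIN, _SIGMA_MAX = 160e-6, 800e-6


class DetectionError(RuntimeError):
    pass


def _nearest(table: dict[float, float], force: float) -> float:
    key = min(table, key=lambda f: abs(f - abs(force)))
    return table[key]


@dataclass
class DetectionConfig:
    """Event-detection parameters.

    ``gaussian_sigma_s``: smoothing SD (s); if None the per-force default is
    used.  ``threshold_fraction``: velocity threshold as a fraction of the
    mean unbound speed (set by :func:`select_threshold`); 0.5 is the
    noise-free tie-break.  ``deadtime_s``/``sigma_t_s``: per-force overrides;
    None selects from the default tables.
    """

    gaussian_sigma_s: float | None = None
    threshold_fraction: float | None = None
    threshold_nm_per_s: float | None = None
    target_false_fraction: float = 0.01
    deadtime_s: float | None = None
    sigma_t_s: float | None = None
    filter_delay_correction: bool = True
    deadtime_table: dict = field(default_factory=lambda: dict(DEADTIME_TABLE))
    sigma_t_table: dict = field(default_factory=lambda: dict(SIGMA_T_TABLE))
    sigma_s_table: dict = field(default_factory=lambda: dict(SIGMA_S_TABLE))

    def sigma_for(self, force: float) -> float:
        s = self.gaussian_sigma_s if self.gaussian_sigma_s is not None else _nearest(self.sigma_s_table, force)
        if not (_SIGMA_MIN <= s <= _SIGMA_MAX):
            raise ValidationError(f"gaussian_sigma_s {s} outside [{_SIGMA_MIN}, {_SIGMA_MAX}] s")
        return s

    def deadtime_for(self, force: float) -> float:
        return self.deadtime_s if self.deadtime_s is not None else _nearest(self.deadtime_table, force)

    def sigma_t_for(self, force: float) -> float:
        return self.sigma_t_s if self.sigma_t_s is not None else _nearest(self.sigma_t_table, force)


def smoothed_velocity(trace: Trace, sigma_s: float):
    """Gaussian-smoothed velocity of the leading trap, nm/s.

    Pause spans are interpolated across before differentiation and flagged
    invalid.  Returns ``(velocity, valid_mask)``, both the length of the
    trace.  Because the trap is frozen while the feedback pauses, pause spans
    read as arrest-like (near-zero velocity); downstream detection treats
    them as barriers that no event may contain.
    """
    if sigma_s < 2 * trace.dt:
        raise ValidationError("sigma_s must be at least 2*dt")
    x = trace.trap_pos_lead
    valid = ~trace.pause_flag
    if not valid.all():
        idx = np.arange(len(x))
        x = x.copy()
        x[~valid] = np.interp(idx[~valid], idx[valid], x[valid])
    # smoothed derivative in one pass: convolve position with the Gaussian
    # derivative kernel (overlap-add; edges padded by replication)
    dt = trace.dt
    half_w = int(np.ceil(4 * sigma_s / dt))
    tt = np.arange(-half_w, half_w + 1) * dt
    g = np.exp(-0.5 * (tt / sigma_s) ** 2)
    g /= g.sum() * dt
    kernel = -(tt / sigma_s**2) * g * dt  # g'(t) sampled; convolution flips it
    xp = np.r_[np.full(half_w, x[0]), x, np.full(half_w, x[-1])]
    v = oaconvolve(xp, kernel, mode="valid")
    return v, valid


def unbound_speed_estimate(v: np.ndarray, valid: np.ndarray) -> float:
    """Robust estimate of the mean unbound speed from a velocity trace.

    The median of |v| over valid samples; robust to a modest duty cycle of
    arrested (bound) samples.
    """
    speed = float(np.median(np.abs(v[valid])))
    if speed <= 0:
        raise DetectionError("cannot estimate unbound speed (zero median velocity)")
    return speed


def _runs(mask: np.ndarray):
    """Start/end (half-open) indices of maximal True runs."""
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, len(mask)]
    return starts, ends


def _delay_shift(sigma_s: float, theta: float) -> float:
    """Crossing delay of a Gaussian-smoothed ideal stop at threshold fraction
    ``theta``: the smoothed velocity crosses theta*v a time
    ``sigma * Phi^-1(1-theta)`` after the true stop (and symmetrically before
    the true restart)."""
    theta = min(max(theta, 1e-6), 1 - 1e-6)
    return sigma_s * float(ndtri(1.0 - theta))


def _candidate_events(v, valid, threshold, dt, sigma_s, theta, correct_delay):
    """Raw sub-threshold spans (s), delay-corrected.

    A pause span is itself arrest-like, so candidate spans are sub-threshold
    runs of |v|; any run containing a masked (pause) sample is discarded --
    true attachments never contain pauses, because the trap only reaches the
    excursion endpoints (the pause triggers) while unbound.  Runs touching
    the trace boundaries (unknown start or end) are discarded too.
    """
    below = np.abs(v) < threshold
    if not below.any():
        return []
    starts, ends = _runs(below)
    shift = _delay_shift(sigma_s, theta) if correct_delay else 0.0
    out = []
    n = len(v)
    has_pause = ~valid
    cum_pause = np.r_[0, np.cumsum(has_pause)]
    for a, b in zip(starts, ends):
        if a == 0 or b == n:
            continue  # unknown start or end
        if cum_pause[b] - cum_pause[a] > 0:
            continue  # span contains a feedback pause
        t0 = a * dt - shift
        t1 = b * dt + shift
        if t1 > t0:
            out.append((t0, t1))
    return out


def _trim_approach_start(
    x: np.ndarray,
    i0: int,
    i1: int,
    dt: float,
    polarity: int,
    window_s: float | None = None,
    sigma_s: float = 4e-4,
    block_s: float = 48e-6,
    gap_nm: float = 6.0,
    settle_nm: float = 3.0,
) -> int | None:
    """Advance a hindering-event start that still lies on the approach.

    A binding that occurs shortly after a trap direction switch merges with
    the switch's velocity dip, so the crossing-based start can precede the
    true arrest by up to the switch dip width.  For a hindering event the
    filament approaches from above (in stroke coordinates) and stops at its
    trajectory minimum, so if the position at the nominal start sits well
    above the early block-mean minimum, the start is moved to that minimum's
    block.  Returns the new index, or None to keep the original.
    """
    if window_s is None:
        window_s = 0.8e-3 + 3.0 * sigma_s  # wider reach under heavier smoothing
    n_b = max(1, int(round(block_s / dt)))
    b = min(len(x), i1, i0 + int(round(window_s / dt)))
    w = (x[i0:b] * polarity).astype(float)
    m = (len(w) // n_b) * n_b
    if m < 2 * n_b:
        return None
    blocks = w[:m].reshape(-1, n_b).mean(axis=1)
    lvl = blocks.min()
    if blocks[0] - lvl <= gap_nm:
        return None
    j = int(np.argmax(blocks <= lvl + settle_nm))  # first block near the arrest level
    return i0 + j * n_b


def _trim_departure_end(
    x: np.ndarray,
    i0: int,
    i1: int,
    dt: float,
    polarity: int,
    window_s: float | None = None,
    sigma_s: float = 4e-4,
    block_s: float = 48e-6,
    gap_nm: float = 6.0,
    settle_nm: float = 3.0,
) -> int | None:
    """Pull back a hindering-event end that already lies on the departure.

    Mirror of :func:`_trim_approach_start`: after release under hindering
    load the filament departs downward (in stroke coordinates) from the
    attached plateau, so if the position at the nominal end sits well below
    the late block-mean maximum, the end is moved back to the last block
    near that plateau level.
    """
    if window_s is None:
        window_s = 0.8e-3 + 3.0 * sigma_s
    n_b = max(1, int(round(block_s / dt)))
    a = max(i0, i1 - int(round(window_s / dt)))
    w = (x[a:i1] * polarity).astype(float)
    m = (len(w) // n_b) * n_b
    if m < 2 * n_b:
        return None
    blocks = w[len(w) - m :].reshape(-1, n_b).mean(axis=1)
    lvl = blocks.max()
    if lvl - blocks[-1] <= gap_nm:
        return None
    near = np.flatnonzero(blocks >= lvl - settle_nm)
    j = int(near[-1])  # last block still at the attached plateau
    return (i1 - m) + (j + 1) * n_b


def detect_events(
    trace: Trace,
    config: DetectionConfig,
    polarity: int | None = None,
    force: float | None = None,
) -> pd.DataFrame:
    """Detect binding events on a trace; returns a validated event table.

    Direction is assigned from the clamp's recorded force sign during the
    event and the actin polarity; events shorter than the per-force deadtime
    are excluded; start/end times carry the analytic filter-delay correction.
    """
    force = trace.meta.applied_force if force is None else force
    polarity = trace.polarity if polarity is None else polarity
    sigma_s = config.sigma_for(force)
    v, valid = smoothed_velocity(trace, sigma_s)
    v_unb = unbound_speed_estimate(v, valid)
    if config.threshold_nm_per_s is not None:
        threshold = config.threshold_nm_per_s
    elif config.threshold_fraction is not None:
        threshold = config.threshold_fraction * v_unb
    else:
        raise DetectionError("no velocity threshold set; run select_threshold first")
    theta = threshold / v_unb
    deadtime = config.deadtime_for(force)
    sigma_t = config.sigma_t_for(force)
    dt = trace.dt
    spans = _candidate_events(v, valid, threshold, dt, sigma_s, theta, config.filter_delay_correction)

    records = []
    f = trace.force_lead
    x = trace.trap_pos_lead
    for t0, t1 in spans:
        if t1 - t0 < deadtime:
            continue
        i0 = int(round(t0 / dt))
        i1 = int(round(t1 / dt))
        # the clamp's recorded force sign during the event gives the motion
        # direction at binding (the force is held through the attachment)
        med_f = float(np.median(f[max(i0, 0) : max(i1, i0 + 1)]))
        d_pre = 1 if med_f >= 0 else -1
        direction = "hindering" if d_pre != polarity else "assisting"
        if direction == "hindering":
            adv = _trim_approach_start(x, i0, i1, dt, polarity, sigma_s=sigma_s)
            if adv is not None:
                i0, t0 = adv, adv * dt
            # the end trim corrects departure merges on long plateaus; on
            # near-deadtime spans it mostly responds to noise and shortens
            # durations, so it is skipped there
            if t1 - t0 >= 3e-3:
                ret = _trim_departure_end(x, i0, i1, dt, polarity, sigma_s=sigma_s)
                if ret is not None:
                    i1, t1 = ret, ret * dt
            if t1 - t0 < deadtime:
                continue
        records.append(
            {
                "start_s": t0,
                "end_s": t1,
                "duration_s": t1 - t0,
                "force_pN": abs(force) if direction == "hindering" else -abs(force),
                "direction": direction,
                "molecule_id": trace.molecule_id,
                "trace_id": trace.trace_id,
                "sigma_t_s": sigma_t,
            }
        )
    return events_dataframe(records)


def count_false_events(
    trace_free: Trace,
    config: DetectionConfig,
    theta: float,
    sigma_s: float | None = None,
    force: float | None = None,
) -> int:
    """Number of sub-threshold spans of at least the deadtime on a
    binding-free trace at threshold fraction ``theta``."""
    force = trace_free.meta.applied_force if force is None else force
    sigma_s = config.sigma_for(force) if sigma_s is None else sigma_s
    v, valid = smoothed_velocity(trace_free, sigma_s)
    v_unb = unbound_speed_estimate(v, valid)
    deadtime = config.deadtime_for(force)
    spans = _candidate_events(
        v, valid, theta * v_unb, trace_free.dt, sigma_s, theta, config.filter_delay_correction
    )
    return sum(1 for t0, t1 in spans if t1 - t0 >= deadtime)


_THETA_GRID = np.round(np.arange(0.50, 0.049, -0.025), 3)


def select_threshold(
    trace_free: Trace,
    config: DetectionConfig,
    expected_event_count: float,
    force: float | None = None,
    sigma_s: float | None = None,
) -> float:
    """Choose the velocity threshold (fraction of mean unbound speed).

    Returns the largest threshold fraction (<= 0.5, the noise-free tie-break)
    for which the number of false events on the binding-free trace is at most
    ``target_false_fraction`` of ``expected_event_count``.  Raises advising a
    larger smoothing width if no grid value qualifies.
    """
    if expected_event_count <= 0:
        raise ValidationError("expected_event_count must be > 0")
    budget = config.target_false_fraction * expected_event_count
    for theta in _THETA_GRID:
        if count_false_events(trace_free, config, float(theta), sigma_s, force) <= budget:
            return float(theta)
    raise DetectionError(
        "false-event target unattainable at any threshold; use a larger gaussian_sigma_s"
    )


def select_detection_params(
    trace_free: Trace,
    config: DetectionConfig,
    expected_event_count: float,
    force: float | None = None,
    theta_floor: float = 0.15,
) -> DetectionConfig:
    """Auto-select smoothing (160-800 us) and threshold on a binding-free trace.

    Picks the smallest smoothing SD that admits a threshold fraction of at
    least ``theta_floor`` while keeping the estimated false-event fraction at
    or below the target, then the largest such threshold; smaller smoothing
    shortens the attainable deadtime, so less is better when the noise allows.
    Returns a copy of ``config`` with both parameters set.
    """
    force = trace_free.meta.applied_force if force is None else force
    grid = [160e-6, 240e-6, 320e-6, 480e-6, 640e-6, 800e-6]
    for sigma in grid:
        try:
            theta = select_threshold(trace_free, config, expected_event_count, force, sigma)
        except DetectionError:
            continue
        if theta >= theta_floor:
            return replace(config, gaussian_sigma_s=sigma, threshold_fraction=theta)
    raise DetectionError("no smoothing width in [160, 800] us meets the false-event target")


# ---------------------------------------------------------------------------
# Deadtime / sigma_t calibration by injected arrests
# ---------------------------------------------------------------------------


def _arrest_injection_trace(
    instrument: InstrumentConfig,
    force: float,
    arrest_s: float,
    n_arrests: int,
    rng: np.random.Generator,
    spacing_s: float = 0.05,
    dt: float = 4e-6,
):
    """Myosin-free trace with ``n_arrests`` rigid arrests of fixed duration
    injected mid-leg; returns (trace, true start times)."""
    from .simulate import _ou_noise, _triangle  # local to avoid cycle

    inst = replace(instrument, applied_force=abs(force))
    half = inst.excursion / 2.0
    v = inst.unbound_speed
    n = int(round((n_arrests * spacing_s + spacing_s) / dt))
    x = np.empty(n)
    idx = 0
    x0, dir0 = 0.0, 1
    starts = []
    n_arr = max(1, int(round(arrest_s / dt)))
    n_gap = int(round(spacing_s / dt)) - n_arr
    while idx < n:
        n_seg = min(n - idx, n_gap)
        tau = np.arange(n_seg) * dt
        seg_x, _ = _triangle(x0, dir0, v, half, tau)
        x[idx : idx + n_seg] = seg_x
        nx, nd = _triangle(x0, dir0, v, half, np.array([n_seg * dt]))
        x0, dir0 = float(nx[0]), int(nd[0])
        idx += n_seg
        if idx >= n:
            break
        m = min(n - idx, n_arr)
        x[idx : idx + m] = x0
        starts.append(idx * dt)
        idx += m
    if inst.noise_sd > 0:
        x = x + rng.normal(0.0, inst.noise_sd, n)
    if inst.ou_noise_sd > 0:
        x = x + _ou_noise(n, inst.ou_noise_sd, inst.ou_tau_s, dt, rng)
    trace = Trace(
        dt=dt,
        trap_pos_lead=x,
        trap_pos_trail=x - 500.0,
        force_lead=np.full(n, abs(force)),
        force_trail=np.full(n, inst.pretension),
        pause_flag=np.zeros(n, dtype=bool),
        meta=inst,
    )
    return trace, np.array(starts[: n_arrests])


def calibrate_deadtime_sigma(
    instrument: InstrumentConfig,
    force: float,
    config: DetectionConfig,
    rng_seed,
    n_trials: int = 200,
    detect_fraction: float = 0.95,
    bracket=(1e-4, 1e-2),
    n_grid: int = 13,
):
    """Empirical deadtime and binding-time uncertainty at one force.

    The deadtime is the shortest injected arrest duration detected in at least
    ``detect_fraction`` of ``n_trials`` trials (geometric grid over
    ``bracket``); sigma_t is the SD of (detected - true) start times for
    well-detected arrests (2x the deadtime).  Raises if detection never
    reaches the target fraction within the bracket.
    """
    rng = np.random.default_rng(rng_seed)
    sigma_s = config.sigma_for(force)
    cfg = replace(config, deadtime_s=2 * instrument.response_time)

    def fraction_detected(arrest_s):
        trace, starts = _arrest_injection_trace(instrument, force, arrest_s, n_trials, rng)
        if cfg.threshold_fraction is None and cfg.threshold_nm_per_s is None:
            raise DetectionError("config needs a threshold; run select_threshold first")
        events = detect_events(trace, cfg, force=force)
        hits = 0
        errs = []
        for s in starts:
            m = events[(events.end_s > s) & (events.start_s < s + arrest_s)]
            if len(m):
                hits += 1
                errs.append(m.start_s.iloc[0] - s)
        return hits / len(starts), np.asarray(errs)

    grid = np.geomspace(bracket[0], bracket[1], n_grid)
    deadtime = None
    for arrest_s in grid:
        frac, _ = fraction_detected(arrest_s)
        if frac >= detect_fraction:
            deadtime = float(arrest_s)
            break
    if deadtime is None:
        raise DetectionError(f"no arrest duration in {bracket} reaches {detect_fraction:.0%} detection")
    _, errs = fraction_detected(min(2 * deadtime, bracket[1]))
    sigma_t = float(np.std(errs)) if len(errs) > 1 else float("nan")
    return deadtime, sigma_t
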