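"""Offline drift-and-slope correction (DSC) from feedback pauses.

During each feedback pause the applied force is off and the recorded force
channel reads the zero-force baseline F0.  Averaging the last 1.5 ms of each
pause gives per-pause baseline estimates; pauses at the top and bottom of the
excursion give, via

    eod_slope = (F0_high - F0_low) / d,

the position-proportional force error of the deflector over the excursion
``d`` (the printed form of this relation is typographically garbled in the
source methods; it is read as the difference over the excursion).  The
recorded forces are corrected by ``F0(x, t) = F0_low(t) + eod_slope(t) * (x -
x_low)``, with per-pause estimates rolling-averaged over 20 pauses and
linearly interpolated in time (the real-time system applies the latest
estimate; offline interpolation is more accurate).  Pause samples stay
flagged and are excluded from downstream velocity statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Trace, ValidationError


class BaselineError(RuntimeError):
    pass


@dataclass
class BaselineEstimate:
    """Per-pause zero-force baselines and the derived deflector slope."""

    times_low: np.ndarray   # s, end of each bottom pause
    f0_low: np.ndarray      # pN, rolling-averaged
    times_high: np.ndarray
    f0_high: np.ndarray
    pair_times: np.ndarray  # s, midpoint of each top/bottom pair
    eod_slope: np.ndarray   # pN/nm, rolling-averaged
    x_low: float            # nm, mean trap position during bottom pauses
    x_high: float
    window: int = 20

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValidationError("window must be >= 1")
        for arr in (self.f0_low, self.f0_high, self.eod_slope):
            if not np.all(np.isfinite(arr)):
                raise ValidationError("non-finite baseline estimate")


def _pause_blocks(trace: Trace):
    flag = trace.pause_flag
    d = np.diff(flag.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if flag[0]:
        starts = np.r_[0, starts]
    if flag[-1]:
        ends = np.r_[ends, len(flag)]
    return starts, ends


def _rolling(a: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling mean with truncated edges (min_periods=1)."""
    kernel = np.ones(min(window, len(a)))
    num = np.convolve(a, kernel, mode="same")
    den = np.convolve(np.ones_like(a), kernel, mode="same")
    return num / den


def estimate_baseline(trace: Trace, window: int = 20, average_s: float = 1.5e-3) -> BaselineEstimate:
    """Estimate F0 baselines and the deflector slope from pause blocks.

    Per pause, F0 is the mean recorded force over the last ``average_s`` of
    the pause; pauses are classified top/bottom by the trap position at pause
    onset relative to the median.  Raises if the trace contains no pauses
    (zero-baseline mode must then be used explicitly).
    """
    starts, ends = _pause_blocks(trace)
    if len(starts) == 0:
        raise BaselineError(
            "trace contains no feedback pauses; skip DSC (zero-baseline mode)"
        )
    n_avg = max(1, int(round(average_s / trace.dt)))
    f0 = np.empty(len(starts))
    xp = np.empty(len(starts))
    tp = np.empty(len(starts))
    for i, (a, b) in enumerate(zip(starts, ends)):
        sl = slice(max(a, b - n_avg), b)
        f0[i] = trace.force_lead[sl].mean()
        xp[i] = trace.trap_pos_lead[sl].mean()
        tp[i] = (b - 1) * trace.dt
    is_top = xp > np.median(xp)
    if is_top.all() or not is_top.any():
        raise BaselineError("pauses do not alternate between top and bottom of excursion")

    t_hi, f_hi, x_hi = tp[is_top], f0[is_top], xp[is_top]
    t_lo, f_lo, x_lo = tp[~is_top], f0[~is_top], xp[~is_top]

    # pair each top pause with the nearest bottom pause in time
    j = np.clip(np.searchsorted(t_lo, t_hi), 0, len(t_lo) - 1)
    j_prev = np.clip(j - 1, 0, len(t_lo) - 1)
    j = np.where(np.abs(t_lo[j_prev] - t_hi) < np.abs(t_lo[j] - t_hi), j_prev, j)
    dx = x_hi - x_lo[j]
    if np.any(np.abs(dx) < 1.0):
        raise BaselineError("top/bottom pause positions too close to derive a slope")
    slope = (f_hi - f_lo[j]) / dx

    return BaselineEstimate(
        times_low=t_lo,
        f0_low=_rolling(f_lo, window),
        times_high=t_hi,
        f0_high=_rolling(f_hi, window),
        pair_times=(t_hi + t_lo[j]) / 2.0,
        eod_slope=_rolling(slope, window),
        x_low=float(x_lo.mean()),
        x_high=float(x_hi.mean()),
        window=window,
    )


def correct_forces(trace: Trace, baseline: BaselineEstimate) -> Trace:
    """Subtract the interpolated baseline ``F0(x, t)`` from the lead force.

    Returns a new trace; pause samples remain flagged so downstream velocity
    statistics ignore them.  Applying the correction twice changes forces
    only by the (small) re-estimation noise.
    """
    t = trace.time()
    f0_low = np.interp(t, baseline.times_low, baseline.f0_low)
    slope = np.interp(t, baseline.pair_times, baseline.eod_slope)
    f0 = f0_low + slope * (trace.trap_pos_lead - baseline.x_low)
    return Trace(
        dt=trace.dt,
        trap_pos_lead=trace.trap_pos_lead,
        trap_pos_trail=trace.trap_pos_trail,
        force_lead=trace.force_lead - f0,
        force_trail=trace.force_trail,
        pause_flag=trace.pause_flag,
        meta=trace.meta,
        molecule_id=trace.molecule_id,
        trace_id=trace.trace_id,
        polarity=trace.polarity,
    )
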