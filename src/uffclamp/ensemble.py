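"""Time-forward ensemble averaging of working-stroke displacements.

Events are aligned at their detected binding times and averaged forward in
time.  Each event's displacement beyond its extension point (the value at
``sigma_t`` before its detected end) is held constant so events of unequal
duration can be averaged on one grid; each molecule contributes equally to
the average by default.  Quantification of an average yields the initial
stroke amplitude and rate, the later "dip" attributed to stroke reversals,
and the total displacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io import Trace, ValidationError


class EnsembleError(RuntimeError):
    pass


@dataclass
class EnsembleAverage:
    """Aligned, extended, molecule-weighted mean displacement vs time.

    ``time_s`` runs from a small pre-trigger span (<= 0) in steps of the trace
    dt; displacement is in nm, zeroed at the detected binding time of each
    event before averaging.
    """

    time_s: np.ndarray
    mean_displacement_nm: np.ndarray
    n_events: int
    n_molecules: int
    force_pN: float
    min_duration_s: float
    max_duration_s: float | None = None
    condition: str = ""
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValidationError("ensemble requires at least one event")
        if self.time_s[0] > 0:
            raise ValidationError("grid must start at or before 0")

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0])


@dataclass
class StrokeQuantification:
    t_init_s: float
    initial_displacement_nm: float
    k_stroke: float | None = None
    k_stroke_ci95: tuple | None = None
    dip_amplitude_nm: float | None = None
    dip_time_s: float | None = None
    total_displacement_nm: float = 0.0
    t_min_s: float = 0.0
    zero_level_nm: float = 0.0


def _extend(seg: np.ndarray, t: np.ndarray, hold_after_s: float, block_s: float = 1e-4) -> np.ndarray:
    """Hold the segment at its displacement at ``hold_after_s`` onward.

    The held displacement is estimated as the mean over the ``block_s``
    window ending at the extension point rather than the single sample
    there: a single frozen sample would propagate its noise (and its
    correlation with the detected end) into every later time point of the
    average."""
    dt = t[1] - t[0]
    i = np.searchsorted(t, hold_after_s)
    i = min(max(i, 1), len(seg) - 1)
    a = max(0, i - int(round(block_s / dt)))
    out = seg.copy()
    out[i:] = seg[a : i + 1].mean()
    return out


def average_segments(
    segments: np.ndarray,
    time_s: np.ndarray,
    durations_s: np.ndarray,
    sigma_t_s: np.ndarray,
    molecule_ids: np.ndarray,
    weighting: str = "molecule",
) -> np.ndarray:
    """Core averaging routine shared by data analysis and model prediction.

    ``segments`` is (n_events, n_samples) displacement aligned at binding
    (t=0); each row is extended from ``duration - sigma_t`` onward, then
    averaged with equal weight per molecule (or per event).
    """
    segs = np.array(
        [
            _extend(seg, time_s, d - s)
            for seg, d, s in zip(segments, durations_s, sigma_t_s)
        ]
    )
    if weighting == "molecule":
        _, inv, counts = np.unique(molecule_ids, return_inverse=True, return_counts=True)
        w = 1.0 / counts[inv]
    elif weighting == "event":
        w = np.ones(len(segs))
    else:
        raise ValidationError(f"unknown weighting {weighting!r}")
    w = w / w.sum()
    return w @ segs


def _binding_position(
    x: np.ndarray,
    i0: int,
    dt: float,
    hindering: bool,
    polarity: int,
    back_s: float = 0.3e-3,
    fwd_s: float = 0.6e-3,
    block_s: float = 48e-6,
) -> float:
    """Robust estimate of the trap position at binding.

    The single sample at the detected start carries an error of (unbound
    speed) x (start-time error), which at desk-scale event counts dominates
    ensemble averages.  The position where the filament stopped is instead
    estimated as the extremal short-block mean around the detected start: for
    a hindering event the approach comes from above (in stroke coordinates)
    and the trajectory minimum near the start is the post-stretch binding
    level, so the block minimum is insensitive to start-timing error (and
    conversely the maximum for assisting events).  The estimator's small
    constant offset (stretch plus noise-extremum bias) is common to all
    events and cancels in the ensemble's internal zeroing.
    """
    n_b = max(1, int(round(block_s / dt)))
    a = max(0, i0 - int(round(back_s / dt)))
    b = min(len(x), i0 + int(round(fwd_s / dt)))
    w = x[a:b]
    m = (len(w) // n_b) * n_b
    if m < n_b:
        return float(x[i0])
    blocks = w[:m].reshape(-1, n_b).mean(axis=1)
    # in stroke coordinates (x * polarity) hindering approaches from above
    signed = blocks * polarity
    return float(signed.min() if hindering else signed.max()) * polarity


def build_ensemble(
    events: pd.DataFrame,
    traces: Trace | list[Trace] | dict,
    min_duration_s: float,
    max_duration_s: float | None = None,
    weighting: str = "molecule",
    span_s: float = 0.030,
    pre_s: float = 0.001,
    force_pN: float | None = None,
    condition: str = "",
    reference: str = "robust",
) -> EnsembleAverage:
    """Build the ensemble average of event displacements from traces.

    Per event the displacement is the leading-trap position minus its value
    at the detected binding time, multiplied by the trace polarity so the
    working stroke is positive.  With ``reference='robust'`` (default) the
    value at binding is the timing-insensitive block-extremum estimate of
    :func:`_binding_position`; ``reference='sample'`` uses the raw sample at
    the detected start.  Events shorter than ``min_duration_s`` are excluded;
    a ``max_duration_s``, if given, is recorded in the metadata but does not
    exclude events (the analysis filters only by minimum duration).  Events
    without full trace coverage of the grid are skipped and counted.
    """
    if isinstance(traces, Trace):
        traces = [traces]
    if not isinstance(traces, dict):
        traces = {tr.trace_id: tr for tr in traces}
    sel = events[events.duration_s >= min_duration_s]
    if not len(sel):
        raise EnsembleError("no events pass the duration filter")
    segs, kept, skipped = [], [], 0
    for tid, tr in traces.items():
        part = sel[sel.trace_id == tid]
        if not len(part):
            continue
        s, k, n_skip = extract_event_segments(part, tr, span_s, pre_s, reference)
        segs.append(s)
        kept.append(k)
        skipped += n_skip
    skipped += int((~sel.trace_id.isin(traces)).sum())
    if not segs or not sum(len(s) for s in segs):
        raise EnsembleError("no events with trace coverage")
    segments = np.concatenate(segs)
    kept = pd.concat(kept, ignore_index=True)
    dt = next(iter(traces.values())).dt
    n_pre = int(round(pre_s / dt))
    time_s = (np.arange(segments.shape[1]) - n_pre) * dt
    return ensemble_from_segments(
        segments,
        kept,
        time_s,
        weighting=weighting,
        force_pN=force_pN,
        min_duration_s=min_duration_s,
        max_duration_s=max_duration_s,
        condition=condition,
        n_skipped=skipped,
    )


def extract_event_segments(
    events: pd.DataFrame,
    trace: Trace,
    span_s: float = 0.030,
    pre_s: float = 0.001,
    reference: str = "robust",
):
    """Per-event displacement segments of one trace, for incremental
    (memory-bounded) ensemble building: returns ``(segments, kept_events,
    n_skipped)``.  Segments are aligned at the detected binding time and
    referenced per :func:`build_ensemble`; events without full trace coverage
    of the grid are skipped."""
    dt = trace.dt
    n_pre = int(round(pre_s / dt))
    n_post = int(round(span_s / dt))
    segs, rows = [], []
    skipped = 0
    for _, ev in events.iterrows():
        i0 = int(round(ev.start_s / dt))
        a, b = i0 - n_pre, i0 + n_post
        if a < 0 or b > trace.n_samples or i0 >= trace.n_samples:
            skipped += 1
            continue
        x = trace.trap_pos_lead[a:b]
        if reference == "robust":
            ref = _binding_position(
                trace.trap_pos_lead, i0, dt, ev.direction == "hindering", trace.polarity
            )
        else:
            ref = trace.trap_pos_lead[i0]
        segs.append(trace.polarity * (x - ref))
        rows.append(ev)
    segments = np.array(segs) if segs else np.empty((0, n_pre + n_post))
    kept = pd.DataFrame(rows) if rows else events.iloc[0:0]
    return segments, kept, skipped


def ensemble_from_segments(
    segments: np.ndarray,
    events: pd.DataFrame,
    time_s: np.ndarray,
    weighting: str = "molecule",
    force_pN: float | None = None,
    min_duration_s: float = 0.0,
    max_duration_s: float | None = None,
    condition: str = "",
    n_skipped: int = 0,
) -> EnsembleAverage:
    """Average pre-extracted displacement segments (extension + weighting)."""
    if not len(segments):
        raise EnsembleError("no segments to average")
    mean = average_segments(
        segments,
        time_s,
        events.duration_s.to_numpy(),
        events.sigma_t_s.to_numpy(),
        events.molecule_id.to_numpy(),
        weighting,
    )
    if force_pN is None:
        force_pN = float(np.median(np.abs(events.force_pN)))
    return EnsembleAverage(
        time_s=time_s,
        mean_displacement_nm=mean,
        n_events=len(segments),
        n_molecules=len(set(events.molecule_id)),
        force_pN=force_pN,
        min_duration_s=min_duration_s,
        max_duration_s=max_duration_s,
        condition=condition,
        n_skipped=n_skipped,
    )


def _moving_average(y: np.ndarray, n: int) -> np.ndarray:
    """Moving average with windows truncated at the series edges."""
    kernel = np.ones(n)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return num / den


def quantify_stroke(avg: EnsembleAverage, dip_required: bool = False) -> StrokeQuantification:
    """Quantify stroke amplitude, dip, and total displacement of an average.

    Zero displacement is the minimum within the first 1 ms after binding;
    ``t_init`` is the argmax of the raw average within 1.2 ms after that
    minimum (5 ms at 1.5 pN, where smoothing is heaviest); the initial
    displacement averages a 200 us window centered on ``t_init``.  The dip is
    located on a 1 ms moving average between ``t_init`` and 15 ms; the total
    displacement is the mean of the last 200 us of the grid.  Dip metrics are
    omitted (None) when the average does not span 15 ms.
    """
    t = avg.time_s
    y = avg.mean_displacement_nm
    dt = avg.dt
    post = t >= 0
    if t[post][-1] < 0.005:
        raise EnsembleError("average must span at least 5 ms after binding")

    w1 = post & (t <= 1e-3)
    i_min = np.flatnonzero(w1)[np.argmin(y[w1])]
    zero = y[i_min]
    t_min = t[i_min]

    search = 5e-3 if abs(avg.force_pN) <= 1.5 + 1e-9 else 1.2e-3
    w2 = (t > t_min) & (t <= t_min + search)
    if not w2.any():
        raise EnsembleError("empty t_init search window")
    i_init = np.flatnonzero(w2)[np.argmax(y[w2])]
    t_init = t[i_init]

    half = int(round(100e-6 / dt))
    init_disp = float(np.mean(y[max(0, i_init - half) : i_init + half + 1]) - zero)

    n_tail = int(round(200e-6 / dt))
    total = float(np.mean(y[-n_tail:]) - zero)

    dip_amp = dip_time = None
    if t[-1] >= 0.015:
        ma = _moving_average(y, int(round(1e-3 / dt)))
        w3 = (t >= t_init) & (t <= 0.015)
        i_dip = np.flatnonzero(w3)[np.argmin(ma[w3])]
        dip_amp = max(0.0, init_disp - float(ma[i_dip] - zero))
        dip_time = float(t[i_dip] - t_init)
    elif dip_required:
        raise EnsembleError("average shorter than 15 ms: dip metrics unavailable")

    return StrokeQuantification(
        t_init_s=float(t_init),
        initial_displacement_nm=init_disp,
        dip_amplitude_nm=dip_amp,
        dip_time_s=dip_time,
        total_displacement_nm=total,
        t_min_s=float(t_min),
        zero_level_nm=float(zero),
    )


def fit_stroke_rate(
    avg: EnsembleAverage,
    quant: StrokeQuantification | None = None,
) -> tuple[float, tuple]:
    """Single-exponential rise rate of the normalized initial stroke.

    The displacement between the minimum position and ``t_init`` is normalized
    to [0, 1] and fit with ``y = 1 - exp(-k (t - t_min))`` (amplitude fixed at
    1, origin anchored at the minimum).  Returns ``(k, (lo, hi))`` with a 95%
    confidence interval from the fit covariance.
    """
    if quant is None:
        quant = quantify_stroke(avg)
    t = avg.time_s
    y = avg.mean_displacement_nm
    w = (t >= quant.t_min_s) & (t <= quant.t_init_s)
    if w.sum() < 10:
        raise EnsembleError("fewer than 10 samples between t_min and t_init")
    y_max = np.max(y[w])
    denom = y_max - quant.zero_level_nm
    if denom <= 0:
        raise EnsembleError("non-positive stroke amplitude; cannot normalize")
    yn = (y[w] - quant.zero_level_nm) / denom
    tn = t[w] - quant.t_min_s

    def model(tt, k):
        return 1.0 - np.exp(-k * tt)

    k0 = 1.0 / max(np.median(tn), avg.dt)
    popt, pcov = curve_fit(model, tn, yn, p0=[k0], maxfev=10000)
    k = float(popt[0])
    se = float(np.sqrt(pcov[0, 0]))
    return k, (k - 1.96 * se, k + 1.96 * se)
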