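"""Mechanochemical kinetic schemes and stochastic state-path simulation.

A :class:`KineticScheme` is a continuous-time Markov chain over myosin states.
Each attached state carries a mean lever-arm position contribution (nm); each
transition has a zero-load rate ``k0`` and a Bell force-sensitivity distance
``d`` so that ``k(F) = k0 * exp(F * d / kT)``.  Hindering load is positive by
convention (force opposing the working stroke).  Detached states are absorbing
within a single interaction.

State paths are drawn by the first-reaction (Gillespie) rule: for each
transition out of the current state a candidate exponential time is drawn and
the minimum wins, so the expected flux through transition i->j is
``k_ij / k_sum`` and the state dwell is Exponential(k_sum).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .io import ValidationError

#: Thermal energy at ~25 C, pN*nm.
KT = 4.11


class SchemeError(ValueError):
    """A kinetic scheme is structurally invalid."""


@dataclass
class KineticState:
    name: str
    attached: bool
    position_nm: float = 0.0
    strong: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.position_nm):
            raise ValidationError("state position must be finite")


@dataclass
class Transition:
    """A force-dependent transition between scheme states.

    ``bell_distance_nm`` applies for hindering (positive) force; if
    ``bell_distance_neg_nm`` is given it replaces it for assisting (negative)
    force, allowing the asymmetric force dependence reported for the
    stroke-reversal pathway.
    """

    from_state: str
    to_state: str
    k0: float
    bell_distance_nm: float = 0.0
    label: str = ""
    bell_distance_neg_nm: float | None = None

    def __post_init__(self) -> None:
        if self.k0 < 0:
            raise ValidationError("transition k0 must be >= 0")


def rate_at_force(transition: Transition, force: float, kT: float = KT) -> float:
    """Bell-model rate ``k0 * exp(F * d / kT)`` at signed force (pN).

    Returns ``k0`` when the Bell distance is zero.  Raises on non-finite
    results (pathological parameters).
    """
    if not np.isfinite(force):
        raise ValidationError("force must be finite")
    d = transition.bell_distance_nm
    if force < 0 and transition.bell_distance_neg_nm is not None:
        d = transition.bell_distance_neg_nm
    k = transition.k0 * np.exp(force * d / kT)
    if not np.isfinite(k):
        raise ValidationError(
            f"non-finite rate for transition {transition.from_state}->"
            f"{transition.to_state} at {force} pN"
        )
    return float(k)


def bell_distance_from_endpoints(k_lo: float, k_hi: float, force_span: float, kT: float = KT) -> float:
    """Bell distance that carries a rate from ``k_lo`` at 0 pN to ``k_hi`` at
    ``force_span`` pN of hindering load."""
    return float(kT * np.log(k_hi / k_lo) / force_span)


@dataclass
class KineticScheme:
    """States plus transitions; first state is the state entered on binding."""

    states: list[KineticState]
    transitions: list[Transition]
    pi_concentration_mM: float = 0.0
    name: str = "scheme"

    def __post_init__(self) -> None:
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            raise SchemeError("duplicate state names")
        by_name = {s.name: s for s in self.states}
        for tr in self.transitions:
            for endpoint in (tr.from_state, tr.to_state):
                if endpoint not in by_name:
                    raise SchemeError(f"transition endpoint {endpoint!r} not a state")
            if not by_name[tr.from_state].attached:
                raise SchemeError(
                    f"detached state {tr.from_state!r} must be absorbing "
                    "(no outgoing transitions)"
                )
        if not any(not s.attached for s in self.states):
            raise SchemeError("scheme needs at least one detached (absorbing) state")
        if not self.states[0].attached:
            raise SchemeError("initial (first) state must be attached")
        self._by_name = by_name
        self._outgoing = {s.name: [t for t in self.transitions if t.from_state == s.name] for s in self.states}
        for s in self.states:
            if s.attached and not self._outgoing[s.name]:
                raise SchemeError(f"attached state {s.name!r} has no outgoing transitions")

    def state(self, name: str) -> KineticState:
        return self._by_name[name]

    def outgoing(self, name: str) -> list[Transition]:
        return self._outgoing[name]

    @property
    def initial_state(self) -> str:
        return self.states[0].name

    def rates_out(self, name: str, force: float) -> np.ndarray:
        return np.array([rate_at_force(t, force) for t in self.outgoing(name)])


@dataclass
class StatePath:
    """Ordered (state name, entry time s) pairs ending in a detached state."""

    states: list[str]
    entry_times: list[float]
    labels: list[str] = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        return self.entry_times[-1] - self.entry_times[0]

    def stroke_time(self) -> float | None:
        """Entry time of the first transition labeled 'stroke', if any."""
        for i, lab in enumerate(self.labels):
            if lab == "stroke":
                return self.entry_times[i + 1]
        return None


def simulate_state_path(
    scheme: KineticScheme,
    force: float,
    rng: np.random.Generator | int | None = None,
) -> StatePath:
    """Draw one interaction's state path by the first-reaction rule."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    current = scheme.initial_state
    t = 0.0
    states = [current]
    times = [0.0]
    labels: list[str] = []
    while scheme.state(current).attached:
        out = scheme.outgoing(current)
        rates = scheme.rates_out(current, force)
        total = rates.sum()
        if total <= 0:
            raise SchemeError(f"attached state {current!r} has zero total exit rate")
        # first-reaction rule: one candidate exponential per transition
        candidates = np.where(rates > 0, rng.exponential(1.0, len(out)) / np.where(rates > 0, rates, 1.0), np.inf)
        j = int(np.argmin(candidates))
        t += candidates[j]
        current = out[j].to_state
        states.append(current)
        times.append(t)
        labels.append(out[j].label)
    return StatePath(states=states, entry_times=times, labels=labels)


def simulate_paths_batch(
    scheme: KineticScheme,
    force: float,
    n: int,
    rng: np.random.Generator | int | None = None,
):
    """Vectorized batch of ``n`` state paths for statistics.

    Returns a dict with per-path ``durations`` (s), ``stroked`` flags, and
    per-transition ``flux_counts``/``visits`` plus per-state dwell samples
    (``dwells``), suitable for oracle-equivalence checks against the analytic
    branching fractions and Exponential(k_sum) dwell law.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    state_names = [s.name for s in scheme.states]
    idx = {name: i for i, name in enumerate(state_names)}
    attached = np.array([s.attached for s in scheme.states])

    current = np.full(n, idx[scheme.initial_state], dtype=np.int64)
    t_total = np.zeros(n)
    stroked = np.zeros(n, dtype=bool)
    active = attached[current]

    flux_counts = {(t.from_state, t.to_state, t.label): 0 for t in scheme.transitions}
    visits = {name: 0 for name in state_names}
    dwells: dict[str, list[np.ndarray]] = {name: [] for name in state_names}

    while np.any(active):
        for s_i in np.unique(current[active]):
            name = state_names[s_i]
            sel = active & (current == s_i)
            m = int(sel.sum())
            out = scheme.outgoing(name)
            rates = scheme.rates_out(name, force)
            pos = rates > 0
            cand = np.full((m, len(out)), np.inf)
            if pos.any():
                cand[:, pos] = rng.exponential(1.0, (m, int(pos.sum()))) / rates[pos]
            j = np.argmin(cand, axis=1)
            dwell = cand[np.arange(m), j]
            t_total[sel] += dwell
            visits[name] += m
            dwells[name].append(dwell)
            for jj, tr in enumerate(out):
                cnt = int((j == jj).sum())
                flux_counts[(tr.from_state, tr.to_state, tr.label)] += cnt
                if tr.label == "stroke" and cnt:
                    took = np.zeros(n, dtype=bool)
                    took[np.flatnonzero(sel)[j == jj]] = True
                    stroked |= took
            nxt = np.array([idx[tr.to_state] for tr in out])[j]
            current[sel] = nxt
        active = attached[current]

    return {
        "durations": t_total,
        "stroked": stroked,
        "flux_counts": flux_counts,
        "visits": visits,
        "dwells": {k: (np.concatenate(v) if v else np.array([])) for k, v in dwells.items()},
    }


def branching_fraction(k_target: float, k_competitors: Sequence[float]) -> float:
    """Probability that the target transition wins the exponential race.

    ``k_target / (k_target + sum(k_competitors))``, exact.
    """
    ks = np.asarray(list(k_competitors), dtype=float)
    if k_target < 0 or np.any(ks < 0):
        raise ValidationError("rates must be >= 0")
    total = k_target + ks.sum()
    if total <= 0:
        raise ValidationError("branching fraction undefined for all-zero rates")
    return float(k_target / total)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

#: Bell distance carrying the fast-detach rate from ~500 s^-1 (unloaded) to
#: ~5000 s^-1 at 4.5 pN hindering load.
_D_FAST_DETACH = bell_distance_from_endpoints(500.0, 5000.0, 4.5)  # ~2.10 nm


def preset_scheme(
    name: str,
    pi_mM: float = 0.0,
    atp_uM: float = 1.0,
    stroke_size_nm: float = 6.0,
    second_phase_nm: float = 1.0,
) -> KineticScheme:
    """Fully parameterized preset schemes.

    ``stroke_first``: binding enters a short-lived, weakly bound pre-stroke
    state (lifetime ~300 us under moderate hindering load) that either detaches
    at the fast, strongly force-dependent rate (500 -> 5000 s^-1 over
    0 -> 4.5 pN) or performs the working stroke.  Phosphate release (17 s^-1)
    follows the stroke; phosphate rebinding (pseudo-first-order in [Pi])
    re-enables stroke reversal into a distinct post-reversal pre-stroke state
    with ~1 ms lifetime under load.  The slow exit (ATP-gated, ~7 s^-1 at
    1 uM MgATP) terminates full-cycle events.

    ``pi_first``: the alternative ordering with phosphate release and
    rebinding between binding and the stroke.  For this ordering to be
    compatible with the observed sub-millisecond stroke its release step must
    be very fast (10,000 s^-1 here); rapid rebinding then predicts a
    phosphate-dependent slowing of the observed stroke rate, which is the
    discriminating signature.
    """
    if pi_mM < 0:
        raise ValidationError("pi_mM must be >= 0")
    k_pi_rebind_sf = 30.0 * pi_mM  # pseudo-first-order, 30 s^-1 per mM
    if name == "stroke_first":
        # Pi rebinding enters a distinct rebound state (post_stroke_pi2) with
        # its own, stronger reversal pathway: rebinding re-enables reversal
        # without reopening the cleft fully, so the post-rebound reversal and
        # the ~1 ms post-reversal pre-stroke lifetime differ from the initial
        # post-stroke state's.
        states = [
            KineticState("pre_stroke", True, 0.0, strong=False),
            KineticState("post_stroke_pi", True, stroke_size_nm, strong=True),
            KineticState("post_stroke", True, stroke_size_nm, strong=True),
            KineticState("post_stroke_pi2", True, stroke_size_nm, strong=True),
            KineticState("rigor_like", True, stroke_size_nm + second_phase_nm, strong=True),
            KineticState("pre_stroke_rev", True, 0.0, strong=False),
            KineticState("pre_stroke_rev2", True, 0.0, strong=False),
            KineticState("detached", False, 0.0),
        ]
        transitions = [
            Transition("pre_stroke", "detached", 500.0, _D_FAST_DETACH, "detach_fast", bell_distance_neg_nm=-1.0),
            Transition("pre_stroke", "post_stroke_pi", 300.0, 1.2, "stroke"),
            Transition("post_stroke_pi", "post_stroke", 17.0, 0.0, "pi_release"),
            Transition("post_stroke_pi", "pre_stroke_rev", 12.0, 1.55, "stroke_reversal", bell_distance_neg_nm=0.3),
            Transition("post_stroke", "post_stroke_pi2", k_pi_rebind_sf, 0.0, "pi_rebind"),
            Transition("post_stroke", "rigor_like", 60.0, 0.0, "adp_release"),
            Transition("rigor_like", "detached", 7.0 * atp_uM, 0.0, "atp_binding"),
            Transition("pre_stroke_rev", "detached", 12.0, 1.5, "detach_int"),
            Transition("pre_stroke_rev", "post_stroke_pi", 300.0, 1.2, "stroke"),
            Transition("post_stroke_pi2", "post_stroke", 17.0, 0.0, "pi_release"),
            Transition("post_stroke_pi2", "pre_stroke_rev2", 150.0, 1.55, "stroke_reversal", bell_distance_neg_nm=0.3),
            Transition("pre_stroke_rev2", "detached", 25.0, 1.5, "detach_int"),
            Transition("pre_stroke_rev2", "post_stroke_pi2", 300.0, 1.2, "stroke"),
        ]
        return KineticScheme(states, transitions, pi_concentration_mM=pi_mM, name="stroke_first")
    if name == "pi_first":
        k_pi_rebind_pf = 2000.0 * pi_mM
        states = [
            KineticState("pre_stroke_pi", True, 0.0, strong=False),
            KineticState("pre_stroke", True, 0.0, strong=False),
            KineticState("post_stroke", True, stroke_size_nm, strong=True),
            KineticState("rigor_like", True, stroke_size_nm + second_phase_nm, strong=True),
            KineticState("detached", False, 0.0),
        ]
        transitions = [
            Transition("pre_stroke_pi", "detached", 500.0, _D_FAST_DETACH, "detach_fast"),
            Transition("pre_stroke_pi", "pre_stroke", 10000.0, 0.0, "pi_release"),
            Transition("pre_stroke", "pre_stroke_pi", k_pi_rebind_pf, 0.0, "pi_rebind"),
            Transition("pre_stroke", "post_stroke", 10000.0, 0.0, "stroke"),
            Transition("post_stroke", "rigor_like", 60.0, 0.0, "adp_release"),
            Transition("rigor_like", "detached", 7.0 * atp_uM, 0.0, "atp_binding"),
        ]
        return KineticScheme(states, transitions, pi_concentration_mM=pi_mM, name="pi_first")
    raise SchemeError(f"unknown preset scheme {name!r}")


# ---------------------------------------------------------------------------
# Scheme files
# ---------------------------------------------------------------------------


def scheme_to_dict(scheme: KineticScheme) -> dict:
    return {
        "format_version": "1.0",
        "name": scheme.name,
        "pi_concentration_mM": scheme.pi_concentration_mM,
        "states": [
            {"name": s.name, "attached": s.attached, "position_nm": s.position_nm, "strong": s.strong}
            for s in scheme.states
        ],
        "transitions": [
            {
                "from": t.from_state,
                "to": t.to_state,
                "k0": t.k0,
                "bell_distance_nm": t.bell_distance_nm,
                "label": t.label,
                **(
                    {"bell_distance_neg_nm": t.bell_distance_neg_nm}
                    if t.bell_distance_neg_nm is not None
                    else {}
                ),
            }
            for t in scheme.transitions
        ],
    }


def scheme_from_dict(d: dict) -> KineticScheme:
    states = [
        KineticState(s["name"], bool(s["attached"]), float(s.get("position_nm", 0.0)), bool(s.get("strong", False)))
        for s in d["states"]
    ]
    transitions = [
        Transition(
            t["from"],
            t["to"],
            float(t["k0"]),
            float(t.get("bell_distance_nm", 0.0)),
            str(t.get("label", "")),
            t.get("bell_distance_neg_nm"),
        )
        for t in d["transitions"]
    ]
    return KineticScheme(
        states,
        transitions,
        pi_concentration_mM=float(d.get("pi_concentration_mM", 0.0)),
        name=str(d.get("name", "scheme")),
    )


def write_scheme(scheme: KineticScheme, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(scheme_to_dict(scheme), f, sort_keys=False)


def read_scheme(path: str | Path) -> KineticScheme:
    with open(path) as f:
        return scheme_from_dict(yaml.safe_load(f))
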