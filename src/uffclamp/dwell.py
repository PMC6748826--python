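"""Deadtime-corrected maximum-likelihood analysis of attachment durations.

Durations observed above an experimental deadtime ``t_d`` are modeled as a
left-truncated mixture of 1-3 exponentials,

    f(t) = sum_i a_i k_i exp(-k_i t) / sum_j a_j exp(-k_j t_d),   t >= t_d,

where the ``a_i`` are the deadtime-corrected (untruncated) mixture fractions.
The observed fractions are the truncation image
``A_i = a_i exp(-k_i t_d) / Z``; both sets are reported and their round trip
is exact.  Model order is chosen by the nested log-likelihood-ratio test
(chi-squared with 2 df per added component, p < 0.05), each molecule can be
weighted equally (default) or each event, and confidence intervals come from
a molecule-level bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .io import ValidationError

_LOGK_MIN, _LOGK_MAX = np.log(1e-3), np.log(1e6)


class FitError(RuntimeError):
    pass


@dataclass
class DwellSample:
    """Durations (s) with molecule labels and the truncation deadtime."""

    durations_s: np.ndarray
    molecule_ids: np.ndarray
    deadtime_s: float
    force_pN: float = 0.0
    condition: str = ""

    def __post_init__(self) -> None:
        self.durations_s = np.asarray(self.durations_s, dtype=float)
        self.molecule_ids = np.asarray(self.molecule_ids)
        if self.deadtime_s <= 0:
            raise ValidationError("deadtime_s must be > 0")
        if len(self.durations_s) != len(self.molecule_ids):
            raise ValidationError("durations and molecule_ids length mismatch")
        if np.any(self.durations_s < self.deadtime_s - 1e-12):
            raise ValidationError("all durations must be >= deadtime_s")

    @property
    def n_events(self) -> int:
        return len(self.durations_s)

    @property
    def n_molecules(self) -> int:
        return len(np.unique(self.molecule_ids))

    def weights(self, weighting: str) -> np.ndarray:
        """Per-event weights; 'molecule' weighting makes each molecule
        contribute equally, normalized so the weights sum to n_events."""
        if weighting == "event":
            return np.ones(self.n_events)
        if weighting == "molecule":
            _, inv, counts = np.unique(self.molecule_ids, return_inverse=True, return_counts=True)
            w = 1.0 / counts[inv]
            return w * (self.n_events / w.sum())
        raise ValidationError(f"unknown weighting {weighting!r}")


@dataclass
class DwellFitResult:
    n_components: int
    rates: np.ndarray  # s^-1, sorted descending (k_f >= k_int >= k_s)
    amplitudes_observed: np.ndarray  # sum to 1
    amplitudes_corrected: np.ndarray  # sum to 1
    log_likelihood: float
    n_events: int
    n_molecules: int
    deadtime_s: float
    weighting: str = "molecule"
    llr_pvalues: dict = field(default_factory=dict)  # {"1->2": p, "2->3": p}
    ci: dict = field(default_factory=dict)  # parameter -> {level: (lo, hi)}
    boundary_warning: bool = False


def truncated_mixture_density(
    t: np.ndarray | float,
    amplitudes: np.ndarray,
    rates: np.ndarray,
    deadtime: float,
) -> np.ndarray | float:
    """Density of the left-truncated exponential mixture on [deadtime, inf).

    ``amplitudes`` are the untruncated (deadtime-corrected) mixture fractions
    and must sum to 1; the density integrates to 1 over its support.
    """
    t = np.asarray(t, dtype=float)
    a = np.asarray(amplitudes, dtype=float)
    k = np.asarray(rates, dtype=float)
    if not np.isclose(a.sum(), 1.0, atol=1e-9):
        raise ValidationError("amplitudes must sum to 1")
    if np.any(t < deadtime - 1e-12):
        raise ValidationError("t < deadtime is outside the density support")
    z = np.sum(a * np.exp(-k * deadtime))
    out = np.einsum("i,i,ij->j", a, k, np.exp(-np.outer(k, np.atleast_1d(t)))) / z
    return out if t.ndim else float(out[0])


def observed_amplitudes(corrected: np.ndarray, rates: np.ndarray, deadtime: float) -> np.ndarray:
    """Truncation image of the corrected fractions: ``a_i e^{-k_i td} / Z``."""
    a = np.asarray(corrected, dtype=float)
    w = a * np.exp(-np.asarray(rates, dtype=float) * deadtime)
    return w / w.sum()


def corrected_amplitudes(observed: np.ndarray, rates: np.ndarray, deadtime: float) -> np.ndarray:
    """Deadtime-corrected fractions: re-inflate the observed fractions by the
    events missed below the deadtime, ``A_i e^{+k_i td}``, renormalized."""
    k = np.asarray(rates, dtype=float)
    if np.any(k * deadtime > 50):
        raise ValidationError("k*deadtime > 50: correction would overflow")
    w = np.asarray(observed, dtype=float) * np.exp(k * deadtime)
    return w / w.sum()


def _unpack(params: np.ndarray, m: int):
    logk = params[:m]
    k = np.exp(logk)
    if m == 1:
        a = np.array([1.0])
    else:
        logits = np.r_[params[m:], 0.0]
        e = np.exp(logits - logits.max())
        a = e / e.sum()
    return k, a


def _nll(params: np.ndarray, t: np.ndarray, w: np.ndarray, td: float, m: int) -> float:
    k, a = _unpack(params, m)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        z = np.sum(a * np.exp(-k * td))
        dens = np.exp(-np.outer(t, k)) @ (a * k) / z
        if np.any(dens <= 0) or not np.all(np.isfinite(dens)):
            return 1e300
        return -float(w @ np.log(dens))


def _starts(t: np.ndarray, td: float, m: int, rng: np.random.Generator):
    # start grid; respects the same identifiability ceiling as the bounds
    med = max(np.median(t) - td, 1e-9)
    base = 1.0 / med
    spread = np.logspace(-(m - 1) / 2, (m - 1) / 2, m) if m > 1 else np.array([1.0])
    starts = []
    k_hi = 0.9 * (5.0 / td) if td > 0 else 5e5
    for scale in (1.0, 10.0, 0.1):
        k = np.clip(base * scale * spread, 2e-3, min(5e5, k_hi))
        starts.append(np.r_[np.log(k), np.zeros(m - 1)])
    for _ in range(5):
        k = np.exp(rng.uniform(np.log(base / 100), np.log(base * 100), m))
        k = np.clip(np.sort(k)[::-1], 2e-3, min(5e5, k_hi))
        logits = rng.normal(0, 1, m - 1)
        starts.append(np.r_[np.log(k), logits])
    return starts


def fit_mixture_mle(
    sample: DwellSample,
    n_components: int,
    weighting: str = "molecule",
    rng_seed: int = 0,
) -> DwellFitResult:
    """Maximum-likelihood fit of the deadtime-truncated exponential mixture.

    Requires at least 10 events per free parameter.  Multi-start optimization
    (quantile-based plus random log-uniform starts); rates are constrained to
    [1e-3, 1e6] s^-1 in log space and reported sorted descending.
    """
    m = int(n_components)
    if m not in (1, 2, 3):
        raise ValidationError("n_components must be 1, 2 or 3")
    n_par = 2 * m - 1
    if sample.n_events < 10 * n_par:
        raise FitError(
            f"need >= {10 * n_par} events for {m} components, have {sample.n_events}"
        )
    t = sample.durations_s
    w = sample.weights(weighting)
    td = sample.deadtime_s
    rng = np.random.default_rng(rng_seed)

    if m == 1:
        # closed form: weighted mean residual life above the deadtime
        k_hat = 1.0 / max(np.average(t, weights=w) - td, 1e-12)
        ll = -_nll(np.array([np.log(k_hat)]), t, w, td, 1)
        return DwellFitResult(
            1,
            np.array([k_hat]),
            np.array([1.0]),
            np.array([1.0]),
            ll,
            sample.n_events,
            sample.n_molecules,
            td,
            weighting,
        )

    # rates far above 1/deadtime are unidentifiable (virtually no mass
    # survives truncation), so cap the search at 5/deadtime
    logk_cap = min(_LOGK_MAX, np.log(5.0 / td)) if td > 0 else _LOGK_MAX
    bounds = [(_LOGK_MIN, logk_cap)] * m + [(-12.0, 12.0)] * (m - 1)
    best = None
    for x0 in _starts(t, td, m, rng):
        res = minimize(_nll, x0, args=(t, w, td, m), method="L-BFGS-B", bounds=bounds)
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    if best is None:
        raise FitError("optimizer failed to converge from any start")

    k, a = _unpack(best.x, m)
    order = np.argsort(k)[::-1]
    k, a = k[order], a[order]
    boundary = bool(np.any(np.abs(np.log(k) - _LOGK_MIN) < 1e-6) or np.any(np.abs(np.log(k) - _LOGK_MAX) < 1e-6))
    a_obs = observed_amplitudes(a, k, td)
    return DwellFitResult(
        m,
        k,
        a_obs,
        a,
        -float(best.fun),
        sample.n_events,
        sample.n_molecules,
        td,
        weighting,
        boundary_warning=boundary,
    )


def select_model(
    sample: DwellSample,
    weighting: str = "molecule",
    max_components: int = 3,
    alpha: float = 0.05,
    rng_seed: int = 0,
) -> DwellFitResult:
    """Greedy nested model selection 1 -> 2 -> 3 by the log-likelihood-ratio
    test (2*dlogL ~ chi2 with 2 df per added rate+amplitude, p < alpha)."""
    fits = {1: fit_mixture_mle(sample, 1, weighting, rng_seed)}
    pvals: dict[str, float] = {}
    chosen = 1
    for m in range(2, max_components + 1):
        if sample.n_events < 10 * (2 * m - 1):
            break
        fits[m] = fit_mixture_mle(sample, m, weighting, rng_seed)
        lam = 2.0 * (fits[m].log_likelihood - fits[chosen].log_likelihood)
        p = float(chi2.sf(max(lam, 0.0), df=2))
        pvals[f"{chosen}->{m}"] = p
        if p < alpha:
            chosen = m
        else:
            break
    result = fits[chosen]
    result.llr_pvalues = pvals
    return result


def bootstrap_ci(
    sample: DwellSample,
    fit: DwellFitResult,
    n_boot: int = 500,
    levels: tuple = (0.68, 0.90),
    rng_seed: int = 0,
) -> dict:
    """Molecule-level (cluster) bootstrap percentile confidence intervals.

    Molecules are resampled with replacement and the selected model refit;
    intervals are attached to ``fit.ci`` and returned.  Raises if more than
    10% of refits fail.
    """
    rng = np.random.default_rng(rng_seed)
    mols = np.unique(sample.molecule_ids)
    by_mol = {m: sample.durations_s[sample.molecule_ids == m] for m in mols}
    m_comp = fit.n_components
    draws_k = []
    draws_a = []
    failures = 0
    for _ in range(n_boot):
        pick = rng.choice(mols, size=len(mols), replace=True)
        t = np.concatenate([by_mol[m] for m in pick])
        ids = np.concatenate([np.full(len(by_mol[m]), i) for i, m in enumerate(pick)])
        try:
            boot = DwellSample(t, ids, sample.deadtime_s)
            res = fit_mixture_mle(boot, m_comp, fit.weighting, rng_seed=int(rng.integers(2**31)))
            draws_k.append(res.rates)
            draws_a.append(res.amplitudes_corrected)
        except (FitError, ValidationError):
            failures += 1
    if failures > 0.1 * n_boot:
        raise FitError(f"{failures}/{n_boot} bootstrap refits failed")
    draws_k = np.array(draws_k)
    draws_a = np.array(draws_a)
    ci: dict = {}
    for i in range(m_comp):
        for name, arr in ((f"k{i}", draws_k[:, i]), (f"a{i}", draws_a[:, i])):
            ci[name] = {
                lev: tuple(np.percentile(arr, [50 * (1 - lev), 50 * (1 + lev)]))
                for lev in levels
            }
    fit.ci = ci
    return ci


def dwell_sample_from_events(events, deadtime_s: float, force_pN: float = 0.0, condition: str = "") -> DwellSample:
    """Build a DwellSample from an event table, dropping sub-deadtime rows."""
    keep = events[events.duration_s >= deadtime_s]
    return DwellSample(
        keep.duration_s.to_numpy(),
        keep.molecule_id.to_numpy(),
        deadtime_s,
        force_pN=force_pN,
        condition=condition,
    )
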