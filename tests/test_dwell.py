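import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uffclamp import ValidationError
from uffclamp.dwell import (
    DwellSample,
    FitError,
    bootstrap_ci,
    corrected_amplitudes,
    fit_mixture_mle,
    observed_amplitudes,
    select_model,
    truncated_mixture_density,
)


def draw_truncated_mixture(n, amps, rates, deadtime, rng):
    """Rejection sampling from the deadtime-truncated mixture."""
    out = []
    amps = np.asarray(amps)
    rates = np.asarray(rates)
    while len(out) < n:
        comp = rng.choice(len(amps), size=n, p=amps)
        t = rng.exponential(1.0 / rates[comp])
        out.extend(t[t >= deadtime].tolist())
    return np.array(out[:n])


class TestTruncatedDensity:
    def test_plain_exponential_at_zero_deadtime(self):
        t = np.linspace(0.0, 0.1, 50)
        f = truncated_mixture_density(t, np.array([1.0]), np.array([100.0]), 0.0)
        np.testing.assert_allclose(f, 100.0 * np.exp(-100.0 * t), rtol=1e-12)

    def test_worked_observed_fraction(self):
        # equal corrected fractions at k = (1000, 10), deadtime 1 ms:
        # observed fast fraction 0.5 e^-1 / (0.5 e^-1 + 0.5 e^-0.01) ~= 0.271
        obs = observed_amplitudes(np.array([0.5, 0.5]), np.array([1000.0, 10.0]), 1e-3)
        expect = 0.5 * np.exp(-1.0) / (0.5 * np.exp(-1.0) + 0.5 * np.exp(-0.01))
        assert obs[0] == pytest.approx(expect, rel=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        k1=st.floats(50, 5000),
        ratio=st.floats(2, 200),
        a=st.floats(0.05, 0.95),
        td=st.floats(1e-4, 3e-3),
    )
    def test_density_normalizes_on_support(self, k1, ratio, a, td):
        rates = np.array([k1, k1 / ratio])
        amps = np.array([a, 1 - a])
        t = np.linspace(td, td + 40.0 / rates.min(), 200_001)
        f = truncated_mixture_density(t, amps, rates, td)
        assert np.trapezoid(f, t) == pytest.approx(1.0, abs=1e-3)

    def test_below_deadtime_is_domain_error(self):
        with pytest.raises(ValidationError):
            truncated_mixture_density(1e-4, np.array([1.0]), np.array([10.0]), 1e-3)


class TestAmplitudeCorrection:
    def test_zero_deadtime_identity(self):
        a = np.array([0.3, 0.7])
        out = corrected_amplitudes(a, np.array([1000.0, 10.0]), 0.0)
        np.testing.assert_allclose(out, a, rtol=1e-15)

    def test_worked_inverse_pair(self):
        corr = corrected_amplitudes(
            np.array([0.27091208, 0.72908792]), np.array([1000.0, 10.0]), 1e-3
        )
        np.testing.assert_allclose(corr, [0.5, 0.5], atol=1e-7)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        k1=st.floats(10, 1e4),
        ratio=st.floats(1.5, 1000),
        a=st.floats(0.01, 0.99),
        td=st.floats(0.0, 2e-3),
    )
    def test_round_trip_exact(self, k1, ratio, a, td):
        rates = np.array([k1, k1 / ratio])
        corrected = np.array([a, 1 - a])
        back = corrected_amplitudes(observed_amplitudes(corrected, rates, td), rates, td)
        np.testing.assert_allclose(back, corrected, atol=1e-12)

    def test_single_component_always_one(self):
        out = corrected_amplitudes(np.array([1.0]), np.array([100.0]), 5e-3)
        assert out[0] == 1.0

    def test_overflow_guard(self):
        with pytest.raises(ValidationError):
            corrected_amplitudes(np.array([0.5, 0.5]), np.array([1e5, 1.0]), 1e-3)


class TestFitting:
    def test_single_exponential_recovered(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(1 / 100.0, 5000)
        s = DwellSample(t + 1e-9, np.zeros(len(t), int), 1e-9)
        fit = fit_mixture_mle(s, 1)
        se = 100.0 / np.sqrt(5000)
        assert abs(fit.rates[0] - 100.0) < 3 * se

    def test_molecule_weighting_equalizes_molecules(self):
        rng = np.random.default_rng(1)
        fast = rng.exponential(1 / 50.0, 400) + 1e-9
        slow = rng.exponential(1 / 5.0, 40) + 1e-9
        t = np.r_[fast, slow]
        ids = np.r_[np.zeros(400, int), np.ones(40, int)]
        s = DwellSample(t, ids, 1e-9)
        fit = fit_mixture_mle(s, 1, weighting="molecule")
        # equal-molecule closed form: 1/k = mean of the two molecule means
        k_equal = 1.0 / np.mean([fast.mean(), slow.mean()])
        k_pooled = 1.0 / t.mean()
        assert fit.rates[0] == pytest.approx(k_equal, rel=0.05)
        assert abs(fit.rates[0] - k_pooled) > 0.5 * abs(k_equal - k_pooled)

    def test_unit_invariance_seconds_vs_milliseconds(self):
        rng = np.random.default_rng(2)
        t = draw_truncated_mixture(1500, [0.4, 0.6], [800.0, 12.0], 1e-3, rng)
        s_s = DwellSample(t, np.arange(len(t)) % 5, 1e-3)
        s_ms = DwellSample(t * 1e3, np.arange(len(t)) % 5, 1.0)
        f_s = fit_mixture_mle(s_s, 2, rng_seed=0)
        f_ms = fit_mixture_mle(s_ms, 2, rng_seed=0)
        np.testing.assert_allclose(f_s.rates, f_ms.rates * 1e3, rtol=1e-3)
        np.testing.assert_allclose(
            f_s.amplitudes_corrected, f_ms.amplitudes_corrected, atol=1e-3
        )

    def test_too_few_events_rejected(self):
        s = DwellSample(np.full(15, 0.01), np.zeros(15, int), 1e-3)
        with pytest.raises(FitError):
            fit_mixture_mle(s, 2)


class TestModelSelection:
    def test_well_separated_pair_found(self):
        rng = np.random.default_rng(3)
        found = 0
        for rep in range(20):
            t = draw_truncated_mixture(1000, [0.5, 0.5], [1000.0, 10.0], 1e-9, rng)
            s = DwellSample(t, np.arange(len(t)) % 5, 1e-9)
            if select_model(s, rng_seed=rep).n_components >= 2:
                found += 1
        assert found >= 18

    def test_small_sample_capped_at_one_component(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(0.01, 15) + 1e-3
        s = DwellSample(t, np.zeros(15, int), 1e-3)
        assert select_model(s).n_components == 1

    def test_nesting_monotonicity(self):
        rng = np.random.default_rng(5)
        t = draw_truncated_mixture(600, [0.5, 0.5], [500.0, 20.0], 5e-4, rng)
        s = DwellSample(t, np.arange(len(t)) % 6, 5e-4)
        lls = [fit_mixture_mle(s, m, rng_seed=0).log_likelihood for m in (1, 2, 3)]
        assert lls[1] >= lls[0] - 1e-6
        assert lls[2] >= lls[1] - 1e-6


class TestBootstrap:
    def test_ci_width_matches_asymptotics_and_contains_estimate(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(1 / 100.0, 5000) + 1e-9
        s = DwellSample(t, np.arange(len(t)) % 20, 1e-9)
        fit = fit_mixture_mle(s, 1)
        ci = bootstrap_ci(s, fit, n_boot=300, levels=(0.68,), rng_seed=0)
        lo, hi = ci["k0"][0.68]
        assert lo <= fit.rates[0] <= hi
        width_expected = 2 * 100.0 / np.sqrt(5000)
        assert hi - lo == pytest.approx(width_expected, rel=0.3)

    def test_coverage_near_nominal(self):
        rng = np.random.default_rng(7)
        hits = 0
        n_sets = 200
        for _ in range(n_sets):
            t = rng.exponential(1 / 100.0, 200) + 1e-9
            s = DwellSample(t, np.arange(len(t)) % 10, 1e-9)
            fit = fit_mixture_mle(s, 1)
            ci = bootstrap_ci(s, fit, n_boot=120, levels=(0.68,), rng_seed=int(rng.integers(2**31)))
            lo, hi = ci["k0"][0.68]
            hits += lo <= 100.0 <= hi
        assert 0.58 <= hits / n_sets <= 0.78
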