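import numpy as np
import pytest
from scipy import stats

from uffclamp import ValidationError
from uffclamp.kinetics import (
    KT,
    KineticScheme,
    KineticState,
    SchemeError,
    Transition,
    branching_fraction,
    preset_scheme,
    rate_at_force,
    read_scheme,
    simulate_paths_batch,
    simulate_state_path,
    write_scheme,
)

from conftest import single_exit_scheme, two_exit_scheme


class TestBellRates:
    @pytest.mark.parametrize("force", [-4.5, 0.0, 2.25, 4.5])
    def test_zero_distance_is_force_independent(self, force):
        tr = Transition("a", "b", 500.0, 0.0)
        assert rate_at_force(tr, force) == pytest.approx(500.0)

    def test_geometric_mean_at_half_force(self):
        # d calibrated so k(4.5 pN) = 10 * k0; at 2.25 pN the Bell form gives
        # the geometric mean sqrt(500 * 5000) ~= 1581 s^-1
        d = KT * np.log(10.0) / 4.5
        tr = Transition("a", "b", 500.0, d)
        assert rate_at_force(tr, 4.5) == pytest.approx(5000.0, rel=1e-9)
        assert rate_at_force(tr, 2.25) == pytest.approx(np.sqrt(500.0 * 5000.0), rel=1e-9)

    def test_preset_fast_detach_spans_500_to_5000(self):
        scheme = preset_scheme("stroke_first")
        fast = [t for t in scheme.transitions if t.label == "detach_fast"][0]
        assert rate_at_force(fast, 0.0) == pytest.approx(500.0)
        assert rate_at_force(fast, 4.5) == pytest.approx(5000.0, rel=0.01)

    def test_nonfinite_force_rejected(self):
        with pytest.raises(ValidationError):
            rate_at_force(Transition("a", "b", 1.0, 1.0), np.inf)


class TestBranchingFraction:
    def test_closed_forms(self):
        assert branching_fraction(17.0, [500.0]) == pytest.approx(17.0 / 517.0)
        assert branching_fraction(17.0, [5000.0]) == pytest.approx(17.0 / 5017.0)
        assert branching_fraction(3.0, []) == 1.0

    def test_all_zero_rates_undefined(self):
        with pytest.raises(ValidationError):
            branching_fraction(0.0, [0.0, 0.0])

    def test_monte_carlo_race_agrees(self):
        rng = np.random.default_rng(11)
        n = 200_000
        won = rng.exponential(1 / 17.0, n) < rng.exponential(1 / 500.0, n)
        p = branching_fraction(17.0, [500.0])
        assert abs(won.mean() - p) < 3 * np.sqrt(p * (1 - p) / n)


class TestStatePaths:
    def test_single_exit_mean_dwell(self):
        res = simulate_paths_batch(single_exit_scheme(100.0), 0.0, 20_000, rng=1)
        mean = res["durations"].mean()
        se = res["durations"].std() / np.sqrt(len(res["durations"]))
        assert abs(mean - 0.01) < 3 * se

    def test_two_exit_branching(self):
        res = simulate_paths_batch(two_exit_scheme(300.0, 700.0), 0.0, 20_000, rng=2)
        frac = res["stroked"].mean()
        assert abs(frac - 0.30) < 3 * np.sqrt(0.3 * 0.7 / 20_000)

    def test_release_before_stroke_produces_under_4pct_strokes(self):
        # a variant with phosphate release (17 s^-1) racing fast detachment
        scheme = KineticScheme(
            [
                KineticState("pre_pi", True, 0.0),
                KineticState("pre", True, 0.0),
                KineticState("post", True, 6.0),
                KineticState("D", False, 0.0),
            ],
            [
                Transition("pre_pi", "D", 500.0, 0.0, "detach_fast"),
                Transition("pre_pi", "pre", 17.0, 0.0, "pi_release"),
                Transition("pre", "post", 1e5, 0.0, "stroke"),
                Transition("post", "D", 10.0, 0.0, "atp_binding"),
            ],
        )
        res = simulate_paths_batch(scheme, 0.0, 50_000, rng=3)
        assert res["stroked"].mean() < 0.04

    def test_path_structure_and_determinism(self):
        scheme = two_exit_scheme()
        p1 = simulate_state_path(scheme, 0.0, rng=7)
        p2 = simulate_state_path(scheme, 0.0, rng=7)
        assert p1.states == p2.states and p1.entry_times == p2.entry_times
        assert p1.states[0] == "A"
        assert p1.states[-1] == "D"
        assert all(b > a for a, b in zip(p1.entry_times, p1.entry_times[1:]))

    def test_zero_bell_distances_make_paths_force_independent(self):
        scheme = two_exit_scheme()
        a = simulate_state_path(scheme, 0.0, rng=5)
        b = simulate_state_path(scheme, 4.5, rng=5)
        assert a.states == b.states
        assert a.entry_times == pytest.approx(b.entry_times)

    def test_attached_dead_end_rejected(self):
        with pytest.raises(SchemeError):
            KineticScheme(
                [KineticState("A", True, 0.0), KineticState("D", False, 0.0)],
                [],
            )

    def test_detached_state_must_be_absorbing(self):
        with pytest.raises(SchemeError):
            KineticScheme(
                [KineticState("A", True, 0.0), KineticState("D", False, 0.0)],
                [
                    Transition("A", "D", 10.0),
                    Transition("D", "A", 5.0),
                ],
            )


class TestOracleEquivalence:
    """Batch simulation against the analytic branching/dwell laws."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_scheme_flux_and_dwells(self, seed):
        rng = np.random.default_rng(seed)
        n_states = int(rng.integers(2, 4))
        states = [KineticState(f"S{i}", True, float(rng.normal(0, 3))) for i in range(n_states)]
        states.append(KineticState("D", False, 0.0))
        transitions = []
        for i in range(n_states):
            transitions.append(Transition(f"S{i}", "D", float(rng.uniform(50, 2000))))
            if i + 1 < n_states:
                transitions.append(Transition(f"S{i}", f"S{i+1}", float(rng.uniform(50, 2000))))
        scheme = KineticScheme(states, transitions)
        n = 100_000
        res = simulate_paths_batch(scheme, 0.0, n, rng=seed + 100)
        for name in (s.name for s in states if s.attached):
            out = scheme.outgoing(name)
            rates = scheme.rates_out(name, 0.0)
            ksum = rates.sum()
            visits = res["visits"][name]
            if visits < 100:
                continue
            for tr, k in zip(out, rates):
                p = k / ksum
                emp = res["flux_counts"][(tr.from_state, tr.to_state, tr.label)] / visits
                assert abs(emp - p) <= 3 * np.sqrt(p * (1 - p) / visits) + 1e-12
            dw = res["dwells"][name]
            p_ks = stats.kstest(dw, "expon", args=(0, 1 / ksum)).pvalue
            assert p_ks > 0.01


class TestPresets:
    def test_stroke_first_zero_pi_has_no_rebinding(self):
        scheme = preset_scheme("stroke_first", pi_mM=0.0)
        rebind = [t for t in scheme.transitions if t.label == "pi_rebind"][0]
        assert rebind.k0 == 0.0

    def test_initial_state_lifetime_300us_under_load(self):
        # ~300 us lifetime of the pre-stroke state under moderate hindering load
        scheme = preset_scheme("stroke_first")
        ksum = scheme.rates_out(scheme.initial_state, 3.0).sum()
        assert 1.0 / ksum == pytest.approx(300e-6, rel=0.35)

    def test_post_reversal_lifetime_about_1ms_under_load(self):
        scheme = preset_scheme("stroke_first")
        ksum = scheme.rates_out("pre_stroke_rev", 3.0).sum()
        assert 1e-3 / 3 < 1.0 / ksum < 3e-3

    def test_slow_exit_rate_matches_1uM_ATP(self):
        scheme = preset_scheme("stroke_first", atp_uM=1.0)
        atp = [t for t in scheme.transitions if t.label == "atp_binding"][0]
        assert 6.0 <= atp.k0 <= 8.0

    def test_pi_first_topology_release_precedes_stroke(self):
        scheme = preset_scheme("pi_first", pi_mM=10.0)
        # no stroke leaves the initial state; the release product strokes
        initial_labels = {t.label for t in scheme.outgoing(scheme.initial_state)}
        assert "stroke" not in initial_labels
        assert "pi_release" in initial_labels
        release = [t for t in scheme.transitions if t.label == "pi_release"][0]
        assert "stroke" in {t.label for t in scheme.outgoing(release.to_state)}

    def test_unknown_preset_rejected(self):
        with pytest.raises(SchemeError):
            preset_scheme("both_at_once")


def test_scheme_file_round_trip(tmp_path):
    scheme = preset_scheme("stroke_first", pi_mM=10.0)
    path = tmp_path / "scheme.yaml"
    write_scheme(scheme, path)
    back = read_scheme(path)
    assert [s.name for s in back.states] == [s.name for s in scheme.states]
    for a, b in zip(back.transitions, scheme.transitions):
        assert (a.from_state, a.to_state, a.label) == (b.from_state, b.to_state, b.label)
        assert a.k0 == pytest.approx(b.k0)
        assert a.bell_distance_nm == pytest.approx(b.bell_distance_nm)
    assert back.pi_concentration_mM == 10.0
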