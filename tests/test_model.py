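"""Colony-model recurrence: defaults, single steps, trajectories, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import whiteflysim as w
from whiteflysim.model import (
    BETA_DEFAULT,
    ConfigurationError,
    calibrate_beta,
    inoculation_state,
)


def in_bounds_params(draw_dict):
    return w.default_parameters(draw_dict)


bounded = {
    "mu_A": st.floats(0.43, 0.70),
    "delta": st.floats(0.43, 0.58),
    "gamma": st.floats(0.78, 1.0),
    "mu_N": st.floats(0.20, 0.40),
    "mu_E": st.floats(0.20, 0.40),
    "beta": st.floats(0.0, 1e-4),
}
params_strategy = st.fixed_dictionaries(bounded).map(in_bounds_params)


class TestDefaults:
    def test_documented_default_values(self, default_params):
        p = default_params
        assert p.r == 25.0  # 109 lifetime eggs -> ~50/week over 2 weeks, halved
        assert p.gamma == pytest.approx(0.89)  # midpoint of [0.78, 1.0]
        assert p.mu_A == pytest.approx(0.565)
        assert p.delta == pytest.approx(0.505)
        assert p.mu_N == pytest.approx(0.30)
        assert p.mu_E == pytest.approx(0.30)
        assert p.G_m**6 == pytest.approx(4.0, abs=1e-9)
        assert p.K == pytest.approx(0.25 * 125.0)

    def test_defaults_within_bounds(self, default_params):
        assert default_params.within_bounds(w.default_bounds())

    def test_unknown_override_rejected(self):
        with pytest.raises(ConfigurationError):
            w.default_parameters({"mu_X": 0.5})

    def test_invalid_parameter_values_rejected(self):
        with pytest.raises(ValueError):
            w.default_parameters({"gamma": 1.5})
        with pytest.raises(ValueError):
            w.default_parameters({"K": 0.0})
        with pytest.raises(ValueError):
            w.default_parameters({"mu_A": -0.1})

    def test_beta_default_reproducible_by_calibration(self):
        # frozen constant regenerates from the documented calibration recipe
        assert calibrate_beta() == pytest.approx(BETA_DEFAULT, rel=1e-6)


class TestStep:
    def test_zero_insect_step_is_pure_plant_growth(self, default_params):
        s = w.ColonyState(week=0, P=80.0, A=0, N=0, E=0, T=0)
        nxt = w.step(s, default_params)
        assert nxt.P == pytest.approx(80.0 * default_params.G_m)
        assert nxt.A == nxt.N == nxt.E == nxt.T == 0.0

    def test_adult_only_state_leaves_sink_unchanged(self, default_params):
        s = w.ColonyState(week=0, P=125.0, A=100, N=0, E=0, T=100)
        assert w.step(s, default_params).T == 100.0

    def test_one_step_matches_hand_calculation(self, default_params):
        """Spreadsheet-style arithmetic for the inoculation state, written
        out independently of the step() code path."""
        p = default_params
        s = inoculation_state()  # P=125, A=T=100, E=N=0
        nxt = w.step(s, p)
        # plant: growth minus damage from 100 adult-equivalents
        assert nxt.P == pytest.approx(125 * 4 ** (1 / 6) - p.beta * 125 * 100)
        # adults: no emergence yet, survival division only
        assert nxt.A == pytest.approx(100 / (1 + 0.565))
        # eggs: saturation factor 125/(31.25+125) = 0.8
        assert nxt.E == pytest.approx(25 * 0.8 * 100 / (1 + 0.30))
        assert nxt.N == 0.0
        assert nxt.T == 100.0

    def test_last_term_denominator_reading(self, default_params):
        p = default_params.replace(denominator_scope="last_term")
        s = w.ColonyState(week=0, P=125.0, A=100, N=40, E=200, T=150)
        nxt = w.step(s, p)
        assert nxt.A == pytest.approx(p.delta * 40 + 100 / (1 + p.mu_A))
        assert nxt.N == pytest.approx(p.gamma * 200 + (1 - p.delta) * 40 / (1 + p.mu_N))

    def test_plant_collapse_clamped_and_flagged(self, default_params):
        p = default_params.replace(beta=1e-2)
        traj = w.simulate(inoculation_state(10000, 125.0), p, 5)
        assert traj.collapsed
        assert all(s.P >= 0 for s in traj)


class TestSimulate:
    def test_zero_weeks_returns_initial_only(self, default_params):
        traj = w.simulate(inoculation_state(), default_params, 0)
        assert len(traj) == 1 and traj.initial == traj.final

    def test_standard_run_exceeds_5000_total_adults(self, standard_run):
        assert standard_run.final.T >= 5000.0

    def test_zero_insect_six_week_fold_is_four(self, default_params):
        traj = w.simulate(inoculation_state(0.0, 125.0), default_params, 6)
        assert traj.final.P / 125.0 == pytest.approx(4.0, rel=0.01)

    def test_zero_insect_area_follows_geometric_law(self, default_params):
        traj = w.simulate(inoculation_state(0.0, 50.0), default_params, 10)
        for s in traj:
            assert s.P == pytest.approx(50.0 * default_params.G_m**s.week, rel=1e-12)

    def test_negative_weeks_rejected(self, default_params):
        with pytest.raises(ValueError):
            w.simulate(inoculation_state(), default_params, -1)


class TestViableAndDead:
    @pytest.mark.parametrize(
        "A,T,expected",
        [(100.0, 100.0, (100.0, 0.0)), (0.0, 500.0, (0.0, 500.0))],
    )
    def test_split(self, A, T, expected):
        s = w.ColonyState(week=0, P=1.0, A=A, N=0, E=0, T=T)
        assert w.viable_and_dead(s) == expected

    def test_state_with_more_viable_than_total_is_invalid(self):
        with pytest.raises(ValueError):
            w.ColonyState(week=0, P=1.0, A=10.0, N=0, E=0, T=5.0)

    def test_dead_count_matches_death_ledger(self, default_params, standard_run):
        """Independent bookkeeping: weekly adult deaths are (A + delta*N) -
        A', and their running sum must equal T - A at every week."""
        p = default_params
        dead_ledger = 0.0
        for prev, nxt in zip(standard_run.states, standard_run.states[1:]):
            dead_ledger += (prev.A + p.delta * prev.N) - nxt.A
            assert nxt.T - nxt.A == pytest.approx(dead_ledger, rel=1e-9)


def naive_recurrence(P, A, N, E, T, p, n_weeks):
    """Independent reimplementation of the weekly map (oracle)."""
    out = [(P, A, N, E, T)]
    for _ in range(n_weeks):
        lay = p.r * P / (p.K + P) * A if P > 0 else 0.0
        P, A, N, E, T = (
            max(P * p.G_m - p.beta * P * (A + E / 4 + N / 2), 0.0),
            (p.delta * N + A) / (1 + p.mu_A),
            (p.gamma * E + (1 - p.delta) * N) / (1 + p.mu_N),
            (lay + (1 - p.gamma) * E) / (1 + p.mu_E),
            T + p.delta * N,
        )
        out.append((P, A, N, E, T))
    return out


class TestInvariants:
    def test_oracle_equivalence_over_random_parameter_draws(self):
        rng = np.random.default_rng(20260922)
        b = w.default_bounds()
        for _ in range(100):
            overrides = {
                name: rng.uniform(*b[name])
                for name in ("mu_A", "delta", "gamma", "mu_N", "mu_E", "beta")
            }
            p = w.default_parameters(overrides)
            traj = w.simulate(inoculation_state(), p, 10)
            oracle = naive_recurrence(125.0, 100.0, 0.0, 0.0, 100.0, p, 10)
            for s, (P, A, N, E, T) in zip(traj, oracle):
                for got, exp in zip((s.P, s.A, s.N, s.E, s.T), (P, A, N, E, T)):
                    assert got == pytest.approx(exp, rel=1e-12, abs=1e-12)

    @given(params_strategy)
    def test_two_week_delay_is_exact(self, p):
        traj = w.simulate(inoculation_state(), p, 2)
        T = traj.series("T")
        assert T[0] == T[1] == T[2] == 100.0

    @given(params_strategy)
    def test_viable_adults_strictly_decrease_through_week_two(self, p):
        traj = w.simulate(inoculation_state(), p, 2)
        A = traj.series("A")
        assert A[0] > A[1] > A[2]

    @given(params_strategy, st.integers(0, 12))
    def test_total_adults_never_decrease(self, p, n_weeks):
        traj = w.simulate(inoculation_state(), p, n_weeks)
        T = traj.series("T")
        assert all(b >= a for a, b in zip(T, T[1:]))

    def test_final_total_monotone_in_inoculum_without_damage(self, default_params):
        p = default_params.replace(beta=0.0)
        finals = [
            w.simulate(inoculation_state(a0, 125.0), p, 7).final.T
            for a0 in (10, 50, 100, 200, 400)
        ]
        assert finals == sorted(finals)

    def test_trajectory_weeks_consecutive_from_zero(self, standard_run):
        assert [s.week for s in standard_run] == list(range(8))
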