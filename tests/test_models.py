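import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hawkdove.game import Action, GameRecord, PayoffMatrix
from hawkdove.models import (
    CoxParams,
    CoxState,
    FSParams,
    SCParams,
    SCState,
    action_probability,
    ces_utility,
    cox_update,
    expected_payoffs,
    fs_utility,
    kindness,
    player_loglik,
    sc_reciprocity,
    sc_update,
    sequence_loglik,
    signed_power,
)

from conftest import record_from_codes
from _oracle import naive_player_loglik


class TestParamBounds:
    def test_fs_joint_constraint(self):
        with pytest.raises(ValueError):
            FSParams(alpha=0.2, beta=0.5)
        with pytest.raises(ValueError):
            FSParams(alpha=2.0, beta=1.0)
        FSParams(alpha=0.5, beta=0.5)  # beta == alpha allowed

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": 0.0},
            {"alpha": 1.2},
            {"beta": -1.5},
            {"gamma": 1.1},
            {"delta": -0.1},
        ],
    )
    def test_cox_sc_bounds(self, kwargs):
        base = {"alpha": 0.9, "beta": 0.0, "gamma": 0.5, "delta": 0.5}
        for cls in (CoxParams, SCParams):
            with pytest.raises(ValueError):
                cls(**{**base, **kwargs})


class TestKindness:
    def test_avoid_is_plus_one_rush_minus_one(self, matrix):
        assert kindness(matrix, Action.AVOID) == pytest.approx(1.0)
        assert kindness(matrix, Action.RUSH) == pytest.approx(-1.0)

    def test_kindness_sums_to_zero_for_any_valid_matrix(self):
        for transfer, crash in [(500, 1000), (300, 900), (100, 150)]:
            m = PayoffMatrix(transfer=transfer, crash_cost=crash)
            total = kindness(m, Action.AVOID) + kindness(m, Action.RUSH)
            assert total == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_matrix_raises(self):
        class Flat:
            def payoff_table(self):
                return np.zeros((2, 2, 2))

        with pytest.raises(ValueError, match="degenerate"):
            kindness(Flat(), Action.AVOID)


class TestExpectedPayoffs:
    def test_zero_history_both_actions(self, matrix):
        # avoiding: (0 + (-500)) / 2; rushing: (500 + (-1000)) / 2
        assert expected_payoffs(matrix, Action.AVOID)[0] == pytest.approx(-250.0)
        assert expected_payoffs(matrix, Action.RUSH)[0] == pytest.approx(-250.0)

    def test_history_is_additive(self, matrix):
        e = expected_payoffs(matrix, Action.AVOID, history=(1000.0, -1000.0))
        assert e[0] == pytest.approx(750.0)
        assert e[1] == pytest.approx(-1000.0 + 250.0)


class TestUtilities:
    def test_fs_equal_totals_gives_own_total(self):
        for alpha, beta in [(0.0, 0.0), (1.0, 0.5), (3.0, 0.9)]:
            assert fs_utility(FSParams(alpha, beta), 10.0, 10.0) == pytest.approx(10.0)

    def test_fs_pure_self_interest_limit(self):
        p = FSParams(0.0, 0.0)
        assert fs_utility(p, 7.0, -3.0) == 7.0
        assert fs_utility(p, -2.0, 5.0) == -2.0

    def test_fs_disadvantageous_penalty(self):
        assert fs_utility(FSParams(0.5, 0.0), 10.0, 20.0) == pytest.approx(5.0)

    def test_ces_weight_zero_ignores_other(self):
        u1 = ces_utility(0.7, 0.0, 2.0, 100.0)
        u2 = ces_utility(0.7, 0.0, 2.0, -50.0)
        assert u1 == pytest.approx(u2)

    def test_ces_linear_limits(self):
        assert ces_utility(1.0, 1.0, 3.0, 4.0) == pytest.approx(7.0)
        assert ces_utility(1.0, -1.0, 3.0, 4.0) == pytest.approx(-1.0)

    def test_ces_rejects_bad_convexity(self):
        with pytest.raises(ValueError):
            ces_utility(0.0, 1.0, 1.0, 1.0)

    def test_signed_power_is_odd(self):
        assert signed_power(-8.0, 1 / 3) == pytest.approx(-2.0)
        assert signed_power(8.0, 1 / 3) == pytest.approx(2.0)
        assert signed_power(0.0, 0.5) == 0.0


class TestStateUpdates:
    def test_cox_accumulate_matches_raw_recursion(self):
        p = CoxParams(alpha=0.5, beta=0.0, gamma=0.5, delta=1.0)
        s = cox_update(CoxState(0.0), p, 1.0, update_rule="accumulate")
        assert s.theta == pytest.approx(1.0)

    def test_cox_smooth_scales_kindness_by_one_minus_gamma(self):
        p = CoxParams(alpha=0.5, beta=0.0, gamma=0.5, delta=1.0)
        s = cox_update(CoxState(0.0), p, 1.0, update_rule="smooth")
        assert s.theta == pytest.approx(0.5)

    def test_rules_coincide_in_memoryless_limit(self):
        p = CoxParams(alpha=0.5, beta=0.3, gamma=0.0, delta=1.0)
        for rule in ("smooth", "accumulate"):
            s = cox_update(CoxState(5.0), p, -1.0, update_rule=rule)
            assert s.theta == pytest.approx(-0.7)

    def test_cox_insensitive_when_delta_zero(self):
        p = CoxParams(alpha=0.5, beta=0.0, gamma=0.7, delta=0.0)
        for f in (-1.0, 1.0):
            assert cox_update(CoxState(0.0), p, f).theta == 0.0

    def test_sc_accumulate_running_sum_at_full_retention(self):
        p = SCParams(alpha=0.5, beta=0.0, gamma=1.0, delta=0.5)
        s = SCState()
        for _ in range(4):  # repeated mutual avoidance
            s = sc_update(s, p, 1.0, 1.0, update_rule="accumulate")
        assert (s.F_self, s.F_other) == (4.0, 4.0)

    def test_sc_smooth_state_stays_bounded_at_high_retention(self):
        p = SCParams(alpha=0.5, beta=0.0, gamma=0.95, delta=0.5)
        s = SCState()
        for _ in range(500):
            s = sc_update(s, p, 1.0, 1.0, update_rule="smooth")
        assert s.F_self == pytest.approx(1.0, abs=1e-6)

    def test_sc_beta_enters_other_ledger_only(self):
        p = SCParams(alpha=0.5, beta=0.5, gamma=0.5, delta=0.5)
        s = sc_update(SCState(), p, 1.0, 1.0, update_rule="accumulate")
        assert (s.F_self, s.F_other) == (1.0, 1.5)

    def test_memoryless_state_forgets_earlier_trials(self):
        p = SCParams(alpha=0.5, beta=0.1, gamma=0.0, delta=0.5)
        s_a = SCState()
        for f in (1.0, -1.0, 1.0):
            s_a = sc_update(s_a, p, f, f)
        s_b = sc_update(SCState(), p, 1.0, 1.0)
        assert (s_a.F_self, s_a.F_other) == (s_b.F_self, s_b.F_other)


class TestReciprocity:
    def test_balanced_delta_is_ledger_difference(self):
        p = SCParams(alpha=0.5, beta=0.0, gamma=0.5, delta=0.5)
        s = SCState(F_self=0.3, F_other=1.1)
        assert sc_reciprocity(s, p) == pytest.approx(1.1 - 0.3)

    def test_equal_ledgers_give_zero(self):
        p = SCParams(alpha=0.5, beta=0.0, gamma=0.5, delta=0.5)
        assert sc_reciprocity(SCState(0.7, 0.7), p) == 0.0

    def test_full_other_weight(self):
        p = SCParams(alpha=0.5, beta=0.0, gamma=0.5, delta=1.0)
        assert sc_reciprocity(SCState(123.0, 0.8), p) == pytest.approx(1.6)


class TestChoiceRule:
    def test_equal_utilities_give_half(self):
        assert action_probability(2.0, 2.0) == pytest.approx(0.5)

    def test_log_three_gap(self):
        assert action_probability(math.log(3.0), 0.0) == pytest.approx(0.75)

    def test_saturation_without_overflow(self):
        assert action_probability(1e6, 0.0) == pytest.approx(1.0)
        assert action_probability(0.0, 1e6) == pytest.approx(0.0)

    @given(st.floats(-50, 50), st.floats(-50, 50))
    @settings(deadline=None, max_examples=50)
    def test_probabilities_are_complementary_and_monotone(self, z1, z2):
        p1 = action_probability(z1, 0.0)
        p2 = action_probability(z2, 0.0)
        assert float(p1) + float(action_probability(0.0, z1)) == pytest.approx(1.0)
        if z1 < z2:
            assert p1 <= p2


def _random_record(rng, n_trials, matrix):
    return GameRecord("r", rng.integers(0, 2, size=(n_trials, 2), dtype=np.int8), matrix=matrix)


def _random_params(rng, model):
    if model == "fs":
        alpha = rng.uniform(0, 5)
        return FSParams(alpha, rng.uniform(0, min(alpha, 0.99)))
    cls = CoxParams if model == "cox" else SCParams
    return cls(rng.uniform(0.05, 1.0), rng.uniform(-1, 1), rng.random(), rng.random())


class TestSequenceLoglik:
    def test_chance_model_hits_closed_form(self, matrix):
        """FS with alpha=beta=0 is a pure expected-own-payoff maximizer; with
        crash = 2 * transfer both actions have equal expected own payoff, so
        every trial is predicted at exactly one half."""
        rng = np.random.default_rng(1)
        rec = _random_record(rng, 100, matrix)
        p = FSParams(0.0, 0.0)
        assert sequence_loglik("fs", p, p, rec, matrix) == pytest.approx(
            200.0 * math.log(0.5), abs=1e-9
        )

    @pytest.mark.parametrize("model", ["fs", "cox", "sc"])
    @pytest.mark.parametrize("rule", ["smooth", "accumulate"])
    def test_matches_naive_replay(self, matrix, model, rule):
        rng = np.random.default_rng(42)
        for _ in range(8):
            rec = _random_record(rng, rng.integers(2, 60), matrix)
            for player in (0, 1):
                params = _random_params(rng, model)
                got = player_loglik(
                    model, params, rec, matrix, player=player, update_rule=rule
                )
                want = naive_player_loglik(
                    model,
                    tuple(params.to_array()),
                    [tuple(a) for a in rec.actions],
                    player=player,
                    update_rule=rule,
                )
                assert got == pytest.approx(want, abs=1e-10)

    def test_joint_loglik_sums_players(self, matrix):
        rng = np.random.default_rng(3)
        rec = _random_record(rng, 40, matrix)
        p1 = _random_params(rng, "sc")
        p2 = _random_params(rng, "sc")
        joint = sequence_loglik("sc", p1, p2, rec, matrix)
        split = player_loglik("sc", p1, rec, matrix, 0) + player_loglik(
            "sc", p2, rec, matrix, 1
        )
        assert joint == pytest.approx(split)
        assert joint <= 0.0

    def test_replay_is_order_sensitive(self, matrix):
        rec = record_from_codes("RARARRAA", "AARRRAAR", matrix)
        perm = GameRecord("perm", rec.actions[::-1].copy(), matrix=matrix)
        p = SCParams(0.9, 0.2, 0.6, 0.8)
        assert sequence_loglik("sc", p, p, rec, matrix) != pytest.approx(
            sequence_loglik("sc", p, p, perm, matrix)
        )

    def test_empty_record_rejected(self, matrix):
        rec = GameRecord("e", np.empty((0, 2), dtype=np.int8), matrix=matrix)
        with pytest.raises(ValueError):
            player_loglik("sc", SCParams(0.5, 0.0, 0.5, 0.5), rec, matrix)

    def test_mismatched_params_rejected(self, matrix, mixed_record):
        with pytest.raises(ValueError):
            sequence_loglik(
                "cox",
                SCParams(0.5, 0.0, 0.5, 0.5),
                SCParams(0.5, 0.0, 0.5, 0.5),
                mixed_record,
                matrix,
            )
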