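import numpy as np
import pytest

from hawkdove.game import count_patterns
from hawkdove.models import SCParams
from hawkdove.reference import pattern_params
from hawkdove.simulate import (
    EnsembleStats,
    SimConfig,
    derive_thresholds,
    linear_trajectory,
    sample_uniform_params,
    simulate_ensemble,
    simulate_nonstationary_pair,
    simulate_pair,
)


@pytest.fixture
def switching_config(matrix):
    p1, p2 = pattern_params("sc", "switching")
    return SimConfig("sc", p1, p2, matrix, n_trials=100, n_sims=500, seed=11)


class TestSimulatePair:
    def test_same_seed_reproduces_exactly(self, switching_config):
        a = simulate_pair(switching_config)
        b = simulate_pair(switching_config)
        assert a == b

    def test_different_seed_changes_play(self, switching_config, matrix):
        a = simulate_pair(switching_config)
        other = SimConfig(
            "sc",
            switching_config.params_1,
            switching_config.params_2,
            matrix,
            n_trials=100,
            seed=12,
        )
        assert a != simulate_pair(other)

    def test_payoffs_realized_from_matrix(self, switching_config, matrix):
        rec = simulate_pair(switching_config)
        assert rec.n_trials == 100
        assert rec.payoffs_consistent(matrix)

    def test_single_trial_game(self, matrix):
        p1, p2 = pattern_params("sc", "switching")
        rec = simulate_pair(SimConfig("sc", p1, p2, matrix, n_trials=1, seed=0))
        assert rec.n_trials == 1
        with pytest.raises(ValueError):
            count_patterns(rec)

    def test_config_validation(self, matrix):
        p1, p2 = pattern_params("sc", "switching")
        with pytest.raises(ValueError):
            SimConfig("nope", p1, p2, matrix)
        with pytest.raises(ValueError):
            SimConfig("cox", p1, p2, matrix)  # sc params under cox name
        with pytest.raises(ValueError):
            SimConfig("sc", p1, p2, matrix, update_rule="bogus")


class TestUniformParams:
    def test_sc_draws_respect_bounds(self):
        rng = np.random.default_rng(0)
        draws = sample_uniform_params("sc", rng, size=5000)
        assert draws.shape == (5000, 4)
        assert (draws[:, 0] > 0).all() and (draws[:, 0] <= 1).all()
        assert (np.abs(draws[:, 1]) <= 1).all()
        assert ((draws[:, 2] >= 0) & (draws[:, 2] <= 1)).all()
        assert ((draws[:, 3] >= 0) & (draws[:, 3] <= 1)).all()

    def test_delta_marginal_mean_is_half(self):
        rng = np.random.default_rng(1)
        draws = sample_uniform_params("sc", rng, size=20000)
        assert draws[:, 3].mean() == pytest.approx(0.5, abs=0.02)

    def test_fs_joint_constraint_always_holds(self):
        rng = np.random.default_rng(2)
        draws = sample_uniform_params("fs", rng, size=5000)
        assert (draws[:, 1] <= draws[:, 0] + 1e-12).all()
        assert (draws[:, 1] < 1.0).all()

    def test_single_draw_is_validated_object(self):
        rng = np.random.default_rng(3)
        p = sample_uniform_params("sc", rng)
        assert isinstance(p, SCParams)


class TestEnsemble:
    def test_stats_shape_and_ranges(self, switching_config):
        st = simulate_ensemble(switching_config)
        assert isinstance(st, EnsembleStats)
        for name in ("switching", "mutual_rush", "mutual_avoid", "unfair"):
            assert 0.0 <= st.means[name] <= 99.0
            assert st.sds[name] >= 0.0

    def test_monte_carlo_reproducibility(self, matrix):
        """Means from two independent ensembles agree within Monte-Carlo error."""
        p1, p2 = pattern_params("sc", "switching")
        a = simulate_ensemble(SimConfig("sc", p1, p2, matrix, 100, 1500, seed=5))
        b = simulate_ensemble(SimConfig("sc", p1, p2, matrix, 100, 1500, seed=6))
        for name in a.means:
            se = max(a.sds[name], b.sds[name]) / np.sqrt(1500)
            assert abs(a.means[name] - b.means[name]) < 3 * np.sqrt(2) * se + 1e-9

    def test_extreme_benevolence_gap_drives_unfair_play(self, matrix):
        """Opposite-extreme benevolence produces more unfair windows than a
        symmetric-benevolence pair with otherwise identical parameters."""
        base = dict(alpha=0.9, gamma=0.5, delta=0.9)
        extreme = SimConfig(
            "sc",
            SCParams(beta=1.0, **base),
            SCParams(beta=-1.0, **base),
            matrix,
            100,
            1000,
            seed=7,
        )
        symmetric = SimConfig(
            "sc",
            SCParams(beta=0.0, **base),
            SCParams(beta=0.0, **base),
            matrix,
            100,
            1000,
            seed=8,
        )
        ue = simulate_ensemble(extreme)
        us = simulate_ensemble(symmetric)
        assert ue.means["unfair"] > us.means["unfair"]

    def test_saturated_benevolent_agents_always_avoid(self, matrix):
        """At beta = +1, delta = 1 and high retention the avoidance loop
        saturates: nearly every window is mutual avoidance with tiny spread."""
        p = SCParams(alpha=0.9, beta=1.0, gamma=0.9, delta=1.0)
        st = simulate_ensemble(SimConfig("sc", p, p, matrix, 100, 500, seed=9))
        assert st.means["mutual_avoid"] > 90.0
        assert st.sds["mutual_avoid"] < 5.0

    def test_requires_two_sims(self, matrix):
        p1, p2 = pattern_params("sc", "switching")
        with pytest.raises(ValueError):
            simulate_ensemble(SimConfig("sc", p1, p2, matrix, 100, 1, seed=0))


class TestNonstationaryPair:
    def test_trajectory_interpolates_endpoints(self):
        tr = linear_trajectory((0.0, 1.0), (1.0, -1.0), 5)
        assert tr.shape == (5, 2)
        assert tr[0].tolist() == [0.0, 1.0]
        assert tr[-1].tolist() == [1.0, -1.0]

    def test_constant_trajectory_matches_fixed_params(self, matrix):
        p = SCParams(0.9, 0.2, 0.5, 0.8)
        tr = linear_trajectory(p.to_array(), p.to_array(), 50)
        a = simulate_nonstationary_pair("sc", tr, tr, matrix, seed=4)
        b = simulate_pair(SimConfig("sc", p, p, matrix, n_trials=50, seed=4))
        assert np.array_equal(a.actions, b.actions)

    def test_shape_mismatch_rejected(self, matrix):
        with pytest.raises(ValueError):
            simulate_nonstationary_pair(
                "sc", np.zeros((10, 4)), np.zeros((9, 4)), matrix
            )


class TestThresholds:
    def test_small_run_is_deterministic_and_valid(self, matrix):
        a = derive_thresholds(4000, n_trials=100, matrix=matrix, seed=21)
        b = derive_thresholds(4000, n_trials=100, matrix=matrix, seed=21)
        assert a == b
        for v in a.as_dict().values():
            assert 1 <= v <= 99

    def test_order_statistic_convergence(self, matrix):
        """Cutoffs stabilize as the simulation count grows."""
        small = derive_thresholds(8000, matrix=matrix, seed=22)
        large = derive_thresholds(32000, matrix=matrix, seed=23)
        for name, v in small.as_dict().items():
            assert abs(v - large.as_dict()[name]) <= 3

    def test_top_order_statistic_quantile(self, matrix):
        """A quantile leaving exactly one game above it returns the maximum."""
        counts = []

        th = derive_thresholds(200, quantile=1.0 - 1.0 / 200, matrix=matrix, seed=24)
        # re-derive the max by brute force with the same seed path
        from hawkdove.simulate import sample_uniform_params, simulate_batch
        from hawkdove.game import count_patterns_batch

        ss = np.random.SeedSequence(24)
        rng = np.random.default_rng(ss.spawn(1)[0])
        p1 = sample_uniform_params("sc", rng, size=200)
        p2 = sample_uniform_params("sc", rng, size=200)
        actions = simulate_batch("sc", p1, p2, 100, matrix, rng=rng)
        counts = count_patterns_batch(actions)
        for name, arr in counts.items():
            assert getattr(th, name) == int(arr.max())

    def test_insufficient_sims_rejected(self, matrix):
        with pytest.raises(ValueError):
            derive_thresholds(10, quantile=0.95, matrix=matrix, seed=0)
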