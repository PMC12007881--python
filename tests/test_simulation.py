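"""Trajectory engine: activities, reached states, transition counts."""

import numpy as np
import pandas as pd
import pytest

from boolnoise import (BNpParams, SDDSParams, SimulationConfig,
                       calc_node_activities, count_pairwise_trans,
                       decode_state, encode_state, evaluate_rule,
                       get_reached_states, parse_network, sample_initial_state)
from boolnoise.exact_markov import (build_transition_matrix, evolve,
                                    marginal_activities, product_distribution,
                                    stationary_distribution)
from boolnoise.fixtures import GeneratorSpec, random_network, random_params

from conftest import SEED


def deterministic_trajectory(net, state, steps):
    out = [np.asarray(state, dtype=int)]
    for _ in range(steps):
        out.append(np.array([evaluate_rule(net, i, out[-1])
                             for i in range(net.n)]))
    return np.array(out)


class TestSampleInitialState:
    def test_degenerate_probabilities(self, rng):
        assert not sample_initial_state(0.0, rng, n=6).any()
        assert sample_initial_state(1.0, rng, n=6).all()

    def test_half_probability_marginals(self, rng, lac):
        draws = 50_000
        batch = sample_initial_state(0.5, rng, n=lac.n, size=draws)
        tol = 3 * np.sqrt(0.25 / draws)
        assert np.all(np.abs(batch.mean(axis=0) - 0.5) < tol)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_initial_state([0.5, 0.5], rng, n=3)


class TestCalcNodeActivities:
    def test_deterministic_run_reports_indicator_rows(self, lac):
        state = np.zeros(13, int)
        params = BNpParams.uniform(lac, 0.0)
        cfg = SimulationConfig(steps=6, repeats=7, seed=SEED,
                               initial_states=[state])
        act = calc_node_activities(lac, params, cfg)
        expected = deterministic_trajectory(lac, state, 6)
        np.testing.assert_array_equal(act.to_numpy(), expected)

    def test_entries_are_multiples_of_one_over_repeats(self, lac):
        params = SDDSParams.uniform(lac, 0.9)
        cfg = SimulationConfig(steps=5, repeats=37, seed=SEED)
        act = calc_node_activities(lac, params, cfg).to_numpy()
        np.testing.assert_allclose(act * 37, np.round(act * 37), atol=1e-9)
        assert ((act >= 0) & (act <= 1)).all()

    def test_last_step_only(self, lac):
        params = SDDSParams.uniform(lac, 0.9)
        full = calc_node_activities(lac, params, SimulationConfig(
            steps=5, repeats=100, seed=SEED))
        last = calc_node_activities(lac, params, SimulationConfig(
            steps=5, repeats=100, seed=SEED, last_step_only=True))
        assert list(last.index) == [5]
        pd.testing.assert_frame_equal(last, full.iloc[[5]], check_names=False)

    def test_seeded_runs_are_bit_reproducible(self, lac):
        params = SDDSParams.uniform(lac, 0.9)
        for scheme in ("sync", "async"):
            cfg = SimulationConfig(steps=5, repeats=200, seed=SEED,
                                   scheme=scheme, update_prob=0.6)
            a = calc_node_activities(lac, params, cfg)
            b = calc_node_activities(lac, params, cfg)
            pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("method", ["bnp", "sdds", "pew"])
    @pytest.mark.parametrize("scheme", ["sync", "async"])
    def test_marginals_match_exact_chain(self, method, scheme):
        """Per-step Monte-Carlo marginals vs the exact transition matrix."""
        net = random_network(GeneratorSpec(n=3, k=2, p_identity=0.1, seed=SEED))
        params = random_params(net, method, (0.1, 0.9), seed=SEED + 1)
        M = build_transition_matrix(net, params, scheme=scheme, update_prob=0.7)
        repeats, steps = 100_000, 5
        cfg = SimulationConfig(steps=steps, repeats=repeats, scheme=scheme,
                               update_prob=0.7, init_prob=0.5, seed=SEED + 2)
        act = calc_node_activities(net, params, cfg).to_numpy()
        pi = product_distribution(0.5, net.n)
        # 4 sigma per cell: family-wise bound across the 108 comparisons
        # this parametrized test performs (6 combos x 6 steps x 3 nodes)
        for t in range(steps + 1):
            exact = marginal_activities(pi, net.n)
            tol = 4 * np.sqrt(exact * (1 - exact) / repeats) + 1e-9
            assert np.all(np.abs(act[t] - exact) < tol), f"step {t}"
            pi = evolve(M, pi, 1)

    def test_monte_carlo_error_shrinks_with_repeats(self):
        net = random_network(GeneratorSpec(n=3, k=2, seed=SEED))
        params = random_params(net, "sdds", (0.2, 0.8), seed=SEED)
        M = build_transition_matrix(net, params)
        pi = product_distribution(0.5, net.n)
        exact = [marginal_activities(pi, net.n)]
        for _ in range(5):
            pi = evolve(M, pi, 1)
            exact.append(marginal_activities(pi, net.n))
        exact = np.array(exact)
        mads = []
        for repeats in (200, 5_000, 50_000):
            act = calc_node_activities(net, params, SimulationConfig(
                steps=5, repeats=repeats, init_prob=0.5, seed=SEED)).to_numpy()
            mads.append(np.abs(act - exact).mean())
        assert mads[2] < mads[1] < mads[0]


class TestGetReachedStates:
    def test_fixed_point_is_absorbing_without_noise(self, lac):
        # all-off inputs lead to the uninduced steady state; find it first
        traj = deterministic_trajectory(lac, np.zeros(13, int), 30)
        fp = traj[-1]
        np.testing.assert_array_equal(
            fp, [evaluate_rule(lac, i, fp) for i in range(13)])
        params = BNpParams.uniform(lac, 0.0)
        cfg = SimulationConfig(steps=4, repeats=11, seed=SEED)
        reached = get_reached_states(lac, params, cfg, initial_states=[fp])
        np.testing.assert_array_equal(reached, np.tile(fp, (11, 1)))

    def test_certain_flip_complements_state(self, negation_loop):
        params = BNpParams.uniform(negation_loop, 1.0)
        cfg = SimulationConfig(steps=1, repeats=9, seed=SEED)
        start = np.array([1, 0])
        reached = get_reached_states(negation_loop, params, cfg,
                                     initial_states=[start])
        np.testing.assert_array_equal(reached, np.tile(1 - start, (9, 1)))

    def test_round_robin_initial_assignment(self, negation_loop):
        params = BNpParams.uniform(negation_loop, 0.0)
        starts = [[0, 0], [0, 1], [1, 0]]
        cfg = SimulationConfig(steps=1, repeats=7, seed=SEED)
        reached = get_reached_states(negation_loop, params, cfg,
                                     initial_states=starts)
        expected = [deterministic_trajectory(negation_loop, s, 1)[-1]
                    for s in starts]
        for r in range(7):
            np.testing.assert_array_equal(reached[r], expected[r % 3])

    def test_long_run_distribution_matches_stationary(self):
        net = random_network(GeneratorSpec(n=3, k=2, seed=SEED))
        params = random_params(net, "sdds", (0.2, 0.8), seed=SEED)
        M = build_transition_matrix(net, params)
        pi = stationary_distribution(M)
        repeats = 50_000
        cfg = SimulationConfig(steps=60, repeats=repeats, init_prob=0.5,
                               seed=SEED)
        reached = get_reached_states(net, params, cfg)
        codes = reached @ (1 << np.arange(net.n))
        freq = np.bincount(codes, minlength=8) / repeats
        tol = 3 * np.sqrt(pi * (1 - pi) / repeats) + 1e-9
        assert np.all(np.abs(freq - pi) < tol)


class TestCountPairwiseTrans:
    def test_deterministic_two_cycle_accounts_for_every_step(self, negation_loop):
        # (0,0) -> (0,1) -> (1,1) -> (1,0) -> (0,0): a deterministic 4-cycle;
        # restrict to a 2-state window of it
        params = BNpParams.uniform(negation_loop, 0.0)
        traj = deterministic_trajectory(negation_loop, [0, 0], 4)
        assert encode_state(traj[4]) == encode_state(traj[0])
        states = [traj[0], traj[1], traj[2], traj[3]]
        cfg = SimulationConfig(steps=12, repeats=5, seed=SEED,
                               initial_states=[traj[0]])
        counts = count_pairwise_trans(negation_loop, params, cfg, states)
        assert counts.to_numpy().sum() == 5 * 12  # chain never leaves the list
        a, b = encode_state(traj[0]), encode_state(traj[1])
        assert counts.loc[a, b] == 15
        assert counts.loc[b, a] == 0

    def test_states_outside_reachable_set_count_zero(self, negation_loop):
        params = BNpParams.uniform(negation_loop, 0.0)
        cfg = SimulationConfig(steps=5, repeats=4, seed=SEED,
                               initial_states=[[0, 0]])
        # trajectory cycles through all four states, but consecutive pairs
        # never stay inside {(0,0),(1,1)} (they are two steps apart)
        counts = count_pairwise_trans(negation_loop, params, cfg,
                                      [[0, 0], [1, 1]])
        assert counts.to_numpy().sum() == 0

    def test_duplicate_states_rejected(self, negation_loop):
        params = BNpParams.uniform(negation_loop, 0.0)
        cfg = SimulationConfig(steps=2, repeats=2, seed=SEED)
        with pytest.raises(ValueError, match="distinct"):
            count_pairwise_trans(negation_loop, params, cfg,
                                 [[0, 0], [0, 0]])

    def test_counts_match_stationary_flux(self):
        """count(a->b)/(R*T) estimates stationary(a) * P(b | a)."""
        net = random_network(GeneratorSpec(n=3, k=2, seed=SEED))
        params = random_params(net, "sdds", (0.2, 0.8), seed=SEED)
        M = build_transition_matrix(net, params)
        pi = stationary_distribution(M)
        all_states = [decode_state(c, 3) for c in range(8)]
        repeats, steps = 2_000, 60
        # start every repeat from the stationary law so fluxes are unbiased
        starts = np.random.default_rng(SEED).choice(8, size=repeats, p=pi)
        cfg = SimulationConfig(steps=steps, repeats=repeats, seed=SEED,
                               initial_states=[decode_state(int(c), 3)
                                               for c in starts])
        counts = count_pairwise_trans(net, params, cfg, all_states)
        total = repeats * steps
        assert counts.to_numpy().sum() == total  # full state list
        for a in range(8):
            for b in range(8):
                flux = pi[a] * M[b, a]
                tol = 3 * np.sqrt(flux * (1 - flux) / total) + 1e-9
                # not exactly stationary start; allow a small transient bias
                assert abs(counts.loc[a, b] / total - flux) < tol + 0.01
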