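"""Imitation rule, elementary updates, full runs: limits, determinism, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import oracle_total_payoff

from pggpunish import (
    ModelParams,
    RunConfig,
    SimulationState,
    Strategy,
    build_group_map,
    build_lattice,
    elementary_update,
    imitation_probability,
    initialize_uniform,
    run,
    simulate,
)
from pggpunish.core import total_payoff


class TestImitationProbability:
    def test_equal_payoffs_give_half(self):
        assert imitation_probability(1.3, 1.3, K=0.5) == pytest.approx(0.5)
        assert imitation_probability(0.0, 0.0, K=10.0) == pytest.approx(0.5)

    def test_infinite_noise_limit(self):
        """K -> inf: strategies copied with probability 1/2 regardless of payoffs."""
        assert imitation_probability(5.0, -5.0, K=1e12) == pytest.approx(0.5, abs=1e-10)

    def test_closed_form_value(self):
        assert imitation_probability(1.0, 0.0, K=0.5) == pytest.approx(
            1 / (1 + np.exp(-2)), abs=1e-9
        )

    def test_zero_noise_limit_is_unconditional_imitation(self):
        assert imitation_probability(1.0, 0.99, K=1e-12) == pytest.approx(1.0)
        assert imitation_probability(0.99, 1.0, K=1e-12) == pytest.approx(0.0)

    def test_nonpositive_noise_rejected(self):
        with pytest.raises(ValueError):
            imitation_probability(1.0, 0.0, K=0.0)

    @given(
        gap=st.floats(0.01, 5.0),
        k1=st.floats(0.01, 10.0),
        k2=st.floats(0.01, 10.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_sharpens_toward_step_as_noise_decreases(self, gap, k1, k2):
        lo, hi = sorted((k1, k2))
        assert imitation_probability(gap, 0.0, lo) >= imitation_probability(
            gap, 0.0, hi
        ) - 1e-12
        # and always favors the better payoff
        assert imitation_probability(gap, 0.0, lo) > 0.5


class TestInitialization:
    def test_balanced_gives_exact_quarters(self):
        topo = build_lattice(100)
        state = initialize_uniform(topo, seed=1, balanced=True)
        assert (state.counts() == 2500).all()

    def test_iid_quarters_in_expectation(self):
        topo = build_lattice(100)
        state = initialize_uniform(topo, seed=2)
        assert state.counts().sum() == 10000
        assert np.allclose(state.counts() / 10000, 0.25, atol=0.02)

    def test_seed_reproducibility(self):
        topo = build_lattice(20)
        a = initialize_uniform(topo, seed=3)
        b = initialize_uniform(topo, seed=3)
        assert (a.strategies == b.strategies).all()

    def test_balanced_requires_divisibility(self):
        with pytest.raises(ValueError, match="divisible"):
            initialize_uniform(build_lattice(3), seed=0, balanced=True)

    def test_strategy_subset(self):
        topo = build_lattice(4)
        state = initialize_uniform(
            topo, seed=4, balanced=True, strategies=(Strategy.C, Strategy.M)
        )
        counts = state.counts()
        assert counts[Strategy.C] == counts[Strategy.M] == 8
        assert counts[Strategy.D] == counts[Strategy.I] == 0


class TestElementaryUpdate:
    def test_uniform_state_is_absorbing(self):
        topo = build_lattice(4)
        gmap = build_group_map(topo)
        params = ModelParams(r=3.0, beta=0.5, gamma=0.5)
        state = SimulationState(
            np.full(16, int(Strategy.D), dtype=np.int8), rng=np.random.default_rng(0)
        )
        for _ in range(50):
            ev = elementary_update(state, topo, gmap, params)
            assert not ev.changed
        assert (state.strategies == int(Strategy.D)).all()

    def test_only_the_chosen_neighbor_may_change(self):
        topo = build_lattice(5)
        gmap = build_group_map(topo)
        params = ModelParams(r=4.4, beta=0.1, gamma=0.1)
        state = initialize_uniform(topo, seed=5)
        for _ in range(200):
            before = state.strategies.copy()
            ev = elementary_update(state, topo, gmap, params)
            diff = np.flatnonzero(before != state.strategies)
            assert len(diff) <= 1
            if len(diff) == 1:
                assert diff[0] == ev.y
                assert ev.y in topo.neighbors[ev.x]

    def test_payoffs_equal_when_only_cooperative_strategies_present(self):
        """No defecting players: C and M payoffs coincide, so w = 1/2 (voter)."""
        topo = build_lattice(4)
        params = ModelParams(r=3.7, beta=0.9, gamma=0.9)
        state = initialize_uniform(
            topo, seed=6, strategies=(Strategy.C, Strategy.M)
        )
        payoffs = [total_payoff(i, state, topo, params) for i in range(16)]
        assert np.allclose(payoffs, payoffs[0])
        assert imitation_probability(payoffs[0], payoffs[1], params.K) == 0.5

    def test_fermi_inputs_match_brute_force_oracle(self):
        """The payoff pair entering the imitation rule on a hand-built torus."""
        topo = build_lattice(3)
        params = ModelParams(r=4.4, beta=0.1, gamma=0.1)
        rng = np.random.default_rng(12)
        strategies = rng.integers(0, 4, 9).astype(np.int8)
        strategies[4] = int(Strategy.D)  # focal x
        strategies[5] = int(Strategy.C)  # its E neighbor y
        pi_x = total_payoff(4, strategies, topo, params)
        pi_y = total_payoff(5, strategies, topo, params)
        assert pi_x == pytest.approx(oracle_total_payoff(4, strategies, topo, params))
        assert pi_y == pytest.approx(oracle_total_payoff(5, strategies, topo, params))
        w = imitation_probability(pi_x, pi_y, params.K)
        w_oracle = 1.0 / (1.0 + np.exp((pi_y - pi_x) / params.K))
        assert w == pytest.approx(w_oracle)

    def test_mutation_uniformizes(self):
        topo = build_lattice(5)
        gmap = build_group_map(topo)
        params = ModelParams(r=3.0, mu=1.0)
        state = SimulationState(
            np.full(25, int(Strategy.D), dtype=np.int8), rng=np.random.default_rng(7)
        )
        for _ in range(400):
            elementary_update(state, topo, gmap, params)
        assert set(np.unique(state.strategies)) == {0, 1, 2, 3}


class TestRun:
    def test_zero_iterations_returns_initial_sample_only(self):
        topo = build_lattice(5)
        params = ModelParams(r=3.0)
        state = initialize_uniform(topo, seed=8)
        counts0 = state.counts().copy()
        traj = run(state, RunConfig(t_max=0), topo, None, params)
        assert traj.times.tolist() == [0]
        assert (traj.counts[0] == counts0).all()

    def test_all_defector_start_is_absorbing(self):
        topo = build_lattice(5)
        params = ModelParams(r=3.0, beta=1.0, gamma=1.0)
        state = SimulationState(np.full(25, int(Strategy.D), dtype=np.int8))
        traj = run(state, RunConfig(t_max=50, seed=0), topo, None, params)
        assert traj.stop_reason == "absorbing"
        assert (traj.fractions[:, Strategy.D] == 1.0).all()
        assert traj.extinctions[Strategy.C] == 0

    @pytest.mark.parametrize("engine", ["numba", "python"])
    def test_bit_identical_under_fixed_seed(self, engine):
        topo = build_lattice(6)
        params = ModelParams(r=4.4, beta=0.1, gamma=0.1)
        trajs = []
        for _ in range(2):
            state = initialize_uniform(topo, seed=10)
            cfg = RunConfig(t_max=10, seed=77)
            trajs.append(run(state, cfg, topo, None, params, engine=engine))
        assert (trajs[0].counts == trajs[1].counts).all()
        assert trajs[0].times.tolist() == trajs[1].times.tolist()

    def test_python_and_numba_engines_agree_statistically(self):
        """Same law: mean final defector fraction matches across engines."""
        topo = build_lattice(5)
        params = ModelParams(r=2.0)  # plain PGG, defection spreads

        def mean_fd(engine, n_rep, base):
            out = []
            for i in range(n_rep):
                state = initialize_uniform(topo, seed=base + i,
                                           strategies=(Strategy.C, Strategy.D))
                cfg = RunConfig(t_max=30, seed=base + 1000 + i)
                traj = run(state, cfg, topo, None, params, engine=engine)
                out.append(traj.fractions[-1, Strategy.D])
            return np.array(out)

        py = mean_fd("python", 25, 0)
        nb = mean_fd("numba", 100, 500)
        se = np.sqrt(py.var() / len(py) + nb.var() / len(nb))
        assert abs(py.mean() - nb.mean()) < 4 * se + 0.02

    def test_counts_change_by_at_most_one_per_update(self):
        topo = build_lattice(5)
        params = ModelParams(r=4.4, beta=0.1, gamma=0.1)
        state = initialize_uniform(topo, seed=11)
        traj = run(state, RunConfig(t_max=20, seed=1), topo, None, params)
        # per iteration (25 updates) counts move by at most 25
        assert (np.abs(np.diff(traj.counts, axis=0)) <= topo.n_players).all()
        assert (traj.counts.sum(axis=1) == topo.n_players).all()

    def test_neutral_voter_regime_is_flagged_and_not_stopped(self):
        topo = build_lattice(6)
        params = ModelParams(r=3.0, beta=0.4, gamma=0.4)
        state = initialize_uniform(topo, seed=12,
                                   strategies=(Strategy.C, Strategy.M))
        traj = run(state, RunConfig(t_max=15, seed=2), topo, None, params)
        if traj.stop_reason == "t_max":  # not yet fixated
            assert traj.neutral_voter_regime

    def test_mutation_recovers_extinct_strategies(self):
        topo = build_lattice(6)
        params = ModelParams(r=3.0, mu=0.05)
        state = SimulationState(np.full(36, int(Strategy.D), dtype=np.int8))
        traj = run(state, RunConfig(t_max=60, seed=3, stop_on_absorbing=False),
                   topo, None, params)
        assert set(np.unique(state.strategies)) == {0, 1, 2, 3} or (
            traj.counts[-1] > 0
        ).sum() > 1

    def test_simulate_convenience_reproducible(self):
        params = ModelParams(r=3.5, beta=0.12, gamma=0.005)
        _, a = simulate(params, 10, 20, seed=5)
        _, b = simulate(params, 10, 20, seed=5)
        assert (a.counts == b.counts).all()

    def test_record_every_thins_samples_but_keeps_endpoints(self):
        params = ModelParams(r=3.5, beta=0.12, gamma=0.005)
        _, traj = simulate(params, 10, 100, seed=6, record_every=25,
                           stop_on_absorbing=False)
        assert traj.times[0] == 0
        assert traj.times[-1] == 100
        assert set(traj.times.tolist()) == {0, 25, 50, 75, 100}
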