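"""Fermi imitation, elementary steps, and full Monte Carlo evolution."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from memgame import _kernel
from memgame.dynamics import (
    DynamicsConfig,
    elementary_step,
    fermi_probability,
    monte_carlo_step,
    run,
)
from memgame.lattice import (
    GameParams,
    LatticeState,
    init_random,
    neighbor_index_table,
)
from memgame.memory import MemoryConfig


class TestFermiProbability:
    def test_equal_payoffs_give_half(self):
        assert fermi_probability(1.7, 1.7, 0.1) == 0.5

    def test_worse_player_readily_imitates(self):
        assert fermi_probability(1.0, 2.0, 0.1) == pytest.approx(1 / (1 + math.exp(-10)))

    @given(x=st.floats(-100, 100), K=st.floats(0.01, 10))
    def test_complementarity(self, x, K):
        assert fermi_probability(x, 0.0, K) + fermi_probability(0.0, x, K) == pytest.approx(1.0)

    def test_stable_at_extreme_payoff_gaps(self):
        with np.errstate(over="raise"):
            lo = fermi_probability(100.0, 0.0, 0.1)   # exponent +1000
            hi = fermi_probability(0.0, 100.0, 0.1)
        assert 0.0 <= lo < 1e-300 and hi == pytest.approx(1.0)

    def test_strictly_decreasing_in_gap(self):
        gaps = np.linspace(-1.5, 1.5, 41)  # beyond |gap|/K ~ 37, W saturates in float64
        vals = [fermi_probability(g, 0.0, 0.1) for g in gaps]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_nonpositive_noise_rejected(self):
        with pytest.raises(ValueError):
            fermi_probability(1.0, 2.0, 0.0)


class TestElementaryStep:
    def test_same_strategy_is_noop(self, scripted_rng_factory):
        state = LatticeState(np.ones((3, 3), dtype=np.int8))
        before = state.strategies.copy()
        event = elementary_step(
            state, GameParams(2.0, -1.0), MemoryConfig(), DynamicsConfig(),
            scripted_rng_factory([0.0, 0.0, 0.0]),
        )
        assert event is None
        assert np.array_equal(state.strategies, before)

    def test_imitation_cannot_create_absent_strategy(self, rng):
        state = LatticeState(np.zeros((4, 4), dtype=np.int8))
        for _ in range(200):
            elementary_step(state, GameParams(1.5, 0.5), MemoryConfig(), DynamicsConfig(), rng)
        assert state.n_cooperators == 0

    def test_adoption_decided_by_fermi_threshold(self, scripted_rng_factory):
        # focal (0,0)=C with one D neighbor below; neighbor draw picks "down"
        grid = np.ones((3, 3), dtype=np.int8)
        grid[1, 0] = 0
        params, dyn = GameParams(1.3, -0.4), DynamicsConfig()
        # hand-computed: P_i = 3R + S = 2.6, P_j = 2T + 0 ... neighbor (1,0)=D
        # has neighbors (0,0)=C,(2,0)=C,(1,2)=C,(1,1)=C -> P_j = 4T = 5.2
        w = 1.0 / (1.0 + math.exp((2.6 - 5.2) / 0.1))
        assert w > 1 - 1e-11
        state = LatticeState(grid.copy())
        ev = elementary_step(state, params, MemoryConfig(), dyn,
                             scripted_rng_factory([0.0, 0.3, w - 1e-12]))
        assert ev.adopted and state.strategies[0, 0] == 0
        state = LatticeState(grid.copy())
        ev = elementary_step(state, params, MemoryConfig(), dyn,
                             scripted_rng_factory([0.0, 0.3, (w + 1) / 2]))
        assert not ev.adopted and state.strategies[0, 0] == 1

    def test_at_most_one_change_per_step(self, rng):
        state = init_random(5, 1)
        for _ in range(100):
            before = state.strategies.copy()
            elementary_step(state, GameParams(1.2, -0.2), MemoryConfig(), DynamicsConfig(), rng)
            assert (state.strategies != before).sum() <= 1


class TestMonteCarloStep:
    def test_event_count_bounded_and_bookkeeping_exact(self, rng):
        state = init_random(8, 2)
        n_c0 = state.n_cooperators
        events = monte_carlo_step(state, GameParams(1.2, -0.2), MemoryConfig(), DynamicsConfig(), rng)
        assert len(events) <= state.n_sites
        gain = sum(1 for e in events if e.adopted and e.subgroup_j.strategy == 1)
        loss = sum(1 for e in events if e.adopted and e.subgroup_j.strategy == 0)
        assert state.n_cooperators - n_c0 == gain - loss
        assert state.time == 1

    def test_homogeneous_state_is_absorbing(self, rng):
        state = LatticeState(np.ones((4, 4), dtype=np.int8))
        for _ in range(5):
            monte_carlo_step(state, GameParams(2.0, -1.0), MemoryConfig(), DynamicsConfig(), rng)
        assert state.n_cooperators == 16


@pytest.mark.parametrize(
    "mem",
    [MemoryConfig(), MemoryConfig("averaged", alpha=0.8), MemoryConfig("delayed", tau=3)],
    ids=["none", "averaged", "delayed"],
)
def test_python_path_matches_kernel(mem):
    """The pure-Python protocol and the compiled kernel agree bit for bit."""
    L, n_mcs = 7, 4
    params, dyn = GameParams(1.4, -0.3), DynamicsConfig()
    seed = 99

    state_py = init_random(L, seed)
    state_nb = state_py.copy()

    rng = np.random.default_rng(7)
    all_draws = [rng.random((L * L, _kernel.N_DRAWS[0 if mem.variant == "none" else
                                                    (1 if mem.variant == "averaged" else 2)]))
                 for _ in range(n_mcs)]

    class Replay:
        def __init__(self, flat):
            self.flat, self.pos = flat, 0

        def random(self, k):
            out = self.flat[self.pos : self.pos + k]
            self.pos += k
            return out

    for d in all_draws:
        monte_carlo_step(state_py, params, mem, dyn, Replay(d.reshape(-1)))

    from memgame.dynamics import _VARIANT_CODE, _ensure_histories

    _ensure_histories(state_nb, mem)
    flat = state_nb.strategies.reshape(-1)
    nbr = neighbor_index_table(L)
    for d in all_draws:
        ref = state_nb.reference_strategies().reshape(-1) if mem.reference_lag else flat
        _kernel.mcs_kernel(
            flat, nbr, params.T, params.S, dyn.K,
            _VARIANT_CODE[mem.variant], mem.alpha, mem.M, mem.weight_denominators(),
            int(mem.tau), mem.nu,
            state_nb.last_payoff, state_nb.has_payoff,
            state_nb.snap_hist, state_nb.snap_head, state_nb.snap_len,
            ref, d, np.zeros(16, dtype=np.int64),
        )
        state_nb.time += 1
        state_nb.push_snapshots()
        state_nb.record_strategies()

    assert np.array_equal(state_py.strategies, state_nb.strategies)
    assert np.array_equal(state_py.snap_hist, state_nb.snap_hist)
    assert np.array_equal(state_py.snap_len, state_nb.snap_len)


class TestRun:
    def test_all_cooperators_stay_fixed(self):
        state = LatticeState(np.ones((10, 10), dtype=np.int8))
        result = run(state, GameParams(1.5, -0.5), MemoryConfig(),
                     DynamicsConfig(relaxation_steps=5, measure_steps=5), rng=0)
        assert result.absorbed == "C" and result.stationary_rho == 1.0

    def test_harsh_dilemma_fixates_to_defection(self):
        for seed in range(3):
            state = init_random(30, seed)
            result = run(state, GameParams(2.0, -1.0), MemoryConfig(),
                         DynamicsConfig(relaxation_steps=500, measure_steps=0), rng=seed)
            assert result.absorbed == "D" and result.stationary_rho == 0.0

    def test_seeded_runs_are_bit_identical(self):
        results = []
        for _ in range(2):
            state = init_random(20, 5)
            results.append(run(state, GameParams(1.1, -0.1),
                               MemoryConfig("averaged", alpha=0.5),
                               DynamicsConfig(relaxation_steps=50, measure_steps=50), rng=5))
        assert np.array_equal(results[0].rho_trajectory, results[1].rho_trajectory)
        assert np.array_equal(results[0].state.strategies, results[1].state.strategies)

    def test_memoryless_limit_equals_baseline(self):
        """alpha = 0 averaging consumes the same draws and yields the same run."""
        outs = []
        for mem in (MemoryConfig(), MemoryConfig("averaged", alpha=0.0)):
            state = init_random(20, 3)
            outs.append(run(state, GameParams(1.2, -0.2), mem,
                            DynamicsConfig(relaxation_steps=100, measure_steps=0), rng=11))
        assert np.array_equal(outs[0].rho_trajectory, outs[1].rho_trajectory)
        assert np.array_equal(outs[0].state.strategies, outs[1].state.strategies)

    def test_observers_called_every_mcs(self):
        calls = []
        state = init_random(10, 0)
        run(state, GameParams(0.5, 0.5), MemoryConfig(),
            DynamicsConfig(relaxation_steps=3, measure_steps=2, stop_at_absorption=False),
            rng=0, observers=[lambda s, t, r: calls.append((t, r))])
        assert [t for t, _ in calls] == [1, 2, 3, 4, 5]

    def test_ledger_matches_cooperator_count_change(self):
        state = init_random(20, 4)
        n_c0 = state.n_cooperators
        result = run(state, GameParams(1.3, -0.1), MemoryConfig("averaged", alpha=0.5),
                     DynamicsConfig(relaxation_steps=200, measure_steps=0), rng=4)
        net = result.ledger.net_cooperator_gain().sum()
        assert result.state.n_cooperators - n_c0 == net
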