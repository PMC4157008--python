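import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peakswarm import (
    SwarmConfig,
    inertia,
    make_gmean_fitness,
    position_update_binary,
    position_update_continuous,
    run_rapso,
    run_standard_pso,
    run_swarm,
    transfer,
    velocity_update,
)
from peakswarm.pso import threshold_ranges


class TestInertia:
    def test_endpoints(self):
        cfg = SwarmConfig(k_max=1000)
        assert inertia(0, cfg) == 0.9
        assert inertia(1000, cfg) == pytest.approx(0.4)

    def test_midpoint(self):
        cfg = SwarmConfig(k_max=1000)
        assert inertia(500, cfg) == pytest.approx(0.65)

    def test_monotone_decrease(self):
        cfg = SwarmConfig(k_max=100)
        vals = [inertia(k, cfg) for k in range(101)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestTransfer:
    def test_zero(self):
        assert transfer(0.0) == 0.0

    def test_known_value(self):
        assert transfer(1.0) == pytest.approx(0.7615941559)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=-18, max_value=18, allow_nan=False))
    def test_even_and_bounded(self, v):
        # float64 tanh saturates to exactly 1.0 only beyond |v| ~ 19
        t = transfer(v)
        assert 0.0 <= t < 1.0
        assert t == transfer(-v)


class TestVelocityUpdate:
    def test_null_attraction_keeps_velocity(self):
        v = np.array([1.0, -2.0])
        out = velocity_update(v, np.zeros(2), np.ones(2), np.ones(2), w=1.0, r1=0.5, r2=0.5, c1=0, c2=0)
        np.testing.assert_array_equal(out, v)

    def test_equilibrium_is_zero(self):
        x = np.array([3.0])
        out = velocity_update(np.array([5.0]), x, x, x, w=0.0, r1=0.7, r2=0.2)
        np.testing.assert_array_equal(out, [0.0])

    def test_hand_computed(self):
        # 0.5*2 + 2*0.5*(1-0) + 2*0.5*(3-0) = 5
        out = velocity_update(
            np.array([2.0]), np.array([0.0]), np.array([1.0]), np.array([3.0]),
            w=0.5, r1=0.5, r2=0.5,
        )
        assert out[0] == pytest.approx(5.0)

    def test_clamping(self):
        out = velocity_update(
            np.array([100.0]), np.array([0.0]), np.array([0.0]), np.array([0.0]),
            w=1.0, r1=0.0, r2=0.0, v_max=np.array([6.0]),
        )
        assert out[0] == 6.0


class TestPositionUpdates:
    def test_continuous_identity(self):
        assert position_update_continuous(1.0, 0.0, 0.0, 30.0) == 1.0

    def test_continuous_clips_high(self):
        assert position_update_continuous(29.0, 5.0, 0.0, 30.0) == 30.0

    def test_continuous_clips_low(self):
        assert position_update_continuous(0.0, -1.0, 0.0, 30.0) == 0.0

    def test_binary_never_flips_at_zero_velocity(self):
        u = np.random.default_rng(0).random(1000)
        bits = np.ones(1000, dtype=int)
        np.testing.assert_array_equal(position_update_binary(bits, np.zeros(1000), u), bits)

    def test_binary_keeps_when_u_at_least_transfer(self):
        assert position_update_binary(1, 3.0, float(transfer(3.0))) == 1

    def test_binary_flips_at_high_velocity(self):
        assert position_update_binary(1, 50.0, 0.1) == 0
        assert position_update_binary(0, -50.0, 0.1) == 1


class TestThresholdRanges:
    def test_category_assignment(self):
        lo, hi = threshold_ranges()
        assert np.all(lo == 0)
        assert list(hi[:5]) == [30.0] * 5
        assert list(hi[5:10]) == [781.25] * 5
        assert list(hi[10:]) == [24.16] * 4

    def test_literal_assignment(self):
        _, hi = threshold_ranges(literal=True)
        assert list(hi[5:12]) == [781.25] * 7
        assert list(hi[12:]) == [24.16] * 2


@pytest.fixture(scope="module")
def tiny_problem(separable):
    # trimmed copy of the separable fixture for fast swarm runs
    return separable.train_features[:400], separable.train_labels[:400]


@pytest.mark.parametrize("algorithm", ["synchronous", "random_asynchronous"])
class TestSwarmRuns:
    def run(self, F, y, algorithm, **kw):
        runner = run_standard_pso if algorithm == "synchronous" else run_rapso
        cfg = SwarmConfig(algorithm=algorithm, **kw)
        return runner(F, y, cfg)

    def test_seeded_runs_bit_identical(self, tiny_problem, algorithm):
        F, y = tiny_problem
        m1, h1 = self.run(F, y, algorithm, n_particles=10, k_max=40, seed=11)
        m2, h2 = self.run(F, y, algorithm, n_particles=10, k_max=40, seed=11)
        np.testing.assert_array_equal(h1, h2)
        np.testing.assert_array_equal(m1.mask, m2.mask)
        np.testing.assert_array_equal(m1.thresholds, m2.thresholds)

    def test_gbest_history_non_decreasing(self, tiny_problem, algorithm):
        F, y = tiny_problem
        _, h = self.run(F, y, algorithm, n_particles=10, k_max=60, seed=5)
        assert len(h) == 61
        assert np.all(np.diff(h) >= 0)

    def test_kmax_zero_returns_best_of_initial_population(self, tiny_problem, algorithm):
        F, y = tiny_problem
        _, h = self.run(F, y, algorithm, n_particles=10, k_max=0, seed=5)
        assert len(h) == 1

    def test_positions_and_velocities_stay_in_bounds(self, tiny_problem, algorithm):
        F, y = tiny_problem
        cfg = SwarmConfig(algorithm=algorithm, n_particles=8, k_max=50, seed=2)
        state = run_swarm(make_gmean_fitness(F, y), cfg)
        assert np.all(state.cont >= cfg.lo) and np.all(state.cont <= cfg.hi)
        assert np.all(np.abs(state.vel) <= cfg.v_max + 1e-12)
        assert np.isin(state.bits, [0, 1]).all()

    def test_empty_training_set_rejected(self, tiny_problem, algorithm):
        runner = run_standard_pso if algorithm == "synchronous" else run_rapso
        cfg = SwarmConfig(algorithm=algorithm, n_particles=5, k_max=5)
        with pytest.raises(ValueError):
            runner(np.empty((0, 14)), np.empty(0), cfg)

    def test_fixed_mask_freezes_binary_half(self, tiny_problem, algorithm):
        F, y = tiny_problem
        mask = np.zeros(14, dtype=bool)
        mask[[4, 5, 10, 11]] = True
        cfg = SwarmConfig(algorithm=algorithm, n_particles=8, k_max=40, seed=3, fixed_mask=mask)
        state = run_swarm(make_gmean_fitness(F, y), cfg)
        assert np.all(state.bits == mask.astype(int))
        assert np.array_equal(state.gbest_bits.astype(bool), mask)


def test_rapso_single_particle_degenerates_sequentially(tiny_problem):
    F, y = tiny_problem
    cfg = SwarmConfig(algorithm="random_asynchronous", n_particles=1, k_max=30, seed=9)
    model, h = run_rapso(F, y, cfg)
    assert len(h) == 31
    assert np.all(np.diff(h) >= 0)


def test_mismatched_algorithm_rejected(tiny_problem):
    F, y = tiny_problem
    cfg = SwarmConfig(algorithm="random_asynchronous", n_particles=4, k_max=2)
    with pytest.raises(ValueError):
        run_standard_pso(F, y, cfg)


@pytest.mark.parametrize("algorithm", ["synchronous", "random_asynchronous"])
def test_unimodal_continuous_convergence(algorithm):
    """Sanity harness: with the mask frozen away and a smooth unimodal
    objective over 3 continuous dims, both schedules reach within 1e-2 of the
    optimum in <= 500 iterations for >= 9/10 seeds."""
    target = np.array([3.0, 7.5, 1.2])
    lo, hi = np.zeros(3), np.full(3, 10.0)

    def fitness(bits, th):
        return 1.0 / (1.0 + float(np.sum((th - target) ** 2)))

    hits = 0
    for seed in range(10):
        cfg = SwarmConfig(
            algorithm=algorithm, n_particles=15, k_max=500, n_bits=0,
            lo=lo, hi=hi, seed=seed,
        )
        state = run_swarm(fitness, cfg)
        if state.gbest_score >= 1.0 - 1e-2:
            hits += 1
    assert hits >= 9
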