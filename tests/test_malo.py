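"""Unit and property tests of the binary modified ant lion optimizer."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hldamalo.malo import (
    MALOConfig,
    MALOError,
    binarize,
    crossover,
    levy_step,
    normalize_walk,
    random_walk,
    roulette_select,
    run_malo,
    shrink_bounds,
    stochastic_step,
)


class TestStochasticStep:
    @pytest.mark.parametrize("rdm,expected", [(0.7, 1), (0.5, 0), (0.0, 0), (1.0, 1), (0.5000001, 1)])
    def test_threshold_at_half(self, rdm, expected):
        assert stochastic_step(rdm) == expected

    @pytest.mark.parametrize("rdm", [-0.1, 1.1])
    def test_out_of_range_rejected(self, rdm):
        with pytest.raises(ValueError):
            stochastic_step(rdm)


class TestRandomWalk:
    def test_all_up_steps(self):
        class HighRng:
            def random(self, n):
                return np.full(n, 0.9)

        np.testing.assert_array_equal(random_walk(4, HighRng()), [0, 1, 2, 3, 4])

    def test_all_down_steps(self):
        class LowRng:
            def random(self, n):
                return np.full(n, 0.1)

        np.testing.assert_array_equal(random_walk(3, LowRng()), [0, -1, -2, -3])

    def test_rejects_zero_steps(self):
        with pytest.raises(ValueError):
            random_walk(0, np.random.default_rng(0))

    def test_endpoint_moments_match_simple_walk(self):
        """Mean and variance of the endpoint follow the ±1 walk closed form
        (mean 0, variance n)."""
        n = 25
        rng = np.random.default_rng(42)
        ends = np.array([random_walk(n, rng)[-1] for _ in range(10_000)])
        assert abs(ends.mean()) < 3 * np.sqrt(n) / 100  # 3 sigma of the MC mean
        assert ends.var() == pytest.approx(n, rel=0.05)


class TestShrinkBounds:
    @pytest.mark.parametrize(
        "frac,omega",
        [(0.05, 1), (0.2, 2), (0.51, 3), (0.76, 4), (0.91, 5), (0.96, 6), (1.0, 6)],
    )
    def test_omega_schedule(self, frac, omega):
        K = 100
        assert shrink_bounds(int(frac * K), K, -1, 1).omega == omega

    def test_no_shrink_before_one_tenth(self):
        b = shrink_bounds(5, 100, -1.0, 1.0)
        assert b.shrink == 1.0
        assert b.r == -1.0 and b.t == 1.0

    def test_late_shrink_value(self):
        # k/K = 0.96 -> omega 6 -> J = 1e6 * 0.96
        b = shrink_bounds(96, 100, -1.0, 1.0)
        assert b.shrink == pytest.approx(960_000.0)
        assert b.r == pytest.approx(-1.0 / 960_000.0)

    def test_shrink_monotone_in_k(self):
        K = 200
        J = [shrink_bounds(k, K, -1, 1).shrink for k in range(1, K + 1)]
        assert all(a <= b for a, b in zip(J, J[1:]))

    @pytest.mark.parametrize("k", [0, 101])
    def test_iteration_out_of_range(self, k):
        with pytest.raises(ValueError):
            shrink_bounds(k, 100, -1, 1)


class TestNormalizeWalk:
    def test_identity_shaped_map(self):
        np.testing.assert_allclose(normalize_walk([0, 1, 2], 0, 1), [0, 0.5, 1])

    def test_affine_map_hand_case(self):
        np.testing.assert_allclose(normalize_walk([-3, -1, 1], -1, 1), [-1, 0, 1])

    def test_constant_walk_maps_to_midpoint(self):
        np.testing.assert_allclose(normalize_walk([2, 2, 2], -1, 3), [1, 1, 1])

    def test_degenerate_bounds(self):
        np.testing.assert_allclose(normalize_walk([0, 1, 5], 0.5, 0.5), [0.5, 0.5, 0.5])

    @given(st.lists(st.integers(-50, 50), min_size=2, max_size=30))
    @settings(deadline=None, derandomize=True)
    def test_output_within_bounds(self, walk):
        out = normalize_walk(np.asarray(walk, dtype=float), -0.5, 2.0)
        assert out.min() >= -0.5 - 1e-12 and out.max() <= 2.0 + 1e-12


class TestLevyStep:
    def test_zero_alpha_is_identity(self):
        pos = np.array([0.3, -1.2, 5.0])
        out = levy_step(pos, 0.0, 1.5, np.random.default_rng(0))
        np.testing.assert_array_equal(out, pos)

    def test_rejects_nonfinite_position(self):
        with pytest.raises(ValueError):
            levy_step(np.array([np.nan]), 1.0, 1.5, np.random.default_rng(0))

    def test_tail_exponent(self):
        """P(|L| > x) decays as x^-lambda: log-log slope within 0.3 of -1.5
        over x in [10, 100]."""
        rng = np.random.default_rng(7)
        zero = np.zeros(100_000)
        steps = levy_step(zero, 1.0, 1.5, rng)
        xs = np.logspace(1, 2, 10)
        surv = np.array([(np.abs(steps) > x).mean() for x in xs])
        slope = np.polyfit(np.log(xs), np.log(surv), 1)[0]
        assert abs(slope - (-1.5)) < 0.3


class TestBinarize:
    def test_zero_position_never_sets_bit(self):
        rng = np.random.default_rng(0)
        bits = binarize(np.zeros(10_000), rng)
        assert bits.sum() == 0

    def test_large_position_always_sets_bit(self):
        rng = np.random.default_rng(0)
        bits = binarize(np.full(10_000, 50.0), rng)
        assert bits.sum() == 10_000

    def test_acceptance_probability_matches_tanh(self):
        rng = np.random.default_rng(3)
        bits = binarize(np.ones(100_000), rng)
        assert bits.mean() == pytest.approx(np.tanh(1.0), abs=0.01)


class TestRouletteSelect:
    def test_single_candidate(self):
        rng = np.random.default_rng(0)
        assert all(roulette_select([2.5], rng) == 0 for _ in range(10))

    def test_equal_fitness_is_uniform(self):
        rng = np.random.default_rng(1)
        draws = np.array([roulette_select([1.0, 1.0, 1.0, 1.0], rng) for _ in range(100_000)])
        freq = np.bincount(draws, minlength=4) / draws.size
        sigma = np.sqrt(0.25 * 0.75 / draws.size)
        assert np.all(np.abs(freq - 0.25) < 3 * sigma)

    def test_lower_fitness_selected_more(self):
        rng = np.random.default_rng(2)
        draws = np.array([roulette_select([0.0, 1.0], rng) for _ in range(100_000)])
        assert (draws == 0).sum() > (draws == 1).sum()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            roulette_select([], np.random.default_rng(0))


class TestCrossover:
    def test_identical_parents(self):
        a = np.array([1, 0, 1, 1], dtype=np.int8)
        child = crossover(a, a.copy(), 0.5, np.random.default_rng(0))
        np.testing.assert_array_equal(child, a)

    def test_mean_inheritance_rate(self):
        rng = np.random.default_rng(5)
        a = np.zeros(4, dtype=np.int8)
        b = np.ones(4, dtype=np.int8)
        weights = [crossover(a, b, 0.5, rng).sum() for _ in range(10_000)]
        assert np.mean(weights) == pytest.approx(2.0, abs=0.15)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            crossover(np.zeros(3), np.zeros(4), 0.5, np.random.default_rng(0))

    @given(st.integers(0, 2**10 - 1), st.integers(0, 2**10 - 1), st.integers(0, 1000))
    @settings(deadline=None, derandomize=True)
    def test_child_bits_come_from_parents(self, ia, ib, seed):
        a = np.array([(ia >> j) & 1 for j in range(10)], dtype=np.int8)
        b = np.array([(ib >> j) & 1 for j in range(10)], dtype=np.int8)
        child = crossover(a, b, 0.5, np.random.default_rng(seed))
        assert np.all((child == a) | (child == b))


class TestRunMalo:
    def test_hamming_target_recovered(self):
        target = np.array([1, 0, 1, 1, 0, 0, 1, 0], dtype=np.int8)
        hits = 0
        for seed in range(10):
            cfg = MALOConfig(n_ants=20, n_dims=8, max_iters=100, seed=seed)
            res = run_malo(lambda m: float(np.sum(m != target)), cfg)
            hits += bool(np.array_equal(res.best_mask, target))
        assert hits >= 9

    def test_popcount_reaches_empty_mask(self):
        hits = 0
        for seed in range(10):
            cfg = MALOConfig(n_ants=20, n_dims=10, max_iters=200, seed=seed)
            res = run_malo(lambda m: float(np.sum(m)), cfg)
            hits += res.best_fitness == 0.0
        assert hits >= 9

    def test_constant_fitness(self):
        cfg = MALOConfig(n_ants=5, n_dims=6, max_iters=10, seed=0)
        res = run_malo(lambda m: 3.0, cfg)
        assert set(np.unique(res.best_mask)) <= {0, 1}
        assert np.all(res.elite_history == 3.0)

    def test_nonfinite_fitness_names_mask(self):
        cfg = MALOConfig(n_ants=3, n_dims=4, max_iters=5, seed=0)
        with pytest.raises(MALOError, match="mask"):
            run_malo(lambda m: float("nan"), cfg)

    def test_seed_determinism(self):
        cfg = MALOConfig(n_ants=8, n_dims=12, max_iters=30, seed=11)
        f = lambda m: float(np.sum(m) + 0.1 * np.sum(m[::2]))
        r1 = run_malo(f, cfg)
        r2 = run_malo(f, cfg)
        np.testing.assert_array_equal(r1.best_mask, r2.best_mask)
        np.testing.assert_array_equal(r1.elite_history, r2.elite_history)
        assert r1.evaluations == r2.evaluations

    def test_binary_closure_and_elitism(self):
        """Masks stay binary, elite history never increases, and the final
        fitness matches the recorded minimum."""
        seen = []

        def f(mask):
            assert set(np.unique(mask)) <= {0, 1}
            val = float(np.dot(mask, [3, -2, 1, -5, 4, -1]))
            seen.append(val)
            return val

        cfg = MALOConfig(n_ants=10, n_dims=6, max_iters=50, seed=4)
        res = run_malo(f, cfg)
        assert np.all(np.diff(res.elite_history) <= 0)
        assert res.best_fitness == res.elite_history[-1]
        assert res.best_fitness == min(seen)
        assert res.evaluations == len(seen)

    def test_elitism_randomized_property_suite(self):
        """Elite history is non-increasing in each of 100 randomized runs."""
        meta = np.random.default_rng(2024)
        for _ in range(100):
            d = int(meta.integers(3, 9))
            w = meta.normal(size=d)
            cfg = MALOConfig(
                n_ants=int(meta.integers(2, 8)),
                n_dims=d,
                max_iters=int(meta.integers(1, 15)),
                seed=int(meta.integers(0, 2**31 - 1)),
            )
            res = run_malo(lambda m: float(w @ m), cfg)
            assert np.all(np.diff(res.elite_history) <= 0)

    def test_matches_exhaustive_optimum_on_weighted_linear(self):
        w = np.array([3, -2, 1, -5, 4, -1, 2, -3, 0.5, -0.25])
        masks = np.array(list(itertools.product([0, 1], repeat=10)))
        opt = (masks @ w).min()
        hits = 0
        for seed in range(10):
            cfg = MALOConfig(n_ants=20, n_dims=10, max_iters=100, seed=seed)
            res = run_malo(lambda m: float(w @ m), cfg)
            hits += res.best_fitness == pytest.approx(opt)
        assert hits >= 9


class TestMALOConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_ants": 1},
            {"max_iters": 0},
            {"crossover_rate": 1.5},
            {"levy_exponent": 0.0},
            {"levy_exponent": 2.5},
            {"walk_bounds": (1.0, -1.0)},
            {"levy_alpha": -0.5},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        base = dict(n_ants=4, n_dims=5, max_iters=10)
        base.update(kwargs)
        with pytest.raises(ValueError):
            MALOConfig(**base)
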