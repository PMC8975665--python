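"""Unit and property tests for the hypercube optimization search core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hosmlp.hos import (
    BoundsError,
    DegenerateDimensionError,
    DimensionError,
    EvaluationError,
    HOSConfig,
    Hypercube,
    evaluate_population,
    hos_minimize,
    init_hypercube,
    local_search,
    mean_point_fitness,
    normalized_displacement,
    rastrigin,
    rosenbrock,
    sample_population,
    shrink_factor,
    sphere,
    update_center,
    update_hypercube,
)


class TestInitHypercube:
    @pytest.mark.parametrize(
        "lower,upper,center,half",
        [
            ([0, 0], [2, 4], [1, 2], [1, 2]),
            ([1], [1], [1], [0]),
            ([-1, -1, -1], [1, 1, 1], [0, 0, 0], [1, 1, 1]),
        ],
    )
    def test_center_and_half_size(self, lower, upper, center, half):
        hc = init_hypercube(lower, upper)
        np.testing.assert_allclose(hc.center, center)
        np.testing.assert_allclose(hc.half_size, half)
        np.testing.assert_allclose(hc.global_lower, lower)
        np.testing.assert_allclose(hc.global_upper, upper)

    def test_mismatched_lengths(self):
        with pytest.raises(DimensionError):
            init_hypercube([0, 0], [1])

    def test_inverted_bounds(self):
        with pytest.raises(BoundsError):
            init_hypercube([0, 2], [1, 1])

    def test_hypercube_invariants_enforced(self):
        with pytest.raises(BoundsError):
            Hypercube([0.0], [-1.0], [-5.0], [5.0])
        with pytest.raises(BoundsError):
            # centered far outside the global box with zero half-size
            Hypercube([100.0], [0.0], [-5.0], [5.0])


class TestSamplePopulation:
    def test_default_population_shape_and_bounds(self, rng):
        hc = init_hypercube([-10.0] * 10, [10.0] * 10)
        pts = sample_population(hc, 70, rng)
        assert pts.shape == (70, 10)
        assert np.all(pts >= -10) and np.all(pts <= 10)

    def test_zero_width_box_collapses_to_center(self, rng):
        hc = init_hypercube([3.0, -2.0], [3.0, -2.0])
        pts = sample_population(hc, 5, rng)
        np.testing.assert_allclose(pts, np.tile([3.0, -2.0], (5, 1)))

    def test_reproducible_given_same_seed(self):
        hc = init_hypercube([-1.0, -1.0], [1.0, 1.0])
        a = sample_population(hc, 8, np.random.default_rng(42))
        b = sample_population(hc, 8, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_clamped_to_global_bounds(self, rng):
        hc = Hypercube([0.9], [0.5], [-1.0], [1.0])
        pts = sample_population(hc, 200, rng)
        assert pts.max() <= 1.0


class TestEvaluatePopulation:
    def test_hand_arithmetic(self):
        pop = evaluate_population([[0.0], [1.0], [2.0]], lambda x: float(x[0] ** 2))
        np.testing.assert_allclose(pop.fitness, [0, 1, 4])
        assert pop.best_index == 0
        assert pop.best_fitness == 0.0

    def test_tie_breaks_to_lowest_index(self):
        pop = evaluate_population([[5.0], [1.0], [1.0]], lambda x: float(abs(x[0])))
        assert pop.best_index == 1

    def test_constant_objective(self):
        pop = evaluate_population(np.zeros((4, 2)), lambda x: 3.5)
        assert pop.best_fitness == 3.5

    def test_non_finite_value_reports_row(self):
        def bad(x):
            return math.nan if x[0] > 0.5 else 0.0

        with pytest.raises(EvaluationError) as err:
            evaluate_population([[0.0], [1.0]], bad)
        assert err.value.row_index == 1

    def test_best_point_matches_best_row(self, rng):
        pts = rng.normal(size=(30, 3))
        pop = evaluate_population(pts, sphere)
        np.testing.assert_array_equal(pop.best_point, pts[pop.best_index])
        assert pop.best_fitness == pop.fitness.min()


class TestLocalSearch:
    def test_rate_zero_is_identity(self):
        x = np.array([1.0, 2.0])
        out = local_search(x, sphere, 0.0, 0.01)
        np.testing.assert_array_equal(out, x)

    def test_descends_on_quadratic(self):
        obj = lambda v: float((v[0] - 3.0) ** 2)
        out = local_search(np.array([2.9]), obj, 0.5, 0.01, half_size=np.array([1.0]))
        assert obj(out) <= 0.01
        assert obj(out) <= obj(np.array([2.9]))

    def test_stationary_point_unchanged(self):
        # constant objective has exactly zero estimated slope everywhere
        x = np.array([0.5, -0.5])
        out = local_search(x, lambda v: 1.0, 0.5, 0.01)
        np.testing.assert_array_equal(out, x)

    def test_never_worsens(self, rng):
        for _ in range(10):
            x = rng.uniform(-2, 2, size=3)
            out = local_search(x, rastrigin, 0.5, 0.01, half_size=np.ones(3))
            assert rastrigin(out) <= rastrigin(x)

    def test_result_respects_bounds(self):
        out = local_search(
            np.array([4.9]),
            lambda v: float((v[0] - 100.0) ** 2),
            1.0,
            0.01,
            half_size=np.array([5.0]),
            lower=np.array([-5.0]),
            upper=np.array([5.0]),
        )
        assert out[0] <= 5.0


class TestUpdateCenter:
    def test_midpoint(self):
        np.testing.assert_allclose(
            update_center([2.0, 2.0], [0.0, 0.0]), [1.0, 1.0]
        )

    def test_fixed_point(self):
        c = np.array([1.5, -2.5])
        np.testing.assert_array_equal(update_center(c, c), c)

    def test_geometric_convergence_to_target(self):
        target = np.array([4.0, -2.0])
        center = np.zeros(2)
        prev_dist = np.linalg.norm(target - center)
        for _ in range(20):
            center = update_center(target, center)
            dist = np.linalg.norm(target - center)
            assert dist == pytest.approx(prev_dist / 2)
            prev_dist = dist
        assert prev_dist < 1e-5

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            update_center([1.0], [1.0, 2.0])


class TestNormalizedDisplacement:
    def test_sentinel_when_not_displaced(self):
        assert normalized_displacement([9.0], [0.0], [0.0], [1.0], 1, False) == 1.0

    def test_zero_when_best_did_not_move(self):
        x = np.array([0.3, -0.7])
        d = normalized_displacement(x, x, [0.0, 0.0], [2.0, 2.0], 2, True)
        assert d == 0.0

    def test_hand_computed_example(self):
        # x_n = [0.5, 0.5], x_min_n = [0, 0], d_n = sqrt(0.5), d_nn = sqrt(0.5)/2
        d = normalized_displacement([1.0, 1.0], [0.0, 0.0], [0.0, 0.0], [2.0, 2.0], 2, True)
        assert d == pytest.approx(math.sqrt(0.5) / 2.0)

    def test_degenerate_interval_raises(self):
        with pytest.raises(DegenerateDimensionError):
            normalized_displacement([1.0], [0.0], [0.0], [0.0], 1, True)

    @given(
        st.lists(st.floats(-5, 5), min_size=2, max_size=5),
        st.lists(st.floats(-5, 5), min_size=2, max_size=5),
    )
    @settings(max_examples=50, deadline=None)
    def test_nonnegative(self, a, b):
        m = min(len(a), len(b))
        a, b = a[:m], b[:m]
        d = normalized_displacement(a, b, np.zeros(m), np.ones(m), m, True)
        assert d >= 0.0


class TestShrinkFactor:
    def test_zero_displacement_gives_strongest_contraction(self):
        assert shrink_factor(0.0) == pytest.approx(0.8)

    def test_unit_displacement(self):
        assert shrink_factor(1.0) == pytest.approx(1.0 - 0.2 * math.exp(-3.0))

    def test_limit_approaches_one_from_below(self):
        assert shrink_factor(50.0) < 1.0
        assert shrink_factor(50.0) > 0.999999

    @given(st.floats(0, 100), st.floats(0, 100))
    @settings(max_examples=100, deadline=None)
    def test_range_and_weak_monotonicity(self, a, b):
        sa, sb = shrink_factor(a), shrink_factor(b)
        assert 0.8 <= sa < 1.0
        if a < b:
            assert sa <= sb

    @given(st.floats(0, 10), st.floats(0, 10))
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing_where_floats_resolve(self, a, b):
        # beyond d_nn ~ 12 the exponential underflows below float resolution
        if a < b and b - a > 1e-12:
            assert shrink_factor(a) < shrink_factor(b)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            shrink_factor(-0.1)


class TestUpdateHypercube:
    def test_full_shrink_at_zero_displacement(self):
        hc = init_hypercube([-2.0, -2.0], [2.0, 2.0])
        out = update_hypercube(hc, [0.5, 0.5], 0.0)
        np.testing.assert_allclose(out.half_size, [1.6, 1.6])

    def test_sentinel_leaves_size_unchanged(self):
        hc = init_hypercube([-2.0, -2.0], [2.0, 2.0])
        out = update_hypercube(hc, [0.5, 0.5], 1.0)
        np.testing.assert_allclose(out.half_size, hc.half_size)

    def test_center_moves_to_best(self):
        hc = init_hypercube([-2.0], [2.0])
        out = update_hypercube(hc, [1.25], 0.3)
        np.testing.assert_allclose(out.center, [1.25])

    @given(st.floats(0, 3))
    @settings(max_examples=50, deadline=None)
    def test_half_size_never_increases(self, d_nn):
        hc = init_hypercube([-1.0, -1.0], [1.0, 1.0])
        out = update_hypercube(hc, [0.0, 0.0], d_nn)
        assert np.all(out.half_size <= hc.half_size)


class TestMeanPointFitness:
    def test_degenerate_midpoint(self):
        x = np.array([2.0])
        assert mean_point_fitness(x, x, sphere) == pytest.approx(4.0)

    def test_quadratic_midpoint(self):
        assert mean_point_fitness([2.0], [0.0], sphere) == pytest.approx(1.0)

    def test_linear_objective_averages_endpoints(self):
        lin = lambda v: float(3.0 * v[0] + 1.0)
        a, b = np.array([2.0]), np.array([6.0])
        assert mean_point_fitness(a, b, lin) == pytest.approx((lin(a) + lin(b)) / 2.0)


class TestHosMinimize:
    def test_one_dimensional_quadratic(self):
        obj = lambda v: float((v[0] - 3.0) ** 2)
        best, best_f, trace = hos_minimize(obj, [-10.0], [10.0], HOSConfig(seed=3))
        assert abs(best[0] - 3.0) < 1e-3

    def test_constant_objective_stops_on_fitness_tolerance(self):
        best, best_f, trace = hos_minimize(
            lambda v: 2.0, [-1.0] * 3, [1.0] * 3, HOSConfig(seed=0)
        )
        assert trace.termination_reason == "tol_fitness"
        assert trace.iterations_run < 250
        assert best_f == 2.0

    def test_traces_are_monotone(self):
        _, _, trace = hos_minimize(
            rosenbrock, [-5.0] * 4, [5.0] * 4, HOSConfig(seed=11)
        )
        fit = trace.best_fitness_per_iteration
        half = trace.hypercube_half_size_norm_per_iteration
        assert np.all(np.diff(fit) <= 0)
        assert np.all(np.diff(half) <= 1e-12)

    def test_fixed_seed_reproduces_trace_exactly(self):
        runs = [
            hos_minimize(sphere, [-10.0] * 5, [10.0] * 5, HOSConfig(seed=99))
            for _ in range(2)
        ]
        (x1, f1, t1), (x2, f2, t2) = runs
        np.testing.assert_array_equal(x1, x2)
        assert f1 == f2
        np.testing.assert_array_equal(
            t1.best_fitness_per_iteration, t2.best_fitness_per_iteration
        )
        np.testing.assert_array_equal(t1.dnn_per_iteration, t2.dnn_per_iteration)

    def test_matches_grid_search_oracle_on_2d_quadratic(self):
        obj = lambda v: float((v[0] - 1.2) ** 2 + 2.0 * (v[1] + 2.4) ** 2)
        # independent oracle: dense grid over the same box
        axis = np.linspace(-5.0, 5.0, 201)  # resolution 0.05
        gx, gy = np.meshgrid(axis, axis, indexing="ij")
        vals = (gx - 1.2) ** 2 + 2.0 * (gy + 2.4) ** 2
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        oracle_argmin = np.array([axis[i], axis[j]])

        best, _, _ = hos_minimize(obj, [-5.0, -5.0], [5.0, 5.0], HOSConfig(seed=5))
        assert np.all(np.abs(best - oracle_argmin) <= 0.05)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(BoundsError):
            hos_minimize(sphere, [1.0], [0.0], HOSConfig(seed=0))

    def test_final_trace_value_equals_returned_fitness(self):
        _, best_f, trace = hos_minimize(
            sphere, [-2.0] * 3, [2.0] * 3, HOSConfig(seed=21)
        )
        assert trace.best_fitness_per_iteration[-1] == best_f


class TestBuiltinObjectives:
    def test_known_minima(self):
        assert sphere(np.zeros(6)) == 0.0
        assert rosenbrock(np.ones(4)) == 0.0
        assert rastrigin(np.zeros(5)) == pytest.approx(0.0, abs=1e-12)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"population_size": 0},
            {"max_iterations": 0},
            {"tol_fitness": -1.0},
            {"local_search_rate": 1.5},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            HOSConfig(**kwargs)
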