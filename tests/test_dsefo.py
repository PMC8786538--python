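"""Electric fish optimization operators and the DS-EFO loop."""

import numpy as np
import pytest
from scipy import stats

from ocuclean import dsefo
from ocuclean.dsefo import EFOParams, Individual, OptimizationTrace


def sphere(x):
    return float(x @ x)


@pytest.fixture
def unit_params():
    return EFOParams(bounds=np.array([[0.0, 1.0], [0.0, 1.0]]), pop_size=4, seed=0)


def make_pop(positions, fitnesses, amplitudes=None):
    pop = []
    for i, (p, f) in enumerate(zip(positions, fitnesses)):
        amp = 0.5 if amplitudes is None else amplitudes[i]
        pop.append(Individual(position=np.asarray(p, float), fitness=f, amplitude=amp))
    return pop


class TestInit:
    def test_positions_within_bounds(self, unit_params):
        rng = np.random.default_rng(0)
        pop = dsefo.init_population(unit_params, sphere, rng)
        for ind in pop:
            assert np.all(ind.position >= 0) and np.all(ind.position <= 1)
            assert ind.fitness == sphere(ind.position)

    def test_degenerate_bound_fixes_coordinate(self):
        params = EFOParams(bounds=np.array([[0.3, 0.3], [0.0, 1.0]]), pop_size=5, seed=1)
        pop = dsefo.init_population(params, sphere, np.random.default_rng(1))
        assert all(ind.position[0] == 0.3 for ind in pop)

    def test_coordinates_uniform_by_ks_test(self):
        params = EFOParams(bounds=np.array([[0.0, 1.0]]), pop_size=10_000, seed=2)
        pop = dsefo.init_population(params, lambda x: 0.0, np.random.default_rng(2))
        xs = np.array([ind.position[0] for ind in pop])
        assert stats.kstest(xs, "uniform").pvalue > 0.01


class TestFrequencies:
    def test_linear_map_endpoints_and_midpoint(self, unit_params):
        pop = make_pop([[0, 0]] * 3, [1.0, 2.0, 3.0])
        dsefo.update_frequencies(pop, unit_params)
        assert [ind.frequency for ind in pop] == [1.0, 0.5, 0.0]

    def test_equal_fitness_maps_to_fr_max(self, unit_params):
        pop = make_pop([[0, 0]] * 3, [2.0, 2.0, 2.0])
        dsefo.update_frequencies(pop, unit_params)
        assert all(ind.frequency == 1.0 for ind in pop)

    def test_invariant_under_affine_fitness_rescale(self, unit_params):
        fits = [0.3, 1.7, 0.9, 5.0]
        pop_a = make_pop([[0, 0]] * 4, fits)
        pop_b = make_pop([[0, 0]] * 4, [10 * f - 3 for f in fits])
        dsefo.update_frequencies(pop_a, unit_params)
        dsefo.update_frequencies(pop_b, unit_params)
        for a, b in zip(pop_a, pop_b):
            assert a.frequency == pytest.approx(b.frequency)


class TestAmplitudes:
    def test_beta_zero_tracks_frequency(self):
        params = EFOParams(bounds=[[0, 1]], pop_size=2, beta=0.0, seed=0)
        pop = make_pop([[0], [0]], [1.0, 2.0], amplitudes=[0.9, 0.9])
        dsefo.update_frequencies(pop, params)
        dsefo.update_amplitudes(pop, params)
        for ind in pop:
            assert ind.amplitude == ind.frequency

    def test_beta_one_freezes_amplitude(self):
        params = EFOParams(bounds=[[0, 1]], pop_size=2, beta=1.0, seed=0)
        pop = make_pop([[0], [0]], [1.0, 2.0], amplitudes=[0.33, 0.66])
        dsefo.update_frequencies(pop, params)
        dsefo.update_amplitudes(pop, params)
        assert [i.amplitude for i in pop] == [0.33, 0.66]

    def test_geometric_recursion_closed_form(self):
        # beta=0.5, fr constant 1, amp_0=0 -> amp_k = 1 - 2^-k
        params = EFOParams(bounds=[[0, 1]], pop_size=2, beta=0.5, seed=0)
        ind = Individual(position=np.zeros(1), fitness=0.0, frequency=1.0, amplitude=0.0)
        for k in range(1, 8):
            dsefo.update_amplitudes([ind], params)
            assert ind.amplitude == pytest.approx(1 - 2.0**-k)


class TestRangeAndDistance:
    def test_active_range_cases(self):
        params = EFOParams(bounds=np.array([[0.0, 1.0]] * 3), pop_size=2, seed=0)
        ind = Individual(position=np.zeros(3), fitness=0.0, amplitude=0.0)
        assert dsefo.active_range(ind, params) == 0.0
        ind.amplitude = 0.3
        assert dsefo.active_range(ind, params) == pytest.approx(0.3)
        doubled = EFOParams(bounds=np.array([[0.0, 2.0]] * 3), pop_size=2, seed=0)
        assert dsefo.active_range(ind, doubled) == pytest.approx(0.6)

    def test_cartesian_distance(self):
        assert dsefo.distance([0, 0], [3, 4]) == 5.0
        assert dsefo.distance([1, 2], [1, 2]) == 0.0
        assert dsefo.distance([1, 2], [4, 6]) == dsefo.distance([4, 6], [1, 2])


class _FixedRng:
    """Minimal stand-in driving the stochastic operators deterministically."""

    def __init__(self, uniform_value=0.0, integer_value=0):
        self.u = uniform_value
        self.i = integer_value

    def uniform(self, low=0.0, high=1.0, size=None):
        val = low + self.u * (high - low)
        return np.full(size, val) if size is not None else val

    def integers(self, n):
        return self.i

    def choice(self, n, size, replace, p):
        return np.arange(size)


class TestMoves:
    def test_zero_amplitude_and_no_neighbor_leaves_position(self):
        params = EFOParams(bounds=np.array([[0.0, 1.0]] * 2), pop_size=2, seed=0)
        ind = Individual(position=np.array([0.4, 0.6]), fitness=0.0, amplitude=0.0)
        new = dsefo.active_move(ind, [], params, np.random.default_rng(0))
        np.testing.assert_array_equal(new, ind.position)

    def test_active_move_stays_in_bounds_and_bounded_step(self):
        params = EFOParams(bounds=np.array([[-1.0, 1.0]] * 3), pop_size=2, seed=0)
        rng = np.random.default_rng(1)
        for _ in range(50):
            ind = Individual(
                position=rng.uniform(-1, 1, 3), fitness=0.0, amplitude=rng.uniform()
            )
            nbr = Individual(
                position=np.clip(
                    ind.position + rng.uniform(-0.1, 0.1, 3), -1, 1
                ),
                fitness=0.0,
                amplitude=0.5,
            )
            new = dsefo.active_move(ind, [nbr], params, rng)
            assert np.all(new >= -1) and np.all(new <= 1)
            ar = dsefo.active_range(ind, params)
            sep = np.abs(nbr.position - ind.position)
            # neighbor-relative probe: per-coordinate displacement is at most
            # twice the separation, itself bounded by the active range
            assert np.all(np.abs(new - ind.position) <= 2 * np.maximum(sep, ar) + 1e-12)

    def test_passive_single_active_reference_is_its_position(self):
        params = EFOParams(bounds=np.array([[0.0, 1.0]] * 2), pop_size=2, seed=0)
        ind = Individual(position=np.array([0.2, 0.2]), fitness=1.0, amplitude=0.5)
        ref = Individual(position=np.array([0.8, 0.6]), fitness=0.5, amplitude=0.7)
        # delta forced to 1 -> lands exactly on the reference
        new = dsefo.passive_move(ind, [ref], params, _FixedRng(uniform_value=1.0))
        np.testing.assert_allclose(new, ref.position)
        # delta forced to 0 -> unchanged
        new0 = dsefo.passive_move(ind, [ref], params, _FixedRng(uniform_value=0.0))
        np.testing.assert_allclose(new0, ind.position)

    def test_reinit_probability_zero_and_one(self):
        params0 = EFOParams(bounds=np.array([[0.0, 1.0]] * 4), pop_size=2, reinit_prob=0.0, seed=0)
        pos = np.full(4, 0.5)
        rng = np.random.default_rng(2)
        for _ in range(20):
            np.testing.assert_array_equal(dsefo.stochastic_reinit(pos, params0, rng), pos)
        params1 = EFOParams(bounds=np.array([[0.0, 1.0]] * 4), pop_size=2, reinit_prob=1.0, seed=0)
        changed = dsefo.stochastic_reinit(pos, params1, rng)
        assert np.sum(changed != pos) == 1

    def test_reinit_empirical_rate_matches_probability(self):
        params = EFOParams(bounds=np.array([[0.0, 1.0]]), pop_size=2, reinit_prob=0.1, seed=0)
        rng = np.random.default_rng(3)
        pos = np.array([0.5])
        hits = sum(
            dsefo.stochastic_reinit(pos, params, rng)[0] != 0.5 for _ in range(10_000)
        )
        p = hits / 10_000
        sigma = np.sqrt(0.1 * 0.9 / 10_000)
        assert abs(p - 0.1) < 3 * sigma


class TestModeSelection:
    def test_best_with_neighbor_in_range_is_active(self):
        params = EFOParams(bounds=np.array([[0.0, 10.0]] * 2), pop_size=3, seed=0)
        best = Individual(position=np.array([1.0, 1.0]), fitness=0.0, amplitude=0.9)
        near = Individual(position=np.array([1.5, 1.0]), fitness=1.0, amplitude=0.9)
        far = Individual(position=np.array([9.0, 9.0]), fitness=5.0, amplitude=0.9)
        pop = [best, near, far]
        assert dsefo.dsefo_select_mode(best, pop, best, params) == "active"
        assert dsefo.dsefo_select_mode(far, pop, best, params) == "passive"

    def test_coincident_population_all_passive(self):
        params = EFOParams(bounds=np.array([[0.0, 1.0]] * 2), pop_size=3, seed=0)
        pop = make_pop([[0.5, 0.5]] * 3, [1.0, 1.0, 1.0], amplitudes=[0.5] * 3)
        for ind in pop:
            assert dsefo.dsefo_select_mode(ind, pop, pop[0], params) == "passive"


class TestOptimize:
    BOUNDS = np.array([[-5.0, 5.0]] * 5)

    def test_sphere_median_over_five_seeds(self):
        fits = []
        for seed in range(5):
            params = EFOParams(bounds=self.BOUNDS, pop_size=10, iterations=100, seed=seed)
            _, fit, _ = dsefo.optimize(sphere, params, "ds-efo")
            fits.append(fit)
        assert np.median(fits) <= 1e-2

    def test_trace_monotone_and_budget(self):
        params = EFOParams(bounds=self.BOUNDS, pop_size=10, iterations=100, seed=3)
        _, _, trace = dsefo.optimize(sphere, params, "ds-efo")
        diffs = np.diff(trace.best_fitness)
        assert np.all(diffs <= 1e-15)
        assert trace.evaluations <= 10 + 10 * 100

    def test_positions_always_within_bounds(self):
        seen = []

        def watched(x):
            seen.append(x.copy())
            return sphere(x)

        params = EFOParams(bounds=self.BOUNDS, pop_size=6, iterations=30, seed=1)
        dsefo.optimize(watched, params, "ds-efo")
        arr = np.array(seen)
        assert np.all(arr >= -5) and np.all(arr <= 5)

    def test_forced_all_active_rule_makes_variants_identical(self):
        p1 = EFOParams(bounds=self.BOUNDS, pop_size=8, iterations=25, seed=9)
        p2 = EFOParams(bounds=self.BOUNDS, pop_size=8, iterations=25, seed=9)
        _, f1, t1 = dsefo.optimize(sphere, p1, "efo", mode_override="active")
        _, f2, t2 = dsefo.optimize(sphere, p2, "ds-efo", mode_override="active")
        assert f1 == f2
        assert t1.best_fitness == t2.best_fitness

    def test_nonfinite_objective_rejected_with_warning(self):
        calls = {"n": 0}

        def nasty(x):
            calls["n"] += 1
            return np.nan if calls["n"] % 7 == 0 else sphere(x)

        params = EFOParams(bounds=self.BOUNDS, pop_size=5, iterations=10, seed=2)
        with pytest.warns(UserWarning, match="non-finite"):
            _, fit, _ = dsefo.optimize(nasty, params, "ds-efo")
        assert np.isfinite(fit)

    def test_unknown_variant_rejected(self):
        params = EFOParams(bounds=self.BOUNDS, pop_size=4, iterations=2, seed=0)
        with pytest.raises(ValueError):
            dsefo.optimize(sphere, params, "pso")
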