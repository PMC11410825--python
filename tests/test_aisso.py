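import math

import numpy as np
import pytest

from ppifuse.aisso import (
    AissoConfig,
    Candidate,
    IcmicStream,
    ObjectiveSpec,
    aquila_update,
    gauss_mutate,
    icmic_stream,
    init_population,
    levy_sigma,
    levy_step,
    optimize,
    sso_move,
)


def sphere(x):
    return float(np.sum(x**2))


class OnesRng:
    """Stub generator: every variate is 1 (or 0 for normals), index draws pick 0."""

    def random(self, size=None):
        return 1.0 if size is None else np.ones(size)

    def uniform(self, low, high, size=None):
        return 1.0 if size is None else np.ones(size)

    def integers(self, n):
        return 0

    def standard_normal(self, size=None):
        return 0.0 if size is None else np.zeros(size)

    def normal(self, loc, scale, size=None):
        return np.zeros(size)


class TestInit:
    def test_population_within_bounds(self):
        config = AissoConfig(seed=0)
        pop = init_population(config, np.random.default_rng(0))
        assert len(pop) == 10
        for cand in pop:
            assert np.all((cand.position >= 0) & (cand.position <= 1))
            assert np.all(cand.velocity == 0)

    def test_seed_solution_present_verbatim(self):
        config = AissoConfig(seed=0)
        seed_sol = np.array([0.25, 0.75])
        pop = init_population(config, np.random.default_rng(1), seed_sol)
        assert any(np.array_equal(c.position, seed_sol) for c in pop)

    def test_same_seed_gives_identical_populations(self):
        config = AissoConfig(seed=0)
        p1 = init_population(config, np.random.default_rng(5))
        p2 = init_population(config, np.random.default_rng(5))
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.position, b.position)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            AissoConfig(lb=1.0, ub=0.0)


class TestSsoMove:
    def test_zero_gradient_and_velocity_leave_position_unchanged(self):
        config = AissoConfig(n_dim=1)
        cand = Candidate(np.array([0.5]), np.zeros(1), 0.0)
        obj = ObjectiveSpec(lambda x: 1.0)  # flat objective
        moved = sso_move(cand, cand, config, np.random.default_rng(0), obj)
        np.testing.assert_allclose(moved.position, [0.5], atol=1e-9)

    def test_descends_the_sphere_by_dt_times_gradient(self):
        # eta=1, Rand=1, no momentum, dt=0.1: step = 0.1 * |2x| = 0.1 at x=0.5
        config = AissoConfig(n_dim=1, eta=1.0, inertia=0.0, dt=0.1)
        cand = Candidate(np.array([0.5]), np.zeros(1), sphere(np.array([0.5])))
        moved = sso_move(cand, cand, config, OnesRng(), ObjectiveSpec(sphere))
        assert moved.position[0] == pytest.approx(0.4, abs=1e-6)

    def test_limiter_caps_velocity_magnitude(self):
        config = AissoConfig(n_dim=1, eta=1.0, inertia=0.0, beta_limit=0.5)
        cand = Candidate(np.array([0.9]), np.array([0.01]), sphere(np.array([0.9])))
        moved = sso_move(cand, cand, config, OnesRng(), ObjectiveSpec(sphere))
        # raw gradient step (-1.8) exceeds 0.5 * 0.01, so the applied step is capped
        applied = (moved.position[0] - 0.9) / config.dt
        assert abs(applied) <= 0.5 * 0.01 + 1e-12


class TestLevy:
    def test_sigma_matches_independent_gamma_evaluation(self):
        config = AissoConfig()
        beta = 1.5
        expected = (math.gamma(1 + beta) * math.sin(math.pi * beta / 2)) / (
            math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2)
        )
        assert levy_sigma(config) == pytest.approx(expected, abs=1e-15)
        mantegna = AissoConfig(mantegna_exponent=True)
        assert levy_sigma(mantegna) == pytest.approx(expected ** (1 / beta), abs=1e-15)

    def test_zero_scale_gives_zero_vector(self):
        config = AissoConfig(levy_s=0.0)
        np.testing.assert_array_equal(levy_step(3, config, np.random.default_rng(0)), 0.0)

    def test_fixed_seed_reproducible(self):
        config = AissoConfig()
        s1 = levy_step(4, config, np.random.default_rng(9))
        s2 = levy_step(4, config, np.random.default_rng(9))
        np.testing.assert_array_equal(s1, s2)


class TestAquila:
    def test_spiral_term_at_reference_angle(self):
        # upsilon=0, omega=0, r1=1: theta = 3*pi/2, cos=0, sin=-1, (Pi - K) = r = 1
        config = AissoConfig(n_dim=2, upsilon=0.0, omega=0.0, levy_s=0.0)
        best = Candidate(np.zeros(2), np.zeros(2), 0.0)
        pop = [Candidate(np.zeros(2), np.zeros(2), 0.0)]
        prop = aquila_update(pop[0], best, pop, 1, config, OnesRng(), ra=0.5)
        # proposal = 0 * levy + X_R(=0) + 1 * 0.5 per dimension
        np.testing.assert_allclose(prop, 0.5, atol=1e-9)

    def test_zero_levy_and_zero_ra_reproduce_random_member(self):
        config = AissoConfig(n_dim=2, levy_s=0.0)
        rng = np.random.default_rng(3)
        pop = [Candidate(rng.random(2), np.zeros(2), 0.0) for _ in range(4)]
        best = pop[0]
        prop = aquila_update(pop[1], best, pop, 1, config, np.random.default_rng(1), ra=0.0)
        assert any(np.allclose(prop, c.position) for c in pop)

    def test_proposal_respects_bounds(self):
        config = AissoConfig(n_dim=2)
        rng = np.random.default_rng(4)
        pop = [Candidate(rng.random(2), np.zeros(2), 0.0) for _ in range(4)]
        for _ in range(50):
            prop = aquila_update(pop[0], pop[0], pop, 1, config, rng)
            assert np.all((prop >= 0) & (prop <= 1))


class TestMutationAndChaos:
    def test_zero_delta_leaves_position_unchanged(self):
        config = AissoConfig(delta=0.0)
        pos = np.array([0.3, 0.6])
        np.testing.assert_array_equal(gauss_mutate(pos, config, np.random.default_rng(0)), pos)

    def test_mutation_stays_in_bounds_and_is_reproducible(self):
        config = AissoConfig()
        pos = np.array([0.05, 0.95])
        m1 = gauss_mutate(pos, config, np.random.default_rng(2))
        m2 = gauss_mutate(pos, config, np.random.default_rng(2))
        np.testing.assert_array_equal(m1, m2)
        assert np.all((m1 >= 0) & (m1 <= 1))

    def test_icmic_hand_value(self):
        assert icmic_stream(1.0, 2.0 / math.pi, 1)[0] == pytest.approx(1.0)

    def test_icmic_range_and_determinism(self):
        s1 = icmic_stream(0.7, 0.7, 200)
        s2 = icmic_stream(0.7, 0.7, 200)
        np.testing.assert_array_equal(s1, s2)
        assert np.all((s1 >= -1) & (s1 <= 1))

    def test_icmic_zero_seed_rejected(self):
        with pytest.raises(ValueError):
            IcmicStream(1.0, 0.0)


class TestOptimize:
    def test_sphere_converges_with_monotone_trace(self):
        config = AissoConfig(seed=0)
        result = optimize(sphere, config)
        assert result.best_value <= 1e-2
        assert np.all(np.diff(result.trace) <= 1e-15)

    def test_zero_iterations_return_best_of_initial_population(self):
        config = AissoConfig(seed=1, iter_max=0)
        result = optimize(sphere, config)
        assert result.trace.size == 1
        assert result.best_value == min(c.value for c in result.population)

    def test_identical_config_and_seed_give_identical_traces(self):
        config = AissoConfig(seed=5)
        r1 = optimize(sphere, config)
        r2 = optimize(sphere, config)
        np.testing.assert_array_equal(r1.trace, r2.trace)

    def test_every_evaluated_position_within_bounds(self):
        seen = []

        def recording(x):
            seen.append(x.copy())
            return sphere(x)

        optimize(recording, AissoConfig(seed=2, iter_max=5))
        stacked = np.vstack(seen)
        assert np.all((stacked >= 0) & (stacked <= 1))
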