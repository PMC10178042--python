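"""HBA / tHBA / GA: closed-form pieces, loop contracts and benchmark behaviour."""

import numpy as np
import pytest
import scipy.stats

import badgerlm.optimizers as opt
from badgerlm.optimizers import (
    GAConfig,
    HBAConfig,
    OptimizerRun,
    SearchSpace,
    THBAConfig,
    density_factor,
    ga_optimize,
    hba_optimize,
    hba_step,
    init_population,
    smell_intensity,
    t_mutation,
    thba_optimize,
)

sphere = lambda x: float(np.sum(np.asarray(x) ** 2))  # noqa: E731
BOX5 = SearchSpace.cube(5, -5.0, 5.0)


class TestSearchSpace:
    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            SearchSpace(np.array([0.0, 1.0]), np.array([1.0, 1.0]))

    def test_clamp(self):
        s = SearchSpace.cube(3, -1, 1)
        assert np.array_equal(s.clamp(np.array([-5.0, 0.5, 5.0])), [-1.0, 0.5, 1.0])


class TestInitPopulation:
    def test_within_bounds(self, rng):
        pos = init_population(BOX5, 40, rng)
        assert pos.shape == (40, 5)
        assert np.all(pos >= BOX5.lb) and np.all(pos <= BOX5.ub)

    def test_forced_extremes(self, forced_rng):
        assert np.allclose(init_population(BOX5, 3, forced_rng(0.0)), BOX5.lb)
        assert np.allclose(init_population(BOX5, 3, forced_rng(1.0)), BOX5.ub)


class TestSmellIntensity:
    def test_zero_random_factor(self, forced_rng):
        I = smell_intensity([0.0], [1.0], [2.0], forced_rng(0.0))
        assert np.allclose(I, 0.0)

    def test_inverse_square_substitution(self, forced_rng):
        # S = (0-1)^2 = 1, d = 2, I = 1/(16 pi)
        I = smell_intensity([0.0], [1.0], [2.0], forced_rng(1.0))
        assert np.allclose(I, 1.0 / (16 * np.pi), atol=1e-9)
        assert abs(I[0] - 0.019894) < 1e-6

    def test_doubling_distance_quarters_intensity(self, forced_rng):
        near = smell_intensity([0.0], [1.0], [2.0], forced_rng(1.0))
        far = smell_intensity([0.0], [1.0], [4.0], forced_rng(1.0))
        assert np.allclose(near / far, 4.0)

    def test_zero_distance_guarded(self, forced_rng):
        I = smell_intensity([1.0], [2.0], [1.0], forced_rng(1.0))
        assert np.all(np.isfinite(I))


class TestDensityFactor:
    def test_limits(self):
        # alpha -> C as t/tmax -> 0; alpha = C/e at t = tmax
        assert abs(density_factor(1, 10**9, C=2.0) - 2.0) < 1e-6
        assert abs(density_factor(300, 300, C=2.0) - 2.0 / np.e) < 1e-12

    def test_strictly_decreasing(self):
        vals = [density_factor(t, 50) for t in range(1, 51)]
        assert np.all(np.diff(vals) < 0)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            density_factor(0, 10)
        with pytest.raises(ValueError):
            density_factor(11, 10)


class TestTMutation:
    def test_zero_fixed_point(self, rng):
        assert np.array_equal(t_mutation(np.zeros(6), 3, rng), np.zeros(6))

    def test_high_df_limit_is_gaussian(self):
        """df=1000 Student-t draws pass a KS test against N(0,1)."""
        rng = np.random.default_rng(123)
        draws = t_mutation(np.ones(10_000), 1000, rng) - 1.0
        assert scipy.stats.kstest(draws, "norm").pvalue > 0.01

    def test_low_df_is_heavy_tailed(self):
        rng = np.random.default_rng(7)
        draws = t_mutation(np.ones(10_000), 1, rng) - 1.0  # Cauchy
        assert scipy.stats.kstest(draws, "norm").pvalue < 0.01

    def test_seeded_determinism(self):
        x = np.linspace(-1, 1, 5)
        a = t_mutation(x, 4, np.random.default_rng(9))
        b = t_mutation(x, 4, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_df_below_one_rejected(self, rng):
        with pytest.raises(ValueError):
            t_mutation(np.ones(3), 0, rng)


class TestHBAStep:
    def test_degenerate_collapse_to_prey(self, forced_rng):
        """alpha ~ 0 and I = 0 make both modes return the prey position."""
        prey = np.array([0.2, -0.3])
        positions = np.tile(prey, (4, 1))  # S = 0 -> I = 0, d = 0
        fit = np.full(4, sphere(prey))
        cfg = HBAConfig(pop_size=4, max_iter=10)
        new_pos, _, n = hba_step(
            positions, fit, prey, 5, cfg, SearchSpace.cube(2, -1, 1), sphere, forced_rng(0.49)
        )
        assert np.allclose(new_pos, prey)
        assert n == 4

    def test_greedy_never_accepts_worse(self, rng):
        cfg = HBAConfig(pop_size=8, max_iter=20)
        positions = init_population(BOX5, 8, rng)
        fit = np.array([sphere(x) for x in positions])
        for t in range(1, 11):
            prey = positions[np.argmin(fit)]
            new_pos, new_fit, _ = hba_step(positions, fit, prey, t, cfg, BOX5, sphere, rng)
            assert np.all(new_fit <= fit + 1e-15)
            positions, fit = new_pos, new_fit

    def test_outputs_clamped(self, rng):
        tight = SearchSpace.cube(3, -0.01, 0.01)
        positions = init_population(tight, 6, rng)
        fit = np.array([sphere(x) for x in positions])
        new_pos, _, _ = hba_step(
            positions, fit, positions[0], 1, HBAConfig(pop_size=6, max_iter=5), tight, sphere, rng
        )
        assert np.all(new_pos >= tight.lb) and np.all(new_pos <= tight.ub)


class TestOptimizeLoops:
    @pytest.mark.parametrize("optimizer,config", [
        (hba_optimize, HBAConfig(pop_size=12, max_iter=25, seed=0)),
        (thba_optimize, THBAConfig(pop_size=12, max_iter=25, seed=0)),
        (ga_optimize, GAConfig(pop_size=12, max_iter=25, seed=0)),
    ])
    def test_history_non_increasing_and_consistent(self, optimizer, config):
        run = optimizer(sphere, BOX5, config)
        assert run.history.shape == (25,)
        assert np.all(np.diff(run.history) <= 0)
        assert run.best_fitness == run.history[-1]
        assert np.all(run.best_position >= BOX5.lb) and np.all(run.best_position <= BOX5.ub)
        assert abs(sphere(run.best_position) - run.best_fitness) < 1e-12

    def test_single_iteration_contract(self):
        run = hba_optimize(sphere, BOX5, HBAConfig(pop_size=5, max_iter=1, seed=2))
        assert run.history.shape == (1,)
        assert run.n_evaluations == 5 * (1 + 1)  # init + one proposal round

    def test_evaluation_accounting_exact(self):
        calls = {"n": 0}

        def counted(x):
            calls["n"] += 1
            return sphere(x)

        cfg = THBAConfig(pop_size=9, max_iter=15, mutation_prob=0.6, seed=4)
        run = thba_optimize(counted, BOX5, cfg)
        assert run.n_evaluations == calls["n"]
        n_mut = run.n_evaluations - 9 * (1 + 15)
        assert 0 <= n_mut <= 9 * 15

    def test_p_zero_reduces_to_plain_hba(self):
        """Mutation probability 0 reproduces the HBA trajectory exactly."""
        for seed in range(3):
            h = hba_optimize(sphere, BOX5, HBAConfig(pop_size=10, max_iter=20, seed=seed))
            t = thba_optimize(
                sphere, BOX5, THBAConfig(pop_size=10, max_iter=20, seed=seed, mutation_prob=0.0)
            )
            assert np.array_equal(h.history, t.history)
            assert np.array_equal(h.best_position, t.best_position)
            assert h.n_evaluations == t.n_evaluations

    def test_mutation_df_schedule_matches_iteration(self, monkeypatch):
        """The t-distribution df passed at iteration t equals t."""
        seen: list[tuple[int, int]] = []
        real = opt.t_mutation

        def spy(position, iteration, rng):
            seen.append(iteration)
            return real(position, iteration, rng)

        monkeypatch.setattr(opt, "t_mutation", spy)
        thba_optimize(sphere, BOX5, THBAConfig(pop_size=6, max_iter=12, mutation_prob=1.0, seed=1))
        assert sorted(set(seen)) == list(range(1, 13))
        assert all(seen.count(t) == 6 for t in range(1, 13))  # one gate per agent

    def test_mutation_accept_always_differs(self):
        greedy = thba_optimize(
            sphere, BOX5, THBAConfig(pop_size=8, max_iter=10, seed=3, mutation_accept="greedy")
        )
        always = thba_optimize(
            sphere, BOX5, THBAConfig(pop_size=8, max_iter=10, seed=3, mutation_accept="always")
        )
        assert np.all(np.diff(always.history) <= 0)  # best-so-far still monotone
        assert not np.array_equal(greedy.history, always.history)

    def test_non_finite_fitness_reports_context(self):
        def bad(x):
            return np.inf if x[0] > 0 else sphere(x)

        with pytest.raises(ValueError, match="non-finite"):
            hba_optimize(bad, BOX5, HBAConfig(pop_size=6, max_iter=5, seed=0))

    def test_ga_elitism_never_worsens(self):
        run = ga_optimize(sphere, BOX5, GAConfig(pop_size=15, max_iter=40, seed=6))
        assert np.all(np.diff(run.history) <= 0)

    def test_history_invariant_enforced(self):
        with pytest.raises(ValueError):
            OptimizerRun(
                best_position=np.zeros(2),
                best_fitness=1.0,
                history=np.array([1.0, 2.0]),
                n_evaluations=4,
            )


def test_trace_csv(tmp_path):
    run = hba_optimize(sphere, BOX5, HBAConfig(pop_size=5, max_iter=8, seed=0))
    path = tmp_path / "trace.csv"
    run.write_trace(path)
    lines = path.read_text().splitlines()
    assert lines[0] == "iteration,best_fitness,n_evals"
    assert len(lines) == 9
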