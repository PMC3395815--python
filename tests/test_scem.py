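"""SCEM-UA sampler mechanics: ranking, striping, SEM steps, R-hat, full runs."""

import numpy as np
import pytest

from larvataxis import ParamBounds, SCEMConfig, gelman_rubin, run_scem
from larvataxis.scem import (
    GR_NOT_CONVERGED,
    Complex,
    PopulationArray,
    SequenceChain,
    partition_complexes,
    rank_population,
    sample_prior,
    sem_update,
    shuffle_back,
)


def quadratic_objective(center, scale=1.0):
    center = np.asarray(center, dtype=float)

    def objective(theta):
        d = np.asarray(theta) - center
        return -scale * float(d @ d)

    return objective


@pytest.fixture
def bounds2d():
    return ParamBounds(lower=np.array([-2.0, -2.0]), upper=np.array([2.0, 2.0]))


class TestSamplePrior:
    def test_points_within_box_and_reproducible(self, bounds2d):
        obj = quadratic_objective([0.0, 0.0])
        p1 = sample_prior(bounds2d, 40, obj, rng=11)
        p2 = sample_prior(bounds2d, 40, obj, rng=11)
        assert np.all(p1.points >= bounds2d.lower) and np.all(p1.points <= bounds2d.upper)
        assert np.array_equal(p1.points, p2.points)
        np.testing.assert_allclose(
            p1.log_densities, [obj(p) for p in p1.points]
        )


class TestRankPopulation:
    def test_decreasing_density_with_pairing_preserved(self):
        pts = np.array([[1.0], [2.0], [3.0]])
        pop = rank_population(PopulationArray(points=pts, log_densities=np.array([1.0, 3.0, 2.0])))
        np.testing.assert_array_equal(pop.log_densities, [3.0, 2.0, 1.0])
        np.testing.assert_array_equal(pop.points.ravel(), [2.0, 3.0, 1.0])

    def test_idempotent_on_sorted_input(self):
        pop = PopulationArray(points=np.arange(4.0)[:, None], log_densities=np.array([4.0, 3.0, 2.0, 1.0]))
        ranked = rank_population(pop)
        np.testing.assert_array_equal(ranked.points, pop.points)

    def test_stable_on_ties_against_decorated_sort_oracle(self):
        dens = np.array([2.0, 1.0, 2.0, 1.0, 2.0])
        pts = np.arange(5.0)[:, None]
        ranked = rank_population(PopulationArray(points=pts, log_densities=dens))
        # oracle: index-decorated sort, descending density, original index as tiebreak
        oracle = sorted(range(5), key=lambda i: (-dens[i], i))
        np.testing.assert_array_equal(ranked.points.ravel(), [float(i) for i in oracle])


class TestPartitionAndShuffle:
    def test_striping_s6_q2(self):
        pop = PopulationArray(points=np.arange(6.0)[:, None], log_densities=-np.arange(6.0))
        cs = partition_complexes(pop, 2)
        np.testing.assert_array_equal(cs.complexes[0].points.ravel(), [0.0, 2.0, 4.0])
        np.testing.assert_array_equal(cs.complexes[1].points.ravel(), [1.0, 3.0, 5.0])

    def test_striping_s4_q2(self):
        pop = PopulationArray(points=np.arange(4.0)[:, None], log_densities=-np.arange(4.0))
        cs = partition_complexes(pop, 2)
        np.testing.assert_array_equal(cs.complexes[0].points.ravel(), [0.0, 2.0])
        np.testing.assert_array_equal(cs.complexes[1].points.ravel(), [1.0, 3.0])

    def test_single_complex_is_whole_population(self):
        pop = PopulationArray(points=np.arange(5.0)[:, None], log_densities=-np.arange(5.0))
        cs = partition_complexes(pop, 1)
        np.testing.assert_array_equal(cs.complexes[0].points, pop.points)

    def test_indivisible_population_rejected(self):
        pop = PopulationArray(points=np.arange(5.0)[:, None], log_densities=-np.arange(5.0))
        with pytest.raises(ValueError):
            partition_complexes(pop, 2)

    def test_partition_shuffle_round_trip_conserves_population(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 2))
        dens = rng.normal(size=12)
        pop = rank_population(PopulationArray(points=pts, log_densities=dens))
        back = shuffle_back(partition_complexes(pop, 3))
        np.testing.assert_array_equal(back.points, pop.points)
        np.testing.assert_array_equal(back.log_densities, pop.log_densities)
        assert np.all(np.diff(back.log_densities) <= 0)


class TestSemUpdate:
    def _setup(self, seed=0):
        bounds = ParamBounds(lower=np.array([-5.0, -5.0]), upper=np.array([5.0, 5.0]))
        obj = quadratic_objective([1.0, -0.5], scale=3.0)
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-5, 5, size=(10, 2))
        cx = Complex(points=pts, log_densities=np.array([obj(p) for p in pts]))
        seq = SequenceChain()
        best = int(np.argmax(cx.log_densities))
        seq.append(cx.points[best], cx.log_densities[best])
        return bounds, obj, cx, seq

    def test_uphill_candidates_always_accepted_and_best_never_decreases(self):
        bounds, obj, cx, seq = self._setup()
        cfg = SCEMConfig(seed=0)
        best_before = cx.log_densities.max()
        sem_update(seq, cx, cfg, obj, rng=1, bounds=bounds, n_steps=200)
        assert cx.log_densities.max() >= best_before
        assert len(seq.points) == 201
        # every accepted transition was either uphill or a valid Metropolis downhill
        assert seq.n_accepted <= seq.n_proposed == 200

    def test_out_of_bounds_candidates_rejected(self):
        bounds, _, cx, seq = self._setup()

        def obj(theta):
            return -np.inf if np.any(np.abs(theta) > 5) else quadratic_objective([0, 0])(theta)

        cfg = SCEMConfig(seed=0)
        sem_update(seq, cx, cfg, obj, rng=2, bounds=bounds, n_steps=100)
        assert all(np.isfinite(d) for d in seq.log_densities)

    def test_converges_near_quadratic_optimum(self):
        """Best-ever point after 500 steps within 1% (of box scale) of the optimum."""
        bounds, obj, cx, seq = self._setup(seed=4)
        cfg = SCEMConfig(seed=0)
        sem_update(seq, cx, cfg, obj, rng=3, bounds=bounds, n_steps=500)
        best = seq.points[int(np.argmax(seq.log_densities))]
        assert np.linalg.norm(best - np.array([1.0, -0.5])) < 0.1

    def test_nan_objective_raises(self):
        bounds, _, cx, seq = self._setup()
        cfg = SCEMConfig(seed=0)
        with pytest.raises(RuntimeError):
            sem_update(seq, cx, cfg, lambda t: float("nan"), rng=4, bounds=bounds, n_steps=5)


class TestGelmanRubin:
    def test_hand_computed_example(self):
        """Chains {1,2,3} and {2,3,4}: W=1, B=1.5, R-hat = sqrt(1.1667) ~ 1.080."""
        c1 = np.array([[1.0], [2.0], [3.0]])
        c2 = np.array([[2.0], [3.0], [4.0]])
        diag = gelman_rubin([c1, c2], burn_fraction=0.0)
        assert diag.r_hat[0] == pytest.approx(np.sqrt(7.0 / 6.0), abs=1e-12)
        assert diag.r_hat[0] == pytest.approx(1.080, abs=1e-3)

    def test_same_distribution_chains_approach_one(self):
        rng = np.random.default_rng(8)
        chains = [rng.normal(size=(4000, 2)) for _ in range(4)]
        diag = gelman_rubin(chains, burn_fraction=0.5)
        assert np.all(np.abs(diag.r_hat - 1.0) < 0.05)

    def test_constant_chains_flagged_not_converged(self):
        c = np.ones((10, 1))
        diag = gelman_rubin([c, c], burn_fraction=0.0)
        assert diag.r_hat[0] == GR_NOT_CONVERGED

    def test_requires_two_chains_with_two_draws(self):
        with pytest.raises(ValueError):
            gelman_rubin([np.ones((10, 1))])
        with pytest.raises(ValueError):
            gelman_rubin([np.ones((1, 1)), np.ones((1, 1))], burn_fraction=0.0)


class TestRunScem:
    def test_one_dimensional_gaussian_mode(self):
        """Log-density -(x-0.3)^2/(2*0.01): mode 0.3 found within 0.01."""
        b = ParamBounds(lower=np.array([-1.0]), upper=np.array([1.0]))

        def obj(theta):
            return -((theta[0] - 0.3) ** 2) / 0.02

        res = run_scem(obj, b, SCEMConfig(seed=5, max_shuffles=80))
        assert abs(res.best_theta[0] - 0.3) < 0.01

    def test_reproducible_for_fixed_seed(self, bounds2d):
        obj = quadratic_objective([0.4, -1.1])
        cfg = SCEMConfig(seed=99, max_shuffles=10)
        r1 = run_scem(obj, bounds2d, cfg)
        r2 = run_scem(obj, bounds2d, cfg)
        assert np.array_equal(r1.best_theta, r2.best_theta)
        assert r1.best_log_density == r2.best_log_density
        assert r1.n_shuffles == r2.n_shuffles

    def test_matches_grid_search_oracle_on_quadratic(self, bounds2d):
        center = np.array([0.65, -0.35])
        obj = quadratic_objective(center, scale=2.0)
        res = run_scem(
            obj, bounds2d, SCEMConfig(seed=12, max_shuffles=150, gr_threshold=1.01)
        )
        # dense grid oracle
        g = np.linspace(-2, 2, 161)  # resolution 0.025
        gx, gy = np.meshgrid(g, g)
        vals = -2.0 * ((gx - center[0]) ** 2 + (gy - center[1]) ** 2)
        iy, ix = np.unravel_index(np.argmax(vals), vals.shape)
        oracle = np.array([gx[iy, ix], gy[iy, ix]])
        assert np.all(np.abs(res.best_theta - oracle) <= 0.025 + 1e-9)

    def test_best_density_monotone_under_more_shuffles(self, bounds2d):
        obj = quadratic_objective([0.0, 0.0])
        prev = -np.inf
        for shuffles in (2, 5, 10, 20):
            res = run_scem(obj, bounds2d, SCEMConfig(seed=7, max_shuffles=shuffles, gr_threshold=1.0001))
            assert res.best_log_density >= prev - 1e-15
            prev = res.best_log_density

    def test_sse_objective_on_noiseless_data_reaches_tiny_sse(self, noiseless_550):
        from larvataxis.posterior import log_posterior, sse

        b = ParamBounds(lower=np.array([0.0, 0.0]), upper=np.array([1.0, 10.0]))
        wide = ParamBounds(lower=b.lower - b.width, upper=b.upper + b.width)
        res = run_scem(
            lambda t: log_posterior(t, noiseless_550, wide),
            b,
            SCEMConfig(
                seed=21, population_size=100, n_complexes=10, jump_scale=1.0,
                gr_threshold=1.005, max_shuffles=800,
            ),
        )
        assert sse(res.best_theta, noiseless_550) < 1e-6

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SCEMConfig(seed=0, population_size=7, n_complexes=2)
        with pytest.raises(ValueError):
            SCEMConfig(seed=0, gr_threshold=1.0)
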