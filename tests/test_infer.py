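import numpy as np
import pytest
from scipy import stats

from nucleofit.genome import ParameterPoint
from nucleofit.infer import (
    Dataset,
    Density,
    NuisanceModel,
    credible_region,
    infer_parameters,
    log_likelihood,
    make_log_posterior,
    map_estimate,
    marginal_density,
    run_ensemble_mcmc,
)
from nucleofit.observables import ObservableSet


class TestLogLikelihood:
    def test_zero_residual_unit_sigma(self):
        assert log_likelihood([2.0], [2.0], [1.0]) == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_unit_z_score(self):
        assert log_likelihood([3.0], [2.0], [1.0]) == pytest.approx(-0.5 * np.log(2 * np.pi) - 0.5)

    def test_hand_summed_three_data(self):
        y = [1.0, 2.0, 4.0]
        mu = [1.5, 2.0, 3.0]
        s = [0.5, 1.0, 2.0]
        expected = sum(
            -0.5 * ((yi - mi) / si) ** 2 - 0.5 * np.log(2 * np.pi * si**2)
            for yi, mi, si in zip(y, mu, s)
        )
        assert log_likelihood(y, mu, s) == pytest.approx(expected)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            log_likelihood([1.0], [1.0], [0.0])
        with pytest.raises(ValueError):
            log_likelihood([1.0, 2.0], [1.0], [1.0])


class TestLogPosterior:
    def test_outside_prior_box_is_minus_inf(self, toy_grid):
        truth = ParameterPoint(60.0, 50.0, 30.0, 140.0)
        ds = Dataset(toy_grid.schema, toy_grid.predict(truth).values)
        log_prob, names, fixed, bounds = make_log_posterior(toy_grid, ds)
        xi = [0.1] * (len(names) - 2)
        assert log_prob(np.array([200.0, 50.0, *xi])) == -np.inf
        assert log_prob(np.array([60.0, 20.0, *xi])) == -np.inf
        assert np.isfinite(log_prob(np.array([60.0, 50.0, *xi])))

    def test_equal_likelihood_equal_posterior_under_flat_prior(self, toy_grid):
        # a constant-observable grid gives identical posterior everywhere inside
        import copy

        flat = copy.deepcopy(toy_grid)
        flat.node_values[...] = 100.0
        flat._interp = None
        ds = Dataset(flat.schema, np.full(len(flat.schema), 100.0))
        log_prob, names, _, _ = make_log_posterior(flat, ds)
        xi = [0.1] * (len(names) - 2)
        a = log_prob(np.array([40.0, 40.0, *xi]))
        b = log_prob(np.array([110.0, 80.0, *xi]))
        assert a == pytest.approx(b)

    def test_row_order_invariance(self, toy_grid):
        truth = ParameterPoint(60.0, 50.0, 30.0, 140.0)
        vals = toy_grid.predict(truth).values
        ds1 = Dataset(toy_grid.schema, vals)
        perm = np.random.default_rng(0).permutation(len(vals))
        ds2 = Dataset(tuple(np.array(toy_grid.schema, dtype=object)[perm]), vals[perm])
        lp1, names, _, _ = make_log_posterior(toy_grid, ds1)
        lp2, _, _, _ = make_log_posterior(toy_grid, ds2)
        theta = np.array([70.0, 60.0] + [0.15] * (len(names) - 2))
        assert lp1(theta) == pytest.approx(lp2(theta), rel=1e-12)

    def test_missing_prediction_id_rejected(self, toy_grid):
        from nucleofit.observables import ObservableSpec

        spec = (ObservableSpec(id="unknown", cls="mean_3d_distance"),)
        ds = Dataset(spec, np.array([1.0]))
        with pytest.raises(KeyError, match="unknown"):
            make_log_posterior(toy_grid, ds)


class TestEnsembleMcmc:
    @staticmethod
    def _gaussian_target(mean, cov):
        icov = np.linalg.inv(cov)

        def log_prob(theta):
            theta = np.atleast_2d(theta)
            d = theta - mean
            return -0.5 * np.einsum("ni,ij,nj->n", d, icov, d)

        return log_prob

    def test_gaussian_moments_recovered(self):
        mean = np.array([2.0, -1.0])
        cov = np.array([[1.0, 0.6], [0.6, 2.0]])
        log_prob = self._gaussian_target(mean, cov)
        rng = np.random.default_rng(0)
        init = mean + rng.standard_normal((24, 2))
        sample = run_ensemble_mcmc(log_prob, init, n_steps=4000, seed=1)
        est_mean = sample.draws.mean(axis=0)
        est_cov = np.cov(sample.draws.T)
        n_eff = sample.draws.shape[0] / (2 * sample.metadata["autocorr_time"])
        tol = 4.0 / np.sqrt(n_eff)
        np.testing.assert_allclose(est_mean, mean, atol=tol * np.sqrt(np.diag(cov)).max())
        np.testing.assert_allclose(est_cov, cov, rtol=0.2, atol=0.15)

    def test_flat_box_target_uniform_marginals(self):
        def log_prob(theta):
            theta = np.atleast_2d(theta)
            ok = np.all((theta >= 0.0) & (theta <= 1.0), axis=1)
            return np.where(ok, 0.0, -np.inf)

        rng = np.random.default_rng(2)
        init = rng.uniform(0.2, 0.8, (20, 2))
        sample = run_ensemble_mcmc(log_prob, init, n_steps=3000, seed=3)
        # thinned draws approximately uniform on [0, 1]
        tau = max(1, int(sample.metadata["autocorr_time"]))
        x = sample.column("p0")[:: 4 * tau]
        assert stats.kstest(x, "uniform").pvalue > 0.01

    def test_same_seed_identical_chains(self):
        log_prob = self._gaussian_target(np.zeros(2), np.eye(2))
        init = np.random.default_rng(5).standard_normal((12, 2))
        s1 = run_ensemble_mcmc(log_prob, init, n_steps=500, seed=7)
        s2 = run_ensemble_mcmc(log_prob, init, n_steps=500, seed=7)
        np.testing.assert_array_equal(s1.draws, s2.draws)

    def test_too_few_walkers_rejected(self):
        log_prob = self._gaussian_target(np.zeros(3), np.eye(3))
        with pytest.raises(ValueError, match="n_walkers"):
            run_ensemble_mcmc(log_prob, np.zeros((4, 3)), n_steps=10, seed=0)


def _gaussian_sample(n=20_000, mean=(50.0, 60.0), sd=(4.0, 6.0), rho=0.0, seed=0):
    rng = np.random.default_rng(seed)
    cov = np.array([[sd[0] ** 2, rho * sd[0] * sd[1]], [rho * sd[0] * sd[1], sd[1] ** 2]])
    draws = rng.multivariate_normal(mean, cov, size=n)
    from nucleofit.infer import PosteriorSample

    return PosteriorSample(draws=draws, log_prob=np.zeros(n), param_names=("P", "C"))


class TestMarginalsAndMap:
    def test_density_integrates_to_one(self):
        dens = marginal_density(_gaussian_sample(), ("P", "C"))
        assert dens.integral() == pytest.approx(1.0, abs=1e-6)

    def test_marginal_of_product_matches_component(self):
        dens = marginal_density(_gaussian_sample(), ("P",))
        x = dens.grids[0]
        expected = stats.norm.pdf(x, 50.0, 4.0)
        assert np.max(np.abs(dens.values - expected)) < 0.012

    def test_uninformative_direction_is_flat(self):
        # posterior informative in C only: P marginal ~ flat over its box
        rng = np.random.default_rng(1)
        from nucleofit.infer import PosteriorSample

        draws = np.column_stack([rng.uniform(30, 90, 40_000), rng.normal(60, 3, 40_000)])
        s = PosteriorSample(draws=draws, log_prob=np.zeros(40_000), param_names=("P", "C"))
        dens = marginal_density(s, ("P",), bounds={"P": (30.0, 90.0)})
        inner = dens.values[(dens.grids[0] > 35) & (dens.grids[0] < 85)]
        assert inner.std() / inner.mean() < 0.08

    def test_map_of_gaussian_near_mean(self):
        mp = map_estimate(_gaussian_sample(), ("P", "C"))
        assert mp["estimate"]["P"] == pytest.approx(50.0, abs=1.5)
        assert mp["estimate"]["C"] == pytest.approx(60.0, abs=2.0)
        assert not mp["multimodal"]

    def test_best_draw_map(self):
        s = _gaussian_sample()
        s.log_prob = -((s.draws[:, 0] - 50) ** 2) - (s.draws[:, 1] - 60) ** 2
        mp = map_estimate(s, ("P", "C"), method="best_draw")
        assert mp["estimate"]["P"] == pytest.approx(50.0, abs=1.0)


class TestCredibleRegions:
    def test_enclosed_mass_and_nesting(self):
        dens = marginal_density(_gaussian_sample(), ("P", "C"))
        r68 = credible_region(dens, 0.68)
        r95 = credible_region(dens, 0.95)
        assert r68["enclosed"] == pytest.approx(0.68, abs=0.02)
        assert r95["enclosed"] == pytest.approx(0.95, abs=0.02)
        assert np.all(r95["mask"][r68["mask"]])  # 68 % region nested in 95 %

    def test_bivariate_gaussian_mahalanobis_radius(self):
        dens = marginal_density(_gaussian_sample(n=60_000, seed=3), ("P", "C"))
        level = dens.level_for_mass(0.95)
        gp, gc = np.meshgrid(dens.grids[0], dens.grids[1], indexing="ij")
        m2 = ((gp - 50.0) / 4.0) ** 2 + ((gc - 60.0) / 6.0) ** 2
        boundary = np.abs(dens.values - level) < 0.05 * level
        # chi-square 2 dof: 95 % ellipse at Mahalanobis radius^2 = 5.99
        assert np.median(m2[boundary]) == pytest.approx(5.99, rel=0.15)

    def test_invalid_mass_rejected(self):
        dens = marginal_density(_gaussian_sample(), ("P",))
        with pytest.raises(ValueError):
            dens.level_for_mass(1.5)

    def test_region_polygons_trace_iso_contour(self):
        from nucleofit.infer import region_polygons

        dens = marginal_density(_gaussian_sample(n=40_000, seed=2), ("P", "C"))
        polys = region_polygons(dens, 0.68)
        assert polys, "expected at least one closed contour"
        xy = max(polys, key=len)
        # the 68 % contour of a Gaussian: Mahalanobis radius^2 ~ 2.28 (2 dof)
        m2 = ((xy[:, 0] - 50.0) / 4.0) ** 2 + ((xy[:, 1] - 60.0) / 6.0) ** 2
        assert np.median(m2) == pytest.approx(2.28, rel=0.2)


class TestNuisanceModel:
    def test_sigma_proportional_to_measurement_by_group(self, toy_grid):
        ds = Dataset(toy_grid.schema, toy_grid.predict(ParameterPoint(60, 50, 30, 140)).values)
        nm = NuisanceModel.for_dataset(ds)
        assert set(nm.groups) == {"live_imaging", "fixed_imaging", "hic_A"}
        xi = np.array([0.1, 0.2, 0.3])
        sig = nm.sigmas(xi, ds)
        gidx = nm.group_indices(ds)
        k = int(np.where(gidx == 1)[0][0])
        assert sig[k] == pytest.approx(0.2 * abs(ds.values[k]))

    def test_prior_rejects_non_positive_scale(self, toy_grid):
        ds = Dataset(toy_grid.schema, toy_grid.predict(ParameterPoint(60, 50, 30, 140)).values)
        nm = NuisanceModel.for_dataset(ds)
        assert nm.log_prior(np.array([-0.1, 0.1, 0.1])) == -np.inf


class TestEndToEndToyInference:
    def test_noiseless_node_truth_recovered(self, toy_grid):
        truth = ParameterPoint(60.0, 50.0, 30.0, 140.0)
        ds = Dataset(toy_grid.schema, toy_grid.predict(truth).values)
        res = infer_parameters(toy_grid, ds, n_steps=1500, seed=4)
        assert res.map["estimate"]["P"] == pytest.approx(60.0, abs=2.0)
        assert res.map["estimate"]["C"] == pytest.approx(50.0, abs=2.0)
        assert res.marginal.contains((60.0, 50.0), 0.95)
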