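import numpy as np
import pytest
from scipy import stats
from scipy.optimize import brentq

from ratestab import (
    CountCube,
    EmpiricalBayesSmoother,
    GammaPosterior,
    GammaPrior,
    NeighborhoodDictionary,
    ValidationError,
    global_rates,
    make_prior,
    neighborhood_rates,
    posterior_interval,
    posterior_update,
    parse_age_scheme,
)


class TestGlobalRates:
    def test_pooled_ratio(self, four_bin_scheme):
        cube = CountCube(("A", "B"), four_bin_scheme,
                         y=np.array([[2, 0, 0, 0], [3, 0, 0, 0]]),
                         n=np.full((2, 4), 1000.0))
        assert global_rates(cube)[0] == pytest.approx(0.0025)

    def test_all_zero_events_give_zero_rate(self, four_bin_scheme):
        cube = CountCube(("A", "B"), four_bin_scheme,
                         y=np.zeros((2, 4), dtype=int), n=np.full((2, 4), 500.0))
        assert np.all(global_rates(cube) == 0)

    def test_single_region_equals_its_crude_rate(self, four_bin_scheme):
        cube = CountCube(("A",), four_bin_scheme,
                         y=np.array([[4, 2, 8, 20]]), n=np.full((1, 4), 2000.0))
        assert np.allclose(global_rates(cube), cube.crude_rates()[0])


class TestNeighborhoodRates:
    def _cube(self, scheme, y, n):
        return CountCube(tuple("ABC"[: len(y)]), scheme, y=np.asarray(y), n=np.asarray(n))

    def test_pooled_neighbor_ratio_excludes_focal_region(self):
        scheme = parse_age_scheme((0, 50))
        cube = self._cube(scheme,
                          [[100, 0], [4, 0], [6, 0]],
                          [[1000.0, 1000.0]] * 3)
        nd = NeighborhoodDictionary({"A": ("B", "C"), "B": ("A", "C"), "C": ("A", "B")})
        t = neighborhood_rates(cube, nd)
        assert t[0, 0] == pytest.approx((4 + 6) / 2000)  # A's own 100 events excluded

    def test_island_falls_back_to_global_rate(self):
        scheme = parse_age_scheme((0, 50))
        cube = self._cube(scheme, [[2, 0], [2, 0]], [[1000.0, 1000.0]] * 2)
        nd = NeighborhoodDictionary({"A": (), "B": ()})
        t = neighborhood_rates(cube, nd)
        assert t[0, 0] == pytest.approx(4 / 2000)

    def test_zero_event_neighborhood_falls_back_to_global(self):
        scheme = parse_age_scheme((0, 50))
        cube = self._cube(scheme, [[4, 0], [0, 0], [0, 0]], [[1000.0, 1000.0]] * 3)
        nd = NeighborhoodDictionary({"A": ("B",), "B": ("A", "C"), "C": ("B",)})
        t = neighborhood_rates(cube, nd)
        # A's only neighbor B has zero events -> global rate 4/3000
        assert t[0, 0] == pytest.approx(4 / 3000)

    def test_all_zero_age_group_gets_half_event_pseudo_rate(self):
        # a gamma prior cannot have mean zero, so the target must stay positive
        scheme = parse_age_scheme((0, 50))
        cube = self._cube(scheme, [[1, 0], [2, 0]], [[1000.0, 1000.0]] * 2)
        nd = NeighborhoodDictionary({"A": ("B",), "B": ("A",)})
        t = neighborhood_rates(cube, nd)
        assert t[0, 1] == pytest.approx(0.5 / 2000)
        assert np.all(t > 0)
        make_prior(t, 500.0)  # must be a usable prior center

    def test_region_missing_from_dictionary_rejected(self):
        scheme = parse_age_scheme((0, 50))
        cube = self._cube(scheme, [[1, 0], [2, 0]], [[1000.0, 1000.0]] * 2)
        nd = NeighborhoodDictionary({"A": ()})
        with pytest.raises(ValidationError, match="B"):
            neighborhood_rates(cube, nd)


class TestConjugateUpdate:
    def test_prior_construction(self):
        prior = make_prior(np.array(0.002), 1000.0)
        assert prior.shape == pytest.approx(2.0)
        assert prior.rate == pytest.approx(1000.0)
        assert prior.mean == pytest.approx(0.002)

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValidationError):
            make_prior(np.array(0.0), 1000.0)

    def test_posterior_arithmetic(self):
        post = posterior_update(np.array(3.0), np.array(2000.0), make_prior(np.array(0.002), 1000.0))
        assert post.shape == pytest.approx(5.0)
        assert post.rate == pytest.approx(3000.0)
        assert post.mean == pytest.approx(5 / 3000)

    def test_zero_events_shrink_toward_prior(self):
        post = posterior_update(np.array(0.0), np.array(1000.0), make_prior(np.array(0.002), 1000.0))
        assert post.mean == pytest.approx(0.001)

    def test_shrinkage_identity_random_cases(self):
        """Posterior mean = (n/(n+β))·(y/n) + (β/(n+β))·(α/β), to 1e-12."""
        rng = np.random.default_rng(123)
        y = rng.integers(0, 500, size=1000).astype(float)
        n = rng.uniform(10, 1e5, size=1000)
        t = rng.uniform(1e-5, 0.05, size=1000)
        m = rng.uniform(1, 1e5, size=1000)
        prior = make_prior(t, m)
        post = posterior_update(y, n, prior)
        with np.errstate(invalid="ignore"):
            crude = np.where(n > 0, y / n, 0.0)
        expected = (n / (n + m)) * crude + (m / (n + m)) * t
        assert np.max(np.abs(post.mean - expected)) < 1e-12

    def test_shrinkage_convexity(self):
        """Posterior mean lies between the crude rate and the prior mean."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            y = float(rng.integers(0, 100))
            n = float(rng.uniform(10, 1e4))
            t = float(rng.uniform(1e-4, 0.05))
            m = float(rng.uniform(1, 1e4))
            post = posterior_update(np.array(y), np.array(n), make_prior(np.array(t), m))
            lo, hi = sorted((y / n, t))
            assert lo - 1e-15 <= float(post.mean) <= hi + 1e-15

    def test_prior_weight_limits(self):
        y, n, t = np.array(30.0), np.array(5000.0), np.array(0.002)
        heavy = posterior_update(y, n, make_prior(t, 1e12)).mean
        light = posterior_update(y, n, make_prior(t, 1e-9)).mean
        assert heavy == pytest.approx(0.002, rel=1e-6)
        assert light == pytest.approx(30 / 5000, rel=1e-6)

    def test_posterior_mean_monotone_in_prior_weight(self):
        y, n, t = np.array(30.0), np.array(5000.0), np.array(0.002)
        means = [float(posterior_update(y, n, make_prior(t, m)).mean)
                 for m in (10.0, 100.0, 1000.0, 10000.0)]
        gaps = [abs(mu - 0.002) for mu in means]
        assert gaps == sorted(gaps, reverse=True)


class TestPosteriorInterval:
    def _bisect_quantile(self, q, shape, rate):
        """Independent CDF-inversion oracle via bisection on the gamma CDF."""
        f = lambda x: stats.gamma.cdf(x, shape, scale=1.0 / rate) - q
        hi = shape / rate * 50 + 10 / rate
        return brentq(f, 1e-300, hi, xtol=1e-14, rtol=1e-12)

    def test_endpoints_match_cdf_inversion(self):
        rng = np.random.default_rng(99)
        shapes = rng.uniform(0.5, 200, size=50)
        rates = rng.uniform(100, 1e5, size=50)
        lo, hi = posterior_interval(GammaPosterior(shapes, rates))
        for k in range(50):
            assert lo[k] == pytest.approx(self._bisect_quantile(0.025, shapes[k], rates[k]), abs=1e-8)
            assert hi[k] == pytest.approx(self._bisect_quantile(0.975, shapes[k], rates[k]), abs=1e-8)

    def test_equal_tailed_mass(self):
        rng = np.random.default_rng(5)
        shapes = rng.uniform(0.2, 500, size=100)
        rates = rng.uniform(10, 1e6, size=100)
        lo, hi = posterior_interval(GammaPosterior(shapes, rates))
        mass = stats.gamma.cdf(hi, shapes, scale=1 / rates) - stats.gamma.cdf(lo, shapes, scale=1 / rates)
        assert np.allclose(mass, 0.95, atol=1e-8)
        assert np.all(lo < shapes / rates) and np.all(shapes / rates < hi)

    def test_width_vanishes_in_concentration_limit(self):
        mean = 0.002
        widths = []
        for shape in (10.0, 1e3, 1e6):
            lo, hi = posterior_interval(GammaPosterior(np.array(shape), np.array(shape / mean)))
            widths.append(float(hi - lo))
        assert widths == sorted(widths, reverse=True)
        assert widths[-1] < 1e-5

    def test_invalid_level_rejected(self):
        with pytest.raises(ValidationError):
            posterior_interval(GammaPosterior(np.array(2.0), np.array(100.0)), level=1.5)


class TestCalibration:
    def test_posterior_intervals_cover_rates_drawn_from_prior(self):
        """Under the assumed model (θ ~ prior, y ~ Poisson(nθ)) the 95%
        posterior intervals must cover θ at 0.95 up to Monte-Carlo error."""
        rng = np.random.default_rng(31)
        N = 4000
        t, m, n = 0.005, 2000.0, 3000.0
        prior = make_prior(np.full(N, t), m)
        theta = rng.gamma(prior.shape, 1 / prior.rate)
        y = rng.poisson(n * theta)
        post = posterior_update(y.astype(float), np.full(N, n), prior)
        lo, hi = posterior_interval(post)
        cov = np.mean((lo <= theta) & (theta <= hi))
        # binomial MC error: 3*sqrt(0.95*0.05/4000) ~ 0.010
        assert cov == pytest.approx(0.95, abs=0.011)


class TestEstimatorSurface:
    def test_spatial_equals_nonspatial_on_symmetric_configuration(self, four_bin_scheme):
        """When every region's neighborhood is the rest of the domain and all
        regions are identical, the two smoothing targets coincide exactly."""
        y = np.tile([2, 3, 5, 8], (3, 1))
        n = np.full((3, 4), 1000.0)
        cube = CountCube(("A", "B", "C"), four_bin_scheme, y=y, n=n)
        nd = NeighborhoodDictionary({"A": ("B", "C"), "B": ("A", "C"), "C": ("A", "B")})
        ns = EmpiricalBayesSmoother(strategy="global").fit(cube)
        sp = EmpiricalBayesSmoother(strategy="neighborhood", adjacency=nd).fit(cube)
        assert np.allclose(ns.target_rate_, sp.target_rate_)
        assert np.allclose(ns.posterior_mean(), sp.posterior_mean())

    def test_default_prior_weight_is_median_exposure(self, small_cube):
        sm = EmpiricalBayesSmoother().fit(small_cube)
        assert np.allclose(sm.prior_weight_, np.median(small_cube.n, axis=0))

    def test_sklearn_params_round_trip(self):
        sm = EmpiricalBayesSmoother(strategy="neighborhood", prior_weight=5.0)
        params = sm.get_params()
        clone = EmpiricalBayesSmoother(**params)
        assert clone.get_params() == params

    def test_unfitted_access_rejected(self):
        with pytest.raises(ValidationError, match="not fitted"):
            EmpiricalBayesSmoother().posterior_mean()

    def test_prior_invariant_mean_equals_target(self, small_cube):
        sm = EmpiricalBayesSmoother().fit(small_cube)
        assert np.max(np.abs(sm.prior_.mean - sm.target_rate_)) < 1e-12
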