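import math

import numpy as np
import pytest

from tfpikinetics.inference import (
    Chain,
    LogLikelihood,
    ParameterSpace,
    adaptive_metropolis,
    lhs_preexplore,
    metropolis,
    prediction_bands,
    summarize,
    thin,
)
from tfpikinetics.protocols import (
    Dataset,
    ExperimentCondition,
    MeasurementSeries,
)


def make_chain(samples, names=None):
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] == 1 and samples.shape[1] > 1 and names is None:
        samples = samples.T
    n, d = samples.shape
    names = tuple(names or (f"p{j}" for j in range(d)))
    return Chain(samples, np.zeros(n), np.ones(n, dtype=bool),
                 np.full(n, "MA"), names)


class TestParameterSpace:
    def test_dimensions(self):
        assert ParameterSpace("full").dim == 11
        assert ParameterSpace("no_reaction_7").dim == 9

    def test_support_honours_bounds_and_constraint(self, param_space):
        theta = np.full(11, 0.1)
        theta[param_space.index("k_plus_2")] = 16.0
        theta[param_space.index("k_minus_7")] = 5e-3
        assert param_space.in_support(theta)
        # k+1 too small for the Michaelis constraint: k-1 would go negative
        bad = theta.copy()
        bad[param_space.index("k_plus_1")] = 0.01
        assert not param_space.in_support(bad)
        # zero is outside the open lower bound
        bad = theta.copy()
        bad[param_space.index("sigma")] = 0.0
        assert not param_space.in_support(bad)

    def test_build_rates_derives_tied_constants(self, param_space, table1):
        theta = param_space.theta_from_rates(table1, 0.05)
        r = param_space.build_rates(theta)
        assert r.k_minus_1 == pytest.approx(238.0 * 0.51 - 16.23)
        assert r.k_minus_3 == pytest.approx(520.0 * 0.16)
        assert r.k_minus_4 == pytest.approx(2.63e-2 * 3.67e-3)
        assert r.k_plus_5 == 0.0

    def test_alternative_variant_excludes_reaction_7(self):
        space = ParameterSpace("no_reaction_7")
        assert "k_plus_7" not in space.names
        theta = np.full(space.dim, 0.1)
        theta[space.index("k_plus_2")] = 10.0
        r = space.build_rates(theta)
        assert r.k_plus_7 == r.k_minus_7 == 0.0


class TestLogLikelihood:
    def one_point_dataset(self, mu, value):
        cond = ExperimentCondition.one(0.128)
        return Dataset((MeasurementSeries(cond, np.array([60.0]),
                                          np.array([value])),))

    def test_noise_free_data_attains_analytic_maximum(
        self, noise_free_dataset, reference_design, param_space
    ):
        """At the generating parameters, noise-free data yield exactly
        -sum(log(sigma*mu) + log(2*pi)/2)."""
        ll = LogLikelihood(noise_free_dataset, param_space)
        theta = reference_design.theta_full()
        sigma = reference_design.sigma_true
        expected = 0.0
        for s in noise_free_dataset.series:
            mu = ll.predict(theta, s.condition, s.times)
            expected += float(
                -np.sum(np.log(sigma * mu)) - 0.5 * len(s) * math.log(2 * math.pi)
            )
        assert ll(theta) == pytest.approx(expected, rel=1e-12)

    def test_one_standard_deviation_point(self, param_space, reference_design):
        """A single observation at mu*(1+sigma) contributes
        -log(sigma*mu) - log(2*pi)/2 - 1/2."""
        theta = reference_design.theta_full()
        sigma = reference_design.sigma_true
        cond = ExperimentCondition.one(0.128)
        probe = LogLikelihood(
            self.one_point_dataset(1.0, 1.0), param_space
        )
        mu = float(probe.predict(theta, cond, np.array([60.0]))[0])
        ll = LogLikelihood(self.one_point_dataset(mu, mu * (1 + sigma)), param_space)
        expected = -math.log(sigma * mu) - 0.5 * math.log(2 * math.pi) - 0.5
        assert ll(theta) == pytest.approx(expected, rel=1e-9)

    def test_row_order_invariance(self, reference_dataset, reference_design,
                                  param_space):
        theta = reference_design.theta_full()
        base = LogLikelihood(reference_dataset, param_space)(theta)
        shuffled = Dataset(tuple(reversed(reference_dataset.series)))
        assert LogLikelihood(shuffled, param_space)(theta) == pytest.approx(
            base, rel=1e-12
        )

    def test_out_of_bounds_theta_rejected(self, reference_dataset, param_space,
                                          reference_design):
        ll = LogLikelihood(reference_dataset, param_space)
        theta = reference_design.theta_full()
        theta[param_space.index("k_plus_1")] = 1.5  # above the diffusion limit
        assert ll(theta) == -np.inf

    def test_experiment_decomposition(self, reference_dataset, reference_design,
                                      param_space):
        """The total log-likelihood is the sum of the per-experiment parts."""
        theta = reference_design.theta_full()
        total = LogLikelihood(reference_dataset, param_space)(theta)
        parts = [
            LogLikelihood(Dataset(tuple(reference_dataset.by_experiment(k))),
                          param_space)(theta)
            for k in (1, 2)
        ]
        assert total == pytest.approx(sum(parts), rel=1e-12)


class TestLhsPreexplore:
    @staticmethod
    def quadratic_target(space):
        centre = space.upper / 2.0

        def log_post(theta):
            if not space.in_support(theta):
                return -np.inf
            z = (theta - centre) / space.upper
            return -float(z @ z)

        return log_post

    def test_deterministic_under_seeding(self, param_space):
        lp = self.quadratic_target(param_space)
        a, Va = lhs_preexplore(lp, param_space, 400, 100, seed=3)
        b, Vb = lhs_preexplore(lp, param_space, 400, 100, seed=3)
        assert np.array_equal(a, b)
        assert np.array_equal(Va, Vb)

    def test_centre_is_in_support(self, param_space):
        theta0, V = lhs_preexplore(
            self.quadratic_target(param_space), param_space, 400, 100, seed=3
        )
        assert param_space.in_support(theta0)
        assert np.all(np.diag(V) > 0)
        assert np.array_equal(V, np.diag(np.diag(V)))

    def test_top_k_equal_to_n_uses_every_feasible_sample(self, param_space):
        lp = self.quadratic_target(param_space)
        theta0, _ = lhs_preexplore(lp, param_space, 200, 200, seed=7)
        thetas = param_space.sample_lhs(200, seed=7)
        feasible = np.array([np.isfinite(lp(t)) for t in thetas])
        assert np.allclose(theta0, thetas[feasible].mean(axis=0))

    def test_all_rejected_raises(self, param_space):
        with pytest.raises(RuntimeError, match="-inf"):
            lhs_preexplore(lambda t: -np.inf, param_space, 100, 50, seed=0)


class TestMetropolis:
    def test_zero_spread_keeps_chain_constant(self):
        chain = metropolis(lambda t: 0.0, np.array([1.0, 2.0]),
                           np.zeros((2, 2)), 50, seed=0)
        assert np.all(chain.samples == [1.0, 2.0])

    def test_flat_target_acceptance_matches_inclusion_fraction(self):
        """On a flat density over a box, the acceptance rate equals the
        fraction of proposals landing inside the box."""
        rng = np.random.default_rng(42)
        lo, hi = -1.0, 1.0

        def log_post(t):
            return 0.0 if np.all((t >= lo) & (t <= hi)) else -np.inf

        cov = 0.5**2 * np.eye(1)
        chain = metropolis(log_post, np.array([0.0]), cov, 4000, seed=1)
        # independent estimate of the inclusion probability
        xs = np.zeros(20_000)
        inside = 0
        cur = 0.0
        for i in range(xs.size):
            prop = cur + 0.5 * rng.standard_normal()
            if lo <= prop <= hi:
                inside += 1
                cur = prop
        assert chain.acceptance_rate == pytest.approx(inside / xs.size, abs=0.03)

    def test_standard_normal_target_moments(self):
        chain = metropolis(
            lambda t: -0.5 * float(t @ t), np.array([0.0]),
            np.array([[1.0]]), 20_000, seed=5,
        )
        x = chain.samples[:, 0]
        ess_guess = x.size / 10  # generous correlation allowance
        assert abs(x.mean()) < 3.0 / math.sqrt(ess_guess)
        assert x.std() == pytest.approx(1.0, abs=0.1)

    def test_deterministic_under_seeding(self):
        a = metropolis(lambda t: -0.5 * float(t @ t), np.zeros(2),
                       np.eye(2), 200, seed=9)
        b = metropolis(lambda t: -0.5 * float(t @ t), np.zeros(2),
                       np.eye(2), 200, seed=9)
        assert np.array_equal(a.samples, b.samples)


class TestAdaptiveMetropolis:
    @staticmethod
    def gaussian_target(variances):
        v = np.asarray(variances)

        def log_post(t):
            return -0.5 * float(np.sum(t * t / v))

        return log_post

    def test_proposal_covariance_tracks_target(self):
        """On independent normals the adapted proposal covariance approaches
        (2.38^2/d) * diag(variances) within a factor of two."""
        var = np.array([1.0, 4.0])
        lp = self.gaussian_target(var)
        ma = metropolis(lp, np.zeros(2), 0.5 * np.eye(2), 2000, seed=2)
        am = adaptive_metropolis(lp, ma, 30_000, seed=3)
        sd = 2.38**2 / 2
        emp = np.cov(am.samples.T)
        for j in range(2):
            assert sd * emp[j, j] == pytest.approx(sd * var[j], rel=0.5)

    def test_deterministic_under_seeding(self):
        lp = self.gaussian_target([1.0])
        ma = metropolis(lp, np.zeros(1), np.eye(1), 100, seed=4)
        a = adaptive_metropolis(lp, ma, 500, seed=6)
        b = adaptive_metropolis(lp, ma, 500, seed=6)
        assert np.array_equal(a.samples, b.samples)

    def test_adaptation_beats_fixed_proposal_on_correlated_target(self):
        """On a strongly correlated 2-D normal, the adaptive phase mixes at
        least as well (per-parameter effective sample size) as a fixed
        spherical proposal started from the same state."""
        cov = np.array([[1.0, 0.95], [0.95, 1.0]])
        prec = np.linalg.inv(cov)

        def lp(t):
            return -0.5 * float(t @ prec @ t)

        ma = metropolis(lp, np.zeros(2), 0.1 * np.eye(2), 1000, seed=8)
        am = adaptive_metropolis(lp, ma, 8000, seed=9)
        fixed = metropolis(lp, ma.samples[-1], 0.1 * np.eye(2), 8000, seed=9)

        def ess(x):
            x = x - x.mean()
            acf1 = np.dot(x[:-1], x[1:]) / np.dot(x, x)
            return x.size * (1 - acf1) / (1 + acf1)

        assert ess(am.samples[:, 0]) >= ess(fixed.samples[:, 0])


class TestThin:
    def test_paper_scale_counts(self):
        """Burn 1e5 then stride 100 over a 1e5 + 6e6 chain leaves 6e4."""
        n_ma, n_am = 100_000, 6_000_000
        ma = make_chain(np.zeros((n_ma, 1)))
        am = Chain(np.zeros((n_am, 1)), np.zeros(n_am),
                   np.ones(n_am, dtype=bool), np.full(n_am, "AM"), ("p0",))
        thinned = thin(ma, am, burn=100_000, stride=100)
        assert len(thinned) == 60_000

    def test_identity_thinning(self):
        ma = make_chain(np.arange(5.0).reshape(-1, 1))
        am = Chain(np.arange(5.0, 8.0).reshape(-1, 1), np.zeros(3),
                   np.ones(3, dtype=bool), np.full(3, "AM"), ("p0",))
        thinned = thin(ma, am, burn=0, stride=1)
        assert np.array_equal(thinned.samples[:, 0], np.arange(8.0))

    def test_white_noise_autocorrelation_below_target(self):
        rng = np.random.default_rng(0)
        ma = make_chain(rng.standard_normal((500, 1)))
        am = Chain(rng.standard_normal((5000, 1)), np.zeros(5000),
                   np.ones(5000, dtype=bool), np.full(5000, "AM"), ("p0",))
        thinned = thin(ma, am, burn=500, stride=2)
        assert abs(thinned.diagnostics["lag1_autocorr"]["p0"]) < 0.05

    def test_overlong_burn_rejected(self):
        ma = make_chain(np.zeros((10, 1)))
        am = make_chain(np.zeros((10, 1)))
        with pytest.raises(ValueError):
            thin(ma, am, burn=100, stride=1)


class TestSummarize:
    def test_constant_chain_collapses_intervals(self):
        chain = make_chain(np.full((50, 2), 3.25), names=("a", "b"))
        s = summarize(chain)
        assert s.median("a") == 3.25
        assert s.interval("a") == (3.25, 3.25)

    def test_derived_medians_commute_with_fixed_ratios(self, param_space):
        rng = np.random.default_rng(1)
        samples = rng.uniform(0.05, 0.9, size=(400, param_space.dim))
        samples[:, param_space.index("k_plus_2")] *= 20
        chain = make_chain(samples, names=param_space.names)
        s = summarize(chain, param_space)
        assert s.median("k_minus_3") == pytest.approx(
            520.0 * s.median("k_plus_3"), rel=1e-12
        )
        assert s.median("k_minus_4") / s.median("k_plus_4") == pytest.approx(
            2.63e-2, rel=1e-12
        )

    def test_intervals_bracket_medians(self, param_space):
        rng = np.random.default_rng(2)
        samples = rng.uniform(0.05, 0.9, size=(300, param_space.dim))
        s = summarize(make_chain(samples, names=param_space.names), param_space)
        t = s.table
        assert np.all(t["ci_lower"] <= t["median"])
        assert np.all(t["median"] <= t["ci_upper"])


class TestPredictionBands:
    def test_single_sample_chain_collapses_bands(
        self, reference_design, reference_dataset, param_space
    ):
        ll = LogLikelihood(reference_dataset, param_space)
        theta = reference_design.theta_full()
        chain = make_chain(theta.reshape(1, -1), names=param_space.names)
        times = np.array([60.0, 360.0, 720.0])
        bands = prediction_bands(chain, ExperimentCondition.one(0.128),
                                 times, ll)
        for pct in (70, 90, 99):
            assert np.allclose(bands[f"lower_{pct}"], bands["median"])
            assert np.allclose(bands[f"upper_{pct}"], bands["median"])

    def test_bands_are_nested(self, reference_design, reference_dataset,
                              param_space):
        rng = np.random.default_rng(3)
        theta = reference_design.theta_full()
        draws = theta * rng.uniform(0.9, 1.1, size=(30, theta.size))
        chain = make_chain(draws, names=param_space.names)
        ll = LogLikelihood(reference_dataset, param_space)
        times = np.array([120.0, 600.0])
        bands = prediction_bands(chain, ExperimentCondition.one(0.256),
                                 times, ll)
        assert np.all(bands["lower_99"] <= bands["lower_90"])
        assert np.all(bands["lower_90"] <= bands["lower_70"])
        assert np.all(bands["upper_70"] <= bands["upper_90"])
        assert np.all(bands["upper_90"] <= bands["upper_99"])

    def test_truth_inside_wide_band(self, reference_design, reference_dataset,
                                    param_space):
        """A chain of small perturbations around the truth brackets the
        noise-free truth curve within its 99% band nearly everywhere."""
        rng = np.random.default_rng(4)
        theta = reference_design.theta_full()
        draws = theta * rng.uniform(0.95, 1.05, size=(40, theta.size))
        chain = make_chain(draws, names=param_space.names)
        ll = LogLikelihood(reference_dataset, param_space)
        times = np.linspace(60.0, 720.0, 12)
        cond = ExperimentCondition.one(0.128)
        bands = prediction_bands(chain, cond, times, ll)
        truth = ll.predict(theta, cond, times)
        inside = (bands["lower_99"] <= truth) & (truth <= bands["upper_99"])
        assert inside.mean() >= 0.95
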