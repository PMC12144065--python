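import numpy as np
import pytest
from scipy import integrate, stats

from vacmorph import ssm as vs
from vacmorph import synthetic as vg

# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------


class TestBetaProportionLogpdf:
    def test_uniform_reduction(self, rng):
        """mu=0.5, kappa=2 is Beta(1,1): log density 0 everywhere."""
        for theta in rng.uniform(0.01, 0.99, 20):
            assert vs.beta_proportion_logpdf(theta, 0.5, 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_beta_7_3_oracle(self):
        # mu=0.7, kappa=10 -> Beta(7, 3); independent log-gamma implementation
        val = vs.beta_proportion_logpdf(0.3, 0.7, 10.0)
        oracle = stats.beta.logpdf(0.3, 7.0, 3.0)
        assert val == pytest.approx(oracle, abs=1e-10)

    def test_random_triples_match_scipy(self, rng):
        for _ in range(100):
            theta = rng.uniform(0.01, 0.99)
            mu = rng.uniform(0.05, 0.95)
            kappa = rng.uniform(0.5, 200.0)
            assert vs.beta_proportion_logpdf(theta, mu, kappa) == pytest.approx(
                stats.beta.logpdf(theta, mu * kappa, (1 - mu) * kappa), abs=1e-10
            )

    @pytest.mark.parametrize("mu", [0.2, 0.5, 0.8])
    @pytest.mark.parametrize("kappa", [1.5, 10.0, 80.0])
    def test_integrates_to_one(self, mu, kappa):
        val, _ = integrate.quad(
            lambda x: np.exp(vs.beta_proportion_logpdf(x, mu, kappa)), 0.0, 1.0
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_outside_support_is_minus_inf(self):
        assert vs.beta_proportion_logpdf(0.0, 0.5, 5.0) == -np.inf
        assert vs.beta_proportion_logpdf(1.0, 0.5, 5.0) == -np.inf
        assert vs.beta_proportion_logpdf(-0.2, 0.5, 5.0) == -np.inf

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            vs.beta_proportion_logpdf(0.5, 1.2, 5.0)
        with pytest.raises(ValueError):
            vs.beta_proportion_logpdf(0.5, 0.5, -1.0)

    def test_broadcasts(self):
        out = vs.beta_proportion_logpdf(np.array([0.2, 0.5, 0.8]), 0.5, 4.0)
        assert out.shape == (3,)


class TestCauchyLogpdf:
    def test_mode_value(self):
        sigma = 0.7
        assert vs.cauchy_logpdf(1.3, 1.3, sigma) == pytest.approx(np.log(1 / (np.pi * sigma)))

    def test_half_maximum_at_one_scale(self):
        mode = vs.cauchy_logpdf(0.0, 0.0, 2.0)
        assert vs.cauchy_logpdf(2.0, 0.0, 2.0) == pytest.approx(mode - np.log(2.0))

    def test_integrates_to_one(self):
        val, _ = integrate.quad(
            lambda x: np.exp(vs.cauchy_logpdf(x, 0.5, 0.3)), -np.inf, np.inf
        )
        assert val == pytest.approx(1.0, abs=1e-4)

    def test_matches_scipy(self, rng):
        for _ in range(50):
            theta, mu = rng.normal(0, 3, 2)
            sigma = rng.uniform(0.05, 5.0)
            assert vs.cauchy_logpdf(theta, mu, sigma) == pytest.approx(
                stats.cauchy.logpdf(theta, mu, sigma), abs=1e-12
            )

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            vs.cauchy_logpdf(0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------


class TestSSMData:
    def test_from_arrays_drops_nan(self):
        c = np.array([[0.5, np.nan], [0.6, 0.7]])
        e = np.array([[0.4, 0.5], [0.5, 0.6]])
        data = vs.SSMData.from_arrays(c, e)
        assert data.control[1].size == 1

    def test_clipping_policy_warns(self):
        c = np.array([[0.5, 1.0], [0.6, 0.7]])  # the 1.0 is out of support
        e = np.array([[0.4, 0.5], [0.5, 0.6]])
        with pytest.warns(UserWarning, match="clipped"):
            data = vs.SSMData.from_arrays(c, e)
        assert np.all(data.control[1] < 1.0)

    def test_drop_first_excludes_t0(self):
        c = np.full((2, 5), 0.5)
        e = np.full((2, 5), 0.5)
        data = vs.SSMData.from_arrays(c, e, drop_first=True)
        assert data.T == 4

    def test_from_series_excludes_reference_point(self, rng):
        from vacmorph.morphodynamics import NCCSeries

        times = np.arange(5) * 10.0
        mk = lambda cond: NCCSeries(
            f"{cond}{rng.integers(1e6)}", cond,
            times, np.concatenate([[1.0], rng.uniform(0.4, 0.9, 4)]),
        )
        series = [mk("mock"), mk("mock"), mk("wort"), mk("wort")]
        data = vs.SSMData.from_series(series, "mock", "wort")
        assert data.T == 4
        assert all(np.all(v < 1.0) for v in data.control)

    def test_too_short(self):
        with pytest.raises(ValueError):
            vs.SSMData([np.array([0.5])], [np.array([0.5])])


# ---------------------------------------------------------------------------
# log posterior
# ---------------------------------------------------------------------------


class TestLogPosterior:
    def test_hand_computed_T2(self):
        """T=2, one observation per group: sum of the four density terms."""
        data = vs.SSMData(
            control=[np.array([0.6]), np.array([0.55])],
            experimental=[np.array([0.4]), np.array([0.45])],
        )
        params = vs.SSMParams(
            mu=np.array([0.6, 0.58]),
            delta=np.array([-0.15, -0.12]),
            sigma_mu=0.05,
            sigma_delta=0.03,
            kappa=20.0,
        )
        expected = (
            stats.norm.logpdf(0.58, 0.6, 0.05)
            + stats.cauchy.logpdf(-0.12, -0.15, 0.03)
            + stats.beta.logpdf(0.6, 0.6 * 20, 0.4 * 20)
            + stats.beta.logpdf(0.55, 0.58 * 20, 0.42 * 20)
            + stats.beta.logpdf(0.4, 0.45 * 20, 0.55 * 20)
            + stats.beta.logpdf(0.45, 0.46 * 20, 0.54 * 20)
        )
        assert vs.log_posterior(params, data) == pytest.approx(expected, abs=1e-9)

    def test_label_swap_symmetry_at_zero_delta(self):
        obs = [np.array([0.5, 0.6]), np.array([0.55, 0.65])]
        data = vs.SSMData(control=obs, experimental=obs)
        swapped = vs.SSMData(control=obs, experimental=obs)
        params = vs.SSMParams(
            mu=np.array([0.55, 0.6]), delta=np.zeros(2),
            sigma_mu=0.1, sigma_delta=0.1, kappa=10.0,
        )
        assert vs.log_posterior(params, data) == pytest.approx(
            vs.log_posterior(params, swapped)
        )

    def test_duplicated_replicates_add_observation_terms(self):
        c = [np.array([0.6]), np.array([0.5])]
        e = [np.array([0.4]), np.array([0.45])]
        data1 = vs.SSMData(control=c, experimental=e)
        data2 = vs.SSMData(
            control=[np.tile(v, 2) for v in c],
            experimental=[np.tile(v, 2) for v in e],
        )
        params = vs.SSMParams(
            mu=np.array([0.55, 0.52]), delta=np.array([-0.1, -0.08]),
            sigma_mu=0.05, sigma_delta=0.05, kappa=15.0,
        )
        lp1 = vs.log_posterior(params, data1)
        lp2 = vs.log_posterior(params, data2)
        obs_sum = sum(
            vs.beta_proportion_logpdf(c[t][0], params.mu[t], 15.0)
            + vs.beta_proportion_logpdf(
                e[t][0], params.mu[t] + params.delta[t], 15.0
            )
            for t in range(2)
        )
        assert lp2 - lp1 == pytest.approx(obs_sum, abs=1e-9)

    def test_support_violation_minus_inf(self):
        data = vs.SSMData(
            control=[np.array([0.5]), np.array([0.5])],
            experimental=[np.array([0.5]), np.array([0.5])],
        )
        bad = vs.SSMParams(
            mu=np.array([0.9, 0.9]), delta=np.array([0.2, 0.2]),
            sigma_mu=0.1, sigma_delta=0.1, kappa=10.0,
        )
        assert vs.log_posterior(bad, data) == -np.inf

    def test_finite_on_interior_path(self, rng):
        data = vs.SSMData(
            control=[rng.uniform(0.3, 0.7, 3) for _ in range(4)],
            experimental=[rng.uniform(0.3, 0.7, 3) for _ in range(4)],
        )
        for lam in np.linspace(0.05, 0.95, 10):
            params = vs.SSMParams(
                mu=np.full(4, 0.2 + 0.6 * lam), delta=np.full(4, 0.1 * (lam - 0.5)),
                sigma_mu=0.01 + lam, sigma_delta=0.01 + lam, kappa=1.0 + 50 * lam,
            )
            assert np.isfinite(vs.log_posterior(params, data))


class TestTargetGradient:
    def test_matches_finite_differences(self, rng):
        mu = 0.5 + 0.3 * np.sin(np.linspace(0, 3, 6))
        truth = vg.SSMTruth(mu, np.full(6, -0.05), 30.0, 3, 3, seed=5)
        c, e = vg.simulate_ncc_series(truth)
        data = vs.SSMData.from_arrays(c, e)
        target = vs._Target(data)
        z = vs._initial_point(data, target, rng)
        lp, grad = target.logp_grad(z)
        assert np.isfinite(lp)
        h = 1e-6
        for i in range(z.size):
            zp, zm = z.copy(), z.copy()
            zp[i] += h
            zm[i] -= h
            fd = (target.logp_grad(zp)[0] - target.logp_grad(zm)[0]) / (2 * h)
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-4)

    def test_unconstrained_target_consistent_with_log_posterior(self, rng):
        """Up to the transform Jacobian, both routes agree."""
        mu = np.full(5, 0.6)
        truth = vg.SSMTruth(mu, np.full(5, -0.1), 25.0, 3, 3, seed=2)
        c, e = vg.simulate_ncc_series(truth)
        data = vs.SSMData.from_arrays(c, e)
        target = vs._Target(data)
        z = vs._initial_point(data, target, rng)
        lp_unc, _ = target.logp_grad(z)
        params = target.to_params(z)
        lp_con = vs.log_posterior(params, data)
        # jacobian of mu-logit, the increment transform, and the log scales
        from scipy.special import expit

        T = data.T
        a = z[:T]
        ut = z[T + 1 : 2 * T]
        u = expit(ut)
        c_inc = np.tan(np.pi * (u - 0.5))
        sd = np.exp(z[2 * T + 1])
        jmu = np.sum(np.log(expit(a) * (1 - expit(a))))
        # delta_t = delta1 + sd*cumsum(c): d w_t/d utilde = sd*pi*(1+c^2)*u(1-u)
        jdelta = np.sum(np.log(sd * np.pi * (1 + c_inc**2) * u * (1 - u)))
        jscales = z[2 * T] + z[2 * T + 1] + z[2 * T + 2]
        assert lp_unc - (jmu + jdelta + jscales) == pytest.approx(lp_con, abs=1e-8)


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------


def _tiny_fit(data, seed=0, chains=2, warmup=200, draws=200):
    return vs.sample_posterior(
        data,
        vs.SamplerSettings(chains=chains, warmup=warmup, draws=draws, seed=seed),
        compute_diagnostics=False,
    )


@pytest.fixture(scope="module")
def small_data():
    mu = 0.8 - 0.3 * np.linspace(0, 1, 10)
    truth = vg.SSMTruth(mu, np.full(10, -0.12), 60.0, 5, 5, seed=42)
    c, e = vg.simulate_ncc_series(truth)
    return vs.SSMData.from_arrays(c, e), mu


class TestSamplePosterior:
    def test_seed_determinism(self, small_data):
        data, _ = small_data
        p1 = _tiny_fit(data, seed=3, warmup=100, draws=100)
        p2 = _tiny_fit(data, seed=3, warmup=100, draws=100)
        assert np.array_equal(p1.mu, p2.mu)
        assert np.array_equal(p1.delta, p2.delta)

    def test_recovers_small_example(self, small_data):
        data, mu = small_data
        post = _tiny_fit(data, seed=1)
        s = vs.summarize(post)
        assert np.sqrt(np.mean((s["mu_med"].values - mu) ** 2)) < 0.05
        # strong persistent difference should be detected at most times
        assert s["excludes_zero"].mean() > 0.6

    def test_label_swap_antisymmetry(self, small_data):
        data, _ = small_data
        swapped = vs.SSMData(control=data.experimental, experimental=data.control)
        s1 = vs.summarize(_tiny_fit(data, seed=5))
        s2 = vs.summarize(_tiny_fit(swapped, seed=5))
        assert np.allclose(s1["delta_med"], -s2["delta_med"], atol=0.05)

    def test_draw_shapes_and_support(self, small_data):
        data, _ = small_data
        post = _tiny_fit(data, seed=2, warmup=100, draws=50)
        assert post.mu.shape == (2, 50, data.T)
        nu = post.mu + post.delta
        assert np.all((post.mu > 0) & (post.mu < 1))
        assert np.all((nu > 0) & (nu < 1))
        assert np.all(post.kappa > 0)

    def test_diagnostics_table(self, small_data):
        data, _ = small_data
        post = vs.sample_posterior(
            data, vs.SamplerSettings(chains=2, warmup=150, draws=150, seed=4)
        )
        assert post.diagnostics is not None
        assert {"parameter", "rhat", "ess_bulk"} <= set(post.diagnostics.columns)
        assert len(post.diagnostics) == 2 * data.T + 3


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


class TestSummarize:
    def test_degenerate_posterior(self):
        draws = {"mu": np.full((100, 3), 0.6), "delta": np.full((100, 3), -0.1)}
        s = vs.summarize(draws)
        assert np.allclose(s["mu_med"], 0.6)
        assert np.allclose(s["mu_hi"] - s["mu_lo"], 0.0)
        assert s["excludes_zero"].all()

    def test_normal_draws_quantiles(self):
        g = np.random.default_rng(0)
        draws = {
            "mu": g.uniform(0.4, 0.6, (100000, 2)),
            "delta": g.standard_normal((100000, 2)),
        }
        s = vs.summarize(draws)
        assert np.allclose(s["delta_lo"], -1.96, atol=0.02)
        assert np.allclose(s["delta_hi"], 1.96, atol=0.02)
        assert not s["excludes_zero"].any()

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            vs.summarize({"mu": np.empty((0, 2)), "delta": np.empty((0, 2))})

    def test_excludes_zero_flag(self):
        draws = {
            "mu": np.full((1000, 2), 0.5),
            "delta": np.column_stack(
                [np.full(1000, 0.2), np.linspace(-1, 1, 1000)]
            ),
        }
        s = vs.summarize(draws)
        assert bool(s["excludes_zero"][0]) is True
        assert bool(s["excludes_zero"][1]) is False
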