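"""Hierarchical meta-regression: design coding, densities, sampler,
diagnostics and derived quantities, checked against closed forms and a
brute-force grid-integration oracle."""

import math

import numpy as np
import pytest
from scipy import stats

from bluecarbon.compilation import AdjustedEstimate
from bluecarbon.model import (
    DesignMatrix,
    ModelData,
    ModelSpec,
    ParameterState,
    bayes_r2,
    build_design,
    effective_sample_size,
    fit_mcmc,
    fold_variation,
    gelman_rubin,
    log_likelihood,
    log_posterior,
    log_prior,
    model_data,
)
from tests.conftest import make_adjusted


def adj(eid, sid, habitat="mangrove", climate="tropical", method="bayesian",
        depth=0.2, nend=3, nrep=6, lr=0.0, sd=0.5):
    return AdjustedEstimate(
        estimate_id=eid, study_id=sid, habitat=habitat, climate=climate,
        method=method, depth_mid_m=depth, n_endmembers=nend, n_replicates=nrep,
        logratio_mean=lr, logratio_sd=sd,
    )


class TestBuildDesign:
    def setup_method(self):
        self.spec = ModelSpec(chains=2, iterations=20, warmup=10)

    def test_reference_record_codes_to_zero_dummies(self):
        ests = [
            adj("a", "s1"),
            adj("b", "s2", habitat="saltmarsh", climate="temperate",
                method="standard", depth=0.4, nend=5, nrep=10),
        ]
        d = build_design(ests, self.spec)
        row = d.X[0]
        dummy_cols = [j for j, n in enumerate(d.column_names) if "[" in n]
        assert all(row[j] == 0.0 for j in dummy_cols)
        assert row[0] == 1.0  # intercept

    def test_centering_and_scaling(self):
        ests = [
            adj("a", "s1", depth=0.1, nend=2, nrep=4),
            adj("b", "s2", habitat="saltmarsh", climate="temperate",
                method="standard", depth=0.3, nend=4, nrep=8),
            adj("c", "s3", habitat="seagrass", depth=0.2, nend=3, nrep=6),
        ]
        d = build_design(ests, self.spec)
        j = d.column_names.index("depth_mid_m")
        col = d.X[:, j]
        assert np.mean(col) == pytest.approx(0.0, abs=1e-10)
        assert np.std(col, ddof=1) == pytest.approx(1.0, abs=1e-10)
        # record at the mean has scaled depth 0
        assert col[2] == pytest.approx(0.0, abs=1e-12)
        # record one SD above the mean has scaled depth +1 (depends on sample)
        assert col[1] == pytest.approx((0.3 - d.centers["depth_mid_m"]) / d.scales["depth_mid_m"])

    def test_nonreference_levels_code_to_one(self):
        ests = [
            adj("a", "s1"),
            adj("b", "s2", habitat="saltmarsh", climate="temperate", method="standard"),
        ]
        d = build_design(
            ests,
            ModelSpec(fixed_effects=("habitat", "climate", "method"),
                      chains=2, iterations=20, warmup=10),
        )
        names = d.column_names
        row = d.X[1]
        for col in ("habitat[saltmarsh]", "climate[temperate]", "method[standard]"):
            assert row[names.index(col)] == 1.0

    def test_constant_dummy_dropped_with_warning(self):
        ests = [adj("a", "s1"), adj("b", "s2")]  # all mangrove/tropical/bayesian
        with pytest.warns(UserWarning, match="constant dummy"):
            d = build_design(
                ests,
                ModelSpec(fixed_effects=("habitat", "climate", "method"),
                          chains=2, iterations=20, warmup=10),
            )
        assert all("[" not in n for n in d.column_names)

    def test_zero_variance_continuous_is_error_naming_column(self):
        ests = [adj("a", "s1", depth=0.2), adj("b", "s2", habitat="seagrass", depth=0.2)]
        with pytest.raises(ValueError, match="depth_mid_m"):
            build_design(ests, ModelSpec(fixed_effects=("depth_mid_m",),
                                         chains=2, iterations=20, warmup=10))

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            build_design([adj("a", "s1"), adj("b", "s1")], self.spec)


def _null_data(y, s, study_ids):
    labels = tuple(dict.fromkeys(study_ids))
    pos = {g: i for i, g in enumerate(labels)}
    design = DesignMatrix(
        X=np.ones((len(y), 1)),
        column_names=("intercept",),
        centers={},
        scales={},
        group_index=np.array([pos[g] for g in study_ids], dtype=np.intp),
        group_labels=labels,
    )
    return ModelData(y=np.asarray(y, float), sigma_hat=np.asarray(s, float), design=design)


class TestDensities:
    def test_loglik_single_observation_oracle(self):
        data = _null_data([1.0], [1.0], ["s1"])
        state = ParameterState(beta=np.array([1.0]), zeta=np.array([0.0]),
                               sigma_between=0.5, sigma_resid=1.0)
        expected = stats.norm.logpdf(1.0, 1.0, math.sqrt(2.0))
        assert log_likelihood(state, data) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-1.2655, abs=1e-4)

    def test_loglik_standard_normal_mode(self):
        data = _null_data([0.7], [0.0], ["s1"])
        state = ParameterState(beta=np.array([0.7]), zeta=np.array([0.0]),
                               sigma_between=0.5, sigma_resid=1.0)
        assert log_likelihood(state, data) == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_loglik_additivity(self):
        one = _null_data([0.3], [0.4], ["s1"])
        two = _null_data([0.3, 0.3], [0.4, 0.4], ["s1", "s1"])
        state1 = ParameterState(np.array([0.1]), np.array([0.2]), 0.5, 0.6)
        assert log_likelihood(state1, two) == pytest.approx(
            2 * log_likelihood(state1, one), rel=1e-12
        )

    def test_prior_truncated_scale_mode_density(self):
        spec = ModelSpec(chains=2, iterations=20, warmup=10)
        state = ParameterState(np.zeros(2), np.zeros(3), 0.5, 0.5)
        tn = stats.truncnorm(a=(0 - 0.5) / 0.1, b=np.inf, loc=0.5, scale=0.1)
        expected = (
            5 * stats.norm.logpdf(0.0) + 2 * tn.logpdf(0.5)
        )
        assert log_prior(state, spec) == pytest.approx(expected, rel=1e-10)

    def test_prior_additivity_in_zeta_length(self):
        spec = ModelSpec(chains=2, iterations=20, warmup=10)
        short = ParameterState(np.zeros(1), np.array([0.3]), 0.5, 0.5)
        long = ParameterState(np.zeros(1), np.array([0.3, 0.3]), 0.5, 0.5)
        assert log_prior(long, spec) - log_prior(short, spec) == pytest.approx(
            stats.norm.logpdf(0.3), rel=1e-10
        )

    def test_prior_out_of_support(self):
        spec = ModelSpec(chains=2, iterations=20, warmup=10)
        state = ParameterState(np.zeros(1), np.zeros(1), 0.5, -0.1)
        assert log_prior(state, spec) == -np.inf

    def test_posterior_is_likelihood_plus_prior(self):
        rng = np.random.default_rng(0)
        data = _null_data([0.2, -0.4, 0.9], [0.3, 0.5, 0.2], ["s1", "s2", "s1"])
        spec = ModelSpec(chains=2, iterations=20, warmup=10)
        for _ in range(10):
            state = ParameterState(
                beta=rng.normal(size=1),
                zeta=rng.normal(size=2),
                sigma_between=float(rng.uniform(0.1, 1.0)),
                sigma_resid=float(rng.uniform(0.1, 1.0)),
            )
            assert log_posterior(state, data, spec) == pytest.approx(
                log_likelihood(state, data) + log_prior(state, spec), rel=1e-12
            )

    def test_posterior_invariant_to_study_relabeling(self):
        spec = ModelSpec(chains=2, iterations=20, warmup=10)
        a = _null_data([0.2, -0.4], [0.3, 0.5], ["s1", "s2"])
        b = _null_data([-0.4, 0.2], [0.5, 0.3], ["s2", "s1"])
        state = ParameterState(np.array([0.1]), np.array([0.4, -0.7]), 0.5, 0.4)
        swapped = ParameterState(np.array([0.1]), np.array([-0.7, 0.4]), 0.5, 0.4)
        assert log_posterior(state, a, spec) == pytest.approx(
            log_posterior(swapped, b, spec), rel=1e-12
        )


def _grid_posterior_mean_mu(data, spec):
    """Brute-force posterior mean of the study-1 mean mu = beta0 + zeta1*sigma_b
    for an intercept-only, 2-study problem, by dense grid integration."""
    b0 = np.linspace(-3.0, 3.0, 61)
    z1 = np.linspace(-4.0, 4.0, 41)
    z2 = np.linspace(-4.0, 4.0, 41)
    sb = np.linspace(0.05, 1.0, 24)
    sr = np.linspace(0.05, 1.0, 24)
    B0, Z1, Z2, SB, SR = np.meshgrid(b0, z1, z2, sb, sr, indexing="ij", sparse=True)

    def norm_logpdf(x, mean, sd):
        return -0.5 * np.log(2 * np.pi * sd**2) - 0.5 * (x - mean) ** 2 / sd**2

    logp = (
        norm_logpdf(B0, 0.0, 1.0)
        + norm_logpdf(Z1, 0.0, 1.0)
        + norm_logpdf(Z2, 0.0, 1.0)
        + norm_logpdf(SB, 0.5, 0.1)
        + norm_logpdf(SR, 0.5, 0.1)
    )
    zmap = {0: Z1, 1: Z2}
    for i in range(len(data.y)):
        mu_i = B0 + zmap[int(data.design.group_index[i])] * SB
        sd_i = np.sqrt(data.sigma_hat[i] ** 2 + SR**2)
        logp = logp + norm_logpdf(data.y[i], mu_i, sd_i)
    w = np.exp(logp - logp.max())
    mu1 = B0 + Z1 * SB
    return float(np.sum(w * mu1) / np.sum(w))


class TestSampler:
    def test_seeded_determinism(self):
        ests, _ = make_adjusted(n=20, n_studies=8, seed=3)
        spec = ModelSpec(fixed_effects=(), chains=2, iterations=300, warmup=100, seed=9)
        data = model_data(ests, spec)
        a = fit_mcmc(data, spec)
        b = fit_mcmc(data, spec)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.sigma_resid, b.sigma_resid)

    def test_posterior_mean_matches_grid_integration(self):
        data = _null_data([0.8, 0.5, -0.3], [0.3, 0.4, 0.3], ["s1", "s1", "s2"])
        spec = ModelSpec(fixed_effects=(), chains=4, iterations=4000, warmup=1000, seed=21)
        draws = fit_mcmc(data, spec)
        mu1 = (
            draws.beta[:, :, 0] + draws.zeta[:, :, 0] * draws.sigma_between
        ).reshape(-1)
        exact = _grid_posterior_mean_mu(data, spec)
        assert np.mean(mu1) == pytest.approx(exact, abs=0.02)

    def test_draw_shapes_and_positive_scales(self):
        ests, _ = make_adjusted(n=20, n_studies=8, seed=3)
        spec = ModelSpec(fixed_effects=("habitat",), chains=2, iterations=400,
                         warmup=150, seed=1)
        draws = fit_mcmc(model_data(ests, spec), spec)
        assert draws.beta.shape[:2] == (2, 250)
        assert np.all(draws.sigma_between > 0)
        assert np.all(draws.sigma_resid > 0)

    def test_convergence_gate_on_default_fixture(self, small_fit):
        draws, _, _, _ = small_fit
        diag = draws.diagnostics()
        assert (diag["rhat"] <= 1.01).all()
        assert (diag["ess"] >= 400).all()

    def test_null_fit_recovers_grand_mean_on_zero_signal(self):
        ests, _ = make_adjusted(
            n=60, n_studies=30, seed=15, beta_intercept=0.7, beta_saltmarsh=0.0,
            sigma_between=0.3, sigma_resid=0.2,
        )
        spec = ModelSpec(fixed_effects=(), chains=2, iterations=1500, warmup=500, seed=2)
        draws = fit_mcmc(model_data(ests, spec), spec)
        b0 = draws.beta[:, :, 0].reshape(-1)
        lo, hi = np.quantile(b0, [0.025, 0.975])
        assert lo <= 0.7 <= hi

    def test_heterogeneity_interval_tightens_with_more_studies(self):
        widths = []
        for n_studies, n in [(20, 28), (80, 112), (320, 448)]:
            ests, _ = make_adjusted(n=n, n_studies=n_studies, seed=31,
                                    sigma_between=0.5)
            spec = ModelSpec(fixed_effects=(), chains=2, iterations=1200,
                             warmup=400, seed=6)
            draws = fit_mcmc(model_data(ests, spec), spec)
            lo, hi = np.quantile(draws.sigma_between.reshape(-1), [0.025, 0.975])
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]


class TestDiagnostics:
    def test_gelman_rubin_identical_chains_classic_formula(self):
        chains = np.array([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        assert gelman_rubin(chains) == pytest.approx(math.sqrt(3 / 4), rel=1e-12)

    def test_gelman_rubin_converged_chains_near_one(self):
        rng = np.random.default_rng(8)
        chains = rng.standard_normal((2, 20_000))
        assert 0.99 < gelman_rubin(chains) < 1.01

    def test_gelman_rubin_separated_chains(self):
        rng = np.random.default_rng(9)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert gelman_rubin(chains) > 1.5

    def test_gelman_rubin_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.ones((1, 100)))

    def test_ess_independent_draws(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(4000)
        assert effective_sample_size(x) == pytest.approx(4000, rel=0.15)

    def test_ess_ar1_closed_form(self):
        rng = np.random.default_rng(13)
        rho, n = 0.9, 200_000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * math.sqrt(1 - rho**2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        expected = n * (1 - rho) / (1 + rho)
        assert effective_sample_size(x) == pytest.approx(expected, rel=0.25)

    def test_ess_constant_chain_degenerate(self):
        assert effective_sample_size(np.ones(100)) == 0.0


class TestDerived:
    def test_fold_variation_values(self):
        assert fold_variation(np.array([0.65]))[0] == pytest.approx(3.6693, abs=1e-3)
        assert fold_variation(np.array([0.0]))[0] == 1.0
        assert fold_variation(np.array([math.log(2) / 2]))[0] == pytest.approx(2.0)

    def test_bayes_r2_hand_case(self):
        # mu = (0, 1, 2), sigma_hat = 1, sigma = 1:
        # V_fit = 1, V_res = mean(1 + 1) = 2, R2 = 1/3
        mu = np.array([0.0, 1.0, 2.0])
        v_fit = np.var(mu, ddof=1)
        v_res = np.mean(np.ones(3) + 1.0)
        assert v_fit / (v_fit + v_res) == pytest.approx(1 / 3)

    def test_bayes_r2_within_unit_interval(self, small_fit):
        draws, data, _, _ = small_fit
        r2 = bayes_r2(draws, data)
        assert np.all((r2["draws"] >= 0) & (r2["draws"] <= 1))
        assert 0 < r2["median"] < 1

    def test_bayes_r2_noiseless_limit(self):
        data = _null_data([0.0, 1.0, 2.0], [0.0, 0.0, 0.0], ["s1", "s2", "s3"])
        spec = ModelSpec(fixed_effects=(), chains=2, iterations=20, warmup=10)

        class Tiny:
            n_chains = 1
            sigma_resid = np.full((1, 4), 1e-9)

            def linear_predictors(self, design):
                return np.tile(np.array([0.0, 1.0, 2.0]), (4, 1))

        r2 = bayes_r2(Tiny(), data)
        assert r2["median"] == pytest.approx(1.0, abs=1e-12)

    def test_bayes_r2_single_observation_rejected(self, small_fit):
        draws, _, _, _ = small_fit
        data = _null_data([0.5], [0.2], ["s1"])
        with pytest.raises(ValueError):
            bayes_r2(draws, data)
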