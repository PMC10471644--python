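import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pufalakes.hier_bayes import (
    FitResult,
    ModelSpec,
    ParameterState,
    _deviance_from_vector,
    _ModelData,
    fit,
    gelman_rubin,
    linear_predictor,
    log_likelihood,
    mc_error_ratio,
    select_model,
)
from pufalakes.synthetic_data import (
    GeneratorConfig,
    generate_responses,
    generate_survey,
    simulate_parameter_state,
)

from conftest import make_sample


def pooled_normal_setup(n=60, seed=0, mu=2.0):
    """n independent sites with a single mean on the log scale."""
    rng = np.random.default_rng(seed)
    y = np.exp(rng.normal(mu, 1.0, n))
    samples = [
        make_sample({"A": 1}, lake_id=f"L{i // 2:03d}", site_id=f"S{i % 2}")
        for i in range(n)
    ]
    responses = pd.DataFrame(
        {
            "lake_id": [s.lake_id for s in samples],
            "site_id": [s.site_id for s in samples],
            "y": y,
        }
    )
    return samples, responses, y


class TestLinearPredictor:
    def test_intercept_only(self, simple_sample):
        spec = ModelSpec(response="y", family="poisson")
        state = ParameterState(beta0_site={("L001", "S1"): 2.0})
        assert linear_predictor(state, spec, simple_sample) == pytest.approx(2.0)

    def test_log_identity_for_color(self):
        sample = make_sample({"A": 1}, color=math.e)
        spec = ModelSpec(response="y", family="poisson", continuous_terms=("color",))
        state = ParameterState(
            beta0_site={("L001", "S1"): 0.0}, beta_cont={"color": 1.0}
        )
        assert linear_predictor(state, spec, sample) == pytest.approx(1.0)

    def test_matches_dot_product_oracle(self):
        rng = np.random.default_rng(8)
        sample = make_sample(
            {"A": 2}, lake_type="T03", vegetation="V2", substrate="S2",
            latitude=64.2, color=120.0, ph=6.1, tp=40.0, tn=900.0,
        )
        cont = ("latitude", "color", "ph", "tp", "tn")
        betas = dict(zip(cont, rng.normal(size=5)))
        cat = {
            "lake_type": {"T03": 0.4, "T01": -0.4},
            "vegetation": {"V2": -0.2, "V1": 0.2},
            "substrate": {"S2": 0.7, "S1": -0.7},
        }
        spec = ModelSpec(
            response="y", family="poisson",
            categorical_terms=("lake_type", "vegetation", "substrate"),
            continuous_terms=cont,
        )
        state = ParameterState(
            beta0_site={("L001", "S1"): 1.3}, cat_effects=cat, beta_cont=betas
        )
        expected = 1.3 + 0.4 - 0.2 + 0.7 + float(
            np.dot(
                [betas[c] for c in cont],
                [math.log(getattr(sample, c)) for c in cont],
            )
        )
        assert linear_predictor(state, spec, sample) == pytest.approx(expected)

    def test_unknown_level_rejected(self, simple_sample):
        spec = ModelSpec(response="y", family="poisson", categorical_terms=("vegetation",))
        state = ParameterState(
            beta0_site={("L001", "S1"): 0.0},
            cat_effects={"vegetation": {"V9": 0.0}},
        )
        with pytest.raises(KeyError, match="vegetation"):
            linear_predictor(state, spec, simple_sample)


class TestLogLikelihood:
    def test_poisson_zero_count_closed_form(self, simple_sample):
        spec = ModelSpec(response="y", family="poisson")
        state = ParameterState(beta0_site={("L001", "S1"): 0.0})
        value = log_likelihood(state, spec, [simple_sample], {("L001", "S1"): 0.0})
        assert value == pytest.approx(-1.0)

    def test_binomial_fair_coin_closed_form(self):
        sample = make_sample({"A": 1, "B": 2})  # richness 2
        spec = ModelSpec(response="y", family="binomial-logit")
        state = ParameterState(beta0_site={("L001", "S1"): 0.0})
        value = log_likelihood(state, spec, [sample], {("L001", "S1"): 1.0})
        assert value == pytest.approx(math.log(0.5))

    def test_matches_scipy_density_products(self):
        rng = np.random.default_rng(4)
        samples = [
            make_sample({"A": 1, "B": 1, "C": 1}, lake_id=f"L{i}", site_id="S1")
            for i in range(6)
        ]
        etas = {(s.lake_id, s.site_id): float(rng.normal(0.5, 0.3)) for s in samples}
        state = ParameterState(beta0_site=etas, sigma2=0.8)
        counts = {k: int(rng.poisson(3)) for k in etas}
        spec_p = ModelSpec(response="y", family="poisson")
        expected = sum(
            stats.poisson.logpmf(counts[k], math.exp(etas[k])) for k in etas
        )
        assert log_likelihood(state, spec_p, samples, counts) == pytest.approx(expected)

        positives = {k: float(rng.lognormal(1.0, 0.4)) for k in etas}
        spec_n = ModelSpec(response="y", family="normal-on-log")
        expected = sum(
            stats.norm.logpdf(math.log(positives[k]), etas[k], math.sqrt(0.8))
            for k in etas
        )
        assert log_likelihood(state, spec_n, samples, positives) == pytest.approx(expected)

        hits = {k: int(rng.integers(0, 4)) for k in etas}  # richness 3
        spec_b = ModelSpec(response="y", family="binomial-logit")
        expected = sum(
            stats.binom.logpmf(hits[k], 3, 1 / (1 + math.exp(-etas[k]))) for k in etas
        )
        assert log_likelihood(state, spec_b, samples, hits) == pytest.approx(expected)

    def test_normal_family_rejects_nonpositive_response(self, simple_sample):
        spec = ModelSpec(response="y", family="normal-on-log")
        state = ParameterState(beta0_site={("L001", "S1"): 0.0}, sigma2=1.0)
        with pytest.raises(ValueError, match="positive"):
            log_likelihood(state, spec, [simple_sample], {("L001", "S1"): 0.0})


class TestFit:
    def test_conjugate_normal_mean_posterior(self):
        samples, responses, y = pooled_normal_setup(n=100, seed=5)
        spec = ModelSpec(
            response="y", family="normal-on-log",
            pooled_intercept=True, fixed_sigma2=1.0,
        )
        result = fit(
            spec, samples, responses, n_iter=12000, n_chains=2,
            n_adapt=2000, burn_in=2000, thin=5, seed=7,
        )
        z = np.log(y)
        post_prec = len(y) / 1.0 + 1.0 / 1.0e4
        post_mean = z.sum() / post_prec
        post_sd = post_prec**-0.5
        draws = result.draws("beta0")
        mcse = mc_error_ratio(draws) * draws.std(ddof=1)
        assert abs(draws.mean() - post_mean) < 3 * mcse
        assert draws.std(ddof=1) == pytest.approx(post_sd, rel=0.05)

    def test_zero_sum_constraint_in_every_draw(self):
        samples = generate_survey(GeneratorConfig(n_lakes=15, seed=2))
        spec = ModelSpec(
            response="y", family="poisson",
            categorical_terms=("vegetation", "substrate"),
        )
        true = simulate_parameter_state(samples, mu0=1.5, tau0=0.1, sigma0=0.1, seed=3)
        responses = generate_responses(samples, spec, true, seed=4)
        result = fit(
            spec, samples, responses, n_iter=600, n_chains=2,
            n_adapt=200, burn_in=200, thin=5, seed=5, check_acceptance=False,
        )
        pooled = result.pooled()
        for term in ("vegetation", "substrate"):
            cols = [
                i for i, n in enumerate(result.param_names)
                if n.startswith(f"beta_{term}[")
            ]
            assert len(cols) >= 2
            assert np.abs(pooled[:, cols].sum(axis=1)).max() < 1e-10

    def test_dic_identities_and_oracle_recomputation(self):
        samples, responses, _ = pooled_normal_setup(n=40, seed=9)
        spec = ModelSpec(response="y", family="normal-on-log", pooled_intercept=True)
        result = fit(
            spec, samples, responses, n_iter=2000, n_chains=2,
            n_adapt=500, burn_in=500, thin=10, seed=1, check_acceptance=False,
        )
        assert result.dic == result.dbar + result.pd
        assert result.pd == result.dbar - result.d_at_mean
        # posterior mean deviance recomputed per stored draw
        data = _ModelData(spec, samples, responses)
        pooled = result.pooled()
        dev = np.array([_deviance_from_vector(data, v) for v in pooled])
        assert dev.mean() == pytest.approx(result.dbar, rel=1e-12)
        assert _deviance_from_vector(data, pooled.mean(axis=0)) == pytest.approx(
            result.d_at_mean
        )

    def test_degenerate_posterior_has_zero_pd(self):
        samples, responses, _ = pooled_normal_setup(n=10, seed=3)
        spec = ModelSpec(
            response="y", family="normal-on-log",
            pooled_intercept=True, fixed_sigma2=1.0,
        )
        data = _ModelData(spec, samples, responses)
        draws = np.tile(np.array([1.7]), (50, 1))  # all draws identical
        dbar = float(np.mean([_deviance_from_vector(data, v) for v in draws]))
        d_at_mean = _deviance_from_vector(data, draws.mean(axis=0))
        assert dbar - d_at_mean == pytest.approx(0.0, abs=1e-12)  # pD = 0
        assert dbar + (dbar - d_at_mean) == pytest.approx(d_at_mean)  # DIC = D(theta_bar)

    def test_effective_parameter_count_for_linear_model(self):
        samples = generate_survey(GeneratorConfig(n_lakes=150, seed=6))
        spec = ModelSpec(
            response="y", family="normal-on-log", pooled_intercept=True,
            continuous_terms=("color", "tp"), fixed_sigma2=1.0,
        )
        true = simulate_parameter_state(
            samples, mu0=2.0, beta_cont={"color": 0.5, "tp": -0.3},
            sigma2=1.0, seed=7,
        )
        responses = generate_responses(samples, spec, true, seed=8)
        result = fit(
            spec, samples, responses, n_iter=4000, n_chains=2,
            n_adapt=800, burn_in=800, thin=5, seed=9, check_acceptance=False,
        )
        assert result.pd == pytest.approx(3.0, rel=0.2)  # intercept + 2 slopes

    def test_bit_identical_under_same_seed(self):
        samples = generate_survey(GeneratorConfig(n_lakes=10, seed=1))
        spec = ModelSpec(response="y", family="poisson", continuous_terms=("ph",))
        true = simulate_parameter_state(samples, mu0=1.0, tau0=0.1, sigma0=0.1, seed=2)
        responses = generate_responses(samples, spec, true, seed=3)
        kwargs = dict(n_iter=400, n_chains=2, n_adapt=150, burn_in=150, thin=2,
                      seed=11, check_acceptance=False)
        r1 = fit(spec, samples, responses, **kwargs)
        r2 = fit(spec, samples, responses, **kwargs)
        assert all((a == b).all() for a, b in zip(r1.chains, r2.chains))
        assert r1.dic == r2.dic

    def test_acceptance_warning_when_adaptation_disabled(self):
        samples, responses, _ = pooled_normal_setup(n=30, seed=2)
        spec = ModelSpec(
            response="y", family="normal-on-log",
            pooled_intercept=True, fixed_sigma2=1.0,
        )
        with pytest.warns(UserWarning, match="acceptance"):
            fit(
                spec, samples, responses, n_iter=400, n_chains=1,
                n_adapt=0, burn_in=100, thin=2, seed=3,
            )

    def test_latitude_effect_recovered_in_single_survey(self):
        ss = np.random.SeedSequence(77)
        s_sv, s_tr, s_resp, s_fit = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4)]
        samples = generate_survey(GeneratorConfig(seed=s_sv))
        spec = ModelSpec(response="y", family="normal-on-log", continuous_terms=("latitude",))
        mean_loglat = float(np.mean([math.log(s.latitude) for s in samples]))
        true = simulate_parameter_state(
            samples, mu0=3.0 + 2.0 * mean_loglat, tau0=0.05, sigma0=0.05,
            beta_cont={"latitude": -2.0}, sigma2=0.01, seed=s_tr,
        )
        responses = generate_responses(samples, spec, true, seed=s_resp)
        result = fit(
            spec, samples, responses, n_iter=2500, n_chains=2,
            n_adapt=600, burn_in=600, thin=4, seed=s_fit, check_acceptance=False,
        )
        lo, hi = result.credible_interval("beta_latitude")
        assert lo <= -2.0 <= hi
        rhat = result.gelman_rubin[result.param_names.index("beta_latitude")]
        assert rhat < 1.2


class TestDiagnostics:
    def test_identical_chains_give_unit_rhat(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(size=(5000, 3))
        rhat = gelman_rubin([chain, chain.copy()])
        assert np.allclose(rhat, 1.0, atol=0.01)

    def test_stationary_chains_converge(self):
        rng = np.random.default_rng(1)
        chains = [rng.normal(size=(4000, 2)) for _ in range(2)]
        assert np.all(gelman_rubin(chains) < 1.05)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(2)
        c1 = rng.normal(0.0, 1.0, size=(500, 1))
        c2 = rng.normal(100.0, 1.0, size=(500, 1))
        assert gelman_rubin([c1, c2])[0] > 1.1

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin([np.zeros((100, 1))])

    def test_mc_error_ratio_iid_scaling(self):
        rng = np.random.default_rng(3)
        draws = rng.standard_normal(10_000)
        ratio = mc_error_ratio(draws)
        assert ratio == pytest.approx(0.01, abs=0.005)

    def test_mc_error_ratio_grows_with_autocorrelation(self):
        rng = np.random.default_rng(4)
        n = 10_000
        eps = rng.standard_normal(n)
        ar = np.empty(n)
        ar[0] = eps[0]
        for t in range(1, n):
            ar[t] = 0.9 * ar[t - 1] + eps[t]
        iid_ratio = mc_error_ratio(rng.standard_normal(n))
        ar_ratio = mc_error_ratio(ar)
        # effective sample size shrinks by ~(1+rho)/(1-rho) = 19
        assert ar_ratio > 2 * iid_ratio

    def test_constant_draws_flagged_undefined(self):
        assert math.isnan(mc_error_ratio(np.ones(1000)))


class TestSelectModel:
    def test_single_candidate_returned(self):
        samples, responses, _ = pooled_normal_setup(n=30, seed=8)
        spec = ModelSpec(
            response="y", family="normal-on-log",
            pooled_intercept=True, fixed_sigma2=1.0,
        )
        ranking = select_model(
            spec, samples, responses, candidate_continuous=(), candidate_categorical=(),
            n_iter=400, n_chains=1, n_adapt=150, burn_in=150, thin=2, seed=1,
            check_acceptance=False,
        )
        assert len(ranking.entries) == 1
        assert ranking.best["continuous_terms"] == ()

    def test_budget_yields_partial_ranking(self):
        samples, responses, _ = pooled_normal_setup(n=30, seed=8)
        spec = ModelSpec(
            response="y", family="normal-on-log",
            pooled_intercept=True, fixed_sigma2=1.0,
        )
        with pytest.warns(UserWarning, match="budget"):
            ranking = select_model(
                spec, samples, responses,
                candidate_continuous=("color", "tp"), candidate_categorical=(),
                budget=2, n_iter=300, n_chains=1, n_adapt=100, burn_in=100,
                thin=2, seed=2, check_acceptance=False,
            )
        assert len(ranking.entries) == 2
        assert not ranking.complete

    def test_strong_effect_selected(self):
        ss = np.random.SeedSequence(123)
        s_sv, s_tr, s_resp, s_fit = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4)]
        samples = generate_survey(GeneratorConfig(seed=s_sv))
        spec = ModelSpec(response="y", family="poisson", continuous_terms=("latitude",))
        mean_loglat = float(np.mean([math.log(s.latitude) for s in samples]))
        true = simulate_parameter_state(
            samples, mu0=3.0 + 10.0 * mean_loglat, tau0=0.05, sigma0=0.05,
            beta_cont={"latitude": -10.0}, seed=s_tr,
        )
        responses = generate_responses(samples, spec, true, seed=s_resp)
        ranking = select_model(
            spec, samples, responses,
            candidate_continuous=("latitude", "color"), candidate_categorical=(),
            n_iter=800, n_chains=1, n_adapt=300, burn_in=300, thin=5, seed=s_fit,
            check_acceptance=False,
        )
        assert "latitude" in ranking.best["continuous_terms"]

    def test_pure_noise_keeps_null_competitive(self):
        hits = 0
        for rep in range(5):
            ss = np.random.SeedSequence(400 + rep)
            s_sv, s_resp, s_fit = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3)]
            samples = generate_survey(GeneratorConfig(n_lakes=25, seed=s_sv))
            spec = ModelSpec(response="y", family="poisson")
            true = simulate_parameter_state(samples, mu0=2.0, tau0=0.05, sigma0=0.05, seed=s_resp)
            responses = generate_responses(samples, spec, true, seed=s_resp)
            ranking = select_model(
                spec, samples, responses,
                candidate_continuous=("color",), candidate_categorical=(),
                n_iter=800, n_chains=1, n_adapt=300, burn_in=300, thin=5,
                seed=s_fit, check_acceptance=False,
            )
            null_dic = next(
                e["dic"] for e in ranking.entries if e["continuous_terms"] == ()
            )
            if null_dic - ranking.best["dic"] < 2.0:
                hits += 1
        assert hits >= 3
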