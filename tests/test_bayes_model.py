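"""Model densities, label posteriors and the MCMC sampler."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import invgamma

from conftest import oracle_label_posterior, oracle_record_log_density, random_model_params
from redstart.bayes_model import (
    MCMCConfig,
    ModelParams,
    PriorSpec,
    _ChainState,
    _Data,
    _sweep,
    admissible_classes,
    inv_wishart_rv,
    label_posterior,
    load_posterior,
    record_log_density,
    run_mcmc,
    save_posterior,
)
from redstart.capture_data import CaptureRecord, table_from_records
from redstart.synthetic_data import apply_missingness, scenario_preset, simulate_captures


def _random_record(rng):
    return dict(
        weight=float(rng.uniform(12, 20)),
        primary=float(rng.uniform(58, 72)),
        day_c=float(rng.uniform(-10, 10)),
        year_c=float(rng.uniform(-15, 15)),
    )


class TestRecordLogDensity:
    def test_matches_textbook_oracle(self, rng):
        for _ in range(300):
            params = random_model_params(rng)
            rec = _random_record(rng)
            age, sex = int(rng.integers(2)), int(rng.integers(2))
            got = record_log_density(params, age=age, sex=sex, **rec)
            want = oracle_record_log_density(params, age, sex, **rec)
            assert got == pytest.approx(want, rel=1e-10, abs=1e-12)

    def test_zero_correlation_factorizes(self, rng):
        from scipy.stats import norm

        params = random_model_params(rng)
        params.sigma[:, 0, 1] = params.sigma[:, 1, 0] = 0.0
        rec = _random_record(rng)
        got = record_log_density(params, age=1, sex=0, **rec)
        g = 0 + 2 * 1
        mu_w = params.w0[g] + params.w1 * rec["day_c"] + params.w2 * rec["year_c"]
        mu_p = params.p0[g] + params.p1 * rec["day_c"] + params.p2 * rec["year_c"]
        want = (
            norm(mu_w, np.sqrt(params.sigma[g, 0, 0])).logpdf(rec["weight"])
            + norm(mu_p, np.sqrt(params.sigma[g, 1, 1])).logpdf(rec["primary"])
            + np.log(1 - expit(params.s0 + params.s1 * rec["day_c"] + params.s2 * rec["year_c"]))
            + np.log(expit(params.a0 + params.a1 * rec["day_c"] + params.a2 * rec["year_c"]))
        )
        assert got == pytest.approx(float(want), rel=1e-10)

    def test_density_at_class_mean(self, rng):
        """At the class mean the MVN term is -log(2 pi) - 0.5 log|Sigma|."""
        params = random_model_params(rng)
        g = 2  # adult female
        val = record_log_density(
            params, age=1, sex=0, weight=params.w0[g], primary=params.p0[g], day_c=0.0, year_c=0.0
        )
        mvn_term = -np.log(2 * np.pi) - 0.5 * np.log(np.linalg.det(params.sigma[g]))
        bern = np.log(1 - expit(params.s0)) + np.log(expit(params.a0))
        assert val == pytest.approx(float(mvn_term + bern), rel=1e-10)

    def test_requires_observed_labels(self, rng):
        params = random_model_params(rng)
        with pytest.raises(ValueError):
            record_log_density(params, age=None, sex=0, **_random_record(rng))


class TestLabelPosterior:
    def test_matches_enumeration_oracle(self, rng):
        for _ in range(300):
            params = random_model_params(rng)
            rec = _random_record(rng)
            pattern = rng.integers(3)  # 0: both missing, 1: sex missing, 2: age missing
            age = None if pattern in (0, 1) else int(rng.integers(2))
            sex = None if pattern in (0, 2) else int(rng.integers(2))
            if pattern == 2:  # age missing, sex observed
                age, sex = None, int(rng.integers(2))
            elif pattern == 1:
                age, sex = int(rng.integers(2)), None
            comps, probs = label_posterior(params, age=age, sex=sex, **rec)
            o_comps, o_probs = oracle_label_posterior(params, **rec, age=age, sex=sex)
            assert comps == o_comps
            np.testing.assert_allclose(probs, o_probs, rtol=1e-10)
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_full_symmetry_gives_uniform(self):
        params = ModelParams.from_sd_rho(
            w0=[16.0] * 4, w1=0, w2=0, p0=[65.0] * 4, p1=0, p2=0,
            sigma_weight=1.0, sigma_primary=1.5, rho=0.3,
            s0=0, s1=0, s2=0, a0=0, a1=0, a2=0,
        )
        comps, probs = label_posterior(params, weight=15.0, primary=66.0, day_c=2.0, year_c=-3.0)
        assert len(comps) == 4
        np.testing.assert_allclose(probs, 0.25, rtol=1e-10)

    def test_degenerate_logit_limit(self, rng):
        params = random_model_params(rng)
        params.a0 = 40.0  # P(adult) -> 1
        params.a1 = params.a2 = 0.0
        comps, probs = label_posterior(params, sex=1, **_random_record(rng))
        assert comps == [(0, 1), (1, 1)]
        assert probs[1] == pytest.approx(1.0, abs=1e-10)

    def test_paradoxus_forces_young_male(self, rng):
        params = random_model_params(rng)
        comps, probs = label_posterior(params, plumage="paradoxus", **_random_record(rng))
        assert comps == [(0, 1)]
        assert probs[0] == 1.0

    def test_contradictory_constraints(self):
        with pytest.raises(ValueError, match="empty admissible"):
            admissible_classes(age=1, sex=None, plumage="paradoxus")

    def test_requires_missing_label(self, rng):
        params = random_model_params(rng)
        with pytest.raises(ValueError):
            label_posterior(params, age=0, sex=1, **_random_record(rng))


def test_inv_wishart_mean(rng):
    S = np.array([[2.0, 0.6], [0.6, 1.5]])
    df = 12.0
    draws = np.mean([inv_wishart_rv(df, S, rng) for _ in range(20000)], axis=0)
    np.testing.assert_allclose(draws, S / (df - 3), rtol=0.05)


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------


def _small_masked_table(seed=50, n_years=3, captures=80):
    spec = scenario_preset(1, n_years=n_years, mean_captures_per_year=captures)
    table = simulate_captures(spec, seed)
    return spec, apply_missingness(table, spec, seed + 1)


class TestRunMCMC:
    def test_seeded_determinism(self):
        _, masked = _small_masked_table()
        cfg = MCMCConfig(n_chains=2, n_iter=400, n_burn=200, thin=2, seed=5)
        d1 = run_mcmc(masked, config=cfg)
        d2 = run_mcmc(masked, config=cfg)
        np.testing.assert_array_equal(d1.class_g, d2.class_g)
        for name in ("w0", "w1", "sigma", "s", "a"):
            np.testing.assert_array_equal(getattr(d1, name), getattr(d2, name))

    def test_draw_count_and_label_bookkeeping(self):
        _, masked = _small_masked_table()
        cfg = MCMCConfig(n_chains=2, n_iter=400, n_burn=200, thin=2, seed=5)
        draws = run_mcmc(masked, config=cfg)
        assert draws.n_draws == 2 * (400 - 200) // 2
        # fully observed records keep a constant class; missing ones vary
        obs = ~draws.missing_any
        assert (draws.class_g[:, obs] == draws.class_g[0, obs]).all()
        # observed labels are never contradicted by an imputed class
        sex_obs = masked.observed_sex()
        for i in np.flatnonzero(sex_obs >= 0):
            assert set(np.unique(draws.class_g[:, i]) % 2) == {(1 + sex_obs[i]) % 2}

    def test_complete_label_posterior_matches_mle(self):
        """With no missing labels and diffuse priors the posterior centers on the MLE."""
        import statsmodels.formula.api as smf

        spec = scenario_preset(1, n_years=10, mean_captures_per_year=500)
        table = simulate_captures(spec, 60)
        f = table.frame.copy()
        f["day_c"] = table.centered_days()
        f["year_c"] = table.centered_years()
        f["g"] = f["sex"].astype(int) + 2 * f["age"].astype(int)
        ols = {}
        for out, pre in (("weight_g", "w"), ("primary_mm", "p")):
            fit = smf.ols(f"{out} ~ C(g) + day_c + year_c", data=f).fit()
            ols[pre + "1"] = fit.params["day_c"]
            ols[pre + "2"] = fit.params["year_c"]
        draws = run_mcmc(table, config=MCMCConfig(n_chains=2, n_iter=1200, n_burn=400, seed=61))
        fr = draws.scalar_frame()
        truth = spec.truth.slopes()
        for name in ("w1", "w2", "p1", "p2"):
            post_mean, post_sd = fr[name].mean(), fr[name].std()
            assert abs(post_mean - ols[name]) < 0.5 * post_sd
            assert abs(post_mean - truth[name]) < 3.5 * post_sd
        for name in ("s1", "s2", "a1", "a2"):
            assert abs(fr[name].mean() - truth[name]) < 3.5 * fr[name].std()

    def test_scenario3_equal_means_centered_near_zero(self):
        spec = scenario_preset(3, n_years=10, mean_captures_per_year=150)
        masked = apply_missingness(simulate_captures(spec, 70), spec, 71)
        draws = run_mcmc(masked, config=MCMCConfig(n_chains=2, n_iter=1000, n_burn=400, seed=72))
        fr = draws.scalar_frame()
        for col in ("w0", "p0"):
            for g in (2, 3, 4):
                diff = fr[f"{col}[{g}]"] - fr[f"{col}[1]"]
                assert abs(diff.mean()) < 4 * diff.std()

    def test_monotone_information(self):
        """More observed sex labels (scenario 1 vs 2) cannot make s1 less precise."""
        sds = {}
        for which in (1, 2):
            spec = scenario_preset(which, n_years=10, mean_captures_per_year=150)
            masked = apply_missingness(simulate_captures(spec, 80), spec, 81)
            draws = run_mcmc(masked, config=MCMCConfig(n_chains=2, n_iter=1500, n_burn=500, seed=82))
            sds[which] = draws.scalar_frame()["s1"].std()
        assert sds[1] <= sds[2] * 1.2

    def test_empty_class_raises(self):
        records = [
            CaptureRecord(f"r{i}", 2000, 280 + i % 5, 0, 0, 15.0 + 0.1 * i, 64.0 + 0.1 * i)
            for i in range(20)
        ]
        table = table_from_records(records)
        with pytest.raises(RuntimeError, match="no attributable records"):
            run_mcmc(table, config=MCMCConfig(n_chains=1, n_iter=20, n_burn=10, seed=1))

    def test_shared_rho_variant(self):
        _, masked = _small_masked_table()
        cfg = MCMCConfig(n_chains=2, n_iter=400, n_burn=200, seed=5, shared_rho=True)
        draws = run_mcmc(masked, config=cfg)
        fr = draws.scalar_frame()
        for g in (2, 3, 4):
            np.testing.assert_allclose(fr[f"rho[{g}]"], fr["rho[1]"], rtol=1e-12)
        assert fr["rho"].std() > 0  # the shared correlation is actually sampled

    def test_save_load_roundtrip(self, tmp_path):
        _, masked = _small_masked_table()
        draws = run_mcmc(masked, config=MCMCConfig(n_chains=2, n_iter=300, n_burn=100, seed=9))
        save_posterior(draws, tmp_path / "post")
        back = load_posterior(tmp_path / "post")
        np.testing.assert_allclose(back.w0, draws.w0, rtol=1e-12)
        np.testing.assert_allclose(back.s, draws.s, rtol=1e-12)
        np.testing.assert_array_equal(back.class_g, draws.class_g)
        np.testing.assert_array_equal(back.chain, draws.chain)
        assert back.converged == draws.converged


class TestKernelInvariance:
    """Geweke-style successive-conditional check of the full transition kernel.

    With data repeatedly regenerated from the current parameters, alternating
    data-regeneration with one kernel sweep must leave the parameter marginals
    equal to the prior.  Run on a tiny instance with moderate priors (so prior
    moments exist) and adaptation disabled.
    """

    PRIORS = PriorSpec(
        w0_mean=16.0, w0_sd=1.5, p0_mean=65.0, p0_sd=1.5, slope_sd=0.3,
        logit_intercept_sd=1.0, iw_scale=np.diag([1.0, 1.5]), iw_df=10.0,
    )

    @staticmethod
    def _prior_draw(priors, rng):
        p = priors
        return dict(
            beta=np.concatenate(
                [
                    p.w0_mean + p.w0_sd * rng.standard_normal(4),
                    p.slope_sd * rng.standard_normal(2),
                    p.p0_mean + p.p0_sd * rng.standard_normal(4),
                    p.slope_sd * rng.standard_normal(2),
                ]
            ),
            sigma=np.array([inv_wishart_rv(p.iw_df, p.iw_scale, rng) for _ in range(4)]),
            s=np.array([p.logit_intercept_sd, p.slope_sd, p.slope_sd]) * rng.standard_normal(3),
            a=np.array([p.logit_intercept_sd, p.slope_sd, p.slope_sd]) * rng.standard_normal(3),
        )

    def test_successive_conditional_equals_prior(self):
        rng = np.random.default_rng(7)
        n = 8
        day_c = np.array([-3.0, -1.0, 0.0, 2.0, 4.0, -2.0, 1.0, 3.0])
        year_c = np.array([0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0])
        miss_sex = np.zeros(n, dtype=bool)
        miss_age = np.zeros(n, dtype=bool)
        miss_sex[[5, 7]] = True
        miss_age[[6, 7]] = True

        records = [
            CaptureRecord(f"r{i}", 2000 + int(year_c[i]), 283 + int(day_c[i]), 0, 0, 15.0, 64.0)
            for i in range(n)
        ]
        table = table_from_records(records, season_midpoint_day=283, reference_year=2000)
        config = MCMCConfig(n_chains=1, n_iter=2, n_burn=1, seed=1)
        data = _Data(table, config)

        def redraw_data(theta):
            sex = (rng.random(n) < expit(theta["s"][0] + theta["s"][1] * day_c + theta["s"][2] * year_c)).astype(int)
            age = (rng.random(n) < expit(theta["a"][0] + theta["a"][1] * day_c + theta["a"][2] * year_c)).astype(int)
            g = sex + 2 * age
            beta = theta["beta"]
            for i in range(n):
                mu = np.array(
                    [
                        beta[g[i]] + beta[4] * day_c[i] + beta[5] * year_c[i],
                        beta[6 + g[i]] + beta[10] * day_c[i] + beta[11] * year_c[i],
                    ]
                )
                data.y[i] = rng.multivariate_normal(mu, theta["sigma"][g[i]], method="cholesky")
            data.obs_sex = np.where(miss_sex, -1, sex)
            data.obs_age = np.where(miss_age, -1, age)
            from redstart.capture_data import CLASS_AGE, CLASS_SEX

            adm = np.ones((n, 4), dtype=bool)
            adm &= (data.obs_age[:, None] < 0) | (CLASS_AGE[None, :] == data.obs_age[:, None])
            adm &= (data.obs_sex[:, None] < 0) | (CLASS_SEX[None, :] == data.obs_sex[:, None])
            data.admissible = adm
            data.free = np.flatnonzero(adm.sum(axis=1) > 1)
            return g

        n_steps = 4000
        theta = self._prior_draw(self.PRIORS, rng)
        state = _ChainState(
            beta=theta["beta"], sigma=theta["sigma"], s=theta["s"], a=theta["a"],
            g=redraw_data(theta),
            log_scale_s=np.log([0.8, 0.3, 0.3]),
            log_scale_a=np.log([0.8, 0.3, 0.3]),
        )
        sc = {"w1": [], "s0": [], "sig_w1": []}
        for step in range(n_steps):
            theta_cur = dict(beta=state.beta, sigma=state.sigma, s=state.s, a=state.a)
            state.g = redraw_data(theta_cur)
            _sweep(data, state, self.PRIORS, config, rng, adapt_it=None)
            if step >= 500:
                sc["w1"].append(state.beta[4])
                sc["s0"].append(state.s[0])
                sc["sig_w1"].append(state.sigma[0, 0, 0])
        sc = {k: np.asarray(v) for k, v in sc.items()}

        # analytic prior marginals: w1 ~ N(0, 0.3^2); s0 ~ N(0, 1);
        # Sigma_w[1] ~ Inv-Gamma((df - 1)/2, scale_11/2)
        assert abs(sc["w1"].mean()) < 0.06
        assert 0.8 < sc["w1"].std() / 0.3 < 1.25
        assert abs(sc["s0"].mean()) < 0.25
        assert 0.75 < sc["s0"].std() / 1.0 < 1.3
        prior_med = invgamma(a=(self.PRIORS.iw_df - 1) / 2, scale=self.PRIORS.iw_scale[0, 0] / 2).median()
        assert 0.7 < np.median(sc["sig_w1"]) / prior_med < 1.4
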