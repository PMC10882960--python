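import math

import numpy as np
import pandas as pd
import pytest

from invacf import nbglmm
from invacf.nbglmm import (
    ModelSpec,
    _LaplaceMachine,
    aicc,
    build_design,
    candidate_specs,
    fit,
    predict_mean,
    r2_nakagawa,
    select_model,
    spearman_screen,
)
from conftest import toy_panel
from oracles import agq_marginal_loglik


class TestSpearmanScreen:
    def test_perfect_monotone_pairs_fail(self):
        panel = toy_panel()
        panel["S_e"] = panel["TR"]  # rank-identical after transform
        mat, passed = spearman_screen(panel, ["logTR", "logS_e"])
        assert mat.loc["logTR", "logS_e"] == pytest.approx(1.0)
        assert not passed

    def test_anti_monotone_fails(self):
        panel = toy_panel()
        panel["D"] = -panel.groupby(["e"])["TR"].rank() * 100 + 10000
        mat, passed = spearman_screen(panel, ["logTR", "D"])
        assert abs(mat.loc["logTR", "D"]) > 0.5
        assert not passed

    def test_independent_draws_pass(self):
        rng = np.random.default_rng(0)
        n = 1000
        panel = pd.DataFrame(
            {
                "TR": np.exp(rng.normal(5, 1, n)),
                "D": rng.uniform(100, 10000, n),
                "S_e": rng.integers(10, 1000, n),
                "S_i": rng.integers(10, 1000, n),
            }
        )
        mat, passed = spearman_screen(panel)
        off = mat.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.nanmax(np.abs(off)) < 0.1
        assert passed

    def test_constant_variable_reported_nan(self):
        panel = toy_panel()
        mat, _ = spearman_screen(panel, ["logTR", "D"])  # D constant
        assert math.isnan(mat.loc["logTR", "D"])


class TestAicc:
    def test_formula_value(self):
        # -2*(-100) + 2*5 + 2*5*6/(50-5-1) = 211.3636...
        assert aicc(-100.0, 5, 50) == pytest.approx(211.364, abs=5e-4)

    def test_undefined_when_n_too_small(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


class TestGlmOracle:
    """With the random effects off, the fit is a plain NB GLM and must agree
    with statsmodels."""

    @pytest.fixture(scope="class")
    def overdispersed_panel(self):
        # interior-theta regime: large counts so dispersion is identifiable
        from invacf.synthetic_world import WorldConfig, generate_world

        cfg = WorldConfig(
            seed=9,
            n_countries=6,
            n_species=4000,
            beta={
                "intercept": -3.0,
                "logTR": 9.3e-3,
                "D": -3.6e-5,
                "logS_e": 8.4e-1,
                "logS_i": 3.3e-1,
            },
            theta=1.5,
            re_sd={"importer_period": 0.0, "exporter_period": 0.0},
        )
        return generate_world(cfg).latent_panel

    def test_betas_match_fixed_theta_glm_irls(self, overdispersed_panel):
        import statsmodels.api as sm

        result = fit(overdispersed_panel, include_random=False)
        y, X, names, _ = build_design(overdispersed_panel, result.spec)
        glm = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=1.0 / result.theta)
        ).fit(tol=1e-12)
        mine = np.array([result.beta[n] for n in names])
        assert np.max(np.abs(mine - glm.params)) < 1e-4

    def test_full_mle_matches_statsmodels_negative_binomial(self, overdispersed_panel):
        from statsmodels.discrete.discrete_model import NegativeBinomial

        result = fit(overdispersed_panel, include_random=False)
        y, X, names, _ = build_design(overdispersed_panel, result.spec)
        sm_fit = NegativeBinomial(y, X, loglike_method="nb2").fit(
            disp=0, maxiter=2000, method="bfgs", gtol=1e-10
        )
        mine = np.array([result.beta[n] for n in names])
        assert np.max(np.abs(mine - sm_fit.params[:-1])) < 1e-4
        assert result.theta == pytest.approx(1.0 / sm_fit.params[-1], rel=1e-3)
        assert result.loglik == pytest.approx(sm_fit.llf, abs=1e-6)


class TestLaplaceOracle:
    def _instance(self, seed, n=60, intercept=4.5, theta=20.0, sig=(0.3, 0.3)):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(n), rng.normal(size=n) * 0.3])
        g1 = rng.integers(0, 2, n).astype(str)
        g2 = rng.integers(0, 2, n).astype(str)
        u1 = rng.normal(0, sig[0], 2)
        u2 = rng.normal(0, sig[1], 2)
        eta = X @ np.array([intercept, 0.3]) + u1[g1.astype(int)] + u2[g2.astype(int)]
        mu = np.exp(eta)
        y = rng.poisson(rng.gamma(theta, mu / theta)).astype(float)
        return y, X, g1, g2, theta, list(sig)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_laplace_matches_adaptive_quadrature(self, seed):
        y, X, g1, g2, theta, sig = self._instance(seed)
        machine = _LaplaceMachine(y, X, [g1, g2])
        ll_laplace = machine.laplace_loglik(theta, sig)
        v, _, _ = machine.joint_mode(theta, sig)
        ll_agq = agq_marginal_loglik(
            y, X, machine.group_codes, v[:2], theta, sig
        )
        assert abs(ll_laplace - ll_agq) < 1e-3

    def test_sigma_to_zero_limit_equals_glm_loglik(self):
        y, X, g1, g2, theta, _ = self._instance(4)
        machine = _LaplaceMachine(y, X, [g1, g2])
        ll_tiny = machine.laplace_loglik(theta, [1e-6, 1e-6])
        _, ll_glm = machine.glm_loglik_and_mode(theta)
        assert ll_tiny == pytest.approx(ll_glm, abs=1e-3)


class TestModelSelection:
    def test_single_candidate_returned_as_best(self, small_world):
        fits = select_model(
            small_world.latent_panel.head(300),
            [ModelSpec(fixed_effects=("logTR",))],
            include_random=False,
        )
        assert len(fits) == 1
        assert fits[0].spec.fixed_effects == ("logTR",)

    def test_candidate_enumeration_counts_all_subsets(self):
        assert len(candidate_specs()) == 16

    def test_true_model_competitive_with_full_model(self):
        # data carry only a trade effect: the true single-variable model
        # should never lose to the full model by more than ~2 AICc on average
        rng = np.random.default_rng(0)
        deltas = []
        for _ in range(6):
            n = 400
            panel = pd.DataFrame(
                {
                    "e": "A",
                    "i": "B",
                    "decade_end": 1999,
                    "TR": np.exp(rng.normal(5, 2, n)),
                    "D": rng.uniform(100, 10000, n),
                    "S_e": rng.integers(10, 1000, n),
                    "S_i": rng.integers(10, 1000, n),
                }
            )
            log_tr = np.log1p(panel["TR"])
            z = (log_tr - log_tr.mean()) / log_tr.std(ddof=0)
            mu = np.exp(0.3 + 0.5 * z)
            panel["AS"] = rng.poisson(rng.gamma(2.0, mu / 2.0))
            fits = select_model(
                panel,
                [ModelSpec(fixed_effects=("logTR",)), ModelSpec()],
                include_random=False,
            )
            by_spec = {f.spec.fixed_effects: f.aicc for f in fits}
            deltas.append(by_spec[("logTR",)] - by_spec[tuple(nbglmm.FIXED_EFFECTS)])
        assert np.mean(deltas) < 2.0


class TestPredictMean:
    def test_intercept_only_model_predicts_exp_intercept(self):
        panel = toy_panel()
        result = fit(panel, ModelSpec(fixed_effects=()), include_random=False)
        mu = predict_mean(result, TR=123.0, D=5.0, S_e=10, S_i=10)
        assert mu == pytest.approx(math.exp(result.beta["intercept"]), rel=1e-9)
        assert mu == pytest.approx(panel["AS"].mean(), rel=1e-4)

    def test_monotone_in_trade_when_coefficient_positive(self, small_fit):
        tr = np.linspace(0, 1e6, 50)
        mu = predict_mean(small_fit, tr, 500.0, 100, 100)
        if small_fit.beta["logTR"] > 0:
            assert np.all(np.diff(mu) > 0)
        else:  # pragma: no cover - sign depends on the draw
            assert np.all(np.diff(mu) < 0)

    def test_hand_computed_linear_predictor(self, small_fit):
        tr, d, se, si = 5000.0, 1234.0, 150, 80
        m, s = small_fit.scaling["logTR"]
        eta = (
            small_fit.beta["intercept"]
            + small_fit.beta["logTR"] * (math.log1p(tr) - m) / s
            + small_fit.beta["D"] * d
            + small_fit.beta["logS_e"] * math.log(se)
            + small_fit.beta["logS_i"] * math.log(si)
        )
        assert predict_mean(small_fit, tr, d, se, si) == pytest.approx(
            math.exp(eta), rel=1e-12
        )

    def test_conditional_mode_requires_known_level(self, small_fit):
        with pytest.raises(KeyError):
            predict_mean(
                small_fit, 1.0, 1.0, 10, 10,
                mode="conditional", importer="nope", exporter="nope", period=1999,
            )


class TestRecoveryAndR2:
    def test_random_effect_variances_recovered(self):
        # counts high enough that the variance components are informative
        from invacf.synthetic_world import WorldConfig, generate_world

        cfg = WorldConfig(
            seed=21,
            n_countries=8,
            n_species=4000,
            beta={
                "intercept": -5.3,
                "logTR": 9.3e-3,
                "D": -3.6e-5,
                "logS_e": 8.4e-1,
                "logS_i": 3.3e-1,
            },
            re_sd={"importer_period": 0.3, "exporter_period": 0.2},
        )
        world = generate_world(cfg)
        assert not world.truth["truncations"]
        result = fit(world.latent_panel)
        for factor in ("importer_period", "exporter_period"):
            assert result.re_sd[factor] == pytest.approx(
                cfg.re_sd[factor], abs=0.12
            )
        assert result.theta == pytest.approx(cfg.theta, rel=0.5)
        assert result.beta["logS_e"] == pytest.approx(
            0.84, abs=2 * result.beta_se["logS_e"]
        )

    def test_no_random_effect_world_marginal_close_to_conditional(self, norandom_world):
        result = fit(norandom_world.latent_panel)
        marginal, conditional = r2_nakagawa(result, norandom_world.latent_panel)
        assert 0 <= marginal <= conditional <= 1
        assert conditional - marginal < 0.05

    def test_pure_noise_world_marginal_near_zero(self):
        from invacf.synthetic_world import WorldConfig, generate_world

        cfg = WorldConfig(
            seed=13,
            n_countries=6,
            n_species=600,
            beta={"intercept": 0.0, "logTR": 0.0, "D": 0.0, "logS_e": 0.0, "logS_i": 0.0},
        )
        world = generate_world(cfg)
        result = fit(world.latent_panel)
        marginal, conditional = r2_nakagawa(result, world.latent_panel)
        assert marginal < 0.02
        assert conditional > marginal

    def test_mixed_fit_close_to_plain_glm_when_no_random_variance(self, norandom_world):
        mixed = fit(norandom_world.latent_panel)
        plain = fit(norandom_world.latent_panel, include_random=False)
        for name in mixed.beta:
            assert mixed.beta[name] == pytest.approx(
                plain.beta[name], abs=5e-3 * max(1.0, abs(plain.beta[name]))
            )


class TestAgainstGlmmTMB:
    def test_fit_matches_r_glmmtmb(self, small_world, small_fit, tmp_path):
        """Independent cross-check against R's glmmTMB on the same panel."""
        import shutil
        import subprocess

        rscript = shutil.which("Rscript")
        assert rscript is not None, "Rscript expected on PATH"
        panel = small_world.latent_panel.copy()
        y, X, names, _ = build_design(panel, small_fit.spec)
        frame = pd.DataFrame(X[:, 1:], columns=names[1:])
        frame["AS"] = y.astype(int)
        frame["ip"] = (panel["i"].astype(str) + ":" + panel["decade_end"].astype(str)).to_numpy()
        frame["ep"] = (panel["e"].astype(str) + ":" + panel["decade_end"].astype(str)).to_numpy()
        csv = tmp_path / "panel.csv"
        frame.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            f"""
            suppressMessages(library(glmmTMB))
            d <- read.csv("{csv}")
            m <- glmmTMB(AS ~ logTR + D + logS_e + logS_i + (1|ip) + (1|ep),
                         family = nbinom2, data = d)
            co <- fixef(m)$cond
            cat(sprintf("%.10f %.10f %.10f %.10f %.10f %.6f %.6f\\n",
                co[1], co["logTR"], co["D"], co["logS_e"], co["logS_i"],
                sigma(m), as.numeric(logLik(m))))
            """
        )
        out = subprocess.run(
            [rscript, str(script)], capture_output=True, text=True, timeout=600
        )
        assert out.returncode == 0, out.stderr
        vals = [float(t) for t in out.stdout.split()]
        r_beta = dict(zip(["intercept", "logTR", "D", "logS_e", "logS_i"], vals[:5]))
        r_theta, r_loglik = vals[5], vals[6]
        for name, se in small_fit.beta_se.items():
            assert small_fit.beta[name] == pytest.approx(
                r_beta[name], abs=max(0.2 * se, 1e-6)
            )
        assert small_fit.theta == pytest.approx(r_theta, rel=0.05)
        assert small_fit.loglik == pytest.approx(r_loglik, abs=0.5)
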