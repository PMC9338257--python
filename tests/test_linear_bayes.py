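"""Gibbs-sampler correctness: conjugate-draw oracle, quadrature and
mixed-model-equation oracles, reproducibility, and heritability summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cottongp as cg
from cottongp._gibbs import draw_scaled_inv_chi2
from cottongp.linear_bayes import (
    HeritabilityEstimate,
    PriorConfig,
    ScaleSet,
    build_scale_parameters,
)


def _single_env_pheno(ids, y, trait="t"):
    return cg.PhenotypeTable(
        pd.DataFrame({"line_id": ids, "year": "1", "experiment": "1", trait: y})
    )


class TestScaledInvChi2:
    def test_matches_inverse_gamma(self):
        # scaled-inv-chi2(df, S) == Inv-Gamma(df/2, S/2)
        rng = np.random.default_rng(0)
        df, S = 5.0, 3.2
        draws = np.array([draw_scaled_inv_chi2(rng, df, S) for _ in range(20000)])
        ks = stats.kstest(draws, stats.invgamma(df / 2.0, scale=S / 2.0).cdf)
        assert ks.pvalue > 0.01

    def test_mean_for_large_df(self):
        rng = np.random.default_rng(1)
        df, S = 200.0, 400.0
        draws = np.array([draw_scaled_inv_chi2(rng, df, S) for _ in range(5000)])
        # E = S / (df - 2)
        assert draws.mean() == pytest.approx(S / (df - 2.0), rel=0.02)


class TestScaleParameters:
    def test_bgblup_scales(self):
        y = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        vy = np.var(y, ddof=1)
        s = build_scale_parameters(y, "bgblup", mean_diag_g=1.25)
        assert s.S0 == pytest.approx(vy * 0.5 * 7.0)
        assert s.Sg == pytest.approx(vy * 0.5 * 7.0 / 1.25)

    def test_pedigree_split(self):
        y = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        vy = np.var(y, ddof=1)
        s = build_scale_parameters(
            y, "bgblup_pedigree", mean_diag_g=1.0, mean_diag_a=1.1
        )
        assert s.S0 == pytest.approx(vy * 0.5 * 7.0)
        assert s.Sg == pytest.approx(vy * 0.4 * 7.0)
        assert s.Sa == pytest.approx(vy * 0.1 * 7.0 / 1.1)

    def test_constant_y_needs_preset(self):
        with pytest.raises(ValueError, match="var"):
            build_scale_parameters(np.ones(5), "bgblup", mean_diag_g=1.0)
        preset = ScaleSet(S0=1.0, Sg=1.0)
        out = build_scale_parameters(
            np.ones(5), "bgblup", PriorConfig(scales=preset), mean_diag_g=1.0
        )
        assert out is preset


class TestLassoQuadratureOracle:
    def test_single_marker_posterior(self):
        # fixed n=8 toy with lambda^2 held fixed; the intercept (flat prior)
        # is integrated analytically, leaving a 2-D grid over (beta, s2e)
        x = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0, 1.0, 2.0])
        y = np.array([-0.8, 0.3, 1.9, 0.7, -0.2, 1.1, 0.1, 2.4])
        n = len(y)
        lam2 = 4.0
        lam = math.sqrt(lam2)
        df = 5
        S0 = np.var(y, ddof=1) * 0.5 * (df + 2.0)
        xc = x - x.mean()
        yc = y - y.mean()
        bgrid = np.linspace(-4, 4, 2001)
        sgrid = np.linspace(1e-3, 12.0, 2000)
        B, S = np.meshgrid(bgrid, sgrid, indexing="ij")
        rss = ((yc[None, :] - np.outer(bgrid, xc)) ** 2).sum(axis=1)
        logpost = (
            -((n - 1) / 2.0) * np.log(S)
            - rss[:, None] / (2 * S)
            - lam * np.abs(B)
            - (df / 2.0 + 1.0) * np.log(S)
            - S0 / (2 * S)
        )
        w = np.exp(logpost - logpost.max())
        Z = w.sum()
        Eb = (B * w).sum() / Z
        Eb2 = (B**2 * w).sum() / Z

        ids = [f"L{i}" for i in range(n)]
        geno = cg.GenotypeMatrix(
            np.array(ids, dtype=object),
            np.array(["M1"], dtype=object),
            x[:, None].astype(float),
        )
        data = cg.ModelData.from_tables(
            _single_env_pheno(ids, y), "t", genotypes=geno
        )
        fit = cg.fit_bayesian_lasso(
            data,
            priors=PriorConfig(lasso_fixed_lambda2=lam2),
            mcmc=cg.MCMCSettings(n_iter=60000, burn_in=10000, thin=5, seed=11),
        )
        beta = fit.draws["beta"][:, 0]
        nb = 20
        batches = np.array_split(beta, nb)
        bm = np.array([b.mean() for b in batches])
        b2 = np.array([(b**2).mean() for b in batches])
        se_m = bm.std(ddof=1) / math.sqrt(nb)
        se_2 = b2.std(ddof=1) / math.sqrt(nb)
        assert abs(beta.mean() - Eb) < 3 * se_m
        assert abs((beta**2).mean() - Eb2) < 3 * se_2


class TestBGBLUPMMEOracle:
    def test_clamped_variance_matches_mme(self):
        rng = np.random.default_rng(5)
        n = 50
        L = rng.standard_normal((n, 60)) / math.sqrt(60)
        G = L @ L.T
        ids = [f"L{i:02d}" for i in range(n)]
        u_true = np.linalg.cholesky(G + 1e-8 * np.eye(n)) @ rng.standard_normal(n)
        y = 2.0 + u_true + rng.standard_normal(n) * 0.7
        Gm = cg.RelationshipMatrix(np.array(ids, dtype=object), G, "genomic")
        data = cg.ModelData.from_tables(_single_env_pheno(ids, y), "t", G=Gm)
        s2g, s2e = 1.0, 0.49
        fit = cg.fit_bgblup(
            data,
            priors=PriorConfig(scales=ScaleSet(S0=1.0, Sg=1.0)),
            mcmc=cg.MCMCSettings(n_iter=6000, burn_in=1000, thin=1, seed=9),
            fixed_variances={"sigma2_g": s2g, "sigma2_e": s2e},
        )
        Gi = np.linalg.pinv(G)
        C = np.zeros((n + 1, n + 1))
        C[0, 0] = n / s2e
        C[0, 1:] = C[1:, 0] = 1 / s2e
        C[1:, 1:] = np.eye(n) / s2e + Gi / s2g
        rhs = np.concatenate([[y.sum() / s2e], y / s2e])
        u_mme = np.linalg.lstsq(C, rhs, rcond=None)[0][1:]
        u_fit = fit.gebv_mean.loc[ids].to_numpy() - fit.draws["beta0"].mean()
        assert np.corrcoef(u_mme, u_fit)[0, 1] > 0.999

    def test_joint_test_prediction_matches_conditional_mean(self):
        # held-out lines are predicted by treating their phenotypes as
        # missing; with clamped variances the posterior mean GEBV of a test
        # line must match E[u_test | y_train] from the joint Gaussian
        rng = np.random.default_rng(6)
        n, n_test = 40, 8
        L = rng.standard_normal((n, 50)) / math.sqrt(50)
        G = L @ L.T + 0.05 * np.eye(n)
        ids = [f"L{i:02d}" for i in range(n)]
        u_true = np.linalg.cholesky(G) @ rng.standard_normal(n)
        y = 1.0 + u_true + rng.standard_normal(n) * 0.6
        Gm = cg.RelationshipMatrix(np.array(ids, dtype=object), G, "genomic")
        data = cg.ModelData.from_tables(_single_env_pheno(ids, y), "t", G=Gm)
        train, test = ids[:-n_test], ids[-n_test:]
        s2g, s2e = 0.8, 0.36
        fit = cg.fit_bgblup(
            data,
            priors=PriorConfig(scales=ScaleSet(S0=1.0, Sg=1.0)),
            mcmc=cg.MCMCSettings(n_iter=12000, burn_in=2000, thin=2, seed=3),
            train_lines=train,
            fixed_variances={"sigma2_g": s2g, "sigma2_e": s2e},
        )
        b0 = fit.draws["beta0"].mean()
        tr = np.arange(n - n_test)
        te = np.arange(n - n_test, n)
        V = s2g * G[np.ix_(tr, tr)] + s2e * np.eye(n - n_test)
        u_cond = s2g * G[np.ix_(te, tr)] @ np.linalg.solve(V, y[tr] - b0)
        u_fit = fit.gebv_mean.loc[test].to_numpy() - b0
        assert np.corrcoef(u_cond, u_fit)[0, 1] > 0.99
        np.testing.assert_allclose(u_fit, u_cond, atol=0.15)


class TestSamplerMechanics:
    def test_reproducible_with_same_seed(self, panel_data, fast_mcmc):
        f1 = cg.fit_bgblup(panel_data, mcmc=fast_mcmc)
        f2 = cg.fit_bgblup(panel_data, mcmc=fast_mcmc)
        np.testing.assert_array_equal(f1.draws["u"], f2.draws["u"])
        np.testing.assert_array_equal(f1.draws["sigma2_e"], f2.draws["sigma2_e"])

    def test_seed_changes_draws(self, panel_data, fast_mcmc):
        other = cg.MCMCSettings(
            n_iter=fast_mcmc.n_iter,
            burn_in=fast_mcmc.burn_in,
            thin=fast_mcmc.thin,
            seed=fast_mcmc.seed + 1,
        )
        f1 = cg.fit_bgblup(panel_data, mcmc=fast_mcmc)
        f2 = cg.fit_bgblup(panel_data, mcmc=other)
        assert not np.array_equal(f1.draws["sigma2_e"], f2.draws["sigma2_e"])

    def test_stored_draw_count(self, panel_data):
        mc = cg.MCMCSettings(n_iter=1000, burn_in=300, thin=7, seed=0)
        fit = cg.fit_bgblup(panel_data, mcmc=mc)
        assert fit.n_stored == (1000 - 300) // 7
        assert fit.draws["sigma2_g"].shape == (fit.n_stored,)

    def test_single_level_factors_dropped(self, panel_data):
        # one year and one experiment: no environment variance components
        fit = cg.fit_bgblup(panel_data, mcmc=cg.MCMCSettings(200, 50, 3, 0))
        assert "sigma2_alpha" not in fit.draws
        assert "sigma2_gamma" not in fit.draws

    def test_multi_level_factors_present(self, multiyear_study, fast_mcmc):
        g = cg.filter_markers(multiyear_study.genotypes, 0.0, 0.025)
        data = cg.ModelData.from_tables(
            multiyear_study.phenotypes, "t", G=cg.compute_grm(g)
        )
        fit = cg.fit_bgblup(data, mcmc=fast_mcmc)
        assert fit.draws["sigma2_alpha"].shape == (fit.n_stored,)
        assert fit.draws["gamma_year"].shape[1] == 3

    def test_unknown_training_line_rejected(self, panel_data, fast_mcmc):
        with pytest.raises(KeyError, match="nonsense"):
            cg.fit_bgblup(panel_data, mcmc=fast_mcmc, train_lines=["nonsense"])

    def test_bgblup_requires_g(self, panel_study, fast_mcmc):
        data = cg.ModelData.from_tables(panel_study.phenotypes, "t")
        with pytest.raises(ValueError, match="relationship"):
            cg.fit_bgblup(data, mcmc=fast_mcmc)


class TestBayesC:
    def test_pip_and_pi_stored(self, panel_data, fast_mcmc):
        fit = cg.fit_bayes_c(panel_data, mcmc=fast_mcmc)
        assert fit.pip is not None and len(fit.pip) == panel_data.X.shape[1]
        assert ((fit.pip >= 0) & (fit.pip <= 1)).all()
        assert ((fit.draws["pi"] > 0) & (fit.draws["pi"] < 1)).all()

    def test_strong_signal_recovered(self):
        rng = np.random.default_rng(21)
        n, p = 150, 60
        X = rng.integers(0, 3, size=(n, p)).astype(float)
        y = X[:, 7] * 1.5 + rng.standard_normal(n) * 0.5
        ids = [f"L{i}" for i in range(n)]
        geno = cg.GenotypeMatrix(
            np.array(ids, dtype=object),
            np.array([f"M{j}" for j in range(p)], dtype=object),
            X,
        )
        data = cg.ModelData.from_tables(_single_env_pheno(ids, y), "t", genotypes=geno)
        fit = cg.fit_bayes_c(data, mcmc=cg.MCMCSettings(2000, 500, 3, 2))
        assert fit.pip.iloc[7] > 0.9
        assert fit.draws["beta"][:, 7].mean() == pytest.approx(1.5, abs=0.2)


class TestHeritability:
    def test_hand_computed_from_draws(self, panel_data, fast_mcmc):
        fit = cg.fit_bgblup(panel_data, mcmc=fast_mcmc)
        h2 = cg.estimate_heritability(fit)
        d = fit.draws
        per_draw = d["sigma2_g"] / (d["sigma2_g"] + d["sigma2_e"])
        assert h2.mean == pytest.approx(per_draw.mean())
        lo, hi = np.quantile(per_draw, [0.025, 0.975])
        assert h2.ci_low == pytest.approx(lo)
        assert h2.ci_high == pytest.approx(hi)
        assert h2.ci_low <= h2.mean <= h2.ci_high

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            HeritabilityEstimate(mean=0.5, ci_low=0.7, ci_high=0.6)


class TestPredictGEBV:
    def test_new_lines_from_marker_effects(self, panel_data, panel_geno):
        fit = cg.fit_bayesian_lasso(panel_data, mcmc=cg.MCMCSettings(800, 200, 3, 4))
        # lines inside the fit: read back the stored posterior mean
        inside = list(panel_data.line_ids[:5])
        out = cg.predict_gebv(fit, inside)
        pd.testing.assert_series_equal(out, fit.gebv_mean.loc[inside])
        # genuinely new lines (fresh ids, dosages copied from known lines)
        # go through the X_new @ beta-hat path
        src = panel_geno.subset_lines(inside)
        new_ids = [f"NEW{i}" for i in range(len(inside))]
        new_geno = cg.GenotypeMatrix(
            np.array(new_ids, dtype=object), src.marker_ids, src.dosages.copy()
        )
        new = cg.predict_gebv(fit, new_ids, genotypes=new_geno)
        expected = (
            fit.draws["beta0"].mean()
            + (src.dosages - fit.x_center) @ fit.draws["beta"].mean(axis=0)
        )
        np.testing.assert_allclose(new.to_numpy(), expected, atol=1e-10)

    def test_kernel_model_cannot_extrapolate(self, panel_data, panel_geno):
        fit = cg.fit_bgblup(panel_data, mcmc=cg.MCMCSettings(300, 100, 2, 4))
        with pytest.raises(KeyError):
            cg.predict_gebv(fit, ["not-a-line"])
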