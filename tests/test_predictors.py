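import numpy as np
import pandas as pd
import pytest

import leakscan as lk
from leakscan.kinship import SparsePrecision
from leakscan.mme import VarianceComponents, solve_animal_mme
from leakscan.pedigree import ConfigError, Pedigree
from leakscan.predictors import (BayesianWGR, GibbsConfig, PedigreeBLUP,
                                 SingleStepGBLUP, effective_sample_size,
                                 predict_out_of_sample)
from leakscan.simdata import GenotypeMatrix, MarkerMap

from conftest import random_pedigree
from test_kinship import small_gm


def gblup_oracle(y, ids_obs, G, sigma2_g, sigma2_e):
    """Independent GBLUP via the variance-form BLUP equations.

    V = Z G Z' sg2 + I se2; mu = GLS; u = sg2 G Z' V^-1 (y - mu).
    """
    n_all = G.shape[0]
    Z = np.zeros((len(ids_obs), n_all))
    for r, i in enumerate(ids_obs):
        Z[r, i] = 1.0
    V = Z @ G @ Z.T * sigma2_g + np.eye(len(ids_obs)) * sigma2_e
    Vi = np.linalg.inv(V)
    one = np.ones(len(ids_obs))
    mu = (one @ Vi @ y) / (one @ Vi @ one)
    u = sigma2_g * G @ Z.T @ Vi @ (y - mu)
    return mu, u


class TestPrecorrection:
    def test_translation_invariance(self, tiny_pop):
        pop, _ = tiny_pop
        vc = VarianceComponents(0.5, 0.4, 0.1)
        base = lk.precorrect_phenotypes(pop.trait.phenotypes, pop.pedigree, vc)
        shifted = pop.trait.phenotypes.copy()
        shifted["raw_y"] = shifted["raw_y"] + 17.5
        out = lk.precorrect_phenotypes(shifted, pop.pedigree, vc)
        assert np.allclose(out["precorrected_y"], base["precorrected_y"], atol=1e-8)

    def test_cg_effects_recovered(self, medium_pop):
        pop, cfg = medium_pop
        vc = VarianceComponents(0.50, 0.40, 0.10)
        out = lk.precorrect_phenotypes(pop.trait.phenotypes, pop.pedigree, vc)
        # rebuild the true CG effects used by the simulator
        sim = pop.trait
        truth = sim.phenotypes.groupby("cg")["raw_y"].mean()  # rough proxy
        est = pd.Series(out.attrs["cg_solutions"],
                        index=pd.factorize(out["cg"])[1])
        merged = pd.concat([truth, est], axis=1, keys=["truth", "est"]).dropna()
        r = np.corrcoef(merged["truth"], merged["est"])[0, 1]
        assert r > 0.95

    def test_covariate_slope_recovered(self):
        ped = lk.simulate_pedigree(600, 3, litter_size=2, seed=21)
        mm = MarkerMap(np.array(["a", "b"], dtype=object), [1, 1], [100, 200],
                       [False, False])
        H = lk.simulate_founder_haplotypes(mm, 600, (0.3, 0.5), 1e-6, seed=21)
        gm = lk.gene_drop(ped, H, mm, 1e-8, seed=21)
        arch = lk.assign_qtl(gm, 2, 1.0, seed=21)
        cfg = lk.TraitSimConfig(h2_qtl=0.0, h2_polygenic=0.3, litter_var_frac=0.1,
                                covariate_slope=2.0, seed=21)
        sim = lk.simulate_phenotypes(gm, ped, arch, cfg)
        vc = VarianceComponents(0.3, 0.6, 0.1)
        out = lk.precorrect_phenotypes(sim.phenotypes, ped, vc, covariate_flag=True)
        assert 1.8 <= out.attrs["covariate_slope"] <= 2.2

    def test_residual_plus_genetic_retained(self, tiny_pop):
        """Pre-correction removes CG and litter but keeps genetic + residual."""
        pop, _ = tiny_pop
        vc = VarianceComponents(0.50, 0.40, 0.10)
        out = lk.precorrect_phenotypes(pop.trait.phenotypes, pop.pedigree, vc)
        g = pop.trait.true_genetic.reindex(out["animal_id"]).to_numpy()
        r = np.corrcoef(out["precorrected_y"], g)[0, 1]
        raw_r = np.corrcoef(out["raw_y"], g)[0, 1]
        assert r > raw_r  # stripping nuisance effects sharpens the signal


class TestPBLUP:
    def test_single_record_closed_form(self):
        # (1 + lambda) u = y with one founder, lambda=1, y=1 -> u = 0.5
        ped = Pedigree([1], [0], [0], [0], [1])
        y = pd.Series([1.0], index=[1])
        vc = VarianceComponents(1.0, 1.0)
        res = PedigreeBLUP(y, ped, vc).fit()
        # intercept absorbs the mean; with a single record the MME gives
        # mu + u = y and u = y - mu with shrinkage; check the residual identity
        resid = res.residuals(y)
        assert np.allclose(res.predict([1]) + resid, y)

    def test_infinite_shrinkage_limit(self):
        ped = random_pedigree(30, seed=1)
        rng = np.random.default_rng(0)
        y = pd.Series(rng.normal(size=30), index=ped.animal_id)
        res = PedigreeBLUP(y, ped, VarianceComponents(1e-8, 1.0)).fit()
        assert np.max(np.abs(res.u)) < 1e-4
        resid = res.residuals(y)
        assert np.allclose(resid, y - y.mean(), atol=1e-3)

    def test_no_shrinkage_limit(self):
        ped = random_pedigree(30, seed=2)
        rng = np.random.default_rng(0)
        y = pd.Series(rng.normal(size=30), index=ped.animal_id)
        res = PedigreeBLUP(y, ped, VarianceComponents(1.0, 1e-8)).fit()
        assert np.max(np.abs(res.residuals(y))) < 1e-4

    def test_residual_identity_exact(self, tiny_pop):
        pop, _ = tiny_pop
        pheno = lk.precorrect_phenotypes(pop.trait.phenotypes, pop.pedigree,
                                         VarianceComponents(0.50, 0.40, 0.10))
        y = pd.Series(pheno["precorrected_y"].to_numpy(),
                      index=pheno["animal_id"].to_numpy())
        res = PedigreeBLUP(y, pop.pedigree, VarianceComponents(0.50, 0.40)).fit()
        frame = res.fit_frame(y)
        recon = frame["prediction"] + frame["residual"]
        assert np.max(np.abs(recon.to_numpy() - y.to_numpy())) < 1e-8

    def test_bad_lambda(self):
        with pytest.raises(ConfigError):
            VarianceComponents(0.0, 1.0)


class TestSolverPaths:
    def test_pcg_matches_dense(self):
        ped = random_pedigree(120, seed=5)
        rng = np.random.default_rng(3)
        obs = np.sort(rng.choice(ped.animal_id, 80, replace=False))
        y = pd.Series(rng.normal(size=80), index=obs)
        a_inv = lk.a_inverse(ped)
        mu_d, u_d = solve_animal_mme(y, a_inv, 1.3, method="dense")
        mu_p, u_p = solve_animal_mme(y, a_inv, 1.3, method="pcg")
        assert mu_d == pytest.approx(mu_p, abs=1e-7)
        assert np.max(np.abs(u_d - u_p)) < 1e-7

    def test_pcg_nonconvergence_raises(self):
        from leakscan.kinship import NumericalError

        ped = random_pedigree(50, seed=6)
        y = pd.Series(np.ones(50), index=ped.animal_id)
        with pytest.raises(NumericalError):
            solve_animal_mme(y, lk.a_inverse(ped), 1.0, method="pcg", maxiter=1)


class TestSingleStepGBLUP:
    def _pop(self, n=80, seed=4):
        ped = lk.simulate_pedigree(40, 2, litter_size=2, seed=seed)
        mm = MarkerMap(np.array([f"s{i}" for i in range(300)], dtype=object),
                       np.ones(300, int), (np.arange(300) + 1) * 10_000,
                       np.zeros(300, bool))
        H = lk.simulate_founder_haplotypes(mm, 40, (0.2, 0.5), 1e-6, seed=seed)
        gm = lk.gene_drop(ped, H, mm, 1e-8, seed=seed)
        rng = np.random.default_rng(seed)
        y = pd.Series(rng.normal(size=ped.n), index=ped.animal_id)
        return ped, gm, y

    def test_empty_genotyped_equals_pblup(self):
        ped, gm, y = self._pop()
        vc = VarianceComponents(0.5, 0.5)
        pb = PedigreeBLUP(y, ped, vc).fit()
        ss = SingleStepGBLUP(y, ped, gm, set(), vc).fit()
        assert np.max(np.abs(pb.u - ss.u)) < 1e-8

    def test_all_genotyped_matches_dense_gblup_oracle(self):
        ped, gm, y = self._pop()
        vc = VarianceComponents(0.5, 0.5)
        ss = SingleStepGBLUP(y, ped, gm, set(ped.animal_id), vc,
                             blend_weight=0.95, tune=True).fit()
        # oracle: GBLUP in variance form with the same blended G*
        A22 = lk.a_matrix(ped)
        G = lk.g_matrix(gm)
        Gs = lk.blend_tune_g(G, lk.RelationshipMatrix(A22.values, ped.animal_id, "A22"),
                             0.95, True)
        mu_o, u_o = gblup_oracle(y.to_numpy(), np.arange(ped.n), Gs.values,
                                 vc.sigma2_g, vc.sigma2_e)
        assert ss.intercept == pytest.approx(mu_o, abs=1e-6)
        assert np.max(np.abs(ss.u.to_numpy() - u_o)) < 1e-6

    def test_snp_blup_gblup_duality(self):
        """Ridge with per-SNP variance sg2/(2*sum p q) = GBLUP with VanRaden G."""
        ped, gm, y = self._pop(seed=8)
        X = gm.dosages_float()
        p = X.mean(0) / 2
        keep = (p > 0) & (p < 1)
        X = X[:, keep]
        p = p[keep]
        Z = X - 2 * p
        denom = 2 * np.sum(p * (1 - p))
        sg2, se2 = 0.4, 0.6
        # SNP-BLUP closed form (with intercept absorbed by centering trick):
        n = len(y)
        yv = y.to_numpy()
        lam = se2 / (sg2 / denom)
        one = np.ones(n)
        # solve [ [n, 1'Z]; [Z'1, Z'Z + lam I] ] directly
        C = np.zeros((1 + Z.shape[1],) * 2)
        C[0, 0] = n
        C[0, 1:] = one @ Z
        C[1:, 0] = one @ Z
        C[1:, 1:] = Z.T @ Z + lam * np.eye(Z.shape[1])
        rhs = np.concatenate([[yv.sum()], Z.T @ yv])
        sol = np.linalg.solve(C, rhs)
        pred_snp = sol[0] + Z @ sol[1:]
        # GBLUP route through the package
        G = lk.g_matrix(gm)
        mu_o, u_o = gblup_oracle(yv, np.arange(n), G.values, sg2, se2)
        assert np.max(np.abs(pred_snp - (mu_o + u_o))) < 1e-6

    def test_prediction_accuracy_nondecreasing_in_pct(self, medium_pop):
        """Out-of-sample accuracy improves as more training animals are
        genotyped (PBLUP -> ssGBLUP_20 -> ssGBLUP_100, nested masks)."""
        pop, cfg = medium_pop
        vc = VarianceComponents(0.50, 0.40, 0.10)
        pheno = lk.precorrect_phenotypes(pop.trait.phenotypes, pop.pedigree, vc)
        y = pd.Series(pheno["precorrected_y"].to_numpy(),
                      index=pheno["animal_id"].to_numpy())
        gens = pheno["animal_id"].map(
            dict(zip(pop.pedigree.animal_id, pop.pedigree.generation))).to_numpy()
        last = gens.max()
        y_tr, y_te = y[gens < last], y[gens == last]
        truth = pop.trait.true_genetic.reindex(y_te.index)
        vc2 = VarianceComponents(0.50, 0.40)
        accs = []
        for pct in (0, 20, 100):
            gen = lk.mask_genotyped(y_tr.index.to_numpy(), pct, seed=13)
            gen |= set(int(a) for a in y_te.index)
            res = SingleStepGBLUP(y_tr, pop.pedigree, pop.genotypes, gen, vc2,
                                  pct_genotyped=pct).fit()
            pred = res.u.reindex(truth.index)
            accs.append(np.corrcoef(pred, truth)[0, 1])
        assert accs[2] >= accs[1] >= accs[0] - 0.02  # monotone up to noise
        assert accs[2] > accs[0]  # genomic information beats pedigree alone


class TestGibbs:
    def test_null_design_gives_intercept(self):
        rng = np.random.default_rng(0)
        y = pd.Series(rng.normal(2.0, 1.0, 120), index=np.arange(1, 121))
        X = np.zeros((120, 5), dtype=np.int8)
        gm = small_gm(X)
        cfg = GibbsConfig(n_iter=2000, burn_in=500, thin=2, seed=1)
        res = BayesianWGR(y, gm, "BRR", cfg).fit()
        assert res.intercept == pytest.approx(y.mean(), abs=0.05)
        resid = res.residuals(y)
        assert np.allclose(resid, y - res.intercept, atol=1e-10)

    def test_null_posterior_sigma2e_matches_var(self):
        rng = np.random.default_rng(1)
        n, p = 150, 10
        y = pd.Series(rng.normal(size=n), index=np.arange(1, n + 1))
        X = rng.binomial(2, 0.4, size=(n, p)).astype(np.int8)
        cfg = GibbsConfig(n_iter=20_000, burn_in=4000, thin=5, seed=2)
        res = BayesianWGR(y, small_gm(X), "BRR", cfg).fit()
        assert abs(res.posterior.sigma2_e - y.var()) / y.var() < 0.10

    def test_bayesc_pi_one_equals_brr(self):
        rng = np.random.default_rng(2)
        n, p = 200, 80
        X = rng.binomial(2, rng.uniform(0.2, 0.5, p), size=(n, p)).astype(np.int8)
        b = rng.normal(0, 0.15, p)
        y = pd.Series(X @ b + rng.normal(size=n), index=np.arange(1, n + 1))
        cfg = GibbsConfig(n_iter=6000, burn_in=1500, thin=2, seed=3)
        brr = BayesianWGR(y, small_gm(X), "BRR", cfg).fit()
        bc1 = BayesianWGR(y, small_gm(X), "BayesC", cfg, pi_fixed=1.0).fit()
        r = np.corrcoef(brr.posterior.effect_mean, bc1.posterior.effect_mean)[0, 1]
        assert r > 0.98

    def test_selection_recovers_large_effect_and_ridge_shrinks(self):
        rng = np.random.default_rng(3)
        n, p = 600, 300
        X = rng.binomial(2, rng.uniform(0.2, 0.5, p), size=(n, p)).astype(np.int8)
        Xc = X - X.mean(0)
        b = rng.normal(0, 0.02, p)
        big = 0.55  # carries most of the genetic variance
        b[10] = big
        g = Xc @ b
        y_vals = g + rng.normal(0, g.std(), n)
        y = pd.Series(y_vals, index=np.arange(1, n + 1))
        cfg = GibbsConfig(n_iter=4000, burn_in=1000, thin=2, seed=4)
        bc = BayesianWGR(y, small_gm(X), "BayesC", cfg).fit()
        brr = BayesianWGR(y, small_gm(X), "BRR", cfg).fit()
        assert bc.posterior.inclusion_prob[10] > 0.9
        assert abs(brr.posterior.effect_mean[10]) < big  # Gaussian prior shrinks

    def test_chain_reproducibility(self):
        rng = np.random.default_rng(4)
        X = rng.binomial(2, 0.3, size=(50, 20)).astype(np.int8)
        y = pd.Series(rng.normal(size=50), index=np.arange(1, 51))
        cfg = GibbsConfig(n_iter=500, burn_in=100, seed=9)
        a = BayesianWGR(y, small_gm(X), "BayesB", cfg).fit()
        b = BayesianWGR(y, small_gm(X), "BayesB", cfg).fit()
        assert np.array_equal(a.posterior.effect_mean, b.posterior.effect_mean)

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            GibbsConfig(n_iter=100, burn_in=100)
        with pytest.raises(ConfigError):
            GibbsConfig(prior_R2=1.5)

    def test_ess_sane(self):
        rng = np.random.default_rng(5)
        iid = rng.normal(size=2000)
        ess = effective_sample_size(iid)
        assert 1000 < ess <= 2000
        # strongly autocorrelated chain has far fewer effective samples
        ar = np.zeros(2000)
        for i in range(1, 2000):
            ar[i] = 0.95 * ar[i - 1] + rng.normal()
        assert effective_sample_size(ar) < 400


class TestOutOfSample:
    def test_unrelated_founder_gets_intercept_only(self):
        ped = Pedigree([1, 2, 3, 4], [0, 0, 1, 0], [0, 0, 2, 0],
                       [0, 0, 1, 0], [1, 2, 3, 4])
        y = pd.Series([1.0, -0.5, 0.8], index=[1, 2, 3])
        res = PedigreeBLUP(y, ped, VarianceComponents(0.5, 0.5)).fit()
        y_test = pd.Series([0.3], index=[4])
        frame = predict_out_of_sample(res, y_test)
        # founder 4 is unrelated to all training animals: u = 0
        assert res.u[4] == pytest.approx(0.0, abs=1e-10)
        assert frame["residual"].iloc[0] == pytest.approx(0.3 - res.intercept)

    def test_duplicate_genotype_identical_prediction(self):
        rng = np.random.default_rng(6)
        n, p = 80, 40
        X = rng.binomial(2, 0.4, size=(n, p)).astype(np.int8)
        X[-1] = X[0]  # animal n duplicates animal 1's genotype
        gm = small_gm(X)
        y = pd.Series(rng.normal(size=n - 1), index=np.arange(1, n))
        cfg = GibbsConfig(n_iter=1000, burn_in=200, seed=7)
        res = BayesianWGR(y, gm, "BRR", cfg).fit()
        preds = res.predict([1, n])
        assert preds.iloc[0] == pytest.approx(preds.iloc[1], abs=1e-12)

    def test_testing_residuals_use_training_fit(self, tiny_pop):
        pop, _ = tiny_pop
        pheno = lk.precorrect_phenotypes(pop.trait.phenotypes, pop.pedigree,
                                         VarianceComponents(0.50, 0.40, 0.10))
        y = pd.Series(pheno["precorrected_y"].to_numpy(),
                      index=pheno["animal_id"].to_numpy())
        gens = pheno["animal_id"].map(
            dict(zip(pop.pedigree.animal_id, pop.pedigree.generation)))
        train, test = y[(gens < 2).to_numpy()], y[(gens == 2).to_numpy()]
        res = PedigreeBLUP(train, pop.pedigree, VarianceComponents(0.50, 0.40)).fit()
        frame = predict_out_of_sample(res, test)
        assert set(frame["animal_id"]) == set(test.index)
        recon = frame["prediction"] + frame["residual"]
        assert np.allclose(recon, test.to_numpy(), atol=1e-10)
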