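import numpy as np
import pandas as pd
import pytest

from conftest import random_design, random_psd_grm, simulated_dataset
from gsel.errors import (
    ConfigurationError,
    DegenerateInputError,
    DesignError,
    InsufficientDataError,
)
from gsel.gblup import (
    ModelDesign,
    build_design,
    estimate_heritability,
    fit_gblup_reml,
    predict_genotypic_values,
    scale_phenotypes,
)
from gsel.genotypes import GRM, GenotypeMatrix, compute_grm


def dense_restricted_loglik(y, X, K, s2u, s2e):
    """Textbook REML log-likelihood, independent of the spectral solver."""
    n, p = X.shape
    V = s2u * K + s2e * np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    sign1, ld1 = np.linalg.slogdet(V)
    sign2, ld2 = np.linalg.slogdet(XtViX)
    assert sign1 > 0 and sign2 > 0
    return -0.5 * (ld1 + ld2 + r @ Vi @ r + (n - p) * np.log(2 * np.pi))


class TestScalePhenotypes:
    def _table(self, values_by_env):
        rows = []
        for env, vals in values_by_env.items():
            for i, v in enumerate(vals):
                rows.append((f"a{i}", env, 1, "t", float(v)))
        return pd.DataFrame(rows, columns=["accession_id", "env_id", "rep",
                                           "trait", "value"])

    def test_forced_values(self):
        pt = self._table({"E1": [1, 2, 3], "E2": [10, 20, 30]})
        out = scale_phenotypes(pt)
        e1 = out[out.env_id == "E1"]["value"].to_numpy()
        np.testing.assert_allclose(np.sort(e1), [-1, 0, 1], atol=1e-12)

    def test_single_env_left_raw(self):
        pt = self._table({"E1": [1, 2, 3]})
        out = scale_phenotypes(pt)
        np.testing.assert_array_equal(out["value"], pt["value"])

    def test_two_env_moments(self, rng):
        pt = self._table({"E1": rng.normal(5, 3, 40),
                          "E2": rng.normal(-2, 0.5, 40)})
        out = scale_phenotypes(pt)
        for env in ("E1", "E2"):
            v = out[out.env_id == env]["value"].to_numpy()
            assert abs(v.mean()) < 1e-12
            assert abs(v.var(ddof=1) - 1) < 1e-12

    def test_zero_variance_errors(self):
        pt = self._table({"E1": [1, 1, 1], "E2": [1, 2, 3]})
        with pytest.raises(DegenerateInputError):
            scale_phenotypes(pt)


class TestFitGBLUPReml:
    def test_null_simulation(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = 200
            grm = GRM(np.array([f"a{i}" for i in range(n)], dtype=object),
                      np.eye(n))
            design = ModelDesign(y=rng.standard_normal(n),
                                 X=np.ones((n, 1)), Z=np.eye(n), grm=grm)
            fit = fit_gblup_reml(design)
            if fit.h2_model < 0.1:
                hits += 1
        assert hits >= 45

    def test_grid_search_oracle_six_records(self, rng):
        grm = random_psd_grm(4, rng, n_markers=60)
        grm = GRM(grm.accession_ids, grm.values + 0.05 * np.eye(4))
        rows = [0, 0, 1, 1, 2, 3]
        Z = np.zeros((6, 4))
        Z[np.arange(6), rows] = 1.0
        y = np.array([1.3, 0.9, -0.4, -0.1, 0.7, -1.2])
        X = np.ones((6, 1))
        design = ModelDesign(y=y, X=X, Z=Z, grm=grm)
        fit = fit_gblup_reml(design)
        K = Z @ grm.values @ Z.T

        # brute force over the heritability ratio, profiling the scale
        n, p = 6, 1
        best_ll, best_h2 = -np.inf, None
        for h2 in np.arange(1e-4, 1.0, 1e-4):
            delta = (1 - h2) / h2
            H = K + delta * np.eye(n)
            Hi = np.linalg.inv(H)
            XtHiX = X.T @ Hi @ X
            beta = np.linalg.solve(XtHiX, X.T @ Hi @ y)
            r = y - X @ beta
            s2u = float(r @ Hi @ r) / (n - p)
            ll = dense_restricted_loglik(y, X, K, s2u, delta * s2u)
            if ll > best_ll:
                best_ll, best_h2 = ll, h2

        ll_fit = dense_restricted_loglik(y, X, K, fit.sigma2_u, fit.sigma2_e)
        assert ll_fit >= best_ll - 1e-6
        assert abs(fit.h2_model - best_h2) <= 2e-4

    def test_reml_optimum_dominates_grid(self, rng):
        design, _ = random_design(30, 20, rng)
        fit = fit_gblup_reml(design)
        K = design.Z @ design.grm.values @ design.Z.T
        ll_fit = dense_restricted_loglik(design.y, design.X, K,
                                         fit.sigma2_u, fit.sigma2_e)
        total = fit.sigma2_u + fit.sigma2_e
        for h2 in np.linspace(0.02, 0.98, 25):
            ll = dense_restricted_loglik(design.y, design.X, K,
                                         h2 * total, (1 - h2) * total)
            assert ll_fit >= ll - 1e-8

    def test_record_collapsing_oracle(self, rng):
        # duplicated records act through a shared Z column: the fitted BLUP
        # must equal the hand-derived BLUP of the collapsed model that
        # averages the response and halves the residual variance
        n = 25
        grm = random_psd_grm(n, rng, n_markers=150)
        obs = np.arange(15)
        rows = np.repeat(obs, 2)
        Z = np.zeros((30, n))
        Z[np.arange(30), rows] = 1.0
        y = rng.standard_normal(30) + rng.standard_normal(n)[rows]
        design = ModelDesign(y=y, X=np.ones((30, 1)), Z=Z, grm=grm)
        fit = fit_gblup_reml(design)

        ybar = y.reshape(15, 2).mean(axis=1)
        Zc = np.zeros((15, n))
        Zc[np.arange(15), obs] = 1.0
        Kc = Zc @ grm.values @ Zc.T
        Vc = fit.sigma2_u * Kc + (fit.sigma2_e / 2) * np.eye(15)
        Xc = np.ones((15, 1))
        Vci = np.linalg.inv(Vc)
        beta_c = np.linalg.solve(Xc.T @ Vci @ Xc, Xc.T @ Vci @ ybar)
        u_c = fit.sigma2_u * grm.values @ Zc.T @ Vci @ (ybar - Xc @ beta_c)
        np.testing.assert_allclose(fit.u_hat, u_c, atol=1e-8)
        np.testing.assert_allclose(fit.beta, beta_c, atol=1e-8)

    def test_scale_equivariance(self, rng):
        design, _ = random_design(40, 30, rng)
        fit1 = fit_gblup_reml(design)
        k = 3.7
        design2 = ModelDesign(y=k * design.y, X=design.X, Z=design.Z,
                              grm=design.grm)
        fit2 = fit_gblup_reml(design2)
        np.testing.assert_allclose(fit2.u_hat, k * fit1.u_hat, atol=1e-8)
        assert fit2.sigma2_u == pytest.approx(k**2 * fit1.sigma2_u, rel=1e-6)
        assert fit2.sigma2_e == pytest.approx(k**2 * fit1.sigma2_e, rel=1e-6)

    def test_ridge_duality_small(self, rng):
        # GBLUP through G = WW'/c must equal marker-effect ridge regression
        n, m = 50, 200
        p = rng.uniform(0.1, 0.5, m)
        d = rng.binomial(2, p, size=(n, m)).astype(float)
        keep = (d.mean(axis=0) > 0) & (d.mean(axis=0) < 2)
        d = d[:, keep]
        g = GenotypeMatrix([f"a{i:03d}" for i in range(n)],
                           [f"m{j}" for j in range(d.shape[1])], d)
        grm = compute_grm(g)
        pfreq = d.mean(axis=0) / 2
        W = d - 2 * pfreq
        c = 2 * np.sum(pfreq * (1 - pfreq))

        obs = rng.choice(n, size=35, replace=False)
        Z = np.zeros((35, n))
        Z[np.arange(35), obs] = 1.0
        y = W[obs] @ rng.normal(0, 0.1, W.shape[1]) + rng.standard_normal(35)
        design = ModelDesign(y=y, X=np.ones((35, 1)), Z=Z, grm=grm)
        fit = fit_gblup_reml(design)

        lam = c * fit.sigma2_e / fit.sigma2_u
        Wo = W[obs]
        r = y - fit.beta[0]
        a_hat = np.linalg.solve(Wo.T @ Wo + lam * np.eye(W.shape[1]), Wo.T @ r)
        assert np.max(np.abs(fit.u_hat - W @ a_hat)) < 1e-6

    def test_recovery_small(self):
        ests = []
        for seed in range(8):
            _, _, pheno, _, grm = simulated_dataset(
                n_pool=200, n_train=200, n_markers=500, h2=0.5, seed=seed)
            fit = fit_gblup_reml(build_design(pheno, grm, "trait"))
            ests.append(fit.h2_model)
        assert abs(np.mean(ests) - 0.5) < 0.1


class TestPredictGenotypicValues:
    def test_subset_sizes(self, rng):
        design, _ = random_design(30, 18, rng)
        fit = fit_gblup_reml(design)
        assert len(predict_genotypic_values(fit, "all")) == 30
        assert len(predict_genotypic_values(fit, "tested")) == 18
        assert len(predict_genotypic_values(fit, "untested")) == 12
        with pytest.raises(ConfigurationError):
            predict_genotypic_values(fit, "nope")

    def test_unrelated_untested_gets_zero(self, rng):
        # block-diagonal G: last accession unrelated to every tested one
        n = 11
        base = random_psd_grm(n - 1, rng, n_markers=80)
        vals = np.zeros((n, n))
        vals[:-1, :-1] = base.values
        vals[-1, -1] = 1.0
        grm = GRM(np.append(base.accession_ids, "zzz"), vals)
        obs = np.arange(n - 1)
        Z = np.zeros((n - 1, n))
        Z[np.arange(n - 1), obs] = 1.0
        design = ModelDesign(y=rng.standard_normal(n - 1),
                             X=np.ones((n - 1, 1)), Z=Z, grm=grm)
        fit = fit_gblup_reml(design)
        assert predict_genotypic_values(fit, "untested")["zzz"] == pytest.approx(0.0, abs=1e-12)

    def test_duplicate_accession_same_pgv(self, rng):
        # untested accession genotype-identical to a tested one
        n, m = 20, 120
        p = rng.uniform(0.1, 0.5, m)
        d = rng.binomial(2, p, size=(n, m)).astype(float)
        d[-1] = d[0]  # duplicate of accession 0
        keep = (d.mean(axis=0) > 0) & (d.mean(axis=0) < 2)
        g = GenotypeMatrix([f"a{i:02d}" for i in range(n)],
                           [f"m{j}" for j in range(keep.sum())],
                           d[:, keep])
        grm = compute_grm(g)
        obs = np.arange(n - 1)
        Z = np.zeros((n - 1, n))
        Z[np.arange(n - 1), obs] = 1.0
        design = ModelDesign(y=rng.standard_normal(n - 1),
                             X=np.ones((n - 1, 1)), Z=Z, grm=grm)
        fit = fit_gblup_reml(design)
        assert abs(fit.u_hat[-1] - fit.u_hat[0]) < 1e-8


class TestEstimateHeritability:
    @staticmethod
    def _replicated_trial(n, R, vg, ve, seed, rep_effects=None):
        rng = np.random.default_rng(seed)
        g = rng.normal(0, np.sqrt(vg), n)
        rep_effects = rep_effects or [0.0] * R
        rows = []
        for i in range(n):
            for j in range(R):
                rows.append((f"a{i:03d}", "E1", j + 1, "t",
                             g[i] + rep_effects[j] + rng.normal(0, np.sqrt(ve))))
        return pd.DataFrame(rows, columns=["accession_id", "env_id", "rep",
                                           "trait", "value"])

    def test_formula_identity(self):
        pt = self._replicated_trial(60, 2, 1.0, 1.0, 0)
        est = estimate_heritability(pt, "E1", "t")
        assert est.H2 == pytest.approx(est.V_g / (est.V_g + est.V_e / est.R))
        assert est.R == 2

    def test_plug_in_point(self):
        # Vg = Ve = 1 with R = 2 gives H2 = 2/3
        assert 1.0 / (1.0 + 1.0 / 2) == pytest.approx(2 / 3)
        pt = self._replicated_trial(400, 2, 1.0, 1.0, 1, rep_effects=[0, 0.7])
        est = estimate_heritability(pt, "E1", "t")
        assert est.H2 == pytest.approx(2 / 3, abs=0.08)

    def test_parameter_recovery(self):
        vals = []
        for seed in range(20):
            pt = self._replicated_trial(300, 2, 2.0, 1.0, seed,
                                        rep_effects=[0, 0.5])
            vals.append(estimate_heritability(pt, "E1", "t").H2)
        assert abs(np.mean(vals) - 0.8) < 0.05

    def test_null_signal(self):
        # sampling SD of the boundary-truncated Vg estimate is ~Ve/sqrt(n);
        # n = 600 puts the H2 < 0.1 threshold ~1.9 SDs out
        low = 0
        for seed in range(20):
            pt = self._replicated_trial(600, 2, 0.0, 1.0, seed)
            if estimate_heritability(pt, "E1", "t").H2 < 0.1:
                low += 1
        assert low >= 18

    def test_single_rep_errors(self):
        pt = self._replicated_trial(30, 1, 1.0, 1.0, 0)
        with pytest.raises(InsufficientDataError):
            estimate_heritability(pt, "E1", "t")


class TestBuildDesign:
    def test_multi_env_intercepts(self, rng):
        grm = random_psd_grm(10, rng)
        rows = []
        for env in ("E1", "E2"):
            for i in range(6):
                rows.append((grm.accession_ids[i], env, 1, "t",
                             float(rng.normal())))
        pt = pd.DataFrame(rows, columns=["accession_id", "env_id", "rep",
                                         "trait", "value"])
        design = build_design(pt, grm, "t")
        assert design.X.shape == (12, 2)
        assert (design.X.sum(axis=1) == 1).all()
        # auto-scaling applied per env
        for col in range(2):
            v = design.y[design.X[:, col] == 1]
            assert abs(v.mean()) < 1e-12

    def test_unknown_accession_errors(self, rng):
        grm = random_psd_grm(4, rng)
        pt = pd.DataFrame([("ghost", "E1", 1, "t", 1.0)],
                          columns=["accession_id", "env_id", "rep", "trait",
                                   "value"])
        with pytest.raises(DesignError):
            build_design(pt, grm, "t")
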