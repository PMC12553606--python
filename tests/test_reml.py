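"""REML engine: likelihood oracles, BLUPs, prediction, LRT, heritability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gxeblup as gx
from gxeblup.kernels import kernel_from_features
from gxeblup.reml import _ones_kernel


def _random_kernels(n, m, seed):
    rng = np.random.default_rng(seed)
    G = kernel_from_features(rng.normal(size=(n, 3 * n)),
                             [f"a{i}" for i in range(n)])
    E = kernel_from_features(rng.normal(size=(m, 2 * m)),
                             [f"e{j}" for j in range(m)], scale=True)
    return G, E


def _complete_index(G, E):
    return gx.make_index([a for a in G.labels for _ in E.labels],
                         [e for _ in G.labels for e in E.labels])


def _direct_loglik(y, X, V):
    """Independent dense evaluation of the restricted log-likelihood."""
    n, p = X.shape
    Vi = np.linalg.inv(V)
    M = X.T @ Vi @ X
    beta = np.linalg.solve(M, X.T @ Vi @ y)
    r = y - X @ beta
    return -0.5 * ((n - p) * np.log(2 * np.pi) + np.linalg.slogdet(V)[1]
                   + np.linalg.slogdet(M)[1] + r @ Vi @ r)


def _obs_covariance(terms, index, sigma):
    n = len(index)
    V = sigma[-1] * np.eye(n)
    for t, s in zip(terms, sigma[:-1]):
        V += s * gx.interaction_covariance(t.A, t.B, index)
    return V


class TestInteractionCovariance:
    def test_identity_env_kernel_blocks(self):
        G, E = _random_kernels(3, 2, 0)
        I_E = gx.Kernel(np.eye(2), E.labels)
        idx = _complete_index(G, I_E)
        K = gx.interaction_covariance(G, I_E, idx)
        # cross-environment entries vanish
        for o1 in range(len(idx)):
            for o2 in range(len(idx)):
                if idx["environment"][o1] != idx["environment"][o2]:
                    assert K[o1, o2] == 0.0

    def test_complete_design_equals_kronecker(self):
        G, E = _random_kernels(3, 2, 1)
        idx = _complete_index(G, E)
        K = gx.interaction_covariance(G, E, idx)
        np.testing.assert_allclose(K, np.kron(G.values, E.values), atol=1e-12)

    def test_unbalanced_design_equals_kronecker_with_rows_deleted(self):
        G, E = _random_kernels(3, 2, 2)
        idx = _complete_index(G, E).drop(index=4).reset_index(drop=True)
        K = gx.interaction_covariance(G, E, idx)
        full = np.kron(G.values, E.values)
        keep = [0, 1, 2, 3, 5]
        np.testing.assert_allclose(K, full[np.ix_(keep, keep)], atol=1e-12)

    def test_unknown_label_raises(self):
        G, E = _random_kernels(3, 2, 3)
        idx = gx.make_index(["a0", "zz"], ["e0", "e1"])
        with pytest.raises(KeyError):
            gx.interaction_covariance(G, E, idx)


class TestLikelihoodOracle:
    def test_engine_matches_direct_dense_formula_at_random_points(self):
        """Both the rotated and the dense code path reproduce the direct
        evaluation -(1/2)[log|V| + log|X'V^-1 X| + y'Py + c] at 50 random
        parameter points."""
        rng = np.random.default_rng(4)
        G, E = _random_kernels(5, 4, 4)
        idx = _complete_index(G, E)
        terms = gx.stage2_terms(G, E, model="M2")
        y = rng.normal(size=len(idx))
        X = np.ones((len(y), 1))
        idx_unbal = idx.drop(index=[3, 11]).reset_index(drop=True)
        y_unbal = np.delete(y, [3, 11])
        for _ in range(50):
            sigma = rng.uniform(0.05, 2.0, size=4)
            V = _obs_covariance(terms, idx, sigma)
            assert gx.restricted_loglik(y, idx, terms, sigma) == pytest.approx(
                _direct_loglik(y, X, V), abs=1e-8)
            V2 = _obs_covariance(terms, idx_unbal, sigma)
            assert gx.restricted_loglik(y_unbal, idx_unbal, terms, sigma) == \
                pytest.approx(_direct_loglik(y_unbal, np.ones((len(y_unbal), 1)), V2),
                              abs=1e-8)

    def test_rotated_and_dense_paths_agree(self):
        """Mixing in a DenseTerm forces the dense path; likelihood is identical."""
        rng = np.random.default_rng(5)
        G, E = _random_kernels(6, 3, 5)
        idx = _complete_index(G, E)
        y = rng.normal(size=len(idx))
        kron_terms = gx.stage2_terms(G, E, model="M2")
        dense_terms = [gx.DenseTerm(t.name, gx.interaction_covariance(t.A, t.B, idx))
                       for t in kron_terms]
        sigma = np.array([0.4, 0.3, 0.5, 0.6])
        ll_fast = gx.restricted_loglik(y, idx, kron_terms, sigma)
        ll_dense = gx.restricted_loglik(y, idx, dense_terms, sigma)
        assert ll_fast == pytest.approx(ll_dense, abs=1e-9)

    def test_optimum_beats_grid_search(self):
        """5 accessions x 6 environments: the optimizer's restricted likelihood
        is at least as high as an exhaustive component grid (step 0.01)."""
        rng = np.random.default_rng(6)
        G, E = _random_kernels(5, 6, 6)
        idx = _complete_index(G, E)
        terms = gx.stage2_terms(G, E, model="M1")
        sim = _obs_covariance(terms, idx, np.array([0.5, 0.3, 0.4]))
        y = np.linalg.cholesky(sim + 1e-10 * np.eye(len(idx))) @ rng.normal(size=len(idx))
        fit = gx.reml_fit(y, idx, terms, model="M1")
        center = np.array([max(fit.varcomp[k], 0.0)
                           for k in ("A", "Env", "residual")])
        best_grid = -np.inf
        for da in np.arange(-0.05, 0.051, 0.01):
            for de in np.arange(-0.05, 0.051, 0.01):
                for dr in np.arange(-0.05, 0.051, 0.01):
                    s = np.maximum(center + [da, de, dr], 1e-8)
                    best_grid = max(best_grid,
                                    gx.restricted_loglik(y, idx, terms, s))
        assert fit.loglik >= best_grid - 1e-4

    def test_pure_noise_shrinks_genetic_components(self):
        """Data with only residual variance: genetic and environmental
        component estimates collapse toward the floor (pooled median below
        5% of the residual)."""
        G, E = _random_kernels(25, 6, 7)
        idx = _complete_index(G, E)
        terms = gx.stage2_terms(G, E, model="M2")
        ratios = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            y = rng.normal(size=len(idx))
            fit = gx.reml_fit(y, idx, terms, model="M2")
            res = max(fit.varcomp["residual"], 1e-9)
            ratios += [fit.varcomp[k] / res for k in ("A", "Env", "AxEnv")]
        assert np.median(ratios) < 0.05


class TestBlups:
    def test_zero_variance_component_has_zero_blups(self):
        rng = np.random.default_rng(8)
        G, E = _random_kernels(8, 3, 8)
        idx = _complete_index(G, E)
        terms = gx.stage2_terms(G, E, model="M2")
        y = rng.normal(size=len(idx))
        fit = gx.reml_fit(y, idx, terms, model="M2",
                          init=np.array([0.5, 0.5, 0.0, 0.5]), optimize_vc=False)
        eff = gx.blup_effects(fit)
        np.testing.assert_allclose(eff["AxEnv"].to_numpy(), 0.0, atol=1e-14)

    def test_fitted_values_equal_sum_of_components(self, stage2_data, kernels):
        y, idx = stage2_data["y"], stage2_data["index"]
        terms = gx.stage2_terms(kernels["G_A"], kernels["E"], kernels["G_D"], "M3")
        fit = gx.reml_fit(y, idx[["accession", "environment"]], terms, model="M3")
        comp = fit.fitted_components()
        np.testing.assert_allclose(fit.fitted_values(),
                                   fit.X @ fit.beta + comp.sum(axis=1), atol=1e-10)

    def test_accession_blup_matches_conditional_mean_formula(self):
        """a_hat = sigma2 G Z' V^-1 (y - mu) on a tiny fixed-component fit."""
        rng = np.random.default_rng(9)
        G, E = _random_kernels(2, 3, 9)
        idx = _complete_index(G, E)
        terms = gx.stage2_terms(G, E, model="M1")
        y = rng.normal(size=6)
        sigma = np.array([0.7, 0.4, 0.5])
        fit = gx.reml_fit(y, idx, terms, init=sigma, optimize_vc=False, model="M1")
        V = _obs_covariance(terms, idx, sigma)
        Vi = np.linalg.inv(V)
        X = np.ones((6, 1))
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        Z = np.repeat(np.eye(2), 3, axis=0)
        expected = sigma[0] * G.values @ Z.T @ Vi @ (y - X @ beta)
        eff = gx.blup_effects(fit)
        np.testing.assert_allclose(eff["A"].to_numpy(), expected, atol=1e-10)


class TestPrediction:
    def test_matches_joint_gaussian_conditioning(self):
        """3 accessions x 2 environments, one held-out cell: prediction equals
        brute-force conditioning of the 6-dimensional Gaussian."""
        rng = np.random.default_rng(10)
        G, E = _random_kernels(3, 2, 10)
        full_idx = _complete_index(G, E)
        terms = gx.stage2_terms(G, E, model="M2")
        sigma = np.array([0.5, 0.3, 0.4, 0.2])
        V_full = _obs_covariance(terms, full_idx, sigma)
        y_full = rng.normal(size=6) * 0.8 + 0.3
        hold = 4
        obs = [i for i in range(6) if i != hold]
        fit = gx.reml_fit(y_full[obs], full_idx.iloc[obs], terms,
                          init=sigma, optimize_vc=False, model="M2")
        pred = gx.predict_cells(fit, full_idx.iloc[[hold]])
        mu = fit.mu
        # brute-force: mu + C V^-1 (y_obs - mu); C excludes the residual term
        C = (V_full - sigma[-1] * np.eye(6))[np.ix_([hold], obs)]
        expected = mu + C @ np.linalg.inv(V_full[np.ix_(obs, obs)]) @ (y_full[obs] - mu)
        assert pred["predicted"].iloc[0] == pytest.approx(expected[0], abs=1e-10)

    def test_unrelated_cell_predicts_the_intercept(self):
        rng = np.random.default_rng(11)
        G = gx.Kernel(np.diag([1.0, 1.0, 1.0]), ["a0", "a1", "anew"])
        E = kernel_from_features(rng.normal(size=(3, 5)), ["e0", "e1", "e2"],
                                 scale=True)
        idx = gx.make_index(["a0", "a0", "a1", "a1"], ["e0", "e1", "e0", "e1"])
        terms = gx.stage2_terms(G, E, model="M2")
        y = rng.normal(size=4) + 2.0
        fit = gx.reml_fit(y, idx, terms, init=np.array([0.5, 0.0, 0.5, 0.3]),
                          optimize_vc=False, model="M2")
        # accession with zero kinship to training, environment term off
        new = gx.make_index(["anew"], ["e2"])
        E.values[2, :2] = E.values[:2, 2] = 0.0
        pred = gx.predict_cells(fit, new)
        assert pred["predicted"].iloc[0] == pytest.approx(fit.mu, abs=1e-10)

    def test_leakage_guard(self, stage2_data, kernels):
        y, idx = stage2_data["y"], stage2_data["index"]
        terms = gx.stage2_terms(kernels["G_A"], kernels["E"], kernels["G_D"], "M2")
        fit = gx.reml_fit(y, idx[["accession", "environment"]], terms, model="M2")
        with pytest.raises(ValueError, match="overlap"):
            gx.predict_cells(fit, idx.iloc[[0]])

    def test_interpolation_limit_as_residual_vanishes(self):
        rng = np.random.default_rng(12)
        G, E = _random_kernels(4, 3, 12)
        idx = _complete_index(G, E)
        terms = gx.stage2_terms(G, E, model="M2")
        sim = _obs_covariance(terms, idx, np.array([0.5, 0.3, 0.4, 0.1]))
        y = np.linalg.cholesky(sim) @ rng.normal(size=len(idx))
        fit = gx.reml_fit(y, idx, terms, init=np.array([0.5, 0.3, 0.4, 1e-9]),
                          optimize_vc=False, model="M2")
        pred = gx.predict_cells(fit, idx.iloc[[5]], allow_overlap=True)
        assert pred["predicted"].iloc[0] == pytest.approx(y[5], abs=1e-5)


class TestLRTAndHeritability:
    def test_identical_fits_give_lr_zero_p_one(self, stage2_data, kernels):
        y, idx = stage2_data["y"], stage2_data["index"]
        t1 = gx.stage2_terms(kernels["G_A"], kernels["E"], model="M1")
        t2 = gx.stage2_terms(kernels["G_A"], kernels["E"], model="M2")
        f1 = gx.reml_fit(y, idx[["accession", "environment"]], t1, model="M1")
        f2 = gx.reml_fit(y, idx[["accession", "environment"]], t2, model="M2")
        f2_same = gx.ModelFit(**{**f2.__dict__, "loglik": f1.loglik,
                                 "terms": t2})
        res = gx.lrt(f1, f2_same)
        assert res.lr == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)
        res2 = gx.lrt(f1, f2)
        assert res2.lr >= -1e-4
        assert res2.df == 1
        with pytest.raises(ValueError, match="nested"):
            gx.lrt(f2, f1)

    def test_chi_square_tail_consistent_with_printed_table_pair(self):
        """The published pair (LR 9.2 at df 1, p 2.37e-3) is consistent at the
        table's printed precision: the LR implied by the printed p rounds to
        9.2, and chi2.sf over the LR's rounding interval brackets it."""
        assert round(float(stats.chi2.isf(2.37e-3, 1)), 1) == 9.2
        p_hi = float(stats.chi2.sf(9.15, 1))
        p_lo = float(stats.chi2.sf(9.25, 1))
        assert p_lo <= 2.37e-3 <= p_hi
        assert float(stats.chi2.sf(9.2, 1)) == pytest.approx(2.42e-3, rel=5e-3)

    @pytest.mark.parametrize("vc,expected", [
        ({"A": 1, "D": 0, "AxEnv": 0, "DxEnv": 0, "residual": 1}, 0.5),
        ({"A": 0, "D": 1, "AxEnv": 0, "DxEnv": 0, "residual": 1}, 0.0),
        ({"A": 0.34, "D": 0.15, "AxEnv": 0.18, "DxEnv": 0.18, "residual": 0.15},
         0.34),
    ])
    def test_heritability_arithmetic(self, vc, expected):
        assert gx.heritability(vc) == pytest.approx(expected)

    def test_heritability_excludes_environment_variance(self):
        vc = {"A": 1.0, "Env": 99.0, "residual": 1.0}
        assert gx.heritability(vc) == pytest.approx(0.5)

    def test_all_zero_components_rejected(self):
        with pytest.raises(ValueError):
            gx.heritability({"A": 0.0, "residual": 0.0})

    def test_scale_equivariance(self):
        """Scaling y by c scales every component by c^2 and leaves h2 fixed."""
        rng = np.random.default_rng(13)
        G, E = _random_kernels(10, 4, 13)
        idx = _complete_index(G, E)
        terms = gx.stage2_terms(G, E, model="M2")
        sim = _obs_covariance(terms, idx, np.array([0.5, 0.2, 0.4, 0.3]))
        y = np.linalg.cholesky(sim) @ rng.normal(size=len(idx))
        f1 = gx.reml_fit(y, idx, terms, model="M2")
        c = 3.7
        f2 = gx.reml_fit(c * y, idx, terms, model="M2")
        for k in f1.varcomp:
            assert f2.varcomp[k] == pytest.approx(c ** 2 * f1.varcomp[k],
                                                  rel=1e-3, abs=1e-8)
        assert gx.heritability(f2.varcomp) == pytest.approx(
            gx.heritability(f1.varcomp), abs=1e-5)


class TestParameterRecovery:
    def test_m3_recovers_variance_fractions_small_scale(self, kernels, small_design):
        """Reduced-size twin of the headline recovery study: mean estimated
        fractions over 6 seeds within +-0.08 of the generating fractions."""
        names = ("A", "Env", "AxEnv", "D", "DxEnv", "residual")
        true_vc = {"A": 0.35, "Env": 0.02, "AxEnv": 0.18, "D": 0.15,
                   "DxEnv": 0.17, "residual": 0.15}
        true_frac = np.array([true_vc[k] for k in names])
        terms = gx.stage2_terms(kernels["G_A"], kernels["E"], kernels["G_D"], "M3")
        errs = []
        for seed in range(6):
            y, idx, _ = gx.simulate_stage2(small_design, "TDM3",
                                           kernels["G_A"], kernels["E"],
                                           kernels["G_D"], varcomp=true_vc,
                                           seed=300 + seed)
            fit = gx.reml_fit(y, idx[["accession", "environment"]], terms,
                              model="M3")
            est = np.array([fit.varcomp[k] for k in names])
            errs.append(est / est.sum() - true_frac)
        assert np.abs(np.mean(errs, axis=0)).max() < 0.08
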