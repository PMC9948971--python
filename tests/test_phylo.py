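"""Phylogenetic covariance construction and weighted PGLS with Pagel's lambda.

The GLS fitter is checked against an independent dense matrix-inversion
oracle (explicit V^-1 via numpy.linalg.inv, no Cholesky whitening) and the
lambda profile likelihood against a from-first-principles multivariate-normal
density.
"""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from avican import phylo, synth
from avican.phylo import (
    PhyloCovariance,
    PhyloError,
    design_matrix,
    lambda_scale,
    ml_lambda,
    profile_loglik,
    vcv_from_tree,
    weighted_gls,
)


def dense_gls_oracle(y, X, V):
    """Textbook GLS via explicit inversion of V (independent code path)."""
    Vi = np.linalg.inv(V)
    XtVi = X.T @ Vi
    beta = np.linalg.solve(XtVi @ X, XtVi @ y)
    r = y - X @ beta
    n, p = X.shape
    sigma2 = (r @ Vi @ r) / (n - p)
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtVi @ X)))
    return beta, se, float(sigma2)


def dense_loglik_oracle(y, X, V):
    """MVN profile log-likelihood with ML sigma^2, via inv and slogdet."""
    Vi = np.linalg.inv(V)
    XtVi = X.T @ Vi
    beta = np.linalg.solve(XtVi @ X, XtVi @ y)
    r = y - X @ beta
    n = y.size
    s2 = (r @ Vi @ r) / n
    _, logdet = np.linalg.slogdet(V)
    return -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)


def random_instance(rng, n):
    nwk = synth.simulate_tree(n, seed=int(rng.integers(1 << 30)))
    vcv = vcv_from_tree(nwk)
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x])
    y = rng.normal(size=n) + 0.5 * x
    w = rng.uniform(0.3, 3.0, n)
    return y, X, vcv, w


class TestVCV:
    def test_cherry(self):
        C = vcv_from_tree("(A:1,B:1);", normalize=False)
        np.testing.assert_array_equal(C.matrix, np.eye(2))

    def test_three_taxon_path_arithmetic(self):
        C = vcv_from_tree("((A:1,B:1):1,Cc:2);", normalize=False)
        idx = {s: i for i, s in enumerate(C.species)}
        assert C.matrix[idx["A"], idx["B"]] == 1.0
        assert C.matrix[idx["A"], idx["Cc"]] == 0.0
        np.testing.assert_array_equal(np.diag(C.matrix), [2.0, 2.0, 2.0])

    def test_matches_brute_force_mrca_path_sums(self):
        import dendropy

        nwk = synth.simulate_tree(5, seed=17)
        C = vcv_from_tree(nwk, normalize=False)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = {}
        leaves = {(lf.taxon.label): lf for lf in tree.leaf_node_iter()}
        # brute force: depth of MRCA as root-to-tip minus half patristic distance
        dist = tree.phylogenetic_distance_matrix()
        for a in C.species:
            for b in C.species:
                ta, tb = leaves[a].taxon, leaves[b].taxon
                da = leaves[a].distance_from_root()
                db = leaves[b].distance_from_root()
                pdm[(a, b)] = 0.5 * (da + db - dist.patristic_distance(ta, tb))
        for i, a in enumerate(C.species):
            for j, b in enumerate(C.species):
                assert C.matrix[i, j] == pytest.approx(pdm[(a, b)], abs=1e-12)

    def test_pruning_and_missing_tip(self):
        nwk = "((A:1,B:1):1,(Cc:1.5,D:1.5):0.5);"
        C = vcv_from_tree(nwk, tips=["D", "A"], normalize=False)
        assert C.species == ["D", "A"]
        assert C.matrix[0, 1] == 0.0
        with pytest.raises(PhyloError, match="absent"):
            vcv_from_tree(nwk, tips=["A", "Zz"])

    def test_name_normalization_for_tips(self):
        C = vcv_from_tree("(Anas_alpha:1,Anas_beta:1);",
                          tips=["Anas alpha", "Anas beta"])
        assert C.species == ["Anas alpha", "Anas beta"]

    def test_topology_only_tree_gets_unit_lengths(self):
        C = vcv_from_tree("((A,B),Cc);", normalize=False)
        idx = {s: i for i, s in enumerate(C.species)}
        assert C.matrix[idx["A"], idx["A"]] == 2.0
        assert C.matrix[idx["A"], idx["B"]] == 1.0

    def test_unit_depth_normalization(self):
        C = vcv_from_tree("((A:2,B:2):2,Cc:4);")
        assert np.diag(C.matrix) == pytest.approx([1.0, 1.0, 1.0])


class TestLambdaScale:
    def test_endpoints_and_arithmetic(self):
        C = PhyloCovariance(["a", "b"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        np.testing.assert_array_equal(lambda_scale(C, 1.0).matrix, C.matrix)
        np.testing.assert_array_equal(lambda_scale(C, 0.0).matrix, np.eye(2))
        assert lambda_scale(C, 0.5).matrix[0, 1] == 0.25

    def test_out_of_range_rejected(self):
        C = PhyloCovariance(["a", "b"], np.eye(2))
        for lam in (-0.1, 1.1):
            with pytest.raises(PhyloError):
                lambda_scale(C, lam)


class TestWeightedGLS:
    def test_matches_dense_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            n = int(rng.integers(6, 13))
            y, X, vcv, w = random_instance(rng, n)
            lam = float(rng.uniform(0.1, 1.0))
            fit = weighted_gls(y, X, vcv, weights=w, lam=lam)
            V = lambda_scale(vcv, lam).matrix * np.outer(w, w)
            beta, se, s2 = dense_gls_oracle(y, X, V)
            np.testing.assert_allclose(fit.coefficients, beta, atol=1e-10)
            np.testing.assert_allclose(fit.std_errors, se, atol=1e-10)
            assert fit.sigma2_hat == pytest.approx(s2, abs=1e-10)

    def test_star_tree_unit_weights_reproduces_ols_exactly(self):
        rng = np.random.default_rng(8)
        n = 30
        x = rng.normal(size=n)
        y = 1.0 + 0.3 * x + rng.normal(size=n)
        C = PhyloCovariance([f"t{i}" for i in range(n)], np.eye(n))
        fit = weighted_gls(y, np.column_stack([np.ones(n), x]), C, lam=0.0)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        np.testing.assert_allclose(fit.coefficients, ols.params, rtol=1e-12)
        np.testing.assert_allclose(fit.std_errors, ols.bse, rtol=1e-12)
        np.testing.assert_allclose(fit.t_values, ols.tvalues, rtol=1e-12)
        np.testing.assert_allclose(fit.p_values, ols.pvalues, rtol=1e-10)
        assert fit.f_statistic == pytest.approx(ols.fvalue, rel=1e-12)
        assert fit.r_squared == pytest.approx(ols.rsquared, rel=1e-12)
        assert fit.df_den == int(ols.df_resid)

    def test_perfect_fit_has_zero_residual_r2_one(self):
        nwk = synth.simulate_tree(12, seed=9)
        vcv = vcv_from_tree(nwk)
        x = np.arange(12.0)
        y = 2.0 - 0.5 * x
        fit = weighted_gls(y, np.column_stack([np.ones(12), x]), vcv, lam=0.8)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.association_signs == ["-"]

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(10)
        y, X, vcv, w = random_instance(rng, 20)
        f1 = weighted_gls(y, X, vcv, weights=w, lam=0.6)
        f2 = weighted_gls(y, X, vcv, weights=7.3 * w, lam=0.6)
        np.testing.assert_allclose(f1.coefficients, f2.coefficients, rtol=1e-10)
        np.testing.assert_allclose(f1.t_values, f2.t_values, rtol=1e-10)
        np.testing.assert_allclose(f1.p_values, f2.p_values, rtol=1e-10)
        assert f1.r_squared == pytest.approx(f2.r_squared, rel=1e-10)

    def test_singular_design_raises(self):
        nwk = synth.simulate_tree(10, seed=11)
        vcv = vcv_from_tree(nwk)
        x = np.ones(10)  # duplicates the intercept
        X = np.column_stack([np.ones(10), x])
        with pytest.raises(PhyloError, match="singular"):
            weighted_gls(np.arange(10.0), X, vcv, lam=0.5)


class TestMLLambda:
    def test_profile_likelihood_matches_oracle_on_grid(self):
        rng = np.random.default_rng(77)
        for _ in range(5):
            n = int(rng.integers(6, 13))
            y, X, vcv, w = random_instance(rng, n)
            for lam in np.linspace(1e-6, 1.0, 11):
                V = lambda_scale(vcv, lam).matrix * np.outer(w, w)
                assert profile_loglik(y, X, vcv, w, lam) == pytest.approx(
                    dense_loglik_oracle(y, X, V), abs=1e-8)

    def test_brownian_traits_recover_high_lambda(self):
        nwk = synth.simulate_tree(200, seed=13)
        vcv = vcv_from_tree(nwk)
        tr = synth.simulate_traits(vcv, lambda_true=1.0, sigma2=1.0, seed=14,
                                   n_traits=2)
        y = tr["trait_0"].to_numpy()
        X = np.column_stack([np.ones(200), tr["trait_1"].to_numpy()])
        fit = ml_lambda(y, X, vcv)
        assert fit.lambda_hat >= 0.9

    def test_iid_noise_recovers_lower_bound(self):
        nwk = synth.simulate_tree(150, seed=15)
        vcv = vcv_from_tree(nwk)
        rng = np.random.default_rng(16)
        y = rng.normal(size=150)
        X = np.column_stack([np.ones(150), rng.normal(size=150)])
        fit = ml_lambda(y, X, vcv, tol=1e-6)
        assert fit.lambda_hat <= 1e-6 + 10e-6

    def test_optimum_matches_fine_grid_scan(self):
        rng = np.random.default_rng(21)
        nwk = synth.simulate_tree(40, seed=22)
        vcv = vcv_from_tree(nwk)
        tr = synth.simulate_traits(vcv, lambda_true=0.6, sigma2=1.0, seed=23)
        y = tr["trait_0"].to_numpy()
        X = np.column_stack([np.ones(40), rng.normal(size=40)])
        fit = ml_lambda(y, X, vcv)
        grid = np.linspace(1e-6, 1.0, 1001)
        lls = [profile_loglik(y, X, vcv, None, g) for g in grid]
        lam_grid = grid[int(np.argmax(lls))]
        assert abs(fit.lambda_hat - lam_grid) <= (grid[1] - grid[0]) + 1e-6

    def test_parameter_recovery_slope_and_lambda(self):
        # 200 replicate datasets on one 100-tip tree, known slope, lambda 0.5
        nwk = synth.simulate_tree(100, seed=31)
        vcv = vcv_from_tree(nwk)
        b_true = 0.75
        slopes, lams = [], []
        for rep in range(200):
            sim = synth.simulate_linear_gaussian(
                vcv, beta=[0.0, b_true], lambda_true=0.5, sigma2=0.5,
                seed=1000 + rep)
            X = np.column_stack([np.ones(100), sim["x"]])
            fit = ml_lambda(sim["y"], X, vcv)
            slopes.append(fit.coefficients[1])
            lams.append(fit.lambda_hat)
        assert np.mean(slopes) == pytest.approx(b_true, rel=0.05)
        assert 0.35 <= np.mean(lams) <= 0.65


def test_design_matrix_shapes():
    import pandas as pd

    df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
    X = design_matrix(df, ["b", "a"])
    np.testing.assert_array_equal(X, [[1, 3, 1], [1, 4, 2]])
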