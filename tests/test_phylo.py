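"""Tree handling, covariance, λ transform, PGLS and Brownian simulation tests."""

import numpy as np
import pandas as pd
import pytest

from aposignal import phylo as P
from aposignal.errors import (
    CovarianceError,
    InvalidArgumentError,
    NewickParseError,
    TreeMismatchError,
)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

class TestNewickIO:
    def test_two_tip_parse(self):
        t = P.read_newick("(A:0.5,B:0.5);")
        assert sorted(P.tip_labels(t)) == ["A", "B"]
        lengths = [lf.edge.length for lf in t.leaf_node_iter()]
        assert lengths == [0.5, 0.5]

    def test_round_trip_preserves_structure(self):
        tree = P.simulate_tree(14, seed=3)
        text = P.write_newick(tree)
        back = P.read_newick(text)
        C1 = P.phylo_covariance(tree, taxa=sorted(P.tip_labels(tree))).matrix
        C2 = P.phylo_covariance(back, taxa=sorted(P.tip_labels(back))).matrix
        assert sorted(P.tip_labels(back)) == sorted(P.tip_labels(tree))
        np.testing.assert_allclose(C1, C2, atol=1e-9)

    def test_support_values_preserved(self):
        text = "((A:1,B:1)90:1,C:2);"
        out = P.write_newick(P.read_newick(text))
        assert "90" in out

    def test_malformed_raises(self):
        with pytest.raises(NewickParseError):
            P.read_newick("((A:1,B:1;")


# ---------------------------------------------------------------------------
# Support collapsing
# ---------------------------------------------------------------------------

def root_to_tip_distances(tree):
    d = {}
    for leaf in tree.leaf_node_iter():
        total, nd = 0.0, leaf
        while nd.parent_node is not None:
            total += nd.edge.length or 0.0
            nd = nd.parent_node
        d[leaf.taxon.label] = total
    return d


class TestCollapseLowSupport:
    def test_high_support_untouched(self):
        t = P.read_newick("((A:1,B:1)90:1,C:2);")
        out = P.collapse_low_support(t, threshold=70)
        assert P.write_newick(out) == P.write_newick(t)

    def test_single_collapse_preserves_path_lengths(self):
        t = P.read_newick("((A:1,B:1)60:1,C:2);")
        out = P.collapse_low_support(t, threshold=70)
        assert root_to_tip_distances(out) == {"A": 2.0, "B": 2.0, "C": 2.0}
        root = out.seed_node
        assert len(root.child_nodes()) == 3  # polytomy

    def test_cascade_collapses_to_single_polytomy(self):
        t = P.read_newick("(((A:1,B:1)50:1,C:2)60:1,(D:1,E:1)95:2);")
        out = P.collapse_low_support(t, threshold=70)
        assert sorted(P.tip_labels(out)) == list("ABCDE")
        want = root_to_tip_distances(t)
        assert root_to_tip_distances(out) == want
        # A, B, C and the supported (D,E) clade all hang off the root now
        assert len(out.seed_node.child_nodes()) == 4

    def test_unsupported_nodes_are_kept(self):
        t = P.read_newick("((A:1,B:1):1,C:2);")  # no support label
        out = P.collapse_low_support(t, threshold=70)
        assert len(out.seed_node.child_nodes()) == 2

    def test_random_trees_preserve_tips_and_paths(self):
        rng = np.random.default_rng(4)
        for rep in range(25):
            tree = P.simulate_tree(10, seed=600 + rep)
            for nd in tree.preorder_node_iter():
                if nd.parent_node is not None and not nd.is_leaf():
                    nd.label = str(int(rng.integers(0, 101)))
            before = root_to_tip_distances(tree)
            out = P.collapse_low_support(tree, threshold=70)
            after = root_to_tip_distances(out)
            assert sorted(after) == sorted(before)
            for k in before:
                assert after[k] == pytest.approx(before[k], abs=1e-12)


# ---------------------------------------------------------------------------
# Covariance and λ transform
# ---------------------------------------------------------------------------

class TestPhyloCovariance:
    def test_two_tip_diagonal(self):
        C = P.phylo_covariance(P.read_newick("(A:0.5,B:0.5);"))
        np.testing.assert_allclose(C.matrix, np.diag([0.5, 0.5]))

    def test_balanced_four_tip(self, balanced4_tree):
        C = P.phylo_covariance(balanced4_tree, taxa=list("ABCD")).matrix
        assert C[0, 1] == 1.0  # sisters share the internal branch
        assert C[0, 2] == 0.0  # across the root
        assert np.all(np.diag(C) == 2.0)

    def test_matches_brute_force_mrca_enumeration(self):
        tree = P.simulate_tree(10, seed=11)
        labels = P.tip_labels(tree)
        C = P.phylo_covariance(tree, taxa=labels).matrix
        # independent oracle: patristic distances give C(i,j) on ultrametric
        # trees via depth - d(i,j)/2
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        depth = {lab: C[i, i] for i, lab in enumerate(labels)}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i == j:
                    continue
                d = pdm.patristic_distance(taxa[a], taxa[b])
                want = (depth[a] + depth[b] - d) / 2.0
                assert C[i, j] == pytest.approx(want, abs=1e-9)

    def test_missing_species_listed(self, balanced4_tree):
        with pytest.raises(TreeMismatchError) as err:
            P.phylo_covariance(balanced4_tree, taxa=["A", "B", "X", "Y"])
        assert err.value.missing == ["X", "Y"]


class TestLambdaTransform:
    def test_identity_at_one(self, balanced4_tree):
        C = P.phylo_covariance(balanced4_tree)
        np.testing.assert_array_equal(P.lambda_transform(C, 1.0).matrix, C.matrix)

    def test_diagonal_at_zero(self, balanced4_tree):
        C = P.phylo_covariance(balanced4_tree)
        out = P.lambda_transform(C, 0.0).matrix
        np.testing.assert_array_equal(out, np.diag(np.diag(C.matrix)))

    def test_half_lambda_halves_off_diagonals(self, balanced4_tree):
        C = P.phylo_covariance(balanced4_tree, taxa=list("ABCD"))
        out = P.lambda_transform(C, 0.5).matrix
        assert out[0, 1] == 0.5
        assert out[0, 0] == 2.0

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_out_of_range_rejected(self, balanced4_tree, bad):
        C = P.phylo_covariance(balanced4_tree)
        with pytest.raises(InvalidArgumentError):
            P.lambda_transform(C, bad)


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

def explicit_gls_oracle(C, X, y):
    """Brute-force GLS by explicit matrix inversion (independent of pgls_fit)."""
    Vi = np.linalg.inv(C)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    r = y - X @ beta
    n = len(y)
    sigma2 = float(r @ Vi @ r) / n
    sign, logdet = np.linalg.slogdet(C)
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return beta, sigma2, loglik


class TestPGLS:
    def test_worked_fixture_matches_explicit_inversion(self, worked_gls_fixture):
        tree, y, x = worked_gls_fixture
        fit = P.pgls_fit(y, x, tree=tree, mode="fixed", lam=1.0)
        C = P.phylo_covariance(tree, taxa=list(y.index)).matrix
        X = np.column_stack([np.ones(4), x.to_numpy()])
        beta, sigma2, loglik = explicit_gls_oracle(C, X, y.to_numpy())
        np.testing.assert_allclose(fit.coef.to_numpy(), beta, atol=1e-9)
        assert fit.sigma2 == pytest.approx(sigma2, abs=1e-9)
        assert fit.loglik == pytest.approx(loglik, abs=1e-9)

    def test_star_tree_equals_ols(self):
        tree = P.read_newick("(A:1,B:1,C:1,D:1,E:1,F:1);")
        rng = np.random.default_rng(0)
        y = pd.Series(rng.normal(size=6), index=list("ABCDEF"))
        x = pd.Series(rng.normal(size=6), index=list("ABCDEF"), name="x")
        import statsmodels.api as sm

        ols = sm.OLS(y.to_numpy(), sm.add_constant(x.to_numpy())).fit()
        for lam in (0.0, 0.37, 1.0):
            fit = P.pgls_fit(y, x, tree=tree, mode="fixed", lam=lam)
            np.testing.assert_allclose(fit.coef.to_numpy(), ols.params, atol=1e-10)

    def test_lambda_zero_is_weighted_ls_on_nonultrametric_trees(self):
        # equal root-to-tip depths -> plain OLS at λ=0
        tree = P.read_newick("((A:1.5,B:1.5):0.5,(C:1,D:1):1);")
        rng = np.random.default_rng(1)
        y = pd.Series(rng.normal(size=4), index=list("ABCD"))
        x = pd.Series(rng.normal(size=4), index=list("ABCD"), name="x")
        import statsmodels.api as sm

        fit = P.pgls_fit(y, x, tree=tree, mode="fixed", lam=0.0)
        ols = sm.OLS(y.to_numpy(), sm.add_constant(x.to_numpy())).fit()
        np.testing.assert_allclose(fit.coef.to_numpy(), ols.params, atol=1e-10)
        # unequal depths -> weights 1/C_ii
        tree2 = P.read_newick("((A:2,B:1):0.5,(C:1,D:0.25):1);")
        fit2 = P.pgls_fit(y, x, tree=tree2, mode="fixed", lam=0.0)
        C2 = P.phylo_covariance(tree2, taxa=list("ABCD")).matrix
        w = 1.0 / np.diag(C2)
        wls = sm.WLS(y.to_numpy(), sm.add_constant(x.to_numpy()), weights=w).fit()
        np.testing.assert_allclose(fit2.coef.to_numpy(), wls.params, atol=1e-10)

    def test_ml_loglik_dominates_endpoints(self):
        for rep in range(5):
            tree = P.simulate_tree(20, seed=40 + rep)
            y = P.simulate_bm(tree, sigma2=1.0, lam=0.6, seed=rep)
            fit = P.pgls_fit(y, pd.DataFrame(index=y.index), tree=tree, mode="ml")
            for lam in (0.0, 1.0):
                other = P.pgls_fit(y, pd.DataFrame(index=y.index), tree=tree, mode="fixed", lam=lam)
                assert fit.loglik >= other.loglik - 1e-8

    def test_profile_grid_agrees_with_optimizer(self):
        tree = P.simulate_tree(30, seed=77)
        y = P.simulate_bm(tree, sigma2=1.0, lam=0.5, seed=5)
        fit = P.pgls_fit(y, pd.DataFrame(index=y.index), tree=tree, mode="ml")
        C = P.phylo_covariance(tree, taxa=list(y.index)).matrix
        X = np.ones((len(y), 1))
        grid = np.linspace(0, 1, 101)
        lls = [explicit_gls_oracle(P.lambda_transform(C, g), X, y.to_numpy())[2] for g in grid]
        assert abs(grid[int(np.argmax(lls))] - fit.lam) <= 0.02

    def test_f_pvalues_uniform_under_null(self):
        """F test at fixed λ=1 with Brownian truth: p ~ Uniform(0,1)."""
        from scipy import stats

        tree = P.simulate_tree(12, seed=9)
        C = P.phylo_covariance(tree)
        L = np.linalg.cholesky(C.matrix)
        labels = list(C.labels)
        rng = np.random.default_rng(10)
        ps = []
        for _ in range(1000):
            y = pd.Series(L @ rng.standard_normal(12), index=labels)
            x = pd.Series(L @ rng.standard_normal(12), index=labels, name="x")
            fit = P.pgls_fit(y, x, C=C, mode="fixed", lam=1.0)
            ps.append(P.pgls_ftest(fit, "x")[3])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_rank_deficiency_raises(self, worked_gls_fixture):
        tree, y, x = worked_gls_fixture
        X = pd.DataFrame({"x": x, "x2": x})
        with pytest.raises(P.RankDeficiencyError):
            P.pgls_fit(y, X, tree=tree, mode="fixed", lam=1.0)


class TestSimulateBM:
    def test_deterministic_per_seed(self, balanced4_tree):
        a = P.simulate_bm(balanced4_tree, sigma2=1.0, lam=1.0, seed=3)
        b = P.simulate_bm(balanced4_tree, sigma2=1.0, lam=1.0, seed=3)
        pd.testing.assert_series_equal(a, b)

    def test_tiny_variance_collapses_to_mean(self, balanced4_tree):
        vals = P.simulate_bm(balanced4_tree, sigma2=1e-18, lam=1.0, mu=2.5, seed=0)
        np.testing.assert_allclose(vals.to_numpy(), 2.5, atol=1e-6)

    def test_empirical_covariance_matches_closed_form(self, balanced4_tree):
        """MC tip covariance over 2,000 replicates ≈ σ²·C_λ within 3 MC SE."""
        sigma2, lam, n_rep = 0.8, 1.0, 2000
        draws = np.stack(
            [
                P.simulate_bm(balanced4_tree, sigma2=sigma2, lam=lam, seed=1000 + i).to_numpy()
                for i in range(n_rep)
            ]
        )
        emp = np.cov(draws, rowvar=False)
        want = sigma2 * P.phylo_covariance(balanced4_tree, taxa=list("ABCD")).matrix
        # SE of a covariance entry ≈ sqrt((Cii*Cjj + Cij²)/n)
        for i in range(4):
            for j in range(4):
                se = np.sqrt((want[i, i] * want[j, j] + want[i, j] ** 2) / n_rep)
                assert abs(emp[i, j] - want[i, j]) < 3 * se


class TestSimulateTree:
    def test_two_tips_join_at_root_with_unit_depth(self):
        t = P.simulate_tree(2, seed=0)
        C = P.phylo_covariance(t).matrix
        np.testing.assert_allclose(np.diag(C), 1.0)
        assert C[0, 1] == 0.0
        lens = [lf.edge.length for lf in t.leaf_node_iter()]
        assert lens[0] == pytest.approx(lens[1])

    def test_determinism(self):
        assert P.write_newick(P.simulate_tree(12, seed=1)) == P.write_newick(
            P.simulate_tree(12, seed=1)
        )

    def test_covariance_positive_definite(self):
        C = P.phylo_covariance(P.simulate_tree(12, seed=1)).matrix
        np.linalg.cholesky(C)  # raises if not PD

    def test_rejects_single_species(self):
        with pytest.raises(InvalidArgumentError):
            P.simulate_tree(1, seed=0)

    def test_tips_named_and_ultrametric(self):
        t = P.simulate_tree(9, seed=5)
        labs = P.tip_labels(t)
        assert sorted(labs) == [f"sp{i:02d}" for i in range(1, 10)]
        depths = np.diag(P.phylo_covariance(t).matrix)
        np.testing.assert_allclose(depths, 1.0, atol=1e-12)
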