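"""Discriminant analysis, MANOVA, pairwise tests, Duncan and clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from _oracles import duncan_oracle

from berrymorph import mvstats


@pytest.fixture(scope="module")
def three_groups(rng=None):
    """Three bivariate normal groups with distinct means, n = 30 each."""
    rng = np.random.default_rng(99)
    means = [(0.0, 0.0), (3.0, 1.0), (1.0, 4.0)]
    X = np.vstack([rng.normal(mu, 1.0, size=(30, 2)) for mu in means])
    g = np.repeat(["A", "B", "C"], 30)
    return X, g


class TestEigenvalueIdentities:
    def test_wilks_product_identity(self, three_groups):
        X, g = three_groups
        fit = mvstats.cda_fit(X, g)
        lam = fit.eigenvalues
        L = mvstats.wilks_lambda(lam)
        assert L * np.prod(1.0 + lam) == pytest.approx(1.0, abs=1e-12)

    def test_pillai_two_ways(self, three_groups):
        X, g = three_groups
        fit = mvstats.cda_fit(X, g)
        v1 = mvstats.pillai_trace(fit.eigenvalues)
        v2 = float((fit.canonical_correlations**2).sum())
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_random_fits_identities(self, rng):
        for _ in range(5):
            X = rng.normal(size=(60, 4))
            g = rng.choice(list("abcd"), size=60)
            fit = mvstats.cda_fit(X, g)
            lam = fit.eigenvalues
            assert mvstats.wilks_lambda(lam) * np.prod(1 + lam) == pytest.approx(
                1.0, abs=1e-12
            )
            assert mvstats.pillai_trace(lam) == pytest.approx(
                float((mvstats.canonical_correlations(lam) ** 2).sum()), abs=1e-12
            )


class TestCDA:
    def test_eigenvalue_vs_grid_search_oracle(self):
        # 2-group 2-variable toy set: the single discriminant eigenvalue
        # equals a brute-force Rayleigh-quotient maximization over angles
        X = np.array(
            [[0.0, 0.0], [1.0, 0.5], [0.5, 1.2], [3.0, 2.0], [3.5, 3.1], [2.8, 2.4]]
        )
        g = ["a", "a", "a", "b", "b", "b"]
        fit = mvstats.cda_fit(X, g)
        W, B, *_ = mvstats._scatter_matrices(pd.DataFrame(X, columns=["x", "y"]),
                                             pd.Series(g))
        best = 0.0
        for th in np.linspace(0, np.pi, 200_001):
            v = np.array([np.cos(th), np.sin(th)])
            best = max(best, (v @ B @ v) / (v @ W @ v))
        assert fit.eigenvalues[0] == pytest.approx(best, rel=1e-6)
        assert len(fit.eigenvalues) == 1  # min(p, g-1)

    def test_identical_groups_no_separation(self, rng):
        base = rng.normal(size=(40, 3))
        X = np.vstack([base, base])
        g = ["a"] * 40 + ["b"] * 40
        fit = mvstats.cda_fit(X, g)
        assert fit.eigenvalues.max() < 1e-12
        # classification indistinguishable from chance for coincident groups
        assert fit.confusion.to_numpy().sum() == pytest.approx(200.0)

    def test_structure_and_scores_shapes(self, three_groups):
        X, g = three_groups
        fit = mvstats.cda_fit(X, g, variables=["u", "v"])
        assert fit.structure.shape == (2, 2)
        assert fit.scores.shape == (90, 2)
        assert np.all(np.abs(fit.structure.to_numpy()) <= 1.0 + 1e-9)
        # percent variance sums to 100, eigenvalues nonincreasing
        assert fit.percent_variance.sum() == pytest.approx(100.0)
        assert np.all(np.diff(fit.eigenvalues) <= 0)
        # unit pooled within-group variance of scores
        centered = fit.scores - fit.centroids.loc[list(g)].to_numpy()
        sw = (centered**2).sum(axis=0) / (len(X) - 3)
        np.testing.assert_allclose(sw, 1.0, atol=1e-10)

    def test_singular_covariance_names_columns(self, rng):
        X = rng.normal(size=(30, 2))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])  # exact collinearity
        g = rng.choice(["a", "b"], size=30)
        with pytest.raises(ValueError, match="singular"):
            mvstats.cda_fit(X, g, variables=["p", "q", "r"])

    def test_canonical_correlation_formula(self):
        # lambda = 11.302 -> r = sqrt(lambda / (1 + lambda)) = 0.958
        r = mvstats.canonical_correlations([11.302])[0]
        assert r == pytest.approx(np.sqrt(11.302 / 12.302), abs=1e-12)


class TestManova:
    def test_printed_df_structure(self, rng):
        # 10 variables, 10 groups, N = 400 -> hypothesis df 90;
        # 2 variables -> 18
        X = rng.normal(size=(400, 10))
        g = np.repeat([f"g{i}" for i in range(10)], 40)
        m = mvstats.manova(X, g)
        assert m.df_hypothesis == 90
        assert m.df_error_wilks == pytest.approx(2594.33, abs=0.01)
        assert m.df_error_pillai == 3501
        m2 = mvstats.manova(X[:, :2], g)
        assert m2.df_hypothesis == 18
        assert m2.df_error_wilks == pytest.approx(778.0)
        assert m2.df_error_pillai == 780

    def test_single_group_degenerate(self, rng):
        X = rng.normal(size=(20, 3))
        m = mvstats.manova(X, ["only"] * 20)
        assert m.wilks_lambda == 1.0 and m.pillai_trace == 0.0

    def test_detects_separation(self, three_groups):
        X, g = three_groups
        m = mvstats.manova(X, g)
        assert 0 < m.wilks_lambda < 0.5
        assert m.p_wilks < 1e-6 and m.p_pillai < 1e-6


class TestHotellingPairwise:
    def test_identical_groups(self, rng):
        base = rng.normal(size=(20, 2))
        X = np.vstack([base, base])
        g = ["a"] * 20 + ["b"] * 20
        pw = mvstats.hotelling_pairwise(X, g)
        assert pw.d2.loc["a", "b"] == pytest.approx(0.0, abs=1e-20)
        assert pw.p_corrected.loc["a", "b"] == 1.0

    def test_univariate_closed_form(self, rng):
        x1 = rng.normal(0, 1, size=25)
        x2 = rng.normal(2, 1, size=30)
        X = np.concatenate([x1, x2])[:, None]
        g = ["a"] * 25 + ["b"] * 30
        pw = mvstats.hotelling_pairwise(X, g)
        sp2 = ((len(x1) - 1) * x1.var(ddof=1) + (len(x2) - 1) * x2.var(ddof=1)) / (
            len(x1) + len(x2) - 2
        )
        want = (x1.mean() - x2.mean()) ** 2 / sp2
        assert pw.d2.loc["a", "b"] == pytest.approx(want, rel=1e-12)
        # equivalent to the two-sample t test in one dimension
        t, p = sstats.ttest_ind(x1, x2)
        assert pw.f.loc["a", "b"] == pytest.approx(t**2, rel=1e-10)
        assert pw.p_raw.loc["a", "b"] == pytest.approx(p, rel=1e-9)

    def test_matrix_vs_bruteforce_oracle(self, three_groups):
        X, g = three_groups
        pw = mvstats.hotelling_pairwise(X, g)
        names = ["A", "B", "C"]
        for i in range(3):
            for j in range(i + 1, 3):
                Xi, Xj = X[np.array(g) == names[i]], X[np.array(g) == names[j]]
                S = (
                    np.cov(Xi.T) * (len(Xi) - 1) + np.cov(Xj.T) * (len(Xj) - 1)
                ) / (len(Xi) + len(Xj) - 2)
                diff = Xi.mean(0) - Xj.mean(0)
                want = diff @ np.linalg.inv(S) @ diff
                assert pw.d2.iloc[i, j] == pytest.approx(want, abs=1e-10)
        # symmetry, zero diagonal, Bonferroni multiplier = 3 pairs
        np.testing.assert_allclose(pw.d2.to_numpy(), pw.d2.to_numpy().T)
        assert np.all(np.diag(pw.d2.to_numpy()) == 0)
        off = ~np.eye(3, dtype=bool)
        expect = np.minimum(1.0, pw.p_raw.to_numpy()[off] * 3)
        np.testing.assert_allclose(pw.p_corrected.to_numpy()[off], expect)

    def test_affine_invariance_of_d2(self, three_groups, rng):
        X, g = three_groups
        A = rng.normal(size=(2, 2)) + 2 * np.eye(2)
        Y = X @ A.T + [5.0, -3.0]
        d_x = mvstats.hotelling_pairwise(X, g).d2
        d_y = mvstats.hotelling_pairwise(Y, g).d2
        np.testing.assert_allclose(d_x.to_numpy(), d_y.to_numpy(), atol=1e-8)

    def test_small_group_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        g = ["a", "a", "a", "b", "b"]  # n_b = 2 <= p = 3
        with pytest.raises(ValueError, match="undefined"):
            mvstats.hotelling_pairwise(X, g)


class TestDuncan:
    def test_far_apart_groups_distinct(self, rng):
        y = np.concatenate([rng.normal(0, 1, 40), rng.normal(100, 1, 40)])
        g = ["lo"] * 40 + ["hi"] * 40
        res = mvstats.anova_duncan(y, g)
        assert res.letters["lo"] != res.letters["hi"]
        assert res.p_value < 1e-10

    def test_identical_groups_share_letter(self, rng):
        base = rng.normal(size=30)
        y = np.concatenate([base, base, base])
        g = np.repeat(["a", "b", "c"], 30)
        res = mvstats.anova_duncan(y, g)
        assert len({v for v in res.letters.values()}) == 1

    @pytest.mark.parametrize("shift", [0.0, 0.35, 0.8, 3.0])
    def test_letters_match_range_test_oracle(self, shift, rng):
        # three groups with an intermediate mean; letters must encode the
        # same 'differ' relation as the brute-force all-pairs range test
        y = np.concatenate(
            [
                rng.normal(0.0, 1.0, 25),
                rng.normal(shift, 1.0, 25),
                rng.normal(2 * shift, 1.0, 25),
            ]
        )
        g = np.repeat(["g1", "g2", "g3"], 25)
        res = mvstats.anova_duncan(y, g, alpha=0.05)
        oracle = duncan_oracle(y, g, 0.05)
        for a in oracle.index:
            for b in oracle.columns:
                if a == b:
                    continue
                shares = bool(set(res.letters[a]) & set(res.letters[b]))
                assert shares != oracle.loc[a, b], (
                    f"{a} vs {b}: letters {res.letters[a]}/{res.letters[b]}, "
                    f"oracle differ={oracle.loc[a, b]}"
                )

    def test_zero_variance_distinct_means(self):
        y = [1.0, 1.0, 2.0, 2.0, 3.0, 3.0]
        g = ["a", "a", "b", "b", "c", "c"]
        res = mvstats.anova_duncan(y, g)
        assert np.isinf(res.f_statistic)
        assert len({v for v in res.letters.values()}) == 3


class TestClassification:
    def test_well_separated_is_perfect(self, rng):
        means = [(0, 0), (20, 0), (0, 20)]  # gaps >> pooled SD
        X = np.vstack([rng.normal(mu, 1.0, size=(20, 2)) for mu in means])
        g = np.repeat(list("abc"), 20)
        fit = mvstats.cda_fit(X, g)
        assert fit.percent_correct == 100.0
        np.testing.assert_allclose(np.diag(fit.confusion.to_numpy()), 100.0)

    def test_shuffled_labels_near_chance(self, rng):
        X = np.vstack(
            [rng.normal(mu, 1.0, size=(50, 2)) for mu in [(0, 0), (8, 0), (0, 8), (8, 8)]]
        )
        g = rng.permutation(np.repeat(list("abcd"), 50))
        fit = mvstats.cda_fit(X, g)
        # permutation baseline: ~100/g percent with binomial spread
        p0 = 100.0 / 4
        se = 100 * np.sqrt(0.25 * 0.75 / 200)
        assert abs(fit.percent_correct - p0) < 4 * se

    def test_confusion_rows_sum_100(self, three_groups):
        X, g = three_groups
        fit = mvstats.cda_fit(X, g)
        np.testing.assert_allclose(fit.confusion.sum(axis=1), 100.0)

    def test_unseen_label_rejected(self, three_groups):
        X, g = three_groups
        fit = mvstats.cda_fit(X, g)
        with pytest.raises(ValueError, match="unseen"):
            mvstats.classify_resubstitution(fit, X[:3], ["Z", "Z", "Z"])


class TestClusterCentroids:
    def test_coincident_centroids_merge_at_zero(self):
        tab = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]], index=list("abc"))
        tree = mvstats.cluster_centroids(tab)
        assert tree.heights[0] == 0.0

    def test_hand_computed_heights(self):
        # mutual distances 1 (A-B), 2 (A-C), 3 (B-C): merge {A,B} at 1,
        # then C joins at (2 + 3) / 2 = 2.5
        tab = pd.DataFrame({"x": [0.0, 1.0, -2.0]}, index=["A", "B", "C"])
        tree = mvstats.cluster_centroids(tab)
        np.testing.assert_allclose(tree.heights, [1.0, 2.5])

    def test_planted_clusters_recovered(self, rng):
        centers = np.array([(0, 0), (10, 0), (0, 10), (10, 10)], dtype=float)
        rows, labels, want = [], [], {}
        for ci, c in enumerate(centers):
            for j in range(3):
                name = f"g{ci}{j}"
                rows.append(c + rng.normal(0, 0.3, 2))
                labels.append(name)
                want[name] = ci
        tree = mvstats.cluster_centroids(pd.DataFrame(rows, index=labels))
        cut = tree.cut(4)
        # same planted centre <=> same recovered cluster
        for a in labels:
            for b in labels:
                assert (cut[a] == cut[b]) == (want[a] == want[b])

    def test_heights_nondecreasing(self, rng):
        tab = pd.DataFrame(rng.normal(size=(8, 3)), index=[f"v{i}" for i in range(8)])
        tree = mvstats.cluster_centroids(tab)
        assert np.all(np.diff(tree.heights) >= 0)

    def test_newick_parseable(self):
        tab = pd.DataFrame(
            np.random.default_rng(1).normal(size=(5, 2)),
            index=["Va", "Vb", "Vc", "Vd", "Ve"],
        )
        tree = mvstats.cluster_centroids(tab)
        import io

        from Bio import Phylo

        t = Phylo.read(io.StringIO(tree.to_newick()), "newick")
        assert sorted(x.name for x in t.get_terminals()) == sorted(tab.index)

    def test_duplicate_labels_rejected(self):
        tab = pd.DataFrame(np.zeros((2, 2)), index=["x", "x"])
        with pytest.raises(ValueError, match="duplicate"):
            mvstats.cluster_centroids(tab)
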