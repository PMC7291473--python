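"""Neighbor joining, covariance PCA, bootstrap and matrix correlations."""

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from tbpkit import (
    bootstrap_support,
    cophenetic_correlation,
    dissimilarity_matrix,
    matrix_correlation,
    nj_tree,
    pca_covariance,
)
from tbpkit.errors import TBPKitError, ZeroVarianceError

from conftest import make_matrix, random_additive_distances, treenode_bipartitions


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = DistanceMatrix([[0, 5, 9], [5, 0, 10], [9, 10, 0]], ids=list("abc"))
        tree = nj_tree(d)
        lengths = {t.name: t.length for t in tree.tree.tips()}
        # la = (dab+dac-dbc)/2 etc.
        assert lengths["a"] == pytest.approx(2.0)
        assert lengths["b"] == pytest.approx(3.0)
        assert lengths["c"] == pytest.approx(7.0)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # classic additive example: ((a:2,b:3):1,(c:4,d:5)) style distances
        D = np.array(
            [
                [0, 5, 9, 9],
                [5, 0, 10, 10],
                [9, 10, 0, 8],
                [9, 10, 8, 0],
            ],
            dtype=float,
        )
        d = DistanceMatrix(D, ids=list("abcd"))
        tree = nj_tree(d)
        coph = tree.cophenetic().filter(list("abcd"))
        assert np.allclose(np.asarray(coph.data), D, atol=1e-12)
        assert frozenset("cd") in tree.bipartitions()

    def test_random_additive_matrices_round_trip(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 13))
            D = random_additive_distances(rng, n)
            ids = [f"t{i:02d}" for i in range(n)]
            tree = nj_tree(DistanceMatrix(D, ids=ids))
            coph = tree.cophenetic().filter(ids)
            assert np.allclose(np.asarray(coph.data), D, rtol=1e-9, atol=1e-9)

    def test_topology_agrees_with_independent_nj(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 10))
            D = random_additive_distances(rng, n)
            ids = [f"t{i:02d}" for i in range(n)]
            dm = DistanceMatrix(D, ids=ids)
            ours = nj_tree(dm).bipartitions()
            theirs = treenode_bipartitions(skbio_nj(dm))
            assert ours == theirs

    def test_ultrametric_matrix_matches_single_linkage_grouping(self):
        D = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]], dtype=float
        )
        tree = nj_tree(DistanceMatrix(D, ids=list("abcd")))
        assert tree.bipartitions() == {frozenset("cd")}

    def test_invalid_distances_rejected(self):
        neg = np.array([[0, 0.5, -0.2], [0.5, 0, 0.3], [-0.2, 0.3, 0]])
        with pytest.raises(TBPKitError, match="negative"):
            nj_tree(DistanceMatrix(neg, ids=list("abc")))
        with pytest.raises(TBPKitError, match=">= 3"):
            nj_tree(DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]), ids=list("ab")))

    def test_newick_serialization_is_parseable(self):
        from io import StringIO
        from skbio import TreeNode

        D = random_additive_distances(np.random.default_rng(7), 6)
        ids = [f"t{i}" for i in range(6)]
        nwk = nj_tree(DistanceMatrix(D, ids=ids)).newick()
        parsed = TreeNode.read(StringIO(nwk))
        assert {t.name for t in parsed.tips()} == set(ids)


class TestPca:
    def test_identical_rows_flagged_degenerate(self):
        res = pca_covariance(make_matrix({"A": "101", "B": "101", "C": "101"}))
        assert res.degenerate
        assert res.eigenvalues.sum() == pytest.approx(0.0, abs=1e-12)

    def test_one_dimensional_variation_loads_on_pc1(self):
        res = pca_covariance(make_matrix({"A": "110", "B": "110", "C": "111"}))
        assert res.percent_variance[0] == pytest.approx(100.0)

    def test_matches_independent_eigensolver(self, rng):
        from sklearn.decomposition import PCA

        for _ in range(5):
            rows = {f"S{i}": "".join(map(str, rng.integers(0, 2, 10))) for i in range(6)}
            m = make_matrix(rows)
            res = pca_covariance(m)
            sk = PCA().fit(m.values)
            k = len(sk.explained_variance_ratio_)
            assert np.allclose(
                res.percent_variance[:k], 100 * sk.explained_variance_ratio_, atol=1e-8
            )
            # scores agree up to per-component sign
            sk_scores = sk.transform(m.values)
            for comp in range(k):
                ours = res.scores.values[:, comp]
                theirs = sk_scores[:, comp]
                assert np.allclose(ours, theirs, atol=1e-8) or np.allclose(
                    ours, -theirs, atol=1e-8
                )

    def test_percent_variance_sums_to_100(self, rng):
        rows = {f"S{i}": "".join(map(str, rng.integers(0, 2, 7))) for i in range(5)}
        res = pca_covariance(make_matrix(rows))
        assert res.percent_variance.sum() == pytest.approx(100.0, rel=1e-9)


SEPARATED = {
    # two 3-sample groups with many fixed private markers
    "A1": "111111110000000010",
    "A2": "111111110000000001",
    "A3": "111111110000000000",
    "B1": "000000001111111100",
    "B2": "000000001111111110",
    "B3": "000000001111111101",
}


class TestBootstrap:
    def test_well_separated_groups_get_full_support(self):
        m = make_matrix(SEPARATED)
        res = bootstrap_support(m, n_reps=200, seed=1)
        assert res.support_for(["A1", "A2", "A3"]) > 95.0

    def test_single_replicate_supports_are_zero_or_hundred(self):
        res = bootstrap_support(make_matrix(SEPARATED), n_reps=1, seed=3)
        assert set(res.supports.values()) <= {0.0, 100.0}

    def test_same_seed_reproduces_supports(self):
        m = make_matrix(SEPARATED)
        r1 = bootstrap_support(m, n_reps=50, seed=11)
        r2 = bootstrap_support(m, n_reps=50, seed=11)
        assert r1.supports == r2.supports
        assert r1.newick() == r2.newick()

    def test_sample_order_does_not_change_supports(self):
        rows = SEPARATED
        m1 = make_matrix(rows)
        m2 = make_matrix({k: rows[k] for k in reversed(list(rows))})
        r1 = bootstrap_support(m1, n_reps=50, seed=11)
        r2 = bootstrap_support(m2, n_reps=50, seed=11)
        assert r1.supports == r2.supports


class TestCorrelations:
    def test_tree_from_additive_matrix_fits_perfectly(self, rng):
        D = random_additive_distances(rng, 7)
        ids = [f"t{i}" for i in range(7)]
        dm = DistanceMatrix(D, ids=ids)
        tree = nj_tree(dm)
        res = cophenetic_correlation(tree, dm)
        assert res.r == pytest.approx(1.0, abs=1e-9)

    def test_leaf_permutation_degrades_cophenetic_fit(self, rng):
        D = random_additive_distances(rng, 7)
        ids = [f"t{i}" for i in range(7)]
        dm = DistanceMatrix(D, ids=ids)
        tree = nj_tree(dm)
        perm = list(rng.permutation(ids))
        shuffled = DistanceMatrix(dm.data, ids=perm)
        matched = cophenetic_correlation(tree, dm).r
        degraded = cophenetic_correlation(tree, shuffled).r
        assert degraded < matched

    def test_identical_matrices_correlate_perfectly(self, rng):
        D = random_additive_distances(rng, 6)
        ids = [f"t{i}" for i in range(6)]
        dm = DistanceMatrix(D, ids=ids)
        res = matrix_correlation(dm, dm, n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert 0 < res.p <= 1

    def test_constant_matrix_has_undefined_correlation(self):
        ids = list("abcd")
        c = DistanceMatrix(np.ones((4, 4)) - np.eye(4), ids=ids)
        flat = DistanceMatrix(
            np.full((4, 4), 0.5) - 0.5 * np.eye(4), ids=ids
        )
        with pytest.raises(ZeroVarianceError):
            matrix_correlation(c, flat, n_permutations=0)

    def test_mismatched_sample_sets_listed(self, rng):
        D = random_additive_distances(rng, 4)
        d1 = DistanceMatrix(D, ids=list("abcd"))
        d2 = DistanceMatrix(D, ids=list("abce"))
        with pytest.raises(TBPKitError, match="e"):
            matrix_correlation(d1, d2)

    def test_matches_independent_mantel_implementation(self, rng):
        from skbio.stats.distance import mantel

        for _ in range(5):
            n = 8
            D1 = random_additive_distances(rng, n)
            noise = rng.uniform(0, 0.3, (n, n))
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0)
            D2 = D1 + noise
            ids = [f"t{i}" for i in range(n)]
            d1, d2 = DistanceMatrix(D1, ids=ids), DistanceMatrix(D2, ids=ids)
            ours = matrix_correlation(d1, d2, n_permutations=0)
            r_skbio, _, _ = mantel(d1, d2, permutations=0)
            assert ours.r == pytest.approx(float(r_skbio), abs=1e-12)

    def test_related_matrices_beat_shuffled_ones(self, rng):
        """Statistical sanity: the matched correlation exceeds the
        label-shuffled one on structured input."""
        D = random_additive_distances(rng, 8)
        ids = [f"t{i}" for i in range(8)]
        dm = DistanceMatrix(D, ids=ids)
        tree = nj_tree(dm)
        matched = cophenetic_correlation(tree, dm).r
        perm = list(rng.permutation(ids))
        shuffled = matrix_correlation(
            dm, DistanceMatrix(dm.data, ids=perm).filter(ids), n_permutations=0
        ).r
        assert matched >= shuffled
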