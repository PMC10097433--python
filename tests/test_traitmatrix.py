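"""Pairwise score matrices, cross-method correlation, Mantel test and
hierarchical cluster ordering."""

import itertools

import numpy as np
import pytest

from traitmap import (
    Orientation,
    ScoreMatrix,
    batet_matrix,
    build_ngram_embedder,
    cluster_order,
    levenshtein_backend,
    mantel,
    method_spearman,
    pairwise_score_matrix,
    simulate_ontology,
    top_split,
)


def similarity_matrix(values, items=None, name="m"):
    values = np.asarray(values, dtype=float)
    items = items or [f"i{k}" for k in range(values.shape[0])]
    return ScoreMatrix(items=tuple(items), values=values,
                       orientation=Orientation.SIMILARITY, method_name=name)


class TestScoreMatrix:
    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            similarity_matrix([[1, 0.5], [0.2, 1]])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            similarity_matrix([[1, np.nan], [np.nan, 1]])

    def test_orientation_normalization_is_idempotent(self):
        m = ScoreMatrix(
            items=("a", "b", "c"),
            values=np.array([[0, 2, 3], [2, 0, 1], [3, 1, 0]], dtype=float),
            orientation=Orientation.DISTANCE,
        )
        once = m.as_similarity()
        twice = once.as_similarity()
        assert once.orientation is Orientation.SIMILARITY
        np.testing.assert_array_equal(once.values, twice.values)
        np.testing.assert_array_equal(once.upper_triangle(), [-2.0, -3.0, -1.0])

    def test_tsv_round_trip(self, tmp_path):
        m = similarity_matrix([[1, 0.3, 0.1], [0.3, 1, 0.7], [0.1, 0.7, 1]])
        path = tmp_path / "m.tsv"
        m.to_tsv(path)
        back = ScoreMatrix.from_tsv(path)
        assert back.items == m.items
        np.testing.assert_allclose(back.values, m.values)


class TestPairwiseMatrix:
    def test_levenshtein_triangle_from_dp_oracle(self):
        m = pairwise_score_matrix(levenshtein_backend(), ["aa", "ab", "bb"])
        np.testing.assert_allclose(m.upper_triangle(), [0.5, 0.0, 0.5])
        assert m.orientation is Orientation.SIMILARITY

    def test_duplicate_traits_after_normalization_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            pairwise_score_matrix(levenshtein_backend(), ["Heart ", "heart", "x"])

    def test_symmetry_for_every_backend(self):
        rng = np.random.default_rng(8)
        traits = [
            "".join(rng.choice(list("abcdef "), 10)).strip() or f"t{i}"
            for i in range(20)
        ]
        traits = list(dict.fromkeys(traits))
        for backend in (levenshtein_backend(),
                        build_ngram_embedder(traits, seed=0)):
            m = pairwise_score_matrix(backend, traits)
            np.testing.assert_allclose(m.values, m.values.T)


class TestBatetMatrix:
    def test_toy_graph_values(self, toy_graph):
        m = batet_matrix(toy_graph, ["C", "A", "B"])
        assert m.values[0, 0] == 1.0
        assert m.values[0, 1] == pytest.approx(0.5849625007211562)
        assert m.values[0, 2] == pytest.approx(0.19264507794239594)

    def test_disconnected_terms_score_zero(self, two_roots_graph):
        m = batet_matrix(two_roots_graph, ["r1", "r2"])
        assert m.values[0, 1] == 0.0


class TestMethodSpearman:
    @pytest.fixture
    def base(self):
        rng = np.random.default_rng(1)
        v = rng.random((6, 6))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        return similarity_matrix(v)

    def test_self_correlation_is_one(self, base):
        assert method_spearman(base, base) == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_transform(self, base):
        transformed = similarity_matrix(np.exp(3 * base.values), name="exp")
        assert method_spearman(base, transformed) == pytest.approx(1.0)

    def test_orientation_contract_negated_distance(self, base):
        as_distance = ScoreMatrix(
            items=base.items, values=-base.values,
            orientation=Orientation.DISTANCE, method_name="neg",
        )
        assert method_spearman(base, as_distance) == pytest.approx(1.0)

    def test_item_mismatch_rejected(self, base):
        other = similarity_matrix(base.values, items=list("abcdef"))
        with pytest.raises(ValueError, match="item"):
            method_spearman(base, other)


def random_similarity(n, rng):
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 1.0)
    return similarity_matrix(v)


class TestMantel:
    def test_self_comparison_hits_the_p_floor(self):
        rng = np.random.default_rng(0)
        m = random_similarity(10, rng)
        r, p = mantel(m, m, permutations=999, seed=1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1000)

    def test_r_symmetric_in_arguments(self):
        rng = np.random.default_rng(5)
        a, b = random_similarity(8, rng), random_similarity(8, rng)
        ra, _ = mantel(a, b, permutations=99, seed=0)
        rb, _ = mantel(b, a, permutations=99, seed=0)
        assert ra == pytest.approx(rb)

    def test_sign_agrees_with_spearman_on_linear_relation(self):
        rng = np.random.default_rng(2)
        a = random_similarity(8, rng)
        b = similarity_matrix(0.2 + 0.5 * a.values, name="linear")
        r, _ = mantel(a, b, permutations=99, seed=0)
        assert np.sign(r) == np.sign(method_spearman(a, b)) == 1.0

    def test_exhaustive_enumeration_on_four_items(self):
        """Random-permutation p approaches the exact p over all 4! = 24
        relabelings, and the exact p matches a from-scratch enumeration."""
        rng = np.random.default_rng(7)
        a, b = random_similarity(4, rng), random_similarity(4, rng)
        r_obs, p_exact = mantel(a, b, permutations=None)

        # independent enumeration oracle
        iu = np.triu_indices(4, k=1)
        x = a.values[iu]
        hits = 0
        for perm in itertools.permutations(range(4)):
            bp = b.values[np.ix_(perm, perm)][iu]
            r = np.corrcoef(x, bp)[0, 1]
            hits += abs(r) >= abs(r_obs) - 1e-12
        assert p_exact == pytest.approx(hits / 24)

        _, p_mc = mantel(a, b, permutations=4999, seed=3)
        assert p_mc == pytest.approx(p_exact, abs=0.03)

    def test_p_uniform_under_independence(self):
        """Across 200 independent matrix pairs the Mantel p-value must
        be approximately uniform (calibration)."""
        from scipy import stats

        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            a = random_similarity(10, rng)
            b = random_similarity(10, rng)
            _, p = mantel(a, b, permutations=99, seed=seed)
            pvals.append(p)
        ks_p = stats.kstest(pvals, "uniform").pvalue
        assert ks_p > 0.01

    def test_requires_min_permutations(self):
        rng = np.random.default_rng(0)
        m = random_similarity(5, rng)
        with pytest.raises(ValueError, match="99"):
            mantel(m, m, permutations=10)

    def test_agrees_with_scikit_bio_statistic(self):
        """Independent cross-check: the Mantel r equals scikit-bio's on
        distance-oriented inputs."""
        from skbio import DistanceMatrix
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(11)
        n = 8
        da = rng.random((n, n)); da = (da + da.T) / 2; np.fill_diagonal(da, 0)
        db = rng.random((n, n)); db = (db + db.T) / 2; np.fill_diagonal(db, 0)
        items = tuple(f"i{k}" for k in range(n))
        a = ScoreMatrix(items=items, values=da, orientation=Orientation.DISTANCE)
        b = ScoreMatrix(items=items, values=db, orientation=Orientation.DISTANCE)
        r_ours, _ = mantel(a, b, permutations=99, seed=0)
        r_skbio, _, _ = skbio_mantel(
            DistanceMatrix(da, items), DistanceMatrix(db, items),
            permutations=0,
        )
        assert r_ours == pytest.approx(r_skbio)


class TestClusterOrder:
    def test_single_item_is_trivial(self):
        m = ScoreMatrix(items=("only",), values=np.array([[1.0]]),
                        orientation=Orientation.SIMILARITY)
        order, linkage = cluster_order(m)
        assert order == ["only"]
        assert linkage.shape == (0, 4)

    def test_perfect_pair_merges_first(self):
        v = np.array([
            [1.0, 1.0, 0.1],
            [1.0, 1.0, 0.2],
            [0.1, 0.2, 1.0],
        ])
        _, linkage = cluster_order(similarity_matrix(v, items=["a", "b", "c"]))
        assert sorted(linkage[0, :2]) == [0, 1]  # a and b merge first
        assert linkage[0, 2] == 0.0

    def test_planted_blocks_separate_at_top_split(self):
        block = np.full((6, 6), 0.05)
        block[:3, :3] = 0.9
        block[3:, 3:] = 0.9
        np.fill_diagonal(block, 1.0)
        m = similarity_matrix(block, items=list("abcdef"))
        left, right = top_split(m)
        assert {frozenset(left), frozenset(right)} == {
            frozenset("abc"), frozenset("def")
        }

    def test_leaf_order_deterministic(self):
        rng = np.random.default_rng(9)
        m = random_similarity(12, rng)
        assert cluster_order(m)[0] == cluster_order(m)[0]

    def test_two_family_labels_separate_with_ngram_scores(self):
        """Labels drawn from disjoint branch vocabularies cluster into
        their families at the top split of the n-gram score matrix."""
        graph = simulate_ontology(40, n_roots=2, seed=3)
        terms = graph.terms
        root0 = graph.roots[0]
        family = {
            t: "fam0" if root0 in graph.ancestors(t) else "fam1" for t in terms
        }
        labels = [graph.label(t) for t in terms]
        backend = build_ngram_embedder(labels, seed=0)
        matrix = pairwise_score_matrix(backend, labels)
        left, right = top_split(matrix)
        by_label = {graph.label(t): family[t] for t in terms}
        left_fams = {by_label[l] for l in left}
        right_fams = {by_label[r] for r in right}
        assert left_fams.isdisjoint(right_fams)
        assert len(left_fams) == len(right_fams) == 1
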