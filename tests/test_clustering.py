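"""Binary matrix, Jaccard distances, agglomeration, tree cut, MDS, Newick."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy as scipy_hierarchy
from scipy.spatial.distance import pdist, squareform

from rootsig import (
    CorpusSpec,
    build_matrix,
    classical_mds,
    cut_tree,
    generate_list_corpus,
    hierarchical_cluster,
    jaccard_distance_matrix,
    jaccard_similarity,
    to_newick,
)
from conftest import make_bioset


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"A", "B", "C"}, {"B", "C", "D"}, 0.5),
            ({"A", "B"}, {"A", "B"}, 1.0),
            ({"A"}, {"B"}, 0.0),
            (set(), set(), 0.0),  # empty-vs-empty convention
            (set(), {"A"}, 0.0),
        ],
    )
    def test_similarity(self, a, b, expected):
        assert jaccard_similarity(a, b) == expected

    def test_matrix_distances_equal_set_oracle_on_all_pairs(self):
        spec = CorpusSpec(n_experiments=4, biosets_per_experiment=3,
                          universe_size=150, baseline_inclusion_prob=0.15,
                          seed=21)
        corpus, _ = generate_list_corpus(spec)
        d = jaccard_distance_matrix(build_matrix(corpus))
        for i, j in itertools.combinations(range(len(corpus)), 2):
            expected = 1.0 - jaccard_similarity(corpus[i].genes,
                                                corpus[j].genes)
            assert d.iloc[i, j] == pytest.approx(expected, abs=1e-12)
            assert d.iloc[j, i] == d.iloc[i, j]
        assert (np.diag(d.to_numpy()) == 0).all()

    def test_matrix_distances_match_scipy_pdist_on_nonempty_rows(self):
        spec = CorpusSpec(n_experiments=3, biosets_per_experiment=3,
                          universe_size=100, baseline_inclusion_prob=0.3,
                          seed=8)
        corpus, _ = generate_list_corpus(spec)
        m = build_matrix(corpus)
        ours = jaccard_distance_matrix(m).to_numpy()
        ref = squareform(pdist(m.data.to_numpy(dtype=bool), metric="jaccard"))
        assert np.allclose(ours, ref, atol=1e-12)

    def test_triangle_inequality_on_all_triples(self):
        spec = CorpusSpec(n_experiments=3, biosets_per_experiment=3,
                          universe_size=80, baseline_inclusion_prob=0.25,
                          seed=17)
        corpus, _ = generate_list_corpus(spec)
        d = jaccard_distance_matrix(build_matrix(corpus)).to_numpy()
        n = d.shape[0]
        for i, j, k in itertools.permutations(range(n), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestBinaryGeneMatrix:
    def test_row_and_column_sums(self):
        corpus = [make_bioset("b1", ["A", "B"]), make_bioset("b2", ["B", "C"])]
        m = build_matrix(corpus)
        assert m.data.shape == (2, 3)
        assert list(m.data.sum(axis=1)) == [2, 2]
        assert list(m.data.sum(axis=0)) == [1, 2, 1]
        assert m.genes == ["A", "B", "C"]  # lexicographic columns

    def test_shared_gene_column_sums_to_corpus_size(self):
        corpus = [
            make_bioset(f"b{i}", ["SHARED", f"G{i}"]) for i in range(27)
        ]
        m = build_matrix(corpus)
        assert m.data["SHARED"].sum() == 27

    def test_round_trip_matrix_sets_matrix(self):
        spec = CorpusSpec(n_experiments=3, biosets_per_experiment=2,
                          universe_size=60, baseline_inclusion_prob=0.3,
                          seed=2)
        corpus, _ = generate_list_corpus(spec)
        m = build_matrix(corpus)
        again = build_matrix(m.to_corpus())
        pd.testing.assert_frame_equal(m.data, again.data)

    def test_duplicate_bioset_id_rejected(self):
        corpus = [make_bioset("b1", ["A"]), make_bioset("b1", ["B"])]
        with pytest.raises(ValueError, match="b1"):
            build_matrix(corpus)

    def test_no_all_zero_columns(self):
        corpus = [make_bioset("b1", ["A", "B"]), make_bioset("b2", [])]
        m = build_matrix(corpus)
        assert (m.data.sum(axis=0) >= 1).all()


def random_distance_matrix(rng, n):
    x = rng.random((n, 3))
    d = squareform(pdist(x))
    return d


class TestHierarchicalCluster:
    def test_closest_pair_merges_first_under_every_linkage(self):
        d = np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
        for linkage in ("average", "complete", "single"):
            tree = hierarchical_cluster(d, linkage=linkage)
            assert tuple(tree.merges[0, :2]) == (0, 1)
            assert tree.merges[0, 2] == pytest.approx(0.1)

    def test_duplicate_items_merge_first_at_height_zero(self):
        corpus = [
            make_bioset("b1", ["A", "B"]),
            make_bioset("b2", ["C", "D"]),
            make_bioset("b3", ["A", "B"]),  # duplicate of b1
        ]
        d = jaccard_distance_matrix(build_matrix(corpus))
        tree = hierarchical_cluster(d)
        assert tree.merges[0, 2] == 0.0
        assert tuple(tree.merges[0, :2]) == (0, 2)

    @pytest.mark.parametrize("linkage", ["average", "complete", "single"])
    def test_merge_sequence_matches_scipy_oracle(self, linkage):
        # tie-free random matrices: merge pairs and heights must agree
        for seed in range(20):
            rng = np.random.default_rng(seed)
            d = random_distance_matrix(rng, 8)
            ours = hierarchical_cluster(d, linkage=linkage).merges
            ref = scipy_hierarchy.linkage(squareform(d), method=linkage)
            assert np.allclose(sorted(ours[:, 2]), sorted(ref[:, 2]),
                               atol=1e-10)
            for row_a, row_b in zip(ours, ref):
                assert sorted(row_a[:2]) == sorted(row_b[:2])
                assert row_a[2] == pytest.approx(row_b[2], abs=1e-10)
                assert row_a[3] == row_b[3]

    def test_merge_heights_nondecreasing(self):
        spec = CorpusSpec(n_experiments=4, biosets_per_experiment=3,
                          universe_size=100, baseline_inclusion_prob=0.2,
                          seed=33)
        corpus, _ = generate_list_corpus(spec)
        tree = hierarchical_cluster(jaccard_distance_matrix(build_matrix(corpus)))
        heights = tree.merges[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_partition_invariant_to_input_order(self):
        # distances here are pairwise distinct, so the tree is order-free
        rng = np.random.default_rng(42)
        d = random_distance_matrix(rng, 9)
        assert len(np.unique(squareform(d).round(12))) == 36
        names = [f"b{i}" for i in range(9)]
        part = cut_tree(hierarchical_cluster(
            pd.DataFrame(d, index=names, columns=names)), 3)
        perm = rng.permutation(9)
        d2 = d[np.ix_(perm, perm)]
        names2 = [names[i] for i in perm]
        part2 = cut_tree(hierarchical_cluster(
            pd.DataFrame(d2, index=names2, columns=names2)), 3)
        groups = {frozenset(part.members_of(c)) for c in range(1, 4)}
        groups2 = {frozenset(part2.members_of(c)) for c in range(1, 4)}
        assert groups == groups2

    def test_asymmetric_input_rejected(self):
        d = np.array([[0, 0.5], [0.4, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            hierarchical_cluster(d)

    def test_experiment_batch_structure_clusters_by_experiment(self):
        spec = CorpusSpec(n_experiments=4, biosets_per_experiment=3,
                          universe_size=1000, baseline_inclusion_prob=0.05,
                          experiment_specific_genes=60,
                          experiment_share_prob=0.7, seed=5)
        corpus, _ = generate_list_corpus(spec)
        tree = hierarchical_cluster(jaccard_distance_matrix(build_matrix(corpus)))
        part = cut_tree(tree, 4)
        for b in corpus:
            same = [c for c in corpus if c.experiment_id == b.experiment_id]
            labels = {part.assignment[c.bioset_id] for c in same}
            assert len(labels) == 1


class TestCutTree:
    def setup_method(self):
        d = np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
        self.tree = hierarchical_cluster(
            pd.DataFrame(d, index=["b1", "b2", "b3"], columns=["b1", "b2", "b3"])
        )

    def test_k_one_is_single_cluster(self):
        part = cut_tree(self.tree, 1)
        assert set(part.assignment.values()) == {1}

    def test_k_n_is_singletons(self):
        part = cut_tree(self.tree, 3)
        assert sorted(part.assignment.values()) == [1, 2, 3]

    def test_k_two_splits_at_highest_merge(self):
        part = cut_tree(self.tree, 2)
        assert part.assignment["b1"] == part.assignment["b2"]
        assert part.assignment["b3"] != part.assignment["b1"]

    @pytest.mark.parametrize("k", [0, 4])
    def test_k_out_of_range_rejected(self, k):
        with pytest.raises(ValueError, match="k must be"):
            cut_tree(self.tree, k)


class TestClassicalMDS:
    def test_equilateral_triangle_recovered(self):
        d = np.ones((3, 3)) - np.eye(3)
        coords = classical_mds(d).to_numpy()
        rec = squareform(pdist(coords))
        assert np.allclose(rec, d, atol=1e-9)

    def test_identical_points_coincide(self):
        d = np.zeros((2, 2))
        coords = classical_mds(d).to_numpy()
        assert np.allclose(coords[0], coords[1], atol=1e-12)

    def test_euclidean_distances_recovered_exactly(self):
        rng = np.random.default_rng(1)
        x = rng.random((10, 2))
        d = squareform(pdist(x))
        coords = classical_mds(d, dims=2).to_numpy()
        rec = squareform(pdist(coords))
        assert np.abs(rec - d).max() <= 1e-8


class TestNewick:
    def test_round_trip_preserves_leaves_and_root_heights(self):
        import dendropy

        spec = CorpusSpec(n_experiments=3, biosets_per_experiment=3,
                          universe_size=120, baseline_inclusion_prob=0.2,
                          seed=10)
        corpus, _ = generate_list_corpus(spec)
        tree = hierarchical_cluster(jaccard_distance_matrix(build_matrix(corpus)))
        newick = to_newick(tree)
        parsed = dendropy.Tree.get(data=newick, schema="newick",
                                   preserve_underscores=True)
        leaves = {lf.taxon.label for lf in parsed.leaf_node_iter()}
        assert leaves == {b.bioset_id for b in corpus}
        # each root-to-leaf path length equals the root merge height
        root_height = tree.merges[-1, 2]
        for leaf in parsed.leaf_node_iter():
            depth = leaf.distance_from_root()
            assert depth == pytest.approx(root_height, abs=1e-9)
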