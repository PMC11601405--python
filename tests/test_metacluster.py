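"""Filtering, Jaccard similarity, UPGMA grouping and meta summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import traitblocks as tb


def make_set(gene_sets, trait_sets=None, n_traits=10, n_genes=40):
    """Build a BiclusterSet from explicit index sets."""
    trait_sets = trait_sets or [(0, 1)] * len(gene_sets)
    bics = [
        tb.Bicluster(id=f"B{i}", trait_indices=tuple(t), gene_indices=tuple(g))
        for i, (t, g) in enumerate(zip(trait_sets, gene_sets))
    ]
    return tb.BiclusterSet(
        bics,
        trait_ids=[f"T{i}" for i in range(n_traits)],
        gene_ids=[f"G{j}" for j in range(n_genes)],
        params={},
    )


def random_distance_matrix(rng, n):
    d = rng.random((n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


def partition_from_labels(labels):
    labels = np.asarray(labels)
    return {
        frozenset(np.flatnonzero(labels == g).tolist()) for g in np.unique(labels)
    }


class TestFilter:
    def test_gene_count_and_required_trait(self):
        bset = make_set(
            gene_sets=[range(5), range(12), range(15)],
            trait_sets=[(0, 1), (2, 3), (4, 5)],
        )
        kept = tb.filter_biclusters(bset, min_genes=10, required_trait_ids={"T2"})
        assert [b.id for b in kept] == ["B1"]

    def test_no_constraints_is_identity(self):
        bset = make_set(gene_sets=[range(3), range(4)])
        kept = tb.filter_biclusters(bset, min_genes=0)
        assert [b.id for b in kept] == ["B0", "B1"]

    def test_unreachable_min_genes_empties_the_set(self):
        bset = make_set(gene_sets=[range(3), range(4)])
        assert len(tb.filter_biclusters(bset, min_genes=100)) == 0

    def test_trait_regex_selection(self):
        bset = make_set(
            gene_sets=[range(12), range(12)], trait_sets=[(1,), (2,)]
        )
        kept = tb.filter_biclusters(bset, min_genes=10, trait_pattern=r"^T1$")
        assert [b.id for b in kept] == ["B0"]


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"A", "B", "C"}, {"B", "C", "D"}, 0.5),
            ({"A"}, {"A"}, 1.0),
            ({"A"}, {"B"}, 0.0),
            (set(), set(), 0.0),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert tb.jaccard(a, b) == expected

    @given(
        st.sets(st.integers(0, 30)),
        st.sets(st.integers(0, 30)),
    )
    def test_bounded_symmetric_and_one_iff_equal(self, a, b):
        j = tb.jaccard(a, b)
        assert 0.0 <= j <= 1.0
        assert j == tb.jaccard(b, a)
        if a or b:
            assert (j == 1.0) == (a == b)


class TestPairwiseSimilarity:
    def test_matches_per_pair_jaccard(self):
        sets = [set(range(10)), set(range(5, 15)), set(range(20, 30))]
        sim = tb.pairwise_similarity(make_set(gene_sets=sets))
        for i in range(3):
            for j in range(3):
                assert sim.values[i, j] == pytest.approx(
                    tb.jaccard(sets[i], sets[j])
                )
        assert np.all(np.diag(sim.values) == 1.0)

    def test_fewer_than_two_biclusters_rejected(self):
        with pytest.raises(ValueError):
            tb.pairwise_similarity(make_set(gene_sets=[range(3)]))


class TestAverageLinkage:
    def test_hand_worked_three_point_example(self):
        # d(A,B)=0.1, d(A,C)=0.9, d(B,C)=0.8 -> k=2 groups {A,B} and {C}
        sim = tb.SimilarityMatrix(
            ["A", "B", "C"],
            1.0 - np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.8], [0.9, 0.8, 0.0]]),
        )
        labels = tb.average_linkage_cluster(sim, 2)
        assert partition_from_labels(labels) == {frozenset({0, 1}), frozenset({2})}

    def test_k_equals_n_and_k_equals_one(self):
        rng = np.random.default_rng(0)
        d = random_distance_matrix(rng, 6)
        sim = tb.SimilarityMatrix([f"B{i}" for i in range(6)], 1.0 - d)
        assert partition_from_labels(tb.average_linkage_cluster(sim, 6)) == {
            frozenset({i}) for i in range(6)
        }
        assert partition_from_labels(tb.average_linkage_cluster(sim, 1)) == {
            frozenset(range(6))
        }

    def test_k_out_of_range_rejected(self):
        sim = tb.SimilarityMatrix(["A", "B"], np.eye(2))
        for k in (0, 3):
            with pytest.raises(ValueError):
                tb.average_linkage_cluster(sim, k)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_reference_upgma_at_every_k(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 16))
        d = random_distance_matrix(rng, n)
        sim = tb.SimilarityMatrix([f"B{i}" for i in range(n)], 1.0 - d)
        reference = tb.reference_upgma_partitions(d)
        for k in range(1, n + 1):
            got = partition_from_labels(tb.average_linkage_cluster(sim, k))
            expect = {frozenset(g) for g in reference[k]}
            assert got == expect, f"partition mismatch at k={k}"

    @pytest.mark.parametrize("seed", range(5))
    def test_cuts_are_nested(self, seed):
        rng = np.random.default_rng(50 + seed)
        n = 10
        d = random_distance_matrix(rng, n)
        sim = tb.SimilarityMatrix([f"B{i}" for i in range(n)], 1.0 - d)
        prev = partition_from_labels(tb.average_linkage_cluster(sim, n))
        for k in range(n - 1, 0, -1):
            cur = partition_from_labels(tb.average_linkage_cluster(sim, k))
            # moving from k+1 to k merges exactly two existing groups
            merged = prev - cur
            created = cur - prev
            assert len(merged) == 2 and len(created) == 1
            assert frozenset().union(*merged) == next(iter(created))
            prev = cur

    def test_disjoint_gene_families_split_exactly_at_k2(self):
        fam1 = [set(range(0, 10)), set(range(2, 12)), set(range(1, 9))]
        fam2 = [set(range(20, 30)), set(range(22, 33))]
        bset = make_set(gene_sets=fam1 + fam2)
        sim = tb.pairwise_similarity(bset)
        labels = tb.average_linkage_cluster(sim, 2)
        assert partition_from_labels(labels) == {
            frozenset({0, 1, 2}),
            frozenset({3, 4}),
        }


class TestSummarize:
    def test_union_and_frequencies(self):
        bset = make_set(gene_sets=[(0, 1), (1, 2)], trait_sets=[(0, 1), (1, 2)])
        metas = tb.summarize_meta(bset, [0, 0])
        assert len(metas) == 1
        meta = metas[0]
        assert meta.label == "C1"
        assert meta.gene_union == {"G0", "G1", "G2"}
        assert meta.gene_frequency == [("G1", 2), ("G0", 1), ("G2", 1)]
        assert meta.trait_frequency == [("T1", 2), ("T0", 1), ("T2", 1)]

    def test_singleton_group(self):
        bset = make_set(gene_sets=[(0, 1), (5, 6)])
        metas = tb.summarize_meta(bset, [0, 1])
        assert metas[1].gene_union == {"G5", "G6"}
        assert metas[1].member_ids == ["B1"]

    def test_labels_must_cover_every_bicluster(self):
        bset = make_set(gene_sets=[(0, 1), (5, 6)])
        with pytest.raises(ValueError):
            tb.summarize_meta(bset, [0])
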