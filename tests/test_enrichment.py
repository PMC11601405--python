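"""GMT parsing and hypergeometric over-representation analysis."""

import math
from itertools import permutations

import pytest

import traitblocks as tb
from traitblocks.enrichment import GMTFormatError


def hypergeom_upper_tail(N, K, n, k):
    """Independent combinatorial oracle: P(X >= k) by direct summation."""
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total


class TestReadGMT:
    def test_duplicate_members_within_a_term_collapse(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("T1\tdesc\tG1\tG2\tG2\n")
        coll = tb.read_gmt(path)
        assert coll.members("T1") == {"G1", "G2"}

    def test_short_line_is_an_error(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("T1\tdesc\n")
        with pytest.raises(GMTFormatError):
            tb.read_gmt(path)

    def test_duplicate_term_id_is_an_error_naming_it(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("T1\tdesc\tG1\nT1\tother\tG2\n")
        with pytest.raises(GMTFormatError, match="T1"):
            tb.read_gmt(path)

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("")
        with pytest.warns(UserWarning):
            coll = tb.read_gmt(path)
        assert len(coll) == 0

    def test_gmt_roundtrip(self, tmp_path):
        coll = tb.GeneSetCollection(
            {"T1": ("a name", frozenset({"G1", "G2"})), "T2": ("b", frozenset({"G9"}))}
        )
        coll.write_gmt(tmp_path / "x.gmt")
        assert tb.read_gmt(tmp_path / "x.gmt").terms == coll.terms


def one_term_collection(members, axis="gene"):
    return tb.GeneSetCollection({"TERM": ("t", frozenset(members))}, axis=axis)


class TestORA:
    def test_worked_example_66_over_252(self):
        # N=10, K=4, n=5, k=3
        universe = [f"G{i}" for i in range(10)]
        term = universe[:4]
        query = universe[:3] + universe[8:]  # 3 in the term, 2 outside
        res = tb.ora(query, one_term_collection(term), universe)
        assert len(res) == 1
        assert res[0].overlap_k == 3
        assert res[0].p_value == pytest.approx(66 / 252, abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"G{i}" for i in range(10)]
        res = tb.ora(universe[5:7], one_term_collection(universe[:3]), universe)
        assert res[0].overlap_k == 0
        assert res[0].p_value == 1.0

    def test_term_covering_universe_gives_p_one(self):
        universe = [f"G{i}" for i in range(8)]
        res = tb.ora(universe[:4], one_term_collection(universe), universe)
        assert res[0].overlap_k == 4
        assert res[0].p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("N", [5, 8])
    def test_exact_against_combinatorial_enumeration(self, N):
        universe = [f"G{i}" for i in range(N)]
        for K in range(1, N + 1):
            term = universe[:K]
            for n in range(1, N + 1):
                for k in range(max(0, n + K - N), min(K, n) + 1):
                    query = universe[:k] + universe[K : K + (n - k)]
                    res = tb.ora(query, one_term_collection(term), universe)
                    assert res[0].p_value == pytest.approx(
                        hypergeom_upper_tail(N, K, n, k), abs=1e-12
                    )

    def test_p_nonincreasing_in_overlap(self):
        N, K, n = 20, 8, 10
        ps = [hypergeom_upper_tail(N, K, n, k) for k in range(0, min(K, n) + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        # and the implementation agrees at each k
        universe = [f"G{i}" for i in range(N)]
        term = universe[:K]
        for k in range(0, min(K, n) + 1):
            query = universe[:k] + universe[K : K + (n - k)]
            res = tb.ora(query, one_term_collection(term), universe)
            assert res[0].p_value == pytest.approx(ps[k], abs=1e-12)

    def test_query_members_outside_universe_are_dropped(self):
        universe = [f"G{i}" for i in range(10)]
        res = tb.ora(
            universe[:3] + ["NOT_IN_UNIVERSE"],
            one_term_collection(universe[:4]),
            universe,
        )
        assert res[0].query_size_n == 3

    def test_empty_universe_and_empty_query_rejected(self):
        coll = one_term_collection(["G1"])
        with pytest.raises(ValueError):
            tb.ora(["G1"], coll, [])
        with pytest.raises(ValueError):
            tb.ora(["X"], coll, ["G1", "G2"])

    def test_terms_outside_universe_are_dropped_before_adjustment(self):
        universe = [f"G{i}" for i in range(6)]
        coll = tb.GeneSetCollection(
            {
                "IN": ("x", frozenset(universe[:3])),
                "OUT": ("y", frozenset({"Z1", "Z2"})),
            }
        )
        res = tb.ora(universe[:2], coll, universe)
        assert [r.term_id for r in res] == ["IN"]

    def test_bh_adjustment_properties(self):
        universe = [f"G{i}" for i in range(30)]
        coll = tb.GeneSetCollection(
            {
                f"T{j}": ("", frozenset(universe[j : j + 8]))
                for j in range(0, 20, 4)
            }
        )
        res = tb.ora(universe[:8], coll, universe)
        assert all(r.adjusted_p >= r.p_value for r in res)
        ordered = sorted(res, key=lambda r: r.p_value)
        adj = [r.adjusted_p for r in ordered]
        assert all(a <= b for a, b in zip(adj, adj[1:]))

    def test_single_term_adjusted_equals_raw(self):
        universe = [f"G{i}" for i in range(10)]
        res = tb.ora(universe[:5], one_term_collection(universe[:4]), universe)
        assert res[0].adjusted_p == pytest.approx(res[0].p_value)

    def test_term_order_does_not_change_sorted_output(self):
        universe = [f"G{i}" for i in range(12)]
        base = {
            "A": ("", frozenset(universe[:4])),
            "B": ("", frozenset(universe[2:7])),
            "C": ("", frozenset(universe[6:11])),
        }
        outputs = []
        for order in permutations(base):
            coll = tb.GeneSetCollection({t: base[t] for t in order})
            outputs.append(tb.ora(universe[:5], coll, universe))
        for other in outputs[1:]:
            assert other == outputs[0]


class TestEnrichMeta:
    def build_meta(self, label, genes, traits):
        return tb.MetaBicluster(
            label=label,
            member_ids=["B0"],
            gene_union=frozenset(genes),
            gene_frequency=[(g, 1) for g in sorted(genes)],
            trait_frequency=[(t, 1) for t in sorted(traits)],
        )

    def test_truth_aligned_term_ranks_first(self, clean_planted):
        ds = clean_planted
        binary = tb.binarize(ds.pvalues, 5.49e-10)
        found = tb.run_bibit(binary, 2, 2)
        filtered = tb.filter_biclusters(found, min_genes=10)
        sim = tb.pairwise_similarity(filtered)
        labels = tb.average_linkage_cluster(sim, 3)
        metas = tb.summarize_meta(filtered, labels)
        tables = tb.enrich_meta(
            metas,
            ds.gene_annotations,
            ds.trait_annotations,
            gene_universe=ds.pvalues.gene_ids,
            trait_universe=ds.pvalues.trait_ids,
        )
        for meta in metas:
            for axis in ("gene", "trait"):
                top = tables[meta.label][axis][0]
                assert top.term_id.startswith("TRUTH_")
                assert top.adjusted_p < 0.05

    def test_disjoint_union_gives_all_p_one(self):
        universe = [f"G{i}" for i in range(20)]
        gene_sets = tb.GeneSetCollection(
            {"T1": ("", frozenset(universe[10:15]))}, axis="gene"
        )
        trait_sets = tb.GeneSetCollection(
            {"D1": ("", frozenset({"X0"}))}, axis="trait"
        )
        meta = self.build_meta("C1", universe[:5], ["X1"])
        tables = tb.enrich_meta(
            [meta], gene_sets, trait_sets, universe, ["X0", "X1"]
        )
        assert all(r.p_value == 1.0 for r in tables["C1"]["gene"])

    def test_identical_unions_give_identical_tables(self):
        universe = [f"G{i}" for i in range(20)]
        gene_sets = tb.GeneSetCollection(
            {"T1": ("", frozenset(universe[:6]))}, axis="gene"
        )
        trait_sets = tb.GeneSetCollection(
            {"D1": ("", frozenset({"X0"}))}, axis="trait"
        )
        m1 = self.build_meta("C1", universe[:5], ["X0"])
        m2 = self.build_meta("C2", universe[:5], ["X0"])
        tables = tb.enrich_meta(
            [m1, m2], gene_sets, trait_sets, universe, ["X0", "X1"]
        )
        assert tables["C1"] == tables["C2"]
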