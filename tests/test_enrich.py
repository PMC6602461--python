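import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from overrep.annotation import GmtRecord, TermStore, build_store
from overrep.enrich import (
    Query,
    hypergeom_tail,
    parse_query_text,
    query_from_identifiers,
    run_multiquery,
    run_ordered,
    run_unordered,
)
from oracles import exact_tail


class TestHypergeomTail:
    def test_worked_example_10_4_5_3(self):
        # verified by exhaustive enumeration of all 252 draws of 5 from 10
        assert hypergeom_tail(10, 4, 5, 3) == pytest.approx(66 / 252, abs=1e-12)

    def test_worked_example_maximal_overlap(self):
        assert hypergeom_tail(10, 5, 5, 5) == pytest.approx(1 / 252, abs=1e-12)

    def test_k_zero_is_whole_sample_space(self):
        assert hypergeom_tail(50, 7, 13, 0) == 1.0

    @pytest.mark.parametrize(
        "N,K,n,k",
        [(10, 11, 5, 1), (10, 4, 11, 1), (10, 4, 5, 5), (10, 4, 5, -1)],
    )
    def test_bound_violations_raise(self, N, K, n, k):
        with pytest.raises(ValueError):
            hypergeom_tail(N, K, n, k)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.data())
    def test_non_increasing_in_k_and_matches_exact(self, data):
        N = data.draw(st.integers(2, 60))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        prev = None
        for k in range(min(n, K) + 1):
            p = hypergeom_tail(N, K, n, k)
            assert p == pytest.approx(float(exact_tail(N, K, n, k)), rel=1e-10)
            if prev is not None:
                assert p <= prev + 1e-15
            prev = p


class TestRunUnordered:
    def test_query_equal_to_term(self, store10):
        query, _ = query_from_identifiers(
            "q", ["g1", "g2", "g3", "g4"], store10.universe
        )
        records = run_unordered(query, store10, method="bonferroni")
        rec = next(r for r in records if r.term_id == "T1")
        assert (rec.N, rec.K, rec.n, rec.k) == (10, 4, 4, 4)
        assert rec.p_raw == pytest.approx(float(exact_tail(10, 4, 4, 4)), rel=1e-12)
        assert rec.intersection_genes == ("g1", "g2", "g3", "g4")

    def test_disjoint_query_all_p_one(self, store10):
        query, _ = query_from_identifiers("q", ["g8", "g9", "g10"], store10.universe)
        for rec in run_unordered(query, store10, method="fdr"):
            assert rec.k == 0
            assert rec.p_raw == 1.0
            assert rec.p_adj == 1.0

    def test_duplicate_genes_counted_once(self, store10):
        query, _ = query_from_identifiers(
            "q", ["g1", "g1", "g2", "gZZ"], store10.universe
        )
        assert query.size == 2
        rec = run_unordered(query, store10, method="bonferroni")[0]
        assert rec.n == 2

    def test_projection_drops_and_reports(self, store10):
        _, dropped = query_from_identifiers("q", ["g1", "gZZ"], store10.universe)
        assert dropped == ("gZZ",)

    def test_empty_projected_query_errors(self, store10):
        query, _ = query_from_identifiers("q", ["gZZ"], store10.universe)
        with pytest.raises(ValueError, match="empty"):
            run_unordered(query, store10, method="fdr")

    def test_records_invariant_under_store_permutation(self, store10):
        query, _ = query_from_identifiers("q", ["g1", "g3", "g5"], store10.universe)
        base = {
            r.term_id: r for r in run_unordered(query, store10, method="bonferroni")
        }
        permuted = TermStore(
            universe=store10.universe, terms=store10.terms[::-1]
        )
        for rec in run_unordered(query, permuted, method="bonferroni"):
            assert rec == base[rec.term_id]

    def test_significance_flag_respects_alpha(self, universe10):
        store, _ = build_store(
            [GmtRecord("T", "d", tuple(f"g{i}" for i in range(1, 6)))], universe10
        )
        query, _ = query_from_identifiers(
            "q", [f"g{i}" for i in range(1, 6)], universe10
        )
        (rec,) = run_unordered(query, store, method="bonferroni", alpha=0.05)
        assert rec.p_adj == pytest.approx(1 / 252)
        assert rec.significant


class TestRunOrdered:
    @pytest.fixture
    def ordered_setup(self, universe10):
        store, _ = build_store([GmtRecord("T", "d", ("g1", "g2"))], universe10)
        query, _ = query_from_identifiers(
            "q", ["g1", "g2", "g3"], universe10, ordered=True
        )
        return store, query

    def test_prefix_scan_hand_example(self, ordered_setup):
        # tails by hand: l=1 -> 2/10, l=2 -> 1/45, l=3 -> 8/120; min at l=2
        store, query = ordered_setup
        (rec,) = run_ordered(query, store, method="bonferroni")
        assert rec.p_raw == pytest.approx(1 / 45, rel=1e-12)
        assert rec.prefix_length == 2
        assert rec.n == 2
        assert rec.k == 2

    def test_disjoint_term_ties_to_smallest_prefix(self, universe10):
        store, _ = build_store([GmtRecord("T", "d", ("g9", "g10"))], universe10)
        query, _ = query_from_identifiers(
            "q", ["g1", "g2", "g3"], universe10, ordered=True
        )
        (rec,) = run_ordered(query, store, method="bonferroni")
        assert rec.p_raw == 1.0
        assert rec.prefix_length == 1

    def test_full_list_optimum_when_term_equals_query(self, universe10):
        store, _ = build_store([GmtRecord("T", "d", ("g1", "g2", "g3"))], universe10)
        query, _ = query_from_identifiers(
            "q", ["g1", "g2", "g3"], universe10, ordered=True
        )
        (rec,) = run_ordered(query, store, method="bonferroni")
        assert rec.prefix_length == 3

    def test_length_one_equals_unordered(self, store10):
        oq, _ = query_from_identifiers("q", ["g3"], store10.universe, ordered=True)
        uq, _ = query_from_identifiers("q", ["g3"], store10.universe)
        ordered = run_ordered(oq, store10, method="bonferroni")
        unordered = run_unordered(uq, store10, method="bonferroni")
        for ro, ru in zip(ordered, unordered):
            assert ro.p_raw == ru.p_raw
            assert ro.k == ru.k

    def test_ordered_minp_never_exceeds_unordered(self, store10):
        genes = ["g4", "g1", "g7", "g2", "g9"]
        oq, _ = query_from_identifiers("q", genes, store10.universe, ordered=True)
        uq, _ = query_from_identifiers("q", genes, store10.universe)
        ordered = {r.term_id: r for r in run_ordered(oq, store10, method="bonferroni")}
        for ru in run_unordered(uq, store10, method="bonferroni"):
            assert ordered[ru.term_id].p_raw <= ru.p_raw + 1e-15

    def test_unordered_query_rejected(self, store10):
        query, _ = query_from_identifiers("q", ["g1"], store10.universe)
        with pytest.raises(ValueError, match="ordered"):
            run_ordered(query, store10)


class TestQueryParsing:
    def test_named_lists(self):
        parsed = parse_query_text(">A\ng1 g2\n>B\ng3\n")
        assert parsed == [("A", ["g1", "g2"]), ("B", ["g3"])]

    def test_unnamed_prefix_becomes_query_1(self):
        parsed = parse_query_text("g1\ng2 g3 # comment\n")
        assert parsed == [("query_1", ["g1", "g2", "g3"])]

    def test_empty_header_errors(self):
        with pytest.raises(ValueError, match="B"):
            parse_query_text(">A\ng1\n>B\n")

    def test_query_rejects_duplicate_positions(self):
        with pytest.raises(ValueError):
            Query("q", (1, 1, 2))


class TestMultiQuery:
    def test_union_of_significant_terms(self, store10):
        text = ">A\ng1 g2 g3 g4\n>B\ng8 g9 g10\n"
        result = run_multiquery(text, store10, method="bonferroni", alpha=0.05)
        assert set(result.records) == {"A", "B"}
        sig_a = {r.term_id for r in result.records["A"] if r.significant}
        assert sig_a  # the T1-matching query is significant somewhere
        assert set(result.joint["term_id"]) == sig_a
        # B's (insignificant) adjusted p is still shown for those terms
        assert (result.joint["p_adj_B"] == 1.0).all()

    def test_identical_lists_identical_columns(self, store10):
        text = ">A\ng1 g2 g3\n>B\ng1 g2 g3\n"
        result = run_multiquery(text, store10, method="fdr", alpha=0.9)
        assert (result.joint["p_adj_A"] == result.joint["p_adj_B"]).all()

    def test_gscs_multiquery_deterministic(self, store10):
        text = ">A\ng1 g2 g3 g4\n>B\ng3 g4 g5\n"
        r1 = run_multiquery(text, store10, method="gscs", seed=5, R=200)
        r2 = run_multiquery(text, store10, method="gscs", seed=5, R=200)
        for name in r1.records:
            assert r1.records[name] == r2.records[name]


def test_padj_floor_keeps_log_finite(universe10):
    store, _ = build_store(
        [GmtRecord("T", "d", tuple(f"g{i}" for i in range(1, 6)))], universe10
    )
    query, _ = query_from_identifiers("q", [f"g{i}" for i in range(1, 6)], universe10)
    (rec,) = run_unordered(query, store, method="bonferroni")
    assert rec.p_raw > 0
    assert math.isfinite(-math.log10(rec.p_raw))
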