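"""Overlap coefficient, enrichment engine, and the selection cascade."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdtp.filters import (
    AnnotationMap,
    conserved_neighbors,
    deg_containment_filter,
    disease_term_filter,
    enrich_terms,
    first_order_neighbors,
    is_overlapped,
    neighbor_score,
    neighbor_threshold,
    overlap_coefficient,
    pathway_overlap_count,
    read_annotation,
    read_gmt,
    significant_terms,
    size_filter,
    term_overlap_filter,
    top_k_modules,
    write_annotation,
    write_gmt,
)
from sdtp.netprep import WeightedNetwork
from sdtp.rhs_miner import RhsModule
from sdtp.synthdata import table1_fixture


def module(genes, rank=1):
    return RhsModule(
        genes=frozenset(genes), layers=frozenset({"L0"}), heaviness=1.0,
        density=0.5, rank=rank,
    )


class TestOverlapCoefficient:
    def test_published_module_pair(self):
        t1 = table1_fixture()
        c = overlap_coefficient(t1["M17"], t1["M18"])
        assert c == pytest.approx(0.5)
        assert not is_overlapped(t1["M17"], t1["M18"])

    def test_identity_and_containment(self):
        assert overlap_coefficient({"a", "b"}, {"a", "b"}) == 1.0
        assert is_overlapped({"a", "b"}, {"a", "b", "c", "d"})  # contained => c = 1

    def test_disjoint(self):
        assert overlap_coefficient({"a"}, {"b"}) == 0.0

    def test_two_thirds_boundary_counts_as_overlapped(self):
        assert is_overlapped({"a", "b", "c"}, {"a", "b", "x", "y", "z"})

    def test_empty_set_error(self):
        with pytest.raises(ValueError):
            overlap_coefficient(set(), {"a"})

    @given(
        a=st.sets(st.sampled_from("abcdefgh"), min_size=1),
        b=st.sets(st.sampled_from("abcdefgh"), min_size=1),
    )
    @settings(max_examples=80, deadline=None)
    def test_symmetric_bounded_and_containment_iff_one(self, a, b):
        c = overlap_coefficient(a, b)
        assert 0.0 <= c <= 1.0
        assert c == overlap_coefficient(b, a)
        assert (c == 1.0) == (a <= b or b <= a)


class TestSizeAndDegFilters:
    def test_size_filter(self):
        mods = [module("ab", 1), module("abc", 2), module("abcde", 3)]
        kept = size_filter(mods, 3)
        assert [len(m.genes) for m in kept] == [3, 5]

    def test_size_filter_on_published_modules(self):
        mods = [module(genes, i) for i, genes in enumerate(table1_fixture().values())]
        assert len(size_filter(mods, 3)) == 26

    def test_size_one_is_identity(self):
        mods = [module("ab", 1), module("abc", 2)]
        assert size_filter(mods, 1) == mods

    def test_deg_containment_any_and_all(self):
        mods = [module({"a", "b", "c"}), module({"x", "y", "z"})]
        concordant = {"d1": {"a"}, "d2": {"q"}, "d3": {"b"}}
        assert deg_containment_filter(mods, concordant, mode="any") == [mods[0]]
        # mods[0] misses d2 entirely, so the conjunction drops everything
        assert deg_containment_filter(mods, concordant, mode="all") == []

    def test_cascade_stages_return_subsets(self):
        mods = [module({"a", "b", "c"}, 1), module({"x", "y"}, 2)]
        assert set(size_filter(mods, 2)) <= set(mods)
        assert set(deg_containment_filter(mods, {"d": {"a"}})) <= set(mods)


def brute_force_upper_tail(N, K, n, k):
    """P(X >= k) by direct hypergeometric mass summation."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
    return total


class TestEnrichTerms:
    @pytest.fixture
    def annotation_100(self):
        background = {f"g{i}" for i in range(100)}
        gene_terms = {f"g{i}": {("BP", "T")} for i in range(5)}
        for g in background:
            gene_terms.setdefault(g, set()).add(("BP", "EVERY"))
        return AnnotationMap(gene_terms=gene_terms, background=background)

    def test_closed_form_example(self, annotation_100):
        query = {f"g{i}" for i in range(5)}
        results = {r.term: r for r in enrich_terms(query, annotation_100, "BP")}
        expected = 1.0 / math.comb(100, 5)
        assert results["T"].p_raw == pytest.approx(expected, rel=1e-9)

    def test_universal_term_has_p_one(self, annotation_100):
        query = {f"g{i}" for i in range(5)}
        results = {r.term: r for r in enrich_terms(query, annotation_100, "BP")}
        assert results["EVERY"].p_raw == pytest.approx(1.0)

    def test_zero_overlap_terms_omitted(self):
        ann = AnnotationMap(
            gene_terms={"a": {("BP", "T1")}, "b": {("BP", "T2")}},
            background={"a", "b", "c"},
        )
        terms = {r.term for r in enrich_terms({"a"}, ann, "BP")}
        assert terms == {"T1"}

    def test_query_outside_background_error(self):
        ann = AnnotationMap(gene_terms={"a": {("BP", "T")}}, background={"a"})
        with pytest.raises(ValueError, match="zz"):
            enrich_terms({"zz"}, ann, "BP")

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_small_backgrounds(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(8, 31))
        background = {f"g{i}" for i in range(N)}
        gene_terms = {}
        for t in range(4):
            K = int(rng.integers(1, N + 1))
            for g in rng.choice(sorted(background), size=K, replace=False):
                gene_terms.setdefault(g, set()).add(("BP", f"T{t}"))
        ann = AnnotationMap(gene_terms=gene_terms, background=background)
        n = int(rng.integers(1, N + 1))
        query = set(rng.choice(sorted(background), size=n, replace=False))
        for r in enrich_terms(query, ann, "BP"):
            assert r.p_raw == pytest.approx(
                brute_force_upper_tail(r.N, r.K, r.n, r.k), rel=1e-9
            )
            assert r.k <= min(r.K, r.n)
            assert r.p_adjusted >= r.p_raw

    def test_bh_adjustment_monotone_after_stepup(self):
        rng = np.random.default_rng(0)
        N = 40
        background = {f"g{i}" for i in range(N)}
        gene_terms = {}
        for t in range(10):
            K = int(rng.integers(2, 20))
            for g in rng.choice(sorted(background), size=K, replace=False):
                gene_terms.setdefault(g, set()).add(("BP", f"T{t}"))
        ann = AnnotationMap(gene_terms=gene_terms, background=background)
        results = enrich_terms(set(list(background)[:10]), ann, "BP")
        adjusted = [r.p_adjusted for r in results]  # sorted by p_raw
        assert adjusted == sorted(adjusted)


class TestTermFilters:
    @pytest.fixture
    def planted(self):
        background = {f"g{i}" for i in range(200)}
        mod_genes = {f"g{i}" for i in range(6)}
        gene_terms = {}
        for ns in ("BP", "MF", "CC"):
            for g in mod_genes:
                gene_terms.setdefault(g, set()).add((ns, f"{ns}:mod"))
        ann = AnnotationMap(gene_terms=gene_terms, background=background)
        return module(mod_genes), ann

    def test_identical_terms_kept_with_proportion_one(self, planted):
        mod, ann = planted
        reference = {(ns, f"{ns}:mod") for ns in ("BP", "MF", "CC")}
        kept, report = term_overlap_filter([mod], reference, ann, min_proportion=0.2)
        assert kept == [mod]
        assert all(report[0][ns] == 1.0 for ns in ("BP", "MF", "CC"))

    def test_no_common_terms_in_one_namespace_drops(self, planted):
        mod, ann = planted
        reference = {("BP", "BP:mod"), ("MF", "MF:other"), ("CC", "CC:mod")}
        kept, report = term_overlap_filter([mod], reference, ann, min_proportion=0.1)
        assert kept == []
        assert report[0]["MF"] == 0.0

    def test_partial_proportion_value(self):
        background = {f"g{i}" for i in range(300)}
        mod_genes = {f"g{i}" for i in range(6)}
        gene_terms = {}
        for t in range(6):  # six significant BP terms, three shared with reference
            for g in mod_genes:
                gene_terms.setdefault(g, set()).add(("BP", f"B{t}"))
        for ns in ("MF", "CC"):
            for g in mod_genes:
                gene_terms.setdefault(g, set()).add((ns, f"{ns}:mod"))
        ann = AnnotationMap(gene_terms=gene_terms, background=background)
        reference = {("BP", "B0"), ("BP", "B1"), ("BP", "B2")} | {
            (ns, f"{ns}:mod") for ns in ("MF", "CC")
        }
        _, report = term_overlap_filter([module(mod_genes)], reference, ann)
        assert report[0]["BP"] == pytest.approx(0.5)

    def test_module_without_significant_terms_dropped(self, planted):
        mod, ann = planted
        bare = module({f"g{i}" for i in range(100, 104)})  # annotated by nothing
        reference = {(ns, f"{ns}:mod") for ns in ("BP", "MF", "CC")}
        kept, report = term_overlap_filter([mod, bare], reference, ann)
        assert kept == [mod]
        assert "no significant" in report[1]["reason"]

    def test_disease_filter_requires_every_disease_and_namespace(self, planted):
        mod, ann = planted
        full = {(ns, f"{ns}:mod") for ns in ("BP", "MF", "CC")}
        no_cc = {(ns, f"{ns}:mod") for ns in ("BP", "MF")}
        assert disease_term_filter([mod], {"d1": full, "d2": full}, ann) == [mod]
        assert disease_term_filter([mod], {"d1": full, "d2": no_cc}, ann) == []
        assert disease_term_filter([mod], {"d1": set()}, ann) == []


class TestNeighborOps:
    @pytest.fixture
    def net(self):
        return WeightedNetwork.from_edges(
            [
                ("m1", "m2", 1.0),
                ("m1", "n1", 0.3),
                ("m2", "n1", 0.5),
                ("m2", "n2", 0.2),
                ("n2", "n3", 0.9),
            ]
        )

    def test_score_sums_edges_into_module(self, net):
        assert neighbor_score(net, {"m1", "m2"}, "n1") == pytest.approx(0.8)
        assert neighbor_score(net, {"m1", "m2"}, "n3") == 0.0

    def test_score_full_star(self):
        net = WeightedNetwork.from_edges([(f"m{i}", "x", 1.0) for i in range(4)])
        assert neighbor_score(net, {f"m{i}" for i in range(4)}, "x") == 4.0

    def test_gene_inside_module_error(self, net):
        with pytest.raises(ValueError, match="inside"):
            neighbor_score(net, {"m1", "m2"}, "m1")

    def test_first_order_neighbors(self, net):
        assert first_order_neighbors(net, {"m1", "m2"}) == {"n1", "n2"}

    def test_threshold_constant_scores(self):
        net = WeightedNetwork.from_edges(
            [("m1", "n1", 0.4), ("m1", "n2", 0.4), ("m1", "n3", 0.4)]
        )
        thr = neighbor_threshold(net, {"m1"}, n_samples=1000, rank=50, seed=1)
        assert thr == pytest.approx(0.4)

    def test_threshold_picks_high_scorer(self, net):
        # neighbors n1 (0.8) and n2 (0.2); 50th of 1000 draws is 0.8 w.h.p.
        thr = neighbor_threshold(net, {"m1", "m2"}, n_samples=1000, rank=50, seed=1)
        assert thr == pytest.approx(0.8)

    def test_threshold_rank_equals_n_samples_is_minimum(self, net):
        thr = neighbor_threshold(net, {"m1", "m2"}, n_samples=500, rank=500, seed=1)
        assert thr == pytest.approx(0.2)

    def test_threshold_validation(self, net):
        with pytest.raises(ValueError, match="rank"):
            neighbor_threshold(net, {"m1", "m2"}, n_samples=10, rank=11)
        with pytest.raises(ValueError, match="no first-order"):
            neighbor_threshold(net, {"n3", "n2", "m2", "m1", "n1"}, n_samples=10, rank=1)

    def test_threshold_two_seeds_agree_on_big_samples(self, net):
        a = neighbor_threshold(net, {"m1", "m2"}, n_samples=200_000, rank=50, seed=1)
        b = neighbor_threshold(net, {"m1", "m2"}, n_samples=200_000, rank=50, seed=2)
        assert a == b  # far into the upper tail, both hit the top score

    def test_conserved_neighbors_strict_inequality(self, net):
        assert conserved_neighbors(net, {"m1", "m2"}, 0.5) == {"n1"}
        assert conserved_neighbors(net, {"m1", "m2"}, 0.8) == set()
        assert conserved_neighbors(net, {"m1", "m2"}, 0.0) == {"n1", "n2"}

    def test_conserved_above_all_scores_empty(self, net):
        assert conserved_neighbors(net, {"m1", "m2"}, 99.0) == set()


class TestPathwayOverlap:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"p1", "p2", "p3", "p4"}, {"p1", "p2", "p3", "p4"}, 4),
            ({"p1"}, {"p2"}, 0),
            ({"p1", "p2", "p3"}, {"p2", "p3", "p4"}, 2),
        ],
    )
    def test_counts(self, a, b, expected):
        assert pathway_overlap_count(a, b) == expected

    def test_top_k_selection(self):
        mods = [module({"a", "b"}, r) for r in (1, 2, 3)]
        scored = list(zip(mods, [3.0, 8.0, 8.0]))
        top = top_k_modules(scored, k=2)
        assert [m.rank for m in top] == [2, 3]  # tie broken by discovery rank


class TestFormats:
    def test_gmt_round_trip(self, tmp_path):
        sets = {"s1": {"a", "b"}, "s2": {"c"}}
        p = tmp_path / "x.gmt"
        write_gmt(sets, p)
        assert read_gmt(p) == sets

    def test_annotation_round_trip(self, tmp_path):
        ann = AnnotationMap(
            gene_terms={"a": {("BP", "T1"), ("MF", "T2")}, "b": {("BP", "T1")}},
            background={"a", "b"},
        )
        p = tmp_path / "ann.tsv"
        write_annotation(ann, p)
        back = read_annotation(p)
        assert back.gene_terms == ann.gene_terms

    def test_annotated_gene_outside_background_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            AnnotationMap(gene_terms={"a": {("BP", "T")}}, background={"b"})
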