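"""Category schemes, anchor propagation and term/gene categorization."""

import pytest

from gocat.annotation_ic import AnnotationSet, ICTable
from gocat.categorizer import (
    DEFAULT_THRESHOLD,
    CategoryScheme,
    SchemeError,
    build_anchor_map,
    categorize_gene,
    categorize_geneset,
    categorize_term,
    load_category_scheme,
    read_assignments,
    write_assignments,
)
from gocat.fixtures import random_ontology
from gocat.ontology import OntologyGraph

from conftest import naive_similarity, random_ic_table


# ---------------------------------------------------------------------------
# Independent oracle: fixpoint labelling + definitional similarity scores

def naive_categorize_term(
    graph: OntologyGraph,
    table: ICTable,
    scheme: CategoryScheme,
    t: str,
    mode: str,
    threshold: float,
) -> list[tuple[str, float]]:
    """Reference categorization by fixpoint label propagation.

    Labels (seeds plus single-category resolutions) are iterated to a
    fixpoint in arbitrary order rather than topologically, and similarities
    are recomputed from the definitional formulas.
    """
    label = {}
    for cat, seeds in scheme.categories.items():
        for s in seeds:
            label[s] = cat
    changed = True
    while changed:
        changed = False
        for term in graph.terms:
            if term in label:
                continue
            cats = {
                label[a] for a in graph.ancestors(term) | {term} if a in label
            }
            if len(cats) == 1:
                label[term] = next(iter(cats))
                changed = True

    anchors = [
        (label[a], a) for a in sorted(graph.ancestors(t) | {t}) if a in label
    ]
    if not anchors:
        return []
    cats = {c for c, _ in anchors}
    if len(cats) == 1:
        return [(next(iter(cats)), 1.0)]
    scores: dict[str, float] = {}
    for cat, anchor in anchors:
        s = 1.0 if anchor == t else naive_similarity(graph, table, t, anchor)
        scores[cat] = max(scores.get(cat, -1.0), s)
    best = max(scores.values())
    if mode == "best":
        return [(min(c for c, s in scores.items() if s == best), best)]
    keep = [(c, s) for c, s in scores.items() if s >= threshold or s == best]
    return sorted(keep, key=lambda cs: (-cs[1], cs[0]))


class TestLoadScheme:
    def test_nine_category_file(self, tmp_path):
        from gocat.schemes import load_shipped_scheme

        scheme = load_shipped_scheme("hd_modifiers")
        assert len(scheme) == 9
        assert all(len(seeds) == 1 for seeds in scheme.categories.values())
        assert scheme.categories["cell_cycle"] == {"GO:0007049"}

    def test_seeds_accumulate_per_category(self, tmp_path):
        path = tmp_path / "scheme.tsv"
        path.write_text("X\tG21\nX\tG22\n")
        scheme = load_category_scheme(path)
        assert scheme.categories == {"X": {"G21", "G22"}}

    def test_duplicate_seed_across_categories_rejected(self, tmp_path):
        path = tmp_path / "scheme.tsv"
        path.write_text("X\tG21\nY\tG21\n")
        with pytest.raises(SchemeError, match="listed under both"):
            load_category_scheme(path)

    def test_empty_scheme_rejected(self, tmp_path):
        path = tmp_path / "scheme.tsv"
        path.write_text("# only comments\n")
        with pytest.raises(SchemeError, match="empty"):
            load_category_scheme(path)

    def test_unresolvable_seed_listed(self, toy, tmp_path):
        path = tmp_path / "scheme.tsv"
        path.write_text("X\tG22\nY\tG99\n")
        with pytest.raises(SchemeError, match="G99"):
            load_category_scheme(path, graph=toy.graph)


class TestAnchorMap:
    def test_single_category_resolutions(self, toy):
        amap = build_anchor_map(toy.graph, toy.scheme)
        assert amap.single_category["G31"] == "A"
        assert amap.single_category["G33"] == "B"
        assert amap.single_category["G42"] == "B"

    def test_multi_parent_terms_not_resolved(self, toy):
        amap = build_anchor_map(toy.graph, toy.scheme)
        for t in ("G32", "G41", "G43"):
            assert t not in amap.single_category

    def test_anchors_of_g43_span_both_categories(self, toy):
        amap = build_anchor_map(toy.graph, toy.scheme)
        assert amap.anchors["G43"] == {
            ("A", "G31"), ("A", "G22"), ("B", "G33"), ("B", "G23"),
        }

    def test_uncovered_term_has_no_anchors(self, toy):
        amap = build_anchor_map(toy.graph, toy.scheme)
        assert amap.anchors["G21"] == set()
        assert amap.anchors["G0"] == set()

    def test_anchor_is_ancestor_or_self(self, toy):
        amap = build_anchor_map(toy.graph, toy.scheme)
        for t, anchors in amap.anchors.items():
            for _, a in anchors:
                assert a == t or toy.graph.is_ancestor(a, t)


class TestCategorizeTerm:
    def test_single_anchor_scores_one(self, toy):
        amap = build_anchor_map(toy.graph, toy.scheme)
        assert categorize_term(toy.graph, toy.ic, amap, "G31") == [("A", 1.0)]

    def test_seed_term_owns_its_category(self, toy):
        amap = build_anchor_map(toy.graph, toy.scheme)
        assert categorize_term(toy.graph, toy.ic, amap, "G22") == [("A", 1.0)]

    def test_best_mode_picks_larger_score(self, toy):
        amap = build_anchor_map(toy.graph, toy.scheme)
        result = categorize_term(toy.graph, toy.ic, amap, "G32", mode="best")
        assert len(result) == 1
        cat, score = result[0]
        assert cat == "A"
        assert score == pytest.approx(0.815, abs=1e-3)

    def test_multi_mode_default_threshold(self, toy):
        """At the 0.3 cutoff the deep multi-parent term joins one category only."""
        amap = build_anchor_map(toy.graph, toy.scheme)
        result = categorize_term(
            toy.graph, toy.ic, amap, "G43", mode="multi", threshold=0.3
        )
        assert [cat for cat, _ in result] == ["A"]

    def test_uncovered_term_empty(self, toy):
        amap = build_anchor_map(toy.graph, toy.scheme)
        assert categorize_term(toy.graph, toy.ic, amap, "G21") == []

    def test_argmax_included_below_threshold(self, toy):
        """multi mode always reports the best category, even under the cutoff."""
        amap = build_anchor_map(toy.graph, toy.scheme)
        result = categorize_term(
            toy.graph, toy.ic, amap, "G43", mode="multi", threshold=0.99
        )
        assert [cat for cat, _ in result] == ["A"]

    def test_invalid_inputs(self, toy):
        amap = build_anchor_map(toy.graph, toy.scheme)
        with pytest.raises(ValueError, match="threshold"):
            categorize_term(toy.graph, toy.ic, amap, "G32", threshold=1.5)
        with pytest.raises(ValueError, match="mode"):
            categorize_term(toy.graph, toy.ic, amap, "G32", mode="all")

    def test_scores_bounded_and_one_iff_single_or_seed(self, toy):
        amap = build_anchor_map(toy.graph, toy.scheme)
        for t in toy.graph.terms:
            for cat, score in categorize_term(toy.graph, toy.ic, amap, t):
                assert 0.0 <= score <= 1.0
                if score == 1.0:
                    assert (
                        t in amap.single_category
                        or t in toy.scheme.categories[cat]
                    )

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("mode", ["best", "multi"])
    def test_matches_naive_reference(self, seed, mode):
        graph = random_ontology(45, max_parents=3, seed=seed)
        table = random_ic_table(graph, seed=seed)
        terms = sorted(graph.terms)
        scheme = CategoryScheme(
            name="rand",
            categories={"C1": {terms[2]}, "C2": {terms[5]}, "C3": {terms[9]}},
        )
        amap = build_anchor_map(graph, scheme)
        for t in terms:
            got = categorize_term(graph, table, amap, t, mode=mode, threshold=0.3)
            want = naive_categorize_term(graph, table, scheme, t, mode, 0.3)
            assert [c for c, _ in got] == [c for c, _ in want]
            for (_, s1), (_, s2) in zip(got, want):
                assert s1 == pytest.approx(s2)


class TestCategorizeGene:
    @pytest.fixture()
    def toy_ann(self):
        return AnnotationSet(
            records=[
                ("g1", "G32"),
                ("g2", "G31"), ("g2", "G33"),
                ("g3", "G21"),
            ]
        )

    def test_single_annotation_passthrough(self, toy, toy_ann):
        amap = build_anchor_map(toy.graph, toy.scheme)
        a = categorize_gene(toy.graph, toy.ic, amap, toy_ann, "g1", mode="best")
        assert [c for c, _, _ in a.assigned] == ["A"]
        assert a.assigned[0][2] == "G32"

    def test_two_single_category_terms(self, toy, toy_ann):
        amap = build_anchor_map(toy.graph, toy.scheme)
        a = categorize_gene(toy.graph, toy.ic, amap, toy_ann, "g2")
        assert {(c, s) for c, s, _ in a.assigned} == {("A", 1.0), ("B", 1.0)}

    def test_uncovered_gene_unclassified(self, toy, toy_ann):
        amap = build_anchor_map(toy.graph, toy.scheme)
        a = categorize_gene(toy.graph, toy.ic, amap, toy_ann, "g3")
        assert a.unclassified
        assert a.assigned == []

    def test_unknown_gene_raises(self, toy, toy_ann):
        amap = build_anchor_map(toy.graph, toy.scheme)
        with pytest.raises(KeyError):
            categorize_gene(toy.graph, toy.ic, amap, toy_ann, "gX")


class TestCategorizeGeneset:
    def test_counts_from_single_category_terms(self, toy):
        ann = AnnotationSet(records=[("g1", "G31"), ("g2", "G33")])
        amap = build_anchor_map(toy.graph, toy.scheme)
        _, counts = categorize_geneset(
            toy.graph, toy.ic, amap, ann, ["g1", "g2"]
        )
        assert counts["A"] == 1
        assert counts["B"] == 1
        assert counts["unclassified"] == 0

    def test_all_unclassified(self, toy):
        ann = AnnotationSet(records=[("g1", "G21")])
        amap = build_anchor_map(toy.graph, toy.scheme)
        _, counts = categorize_geneset(toy.graph, toy.ic, amap, ann, ["g1", "g2"])
        assert counts == {"unclassified": 2}

    def test_counts_order_invariant(self, toy):
        ann = AnnotationSet(
            records=[("g1", "G31"), ("g2", "G33"), ("g3", "G32"), ("g4", "G43")]
        )
        amap = build_anchor_map(toy.graph, toy.scheme)
        genes = ["g1", "g2", "g3", "g4"]
        _, c1 = categorize_geneset(toy.graph, toy.ic, amap, ann, genes)
        _, c2 = categorize_geneset(toy.graph, toy.ic, amap, ann, genes[::-1])
        assert c1 == c2

    def test_empty_gene_list_rejected(self, toy):
        amap = build_anchor_map(toy.graph, toy.scheme)
        with pytest.raises(ValueError):
            categorize_geneset(toy.graph, toy.ic, amap, AnnotationSet(), [])

    def test_irrelevant_category_changes_nothing(self, toy):
        """A category seeded outside every annotated lineage is inert."""
        ann = AnnotationSet(records=[("g1", "G31"), ("g2", "G32"), ("g3", "G43")])
        genes = ["g1", "g2", "g3"]
        amap = build_anchor_map(toy.graph, toy.scheme)
        base, _ = categorize_geneset(toy.graph, toy.ic, amap, ann, genes)

        wider = CategoryScheme(
            name="wider",
            categories={**{k: set(v) for k, v in toy.scheme.categories.items()},
                        "C": {"G21"}},
        )
        amap2 = build_anchor_map(toy.graph, wider)
        out, _ = categorize_geneset(toy.graph, toy.ic, amap2, ann, genes)
        for a, b in zip(base, out):
            assert a.gene == b.gene
            assert a.assigned == b.assigned


def test_assignment_tsv_round_trip(toy, tmp_path):
    ann = AnnotationSet(records=[("g1", "G31"), ("g2", "G32"), ("g3", "G21")])
    amap = build_anchor_map(toy.graph, toy.scheme)
    assignments, _ = categorize_geneset(
        toy.graph, toy.ic, amap, ann, ["g1", "g2", "g3"]
    )
    path = tmp_path / "assignments.tsv"
    write_assignments(assignments, path)
    loaded = {a.gene: a for a in read_assignments(path)}
    for a in assignments:
        b = loaded[a.gene]
        assert b.unclassified == a.unclassified
        assert [(c, t) for c, _, t in b.assigned] == [(c, t) for c, _, t in a.assigned]
        for (_, s1, _), (_, s2, _) in zip(b.assigned, a.assigned):
            assert s1 == pytest.approx(s2, abs=1e-6)


def test_default_threshold_value():
    assert DEFAULT_THRESHOLD == 0.3
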