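"""Deterministic toy instances and synthetic generators for testing and demos.

`toy_instance` builds the worked eleven-term example used throughout the
documentation: a single-rooted DAG in which term G22 (category A) and G23
(category B) are user-assigned seeds, with hand-set information content
scores.  The ICs of G0, G22, G32, G41 and G43 (and every α/β/γ/S value in
``printed``) are authoritative reference values; the remaining ICs are
synthetic placeholders chosen to respect edge monotonicity and to keep the
example's categorization outcomes (G31→A, G33/G42→B, G32/G41→A, G43→A only
at the 0.3 cutoff), and must not be treated as reference values.

`random_ontology` and `synthetic_corpus` generate arbitrary single-rooted
DAGs and depth-skewed annotation corpora for property tests;
`spike_in_geneset` builds enrichment positive controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation_ic import AnnotationSet, ICTable
from .categorizer import Assignment, CategoryScheme
from .ontology import OntologyGraph, graph_from_edges

#: Edges (child, parent) of the toy eleven-term DAG.
TOY_EDGES: list[tuple[str, str]] = [
    ("G11", "G0"),
    ("G21", "G11"),
    ("G22", "G11"),
    ("G23", "G11"),
    ("G31", "G22"),
    ("G32", "G22"),
    ("G32", "G23"),
    ("G33", "G23"),
    ("G42", "G23"),
    ("G41", "G32"),
    ("G43", "G31"),
    ("G43", "G33"),
]

#: Reference ICs of the toy instance (authoritative entries only).
TOY_REFERENCE_IC = {"G0": 0.0, "G22": 12.20, "G32": 12.31, "G41": 13.17, "G43": 13.90}

#: Synthetic placeholder ICs — monotone fillers, not reference values.
TOY_PLACEHOLDER_IC = {
    "G11": 1.0,
    "G21": 3.0,
    "G23": 5.8,
    "G31": 12.23,
    "G33": 11.75,
    "G42": 12.0,
}


@dataclass
class ToyInstance:
    """The worked toy example: graph, injected ICs, scheme, reference values."""

    graph: OntologyGraph
    ic: ICTable
    scheme: CategoryScheme
    #: Reference quantities of the worked example, asserted in one place.
    printed: dict[str, float] = field(default_factory=dict)


def toy_instance() -> ToyInstance:
    """Build the deterministic worked example (seeds: A = G22, B = G23)."""
    graph = graph_from_edges(TOY_EDGES)
    ic_values = dict(TOY_REFERENCE_IC, **TOY_PLACEHOLDER_IC)
    table = ICTable(
        p={t: float(np.exp(-v)) for t, v in ic_values.items()},
        ic=dict(ic_values),
        corpus_meta={"n_records": 0, "namespace_totals": {"toy": 0},
                     "log_base": "e", "injected": "toy_instance"},
    )
    scheme = CategoryScheme(name="toy", categories={"A": {"G22"}, "B": {"G23"}})
    printed = {
        "alpha_G22": 12.20,
        "beta_G32_G22": 1.28,
        "gamma_G32_G22": 0.11,
        "S_G22_G32": 0.815,
        "S_G22_G41": 0.475,
        "S_G22_G43": 0.346,
    }
    return ToyInstance(graph=graph, ic=table, scheme=scheme, printed=printed)



def toy_two_record_annotations() -> AnnotationSet:
    """The two-record corpus {(p1, G21), (p2, G22)} of the IC walk-through."""
    return AnnotationSet(records=[("p1", "G21"), ("p2", "G22")])


def random_ontology(n_terms: int, max_parents: int = 3, seed: int = 0) -> OntologyGraph:
    """Random connected single-rooted DAG with 1..max_parents parents per term.

    Terms are named T000, T001, ... with T000 the root; each later term
    attaches to parents among earlier terms, so acyclicity holds by
    construction and the edge set is a deterministic function of the seed.
    """
    if n_terms < 2:
        raise ValueError(f"need at least 2 terms, got {n_terms}")
    if max_parents < 1:
        raise ValueError("max_parents must be >= 1")
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_terms - 1)))
    names = [f"T{i:0{width}d}" for i in range(n_terms)]
    edges: list[tuple[str, str]] = []
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(max_parents, i) + 1))
        parents = rng.choice(i, size=k, replace=False)
        for p in sorted(parents):
            edges.append((names[i], names[int(p)]))
    return graph_from_edges(edges)


def _depths(graph: OntologyGraph) -> dict[str, int]:
    """Longest-path depth from the root, per term."""
    depth = {}
    for t in graph.topological_order():
        parents = graph.parents(t)
        depth[t] = 0 if not parents else 1 + max(depth[p] for p in parents)
    return depth


def synthetic_corpus(
    graph: OntologyGraph,
    n_genes: int,
    ann_per_gene: int = 3,
    skew: float = 1.0,
    seed: int = 0,
) -> AnnotationSet:
    """Random annotation corpus with depth-skewed term usage.

    Term weights are proportional to exp(skew · depth): positive skew biases
    annotations toward deep (specific) terms, emulating real curation;
    skew = 0 gives uniform term usage.  Each gene receives up to
    ``ann_per_gene`` distinct terms.
    """
    if len(graph) == 0:
        raise ValueError("empty graph")
    rng = np.random.default_rng(seed)
    terms = sorted(graph.terms)
    depth = _depths(graph)
    w = np.array([np.exp(skew * depth[t]) for t in terms])
    w = w / w.sum()
    records = []
    n_digits = max(4, len(str(n_genes)))
    k = min(ann_per_gene, len(terms))
    for i in range(n_genes):
        gene = f"g{i:0{n_digits}d}"
        chosen = rng.choice(len(terms), size=k, replace=False, p=w)
        for j in sorted(chosen):
            records.append((gene, terms[int(j)]))
    return AnnotationSet(records=records)


def spike_in_geneset(
    background: list[Assignment],
    category: str,
    fraction: float,
    size: int,
    seed: int = 0,
) -> list[str]:
    """Test gene list enriched for ``category`` by construction.

    A ``fraction`` of the list is drawn from the category's member genes,
    the remainder uniformly from the whole background; used as a positive
    control for the enrichment test.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    members = sorted(a.gene for a in background if category in a.categories)
    all_genes = sorted(a.gene for a in background)
    if not members:
        raise ValueError(f"category {category!r} has no member genes in background")
    n_member = round(fraction * size)
    if n_member > len(members):
        raise ValueError(
            f"category {category!r} has only {len(members)} members, "
            f"need {n_member}"
        )
    rng = np.random.default_rng(seed)
    picked = list(rng.choice(members, size=n_member, replace=False))
    rest_pool = [g for g in all_genes if g not in set(picked)]
    n_rest = size - n_member
    if n_rest > len(rest_pool):
        raise ValueError("background too small for requested test-set size")
    picked += list(rng.choice(rest_pool, size=n_rest, replace=False))
    return [str(g) for g in picked]
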