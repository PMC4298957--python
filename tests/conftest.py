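"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from gocat.annotation_ic import AnnotationSet, ICTable
from gocat.fixtures import random_ontology, synthetic_corpus, toy_instance
from gocat.ontology import OntologyGraph


@pytest.fixture(scope="session")
def toy():
    return toy_instance()


@pytest.fixture()
def small_random_graph() -> OntologyGraph:
    return random_ontology(50, max_parents=3, seed=11)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive; never share code with the package)

def ancestors_by_expansion(graph: OntologyGraph, term: str) -> set[str]:
    """Ancestors via repeated single-step parent expansion."""
    out: set[str] = set()
    frontier = {term}
    while frontier:
        parents = set()
        for t in frontier:
            parents |= graph.parents(t)
        frontier = parents - out
        out |= parents
    return out


def counts_by_record_closure(graph: OntologyGraph, ann: AnnotationSet) -> dict[str, int]:
    """Propagated counts by accumulating each record's ancestor closure."""
    counts = dict.fromkeys(graph.terms, 0)
    for _, term in ann.records:
        for t in ancestors_by_expansion(graph, term) | {term}:
            counts[t] += 1
    return counts


def naive_similarity(graph: OntologyGraph, table: ICTable, x: str, p: str) -> float:
    """S recomputed from the definitional formulas with explicit enumeration."""
    root = graph.root_of(p)
    a = abs(table.ic[p] - table.ic[root])

    def mic_ic(t: str) -> float:
        desc = graph.descendants(t)
        return max(table.ic[d] for d in desc) if desc else table.ic[t]

    b = (abs(table.ic[p] - mic_ic(p)) + abs(table.ic[x] - mic_ic(x))) / 2.0
    g = abs(table.ic[x] - table.ic[p])
    if a + b == 0:
        return min(1.0, 1.0 / (1.0 + g))
    return min(1.0, (a / (a + b)) / (1.0 + g))


def random_ic_table(graph: OntologyGraph, seed: int = 0) -> ICTable:
    """Edge-monotone random IC values for a graph (root gets 0)."""
    rng = np.random.default_rng(seed)
    ic: dict[str, float] = {}
    for t in graph.topological_order():
        parents = graph.parents(t)
        base = max((ic[p] for p in parents), default=0.0)
        ic[t] = 0.0 if not parents else base + float(rng.uniform(0.0, 3.0))
    return ICTable(
        p={t: float(np.exp(-v)) for t, v in ic.items()},
        ic=ic,
        corpus_meta={"log_base": "e", "injected": "random_ic_table"},
    )


@pytest.fixture()
def corpus_with_ic():
    """A mid-sized random graph plus a synthetic corpus and computed ICs."""
    from gocat.annotation_ic import build_ic_table

    graph = random_ontology(60, max_parents=3, seed=5)
    ann = synthetic_corpus(graph, n_genes=80, ann_per_gene=3, skew=1.0, seed=5)
    return graph, ann, build_ic_table(graph, ann)
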