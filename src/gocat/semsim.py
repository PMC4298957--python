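"""Parent–child semantic similarity from information-content distances.

Categorization asks how well a term *belongs to* an ancestor, not merely how
alike two terms are, so the score is defined only for pairs in an ancestor
relation.  For a term x and a category-assigned ancestor p it combines three
IC distances (d(a, b) = |I(a) − I(b)|, valid along ancestor paths):

    α = d(root, p)                      specificity of the anchor itself
    β = (d(p, mic(p)) + d(x, mic(x)))/2 mean distance to the most
                                        informative descendants (a leaf is
                                        its own most informative descendant)
    γ = d(p, x)                         specificity gap between the pair

    S(p, x) = (α / (α + β)) · (1 / (1 + γ)),   0 ≤ S ≤ 1

A deep (specific) anchor whose subtree adds little extra information and
that sits close to x scores near 1; a shallow anchor over a deep, spread-out
subtree scores near 0.  In the degenerate case α + β = 0 (a root-level
anchor with no informative descendants) the first factor is taken as 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .annotation_ic import ICTable
from .ontology import OntologyGraph

logger = logging.getLogger(__name__)


class SimilarityDomainError(ValueError):
    """Raised when a similarity is requested for terms not in an ancestor relation."""


@dataclass(frozen=True)
class SimilarityBreakdown:
    """The α, β, γ components and the combined score S for one (anchor, term) pair."""

    anchor: str
    term: str
    alpha: float
    beta: float
    gamma: float
    s: float


def _require_related(graph: OntologyGraph, x1: str, x2: str) -> None:
    if x1 == x2:
        return
    if graph.is_ancestor(x1, x2) or graph.is_ancestor(x2, x1):
        return
    raise SimilarityDomainError(
        f"{x1!r} and {x2!r} are not in an ancestor-descendant relation"
    )


def ic_distance(graph: OntologyGraph, table: ICTable, x1: str, x2: str) -> float:
    """IC distance |I(x1) − I(x2)| for terms along one ancestor path."""
    _require_related(graph, x1, x2)
    return abs(table.ic[x1] - table.ic[x2])


def most_informative_descendant(
    graph: OntologyGraph, table: ICTable, x: str
) -> str:
    """The proper descendant of ``x`` with maximal IC; ``x`` itself for a leaf.

    Ties are broken by lexicographic term id for determinism.
    """
    desc = graph.descendants(x)
    if not desc:
        return x
    return max(sorted(desc), key=lambda t: table.ic[t])


def alpha(graph: OntologyGraph, table: ICTable, p: str) -> float:
    """Distance of the anchor ``p`` from its namespace root: I(p) − I(root) = I(p)."""
    root = graph.root_of(p)
    return ic_distance(graph, table, root, p)


def beta(graph: OntologyGraph, table: ICTable, x: str, p: str) -> float:
    """Mean IC distance of ``p`` and ``x`` to their most informative descendants."""
    if not (p == x or graph.is_ancestor(p, x)):
        raise SimilarityDomainError(f"{p!r} is not an ancestor of {x!r}")
    dp = ic_distance(graph, table, p, most_informative_descendant(graph, table, p))
    dx = ic_distance(graph, table, x, most_informative_descendant(graph, table, x))
    return (dp + dx) / 2.0


def gamma(graph: OntologyGraph, table: ICTable, x: str, p: str) -> float:
    """IC gap between the term and its anchor: I(x) − I(p) ≥ 0."""
    if not (p == x or graph.is_ancestor(p, x)):
        raise SimilarityDomainError(f"{p!r} is not an ancestor of {x!r}")
    return ic_distance(graph, table, p, x)


def combine_score(a: float, b: float, g: float) -> float:
    """Combine α, β, γ into S = (α/(α+β))·(1/(1+γ)), clamped to [0, 1].

    For α + β = 0 the anchor factor is taken as 1, leaving S = 1/(1+γ).
    """
    if a < 0 or b < 0 or g < 0:
        raise ValueError("alpha, beta and gamma must be nonnegative")
    if a + b == 0.0:
        logger.warning(
            "alpha + beta = 0: root-level anchor with no informative "
            "descendants; using S = 1/(1+gamma)"
        )
        s = 1.0 / (1.0 + g)
    else:
        s = (a / (a + b)) * (1.0 / (1.0 + g))
    return min(1.0, max(0.0, s))


def similarity(
    graph: OntologyGraph, table: ICTable, x: str, p: str
) -> SimilarityBreakdown:
    """Similarity S(p, x) of term ``x`` to its category-assigned ancestor ``p``.

    Requires ``p`` to be an ancestor of ``x`` (or ``p == x``); categorization
    never compares sibling terms.
    """
    a = alpha(graph, table, p)
    b = beta(graph, table, x, p)
    g = gamma(graph, table, x, p)
    return SimilarityBreakdown(
        anchor=p, term=x, alpha=a, beta=b, gamma=g, s=combine_score(a, b, g)
    )
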