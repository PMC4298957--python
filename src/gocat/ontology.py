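"""Gene Ontology graphs: OBO parsing, validation and ancestor/descendant queries.

The GO vocabulary is a directed acyclic graph (DAG), not a tree: a term may
have several parents, and there may be several paths from a term up to its
namespace root (``biological_process``, ``molecular_function`` or
``cellular_component``).  Parent–child closure is taken over a configurable
set of relations; by default ``is_a`` and ``part_of``, the two GO relations
that obey the true-path rule (an annotation to a term implies annotation to
every ancestor reached through them).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: Relations traversed for ancestor/descendant closure unless overridden.
DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})

#: Relations this package knows how to traverse.
KNOWN_RELATIONS = frozenset({"is_a", "part_of"})


class OntologyError(ValueError):
    """Raised for structural problems: cycles, unknown terms, bad relations."""


@dataclass(frozen=True)
class Term:
    """A single ontology term (one ``[Term]`` stanza)."""

    id: str
    name: str = ""
    namespace: str = "toy"
    obsolete: bool = False


@dataclass
class OntologyGraph:
    """A validated ontology DAG.

    Edges are stored child → parent in ``graph`` with a ``relation``
    attribute, so ``nx.descendants`` in that orientation yields *ancestors*.
    ``roots`` maps each namespace to its unique root term.  ``alt_ids`` maps
    secondary accessions to their primary term id.
    """

    terms: dict[str, Term] = field(default_factory=dict)
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    roots: dict[str, str] = field(default_factory=dict)
    alt_ids: dict[str, str] = field(default_factory=dict)
    relations: frozenset[str] = DEFAULT_RELATIONS

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, term_id: str) -> str | None:
        """Map a (possibly secondary) accession to its primary id, else None."""
        if term_id in self.terms:
            return term_id
        return self.alt_ids.get(term_id)

    def namespace_of(self, term_id: str) -> str:
        return self._lookup(term_id).namespace

    def root_of(self, term_id: str) -> str:
        return self.roots[self._lookup(term_id).namespace]

    def parents(self, term_id: str) -> set[str]:
        self._lookup(term_id)
        return set(self.graph.successors(term_id))

    def children(self, term_id: str) -> set[str]:
        self._lookup(term_id)
        return set(self.graph.predecessors(term_id))

    def ancestors(self, term_id: str) -> set[str]:
        """All proper ancestors of ``term_id`` (transitive closure of parents)."""
        self._lookup(term_id)
        return nx.descendants(self.graph, term_id)

    def descendants(self, term_id: str) -> set[str]:
        """All proper descendants of ``term_id``."""
        self._lookup(term_id)
        return nx.ancestors(self.graph, term_id)

    def is_ancestor(self, a: str, b: str) -> bool:
        """True if ``a`` is a proper ancestor of ``b``."""
        return a in self.ancestors(b)

    def is_leaf(self, term_id: str) -> bool:
        self._lookup(term_id)
        return self.graph.in_degree(term_id) == 0

    def topological_order(self) -> list[str]:
        """Term ids ordered so every parent precedes its children."""
        return list(reversed(list(nx.topological_sort(self.graph))))

    def _lookup(self, term_id: str) -> Term:
        try:
            return self.terms[term_id]
        except KeyError:
            raise OntologyError(f"unknown term id: {term_id!r}") from None

    def validate(self) -> None:
        """Check acyclicity, per-namespace roots and root reachability."""
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise OntologyError(
                f"ontology contains a cycle through {cycle[0][0]!r}"
            )
        for term_id, term in self.terms.items():
            root = self.roots.get(term.namespace)
            if root is None:
                raise OntologyError(
                    f"namespace {term.namespace!r} has no root (term {term_id!r})"
                )
            if term_id != root and root not in nx.descendants(self.graph, term_id):
                raise OntologyError(
                    f"term {term_id!r} cannot reach its namespace root {root!r}"
                )


def _build(
    terms: dict[str, Term],
    edges: list[tuple[str, str, str]],
    alt_ids: dict[str, str],
    relations: frozenset[str],
) -> OntologyGraph:
    """Assemble and validate an OntologyGraph from parsed pieces."""
    g = nx.DiGraph()
    g.add_nodes_from(terms)
    for child, parent, rel in edges:
        if rel not in relations:
            continue
        if child not in terms or parent not in terms:
            continue
        if terms[child].namespace != terms[parent].namespace:
            logger.warning(
                "dropping cross-namespace edge %s -> %s (%s)", child, parent, rel
            )
            continue
        g.add_edge(child, parent, relation=rel)

    roots: dict[str, str] = {}
    for term_id, term in terms.items():
        if g.out_degree(term_id) == 0:
            if term.namespace in roots:
                raise OntologyError(
                    f"namespace {term.namespace!r} has multiple roots: "
                    f"{roots[term.namespace]!r}, {term_id!r}"
                )
            roots[term.namespace] = term_id

    og = OntologyGraph(
        terms=terms, graph=g, roots=roots, alt_ids=alt_ids, relations=relations
    )
    og.validate()
    return og


def parse_obo(
    path: str | Path, relations: frozenset[str] | set[str] = DEFAULT_RELATIONS
) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 file into a validated :class:`OntologyGraph`.

    Obsolete terms are excluded entirely; ``alt_id`` accessions are recorded
    as aliases of their primary id.  Only edges whose relation is in
    ``relations`` (⊆ {is_a, part_of}) are kept.
    """
    relations = frozenset(relations)
    unknown = relations - KNOWN_RELATIONS
    if unknown:
        raise OntologyError(f"unknown relation(s) requested: {sorted(unknown)}")

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # obonet drops obsolete stanzas by default (ignore_obsolete=True)
    multigraph = obonet.read_obo(str(path))

    terms: dict[str, Term] = {}
    alt_ids: dict[str, str] = {}
    for node, data in multigraph.nodes(data=True):
        terms[node] = Term(
            id=node,
            name=data.get("name", ""),
            namespace=data.get("namespace", "toy"),
        )
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node

    edges = []
    for child, parent, rel in multigraph.edges(keys=True):
        edges.append((child, parent, rel))
    return _build(terms, edges, alt_ids, relations)


def load_edges_tsv(
    path: str | Path,
    relations: frozenset[str] | set[str] = DEFAULT_RELATIONS,
    namespace: str = "toy",
) -> OntologyGraph:
    """Load a toy ontology from a 3-column TSV: child, parent, relation.

    Lines starting with ``#`` are comments; the relation column may be
    omitted, defaulting to ``is_a``.
    """
    relations = frozenset(relations)
    terms: dict[str, Term] = {}
    edges: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 2:
                child, parent, rel = fields[0], fields[1], "is_a"
            elif len(fields) == 3:
                child, parent, rel = fields
            else:
                raise OntologyError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated columns"
                )
            for t in (child, parent):
                terms.setdefault(t, Term(id=t, namespace=namespace))
            edges.append((child, parent, rel))
    return _build(terms, edges, {}, relations)


def graph_from_edges(
    edges: list[tuple[str, str]] | list[tuple[str, str, str]],
    namespace: str = "toy",
    relations: frozenset[str] = DEFAULT_RELATIONS,
) -> OntologyGraph:
    """Build a toy graph from in-memory (child, parent[, relation]) tuples."""
    terms: dict[str, Term] = {}
    norm: list[tuple[str, str, str]] = []
    for e in edges:
        child, parent = e[0], e[1]
        rel = e[2] if len(e) == 3 else "is_a"
        for t in (child, parent):
            terms.setdefault(t, Term(id=t, namespace=namespace))
        norm.append((child, parent, rel))
    return _build(terms, norm, {}, relations)


def write_obo(graph: OntologyGraph, path: str | Path) -> None:
    """Serialize a graph to minimal OBO 1.2 (round-trips through parse_obo)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n\n")
        for term_id in sorted(graph.terms):
            term = graph.terms[term_id]
            fh.write("[Term]\n")
            fh.write(f"id: {term_id}\n")
            fh.write(f"name: {term.name or term_id}\n")
            fh.write(f"namespace: {term.namespace}\n")
            for _, parent, data in sorted(
                graph.graph.out_edges(term_id, data=True), key=lambda x: x[1]
            ):
                rel = data["relation"]
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")
            fh.write("\n")
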