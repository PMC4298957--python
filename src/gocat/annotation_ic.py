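"""Annotation corpora and information content (IC) on the GO DAG.

The IC of a term measures its biological specificity: frequently used terms
carry little information.  Occurrences are counted with the true-path rule —
an annotation to a term also counts toward every ancestor — so for a
two-record corpus {(p1, G21), (p2, G22)} on a toy graph rooted at G0 with
intermediate G11, the propagated counts are G0:2, G11:2, G21:1, G22:1.

Counts are converted per namespace:

    p(x) = count(x) / T_ns          (T_ns = records in x's namespace)
    I(x) = -log p(x)                (natural log by default)

so each namespace root has p = 1 and I = 0 — annotations with a root term
are biologically uninformative.  Terms never used in the corpus ("orphan"
terms) receive the smallest nonzero p of their namespace, i.e. the maximal
observed IC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

GAF_COLUMNS = 17
_GAF_GENE_COL = 1  # DB Object ID
_GAF_QUALIFIER_COL = 3
_GAF_TERM_COL = 4


class AnnotationError(ValueError):
    """Raised for malformed or empty annotation inputs."""


@dataclass
class AnnotationSet:
    """Deduplicated (gene, term) annotation records.

    ``skipped`` counts input lines excluded by rule (NOT qualifiers,
    unresolvable terms); they are reported, never silently dropped.
    """

    records: list[tuple[str, str]] = field(default_factory=list)
    skipped: dict[str, int] = field(default_factory=dict)

    @property
    def genes(self) -> set[str]:
        return {g for g, _ in self.records}

    def terms_of(self, gene: str) -> set[str]:
        return {t for g, t in self.records if g == gene}

    def by_gene(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for g, t in self.records:
            out.setdefault(g, set()).add(t)
        return out

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ICTable:
    """Occurrence probabilities p(x) ∈ (0, 1] and IC scores I(x) ≥ 0.

    ``corpus_meta`` records how the table was built: total record count,
    per-namespace totals and the log base tag (``e`` for natural log).
    """

    p: dict[str, float] = field(default_factory=dict)
    ic: dict[str, float] = field(default_factory=dict)
    corpus_meta: dict = field(default_factory=dict)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.ic

    def __getitem__(self, term_id: str) -> float:
        return self.ic[term_id]


def _detect_format(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "gaf" if first.startswith("!") else "tsv"


def load_annotations(
    path: str | Path,
    format: str = "auto",
    graph: OntologyGraph | None = None,
    exclude_evidence: set[str] | None = None,
) -> AnnotationSet:
    """Load gene→GO annotations from GAF 2.x or a 2-column TSV.

    GAF records with a ``NOT`` qualifier are excluded (negative annotations).
    If ``graph`` is given, term accessions are resolved through its alt_id
    map and unresolvable records are counted in ``skipped``.
    ``exclude_evidence`` drops GAF records by evidence code (e.g. {"IEA"}).
    """
    path = Path(path)
    if format == "auto":
        format = _detect_format(path)
    if format not in {"gaf", "tsv"}:
        raise AnnotationError(f"unknown annotation format: {format!r}")

    seen: set[tuple[str, str]] = set()
    records: list[tuple[str, str]] = []
    skipped = {"not_qualifier": 0, "unresolvable_term": 0, "evidence_excluded": 0}

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            fields = line.split("\t")
            if format == "gaf":
                if len(fields) < 15:
                    raise AnnotationError(
                        f"{path}:{lineno}: GAF line has {len(fields)} columns, "
                        f"expected >= 15"
                    )
                gene = fields[_GAF_GENE_COL]
                term = fields[_GAF_TERM_COL]
                qualifier = fields[_GAF_QUALIFIER_COL]
                evidence = fields[6] if len(fields) > 6 else ""
                if "NOT" in qualifier.split("|"):
                    skipped["not_qualifier"] += 1
                    continue
                if exclude_evidence and evidence in exclude_evidence:
                    skipped["evidence_excluded"] += 1
                    continue
            else:
                if len(fields) < 2:
                    raise AnnotationError(
                        f"{path}:{lineno}: expected 2 tab-separated columns"
                    )
                gene, term = fields[0], fields[1]
            if not gene or not term:
                raise AnnotationError(f"{path}:{lineno}: empty gene or term field")
            if graph is not None:
                resolved = graph.resolve(term)
                if resolved is None:
                    skipped["unresolvable_term"] += 1
                    continue
                term = resolved
            if (gene, term) not in seen:
                seen.add((gene, term))
                records.append((gene, term))

    if not records:
        raise AnnotationError(f"{path}: no usable annotation records")
    n_skipped = sum(skipped.values())
    if n_skipped:
        logger.warning("%s: skipped %d records (%s)", path, n_skipped, skipped)
    return AnnotationSet(records=records, skipped=skipped)


def propagate_counts(graph: OntologyGraph, ann: AnnotationSet) -> dict[str, int]:
    """Propagate annotation occurrences up the DAG (true-path rule).

    count(x) = number of records whose term is x or a descendant of x; each
    record contributes at most once per term even when the DAG offers several
    paths.  Every term of the graph appears in the result (orphans at 0).
    """
    counts = dict.fromkeys(graph.terms, 0)
    direct: dict[str, int] = {}
    for _, term in ann.records:
        if term not in graph:
            raise AnnotationError(f"annotation term {term!r} not in ontology")
        direct[term] = direct.get(term, 0) + 1
    for term, n in direct.items():
        counts[term] += n
        for anc in graph.ancestors(term):
            counts[anc] += n
    return counts


def compute_ic(
    graph: OntologyGraph,
    counts: dict[str, int],
    log_base: float | None = None,
) -> ICTable:
    """Convert propagated counts into occurrence probabilities and IC scores.

    ``log_base`` of None means natural log.  Raises if a namespace contains
    terms but received no records at all (its total would be zero).
    """
    ns_total: dict[str, int] = {}
    for ns, root in graph.roots.items():
        ns_total[ns] = counts.get(root, 0)

    log = math.log if log_base is None else (lambda v: math.log(v, log_base))

    # orphan terms get the smallest nonzero p of their namespace
    min_p: dict[str, float] = {}
    p: dict[str, float] = {}
    for term_id, term in graph.terms.items():
        total = ns_total[term.namespace]
        c = counts.get(term_id, 0)
        if c == 0:
            continue
        if total == 0:
            raise AnnotationError(
                f"namespace {term.namespace!r} has counted terms but zero total"
            )
        px = c / total
        p[term_id] = px
        if term.namespace not in min_p or px < min_p[term.namespace]:
            min_p[term.namespace] = px

    for term_id, term in graph.terms.items():
        if term_id in p:
            continue
        ns = term.namespace
        if ns_total[ns] == 0:
            raise AnnotationError(
                f"namespace {ns!r} has zero annotation records"
            )
        p[term_id] = min_p[ns]

    ic = {t: max(0.0, -log(px)) for t, px in p.items()}
    for root in graph.roots.values():
        ic[root] = 0.0

    meta = {
        "n_records": sum(ns_total.values()),
        "namespace_totals": dict(ns_total),
        "log_base": "e" if log_base is None else repr(log_base),
    }
    return ICTable(p=p, ic=ic, corpus_meta=meta)


def build_ic_table(
    graph: OntologyGraph, ann: AnnotationSet, log_base: float | None = None
) -> ICTable:
    """Convenience: propagate counts and compute IC in one call."""
    return compute_ic(graph, propagate_counts(graph, ann), log_base=log_base)


def save_ic(table: ICTable, path: str | Path, graph: OntologyGraph | None = None) -> None:
    """Write an IC table as TSV: term, namespace, p, ic, with #meta: headers."""
    with open(path, "w") as fh:
        for key, value in table.corpus_meta.items():
            fh.write(f"#meta:{key}={value}\n")
        fh.write("term\tnamespace\tp\tic\n")
        for term in sorted(table.p):
            ns = graph.namespace_of(term) if graph and term in graph else "."
            fh.write(f"{term}\t{ns}\t{table.p[term]:.17g}\t{table.ic[term]:.17g}\n")


def load_ic(path: str | Path, graph: OntologyGraph | None = None) -> ICTable:
    """Load an IC table written by :func:`save_ic`.

    Unknown term ids (relative to ``graph``) are retained with a warning;
    missing columns raise a parse error naming the first absent column.
    """
    path = Path(path)
    meta: dict = {}
    p: dict[str, float] = {}
    ic: dict[str, float] = {}
    header: list[str] | None = None
    unknown = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#meta:"):
                key, _, value = line[len("#meta:"):].partition("=")
                meta[key] = value
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                for col in ("term", "namespace", "p", "ic"):
                    if col not in header:
                        raise AnnotationError(
                            f"{path}: missing required column {col!r}"
                        )
                continue
            row = dict(zip(header, fields))
            term = row["term"]
            if graph is not None and term not in graph:
                unknown += 1
            p[term] = float(row["p"])
            ic[term] = float(row["ic"])
    if header is None:
        raise AnnotationError(f"{path}: empty IC table")
    if unknown:
        logger.warning("%s: %d term ids not in current ontology (retained)", path, unknown)
    return ICTable(p=p, ic=ic, corpus_meta=meta)
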