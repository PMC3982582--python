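"""Term graphs with transitive is_a/part_of reasoning.

Anatomy and phenotype vocabularies are loaded as directed acyclic graphs in
which every edge points from a child term to a parent term and carries one of
the two relations ``is_a`` or ``part_of``.  Ancestor queries traverse both
relations, freely interleaved; all other relationship types found in OBO
inputs are skipped (and counted).  Downstream classification assumes a
partial order, so cyclic inputs are rejected outright.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

RELATIONS = frozenset({"is_a", "part_of"})


class OntologyError(ValueError):
    """Raised for malformed or cyclic ontology inputs and unknown terms."""


class RelationCategory(enum.Enum):
    """How two terms relate under transitive is_a/part_of reachability."""

    IDENTICAL = "identical"
    FIRST_BELOW_SECOND = "first_below_second"
    SECOND_BELOW_FIRST = "second_below_first"
    UNRELATED = "unrelated"

    def mirror(self) -> "RelationCategory":
        """The category obtained by swapping the two query terms."""
        if self is RelationCategory.FIRST_BELOW_SECOND:
            return RelationCategory.SECOND_BELOW_FIRST
        if self is RelationCategory.SECOND_BELOW_FIRST:
            return RelationCategory.FIRST_BELOW_SECOND
        return self


@dataclass
class OntologyGraph:
    """A validated DAG of terms connected by is_a/part_of edges.

    Parameters
    ----------
    terms:
        All term identifiers (opaque strings such as ``"MA:0000168"``).
    edges:
        ``(child, relation, parent)`` triples; both endpoints must be in
        ``terms`` and ``relation`` must be ``is_a`` or ``part_of``.
    labels:
        Optional human-readable names keyed by term id.
    """

    terms: set[str] = field(default_factory=set)
    edges: set[tuple[str, str, str]] = field(default_factory=set)
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()
        self._graph = nx.DiGraph()
        self._graph.add_nodes_from(self.terms)
        self._graph.add_edges_from((c, p) for c, _, p in self.edges)
        self._check_acyclic()
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    def _validate(self) -> None:
        for child, relation, parent in self.edges:
            if relation not in RELATIONS:
                raise OntologyError(f"unknown relation token {relation!r}")
            if child not in self.terms or parent not in self.terms:
                raise OntologyError(
                    f"edge ({child}, {relation}, {parent}) references a term "
                    "outside the term set"
                )

    def _check_acyclic(self) -> None:
        if not nx.is_directed_acyclic_graph(self._graph):
            cycle = nx.find_cycle(self._graph)
            path = " -> ".join(str(edge[0]) for edge in cycle)
            raise OntologyError(f"cycle detected in ontology: {path} -> {cycle[0][0]}")

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms reachable from ``term`` via is_a/part_of, excluding itself."""
        if term not in self.terms:
            raise OntologyError(f"unknown term {term!r}")
        cached = self._ancestor_cache.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self._graph, term))
            self._ancestor_cache[term] = cached
        return cached

    def relate(self, a: str, b: str) -> RelationCategory:
        """Categorize the ordered pair ``(a, b)``.

        ``identical`` if the ids are equal, ``first_below_second`` if ``b``
        is an ancestor of ``a``, ``second_below_first`` if ``a`` is an
        ancestor of ``b``, else ``unrelated``.  Acyclicity guarantees the two
        middle cases are mutually exclusive for distinct terms.
        """
        if a not in self.terms:
            raise OntologyError(f"unknown term {a!r}")
        if b not in self.terms:
            raise OntologyError(f"unknown term {b!r}")
        if a == b:
            return RelationCategory.IDENTICAL
        if b in self.ancestors(a):
            return RelationCategory.FIRST_BELOW_SECOND
        if a in self.ancestors(b):
            return RelationCategory.SECOND_BELOW_FIRST
        return RelationCategory.UNRELATED

    def related(self, a: str, b: str) -> bool:
        """True iff the terms are identical or one is below the other."""
        return self.relate(a, b) is not RelationCategory.UNRELATED


# Module-level functional aliases matching the operation surface.

def ancestors(term: str, graph: OntologyGraph) -> frozenset[str]:
    """See :meth:`OntologyGraph.ancestors`."""
    return graph.ancestors(term)


def relate(a: str, b: str, graph: OntologyGraph) -> RelationCategory:
    """See :meth:`OntologyGraph.relate`."""
    return graph.relate(a, b)


def build_graph(
    rows: Iterable[tuple[str, str, str]],
    labels: Mapping[str, str] | None = None,
) -> OntologyGraph:
    """Assemble an :class:`OntologyGraph` from (child, relation, parent) rows."""
    terms: set[str] = set()
    edges: set[tuple[str, str, str]] = set()
    for child, relation, parent in rows:
        if relation not in RELATIONS:
            raise OntologyError(f"unknown relation token {relation!r}")
        terms.add(child)
        terms.add(parent)
        edges.add((child, relation, parent))
    return OntologyGraph(terms=terms, edges=edges, labels=dict(labels or {}))


def load_ontology(path: str | Path) -> OntologyGraph:
    """Load a term graph from a 3-column edge TSV or an OBO 1.2 file.

    The TSV format is ``child_id\\trelation\\tparent_id`` with relation
    tokens exactly ``is_a`` or ``part_of``; lines starting with ``#`` are
    comments.  Files whose first non-blank line is ``format-version:`` or
    that carry a ``.obo`` suffix are parsed as OBO.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix == ".obo" or _looks_like_obo(text):
        return _parse_obo(text)
    return _parse_edge_tsv(text)


def _looks_like_obo(text: str) -> bool:
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        return line.startswith("format-version:") or line == "[Term]"
    return False


def _parse_edge_tsv(text: str) -> OntologyGraph:
    rows: list[tuple[str, str, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[:3] == ["child_id", "relation", "parent_id"]:
            continue  # header
        if len(parts) != 3:
            raise OntologyError(
                f"line {lineno}: expected 3 tab-separated columns, got {len(parts)}"
            )
        child, relation, parent = (p.strip() for p in parts)
        if relation not in RELATIONS:
            raise OntologyError(
                f"line {lineno}: unknown relation token {relation!r}"
            )
        rows.append((child, relation, parent))
    return build_graph(rows)


def _parse_obo(text: str) -> OntologyGraph:
    """Minimal OBO 1.2 reader: [Term] stanzas, id:, name:, is_a:, relationship:.

    Relationship types other than part_of are skipped with a logged count;
    obsolete terms are ignored.
    """
    terms: set[str] = set()
    edges: set[tuple[str, str, str]] = set()
    labels: dict[str, str] = {}
    skipped_relations = 0

    current_id: str | None = None
    in_term = False
    obsolete = False
    pending: list[tuple[str, str]] = []  # (relation, parent) for current term

    def flush() -> None:
        nonlocal pending, current_id, obsolete
        if current_id and not obsolete:
            terms.add(current_id)
            for relation, parent in pending:
                terms.add(parent)
                edges.add((current_id, relation, parent))
        pending = []
        current_id = None
        obsolete = False

    for raw in text.splitlines():
        line = raw.split("!")[0].strip()
        if not line:
            continue
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            continue
        if not in_term:
            continue
        if line.startswith("id:"):
            current_id = line[3:].strip()
        elif line.startswith("name:") and current_id:
            labels[current_id] = line[5:].strip()
        elif line.startswith("is_obsolete:") and "true" in line:
            obsolete = True
        elif line.startswith("is_a:"):
            pending.append(("is_a", line[5:].strip()))
        elif line.startswith("relationship:"):
            fields = line[len("relationship:"):].strip().split()
            if len(fields) >= 2 and fields[0] == "part_of":
                pending.append(("part_of", fields[1]))
            else:
                skipped_relations += 1
    flush()

    if skipped_relations:
        logger.info("skipped %d non-is_a/part_of relationships", skipped_relations)
    return OntologyGraph(terms=terms, edges=edges, labels=labels)
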