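"""Ontologies as typed DAGs: OBO parsing, ancestor queries and profile closure.

The ontology graph is the substrate for everything downstream: information
content and simGIC work on annotation sets *closed* against the superclass
(is-a) relation, and the cross-species entity reasoning additionally walks
part-of edges in anatomy ontologies.  Only the is-a and part-of relations are
interpreted; the graph restricted to those edges must be acyclic.

Obsolete terms are kept as nodes (so ids still resolve) but are stripped of
their outgoing edges and never participate in closures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable

import networkx as nx

from .errors import ParseError, UnknownTermError, ValidationError

logger = logging.getLogger(__name__)


class Relation(str, Enum):
    """Edge types interpreted by the toolkit."""

    IS_A = "is_a"
    PART_OF = "part_of"


class SynonymScope(str, Enum):
    EXACT = "EXACT"
    BROAD = "BROAD"
    NARROW = "NARROW"
    RELATED = "RELATED"


#: default closure relation set: plain superclass closure
IS_A_ONLY = frozenset({Relation.IS_A})
#: closure over is-a and part-of, used for anatomy graphs in EQ reasoning
IS_A_PART_OF = frozenset({Relation.IS_A, Relation.PART_OF})


@dataclass
class Term:
    """A single ontology class.

    Synonyms are (text, scope) pairs; scope follows the OBO synonym scopes
    EXACT / BROAD / NARROW / RELATED.
    """

    id: str
    label: str = ""
    synonyms: list[tuple[str, SynonymScope]] = field(default_factory=list)
    namespace: str = ""
    obsolete: bool = False


@dataclass(frozen=True)
class Edge:
    """A directed child -> parent edge of a given relation type."""

    child: str
    parent: str
    relation: Relation


class OntologyGraph:
    """A directed acyclic multigraph of terms.

    Edges point child -> parent, so graph-reachability *forward* along edges
    yields ancestors.  A child may be linked to the same parent by both an
    is-a and a part-of edge.
    """

    def __init__(self) -> None:
        self.terms: dict[str, Term] = {}
        self._g = nx.MultiDiGraph()
        # ancestor-set cache, keyed by relation subset then term id
        self._anc_cache: dict[frozenset, dict[str, frozenset]] = {}

    # -- construction -------------------------------------------------------

    def add_term(self, term: Term) -> None:
        if not term.id:
            raise ValidationError("term id must be non-empty")
        if term.id in self.terms:
            raise ValidationError(f"duplicate term id {term.id!r}")
        self.terms[term.id] = term
        self._g.add_node(term.id)

    def add_edge(self, child: str, parent: str, relation: Relation) -> None:
        if child == parent:
            raise ValidationError(f"self-edge on {child!r}")
        for t in (child, parent):
            if t not in self.terms:
                raise UnknownTermError(f"unknown term id {t!r}")
        self._g.add_edge(child, parent, key=relation)
        self._anc_cache.clear()

    def validate_acyclic(self) -> None:
        """Raise ValidationError listing one cycle if is-a/part-of edges cycle."""
        try:
            cycle = nx.find_cycle(self._g)
        except nx.NetworkXNoCycle:
            return
        path = " -> ".join(e[0] for e in cycle) + " -> " + cycle[-1][1]
        raise ValidationError(f"cycle over is_a/part_of edges: {path}")

    # -- queries ------------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def edges(self) -> Iterable[Edge]:
        for child, parent, rel in self._g.edges(keys=True):
            yield Edge(child, parent, rel)

    def parents(self, term_id: str, relations: frozenset = IS_A_ONLY) -> set[str]:
        """Direct parents of a term along the given relations."""
        self._check(term_id)
        return {
            p
            for _, p, rel in self._g.out_edges(term_id, keys=True)
            if rel in relations
        }

    def ancestors(self, term_id: str, relations: frozenset = IS_A_ONLY) -> set[str]:
        """All terms reachable from ``term_id`` via the given relations.

        The term itself is not included.  Obsolete terms have no outgoing
        edges (the parser strips them), so their ancestor set is empty.
        """
        self._check(term_id)
        return set(self._ancestors_cached(term_id, frozenset(relations)))

    def close_profile(
        self, term_ids: Iterable[str], relations: frozenset = IS_A_ONLY
    ) -> set[str]:
        """Reflexive closure of a term set against the given relations.

        Returns the input terms plus all their ancestors; reflexive and
        idempotent by construction.
        """
        terms = set(term_ids)
        closed = set(terms)
        rels = frozenset(relations)
        for t in terms:
            self._check(t)
            closed |= self._ancestors_cached(t, rels)
        return closed

    def roots(self, relations: frozenset = IS_A_ONLY) -> set[str]:
        return {
            t
            for t, term in self.terms.items()
            if not term.obsolete and not self.parents(t, relations)
        }

    def _check(self, term_id: str) -> None:
        if term_id not in self.terms:
            raise UnknownTermError(f"unknown term id {term_id!r}")

    def _ancestors_cached(self, term_id: str, rels: frozenset) -> frozenset:
        cache = self._anc_cache.setdefault(rels, {})
        hit = cache.get(term_id)
        if hit is not None:
            return hit
        # iterative DFS with memoisation; the graph is a DAG
        anc: set[str] = set()
        stack = [term_id]
        seen = {term_id}
        while stack:
            node = stack.pop()
            for _, parent, rel in self._g.out_edges(node, keys=True):
                if rel not in rels or parent in anc:
                    continue
                done = cache.get(parent)
                if done is not None:
                    anc.add(parent)
                    anc |= done
                elif parent not in seen:
                    anc.add(parent)
                    seen.add(parent)
                    stack.append(parent)
                else:
                    anc.add(parent)
        result = frozenset(anc)
        cache[term_id] = result
        return result


# ---------------------------------------------------------------------------
# OBO 1.2 flat-file dialect
# ---------------------------------------------------------------------------

_SCOPES = {s.value for s in SynonymScope}


def _parse_synonym(value: str, lineno: int) -> tuple[str, SynonymScope]:
    # synonym: "text" SCOPE [xrefs]
    if not value.startswith('"'):
        raise ParseError(f"line {lineno}: synonym value must start with a quote")
    end = value.find('"', 1)
    if end < 0:
        raise ParseError(f"line {lineno}: unterminated synonym text")
    text = value[1:end]
    rest = value[end + 1 :].strip()
    scope = SynonymScope.RELATED
    if rest:
        word = rest.split()[0].rstrip("[")
        if word in _SCOPES:
            scope = SynonymScope(word)
    return text, scope


def parse_obo(stream: IO[str]) -> OntologyGraph:
    """Parse an OBO 1.2 flat file into an :class:`OntologyGraph`.

    Interprets only ``id``, ``name``, ``synonym``, ``is_a``,
    ``relationship: part_of`` and ``is_obsolete`` inside ``[Term]`` stanzas.
    Unknown relationship types are skipped with a logged warning; all other
    tags are ignored silently.  Obsolete terms are retained as flagged nodes
    with their outgoing edges stripped.

    Raises
    ------
    ParseError
        for a ``[Term]`` stanza lacking an ``id`` tag (names the line).
    ValidationError
        if the is-a/part-of graph contains a cycle (lists one cycle).
    """
    graph = OntologyGraph()
    pending_edges: list[tuple[str, str, Relation, bool]] = []

    in_term = False
    stanza_start = 0
    cur: Term | None = None
    cur_edges: list[tuple[str, Relation]] = []

    def flush(lineno: int) -> None:
        nonlocal cur, cur_edges
        if not in_term:
            return
        if cur is None:
            raise ParseError(
                f"line {stanza_start}: [Term] stanza is missing an 'id' tag"
            )
        graph.add_term(cur)
        for parent, rel in cur_edges:
            pending_edges.append((cur.id, parent, rel, cur.obsolete))
        cur = None
        cur_edges = []

    lineno = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            flush(lineno)
            in_term = line == "[Term]"
            stanza_start = lineno
            continue
        if not in_term:
            continue
        if ":" not in line:
            raise ParseError(f"line {lineno}: expected 'tag: value', got {line!r}")
        tag, _, value = line.partition(":")
        tag = tag.strip()
        value = value.strip()
        if tag == "id":
            if not value:
                raise ParseError(f"line {lineno}: empty id")
            cur = Term(id=value)
        elif cur is None and tag in {
            "name",
            "synonym",
            "is_a",
            "relationship",
            "is_obsolete",
            "namespace",
        }:
            raise ParseError(f"line {stanza_start}: [Term] stanza is missing an 'id' tag")
        elif tag == "name":
            cur.label = value
        elif tag == "namespace":
            cur.namespace = value
        elif tag == "synonym":
            cur.synonyms.append(_parse_synonym(value, lineno))
        elif tag == "is_a":
            cur_edges.append((value, Relation.IS_A))
        elif tag == "relationship":
            parts = value.split()
            if len(parts) < 2:
                raise ParseError(f"line {lineno}: malformed relationship {value!r}")
            rel_name, target = parts[0], parts[1]
            if rel_name == "part_of":
                cur_edges.append((target, Relation.PART_OF))
            else:
                logger.warning(
                    "line %d: ignoring unknown relationship type %r", lineno, rel_name
                )
        elif tag == "is_obsolete":
            cur.obsolete = value.lower() == "true"
    flush(lineno + 1)

    for child, parent, rel, obsolete in pending_edges:
        if obsolete:
            continue  # obsolete terms carry no outgoing edges
        if parent not in graph.terms:
            # dangling parent: materialise a bare node so the edge is kept
            graph.add_term(Term(id=parent))
        graph.add_edge(child, parent, rel)

    graph.validate_acyclic()
    return graph


def parse_obo_path(path) -> OntologyGraph:
    with open(path, encoding="utf-8") as fh:
        return parse_obo(fh)


def write_obo(graph: OntologyGraph, stream: IO[str]) -> None:
    """Serialize to the same OBO dialect the parser reads.

    Stanzas are sorted by term id and tags are emitted in a fixed order
    (id, name, synonym, is_a, relationship, is_obsolete) so that a
    parse -> serialize -> parse round trip is bit-stable.
    """
    stream.write("format-version: 1.2\n")
    by_child: dict[str, list[tuple[str, Relation]]] = {}
    for e in graph.edges():
        by_child.setdefault(e.child, []).append((e.parent, e.relation))
    for tid in sorted(graph.terms):
        term = graph.terms[tid]
        stream.write("\n[Term]\n")
        stream.write(f"id: {term.id}\n")
        if term.label:
            stream.write(f"name: {term.label}\n")
        for text, scope in term.synonyms:
            stream.write(f'synonym: "{text}" {scope.value} []\n')
        edges = sorted(by_child.get(tid, []), key=lambda pr: (pr[1].value, pr[0]))
        for parent, rel in edges:
            if rel is Relation.IS_A:
                stream.write(f"is_a: {parent}\n")
        for parent, rel in edges:
            if rel is Relation.PART_OF:
                stream.write(f"relationship: part_of {parent}\n")
        if term.obsolete:
            stream.write("is_obsolete: true\n")


def write_obo_path(graph: OntologyGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        write_obo(graph, fh)
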