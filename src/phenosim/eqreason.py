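"""Cross-species phenotype subsumption from entity-quality (EQ) definitions.

A phenotype term is decomposed into an affected *entity* (an anatomy or
process term) and a *quality* (a PATO-style term).  One species' phenotype is
inferred to be a kind of another species' phenotype when

* the sub-definition's entity reaches the super-definition's entity through
  is-a / part-of edges, crossing at most one asserted anatomical-homology
  pair, and
* the super-definition's quality is the sub-definition's quality or one of
  its is-a ancestors.

The classic worked case: *Proximal epiphysis of fibula* (human) is part of
*Fibula* (human), which is homologous to *Fibula* (mouse); *Hypertrophic* is
a kind of *Abnormal morphology*; hence *Proximal fibular overgrowth* (human,
HP:0005067) is a kind of *Abnormal fibula morphology* (mouse, MP:0002187).

The resulting bridge axioms can be installed into a merged phenotype graph as
is-a edges so that profile closures span species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .errors import UnknownTermError, ValidationError
from .ontology import IS_A_ONLY, IS_A_PART_OF, OntologyGraph


@dataclass(frozen=True)
class EQDefinition:
    """Decomposition of a phenotype term into entity + quality."""

    phenotype: str
    entity: str
    quality: str

    def __post_init__(self) -> None:
        if not (self.phenotype and self.entity and self.quality):
            raise ValidationError("EQ definition fields must be non-empty")


class HomologyMap:
    """Symmetric cross-species pairs of anatomical terms."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()) -> None:
        self._pairs: set[frozenset[str]] = set()
        for a, b in pairs:
            self.add(a, b)

    def add(self, a: str, b: str) -> None:
        if a == b:
            raise ValidationError(f"homology self-pair on {a!r}")
        self._pairs.add(frozenset((a, b)))

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(p)) for p in self._pairs)

    def partners(self, term_id: str) -> set[str]:
        return {next(iter(p - {term_id})) for p in self._pairs if term_id in p}

    def __len__(self) -> int:
        return len(self._pairs)


@dataclass(frozen=True)
class BridgeAxiom:
    """An inferred is-a edge from one species' phenotype to another's."""

    sub: str
    super: str


def _closure_with_self(graph: OntologyGraph, term_id: str) -> set[str]:
    return graph.close_profile({term_id}, IS_A_PART_OF)


def entity_subsumed(
    e_sub: str,
    e_super: str,
    anatomy_a: OntologyGraph,
    anatomy_b: OntologyGraph,
    homology: HomologyMap,
) -> bool:
    """True iff ``e_super`` is reachable from ``e_sub``.

    Reachability runs along is-a / part-of edges within either anatomy graph,
    crossing at most one homology pair (in either direction, homology being
    symmetric).  Reflexive: a term subsumes itself.
    """

    def graph_of(term_id: str) -> OntologyGraph:
        if term_id in anatomy_a:
            return anatomy_a
        if term_id in anatomy_b:
            return anatomy_b
        raise UnknownTermError(f"unknown anatomy term {term_id!r}")

    g_sub = graph_of(e_sub)
    graph_of(e_super)  # existence check

    reach = _closure_with_self(g_sub, e_sub)
    if e_super in reach:
        return True
    # one homology hop from anything already reached, then continue upward
    for x in reach:
        for y in homology.partners(x):
            if y not in anatomy_a and y not in anatomy_b:
                continue
            g_y = anatomy_a if y in anatomy_a else anatomy_b
            if e_super in _closure_with_self(g_y, y):
                return True
    return False


def eq_subsumes(
    d_sub: EQDefinition,
    d_super: EQDefinition,
    anatomy_a: OntologyGraph,
    anatomy_b: OntologyGraph,
    quality: OntologyGraph,
    homology: HomologyMap,
) -> bool:
    """True iff d_sub's phenotype is a kind of d_super's phenotype.

    Requires entity subsumption (see :func:`entity_subsumed`) *and* quality
    subsumption: the super quality must be the sub quality or one of its is-a
    ancestors in the quality ontology.
    """
    for q in (d_sub.quality, d_super.quality):
        if q not in quality:
            raise UnknownTermError(f"unknown quality term {q!r}")
    if d_super.quality != d_sub.quality and d_super.quality not in quality.ancestors(
        d_sub.quality, IS_A_ONLY
    ):
        return False
    return entity_subsumed(d_sub.entity, d_super.entity, anatomy_a, anatomy_b, homology)


def build_bridge(
    defs_a: Iterable[EQDefinition],
    defs_b: Iterable[EQDefinition],
    anatomy_a: OntologyGraph,
    anatomy_b: OntologyGraph,
    quality: OntologyGraph,
    homology: HomologyMap,
) -> set[BridgeAxiom]:
    """All inferred axioms (a.phenotype is-a b.phenotype), self-pairs excluded.

    Axioms are oriented species A -> species B; call again with the argument
    roles swapped for the reverse direction.  Output is order-independent.
    """
    defs_a = list(defs_a)
    defs_b = list(defs_b)
    if not defs_a or not defs_b:
        raise ValidationError("EQ definition tables must be non-empty")
    axioms: set[BridgeAxiom] = set()
    for a in defs_a:
        for b in defs_b:
            if a.phenotype == b.phenotype:
                continue
            if eq_subsumes(a, b, anatomy_a, anatomy_b, quality, homology):
                axioms.add(BridgeAxiom(sub=a.phenotype, super=b.phenotype))
    return axioms


def merge_with_bridge(
    pheno_a: OntologyGraph,
    pheno_b: OntologyGraph,
    axioms: Iterable[BridgeAxiom],
) -> OntologyGraph:
    """Union of two phenotype graphs with bridge axioms installed as is-a edges.

    Asserts acyclicity after the merge; with both inputs acyclic and axioms
    oriented A -> B only, no cycle can arise.
    """
    from .ontology import Relation

    merged = OntologyGraph()
    for g in (pheno_a, pheno_b):
        for term in g.terms.values():
            if term.id not in merged:
                merged.add_term(term)
        for e in g.edges():
            merged.add_edge(e.child, e.parent, e.relation)
    for ax in axioms:
        merged.add_edge(ax.sub, ax.super, Relation.IS_A)
    merged.validate_acyclic()
    return merged
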