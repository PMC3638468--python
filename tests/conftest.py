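"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own graph machinery: they
enumerate paths, alignments and set contents directly, so they can certify
the optimised implementations on small random instances.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import pytest

from phenosim.ontology import OntologyGraph, Relation, Term


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_ancestors(graph: OntologyGraph, term: str, relations) -> set[str]:
    """Reachability by plain recursive edge-walking (no caching, no networkx)."""
    edges = [(e.child, e.parent) for e in graph.edges() if e.relation in relations]
    out: set[str] = set()

    def walk(node: str) -> None:
        for c, p in edges:
            if c == node and p not in out:
                out.add(p)
                walk(p)

    walk(term)
    return out


def brute_close(graph: OntologyGraph, terms, relations) -> set[str]:
    closed = set(terms)
    for t in terms:
        closed |= brute_ancestors(graph, t, relations)
    return closed


def brute_simgic(terms1, terms2, graph, ic, relations) -> float:
    c1 = brute_close(graph, terms1, relations)
    c2 = brute_close(graph, terms2, relations)
    num = sum(ic.ic[t] for t in c1 & c2)
    den = sum(ic.ic[t] for t in c1 | c2)
    return num / den if den else 0.0


def u_statistic_auc(ranked, truth) -> float:
    """Fraction of (positive, negative) pairs correctly ordered by rank.

    Pairs are pooled across diseases and compared by their within-disease
    rank; equal ranks (necessarily from different diseases) count half.
    """
    pos_ranks, neg_ranks = [], []
    for rl in ranked:
        for model, _score, rank in rl.entries:
            (pos_ranks if (model, rl.disease_id) in truth else neg_ranks).append(rank)
    total = wins = 0.0
    for rp in pos_ranks:
        for rn in neg_ranks:
            total += 1
            if rp < rn:
                wins += 1
            elif rp == rn:
                wins += 0.5
    return wins / total


def enumerate_alignments_score(a: str, b: str, match, mismatch, gap) -> float:
    """Best score over ALL global alignments, by explicit recursion."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            options.append(s + best(i + 1, j + 1))
        if i < len(a):
            options.append(gap + best(i + 1, j))
        if j < len(b):
            options.append(gap + best(i, j + 1))
        return max(options)

    return best(0, 0)


def brute_entity_subsumed(e_sub, e_super, ga, gb, homology) -> bool:
    """Exhaustive search over is-a/part-of paths with <= 1 homology hop."""
    from phenosim.ontology import IS_A_PART_OF

    def up(g, t):
        return {t} | brute_ancestors(g, t, IS_A_PART_OF)

    def home(t):
        if t in ga:
            return ga
        if t in gb:
            return gb
        return None

    start = home(e_sub)
    reach = up(start, e_sub)
    if e_super in reach:
        return True
    for x in reach:
        for pair in homology.pairs():
            if x in pair:
                y = pair[0] if pair[1] == x else pair[1]
                g = home(y)
                if g is not None and e_super in up(g, y):
                    return True
    return False


# ---------------------------------------------------------------------------
# graph builders
# ---------------------------------------------------------------------------

def make_graph(term_ids, edges) -> OntologyGraph:
    """Graph from id list and (child, parent, relation) triples."""
    g = OntologyGraph()
    for tid in term_ids:
        g.add_term(Term(id=tid, label=tid.lower().replace("_", " ")))
    for child, parent, rel in edges:
        g.add_edge(child, parent, rel)
    return g


def random_dag(rng: np.random.Generator, n_terms: int, relations=(Relation.IS_A,),
               p_edge: float = 0.25) -> OntologyGraph:
    """Random DAG over n_terms with edges only from higher to lower index."""
    ids = [f"R:{i:03d}" for i in range(n_terms)]
    g = OntologyGraph()
    for tid in ids:
        g.add_term(Term(id=tid))
    for i in range(1, n_terms):
        for j in range(i):
            if rng.random() < p_edge:
                rel = relations[int(rng.integers(len(relations)))]
                g.add_edge(ids[i], ids[j], rel)
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def chain_graph():
    """A -is_a-> B -is_a-> C."""
    return make_graph(
        ["A", "B", "C"],
        [("A", "B", Relation.IS_A), ("B", "C", Relation.IS_A)],
    )


@pytest.fixture
def fibula_setting():
    """The cross-species fibula scenario: human/mouse anatomy, quality tree,
    homology between the two fibulae, and the two EQ definitions."""
    from phenosim.eqreason import EQDefinition, HomologyMap

    human = make_graph(
        ["UBERON_H:FIBULA", "UBERON_H:PROX_EPI_FIBULA", "UBERON_H:BONE"],
        [
            ("UBERON_H:PROX_EPI_FIBULA", "UBERON_H:FIBULA", Relation.PART_OF),
            ("UBERON_H:FIBULA", "UBERON_H:BONE", Relation.IS_A),
        ],
    )
    mouse = make_graph(
        ["MA:FIBULA", "MA:BONE"],
        [("MA:FIBULA", "MA:BONE", Relation.IS_A)],
    )
    quality = make_graph(
        ["PATO:QUALITY", "PATO:ABNORMAL_MORPHOLOGY", "PATO:HYPERTROPHIC", "PATO:APLASTIC"],
        [
            ("PATO:ABNORMAL_MORPHOLOGY", "PATO:QUALITY", Relation.IS_A),
            ("PATO:HYPERTROPHIC", "PATO:ABNORMAL_MORPHOLOGY", Relation.IS_A),
            ("PATO:APLASTIC", "PATO:ABNORMAL_MORPHOLOGY", Relation.IS_A),
        ],
    )
    homology = HomologyMap([("UBERON_H:FIBULA", "MA:FIBULA")])
    hp = EQDefinition(  # proximal fibular overgrowth (human)
        phenotype="HP:0005067",
        entity="UBERON_H:PROX_EPI_FIBULA",
        quality="PATO:HYPERTROPHIC",
    )
    mp = EQDefinition(  # abnormal fibula morphology (mouse)
        phenotype="MP:0002187",
        entity="MA:FIBULA",
        quality="PATO:ABNORMAL_MORPHOLOGY",
    )
    return human, mouse, quality, homology, hp, mp
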