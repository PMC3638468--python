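"""Information content and simGIC similarity over closed annotation profiles.

The information content of a term x is taken over a reference annotation
corpus: after closing every profile against the superclass relation,

    I(x) = -log2 P(x),   P(x) = (# closed profiles containing x) / N .

A term annotated to every profile (e.g. the root) carries 0 bits; rarer terms
are more informative.  Terms never seen in the closed corpus receive the
finite pseudo-count ceiling -log2(1/(N+1)) so that query profiles using
corpus-unseen terms remain scorable.

simGIC is the information-weighted Jaccard index of two superclass-closed
term sets:

    simGIC(S1, S2) = sum_{x in C1 ∩ C2} I(x) / sum_{x in C1 ∪ C2} I(x)

with C = close(S).  It lies in [0, 1], is symmetric, and equals 1 for
identical profiles with any positive-IC content; a 0/0 ratio is defined as 0
(such pairs share no information).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .errors import UnknownTermError, ValidationError
from .ontology import IS_A_ONLY, OntologyGraph


@dataclass
class PhenotypeProfile:
    """An entity (gene, model or disease) with its phenotype term set."""

    entity_id: str
    terms: set[str] = field(default_factory=set)


class AnnotationCorpus:
    """A keyed collection of phenotype profiles."""

    def __init__(self, profiles: Iterable[PhenotypeProfile] = ()) -> None:
        self.profiles: dict[str, PhenotypeProfile] = {}
        for p in profiles:
            self.add(p)

    def add(self, profile: PhenotypeProfile) -> None:
        if profile.entity_id in self.profiles:
            raise ValidationError(f"duplicate entity id {profile.entity_id!r}")
        self.profiles[profile.entity_id] = profile

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles.values())

    def ids(self) -> list[str]:
        return sorted(self.profiles)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AnnotationCorpus":
        """Build from (entity_id, term_id) pairs, e.g. an annotation TSV."""
        corpus = cls()
        for entity_id, term_id in pairs:
            if entity_id not in corpus.profiles:
                corpus.profiles[entity_id] = PhenotypeProfile(entity_id, set())
            corpus.profiles[entity_id].terms.add(term_id)
        return corpus


@dataclass
class ICTable:
    """Term -> information content (bits), with the corpus size used."""

    ic: dict[str, float]
    N: int

    def __getitem__(self, term_id: str) -> float:
        try:
            return self.ic[term_id]
        except KeyError:
            raise UnknownTermError(f"no information content for term {term_id!r}") from None

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.ic


def compute_ic(
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    relations: frozenset = IS_A_ONLY,
) -> ICTable:
    """Corpus-frequency information content for every non-obsolete graph term.

    Each profile is closed against superclasses before counting; the count is
    over profiles (entities), not individual annotations.  Zero-frequency
    terms get the pseudo-count ceiling -log2(1/(N+1)).
    """
    if len(corpus) == 0:
        raise ValidationError("cannot compute information content on an empty corpus")
    n = len(corpus)
    counts: dict[str, int] = {}
    for profile in corpus:
        for t in graph.close_profile(profile.terms, relations):
            counts[t] = counts.get(t, 0) + 1
    unseen = math.log2(n + 1)
    ic: dict[str, float] = {}
    for tid, term in graph.terms.items():
        if term.obsolete:
            continue
        c = counts.get(tid, 0)
        ic[tid] = -math.log2(c / n) if c else unseen
    return ICTable(ic=ic, N=n)


def simgic(
    p1: PhenotypeProfile,
    p2: PhenotypeProfile,
    ic: ICTable,
    graph: OntologyGraph,
    relations: frozenset = IS_A_ONLY,
) -> float:
    """Information-weighted Jaccard similarity of two closed profiles."""
    if not p1.terms or not p2.terms:
        raise ValidationError("simGIC requires non-empty profiles")
    c1 = graph.close_profile(p1.terms, relations)
    c2 = graph.close_profile(p2.terms, relations)
    return _simgic_closed(c1, c2, ic)


def _simgic_closed(c1: set[str], c2: set[str], ic: ICTable) -> float:
    # summation in sorted term order keeps the score exactly symmetric
    num = sum(ic[t] for t in sorted(c1 & c2))
    den = num + sum(ic[t] for t in sorted(c1 ^ c2))
    if den == 0.0:
        return 0.0
    return num / den


def pairwise_similarity(
    queries: AnnotationCorpus,
    targets: AnnotationCorpus,
    ic: ICTable,
    graph: OntologyGraph,
    relations: frozenset = IS_A_ONLY,
) -> pd.DataFrame:
    """Complete query x target simGIC matrix with sorted-id row/column order.

    Profile closures are computed once per entity, so the cost is linear in
    corpus size plus one set operation per matrix cell.
    """
    if len(queries) == 0 or len(targets) == 0:
        raise ValidationError("both corpora must be non-empty")
    qids = queries.ids()
    tids = targets.ids()

    def close_all(corpus: AnnotationCorpus) -> dict[str, set[str]]:
        out = {}
        for p in corpus:
            if not p.terms:
                raise ValidationError(f"empty profile {p.entity_id!r}")
            out[p.entity_id] = graph.close_profile(p.terms, relations)
        return out

    closed_q = close_all(queries)
    closed_t = closed_q if targets is queries else close_all(targets)
    data = [
        [_simgic_closed(closed_q[q], closed_t[t], ic) for t in tids] for q in qids
    ]
    return pd.DataFrame(data, index=qids, columns=tids)
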