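"""Seeded generators for toy ontologies, corpora and planted-signal benchmarks.

These generators stand in for real phenotype resources (HPO/MP-style term
DAGs, model/disease annotation corpora, curated gene-disease truth sets) so
that the whole pipeline — closure, information content, simGIC, ranking, ROC
— is exercisable without any downloads.  All randomness flows through a
single numpy generator seeded per call; identical inputs give identical
outputs, byte for byte.

A benchmark plants signal by copying a fraction of a disease's terms into
its positive models' profiles: at ``signal=1`` a positive model's closure is
a superset of its disease's closure, at ``signal=0`` positives are
statistically indistinguishable from negatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .evaluate import AssociationSet
from .ontology import OntologyGraph, Relation, Term
from .similarity import AnnotationCorpus, PhenotypeProfile


@dataclass(frozen=True)
class BenchmarkSpec:
    """Parameters of a planted-signal ranking benchmark.

    ``signal`` is the fraction of a positive pair's disease terms copied into
    the model's profile (ceil(signal * profile_size) terms).
    """

    n_terms: int
    n_models: int
    n_diseases: int
    profile_size: int
    n_positives: int
    signal: float
    seed: int
    max_parents: int = 2

    def __post_init__(self) -> None:
        if self.n_positives > self.n_models * self.n_diseases:
            raise ValidationError("n_positives exceeds the number of pairs")
        if not (0.0 <= self.signal <= 1.0):
            raise ValidationError("signal must lie in [0, 1]")
        if self.n_terms < 2:
            raise ValidationError("need at least a root plus one annotatable term")
        if self.profile_size < 1 or self.profile_size > self.n_terms - 1:
            raise ValidationError("profile_size must be in [1, n_terms - 1]")
        if min(self.n_models, self.n_diseases, self.n_positives) < 1:
            raise ValidationError("counts must be positive")


@dataclass
class Benchmark:
    graph: OntologyGraph
    models: AnnotationCorpus
    diseases: AnnotationCorpus
    truth: AssociationSet


def generate_ontology(
    n_terms: int, max_parents: int = 2, seed: int = 0, prefix: str = "SYN"
) -> OntologyGraph:
    """Single-rooted random DAG of ``n_terms`` is-a linked terms.

    Term ``i > 0`` receives between 1 and ``max_parents`` parents drawn
    uniformly (without replacement) from terms ``0..i-1``, so the graph is
    acyclic by construction and term 0 is the unique root.
    """
    if n_terms < 1 or max_parents < 1:
        raise ValidationError("n_terms and max_parents must be >= 1")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_terms - 1)))
    ids = [f"{prefix}:{i:0{width}d}" for i in range(n_terms)]
    graph = OntologyGraph()
    for i, tid in enumerate(ids):
        graph.add_term(Term(id=tid, label=f"synthetic term {i}"))
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(max_parents, i) + 1))
        parents = rng.choice(i, size=k, replace=False)
        for p in sorted(int(x) for x in parents):
            graph.add_edge(ids[i], ids[p], Relation.IS_A)
    return graph


def generate_benchmark(spec: BenchmarkSpec) -> Benchmark:
    """Models, diseases and truth pairs with planted similarity signal.

    Disease profiles are uniform random term sets (the root is never
    sampled: root annotations carry zero information).  Each positive pair's
    model copies ``ceil(signal * profile_size)`` of its disease's terms and
    fills the remainder randomly; negative models are fully random.
    """
    rng = np.random.default_rng(spec.seed)
    graph = generate_ontology(
        spec.n_terms, spec.max_parents, seed=int(rng.integers(2**31))
    )
    term_ids = sorted(graph.terms)
    root = min(term_ids)  # term 0 sorts first by construction
    pool = np.array([t for t in term_ids if t != root])

    disease_ids = [f"disease:{j:04d}" for j in range(spec.n_diseases)]
    model_ids = [f"model:{i:04d}" for i in range(spec.n_models)]

    def sample_profile() -> set[str]:
        return set(rng.choice(pool, size=spec.profile_size, replace=False))

    diseases = AnnotationCorpus(
        PhenotypeProfile(d, sample_profile()) for d in disease_ids
    )

    total = spec.n_models * spec.n_diseases
    chosen = rng.choice(total, size=spec.n_positives, replace=False)
    truth = AssociationSet()
    pos_diseases: dict[str, list[str]] = {m: [] for m in model_ids}
    for k in sorted(int(x) for x in chosen):
        m = model_ids[k % spec.n_models]
        d = disease_ids[k // spec.n_models]
        truth.add(m, d)
        pos_diseases[m].append(d)

    n_copy = math.ceil(spec.signal * spec.profile_size)
    models = AnnotationCorpus()
    for m in model_ids:
        terms: set[str] = set()
        for d in pos_diseases[m]:
            d_terms = sorted(diseases.profiles[d].terms)
            picked = rng.choice(len(d_terms), size=n_copy, replace=False) if n_copy else []
            terms |= {d_terms[int(i)] for i in picked}
        while len(terms) < spec.profile_size:
            terms.add(str(rng.choice(pool)))
        models.add(PhenotypeProfile(m, terms))
    return Benchmark(graph=graph, models=models, diseases=diseases, truth=truth)
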