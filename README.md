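# phenosim

Cross-species phenotype integration and phenotype-driven disease-gene
prioritization.

Model organisms — above all the mouse — carry rich, structured phenotype
annotations, while rare-disease nosologies describe disorders through
clinical signs. `phenosim` turns both into comparable objects: it bridges
species through entity–quality (EQ) phenotype definitions, scores profile
similarity with information-content-weighted simGIC, ranks animal models
against diseases, and evaluates those rankings against gold-standard
gene–disease associations by ROC analysis. It is aimed at computational
biologists building or benchmarking phenotype-based candidate-gene
prioritization pipelines.

## The method

**Closure.** A phenotype profile `S` (the term set annotated to a gene,
mouse model or disease) is closed against the superclass relation of the
ontology `O`: every ancestor of an annotated term is added, so profiles are
comparable at every level of abstraction.

**Information content.** Over a reference annotation corpus of `N` profiles
(each closed), the information content of term `x` is

    I(x) = −log₂ P(x),    P(x) = |{profiles whose closure contains x}| / N.

The root scores 0 bits; terms never seen in the closed corpus receive the
finite ceiling `−log₂(1/(N+1))`.

**simGIC.** The similarity of two profiles is the IC-weighted Jaccard index
of their closures `C₁, C₂`:

    simGIC(S₁, S₂) = Σ_{x ∈ C₁∩C₂} I(x) / Σ_{x ∈ C₁∪C₂} I(x)  ∈ [0, 1].

**Cross-species bridging.** A phenotype decomposes into an affected *entity*
(anatomy or process term) and a *quality* (PATO-style term). Phenotype `A`
is inferred to be a kind of phenotype `B` when `A`'s entity reaches `B`'s
entity along is-a/part-of edges crossing at most one asserted anatomical
homology pair, and `B`'s quality is `A`'s quality or one of its superclasses.
The classic example: *proximal epiphysis of fibula* (human) is part of
*fibula* (human), homologous to *fibula* (mouse), and *hypertrophic* is a
kind of *abnormal morphology* — hence *proximal fibular overgrowth* (human)
is a kind of *abnormal fibula morphology* (mouse). Inferred axioms are
installed as is-a edges in a merged graph, so closures (and therefore
simGIC) span species.

**Evaluation.** For each disease, models are ranked by descending simGIC.
Curated (model, disease) pairs are positives; *every* other pair counts as a
negative — a conservative convention. Sweeping a rank cutoff `r` pooled
across diseases gives TPR(r) and FPR(r), and the trapezoidal area under the
ROC curve summarizes performance: 0.5 is random, 1.0 perfect.

**Lexical mapping.** Free-text clinical-sign labels are mapped to ontology
terms by character-level Needleman–Wunsch global alignment against term
labels and EXACT/NARROW synonyms (match +1, mismatch −1, gap −1; scores
normalized by `max(|a|,|b|)`). Signs with no accepted direct match are
promoted structurally: the nearest ancestor sign with an accepted match
contributes a SUBCLASS_OF assertion.

## Worked example

```
$ phenosim --quiet simulate --spec spec.json --outdir bench/   # spec.json below
$ phenosim --quiet sim --obo bench/graph.obo \
    --queries bench/diseases.tsv --targets bench/models.tsv --out sim.tsv
$ phenosim --quiet roc --matrix sim.tsv --truth bench/truth.tsv --out roc.tsv
{"auc": 0.9814814814814814, "n_pos": 6, "n_neg": 54}
```

with `spec.json`:

```json
{"n_terms": 60, "n_models": 15, "n_diseases": 4, "profile_size": 5,
 "n_positives": 6, "signal": 0.9, "seed": 7}
```

The benchmark plants signal by copying 90% of each positive disease's terms
into its positive model's profile. The ROC summary says the pipeline ranked
the 6 truly associated models almost perfectly above the 54 negative pairs
(AUC 0.981; 0.5 would be random). `roc.tsv` holds the full (FPR, TPR) curve.

The same stages are available as library calls (`generate_benchmark`,
`compute_ic`, `pairwise_similarity`, `rank_all`, `roc`), and
`phenosim bridge` / `phenosim map` expose the cross-species inference and
clinical-sign mapping.

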