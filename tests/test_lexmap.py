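"""Label normalization, Needleman-Wunsch alignment and sign mapping."""

import itertools

import pytest

from phenosim.errors import ValidationError
from phenosim.lexmap import (
    AlignScoring,
    MatchRelation,
    MatchSource,
    SignNode,
    best_lexical_matches,
    normalize_label,
    nw_score,
    structural_superclasses,
)
from phenosim.ontology import OntologyGraph, SynonymScope, Term

from conftest import enumerate_alignments_score

DEFAULT = AlignScoring()


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("Muscle hypotrophy", "muscle hypotrophy"),
        ("cataract,  congenital", "cataract congenital"),
        ("", ""),
        ("  Spastic gait!  ", "spastic gait"),
        ("X-linked (severe)", "x linked severe"),
    ],
)
def test_normalize_label(raw, expected):
    assert normalize_label(raw) == expected


class TestNWScore:
    def test_identity_alignment(self):
        assert nw_score("gait", "gait", DEFAULT) == (4.0, 1.0)

    def test_hand_counted_mismatch(self):
        score, norm = nw_score("abc", "abd", DEFAULT)
        assert score == 1.0  # 2 matches - 1 mismatch
        assert norm == pytest.approx(1 / 3)

    def test_empty_pair_rejected_one_sided_allowed(self):
        with pytest.raises(ValidationError):
            nw_score("", "", DEFAULT)
        score, norm = nw_score("abc", "", DEFAULT)
        assert score == -3.0 and norm == 0.0

    def test_symmetry(self, rng):
        alphabet = "abc"
        for _ in range(50):
            a = "".join(rng.choice(list(alphabet), size=int(rng.integers(1, 7))))
            b = "".join(rng.choice(list(alphabet), size=int(rng.integers(1, 7))))
            assert nw_score(a, b, DEFAULT) == nw_score(b, a, DEFAULT)

    def test_matches_exhaustive_enumeration_all_short_pairs(self):
        """DP equals explicit enumeration of every global alignment: all pairs
        of strings of length <= 3 over a 3-letter alphabet."""
        strings = [
            "".join(s)
            for n in range(4)
            for s in itertools.product("abc", repeat=n)
        ]
        for a in strings:
            for b in strings:
                if not a and not b:
                    continue
                score, _ = nw_score(a, b, DEFAULT)
                assert score == enumerate_alignments_score(a, b, 1.0, -1.0, -1.0)

    def test_matches_enumeration_on_longer_sampled_pairs(self, rng):
        """Seeded sample of pairs up to length 6 against the same oracle,
        including a non-default scoring scheme."""
        alt = AlignScoring(match=2.0, mismatch=-1.5, gap=-0.5)
        for scoring in (DEFAULT, alt):
            for _ in range(150):
                a = "".join(rng.choice(list("abc"), size=int(rng.integers(0, 7))))
                b = "".join(rng.choice(list("abc"), size=int(rng.integers(1, 7))))
                score, _ = nw_score(a, b, scoring)
                assert score == pytest.approx(
                    enumerate_alignments_score(a, b, scoring.match, scoring.mismatch, scoring.gap),
                    abs=1e-12,
                )

    def test_normalized_one_iff_equal(self, rng):
        assert nw_score("kyphosis", "kyphosis", DEFAULT)[1] == 1.0
        for _ in range(60):
            a = "".join(rng.choice(list("abc"), size=int(rng.integers(1, 6))))
            b = "".join(rng.choice(list("abc"), size=int(rng.integers(1, 6))))
            _, norm = nw_score(a, b, DEFAULT)
            assert (norm == 1.0) == (a == b)

    def test_cross_check_against_biopython_aligner(self, rng):
        Align = pytest.importorskip("Bio.Align")
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1.0
        aligner.mismatch_score = -1.0
        aligner.open_gap_score = aligner.extend_gap_score = -1.0
        for _ in range(40):
            a = "".join(rng.choice(list("abcd"), size=int(rng.integers(1, 12))))
            b = "".join(rng.choice(list("abcd"), size=int(rng.integers(1, 12))))
            assert nw_score(a, b, DEFAULT)[0] == pytest.approx(aligner.score(a, b))

    def test_invalid_scoring_rejected(self):
        with pytest.raises(ValidationError):
            AlignScoring(match=1.0, mismatch=1.0, gap=-1.0)
        with pytest.raises(ValidationError):
            AlignScoring(match=1.0, mismatch=-1.0, gap=0.0)


def tiny_ontology() -> OntologyGraph:
    g = OntologyGraph()
    labels = {
        "T:1": "abnormal gait",
        "T:2": "cataract",
        "T:3": "muscle hypotrophy",
        "T:4": "abnormal facial expression",
        "T:5": "kyphosis",
    }
    for tid, label in labels.items():
        g.add_term(Term(id=tid, label=label))
    g.terms["T:2"].synonyms = [
        ("lens opacity", SynonymScope.EXACT),
        ("any eye problem", SynonymScope.BROAD),
    ]
    return g


class TestBestLexicalMatches:
    def test_exact_label_match_dominates(self):
        sign = SignNode("s1", "Cataract")
        hits = best_lexical_matches(sign, tiny_ontology(), DEFAULT, 0.85, k=3)
        assert hits[0].term_id == "T:2"
        assert hits[0].normalized == 1.0
        assert hits[0].relation is MatchRelation.EQUIVALENT
        assert hits[0].source is MatchSource.LEXICAL

    def test_exact_synonym_matches_but_broad_does_not(self):
        hit = best_lexical_matches(
            SignNode("s1", "lens opacity"), tiny_ontology(), DEFAULT, 1.0, k=1
        )
        assert hit and hit[0].term_id == "T:2"
        assert not best_lexical_matches(
            SignNode("s2", "any eye problem"), tiny_ontology(), DEFAULT, 1.0, k=1
        )

    def test_threshold_one_without_exact_match_is_empty(self):
        sign = SignNode("s1", "kyphoscoliosis")
        assert best_lexical_matches(sign, tiny_ontology(), DEFAULT, 1.0, k=5) == []

    def test_equals_brute_force_scoring_and_sorting(self, rng):
        """Top-k output equals scoring every label directly and sorting."""
        g = tiny_ontology()
        sign = SignNode("s1", "abnormal gain")
        k, threshold = 4, 0.0
        got = best_lexical_matches(sign, g, DEFAULT, threshold, k=k)
        query = normalize_label(sign.label)
        scored = []
        for tid in sorted(g.terms):
            term = g.terms[tid]
            cands = [normalize_label(term.label)] + [
                normalize_label(t)
                for t, sc in term.synonyms
                if sc in (SynonymScope.EXACT, SynonymScope.NARROW)
            ]
            norm = max(nw_score(query, c, DEFAULT)[1] for c in cands)
            if norm >= threshold:
                scored.append((tid, norm))
        scored.sort(key=lambda r: (-r[1], r[0]))
        assert [(h.term_id, h.normalized) for h in got] == scored[:k]

    def test_empty_ontology_rejected(self):
        with pytest.raises(ValidationError):
            best_lexical_matches(SignNode("s", "x"), OntologyGraph(), DEFAULT, 0.5, 1)

    def test_obsolete_terms_do_not_match(self):
        g = tiny_ontology()
        g.terms["T:5"].obsolete = True
        assert best_lexical_matches(SignNode("s", "kyphosis"), g, DEFAULT, 1.0, 1) == []

    def test_insertion_order_invariance(self):
        g1 = tiny_ontology()
        g2 = OntologyGraph()
        for tid in reversed(sorted(g1.terms)):
            t = g1.terms[tid]
            g2.add_term(Term(id=t.id, label=t.label, synonyms=list(t.synonyms)))
        sign = SignNode("s1", "abnormal gait")
        assert best_lexical_matches(sign, g1, DEFAULT, 0.0, 3) == best_lexical_matches(
            sign, g2, DEFAULT, 0.0, 3
        )


class TestStructuralSuperclasses:
    def make_signs(self):
        return [
            SignNode("o1", "abnormal facial expression"),
            SignNode("o2", "amimia like facies zzz", ["o1"]),
            SignNode("o3", "qqq xxx yyy", ["o2"]),
        ]

    def test_one_hop_promotion(self):
        signs = self.make_signs()[:2]
        out = structural_superclasses(signs, tiny_ontology(), DEFAULT, 0.85)
        assert len(out) == 1
        m = out[0]
        assert (m.sign_id, m.term_id) == ("o2", "T:4")
        assert m.relation is MatchRelation.SUBCLASS_OF
        assert m.source is MatchSource.STRUCTURAL

    def test_directly_matching_sign_gets_no_structural_entry(self):
        out = structural_superclasses(
            [SignNode("o1", "kyphosis")], tiny_ontology(), DEFAULT, 0.85
        )
        assert out == []

    def test_grandparent_assigned_on_three_level_chain(self):
        """Nearest-first walk reaches the first matching ancestor, here two up."""
        out = structural_superclasses(self.make_signs(), tiny_ontology(), DEFAULT, 0.85)
        by_sign = {m.sign_id: m for m in out}
        assert by_sign["o3"].term_id == "T:4"
        assert by_sign["o2"].term_id == "T:4"

    def test_cycle_in_hierarchy_rejected(self):
        signs = [
            SignNode("a", "zzz one", ["b"]),
            SignNode("b", "zzz two", ["a"]),
        ]
        with pytest.raises(ValidationError, match="cycle"):
            structural_superclasses(signs, tiny_ontology(), DEFAULT, 0.85)

    def test_empty_sign_label_rejected(self):
        with pytest.raises(ValidationError):
            SignNode("s", "")
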