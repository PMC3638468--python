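"""Lexical mapping of clinical-sign labels onto phenotype-ontology terms.

Free-text clinical-sign labels (e.g. from a rare-disease nosology) are
matched against the labels and synonyms of phenotype terms using
Needleman-Wunsch global alignment over characters.  A sign whose best
normalized alignment score reaches the acceptance threshold is asserted
EQUIVALENT to the matched term.  Signs with no direct match are promoted
structurally: walking the sign hierarchy nearest-first, the first ancestor
sign with an accepted lexical match yields a SUBCLASS_OF assertion to that
ancestor's term.

Scores are normalized by ``match_score * max(len(a), len(b))`` and clamped to
[0, 1], so a string aligned to itself scores exactly 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import ValidationError
from .ontology import OntologyGraph, SynonymScope


class MatchRelation(str, Enum):
    EQUIVALENT = "EQUIVALENT"
    SUBCLASS_OF = "SUBCLASS_OF"


class MatchSource(str, Enum):
    LEXICAL = "LEXICAL"
    STRUCTURAL = "STRUCTURAL"


#: synonym scopes that participate in lexical matching at full weight;
#: BROAD/RELATED synonyms are excluded to avoid over-broad equivalences
MATCH_SCOPES = frozenset({SynonymScope.EXACT, SynonymScope.NARROW})


@dataclass(frozen=True)
class AlignScoring:
    """Character-level match / mismatch / gap scores."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -1.0

    def __post_init__(self) -> None:
        if not self.match > self.mismatch:
            raise ValidationError("match score must exceed mismatch score")
        if not self.gap < 0:
            raise ValidationError("gap score must be negative")


@dataclass
class SignNode:
    """A clinical sign with its label and parent signs (the sign hierarchy)."""

    sign_id: str
    label: str
    parent_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.label:
            raise ValidationError(f"sign {self.sign_id!r} has an empty label")


@dataclass(frozen=True)
class LexicalMatch:
    sign_id: str
    term_id: str
    score: float
    normalized: float
    relation: MatchRelation
    source: MatchSource


_PUNCT = re.compile(r"[^\w\s]")
_WS = re.compile(r"\s+")


def normalize_label(s: str) -> str:
    """Lower-case, replace punctuation by spaces, collapse whitespace."""
    s = _PUNCT.sub(" ", s.lower())
    return _WS.sub(" ", s).strip()


def nw_score(a: str, b: str, scoring: AlignScoring = AlignScoring()) -> tuple[float, float]:
    """Optimal global (Needleman-Wunsch) alignment score over characters.

    Returns ``(score, normalized)`` where ``normalized`` is the score divided
    by ``match * max(|a|, |b|)`` and clamped to [0, 1]; for non-empty ``a``,
    ``nw_score(a, a)`` has normalized 1.  Inputs are expected to be already
    normalized (see :func:`normalize_label`).
    """
    if not a and not b:
        raise ValidationError("cannot align two empty strings")
    n, m = len(a), len(b)
    prev = np.arange(m + 1, dtype=np.float64) * scoring.gap
    arr_b = np.frombuffer(b.encode("utf-32-le"), dtype=np.uint32) if m else np.empty(0, np.uint32)
    cur = np.empty(m + 1, dtype=np.float64)
    for i in range(1, n + 1):
        cur[0] = i * scoring.gap
        ca = ord(a[i - 1])
        sub = np.where(arr_b == ca, scoring.match, scoring.mismatch)
        diag = prev[:-1] + sub
        up = prev[1:] + scoring.gap
        best = np.maximum(diag, up)
        # left moves depend on cur itself: sequential pass
        for j in range(1, m + 1):
            left = cur[j - 1] + scoring.gap
            cur[j] = best[j - 1] if best[j - 1] >= left else left
        prev, cur = cur, prev
    score = float(prev[m])
    denom = scoring.match * max(n, m)
    normalized = min(1.0, max(0.0, score / denom)) if denom > 0 else 0.0
    return score, normalized


def _term_strings(term, scopes: frozenset = MATCH_SCOPES) -> list[str]:
    out = []
    if term.label:
        out.append(normalize_label(term.label))
    for text, scope in term.synonyms:
        if scope in scopes:
            out.append(normalize_label(text))
    return [s for s in out if s]


def best_lexical_matches(
    sign: SignNode,
    ontology: OntologyGraph,
    scoring: AlignScoring = AlignScoring(),
    threshold: float = 0.85,
    k: int = 1,
) -> list[LexicalMatch]:
    """Top-k terms whose label or synonym best aligns with the sign label.

    Per term, the best normalized score over its label and EXACT/NARROW
    synonyms is kept; terms at or above the threshold are returned sorted by
    descending normalized score, ties broken by ascending term id, relation
    EQUIVALENT and source LEXICAL.  Obsolete terms do not participate.
    """
    if len(ontology) == 0:
        raise ValidationError("cannot match against an empty ontology")
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError("threshold must lie in [0, 1]")
    if k < 1:
        raise ValidationError("k must be >= 1")
    query = normalize_label(sign.label)
    results: list[tuple[float, str, float]] = []
    for tid in sorted(ontology.terms):
        term = ontology.terms[tid]
        if term.obsolete:
            continue
        best: tuple[float, float] | None = None
        for cand in _term_strings(term):
            if not query and not cand:
                continue
            score, norm = nw_score(query, cand, scoring)
            if best is None or norm > best[1]:
                best = (score, norm)
        if best is not None and best[1] >= threshold:
            results.append((best[1], tid, best[0]))
    results.sort(key=lambda r: (-r[0], r[1]))
    return [
        LexicalMatch(
            sign_id=sign.sign_id,
            term_id=tid,
            score=score,
            normalized=norm,
            relation=MatchRelation.EQUIVALENT,
            source=MatchSource.LEXICAL,
        )
        for norm, tid, score in results[:k]
    ]


def _ancestor_levels(sign: SignNode, by_id: dict[str, SignNode]) -> list[list[SignNode]]:
    """Breadth-first ancestor levels, nearest first; raises on cycles."""
    levels: list[list[SignNode]] = []
    seen = {sign.sign_id}
    frontier = [sign]
    while True:
        nxt: list[SignNode] = []
        for node in frontier:
            for pid in node.parent_ids:
                if pid == sign.sign_id:
                    raise ValidationError(
                        f"cycle in sign hierarchy involving {sign.sign_id!r}"
                    )
                if pid in seen or pid not in by_id:
                    continue
                seen.add(pid)
                nxt.append(by_id[pid])
        if not nxt:
            return levels
        levels.append(nxt)
        frontier = nxt
        if len(seen) > len(by_id):  # pragma: no cover - guarded by seen set
            raise ValidationError("cycle in sign hierarchy")


def _check_acyclic(signs: list[SignNode]) -> None:
    by_id = {s.sign_id: s for s in signs}
    # colour-based DFS over the parent relation
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {sid: WHITE for sid in by_id}

    def visit(sid: str) -> None:
        colour[sid] = GREY
        for pid in by_id[sid].parent_ids:
            if pid not in by_id:
                continue
            if colour[pid] == GREY:
                raise ValidationError(f"cycle in sign hierarchy involving {pid!r}")
            if colour[pid] == WHITE:
                visit(pid)
        colour[sid] = BLACK

    for sid in by_id:
        if colour[sid] == WHITE:
            visit(sid)


def structural_superclasses(
    signs: list[SignNode],
    ontology: OntologyGraph,
    scoring: AlignScoring = AlignScoring(),
    threshold: float = 0.85,
) -> list[LexicalMatch]:
    """SUBCLASS_OF assignments for signs lacking a direct lexical match.

    For each sign whose own label has no accepted EQUIVALENT match, walk its
    ancestors in the sign hierarchy nearest-first (breadth-first by level,
    within a level in parent-list order); the first ancestor with an accepted
    lexical match contributes a SUBCLASS_OF match to that ancestor's term.
    """
    _check_acyclic(signs)
    by_id = {s.sign_id: s for s in signs}

    best_cache: dict[str, LexicalMatch | None] = {}

    def best_for(sign: SignNode) -> LexicalMatch | None:
        if sign.sign_id not in best_cache:
            hits = best_lexical_matches(sign, ontology, scoring, threshold, k=1)
            best_cache[sign.sign_id] = hits[0] if hits else None
        return best_cache[sign.sign_id]

    out: list[LexicalMatch] = []
    for sign in signs:
        if best_for(sign) is not None:
            continue  # own match takes precedence; no structural match emitted
        for level in _ancestor_levels(sign, by_id):
            hit = next((h for a in level if (h := best_for(a)) is not None), None)
            if hit is not None:
                out.append(
                    LexicalMatch(
                        sign_id=sign.sign_id,
                        term_id=hit.term_id,
                        score=hit.score,
                        normalized=hit.normalized,
                        relation=MatchRelation.SUBCLASS_OF,
                        source=MatchSource.STRUCTURAL,
                    )
                )
                break
    return out
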