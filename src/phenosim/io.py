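"""Readers and writers for the flat tab-separated exchange formats.

All formats are plain TSV; lines starting with ``#`` are comments (writers
may emit provenance headers).  Similarity matrices are written with a header
row of target ids, query ids in the first column, and fixed 6-decimal
formatting so outputs are byte-stable.
"""

from __future__ import annotations

import os
import tempfile
from contextlib import contextmanager
from typing import IO, Iterable, Iterator

import pandas as pd

from .eqreason import BridgeAxiom, EQDefinition, HomologyMap
from .errors import ParseError
from .evaluate import AssociationSet, ROCCurve
from .lexmap import LexicalMatch, SignNode
from .similarity import AnnotationCorpus, ICTable


@contextmanager
def atomic_write(path) -> Iterator[IO[str]]:
    """Write to a temp file in the destination directory, then rename."""
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp", text=True)
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _rows(path, n_fields: int, what: str, allow_fewer: bool = False):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < n_fields and not allow_fewer:
                raise ParseError(
                    f"{path}, line {lineno}: expected {n_fields} "
                    f"tab-separated fields for {what}, got {len(fields)}"
                )
            yield lineno, fields


def read_annotations(path) -> AnnotationCorpus:
    """Annotation TSV: entity_id <tab> term_id, one pair per line."""
    return AnnotationCorpus.from_pairs(
        (f[0], f[1]) for _, f in _rows(path, 2, "annotation")
    )


def write_annotations(corpus: AnnotationCorpus, fh: IO[str]) -> None:
    for eid in corpus.ids():
        for term in sorted(corpus.profiles[eid].terms):
            fh.write(f"{eid}\t{term}\n")


def read_truth(path) -> AssociationSet:
    """Truth TSV: model_id <tab> disease_id."""
    return AssociationSet((f[0], f[1]) for _, f in _rows(path, 2, "association"))


def write_truth(truth: AssociationSet, fh: IO[str]) -> None:
    for m, d in sorted(truth.positives):
        fh.write(f"{m}\t{d}\n")


def write_ic(table: ICTable, fh: IO[str]) -> None:
    fh.write("term_id\tic_bits\n")
    for term in sorted(table.ic):
        fh.write(f"{term}\t{table.ic[term]:.6f}\n")


def write_matrix(matrix: pd.DataFrame, fh: IO[str]) -> None:
    fh.write("query_id\t" + "\t".join(matrix.columns) + "\n")
    for qid, row in matrix.iterrows():
        fh.write(qid + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def read_eq_definitions(path) -> list[EQDefinition]:
    """EQ TSV: phenotype_id <tab> entity_id <tab> quality_id."""
    return [
        EQDefinition(phenotype=f[0], entity=f[1], quality=f[2])
        for _, f in _rows(path, 3, "EQ definition")
    ]


def read_homology(path) -> HomologyMap:
    """Homology TSV: term_a <tab> term_b."""
    return HomologyMap((f[0], f[1]) for _, f in _rows(path, 2, "homology pair"))


def write_bridge(axioms: Iterable[BridgeAxiom], fh: IO[str]) -> None:
    fh.write("sub_id\tsuper_id\n")
    for ax in sorted(axioms, key=lambda a: (a.sub, a.super)):
        fh.write(f"{ax.sub}\t{ax.super}\n")


def read_signs(path) -> list[SignNode]:
    """Sign hierarchy TSV: sign_id <tab> label <tab> parent_id (may be empty).

    A sign with several parents repeats its row with different parent ids.
    """
    nodes: dict[str, SignNode] = {}
    for lineno, f in _rows(path, 2, "clinical sign", allow_fewer=False):
        sign_id, label = f[0], f[1]
        parent = f[2] if len(f) > 2 and f[2] else None
        if sign_id not in nodes:
            nodes[sign_id] = SignNode(sign_id=sign_id, label=label, parent_ids=[])
        if parent and parent not in nodes[sign_id].parent_ids:
            nodes[sign_id].parent_ids.append(parent)
    return list(nodes.values())


def write_mappings(matches: Iterable[LexicalMatch], fh: IO[str]) -> None:
    fh.write("sign_id\tterm_id\trelation\tnormalized_score\tsource\n")
    for m in matches:
        fh.write(
            f"{m.sign_id}\t{m.term_id}\t{m.relation.value}\t"
            f"{m.normalized:.6f}\t{m.source.value}\n"
        )


def write_roc(curve: ROCCurve, fh: IO[str]) -> None:
    fh.write("rank\tfpr\ttpr\n")
    for rank, (fpr, tpr) in enumerate(curve.points):
        fh.write(f"{rank}\t{fpr:.6f}\t{tpr:.6f}\n")
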