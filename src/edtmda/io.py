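"""Readers and writers for the TSV matrix dialect, the DAG corpus edge-list
dialect, and long-format prediction tables.

Matrix dialect: first row is a tab-separated header of column ids with an
empty leading cell, each following row starts with its row id; all cells are
strict floats. The DAG corpus is a two-column child<TAB>parent edge list plus
a disease<TAB>term roots file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .types import AssociationMatrix, DiseaseDagCorpus, SimilarityMatrix

__all__ = [
    "ParseError",
    "read_matrix",
    "write_matrix",
    "read_association_matrix",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_dag_corpus",
    "write_dag_corpus",
    "write_predictions",
    "read_predictions",
]


class ParseError(ValueError):
    """Malformed input file; message carries the file and line number."""


def read_matrix(path) -> tuple[list[str], list[str], np.ndarray]:
    """Read the TSV matrix dialect: (row ids, column ids, values)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    col_ids = header[1:]
    if len(set(col_ids)) != len(col_ids):
        dup = next(c for c in col_ids if col_ids.count(c) > 1)
        raise ParseError(f"{path}:1: duplicate column id {dup!r}")
    row_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(col_ids) + 1:
            raise ParseError(
                f"{path}:{lineno}: expected {len(col_ids) + 1} cells, got {len(cells)}"
            )
        rid = cells[0]
        if rid in seen:
            raise ParseError(f"{path}:{lineno}: duplicate row id {rid!r}")
        seen.add(rid)
        try:
            rows.append([float(c) for c in cells[1:]])
        except ValueError as e:
            raise ParseError(f"{path}:{lineno}: non-numeric cell ({e})") from None
        row_ids.append(rid)
    return row_ids, col_ids, np.asarray(rows, dtype=float).reshape(len(row_ids), len(col_ids))


def write_matrix(row_ids, col_ids, values: np.ndarray, path) -> None:
    path = Path(path)
    values = np.asarray(values)
    with path.open("w") as fh:
        fh.write("\t".join(["", *map(str, col_ids)]) + "\n")
        for rid, row in zip(row_ids, values):
            fh.write("\t".join([str(rid), *(repr(float(x)) for x in row)]) + "\n")


def read_association_matrix(path) -> AssociationMatrix:
    row_ids, col_ids, values = read_matrix(path)
    if not np.isin(values, (0.0, 1.0)).all():
        raise ParseError(f"{path}: association matrix entries must be 0 or 1")
    return AssociationMatrix(tuple(row_ids), tuple(col_ids), values.astype(np.int8))


def read_similarity_matrix(path) -> SimilarityMatrix:
    row_ids, col_ids, values = read_matrix(path)
    if row_ids != col_ids:
        raise ParseError(f"{path}: similarity matrix row and column ids differ")
    return SimilarityMatrix(tuple(row_ids), values)


def write_similarity_matrix(sim: SimilarityMatrix, path) -> None:
    write_matrix(sim.ids, sim.ids, sim.values, path)


def read_dag_corpus(edges_path, roots_path, delta: float = 0.5) -> DiseaseDagCorpus:
    """Load child<TAB>parent edges and disease<TAB>term roots into a corpus."""
    edges_path, roots_path = Path(edges_path), Path(roots_path)
    parents: dict[str, set[str]] = {}
    for lineno, line in enumerate(edges_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != 2:
            raise ParseError(f"{edges_path}:{lineno}: expected 2 columns, got {len(cells)}")
        child, parent = cells
        parents.setdefault(child, set()).add(parent)
        parents.setdefault(parent, set())
    disease_term: dict[str, str] = {}
    for lineno, line in enumerate(roots_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != 2:
            raise ParseError(f"{roots_path}:{lineno}: expected 2 columns, got {len(cells)}")
        disease, term = cells
        if disease in disease_term:
            raise ParseError(f"{roots_path}:{lineno}: duplicate disease {disease!r}")
        disease_term[disease] = term
        parents.setdefault(term, set())  # singleton DAGs need no edges
    try:
        return DiseaseDagCorpus(
            parents={t: frozenset(ps) for t, ps in parents.items()},
            disease_term=disease_term,
            delta=delta,
        )
    except ValueError as e:
        raise ParseError(f"{edges_path}: {e}") from None


def write_dag_corpus(corpus: DiseaseDagCorpus, edges_path, roots_path) -> None:
    with Path(edges_path).open("w") as fh:
        for child in sorted(corpus.parents):
            for parent in sorted(corpus.parents[child]):
                fh.write(f"{child}\t{parent}\n")
    with Path(roots_path).open("w") as fh:
        for disease in sorted(corpus.disease_term):
            fh.write(f"{disease}\t{corpus.disease_term[disease]}\n")


def write_predictions(
    scores: np.ndarray, assoc: AssociationMatrix, path, top_k: int | None = None
) -> None:
    """Long-format candidate table: disease, miRNA, score, rank.

    Only unknown pairs are emitted, sorted by disease then descending score
    with ties broken by miRNA id; ranks are 1..n per disease.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("disease\tmirna\tscore\trank\n")
        for j, disease in enumerate(assoc.disease_ids):
            rows = np.flatnonzero(assoc.Y[:, j] == 0)
            entries = sorted(
                ((assoc.mirna_ids[i], float(scores[i, j])) for i in rows),
                key=lambda t: (-t[1], t[0]),
            )
            if top_k is not None:
                entries = entries[:top_k]
            for rank, (mirna, score) in enumerate(entries, start=1):
                fh.write(f"{disease}\t{mirna}\t{score!r}\t{rank}\n")


def read_predictions(path) -> list[tuple[str, str, float, int]]:
    lines = Path(path).read_text().splitlines()
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        disease, mirna, score, rank = line.split("\t")
        out.append((disease, mirna, float(score), int(rank)))
    return out
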