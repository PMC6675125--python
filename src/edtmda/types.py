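"""Core labelled-matrix and DAG-corpus containers shared across the package."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "DiseaseDagCorpus",
    "FeatureMatrix",
]


def _check_unique(ids, what: str) -> tuple[str, ...]:
    ids = tuple(str(x) for x in ids)
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)
    return ids


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary miRNA x disease association matrix with ordered identifiers.

    ``Y[i, j] == 1`` means miRNA ``mirna_ids[i]`` is a known associate of
    disease ``disease_ids[j]``; 0 means the pair is unlabelled (candidate).
    """

    mirna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    Y: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mirna_ids", _check_unique(self.mirna_ids, "miRNA"))
        object.__setattr__(self, "disease_ids", _check_unique(self.disease_ids, "disease"))
        Y = np.asarray(self.Y)
        if Y.ndim != 2 or Y.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValueError(
                f"Y shape {Y.shape} does not match id counts "
                f"({len(self.mirna_ids)}, {len(self.disease_ids)})"
            )
        if not np.isin(Y, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        Y = Y.astype(np.int8)
        Y.setflags(write=False)
        object.__setattr__(self, "Y", Y)

    @property
    def nm(self) -> int:
        return len(self.mirna_ids)

    @property
    def nd(self) -> int:
        return len(self.disease_ids)

    def positive_pairs(self) -> np.ndarray:
        """(k, 2) int array of (miRNA index, disease index) with Y == 1."""
        return np.argwhere(self.Y == 1)

    def unknown_pairs(self) -> np.ndarray:
        """(k, 2) int array of (miRNA index, disease index) with Y == 0."""
        return np.argwhere(self.Y == 0)

    @property
    def n_positive(self) -> int:
        return int(self.Y.sum())

    def fingerprint(self) -> str:
        """Stable digest of Y; used to guard against stale feature matrices."""
        h = hashlib.sha256()
        h.update(str(self.Y.shape).encode())
        h.update(np.ascontiguousarray(self.Y).tobytes())
        return h.hexdigest()

    def with_removed(self, pairs) -> "AssociationMatrix":
        """Copy with the given (i, j) associations set to 0."""
        Y = self.Y.copy()
        for i, j in pairs:
            Y[i, j] = 0
        return AssociationMatrix(self.mirna_ids, self.disease_ids, Y)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric similarity matrix in [0, 1] with ordered identifiers."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ids", _check_unique(self.ids, "entity"))
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"similarity matrix shape {v.shape}, expected ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("similarity matrix is not symmetric")
        if np.nanmin(v) < -1e-12 or np.nanmax(v) > 1 + 1e-12:
            raise ValueError("similarity values outside [0, 1]")
        v = np.clip((v + v.T) / 2.0, 0.0, 1.0)
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, entity: str) -> int:
        try:
            return self.ids.index(entity)
        except ValueError:
            raise KeyError(f"unknown entity id: {entity!r}") from None


class MissingDagError(KeyError):
    """Raised when a semantic-similarity operation needs a DAG the corpus lacks."""


@dataclass(frozen=True)
class DiseaseDagCorpus:
    """Ancestor DAGs for a set of diseases over a shared term vocabulary.

    ``parents`` maps each term to its (possibly empty) set of parent terms;
    the relation must be acyclic. ``disease_term`` maps a disease identifier
    to its own most-specific term; diseases absent from the map have no DAG.
    ``delta`` is the per-edge semantic decay factor, strictly in (0, 1).
    """

    parents: dict[str, frozenset[str]]
    disease_term: dict[str, str]
    delta: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.delta < 1.0):
            raise ValueError(f"delta must lie strictly in (0, 1), got {self.delta}")
        parents = {str(t): frozenset(str(p) for p in ps) for t, ps in self.parents.items()}
        # close the vocabulary over parents that only appear on the right side
        for ps in list(parents.values()):
            for p in ps:
                parents.setdefault(p, frozenset())
        object.__setattr__(self, "parents", parents)
        object.__setattr__(
            self, "disease_term", {str(d): str(t) for d, t in self.disease_term.items()}
        )
        for d, t in self.disease_term.items():
            if t not in parents:
                raise ValueError(f"disease {d!r} maps to unknown term {t!r}")
        self._assert_acyclic()

    def _assert_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 = in progress, 1 = done

        def visit(t: str, stack: list[str]) -> None:
            if state.get(t) == 1:
                return
            if state.get(t) == 0:
                cycle = stack[stack.index(t):] + [t]
                raise ValueError("parent relation contains a cycle: " + " -> ".join(cycle))
            state[t] = 0
            stack.append(t)
            for p in self.parents[t]:
                visit(p, stack)
            stack.pop()
            state[t] = 1

        for t in self.parents:
            visit(t, [])

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(sorted(self.parents))

    def has_dag(self, disease: str) -> bool:
        return disease in self.disease_term

    def _require(self, disease: str) -> str:
        if disease not in self.disease_term:
            raise MissingDagError(f"disease {disease!r} has no DAG in the corpus")
        return self.disease_term[disease]

    @lru_cache(maxsize=None)
    def _closure(self, term: str) -> frozenset[str]:
        out = {term}
        frontier = [term]
        while frontier:
            t = frontier.pop()
            for p in self.parents[t]:
                if p not in out:
                    out.add(p)
                    frontier.append(p)
        return frozenset(out)

    def ancestor_closure(self, disease: str) -> frozenset[str]:
        """T(D): the disease's own term plus all of its ancestors."""
        return self._closure(self._require(disease))

    def __hash__(self):  # pragma: no cover - needed for lru_cache on methods
        return id(self)

    def __eq__(self, other):
        return self is other


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-entity feature table, tagged with the fingerprint of the Y it saw.

    The fingerprint is the staleness guard: every consumer that trains or
    scores against an association matrix must verify the features were built
    from that exact matrix (cross-validation masks Y, so features go stale).
    """

    entity_ids: tuple[str, ...]
    names: tuple[str, ...]
    values: np.ndarray
    y_fingerprint: str = ""

    def __post_init__(self):
        object.__setattr__(self, "entity_ids", _check_unique(self.entity_ids, "entity"))
        object.__setattr__(self, "names", tuple(str(n) for n in self.names))
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.entity_ids), len(self.names)):
            raise ValueError(
                f"feature matrix shape {v.shape}, expected "
                f"({len(self.entity_ids)}, {len(self.names)})"
            )
        if not np.isfinite(v).all():
            raise ValueError("feature matrix contains non-finite entries")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def d(self) -> int:
        return len(self.names)

    def check_fresh(self, assoc: AssociationMatrix) -> None:
        if self.y_fingerprint != assoc.fingerprint():
            raise StaleFeaturesError(
                "feature matrix was built from a different association matrix; "
                "recompute features after masking Y"
            )


class StaleFeaturesError(RuntimeError):
    """Features were computed from a Y other than the one being evaluated."""
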