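"""Disease semantic similarity, Gaussian interaction-profile kernels and the
integrated miRNA/disease similarity matrices.

Two semantic models are computed on disease ancestor DAGs: model 1 decays a
term's contribution geometrically with its distance from the disease; model 2
weights a term by how rarely it occurs across all disease DAGs. Both are
averaged for DAG-bearing disease pairs; everything else falls back to the
Gaussian interaction-profile (GIP) kernel computed from the association
matrix. The miRNA side uses a precomputed functional-similarity matrix where
available, with the same GIP fallback.
"""

from __future__ import annotations

import math

import numpy as np

from .types import AssociationMatrix, DiseaseDagCorpus, MissingDagError, SimilarityMatrix

__all__ = [
    "semantic_value_m1",
    "semantic_sim_m1",
    "term_information",
    "semantic_value_m2",
    "semantic_sim_m2",
    "semantic_similarity_matrices",
    "gip_mirna",
    "gip_disease",
    "integrate_disease",
    "integrate_mirna",
    "compute_integrated_similarities",
]


# ---------------------------------------------------------------------------
# semantic model 1: geometric decay along the DAG


def semantic_value_m1(corpus: DiseaseDagCorpus, disease: str):
    """Contribution map and semantic value of ``disease`` under model 1.

    The disease's own term contributes 1; every other term in the ancestor
    closure contributes ``delta`` times the maximum contribution among its
    children inside the closure. Returns ``(contributions, value)`` where
    ``value`` is the sum of contributions over the closure.
    """
    root = corpus.disease_term.get(disease)
    if root is None:
        raise MissingDagError(f"disease {disease!r} has no DAG in the corpus")
    closure = corpus.ancestor_closure(disease)
    # children within the closure, indexed by parent
    children: dict[str, list[str]] = {t: [] for t in closure}
    for t in closure:
        for p in corpus.parents[t]:
            if p in closure:
                children[p].append(t)

    contrib: dict[str, float] = {}

    def value_of(term: str) -> float:
        if term in contrib:
            return contrib[term]
        if term == root:
            contrib[term] = 1.0
        else:
            contrib[term] = corpus.delta * max(value_of(c) for c in children[term])
        return contrib[term]

    for t in closure:
        value_of(t)
    return contrib, float(sum(contrib.values()))


def semantic_sim_m1(corpus: DiseaseDagCorpus, d_i: str, d_j: str) -> float:
    """Model-1 semantic similarity: shared-ancestor contributions over total."""
    ci, vi = semantic_value_m1(corpus, d_i)
    cj, vj = semantic_value_m1(corpus, d_j)
    shared = set(ci) & set(cj)
    if not shared:
        return 0.0
    return sum(ci[t] + cj[t] for t in shared) / (vi + vj)


# ---------------------------------------------------------------------------
# semantic model 2: DAG-frequency information content


def term_information(corpus: DiseaseDagCorpus) -> dict[str, float]:
    """-log(fraction of disease DAGs containing each term), natural log.

    Only terms that occur in at least one DAG get a value; the denominator is
    the number of diseases that have a DAG.
    """
    n_dags = len(corpus.disease_term)
    if n_dags == 0:
        return {}
    counts: dict[str, int] = {}
    for d in corpus.disease_term:
        for t in corpus.ancestor_closure(d):
            counts[t] = counts.get(t, 0) + 1
    return {t: -math.log(c / n_dags) for t, c in counts.items()}


def semantic_value_m2(corpus: DiseaseDagCorpus, disease: str, info: dict[str, float] | None = None):
    """Contribution map and semantic value of ``disease`` under model 2."""
    if info is None:
        info = term_information(corpus)
    closure = corpus.ancestor_closure(disease)
    contrib = {}
    for t in closure:
        if t not in info:
            raise RuntimeError(f"term {t!r} appears in no DAG; corpus is inconsistent")
        contrib[t] = info[t]
    return contrib, float(sum(contrib.values()))


def semantic_sim_m2(
    corpus: DiseaseDagCorpus, d_i: str, d_j: str, info: dict[str, float] | None = None
) -> float:
    """Model-2 semantic similarity between two DAG-bearing diseases."""
    if info is None:
        info = term_information(corpus)
    ci, vi = semantic_value_m2(corpus, d_i, info)
    cj, vj = semantic_value_m2(corpus, d_j, info)
    if d_i == d_j:
        return 1.0
    shared = set(ci) & set(cj)
    denom = vi + vj
    if not shared or denom == 0.0:
        # denom == 0 only when every shared term occurs in every DAG
        return 0.0
    return sum(ci[t] + cj[t] for t in shared) / denom


def semantic_similarity_matrices(
    corpus: DiseaseDagCorpus, disease_ids
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense SS1 and SS2 over ``disease_ids`` plus a has-DAG boolean mask.

    Entries involving a disease without a DAG are left at 0 and flagged False
    in the mask; the integration step substitutes the GIP kernel there.
    """
    disease_ids = list(disease_ids)
    nd = len(disease_ids)
    has_dag = np.array([corpus.has_dag(d) for d in disease_ids], dtype=bool)
    ss1 = np.zeros((nd, nd))
    ss2 = np.zeros((nd, nd))
    info = term_information(corpus)
    m1 = {d: semantic_value_m1(corpus, d) for d, ok in zip(disease_ids, has_dag) if ok}
    m2 = {d: semantic_value_m2(corpus, d, info) for d, ok in zip(disease_ids, has_dag) if ok}
    for a in range(nd):
        if not has_dag[a]:
            continue
        da = disease_ids[a]
        c1a, v1a = m1[da]
        c2a, v2a = m2[da]
        ss1[a, a] = 1.0
        ss2[a, a] = 1.0
        for b in range(a + 1, nd):
            if not has_dag[b]:
                continue
            db = disease_ids[b]
            c1b, v1b = m1[db]
            shared = set(c1a) & set(c1b)
            if shared:
                ss1[a, b] = ss1[b, a] = sum(c1a[t] + c1b[t] for t in shared) / (v1a + v1b)
                c2b, v2b = m2[db]
                denom = v2a + v2b
                if denom > 0.0:
                    ss2[a, b] = ss2[b, a] = sum(c2a[t] + c2b[t] for t in shared) / denom
    return ss1, ss2, has_dag


# ---------------------------------------------------------------------------
# Gaussian interaction-profile kernels


def _gip(profiles: np.ndarray, gamma_prime: float) -> np.ndarray:
    """exp(-gamma * ||p_i - p_j||^2) with gamma scaled by the mean profile norm."""
    norms = (profiles.astype(float) ** 2).sum(axis=1)
    mean_norm = norms.mean()
    if mean_norm == 0.0:
        raise ValueError("all interaction profiles are zero; kernel bandwidth is undefined")
    gamma = gamma_prime / mean_norm
    sq = norms[:, None] + norms[None, :] - 2.0 * (profiles @ profiles.T)
    np.maximum(sq, 0.0, out=sq)
    k = np.exp(-gamma * sq)
    np.fill_diagonal(k, 1.0)
    return (k + k.T) / 2.0


def gip_mirna(assoc: AssociationMatrix, gamma_prime: float = 1.0) -> SimilarityMatrix:
    """GIP kernel over miRNA interaction profiles (rows of Y)."""
    return SimilarityMatrix(assoc.mirna_ids, _gip(assoc.Y.astype(float), gamma_prime))


def gip_disease(assoc: AssociationMatrix, gamma_prime: float = 1.0) -> SimilarityMatrix:
    """GIP kernel over disease interaction profiles (columns of Y)."""
    return SimilarityMatrix(assoc.disease_ids, _gip(assoc.Y.astype(float).T, gamma_prime))


# ---------------------------------------------------------------------------
# integration


def integrate_disease(
    ss1: np.ndarray, ss2: np.ndarray, gd: SimilarityMatrix, has_dag: np.ndarray
) -> SimilarityMatrix:
    """SD: mean of the two semantic models where both diseases have DAGs,
    GIP kernel otherwise."""
    sem = (np.asarray(ss1) + np.asarray(ss2)) / 2.0
    both = np.outer(has_dag, has_dag)
    values = np.where(both, sem, gd.values)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(gd.ids, values)


def integrate_mirna(
    fs: np.ndarray, gm: SimilarityMatrix, has_fs: np.ndarray
) -> SimilarityMatrix:
    """SM: functional similarity where both miRNAs have it, GIP otherwise."""
    both = np.outer(has_fs, has_fs)
    values = np.where(both, np.asarray(fs), gm.values)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(gm.ids, values)


def compute_integrated_similarities(
    assoc: AssociationMatrix,
    fs: SimilarityMatrix | None,
    corpus: DiseaseDagCorpus,
    gamma_prime: float = 1.0,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Full similarity pipeline: (SM, SD) for the given association matrix.

    ``fs`` may cover only a subset of the miRNAs in ``assoc``; rows absent
    from it fall back to the GIP kernel. Pass ``fs=None`` for a pure-GIP
    miRNA similarity.
    """
    gm = gip_mirna(assoc, gamma_prime)
    gd = gip_disease(assoc, gamma_prime)

    nm = assoc.nm
    fs_full = np.zeros((nm, nm))
    has_fs = np.zeros(nm, dtype=bool)
    if fs is not None:
        pos = {m: k for k, m in enumerate(fs.ids)}
        idx = [(i, pos[m]) for i, m in enumerate(assoc.mirna_ids) if m in pos]
        if idx:
            rows = np.array([i for i, _ in idx])
            cols = np.array([k for _, k in idx])
            fs_full[np.ix_(rows, rows)] = fs.values[np.ix_(cols, cols)]
            has_fs[rows] = True
    sm = integrate_mirna(fs_full, gm, has_fs)

    ss1, ss2, has_dag = semantic_similarity_matrices(corpus, assoc.disease_ids)
    sd = integrate_disease(ss1, ss2, gd, has_dag)
    return sm, sd
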