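"""Synthetic fixture generator.

Produces the three pipeline inputs — a binary association matrix with planted
bicluster structure, a block-correlated miRNA functional-similarity matrix,
and a disease DAG corpus with shared upper-level terms — entirely from one
seed, so the whole pipeline is testable offline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import AssociationMatrix, DiseaseDagCorpus, SimilarityMatrix

__all__ = [
    "SyntheticConfig",
    "generate_dag_corpus",
    "generate_associations",
    "generate_mirna_similarity",
    "generate_inputs",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Shape and noise knobs of the planted-block fixtures.

    Within-block pairs are positive with probability ``contrast`` times the
    cross-block probability, calibrated so the expected overall positive rate
    equals ``density``; ``noise`` then flips each entry independently.
    """

    nm: int = 60
    nd: int = 40
    n_blocks: int = 6
    density: float = 0.10
    contrast: float = 500.0
    noise: float = 0.002
    block_skew: float = 1.0
    dag_depth: int = 3
    dag_branching: int = 2
    frac_no_dag: float = 0.1
    frac_no_fs: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("density", "noise", "frac_no_dag", "frac_no_fs"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_blocks < 1 or self.nm < 1 or self.nd < 1:
            raise ValueError("nm, nd and n_blocks must be positive")
        if self.density * self.nm * self.nd < self.n_blocks:
            raise ValueError("density too low for the requested number of blocks")


def _block_labels(
    n: int, n_blocks: int, skew: float, rng: np.random.Generator
) -> np.ndarray:
    """Random assignment with block weights proportional to (k+1)^-skew.

    ``skew > 0`` makes block sizes (and hence per-entity degrees) heterogeneous,
    echoing the head-heavy degree distribution of curated association data.
    Every block is guaranteed non-empty when n >= n_blocks.
    """
    w = (np.arange(1, n_blocks + 1, dtype=float)) ** (-skew)
    labels = rng.choice(n_blocks, size=n, p=w / w.sum())
    if n >= n_blocks:
        forced = rng.permutation(n)[:n_blocks]
        labels[forced] = np.arange(n_blocks)
    return labels


def generate_associations(cfg: SyntheticConfig):
    """Planted-block association matrix.

    Returns ``(assoc, labels)`` where ``labels`` is a dict with the miRNA and
    disease block assignments (the ground truth for signal-recovery checks).
    """
    rng = np.random.default_rng(cfg.seed)
    m_blocks = _block_labels(cfg.nm, cfg.n_blocks, cfg.block_skew, rng)
    d_blocks = _block_labels(cfg.nd, cfg.n_blocks, cfg.block_skew, rng)
    same = m_blocks[:, None] == d_blocks[None, :]
    frac_in = same.mean()
    # solve contrast * p_out * frac_in + p_out * (1 - frac_in) = density
    p_out = cfg.density / (cfg.contrast * frac_in + (1.0 - frac_in))
    p_in = min(1.0, cfg.contrast * p_out)
    prob = np.where(same, p_in, p_out)
    Y = (rng.random((cfg.nm, cfg.nd)) < prob).astype(np.int8)
    if cfg.noise > 0:
        flips = rng.random((cfg.nm, cfg.nd)) < cfg.noise
        Y = np.where(flips, 1 - Y, Y)
    mirna_ids = tuple(f"mir-{i:03d}" for i in range(cfg.nm))
    disease_ids = tuple(f"dis-{j:03d}" for j in range(cfg.nd))
    assoc = AssociationMatrix(mirna_ids, disease_ids, Y)
    return assoc, {"mirna_blocks": m_blocks, "disease_blocks": d_blocks}


def generate_mirna_similarity(
    cfg: SyntheticConfig, mirna_blocks: np.ndarray
) -> SimilarityMatrix | None:
    """Block-correlated functional similarity over the miRNAs that have one.

    Within-block entries are drawn Beta(5, 2), cross-block Beta(2, 5); the
    matrix is symmetrised with unit diagonal. A ``frac_no_fs`` fraction of
    miRNAs is left out entirely (the integration step falls back to the GIP
    kernel for them); returns None when no miRNA has functional similarity.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    nm = cfg.nm
    keep = rng.random(nm) >= cfg.frac_no_fs
    if cfg.frac_no_fs >= 1.0:
        keep[:] = False
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        return None
    k = idx.size
    blocks = mirna_blocks[idx]
    same = blocks[:, None] == blocks[None, :]
    hi = rng.beta(5, 2, size=(k, k))
    lo = rng.beta(2, 5, size=(k, k))
    v = np.where(same, hi, lo)
    v = (v + v.T) / 2.0
    np.fill_diagonal(v, 1.0)
    ids = tuple(f"mir-{i:03d}" for i in idx)
    return SimilarityMatrix(ids, v)


def generate_dag_corpus(cfg: SyntheticConfig, disease_blocks: np.ndarray) -> DiseaseDagCorpus:
    """Random layered DAGs with shared upper-level terms.

    A shared term hierarchy of ``dag_depth`` layers is built per block (so
    same-block diseases overlap heavily in their ancestor sets) on top of a
    handful of global roots; each DAG-bearing disease gets its own leaf term
    attached to one or two layer-``dag_depth - 1`` terms of its block. With
    ``dag_depth == 0`` every DAG is a single node.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    nd = cfg.nd
    parents: dict[str, set[str]] = {}
    layers_by_block: list[list[list[str]]] = []

    n_roots = max(1, cfg.n_blocks // 2)
    roots = [f"root-{r}" for r in range(n_roots)]
    for t in roots:
        parents[t] = set()

    for b in range(cfg.n_blocks):
        layers: list[list[str]] = [[roots[b % n_roots]]]
        width = 1
        for lvl in range(1, cfg.dag_depth):
            width = max(1, width * cfg.dag_branching)
            layer = [f"b{b}-l{lvl}-t{t}" for t in range(width)]
            for term in layer:
                n_par = 1 + int(rng.random() < 0.3 and len(layers[-1]) > 1)
                ps = rng.choice(len(layers[-1]), size=min(n_par, len(layers[-1])), replace=False)
                parents[term] = {layers[-1][p] for p in ps}
            layers.append(layer)
        layers_by_block.append(layers)

    disease_term: dict[str, str] = {}
    has_dag = rng.random(nd) >= cfg.frac_no_dag
    if cfg.frac_no_dag >= 1.0:
        has_dag[:] = False
    for j in range(nd):
        if not has_dag[j]:
            continue
        name = f"dis-{j:03d}"
        term = f"term-{name}"
        if cfg.dag_depth == 0:
            parents[term] = set()
        else:
            layers = layers_by_block[disease_blocks[j] % cfg.n_blocks]
            top = layers[-1]
            n_par = 1 + int(rng.random() < 0.5 and len(top) > 1)
            ps = rng.choice(len(top), size=min(n_par, len(top)), replace=False)
            parents[term] = {top[p] for p in ps}
        disease_term[name] = term

    return DiseaseDagCorpus(
        parents={t: frozenset(ps) for t, ps in parents.items()},
        disease_term=disease_term,
    )


def generate_inputs(cfg: SyntheticConfig):
    """All three pipeline inputs plus ground-truth block labels."""
    assoc, labels = generate_associations(cfg)
    fs = generate_mirna_similarity(cfg, labels["mirna_blocks"])
    corpus = generate_dag_corpus(cfg, labels["disease_blocks"])
    return assoc, fs, corpus, labels
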