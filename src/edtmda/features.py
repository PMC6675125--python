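"""Per-entity feature extraction from similarity matrices and the association
matrix: statistical summaries, graph-theoretic centralities, and truncated-SVD
factorization features. The three blocks are concatenated into one feature
matrix per side (miRNA and disease), tagged with the fingerprint of the Y
they were derived from.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .types import AssociationMatrix, FeatureMatrix, SimilarityMatrix

__all__ = [
    "FeatureConfig",
    "statistical_features",
    "graph_features",
    "factorization_features",
    "build_feature_matrices",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs for the feature catalogue. Defaults give d = 13 + 6 + 13 = 32.

    ``n_noise_features`` appends that many pure-noise columns to each side
    (deterministic given Y); used to probe how much the per-learner
    dimensionality reduction buys when the catalogue carries junk.
    """

    n_hist_bins: int = 10
    n_neighbors: int = 5
    svd_rank: int = 11
    pagerank_damping: float = 0.85
    n_noise_features: int = 0
    noise_scale: float = 0.1


def statistical_features(
    sim: SimilarityMatrix, assoc_profile: np.ndarray, config: FeatureConfig = FeatureConfig()
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Per-entity summary statistics of the similarity row and Y profile.

    Columns: sum and mean of the similarity row excluding self, equal-width
    histogram proportions of that row over [0, 1], and the entity's degree in
    Y (its association-profile sum).
    """
    v = sim.values
    n = v.shape[0]
    off = v[~np.eye(n, dtype=bool)].reshape(n, n - 1) if n > 1 else np.zeros((n, 0))
    row_sum = off.sum(axis=1)
    row_mean = off.mean(axis=1) if n > 1 else np.zeros(n)
    bins = np.linspace(0.0, 1.0, config.n_hist_bins + 1)
    if n > 1:
        hist = np.stack([np.histogram(row, bins=bins)[0] for row in off]).astype(float)
        hist /= n - 1
    else:
        hist = np.zeros((n, config.n_hist_bins))
    degree = np.asarray(assoc_profile, dtype=float).reshape(n, -1).sum(axis=1)
    block = np.column_stack([row_sum, row_mean, hist, degree])
    names = (
        "sim_sum",
        "sim_mean",
        *(f"sim_hist_{k}" for k in range(config.n_hist_bins)),
        "assoc_degree",
    )
    return block, names


def _similarity_graph(sim: SimilarityMatrix) -> nx.Graph:
    """Weighted graph on the similarity matrix: edges where sim > 0, no
    self-loops; ``weight`` is the similarity, ``distance`` is 1 - similarity."""
    v = sim.values
    g = nx.Graph()
    g.add_nodes_from(range(v.shape[0]))
    ii, jj = np.nonzero(np.triu(v, k=1))
    g.add_weighted_edges_from(
        (int(i), int(j), float(v[i, j])) for i, j in zip(ii, jj)
    )
    for _, _, d in g.edges(data=True):
        d["distance"] = 1.0 - d["weight"]
    return g


def graph_features(
    sim: SimilarityMatrix, config: FeatureConfig = FeatureConfig()
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Centrality measures of each entity in the weighted similarity network.

    Columns: number of neighbours above the mean off-diagonal similarity,
    mean similarity of the k nearest neighbours, weighted betweenness,
    weighted closeness (distance = 1 - similarity; per-component, networkx
    convention), eigenvector centrality of the weighted adjacency (leading
    eigenvector, L2-normalised), and PageRank (sums to 1).
    """
    v = sim.values
    n = v.shape[0]
    if n == 1:
        block = np.zeros((1, 6))
        block[0, 5] = 1.0  # PageRank of a single node
    else:
        off_mask = ~np.eye(n, dtype=bool)
        mean_off = v[off_mask].mean()
        strong = ((v > mean_off) & off_mask).sum(axis=1).astype(float)

        k = min(config.n_neighbors, n - 1)
        off = np.sort(v[off_mask].reshape(n, n - 1), axis=1)[:, ::-1]
        knn_mean = off[:, :k].mean(axis=1)

        g = _similarity_graph(sim)
        btw = nx.betweenness_centrality(g, weight="distance", normalized=True)
        clo = nx.closeness_centrality(g, distance="distance")
        adj = v * off_mask
        w, vecs = np.linalg.eigh(adj)
        lead = np.abs(vecs[:, np.argmax(w)])
        norm = np.linalg.norm(lead)
        eig = lead / norm if norm > 0 else lead
        pr = nx.pagerank(g, alpha=config.pagerank_damping, weight="weight")
        block = np.column_stack(
            [
                strong,
                knn_mean,
                np.array([btw[i] for i in range(n)]),
                np.array([clo[i] for i in range(n)]),
                eig,
                np.array([pr[i] for i in range(n)]),
            ]
        )
    names = ("n_strong_neighbors", "knn_mean_sim", "betweenness", "closeness",
             "eigenvector", "pagerank")
    return block, names


def factorization_features(
    assoc: AssociationMatrix, rank: int
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...], tuple[str, ...]]:
    """Truncated-SVD latent factors of Y plus degree statistics, per side.

    The miRNA block holds the left singular vectors scaled by the singular
    values; the disease block the scaled right singular vectors. Ranks beyond
    min(nm, nd) are rejected; a rank-deficient Y zero-pads. Singular-vector
    signs are fixed so each vector's largest-magnitude entry is positive.
    """
    nm, nd = assoc.nm, assoc.nd
    if rank > min(nm, nd):
        raise ValueError(f"svd rank {rank} exceeds min(nm, nd) = {min(nm, nd)}")
    Y = assoc.Y.astype(float)
    u, s, vt = np.linalg.svd(Y, full_matrices=False)
    u, s, vt = u[:, :rank], s[:rank], vt[:rank]
    # deterministic sign convention
    for k in range(rank):
        pivot = np.argmax(np.abs(u[:, k]))
        if u[pivot, k] < 0:
            u[:, k] = -u[:, k]
            vt[k] = -vt[k]
    m_latent = u * s
    d_latent = vt.T * s
    m_deg = Y.sum(axis=1)
    d_deg = Y.sum(axis=0)
    m_block = np.column_stack([m_latent, m_deg, m_deg / nd])
    d_block = np.column_stack([d_latent, d_deg, d_deg / nm])
    latent_names = tuple(f"svd_{k}" for k in range(rank))
    m_names = (*latent_names, "y_degree", "y_degree_frac")
    d_names = (*latent_names, "y_degree", "y_degree_frac")
    return m_block, d_block, m_names, d_names


def build_feature_matrices(
    sm: SimilarityMatrix,
    sd: SimilarityMatrix,
    assoc: AssociationMatrix,
    config: FeatureConfig = FeatureConfig(),
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Assemble (FM, FD): statistical + graph + factorization blocks.

    Both matrices carry the fingerprint of ``assoc.Y`` so downstream training
    and evaluation can detect stale features after Y is masked.
    """
    if sm.ids != assoc.mirna_ids or sd.ids != assoc.disease_ids:
        raise ValueError("similarity matrices are not aligned with the association matrix")
    m_stat, stat_names = statistical_features(sm, assoc.Y, config)
    d_stat, _ = statistical_features(sd, assoc.Y.T, config)
    m_graph, graph_names = graph_features(sm, config)
    d_graph, _ = graph_features(sd, config)
    # degenerate (small) matrices zero-pad the latent block so d is stable
    eff_rank = min(config.svd_rank, assoc.nm, assoc.nd)
    m_fact, d_fact, m_fact_names, d_fact_names = factorization_features(assoc, eff_rank)
    if eff_rank < config.svd_rank:
        pad = config.svd_rank - eff_rank
        m_fact = np.column_stack(
            [m_fact[:, :eff_rank], np.zeros((assoc.nm, pad)), m_fact[:, eff_rank:]]
        )
        d_fact = np.column_stack(
            [d_fact[:, :eff_rank], np.zeros((assoc.nd, pad)), d_fact[:, eff_rank:]]
        )
        pad_names = tuple(f"svd_{k}" for k in range(eff_rank, config.svd_rank))
        m_fact_names = (*m_fact_names[:eff_rank], *pad_names, *m_fact_names[eff_rank:])
        d_fact_names = (*d_fact_names[:eff_rank], *pad_names, *d_fact_names[eff_rank:])
    fp = assoc.fingerprint()
    m_cols = [m_stat, m_graph, m_fact]
    d_cols = [d_stat, d_graph, d_fact]
    noise_names: tuple[str, ...] = ()
    if config.n_noise_features > 0:
        noise_names = tuple(f"noise_{k}" for k in range(config.n_noise_features))
        rng = np.random.default_rng(int(fp[:12], 16))
        m_cols.append(config.noise_scale * rng.standard_normal((assoc.nm, config.n_noise_features)))
        d_cols.append(config.noise_scale * rng.standard_normal((assoc.nd, config.n_noise_features)))
    fm = FeatureMatrix(
        assoc.mirna_ids,
        (*stat_names, *graph_names, *m_fact_names, *noise_names),
        np.column_stack(m_cols),
        y_fingerprint=fp,
    )
    fd = FeatureMatrix(
        assoc.disease_ids,
        (*stat_names, *graph_names, *d_fact_names, *noise_names),
        np.column_stack(d_cols),
        y_fingerprint=fp,
    )
    return fm, fd
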