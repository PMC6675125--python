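"""Cross-validation protocols and rank-based evaluation.

All protocols mask associations out of Y and then recompute the GIP kernels,
the integrated similarities and the feature matrices from the masked Y before
retraining — the feature fingerprint guard enforces this. AUCs are
Mann-Whitney rank statistics of held-out positives against candidate
(unknown) pairs: the global protocols pool all unknown pairs, the local
protocol ranks within the held-out pair's disease only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import EnsembleConfig, fit_ensemble, predict_scores
from .features import FeatureConfig, build_feature_matrices
from .similarity import compute_integrated_similarities
from .types import AssociationMatrix, DiseaseDagCorpus, SimilarityMatrix

__all__ = [
    "CvResult",
    "rank_auc",
    "roc_points",
    "global_loocv",
    "local_loocv",
    "kfold_cv",
    "label_randomization",
    "rank_candidates",
    "PipelineInputs",
]


@dataclass(frozen=True)
class PipelineInputs:
    """Everything the full pipeline needs: Y, the functional-similarity
    matrix (possibly covering a miRNA subset, or None) and the DAG corpus."""

    assoc: AssociationMatrix
    fs: SimilarityMatrix | None
    corpus: DiseaseDagCorpus
    gamma_prime: float = 1.0
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)


@dataclass
class CvResult:
    protocol: str
    aucs: list[float]
    roc: np.ndarray | None = None  # (k, 2) columns FPR, TPR

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.aucs)) if len(self.aucs) > 1 else 0.0


def rank_auc(test_scores, candidate_scores) -> float:
    """Mann-Whitney AUC: mean over test samples of the fraction of candidates
    scored strictly lower, counting ties as half."""
    t = np.asarray(test_scores, dtype=float)
    c = np.asarray(candidate_scores, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("both test and candidate score sets must be non-empty")
    c_sorted = np.sort(c)
    lower = np.searchsorted(c_sorted, t, side="left")
    upper = np.searchsorted(c_sorted, t, side="right")
    return float(np.mean((lower + 0.5 * (upper - lower)) / c.size))


def roc_points(test_scores, candidate_scores) -> np.ndarray:
    """Explicit ROC sweep over every distinct score threshold.

    Returns (k, 2) points (FPR, TPR) from (0,0) to (1,1); the trapezoidal
    area under these points equals :func:`rank_auc` (ties handled by the
    diagonal segment convention).
    """
    t = np.asarray(test_scores, dtype=float)
    c = np.asarray(candidate_scores, dtype=float)
    thresholds = np.unique(np.concatenate([t, c]))[::-1]
    pts = [(0.0, 0.0)]
    for thr in thresholds:
        tpr = float(np.mean(t >= thr))
        fpr = float(np.mean(c >= thr))
        pts.append((fpr, tpr))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return np.asarray(pts)


def _prepare(inputs: PipelineInputs, assoc_masked: AssociationMatrix):
    """Recompute similarities and features from a masked Y."""
    sm, sd = compute_integrated_similarities(
        assoc_masked, inputs.fs, inputs.corpus, inputs.gamma_prime
    )
    fm, fd = build_feature_matrices(sm, sd, assoc_masked, inputs.feature_config)
    return fm, fd


def _train_and_score(
    inputs: PipelineInputs, assoc_masked: AssociationMatrix, config: EnsembleConfig
) -> np.ndarray:
    fm, fd = _prepare(inputs, assoc_masked)
    model = fit_ensemble(fm, fd, assoc_masked, config)
    return predict_scores(model, fm, fd)


def global_loocv(
    inputs: PipelineInputs,
    config: EnsembleConfig = EnsembleConfig(),
    fast: bool = False,
    scorer=None,
) -> CvResult:
    """Leave-one-association-out, ranking each held-out positive against all
    unknown pairs.

    The faithful protocol retrains per held-out association (expensive). With
    ``fast=True`` the model is trained once on the unmasked data and only the
    candidate pool is masked — an explicitly approximate shortcut. ``scorer``
    replaces the train-and-predict step (protocol tests inject oracles here);
    it maps (inputs, masked assoc, config) to an nm x nd score matrix.
    """
    if scorer is None:
        scorer = _train_and_score
    assoc = inputs.assoc
    positives = assoc.positive_pairs()
    if len(positives) < 2:
        raise ValueError("global LOOCV needs at least two positive associations")
    unknown = assoc.unknown_pairs()

    if fast:
        scores = scorer(inputs, assoc, config)
        test = scores[positives[:, 0], positives[:, 1]]
        cand = scores[unknown[:, 0], unknown[:, 1]]
        auc = rank_auc(test, cand)
        return CvResult("global-loocv(fast)", [auc], roc=roc_points(test, cand))

    # each held-out pair is scored by its own retrained model and ranked
    # against that model's scores for the candidate pool (unknown pairs of
    # the original Y)
    test, per_sample, first_cand = [], [], None
    for i, j in positives:
        masked = assoc.with_removed([(i, j)])
        scores = scorer(inputs, masked, config)
        cand = scores[unknown[:, 0], unknown[:, 1]]
        test.append(scores[i, j])
        per_sample.append(rank_auc([scores[i, j]], cand))
        if first_cand is None:
            first_cand = cand
    auc = float(np.mean(per_sample))
    return CvResult("global-loocv", [auc], roc=roc_points(np.asarray(test), first_cand))


def local_loocv(
    inputs: PipelineInputs,
    config: EnsembleConfig = EnsembleConfig(),
    fast: bool = False,
    scorer=None,
) -> CvResult:
    """Leave-one-out ranking each held-out positive only against the unknown
    pairs of its own disease; AUC is the mean per-sample normalized rank."""
    if scorer is None:
        scorer = _train_and_score
    assoc = inputs.assoc
    positives = assoc.positive_pairs()
    if len(positives) < 2:
        raise ValueError("local LOOCV needs at least two positive associations")
    Y = assoc.Y

    def local_candidates(j: int) -> np.ndarray:
        rows = np.flatnonzero(Y[:, j] == 0)
        return np.column_stack([rows, np.full(len(rows), j)])

    per_sample = []
    ranks = []
    if fast:
        scores = scorer(inputs, assoc, config)
    for i, j in positives:
        if not fast:
            masked = assoc.with_removed([(i, j)])
            scores = scorer(inputs, masked, config)
        cands = local_candidates(j)
        if len(cands) == 0:
            continue
        cs = scores[cands[:, 0], cands[:, 1]]
        a = rank_auc([scores[i, j]], cs)
        per_sample.append(a)
        ranks.append(a)
    if not per_sample:
        raise ValueError("no held-out sample had local candidates")
    auc = float(np.mean(per_sample))
    # ROC by sweeping normalized within-disease rank thresholds
    r = np.asarray(ranks)
    thresholds = np.linspace(0.0, 1.0, 101)
    pts = np.asarray([(1.0 - thr, float(np.mean(r >= thr))) for thr in thresholds[::-1]])
    tag = "local-loocv(fast)" if fast else "local-loocv"
    return CvResult(tag, [auc], roc=pts)


def _partition_folds(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [perm[f::k] for f in range(k)]


def kfold_cv(
    inputs: PipelineInputs,
    config: EnsembleConfig = EnsembleConfig(),
    k: int = 5,
    repeats: int = 1,
    seed: int = 0,
    scorer=None,
) -> CvResult:
    """Repeated k-fold over the positive pairs.

    Per fold: the fold's positives are zeroed out of Y, similarities and
    features are recomputed, the ensemble is retrained, and the hidden
    positives are ranked against all pairs unknown in the original Y. One AUC
    per repeat (folds pooled); mean and population sd over repeats.
    """
    if scorer is None:
        scorer = _train_and_score
    assoc = inputs.assoc
    positives = assoc.positive_pairs()
    if len(positives) < k:
        raise ValueError(f"need at least {k} positives for {k}-fold CV")
    unknown = assoc.unknown_pairs()
    rng = np.random.default_rng(seed)
    aucs = []
    roc = None
    for rep in range(repeats):
        folds = _partition_folds(len(positives), k, rng)
        per_fold_auc = []
        test_all, cand_ref = [], None
        for fold in folds:
            held = positives[fold]
            masked = assoc.with_removed(held)
            scores = scorer(inputs, masked, config)
            test = scores[held[:, 0], held[:, 1]]
            cand = scores[unknown[:, 0], unknown[:, 1]]
            per_fold_auc.append(rank_auc(test, cand))
            test_all.append((test, cand))
        aucs.append(float(np.mean(per_fold_auc)))
        if roc is None:
            t0, c0 = test_all[0]
            roc = roc_points(t0, c0)
    return CvResult(f"{k}fold", aucs, roc=roc)


def label_randomization(assoc: AssociationMatrix, rng: np.random.Generator) -> AssociationMatrix:
    """Uniformly shuffle all entries of Y, preserving the number of 1s."""
    flat = assoc.Y.ravel().copy()
    rng.shuffle(flat)
    return AssociationMatrix(assoc.mirna_ids, assoc.disease_ids, flat.reshape(assoc.Y.shape))


def rank_candidates(
    scores: np.ndarray, assoc: AssociationMatrix, disease: str, top: int | None = None
) -> list[tuple[str, float, int]]:
    """Candidate miRNAs of ``disease`` (unknown pairs only) sorted by
    descending score, ties broken by miRNA identifier. Returns
    (miRNA id, score, rank) tuples."""
    j = assoc.disease_ids.index(disease)
    rows = np.flatnonzero(assoc.Y[:, j] == 0)
    entries = sorted(
        ((assoc.mirna_ids[i], float(scores[i, j])) for i in rows),
        key=lambda t: (-t[1], t[0]),
    )
    ranked = [(m, s, r + 1) for r, (m, s) in enumerate(entries)]
    return ranked[:top] if top is not None else ranked
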