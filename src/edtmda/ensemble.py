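"""Ensemble trainer/predictor: M base learners, each built from a fresh
negative sample, a random feature subset shared by both sides, one PCA
projection per side, and one CART regression tree; the final score of a
miRNA-disease pair is the mean of the tree outputs.

A ``style="rf"`` configuration turns the same machinery into a
random-forest-like baseline: one fixed negative set shared by all learners,
bootstrap resampling of the training pairs, no feature subsetting and no PCA.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .cart import RegressionTree, fit_tree, predict_tree
from .types import AssociationMatrix, FeatureMatrix

__all__ = [
    "EnsembleConfig",
    "LinearProjection",
    "BaseLearner",
    "EnsembleModel",
    "sample_negatives_global",
    "sample_negatives_local",
    "sample_feature_subset",
    "fit_base_learner",
    "fit_ensemble",
    "predict_scores",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class EnsembleConfig:
    """Hyper-parameters of the ensemble.

    ``M`` trees; ``r`` controls the feature-subset size d1 = floor(r * d);
    each side is reduced to min(n_components, d1) principal components unless
    ``use_pca`` is off, in which case the raw subset is spliced directly.
    ``negative_sampling`` is "global" (uniform over all unknown pairs) or
    "local" (per disease, matching its positive count).
    """

    M: int = 50
    r: float = 0.8
    n_components: int = 10
    use_pca: bool = True
    negative_sampling: str = "global"
    style: str = "edtmda"  # or "rf": fixed negatives + bagging, no subset/PCA
    min_samples_split: int = 2
    min_impurity_decrease: float = 0.0
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if not (0.0 < self.r <= 1.0):
            raise ValueError("r must lie in (0, 1]")
        if self.negative_sampling not in ("global", "local"):
            raise ValueError(f"unknown negative_sampling {self.negative_sampling!r}")
        if self.style not in ("edtmda", "rf"):
            raise ValueError(f"unknown style {self.style!r}")


@dataclass
class LinearProjection:
    """Centering + linear map; PCA components or the identity."""

    mean: np.ndarray
    components: np.ndarray  # (n_components, n_features)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.components.T

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def _fit_pca(X: np.ndarray, n_components: int) -> LinearProjection:
    """Plain PCA by SVD of the centred data: centering only, no whitening.
    Component signs are fixed (largest-magnitude loading positive)."""
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    u, s, vt = np.linalg.svd(X - mean, full_matrices=False)
    k = min(n_components, vt.shape[0])
    comps = vt[:k].copy()
    for i in range(k):
        pivot = np.argmax(np.abs(comps[i]))
        if comps[i, pivot] < 0:
            comps[i] = -comps[i]
    return LinearProjection(mean=mean, components=comps)


def _identity_projection(n_features: int) -> LinearProjection:
    return LinearProjection(mean=np.zeros(n_features), components=np.eye(n_features))


@dataclass
class BaseLearner:
    negatives: np.ndarray        # (k, 2) pair indices
    feature_idx: np.ndarray      # sorted indices into the raw feature columns
    proj_m: LinearProjection
    proj_d: LinearProjection
    tree: RegressionTree

    @property
    def input_dim(self) -> int:
        return self.proj_m.n_components + self.proj_d.n_components


@dataclass
class EnsembleModel:
    config: EnsembleConfig
    learners: list[BaseLearner]
    y_fingerprint: str
    mirna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]

    @property
    def n_trees(self) -> int:
        return len(self.learners)


# ---------------------------------------------------------------------------
# sampling


def sample_negatives_global(
    assoc: AssociationMatrix, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform sample without replacement of ``count`` unknown pairs."""
    unknown = assoc.unknown_pairs()
    if count > len(unknown):
        raise ValueError(f"requested {count} negatives but only {len(unknown)} unknown pairs")
    pick = rng.choice(len(unknown), size=count, replace=False)
    return unknown[np.sort(pick)]


def sample_negatives_local(assoc: AssociationMatrix, rng: np.random.Generator) -> np.ndarray:
    """Per-disease negatives: for each disease, sample as many unknown pairs
    as it has positives (capped by availability)."""
    out = []
    Y = assoc.Y
    for j in range(assoc.nd):
        n_pos = int(Y[:, j].sum())
        if n_pos == 0:
            continue
        candidates = np.flatnonzero(Y[:, j] == 0)
        take = min(n_pos, len(candidates))
        if take == 0:
            continue
        pick = rng.choice(len(candidates), size=take, replace=False)
        rows = candidates[np.sort(pick)]
        out.append(np.column_stack([rows, np.full(take, j)]))
    if not out:
        return np.empty((0, 2), dtype=int)
    return np.vstack(out)


def sample_feature_subset(d: int, r: float, rng: np.random.Generator) -> np.ndarray:
    """floor(r * d) distinct feature indices, sorted."""
    d1 = int(np.floor(r * d))
    if d1 < 1:
        raise ValueError(f"feature subset would be empty (d={d}, r={r})")
    return np.sort(rng.choice(d, size=d1, replace=False))


# ---------------------------------------------------------------------------
# training


def _splice(
    fm_red: np.ndarray, fd_red: np.ndarray, pairs: np.ndarray
) -> np.ndarray:
    """Per-pair input: the reduced miRNA vector next to the reduced disease
    vector."""
    return np.hstack([fm_red[pairs[:, 0]], fd_red[pairs[:, 1]]])


def fit_base_learner(
    fm: FeatureMatrix,
    fd: FeatureMatrix,
    assoc: AssociationMatrix,
    config: EnsembleConfig,
    rng: np.random.Generator,
    negatives: np.ndarray | None = None,
) -> BaseLearner:
    """One base learning: negatives + feature subset + per-side PCA + CART.

    ``negatives`` may be supplied to share one fixed set across learners
    (the RF-style baseline); otherwise a fresh set is drawn from ``rng``.
    """
    fm.check_fresh(assoc)
    fd.check_fresh(assoc)
    positives = assoc.positive_pairs()
    if len(positives) == 0:
        raise ValueError("association matrix has no positive pairs to train on")

    if negatives is None:
        if config.negative_sampling == "local":
            negatives = sample_negatives_local(assoc, rng)
        else:
            negatives = sample_negatives_global(assoc, len(positives), rng)

    pairs = np.vstack([positives, negatives])
    y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])

    if config.style == "rf":
        boot = rng.integers(0, len(pairs), size=len(pairs))
        pairs, y = pairs[boot], y[boot]
        feature_idx = np.arange(fm.d)
    else:
        feature_idx = sample_feature_subset(fm.d, config.r, rng)

    fm_sub = fm.values[:, feature_idx]
    fd_sub = fd.values[:, feature_idx]
    if config.use_pca and config.style != "rf":
        # fitted on all entities of the side; labels are not used, no leakage
        proj_m = _fit_pca(fm_sub, config.n_components)
        proj_d = _fit_pca(fd_sub, config.n_components)
    else:
        proj_m = _identity_projection(len(feature_idx))
        proj_d = _identity_projection(len(feature_idx))

    X = _splice(proj_m.transform(fm_sub), proj_d.transform(fd_sub), pairs)
    tree = fit_tree(
        X,
        y,
        min_samples_split=config.min_samples_split,
        min_impurity_decrease=config.min_impurity_decrease,
        max_depth=config.max_depth,
    )
    return BaseLearner(
        negatives=negatives, feature_idx=feature_idx, proj_m=proj_m, proj_d=proj_d, tree=tree
    )


def fit_ensemble(
    fm: FeatureMatrix,
    fd: FeatureMatrix,
    assoc: AssociationMatrix,
    config: EnsembleConfig = EnsembleConfig(),
) -> EnsembleModel:
    """Train M base learners with per-learner random streams derived from the
    master seed (stream k = seed + k, so growing M never reshuffles earlier
    learners)."""
    fm.check_fresh(assoc)
    fd.check_fresh(assoc)
    fixed_negatives = None
    if config.style == "rf":
        rng0 = np.random.default_rng(config.seed)
        fixed_negatives = sample_negatives_global(assoc, assoc.n_positive, rng0)
    learners = []
    for k in range(config.M):
        rng = np.random.default_rng(config.seed + k)
        learners.append(
            fit_base_learner(fm, fd, assoc, config, rng, negatives=fixed_negatives)
        )
    return EnsembleModel(
        config=config,
        learners=learners,
        y_fingerprint=assoc.fingerprint(),
        mirna_ids=assoc.mirna_ids,
        disease_ids=assoc.disease_ids,
    )


# ---------------------------------------------------------------------------
# prediction


def predict_scores(
    model: EnsembleModel,
    fm: FeatureMatrix,
    fd: FeatureMatrix,
    pairs: np.ndarray | None = None,
) -> np.ndarray:
    """Scores for the given (miRNA, disease) index pairs (all pairs when
    omitted, returned as an nm x nd matrix). Each learner projects its
    feature subset through its two projections, splices, and routes through
    its tree; the score is the mean over learners."""
    nm, nd = len(model.mirna_ids), len(model.disease_ids)
    if fm.entity_ids != model.mirna_ids or fd.entity_ids != model.disease_ids:
        raise ValueError("feature matrices are not aligned with the model's identifiers")
    as_matrix = pairs is None
    if as_matrix:
        ii, jj = np.meshgrid(np.arange(nm), np.arange(nd), indexing="ij")
        pairs = np.column_stack([ii.ravel(), jj.ravel()])
    pairs = np.asarray(pairs, dtype=int)
    total = np.zeros(len(pairs))
    for learner in model.learners:
        zm = learner.proj_m.transform(fm.values[:, learner.feature_idx])
        zd = learner.proj_d.transform(fd.values[:, learner.feature_idx])
        X = _splice(zm, zd, pairs)
        total += predict_tree(learner.tree, X)
    scores = total / len(model.learners)
    if as_matrix:
        return scores.reshape(nm, nd)
    return scores


# ---------------------------------------------------------------------------
# persistence


def save_model(model: EnsembleModel, path) -> None:
    """Persist the model as a directory of JSON files (plain text)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": asdict(model.config),
        "y_fingerprint": model.y_fingerprint,
        "mirna_ids": list(model.mirna_ids),
        "disease_ids": list(model.disease_ids),
        "n_learners": len(model.learners),
    }
    (path / "model.json").write_text(json.dumps(meta, indent=1))
    learner_dir = path / "learners"
    learner_dir.mkdir(exist_ok=True)
    for k, lr in enumerate(model.learners):
        blob = {
            "negatives": lr.negatives.tolist(),
            "feature_idx": lr.feature_idx.tolist(),
            "proj_m": {"mean": lr.proj_m.mean.tolist(),
                       "components": lr.proj_m.components.tolist()},
            "proj_d": {"mean": lr.proj_d.mean.tolist(),
                       "components": lr.proj_d.components.tolist()},
            "tree": lr.tree.to_dict(),
        }
        (learner_dir / f"learner_{k:04d}.json").write_text(json.dumps(blob))


def load_model(path) -> EnsembleModel:
    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    config = EnsembleConfig(**meta["config"])
    learners = []
    for k in range(meta["n_learners"]):
        blob = json.loads((path / "learners" / f"learner_{k:04d}.json").read_text())
        learners.append(
            BaseLearner(
                negatives=np.asarray(blob["negatives"], dtype=int).reshape(-1, 2),
                feature_idx=np.asarray(blob["feature_idx"], dtype=int),
                proj_m=LinearProjection(
                    mean=np.asarray(blob["proj_m"]["mean"]),
                    components=np.asarray(blob["proj_m"]["components"]),
                ),
                proj_d=LinearProjection(
                    mean=np.asarray(blob["proj_d"]["mean"]),
                    components=np.asarray(blob["proj_d"]["components"]),
                ),
                tree=RegressionTree.from_dict(blob["tree"]),
            )
        )
    return EnsembleModel(
        config=config,
        learners=learners,
        y_fingerprint=meta["y_fingerprint"],
        mirna_ids=tuple(meta["mirna_ids"]),
        disease_ids=tuple(meta["disease_ids"]),
    )
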