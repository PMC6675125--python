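"""Shared fixtures.

The heavy planted-signal cross-validation runs are session-scoped and cached
so the acceptance tests and the module-level property tests share one
computation per experimental arm.
"""

from __future__ import annotations

import numpy as np
import pytest

from edtmda import (
    AssociationMatrix,
    DiseaseDagCorpus,
    EnsembleConfig,
    FeatureConfig,
    PipelineInputs,
    SyntheticConfig,
    build_feature_matrices,
    compute_integrated_similarities,
    generate_inputs,
)
from edtmda.ensemble import fit_ensemble, predict_scores
from edtmda.evaluation import kfold_cv, label_randomization, rank_auc

N_SEEDS = 10
N_NOISE = 96  # noise columns per side for the dimensionality-reduction arms


# ---------------------------------------------------------------------------
# small hand-built corpora (worked examples)


@pytest.fixture
def chain_corpus() -> DiseaseDagCorpus:
    """D -> p -> g chain."""
    return DiseaseDagCorpus(
        parents={"D": frozenset({"p"}), "p": frozenset({"g"}), "g": frozenset()},
        disease_term={"disD": "D"},
    )


@pytest.fixture
def diamond_corpus() -> DiseaseDagCorpus:
    """D with parents p1, p2 sharing grandparent g."""
    return DiseaseDagCorpus(
        parents={
            "D": frozenset({"p1", "p2"}),
            "p1": frozenset({"g"}),
            "p2": frozenset({"g"}),
            "g": frozenset(),
        },
        disease_term={"disD": "D"},
    )


@pytest.fixture
def two_chain_corpus() -> DiseaseDagCorpus:
    """Two chains a -> r and b -> r sharing only the root r."""
    return DiseaseDagCorpus(
        parents={"a": frozenset({"r"}), "b": frozenset({"r"}), "r": frozenset()},
        disease_term={"disA": "a", "disB": "b"},
    )


@pytest.fixture
def toy_assoc() -> AssociationMatrix:
    Y = np.array(
        [
            [1, 0, 0, 1],
            [0, 1, 0, 0],
            [1, 1, 0, 0],
            [0, 0, 1, 0],
        ]
    )
    return AssociationMatrix(
        tuple(f"m{i}" for i in range(4)), tuple(f"d{j}" for j in range(4)), Y
    )


# ---------------------------------------------------------------------------
# synthetic pipeline fixtures


@pytest.fixture(scope="session")
def synth_inputs():
    assoc, fs, corpus, labels = generate_inputs(SyntheticConfig(seed=0))
    return PipelineInputs(assoc=assoc, fs=fs, corpus=corpus), labels


@pytest.fixture(scope="session")
def synth_features(synth_inputs):
    inputs, _ = synth_inputs
    sm, sd = compute_integrated_similarities(inputs.assoc, inputs.fs, inputs.corpus)
    fm, fd = build_feature_matrices(sm, sd, inputs.assoc)
    return sm, sd, fm, fd


@pytest.fixture(scope="session")
def default_model(synth_inputs, synth_features):
    inputs, _ = synth_inputs
    _, _, fm, fd = synth_features
    return fit_ensemble(fm, fd, inputs.assoc, EnsembleConfig(seed=7))


# ---------------------------------------------------------------------------
# heavy experiment arms (shared by acceptance + property tests)


def kfold_auc(
    seed: int,
    shuffle: bool = False,
    n_noise: int = 0,
    repeats: int = 1,
    **ensemble_kwargs,
):
    """One full-pipeline repeated 5-fold run on planted synthetic data."""
    assoc, fs, corpus, _ = generate_inputs(SyntheticConfig(seed=seed))
    if shuffle:
        assoc = label_randomization(assoc, np.random.default_rng(seed + 10_000))
    inputs = PipelineInputs(
        assoc=assoc,
        fs=fs,
        corpus=corpus,
        feature_config=FeatureConfig(n_noise_features=n_noise),
    )
    cfg = EnsembleConfig(seed=seed, **ensemble_kwargs)
    return kfold_cv(inputs, cfg, k=5, repeats=repeats, seed=seed)


@pytest.fixture(scope="session")
def signal_aucs():
    """Default pipeline, planted signal, one 5-fold AUC per seed."""
    return [kfold_auc(s).mean_auc for s in range(N_SEEDS)]


@pytest.fixture(scope="session")
def null_aucs():
    """Label-randomized pipeline, one 5-fold AUC per seed."""
    return [kfold_auc(s, shuffle=True).mean_auc for s in range(N_SEEDS)]


@pytest.fixture(scope="session")
def pca_arm_aucs():
    """(PCA-on, PCA-off) 5-fold AUCs with noise features added, paired seeds."""
    on = [kfold_auc(s, n_noise=N_NOISE).mean_auc for s in range(N_SEEDS)]
    off = [kfold_auc(s, n_noise=N_NOISE, use_pca=False).mean_auc for s in range(N_SEEDS)]
    return on, off


@pytest.fixture(scope="session")
def local_negative_aucs():
    """Per-disease (local-random) negative sampling, paired seeds."""
    return [kfold_auc(s, negative_sampling="local").mean_auc for s in range(N_SEEDS)]


# ---------------------------------------------------------------------------
# cheap holdout protocol for the many-seed directional checks


def holdout_auc(
    seed: int,
    synth: SyntheticConfig | None = None,
    holdout_frac: float = 0.2,
    n_noise: int = 0,
    **ensemble_kwargs,
) -> float:
    """Mask a fraction of positives, retrain from scratch, rank hidden
    positives against the original unknown pairs."""
    if synth is None:
        synth = SyntheticConfig(nm=40, nd=25, seed=seed)
    else:
        synth = SyntheticConfig(**{**synth.__dict__, "seed": seed})
    assoc, fs, corpus, _ = generate_inputs(synth)
    rng = np.random.default_rng(seed + 20_000)
    pos = assoc.positive_pairs()
    n_hold = max(1, int(holdout_frac * len(pos)))
    held = pos[rng.permutation(len(pos))[:n_hold]]
    masked = assoc.with_removed(held)
    sm, sd = compute_integrated_similarities(masked, fs, corpus)
    fm, fd = build_feature_matrices(
        sm, sd, masked, FeatureConfig(n_noise_features=n_noise)
    )
    cfg = EnsembleConfig(seed=seed, **ensemble_kwargs)
    model = fit_ensemble(fm, fd, masked, cfg)
    scores = predict_scores(model, fm, fd)
    unknown = assoc.unknown_pairs()
    return rank_auc(
        scores[held[:, 0], held[:, 1]], scores[unknown[:, 0], unknown[:, 1]]
    )
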