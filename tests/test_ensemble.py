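import numpy as np
import pytest

from edtmda import AssociationMatrix, EnsembleConfig
from edtmda.ensemble import (
    _fit_pca,
    fit_base_learner,
    fit_ensemble,
    load_model,
    predict_scores,
    sample_feature_subset,
    sample_negatives_global,
    sample_negatives_local,
    save_model,
)
from edtmda.types import StaleFeaturesError

from conftest import holdout_auc


class TestNegativeSampling:
    def test_full_unknown_set(self, toy_assoc):
        rng = np.random.default_rng(0)
        u = toy_assoc.unknown_pairs()
        n = sample_negatives_global(toy_assoc, len(u), rng)
        assert {tuple(p) for p in n} == {tuple(p) for p in u}

    def test_too_many_rejected(self, toy_assoc):
        with pytest.raises(ValueError):
            sample_negatives_global(
                toy_assoc, len(toy_assoc.unknown_pairs()) + 1, np.random.default_rng(0)
            )

    def test_deterministic_given_seed(self, toy_assoc):
        a = sample_negatives_global(toy_assoc, 3, np.random.default_rng(42))
        b = sample_negatives_global(toy_assoc, 3, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_no_overlap_with_positives(self, toy_assoc):
        n = sample_negatives_global(toy_assoc, 5, np.random.default_rng(1))
        pos = {tuple(p) for p in toy_assoc.positive_pairs()}
        assert not ({tuple(p) for p in n} & pos)

    def test_uniformity_binomial(self, toy_assoc):
        """Each unknown pair's selection frequency stays within 3 sigma of the
        uniform expectation over 10^4 draws of 3-negatives samples."""
        rng = np.random.default_rng(7)
        unknown = [tuple(p) for p in toy_assoc.unknown_pairs()]
        counts = {p: 0 for p in unknown}
        draws, k = 10_000, 3
        for _ in range(draws):
            for p in sample_negatives_global(toy_assoc, k, rng):
                counts[tuple(p)] += 1
        p_sel = k / len(unknown)
        mu = draws * p_sel
        sigma = np.sqrt(draws * p_sel * (1 - p_sel))
        for c in counts.values():
            assert abs(c - mu) < 3.5 * sigma

    def test_local_sampling_sizes(self, toy_assoc):
        rng = np.random.default_rng(0)
        n = sample_negatives_local(toy_assoc, rng)
        Y = toy_assoc.Y
        for j in range(toy_assoc.nd):
            n_pos = int(Y[:, j].sum())
            got = int((n[:, 1] == j).sum())
            assert got == min(n_pos, int((Y[:, j] == 0).sum()))

    def test_local_sampling_no_positives_no_negatives(self):
        Y = np.array([[1, 0], [1, 0]])
        assoc = AssociationMatrix(("a", "b"), ("x", "y"), Y)
        n = sample_negatives_local(assoc, np.random.default_rng(0))
        assert not (n[:, 1] == 1).any()  # disease y has no positives

    def test_local_sampling_exhausts_small_pool(self):
        # disease x: 3 positives, 3 unknowns -> all 3 unknowns selected
        Y = np.zeros((6, 1), dtype=int)
        Y[:3, 0] = 1
        assoc = AssociationMatrix(tuple("abcdef"), ("x",), Y)
        n = sample_negatives_local(assoc, np.random.default_rng(0))
        assert sorted(n[:, 0]) == [3, 4, 5]


class TestFeatureSubset:
    @pytest.mark.parametrize(
        "d,r,expected", [(32, 0.5, 16), (32, 1.0, 32), (32, 0.8, 25), (10, 0.35, 3)]
    )
    def test_size(self, d, r, expected):
        idx = sample_feature_subset(d, r, np.random.default_rng(0))
        assert len(idx) == expected
        assert len(set(idx.tolist())) == expected
        assert (np.diff(idx) > 0).all()  # sorted, distinct

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            sample_feature_subset(10, 0.05, np.random.default_rng(0))


class TestPca:
    def test_output_dimension(self):
        rng = np.random.default_rng(0)
        X = rng.random((30, 25))
        p = _fit_pca(X, 10)
        assert p.transform(X).shape == (30, 10)

    def test_fewer_features_than_components(self):
        rng = np.random.default_rng(0)
        X = rng.random((30, 6))
        p = _fit_pca(X, 10)
        assert p.n_components == 6

    def test_matches_sklearn(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(1)
        X = rng.random((40, 12))
        ours = _fit_pca(X, 5).transform(X)
        theirs = PCA(n_components=5, svd_solver="full").fit_transform(X)
        # same subspace up to per-component sign
        for k in range(5):
            assert abs(np.corrcoef(ours[:, k], theirs[:, k])[0, 1]) == pytest.approx(
                1.0, abs=1e-9
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_variance_optimality_vs_random_projections(self, seed):
        """Retained variance of PCA beats any random orthonormal projection."""
        rng = np.random.default_rng(seed)
        X = rng.random((25, 15)) @ np.diag(rng.random(15) * 3)
        p = _fit_pca(X, 5)
        pca_var = p.transform(X).var(axis=0).sum()
        Xc = X - X.mean(axis=0)
        for _ in range(20):
            Q, _ = np.linalg.qr(rng.standard_normal((15, 5)))
            rand_var = (Xc @ Q).var(axis=0).sum()
            assert pca_var >= rand_var - 1e-9


class TestBaseLearner:
    def test_spliced_dimension_default(self, synth_inputs, synth_features):
        inputs, _ = synth_inputs
        _, _, fm, fd = synth_features
        lr = fit_base_learner(
            fm, fd, inputs.assoc, EnsembleConfig(), np.random.default_rng(0)
        )
        assert lr.input_dim == 20
        assert lr.proj_m.n_components == 10
        assert lr.proj_d.n_components == 10

    def test_spliced_dimension_small_subset(self, synth_inputs, synth_features):
        inputs, _ = synth_inputs
        _, _, fm, fd = synth_features
        # r chosen so d1 = 6 < 10 components
        cfg = EnsembleConfig(r=6.4 / 32.0)
        lr = fit_base_learner(fm, fd, inputs.assoc, cfg, np.random.default_rng(0))
        assert lr.input_dim == 12

    def test_balanced_negatives(self, synth_inputs, synth_features):
        inputs, _ = synth_inputs
        _, _, fm, fd = synth_features
        lr = fit_base_learner(
            fm, fd, inputs.assoc, EnsembleConfig(), np.random.default_rng(1)
        )
        assert len(lr.negatives) == inputs.assoc.n_positive
        pos = {tuple(p) for p in inputs.assoc.positive_pairs()}
        assert not ({tuple(p) for p in lr.negatives} & pos)

    def test_training_mse_bounded(self, synth_inputs, synth_features):
        inputs, _ = synth_inputs
        _, _, fm, fd = synth_features
        model = fit_ensemble(fm, fd, inputs.assoc, EnsembleConfig(M=1, max_depth=3, seed=2))
        lr = model.learners[0]
        assert lr.tree.root.n_samples == 2 * inputs.assoc.n_positive
        pairs = np.vstack([inputs.assoc.positive_pairs(), lr.negatives])
        y = np.r_[np.ones(inputs.assoc.n_positive), np.zeros(len(lr.negatives))]
        preds = predict_scores(model, fm, fd, pairs)
        # root alone predicts the mean of balanced 0/1 targets (MSE 0.25)
        assert float(((preds - y) ** 2).mean()) <= 0.25 + 1e-12

    def test_stale_features_rejected(self, synth_inputs, synth_features):
        inputs, _ = synth_inputs
        _, _, fm, fd = synth_features
        pos = inputs.assoc.positive_pairs()
        masked = inputs.assoc.with_removed([tuple(pos[0])])
        with pytest.raises(StaleFeaturesError):
            fit_base_learner(fm, fd, masked, EnsembleConfig(), np.random.default_rng(0))


class TestEnsemble:
    def test_default_tree_count(self, default_model):
        assert default_model.n_trees == 50

    def test_single_learner(self, synth_inputs, synth_features):
        inputs, _ = synth_inputs
        _, _, fm, fd = synth_features
        model = fit_ensemble(fm, fd, inputs.assoc, EnsembleConfig(M=1, seed=0))
        assert model.n_trees == 1

    def test_seed_determinism(self, synth_inputs, synth_features):
        inputs, _ = synth_inputs
        _, _, fm, fd = synth_features
        cfg = EnsembleConfig(M=5, seed=123)
        s1 = predict_scores(fit_ensemble(fm, fd, inputs.assoc, cfg), fm, fd)
        s2 = predict_scores(fit_ensemble(fm, fd, inputs.assoc, cfg), fm, fd)
        np.testing.assert_array_equal(s1, s2)

    def test_growing_m_preserves_early_learners(self, synth_inputs, synth_features):
        inputs, _ = synth_inputs
        _, _, fm, fd = synth_features
        small = fit_ensemble(fm, fd, inputs.assoc, EnsembleConfig(M=3, seed=9))
        big = fit_ensemble(fm, fd, inputs.assoc, EnsembleConfig(M=5, seed=9))
        for a, b in zip(small.learners, big.learners[:3]):
            np.testing.assert_array_equal(a.negatives, b.negatives)
            np.testing.assert_array_equal(a.feature_idx, b.feature_idx)

    def test_scores_bounded(self, synth_inputs, synth_features, default_model):
        inputs, _ = synth_inputs
        _, _, fm, fd = synth_features
        scores = predict_scores(default_model, fm, fd)
        assert scores.shape == (inputs.assoc.nm, inputs.assoc.nd)
        assert scores.min() >= 0.0 and scores.max() <= 1.0

    def test_persistence_round_trip(self, synth_inputs, synth_features, default_model, tmp_path):
        inputs, _ = synth_inputs
        _, _, fm, fd = synth_features
        save_model(default_model, tmp_path / "model")
        clone = load_model(tmp_path / "model")
        assert clone.n_trees == default_model.n_trees
        np.testing.assert_allclose(
            predict_scores(clone, fm, fd), predict_scores(default_model, fm, fd)
        )

    def test_positives_outscore_unknowns_on_planted_data(self):
        """Averaged over seeds, a training positive scores above a random
        unknown pair when the data has planted structure."""
        diffs = []
        for seed in range(20):
            auc = holdout_auc(seed, holdout_frac=0.15, M=10)
            diffs.append(auc - 0.5)
        assert np.mean(diffs) > 0.1

    def test_pca_helps_with_noise_features(self):
        """Directional: with junk feature columns added, reducing each side to
        10 components beats splicing the raw subset (mean over 20 seeds)."""
        on = [holdout_auc(s, n_noise=96, M=15) for s in range(20)]
        off = [holdout_auc(s, n_noise=96, M=15, use_pca=False) for s in range(20)]
        assert np.mean(on) >= np.mean(off)

    def test_ensemble_beats_rf_style_baseline(self):
        """Directional: fresh negatives per learner + all positives beats
        bagging with one fixed negative set (mean over 20 seeds)."""
        edt = [holdout_auc(s, M=15) for s in range(20)]
        rf = [holdout_auc(s, M=15, style="rf") for s in range(20)]
        assert np.mean(edt) >= np.mean(rf)
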