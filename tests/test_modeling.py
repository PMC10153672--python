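import pickle

import numpy as np
import pytest

from vidradiomics import modeling
from vidradiomics.errors import (
    CohortTooSmallError,
    ConfigError,
    DegenerateLabelError,
    ShapeError,
)
from vidradiomics.modeling import (
    CLASSIFIER_KINDS,
    BaseClassifierSpec,
    SplitSpec,
    apply_pca,
    fit_branch,
    fit_pca,
    fuse,
    predict_branch,
    run_model_grid,
    split_cohort,
)


def blobs(n=200, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    X = rng.normal(size=(n, 4)) + sep * y[:, None]
    return X, y


class TestSplit:
    def test_sizes_follow_rounding(self):
        ids = [f"c{i}" for i in range(10)]
        tr, te = split_cohort(ids, np.arange(10) % 2, SplitSpec(ratio=0.8, seed=0))
        assert len(tr) == 8 and len(te) == 2
        assert set(tr) | set(te) == set(ids)
        assert not set(tr) & set(te)

    def test_445_cases_split_as_356_89(self):
        ids = [f"c{i}" for i in range(445)]
        y = (np.arange(445) < 143).astype(int)
        tr, te = split_cohort(ids, y, SplitSpec(ratio=0.8, seed=1))
        assert len(tr) == 356 and len(te) == 89

    def test_same_seed_same_partition(self):
        ids = [f"c{i}" for i in range(37)]
        y = np.arange(37) % 2
        spec = SplitSpec(ratio=0.8, seed=5)
        assert split_cohort(ids, y, spec) == split_cohort(ids, y, spec)

    def test_stratified_preserves_class_fractions(self):
        ids = [f"c{i}" for i in range(100)]
        y = (np.arange(100) < 30).astype(int)
        tr, te = split_cohort(ids, y, SplitSpec(ratio=0.8, seed=2, stratified=True))
        tr_y = y[[ids.index(i) for i in tr]]
        assert len(tr) == 80
        assert abs(tr_y.mean() - 0.3) <= 0.02

    def test_too_small_cohort(self):
        with pytest.raises(CohortTooSmallError):
            split_cohort(["a", "b"], np.array([0, 1]), SplitSpec())


class TestPCA:
    def test_exact_low_rank_needs_two_components(self, rng):
        basis = rng.normal(size=(2, 20))
        coords = rng.normal(size=(50, 2))
        X = coords @ basis
        proj = fit_pca(X, threshold=0.95)
        assert proj.n_components == 2

    def test_components_orthonormal(self, rng):
        X = rng.normal(size=(40, 10))
        proj = fit_pca(X, threshold=0.95)
        G = proj.components @ proj.components.T
        assert np.allclose(G, np.eye(proj.n_components), atol=1e-8)

    def test_full_retention_preserves_pairwise_distances(self, rng):
        X = rng.normal(size=(20, 8))
        proj = fit_pca(X, threshold=1.0)
        Z = apply_pca(proj, X)
        d_x = np.linalg.norm(X[:, None] - X[None], axis=-1)
        d_z = np.linalg.norm(Z[:, None] - Z[None], axis=-1)
        assert np.allclose(d_x, d_z, atol=1e-8)

    def test_column_mismatch_raises(self, rng):
        proj = fit_pca(rng.normal(size=(10, 5)))
        with pytest.raises(ShapeError):
            apply_pca(proj, rng.normal(size=(4, 7)))


class TestBranches:
    @pytest.mark.parametrize("kind", CLASSIFIER_KINDS)
    def test_separable_blobs_high_training_accuracy(self, kind):
        X, y = blobs()
        b = fit_branch(X, y, BaseClassifierSpec(kind=kind, seed=0))
        acc = np.mean((predict_branch(b, X) >= 0.5) == y)
        assert acc >= 0.95

    @pytest.mark.parametrize("kind", ["LR", "RF"])
    def test_permuted_labels_destroy_signal(self, kind):
        from sklearn.metrics import roc_auc_score
        from sklearn.model_selection import StratifiedKFold

        X, y = blobs(n=300)
        rng = np.random.default_rng(3)
        y_perm = rng.permutation(y)
        aucs = []
        for tr, te in StratifiedKFold(5, shuffle=True, random_state=0).split(X, y_perm):
            b = fit_branch(X[tr], y_perm[tr], BaseClassifierSpec(kind=kind, seed=0))
            aucs.append(roc_auc_score(y_perm[te], predict_branch(b, X[te])))
        assert 0.4 <= np.mean(aucs) <= 0.6

    @pytest.mark.parametrize("kind", CLASSIFIER_KINDS)
    def test_contradictory_labels_no_infinite_confidence(self, kind):
        X = np.tile(np.ones((1, 3)), (40, 1))
        y = np.arange(40) % 2
        b = fit_branch(X, y, BaseClassifierSpec(kind=kind, seed=0))
        p = predict_branch(b, X[:4])
        assert np.all(p > 0) and np.all(p < 1)

    def test_single_class_labels_raise(self):
        X, _ = blobs(n=20)
        with pytest.raises(DegenerateLabelError):
            fit_branch(X, np.zeros(20, dtype=int), BaseClassifierSpec(kind="LR"))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigError):
            BaseClassifierSpec(kind="MLP")

    def test_deterministic_per_seed(self):
        X, y = blobs(n=80, sep=1.0)
        spec = BaseClassifierSpec(kind="XGBoost", seed=7)
        p1 = predict_branch(fit_branch(X, y, spec), X)
        p2 = predict_branch(fit_branch(X, y, spec), X)
        assert np.array_equal(p1, p2)


class TestFusion:
    def test_weighted_average(self):
        out = fuse(np.array([0.6]), np.array([0.8]), w=0.5)
        assert out[0] == pytest.approx(0.7, abs=1e-12)

    def test_extreme_weights_are_identities(self):
        pi = np.array([0.1, 0.9])
        pc = np.array([0.7, 0.2])
        assert np.array_equal(fuse(pi, pc, w=1.0), pi)
        assert np.array_equal(fuse(pi, pc, w=0.0), pc)

    def test_fused_probabilities_stay_in_unit_interval(self, rng):
        pi, pc = rng.random(50), rng.random(50)
        for w in (0.0, 0.3, 0.5, 1.0):
            out = fuse(pi, pc, w)
            assert np.all((out >= 0) & (out <= 1))

    def test_length_mismatch_and_bad_weight(self):
        with pytest.raises(ShapeError):
            fuse(np.zeros(3), np.zeros(4))
        with pytest.raises(ConfigError):
            fuse(np.zeros(3), np.zeros(3), w=1.5)

    def test_degenerate_branch_cannot_change_ranking_at_extreme_weight(self, rng):
        pi = rng.random(30)
        pc = np.full(30, 0.5)
        fused = fuse(pi, pc, w=1.0)
        assert np.array_equal(np.argsort(fused), np.argsort(pi))


class TestNoLeakage:
    def test_fitted_branch_independent_of_test_rows(self):
        """Refit after perturbing test rows: artifacts bit-identical."""
        X, y = blobs(n=60, sep=2.0)
        X_test = np.random.default_rng(1).normal(size=(10, 4))
        b1 = fit_branch(X, y, BaseClassifierSpec(kind="LR", seed=0), pca_threshold=0.95)
        _ = predict_branch(b1, X_test)
        b2 = fit_branch(X, y, BaseClassifierSpec(kind="LR", seed=0), pca_threshold=0.95)
        _ = predict_branch(b2, X_test + 100.0)  # wildly different test rows
        assert np.array_equal(b1.pca.mean, b2.pca.mean)
        assert np.array_equal(b1.pca.components, b2.pca.components)
        assert pickle.dumps(b1.classifier) == pickle.dumps(b2.classifier)
        assert np.array_equal(b1.scaler.mean_, b2.scaler.mean_)

    def test_pipeline_refit_identical_after_test_perturbation(self, noisy_cohort_small):
        from vidradiomics import pipeline

        cases, _ = noisy_cohort_small
        feats = pipeline.cohort_features(cases, use_truth_masks=True)
        res1 = pipeline.fit_and_evaluate(feats, imaging_kind="LR", seed=0)
        test_ids = res1["test_ids"]
        feats.dynamic.loc[test_ids] = feats.dynamic.loc[test_ids] * 3.0 + 17.0
        res2 = pipeline.fit_and_evaluate(feats, imaging_kind="LR", seed=0)
        m1, m2 = res1["model"], res2["model"]
        assert np.array_equal(m1.imaging.pca.components, m2.imaging.pca.components)
        assert pickle.dumps(m1.imaging.classifier) == pickle.dumps(m2.imaging.classifier)
        assert pickle.dumps(m1.clinical.classifier) == pickle.dumps(m2.clinical.classifier)


class TestModelGrid:
    def grid_inputs(self, informative_clinical=False, seed=0):
        rng = np.random.default_rng(seed)
        n = 120
        y = (np.arange(n) < 40).astype(int)
        rng.shuffle(y)
        X_img = rng.normal(size=(n, 20))
        X_img[:, 0] += 3.0 * y  # imaging carries signal
        X_cl = rng.normal(size=(n, 6))
        if informative_clinical:
            X_cl[:, 0] += 2.0 * y
        return X_img[:90], X_cl[:90], y[:90], X_img[90:], X_cl[90:], y[90:]

    def test_grid_row_counts(self):
        res = run_model_grid(*self.grid_inputs(), seed=0)
        t = res.table
        assert len(t[t["model"] == "fused"]) == 16
        assert len(t[t["model"] == "imaging"]) == 4
        assert len(t[t["model"] == "clinical"]) == 4

    def test_grid_deterministic(self):
        args = self.grid_inputs()
        r1 = run_model_grid(*args, seed=3)
        r2 = run_model_grid(*args, seed=3)
        assert r1.best == r2.best
        assert r1.table.equals(r2.table)

    def test_uninformative_clinical_fusion_beats_clinical_alone(self):
        res = run_model_grid(*self.grid_inputs(informative_clinical=False), seed=0)
        t = res.table
        clin_auc = t[t["model"] == "clinical"].set_index("clinical_kind")["test_auc"]
        fused = t[t["model"] == "fused"]
        for _, row in fused.iterrows():
            assert row["test_auc"] >= clin_auc[row["clinical_kind"]] - 1e-9

    def test_best_pair_has_max_test_auc(self):
        res = run_model_grid(*self.grid_inputs(informative_clinical=True), seed=0)
        fused = res.table[res.table["model"] == "fused"]
        best_auc = fused.set_index(["imaging_kind", "clinical_kind"]).loc[res.best, "test_auc"]
        assert best_auc == fused["test_auc"].max()
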