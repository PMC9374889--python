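import numpy as np
import pytest
from scipy.stats import mannwhitneyu, spearmanr

from conndyn import cpm_cohort, cpm_fit_predict, select_features, svm_classify
from conndyn.prediction import _spearman_by_column, cohort_feature_matrix


def two_group_features(rng, n_per=40, n_features=200, n_signal=5, delta=2.0, noise=0.5):
    X = rng.normal(0, noise, size=(2 * n_per, n_features))
    X[n_per:, :n_signal] += delta
    y01 = np.concatenate([np.zeros(n_per, dtype=int), np.ones(n_per, dtype=int)])
    return X, y01


class TestSelectFeatures:
    def test_injected_features_recovered(self):
        rng = np.random.default_rng(0)
        recovered, false_pos = [], []
        for _ in range(20):
            X, y = two_group_features(rng)
            mask = select_features(X, y, rng.uniform(21, 50, 80), rng.integers(0, 2, 80).astype(float))
            recovered.append(mask[:5].sum())
            false_pos.append(mask[5:].mean())
        assert np.mean(recovered) >= 4.0
        assert np.mean(false_pos) <= 0.08

    def test_null_mask_size_near_alpha(self):
        rng = np.random.default_rng(1)
        sizes = []
        for _ in range(20):
            X = rng.normal(size=(60, 300))
            y = np.concatenate([np.zeros(30, dtype=int), np.ones(30, dtype=int)])
            mask = select_features(X, y, rng.uniform(21, 50, 60), rng.integers(0, 2, 60).astype(float))
            sizes.append(mask.mean())
        assert abs(np.mean(sizes) - 0.05) < 0.02

    def test_empty_selection_falls_back_to_all(self, caplog):
        # identical groups: no feature can differ; fallback returns everything
        X = np.tile(np.arange(10.0)[:, None], (2, 4))
        y = np.concatenate([np.zeros(10, dtype=int), np.ones(10, dtype=int)])
        mask = select_features(X, y, np.zeros(20), np.zeros(20), alpha=1e-12)
        assert mask.all()


class TestSvmClassify:
    def test_separated_groups_high_accuracy(self):
        rng = np.random.default_rng(2)
        X, y = two_group_features(rng, n_per=50, n_features=30, n_signal=10, delta=3.0, noise=1.0)
        res = svm_classify(X, y, k=10, seed=0)
        assert res.pooled_accuracy >= 0.95
        assert res.auc >= 0.95
        assert res.confusion["tp"] + res.confusion["tn"] + res.confusion["fp"] + res.confusion["fn"] == 100

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(3)
        X, _ = two_group_features(rng, n_per=40, n_features=30, n_signal=0)
        accs, aucs = [], []
        for i in range(10):
            y = rng.permutation(np.repeat([0, 1], 40))
            res = svm_classify(X, y, k=5, seed=i)
            accs.append(res.pooled_accuracy)
            aucs.append(res.auc)
        assert 0.35 <= np.mean(accs) <= 0.65
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_auc_equals_mann_whitney_normalization(self):
        rng = np.random.default_rng(4)
        X, y = two_group_features(rng, n_per=30, n_features=20, n_signal=3, delta=1.0)
        res = svm_classify(X, y, k=5, seed=0)
        d = res.decision_values
        u = mannwhitneyu(d[y == 1], d[y == 0], alternative="two-sided").statistic
        auc_mw = u / (np.sum(y == 1) * np.sum(y == 0))
        assert res.auc == pytest.approx(auc_mw, abs=1e-9)

    def test_too_few_subjects_per_class_rejected(self):
        X = np.random.default_rng(5).normal(size=(12, 4))
        y = np.concatenate([np.zeros(8, dtype=int), np.ones(4, dtype=int)])
        with pytest.raises(ValueError, match="at least k"):
            svm_classify(X, y, k=5)

    def test_invalid_box_constraint_rejected(self):
        X = np.random.default_rng(6).normal(size=(40, 4))
        y = np.repeat([0, 1], 20)
        with pytest.raises(ValueError, match="box constraint"):
            svm_classify(X, y, k=5, C=2.0)

    def test_leaky_preselection_optimistic_on_null(self):
        # pre-CV selection peeks at all labels: on pure-noise data its pooled
        # accuracy should generally exceed the honest in-fold variant
        rng = np.random.default_rng(7)
        diffs = []
        for i in range(5):
            X = rng.normal(size=(60, 400))
            y = np.repeat([0, 1], 30)
            honest = svm_classify(X, y, k=5, seed=i).pooled_accuracy
            leaky = svm_classify(X, y, k=5, seed=i, leaky_preselect=True).pooled_accuracy
            diffs.append(leaky - honest)
        assert np.mean(diffs) > 0


class TestCpm:
    def test_exact_feature_recovered(self):
        # scale equal to one feature with zero noise: at a selection
        # threshold strict enough to shut out chance features the held-out
        # predictions recover the scale essentially perfectly
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 25))
        y = X[:, 3].copy()
        res = cpm_fit_predict(X, y, alpha=1e-4)
        assert res.rho > 0.95

    def test_signal_recovery_with_noise(self):
        # a correlated block of informative features (the realistic regime:
        # subsystem metrics covary) with noise SD = 0.2 x signal SD
        rng = np.random.default_rng(9)
        rhos = []
        for _ in range(5):
            f = rng.normal(size=45)
            X = rng.normal(size=(45, 60))
            X[:, :10] += f[:, None]
            y = f + rng.normal(0, 0.2 * f.std(), 45)
            rhos.append(cpm_fit_predict(X, y).rho)
        assert min(rhos) >= 0.7

    def test_null_rho_near_zero(self):
        rng = np.random.default_rng(10)
        rhos = [
            cpm_fit_predict(rng.normal(size=(45, 60)), rng.normal(size=45)).rho for _ in range(10)
        ]
        assert np.mean(np.abs(rhos) < 0.3) >= 0.8

    def test_no_leakage_from_held_out_scale(self):
        # perturbing one subject's scale must not move that subject's prediction
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 40))
        y = X[:, 0] + rng.normal(0, 0.5, 30)
        base = cpm_fit_predict(X, y)
        for i in (0, 13, 29):
            y2 = y.copy()
            y2[i] = y2[i] + 100.0
            perturbed = cpm_fit_predict(X, y2)
            assert perturbed.y_pred[i] == pytest.approx(base.y_pred[i], abs=1e-10)

    def test_resubstitution_beats_loocv_on_average(self):
        rng = np.random.default_rng(12)
        gaps = []
        for _ in range(5):
            X = rng.normal(size=(40, 80))
            y = X[:, 2] + rng.normal(0, 1.0, 40)
            loocv = cpm_fit_predict(X, y).rho
            # resubstitution: select, sum and regress on the full sample, then
            # evaluate on the same sample
            r, p = _spearman_by_column(X, y)
            preds = []
            for mask in ((r > 0) & (p < 0.05), (r < 0) & (p < 0.05)):
                if mask.any():
                    Z = (X[:, mask] - X[:, mask].mean(0)) / X[:, mask].std(0)
                    preds.append(Z.sum(axis=1))
            D = np.column_stack([np.ones(40), *preds])
            beta = np.linalg.lstsq(D, y, rcond=None)[0]
            resub = spearmanr(D @ beta, y).statistic
            gaps.append(resub - loocv)
        assert np.mean(gaps) >= 0

    def test_both_sets_empty_predicts_training_mean(self, caplog):
        X = np.zeros((12, 5))
        X[:, 0] = np.arange(12)
        y = np.ones(12)
        y[5] = 1.0 + 1e-9  # nearly constant scale: nothing correlates
        res = cpm_fit_predict(X, y, alpha=1e-9)
        assert np.all(np.isfinite(res.y_pred))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            cpm_fit_predict(np.zeros((5, 3)), np.arange(5.0))


class TestCohortInterfaces:
    def test_feature_matrix_shape_and_names(self, small_cohort):
        X, names = cohort_feature_matrix(small_cohort)
        assert X.shape[0] == small_cohort.n_subjects
        assert len(names) == X.shape[1]
        assert all(":" in n for n in names)
        assert np.isfinite(X).all()

    def test_cpm_cohort_runs_on_driven_scale(self, sz_signal_cohort):
        res = cpm_cohort(sz_signal_cohort, "SZ", "BDRS")
        assert len(res.y_true) == 45
        assert res.rho > 0.5
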