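"""Kernel fusion classifier: selection, kernels, SVM duals, nested CV."""

import numpy as np
import pytest

from alffband.classify import (CvConfig, ModalityViews, SvmFit,
                               classification_metrics, decision_scores,
                               elastic_net_select, fuse_kernels, linear_gram,
                               make_views, nested_cv, predict_labels,
                               train_svm_precomputed)


class TestElasticNetSelect:
    def test_vanishing_penalty_keeps_all_features(self, rng):
        X = rng.standard_normal((50, 8))
        X = (X - X.mean(0)) / X.std(0)
        y = np.sign(rng.standard_normal(50))
        sel = elastic_net_select(X, y, alpha=1e-8, l1_ratio=0.5)
        assert len(sel) == 8

    def test_recovers_planted_support(self):
        recovered = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, p = 100, 200
            X = rng.standard_normal((n, p))
            beta = np.zeros(p)
            planted = [3, 40, 77, 120, 195]
            beta[planted] = 1.0
            y = np.sign(X @ beta + 0.5 * rng.standard_normal(n))
            Xs = (X - X.mean(0)) / X.std(0)
            sel = elastic_net_select(Xs, y, alpha=0.05, l1_ratio=0.5)
            recovered.append(len(set(planted) & set(sel.tolist())))
        assert np.median(recovered) >= 4

    def test_extreme_penalty_falls_back_to_one_feature(self, rng):
        X = rng.standard_normal((30, 10))
        y = np.sign(rng.standard_normal(30))
        sel = elastic_net_select(X, y, alpha=1e6, l1_ratio=0.9)
        assert len(sel) == 1


class TestKernels:
    def test_orthonormal_rows_give_identity(self):
        A = np.eye(4)
        assert np.allclose(linear_gram(A, A), np.eye(4))

    def test_matches_double_loop_oracle(self, rng):
        A = rng.standard_normal((5, 3))
        B = rng.standard_normal((4, 3))
        K = linear_gram(A, B)
        for i in range(5):
            for j in range(4):
                assert K[i, j] == pytest.approx(np.dot(A[i], B[j]), rel=1e-12)

    def test_row_scaling_is_bilinear(self, rng):
        A = rng.standard_normal((5, 3))
        assert np.allclose(linear_gram(3 * A, 3 * A), 9 * linear_gram(A, A))

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            linear_gram(rng.standard_normal((3, 4)), rng.standard_normal((3, 5)))

    def test_degenerate_weight_returns_first_gram(self, rng):
        K1 = rng.standard_normal((4, 4))
        K2 = rng.standard_normal((4, 4))
        assert np.array_equal(fuse_kernels([K1, K2], (1.0, 0.0)), K1)

    def test_equal_weights_on_same_kernel_idempotent(self, rng):
        K = rng.standard_normal((4, 4))
        assert np.allclose(fuse_kernels([K, K], (0.5, 0.5)), K)

    def test_fusion_preserves_positive_semidefiniteness(self, rng):
        A = rng.standard_normal((6, 4))
        B = rng.standard_normal((6, 3))
        K = fuse_kernels([A @ A.T, B @ B.T], (0.3, 0.7))
        assert np.linalg.eigvalsh(K).min() >= -1e-9

    def test_bad_weight_sum_rejected(self, rng):
        K = np.eye(3)
        with pytest.raises(ValueError, match="sum to 1"):
            fuse_kernels([K, K], (0.5, 0.6))


class TestSvm:
    def test_two_point_closed_form(self):
        """x = +1, -1 with labels +1, -1: alpha equal, boundary at zero."""
        X = np.array([[1.0], [-1.0]])
        y = np.array([1, -1])
        K = linear_gram(X, X)
        fit = train_svm_precomputed(K, y, C=1e6)
        assert np.allclose(np.abs(fit.alpha_signed), 0.5, atol=1e-6)
        assert fit.bias == pytest.approx(0.0, abs=1e-9)
        scores = decision_scores(fit, K)
        assert np.allclose(scores, [1.0, -1.0], atol=1e-6)

    def test_conflicting_duplicates_hit_box_bound(self):
        X = np.array([[1.0], [1.0]])
        y = np.array([1, -1])
        C = 2.0
        fit = train_svm_precomputed(linear_gram(X, X), y, C=C)
        assert np.allclose(np.abs(fit.alpha_signed), C, atol=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_svm_precomputed(np.eye(3), np.array([1, 1, 1]), 1.0)

    def test_predictions_invariant_to_training_order(self, rng):
        X = rng.standard_normal((20, 5))
        y = np.where(rng.random(20) > 0.5, 1, -1)
        y[:3], y[3:6] = 1, -1  # both classes guaranteed
        perm = rng.permutation(20)
        Xt = rng.standard_normal((7, 5))
        fit_a = train_svm_precomputed(linear_gram(X, X), y, 1.0)
        fit_b = train_svm_precomputed(linear_gram(X[perm], X[perm]), y[perm], 1.0)
        sa = decision_scores(fit_a, linear_gram(Xt, X))
        sb = decision_scores(fit_b, linear_gram(Xt, X[perm]))
        assert np.allclose(sa, sb, atol=1e-4)

    def test_matches_primal_linear_svm(self, rng):
        """Dual scores agree with w.x + b recovered from the dual weights."""
        X = rng.standard_normal((24, 3))
        y = np.where(X[:, 0] + 0.2 * rng.standard_normal(24) > 0, 1, -1)
        if len(set(y.tolist())) < 2:
            pytest.skip("degenerate draw")
        fit = train_svm_precomputed(linear_gram(X, X), y, C=10.0)
        w = fit.alpha_signed @ X[fit.support]
        Xt = rng.standard_normal((10, 3))
        primal = Xt @ w + fit.bias
        dual = decision_scores(fit, linear_gram(Xt, X))
        assert np.allclose(primal, dual, atol=1e-8)

    def test_bias_shift_translates_scores(self, rng):
        X = rng.standard_normal((12, 3))
        y = np.array([1, -1] * 6)
        fit = train_svm_precomputed(linear_gram(X, X), y, 1.0)
        shifted = SvmFit(alpha_signed=fit.alpha_signed, support=fit.support,
                         bias=fit.bias + 2.5, C=fit.C)
        K = linear_gram(X, X)
        assert np.allclose(decision_scores(shifted, K),
                           decision_scores(fit, K) + 2.5)


class TestMetrics:
    def test_perfect_ordering_gives_unit_scores(self):
        labels = np.array([1] * 5 + [-1] * 5)
        scores = np.array([5, 4, 3, 2, 1, -1, -2, -3, -4, -5], float)
        m = classification_metrics(scores, labels)
        assert m["accuracy"] == 1.0 and m["auc"] == 1.0
        assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0

    def test_reversed_ordering_gives_zero_auc(self):
        labels = np.array([1] * 5 + [-1] * 5)
        scores = np.arange(10, dtype=float)  # every control above every patient
        assert classification_metrics(scores, labels)["auc"] == 0.0

    def test_auc_matches_pair_counting_oracle(self, rng):
        labels = np.where(rng.random(20) > 0.4, 1, -1)
        labels[0], labels[1] = 1, -1
        scores = rng.standard_normal(20)
        m = classification_metrics(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == -1]
        pairs = [(0.5 if a == b else float(a > b)) for a in pos for b in neg]
        assert m["auc"] == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_tie_scores_predict_patient_class(self):
        assert np.all(predict_labels(np.zeros(3)) == 1)


def _synthetic_views(rng, n=24, p=20, effect=0.0):
    y = np.array([1] * (n // 2) + [-1] * (n // 2))
    bump = np.zeros(p)
    bump[:4] = effect
    Xa = rng.standard_normal((n, p)) + np.outer(y, bump)
    Xf = rng.standard_normal((n, p)) + np.outer(y, bump)
    return ModalityViews((Xa, Xf), y)


class TestNestedCv:
    CFG = dict(outer_k=4, inner_k=3, repeats=2)

    def test_bit_identical_for_fixed_seed(self, rng):
        views = _synthetic_views(rng, effect=0.8)
        a = nested_cv(views, CvConfig(seed=5, **self.CFG))
        b = nested_cv(views, CvConfig(seed=5, **self.CFG))
        assert a.per_repeat.equals(b.per_repeat)
        assert a.roc_points.equals(b.roc_points)

    def test_beta_locked_to_first_view_equals_single_modality(self, rng):
        views = _synthetic_views(rng, effect=0.8)
        fused = nested_cv(views, CvConfig(seed=9, beta_grid=((1.0, 0.0),),
                                          **self.CFG))
        single = nested_cv(ModalityViews((views.views[0],), views.labels),
                           CvConfig(seed=9, beta_grid=((1.0,),), **self.CFG))
        assert fused.per_repeat.equals(single.per_repeat)

    def test_too_few_per_class_rejected(self, rng):
        y = np.array([1, 1, -1, -1, -1, -1])
        X = rng.standard_normal((6, 4))
        with pytest.raises(ValueError):
            nested_cv(ModalityViews((X,), y), CvConfig(**self.CFG))

    def test_deliberate_selection_leak_inflates_null_accuracy(self):
        """Fitting feature selection on all rows before CV inflates apparent
        accuracy on permuted labels — the honest pipeline stays near chance."""
        honest, leaky = [], []
        for seed in range(4):
            rng = np.random.default_rng(300 + seed)
            n, p = 32, 150
            X = rng.standard_normal((n, p))
            y = np.array([1, -1] * (n // 2))
            views = ModalityViews((X, X.copy()), rng.permutation(y))
            cfg = CvConfig(outer_k=4, inner_k=3, repeats=1, seed=seed,
                           enet_alpha_grid=(0.05,), enet_l1_grid=(0.8,),
                           c_grid=(1.0,))
            honest.append(nested_cv(views, cfg).means["accuracy"])
            leaky.append(nested_cv(views, cfg,
                                   unsafe_full_data_selection=True)
                         .means["accuracy"])
        assert np.mean(leaky) > np.mean(honest) + 0.1


class TestMakeViews:
    def test_builds_patient_positive_labels(self):
        import pandas as pd

        table = pd.DataFrame({
            "subject_id": ["a", "b", "c", "d"],
            "group": ["dAD", "NC", "dAD", "NC"],
            "mALFF__classic__r001": [1.0, 2.0, 3.0, 4.0],
            "mfALFF__classic__r001": [5.0, 6.0, 7.0, 8.0],
        })
        views = make_views(table, ("dAD", "NC"))
        assert np.array_equal(views.labels, [1, -1, 1, -1])
        assert views.views[0].shape == (4, 1)

    def test_unknown_group_rejected(self):
        import pandas as pd

        table = pd.DataFrame({"subject_id": ["a"], "group": ["NC"],
                              "mALFF__classic__r001": [1.0],
                              "mfALFF__classic__r001": [1.0]})
        with pytest.raises(ValueError):
            make_views(table, ("dAD", "NC"))
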