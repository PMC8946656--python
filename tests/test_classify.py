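import itertools

import numpy as np
import pytest

from afmi.classify import (
    ClassificationError,
    InsufficientRankError,
    auc_rank,
    confusion_metrics,
    cross_validate,
    evaluate_roc_auc,
    fit_pca,
    roc_points,
    train_classifier,
)
from afmi.signatures import rss_matrix, signature_matrix, training_rows


def brute_force_auc(scores, y, positive):
    """Independent oracle: pairwise concordance enumeration, ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = scores[y == positive]
    neg = scores[y != positive]
    total = concordant = 0.0
    for p in pos:
        for n in neg:
            total += 1
            if p > n:
                concordant += 1
            elif p == n:
                concordant += 0.5
    return concordant / total


class TestPca:
    def test_exact_low_rank_data(self, rng):
        basis = rng.normal(size=(2, 8))
        coeffs = rng.normal(size=(30, 2))
        X = coeffs @ basis + rng.normal(size=8)  # 2-D affine subspace
        model = fit_pca(X, k=2)
        assert model.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-10)

    def test_full_ratio_sums_to_one(self, rng):
        X = rng.normal(size=(40, 6))
        model = fit_pca(X, k=3)
        assert model.full_variance_ratio.sum() == pytest.approx(1.0, abs=1e-12)

    def test_against_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(6, 3))
        model = fit_pca(X, k=2)
        # independent oracle: eigendecomposition of the sample covariance
        centered = X - X.mean(axis=0)
        cov = centered.T @ centered / (X.shape[0] - 1)
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        for i in range(2):
            v = eigvecs[:, i]
            dot = abs(np.dot(v, model.components[i]))
            assert dot == pytest.approx(1.0, abs=1e-8)
        ratio = eigvals / eigvals.sum()
        assert model.explained_variance_ratio == pytest.approx(ratio[:2], abs=1e-8)
        # scores agree up to sign
        scores = model.transform(X)
        oracle_scores = centered @ eigvecs[:, :2]
        for i in range(2):
            assert np.allclose(np.abs(scores[:, i]), np.abs(oracle_scores[:, i]), atol=1e-8)

    def test_orthonormal_components(self, rng):
        X = rng.normal(size=(50, 10))
        model = fit_pca(X, k=5)
        gram = model.components @ model.components.T
        assert np.allclose(gram, np.eye(5), atol=1e-8)

    def test_nonincreasing_ratio(self, rng):
        X = rng.normal(size=(50, 10))
        model = fit_pca(X, k=5)
        assert np.all(np.diff(model.explained_variance_ratio) <= 1e-12)

    def test_sign_convention_deterministic(self, rng):
        X = rng.normal(size=(30, 7))
        m1, m2 = fit_pca(X, k=3), fit_pca(X.copy(), k=3)
        assert np.array_equal(m1.components, m2.components)
        for i in range(3):
            j = np.argmax(np.abs(m1.components[i]))
            assert m1.components[i, j] > 0

    def test_rank_deficient_rejected(self):
        X = np.ones((10, 5)) * np.arange(5)  # rank 0 after centering... rank 0
        with pytest.raises(InsufficientRankError) as exc:
            fit_pca(X + np.arange(10)[:, None], k=4)
        assert exc.value.rank < 4

    def test_non_finite_rejected(self):
        X = np.ones((10, 3))
        X[0, 0] = np.nan
        with pytest.raises(ClassificationError):
            fit_pca(X, k=1)


class TestAuc:
    def test_worked_example(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        y = np.array([0, 0, 1, 1])
        assert auc_rank(scores, y, 1) == pytest.approx(0.75)

    def test_perfect_ordering(self):
        scores = np.array([1, 2, 3, 10, 11, 12])
        y = np.array([0, 0, 0, 1, 1, 1])
        assert auc_rank(scores, y, 1) == 1.0

    def test_null_scores_near_half(self, rng):
        n = 10_000
        scores = rng.normal(size=n)
        y = rng.integers(0, 2, size=n)
        assert auc_rank(scores, y, 1) == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_brute_force_with_ties(self, rng, trial):
        scores = rng.integers(0, 6, size=40).astype(float)  # many ties
        y = rng.integers(0, 2, size=40)
        if len(set(y)) < 2:
            y[0], y[1] = 0, 1
        assert auc_rank(scores, y, 1) == pytest.approx(
            brute_force_auc(scores, y, 1), abs=1e-12
        )

    def test_swapping_positive_class(self, rng):
        scores = rng.normal(size=50)
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        a = auc_rank(scores, y, 1)
        b = auc_rank(scores, y, 0)
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_roc_points_monotone(self, rng):
        scores = rng.normal(size=100)
        y = rng.integers(0, 2, size=100)
        y[:2] = [0, 1]
        pts = roc_points(scores, y, 1)
        fpr = [p[0] for p in pts]
        tpr = [p[1] for p in pts]
        assert fpr == sorted(fpr)
        assert tpr == sorted(tpr)
        assert pts[0] == (0.0, 0.0)
        assert pts[-1] == (1.0, 1.0)


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        y = np.array(["a", "b", "a"])
        assert confusion_metrics(y, y, "a") == (1.0, 1.0, 1.0)

    def test_worked_counts(self):
        y_true = ["p"] * 50 + ["n"] * 50
        y_pred = ["p"] * 42 + ["n"] * 8 + ["p"] * 5 + ["n"] * 45
        acc, sens, spec = confusion_metrics(y_true, y_pred, "p")
        assert acc == pytest.approx(0.87)
        assert sens == pytest.approx(0.84)
        assert spec == pytest.approx(0.90)

    def test_degenerate_all_negative(self):
        y_true = ["p"] * 5 + ["n"] * 5
        y_pred = ["n"] * 10
        acc, sens, spec = confusion_metrics(y_true, y_pred, "p")
        assert (acc, sens, spec) == (0.5, 0.0, 1.0)

    def test_empty_rejected(self):
        with pytest.raises(ClassificationError):
            confusion_metrics([], [], "p")


class TestTraining:
    def test_separable_classes_high_training_accuracy(self, rng):
        n = 100
        a = rng.normal(0, 1, size=(n, 10))
        b = rng.normal(6, 1, size=(n, 10))  # >= 6 pooled sd apart
        X = np.vstack([a, b])
        y = np.array(["A"] * n + ["B"] * n)
        bundle = train_classifier(X, y, pca_k=5)
        assert (bundle.predict(X) == y).mean() >= 0.99

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 5))
        with pytest.raises(ClassificationError):
            train_classifier(X, ["A"] * 20)

    def test_manifest_records_patients(self, rng):
        X = rng.normal(size=(20, 6))
        y = np.array(["A", "B"] * 10)
        pids = np.array(["p1"] * 10 + ["p2"] * 10)
        bundle = train_classifier(X, y, patient_ids=pids)
        assert bundle.training_manifest["patients"] == ["p1", "p2"]
        assert bundle.training_manifest["sector_counts"] == {"p1": 10, "p2": 10}

    def test_label_permutation_auc_near_half(self, rng):
        n = 120
        X = np.vstack([rng.normal(0, 1, size=(n, 8)), rng.normal(1, 1, size=(n, 8))])
        aucs = []
        for _ in range(20):
            y = np.array(["A"] * n + ["B"] * n)
            rng.shuffle(y)
            pids = np.array(["p%d" % (i % 4) for i in range(2 * n)])
            rep = cross_validate(
                X, y, pids, mode="kfold", k=5, framework="fused", seed=0
            )
            aucs.append(rep.auc)
        assert 0.4 <= np.mean(aucs) <= 0.6


class TestEvaluate:
    def test_missing_class_rejected(self, rng):
        X = np.vstack([rng.normal(0, 1, (20, 6)), rng.normal(3, 1, (20, 6))])
        y = np.array(["A"] * 20 + ["B"] * 20)
        bundle = train_classifier(X, y)
        with pytest.raises(ClassificationError):
            evaluate_roc_auc(bundle, X[:20], y[:20])

    def test_three_way_macro(self, rng):
        X = np.vstack(
            [rng.normal(i * 4, 1, (30, 6)) for i in range(3)]
        )
        y = np.array(["A"] * 30 + ["B"] * 30 + ["C"] * 30)
        bundle = train_classifier(X, y)
        rep = evaluate_roc_auc(bundle, X, y)
        assert set(rep.auc_per_class) == {"A", "B", "C"}
        assert rep.auc == pytest.approx(np.mean(list(rep.auc_per_class.values())))
        assert rep.auc > 0.95


class TestCrossValidation:
    def _cohort(self, rng, n_patients=6, per=30):
        X, y, pids = [], [], []
        for p in range(n_patients):
            X.append(rng.normal(0, 1, size=(per, 8)))
            X.append(rng.normal(3, 1, size=(per, 8)))
            y += ["A"] * per + ["B"] * per
            pids += [f"p{p}"] * (2 * per)
        return np.vstack(X), np.array(y), np.array(pids)

    def test_deterministic_rerun(self, rng):
        X, y, pids = self._cohort(rng)
        r1 = cross_validate(X, y, pids, mode="kfold", k=5, seed=3)
        r2 = cross_validate(X, y, pids, mode="kfold", k=5, seed=3)
        assert r1.to_dict() == r2.to_dict()

    def test_lopo_fold_structure(self, rng):
        X, y, pids = self._cohort(rng, n_patients=5)
        rep = cross_validate(X, y, pids, mode="lopo")
        assert rep.n_folds == 5
        assert set(rep.per_patient_accuracy) == {f"p{i}" for i in range(5)}

    def test_lopo_needs_three_patients(self, rng):
        X, y, pids = self._cohort(rng, n_patients=2)
        with pytest.raises(ClassificationError):
            cross_validate(X, y, pids, mode="lopo")

    def test_no_leakage_in_lopo(self, rng, monkeypatch):
        # audit: training manifest never contains the held-out patient
        import afmi.classify as mod

        X, y, pids = self._cohort(rng, n_patients=4)
        seen = []
        orig = mod.train_classifier

        def spy(Xt, yt, **kw):
            bundle = orig(Xt, yt, **kw)
            seen.append(set(bundle.training_manifest["patients"]))
            return bundle

        monkeypatch.setattr(mod, "train_classifier", spy)
        cross_validate(X, y, pids, mode="lopo")
        all_patients = set(pids)
        held_out = [all_patients - s for s in seen]
        assert all(len(h) == 1 for h in held_out)
        assert set.union(*held_out) == all_patients

    def test_group_kfold_keeps_patients_together(self, rng, monkeypatch):
        import afmi.classify as mod

        X, y, pids = self._cohort(rng, n_patients=6)
        seen = []
        orig = mod.train_classifier

        def spy(Xt, yt, **kw):
            bundle = orig(Xt, yt, **kw)
            seen.append(set(bundle.training_manifest["patients"]))
            return bundle

        monkeypatch.setattr(mod, "train_classifier", spy)
        cross_validate(X, y, pids, mode="kfold", k=3, group_kfold=True, seed=0)
        for s in seen:
            assert len(set(pids) - s) == 2  # exactly two patients held out per fold


class TestDefaultCohortPerformance:
    def test_fused_tenfold_auc_exceeds_point_nine(self, default_rss):
        refs, df = default_rss
        rows = training_rows(df, classes=("PTG", "OSSN"))
        rep = cross_validate(
            rss_matrix(rows),
            rows["label"].to_numpy(),
            rows["patient_id"].to_numpy(),
            mode="kfold",
            k=10,
            framework="fused",
            seed=1,
        )
        assert rep.auc >= 0.9

    def test_lopo_runs_on_default_cohort(self, default_rss):
        refs, df = default_rss
        rows = training_rows(df, classes=("PTG", "OSSN"))
        rep = cross_validate(
            rss_matrix(rows),
            rows["label"].to_numpy(),
            rows["patient_id"].to_numpy(),
            mode="lopo",
            framework="fused",
        )
        assert rep.n_folds == 20
        assert rep.pooled_accuracy >= 0.9


class TestAucProperty:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        scores=st.lists(st.integers(0, 5), min_size=4, max_size=25),
        labels=st.lists(st.booleans(), min_size=4, max_size=25),
    )
    @settings(max_examples=60, deadline=None)
    def test_rank_auc_equals_concordance(self, scores, labels):
        n = min(len(scores), len(labels))
        scores = np.asarray(scores[:n], dtype=float)
        y = np.asarray(labels[:n])
        if y.all() or not y.any():
            y[0] = not y[0]
        assert auc_rank(scores, y, True) == pytest.approx(
            brute_force_auc(scores, y, True), abs=1e-12
        )
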