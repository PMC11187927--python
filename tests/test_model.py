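"""Classification stack: projection algebra, stump forest, CV, metrics, U test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpcrsel import constants as C
from gpcrsel.model import (
    CouplingProjection,
    StumpForestClassifier,
    compute_metrics,
    decide,
    fit_pca,
    fit_standardization,
    mann_whitney_u,
    raw_projection,
    standardize,
    stratified_kfold_cv,
)
from gpcrsel.synth import default_group_models, sample_feature_table


def mixture_table(seed, n_gs=24, n_gio=74):
    tbl = sample_feature_table(default_group_models(), {"GS": n_gs, "GIO": n_gio}, seed=seed)
    X = tbl[["tm5_len", "tm5_tilt", "tm6_outward"]].to_numpy(float)
    return X, tbl["coupling_label"].to_numpy()


class TestStandardization:
    def test_means_of_two_rows(self):
        means, scales = fit_standardization([[20, 8, 18], [21, 9, 19]])
        assert np.allclose(means, [20.5, 8.5, 18.5])
        assert np.all(scales > 0)

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError):
            fit_standardization([[20, 8, 18], [20, 9, 19], [20, 7, 17]])

    def test_standardize_worked_example(self):
        z = standardize([23.1, 12.3, 23.8], C.REPORTED_MEANS, C.REPORTED_SCALES)
        assert np.allclose(z, [0.678, 0.727, 0.552], atol=1e-3)

    def test_mean_maps_to_origin_and_mean_plus_sd_to_ones(self):
        means, scales = np.array([20.0, 8.0, 18.0]), np.array([4.0, 5.0, 9.0])
        assert np.allclose(standardize(means, means, scales), 0.0)
        assert np.allclose(standardize(means + scales, means, scales), 1.0)


class TestPCA:
    def test_collinear_data_gives_diagonal_pc1(self, rng):
        t = rng.normal(size=200)
        Z = np.column_stack([t, t, t]) + 1e-12 * rng.normal(size=(200, 3))
        components, ratio = fit_pca(Z)
        assert np.allclose(np.abs(components[0]), 1 / math.sqrt(3), atol=1e-6)
        assert ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_eigendecomposition(self, rng):
        """sklearn-backed PCA vs an independent covariance eigensolver."""
        for _ in range(50):
            Z = rng.normal(size=(40, 3)) @ rng.normal(size=(3, 3))
            Z = Z - Z.mean(axis=0)
            components, ratio = fit_pca(Z)
            cov = Z.T @ Z / (len(Z) - 1)
            eigvals, eigvecs = np.linalg.eigh(cov)
            order = np.argsort(eigvals)[::-1]
            expected = eigvecs[:, order[:2]].T
            for i, col in enumerate((0, 2)):  # apply the same sign convention
                if expected[i, col] < 0:
                    expected[i] *= -1
            assert np.allclose(components, expected, atol=1e-9)
            assert np.allclose(ratio, eigvals[order[:2]] / eigvals.sum(), atol=1e-9)

    def test_reported_eigenvectors_are_orthonormal(self):
        pc1, pc2 = C.REPORTED_COMPONENTS
        assert np.linalg.norm(pc1) == pytest.approx(1.0, abs=2e-3)
        assert np.linalg.norm(pc2) == pytest.approx(1.0, abs=2e-3)
        assert abs(pc1 @ pc2) <= 2e-3


class TestProjection:
    def test_projection_worked_examples(self):
        model = CouplingProjection.from_reported_constants()
        x_gs, _ = raw_projection([23.1, 12.3, 23.8], model)
        x_gio, _ = raw_projection([18.9, 5.90, 19.7], model)
        assert x_gs == pytest.approx(1.13, abs=0.01)
        assert x_gio == pytest.approx(-0.44, abs=0.01)
        assert model.predict([[23.1, 12.3, 23.8], [18.9, 5.90, 19.7]]).tolist() == ["GS", "GIO"]

    def test_mean_projects_to_origin(self):
        model = CouplingProjection.from_reported_constants()
        assert np.allclose(model.transform([C.REPORTED_MEANS]), 0.0, atol=1e-12)

    def test_unit_pc1_row_projects_to_one(self):
        model = CouplingProjection.from_reported_constants()
        z = model.components_[0] / np.linalg.norm(model.components_[0])
        x = float(z @ model.components_[0])
        assert x == pytest.approx(1.0, abs=2e-3)  # printed rows are rounded

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_raw_projection_equals_composed_path(self, seed):
        """The affine expansion must agree with standardize-then-project exactly."""
        rng = np.random.default_rng(seed)
        X = rng.normal(loc=[20, 8, 18], scale=[4, 5, 9], size=(20, 3))
        model = CouplingProjection().fit(X)
        f = rng.normal(loc=[20, 8, 18], scale=[4, 5, 9], size=3)
        x_raw, y_raw = raw_projection(f, model)
        xy = model.transform([f])[0]
        assert x_raw == pytest.approx(xy[0], abs=1e-9)
        assert y_raw == pytest.approx(xy[1], abs=1e-9)

    def test_decision_rule_boundary(self):
        assert decide(1.13) == "GS"
        assert decide(0.7) == "GIO"  # boundary goes to Gi/o
        assert decide(-0.44) == "GIO"
        with pytest.raises(ValueError):
            decide(float("nan"))

    def test_fit_requires_varying_features(self):
        with pytest.raises(ValueError):
            CouplingProjection().fit(np.tile([20.0, 8.0, 18.0], (5, 1)))

    def test_serialization_round_trip(self):
        model = CouplingProjection.from_reported_constants()
        back = CouplingProjection.from_dict(model.to_dict())
        assert np.allclose(back.means_, model.means_)
        assert np.allclose(back.components_, model.components_)
        assert back.gs_threshold == model.gs_threshold


class TestStumpForest:
    def test_separable_data_learned(self, rng):
        X = np.concatenate([rng.normal(-3, 0.5, size=(40, 1)), rng.normal(3, 0.5, size=(40, 1))])
        y = np.array(["GIO"] * 40 + ["GS"] * 40)
        clf = StumpForestClassifier(random_state=0).fit(X, y)
        assert (clf.predict(X) == y).mean() >= 0.95

    def test_fixed_seed_reproduces_model(self):
        X, y = mixture_table(3)
        t1 = StumpForestClassifier(random_state=42).fit(X, y).trees_
        t2 = StumpForestClassifier(random_state=42).fit(X, y).trees_
        assert t1 == t2

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            StumpForestClassifier(random_state=0).fit(X, ["GS"] * 10)

    def test_class_weights_balance_training_composition(self):
        # 24 Gs x weight 74 == 74 Gi/o x weight 24
        assert C.CLASS_WEIGHT["GS"] * C.TRAINING_COMPOSITION["GS"] == pytest.approx(
            C.CLASS_WEIGHT["GIO"] * C.TRAINING_COMPOSITION["GIO"]
        )

    def test_score_is_fraction_of_gs_votes(self):
        from gpcrsel.model import Stump

        clf = StumpForestClassifier()
        clf.classes_ = np.array(["GIO", "GS"])
        clf.trees_ = [Stump(0, 0.0, "GIO", "GS")] * 8 + [Stump(0, 0.0, "GIO", "GIO")] * 7
        score = clf.predict_score(np.array([[1.0]]))  # right side everywhere
        assert score[0] == pytest.approx(8 / 15)
        assert clf.predict(np.array([[1.0]]))[0] == "GS"
        all_gs = [Stump(0, 0.0, "GS", "GS")] * 15
        clf.trees_ = all_gs
        assert clf.predict_score(np.array([[1.0]]))[0] == 1.0

    def test_unfitted_predict_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            StumpForestClassifier().predict(np.zeros((1, 3)))

    def test_agrees_with_sklearn_forest_on_synthetic_mixture(self):
        """Independent route: sklearn's RF at the same hyperparameters."""
        from sklearn.ensemble import RandomForestClassifier

        X, y = mixture_table(0)
        X_test, y_test = mixture_table(1, n_gs=50, n_gio=50)
        ours = StumpForestClassifier(random_state=0).fit(X, y)
        acc_ours = (ours.predict(X_test) == y_test).mean()
        theirs = RandomForestClassifier(
            max_depth=1, n_estimators=15, max_features=1,
            class_weight={1: 74, 0: 24}, max_samples=0.7, random_state=0,
        ).fit(X, (y == "GS").astype(int))
        acc_theirs = (theirs.predict(X_test) == (y_test == "GS").astype(int)).mean()
        assert abs(acc_ours - acc_theirs) <= 0.15
        assert acc_ours >= 0.6

    def test_serialization_round_trip(self):
        X, y = mixture_table(9)
        clf = StumpForestClassifier(random_state=5).fit(X, y)
        back = StumpForestClassifier.from_dict(clf.to_dict())
        Xt, _ = mixture_table(10)
        assert np.array_equal(back.predict(Xt), clf.predict(Xt))


class TestCrossValidation:
    def test_stratification_arithmetic(self):
        X, y = mixture_table(2)
        from sklearn.model_selection import StratifiedKFold

        for _, test_idx in StratifiedKFold(10, shuffle=True, random_state=0).split(X, y):
            n_gs = int((y[test_idx] == "GS").sum())
            n_gio = int((y[test_idx] == "GIO").sum())
            assert n_gs in (2, 3)
            assert n_gio in (7, 8)

    def test_every_row_tested_once_and_k2(self, rng):
        X = rng.normal(size=(8, 3))
        X[:4] += 5
        y = np.array(["GS"] * 4 + ["GIO"] * 4)
        result = stratified_kfold_cv(X, y, k=2, seed=0)
        assert result["k"] == 2
        assert result["pooled"].confusion.sum() == 8

    def test_k_reduced_with_warning(self, rng):
        X = rng.normal(size=(10, 3))
        X[:5] += 5
        y = np.array(["GS"] * 5 + ["GIO"] * 5)
        with pytest.warns(UserWarning, match="reducing k"):
            result = stratified_kfold_cv(X, y, k=10, seed=0)
        assert result["k"] == 5

    def test_k_below_two_rejected(self):
        X, y = mixture_table(2)
        with pytest.raises(ValueError):
            stratified_kfold_cv(X, y, k=1, seed=0)


class TestMetrics:
    def test_closed_form_mcc(self):
        # TP=3, TN=4, FP=1, FN=0 -> MCC = 12/sqrt(240)
        y_true = ["GS"] * 3 + ["GIO"] * 5
        y_pred = ["GS"] * 4 + ["GIO"] * 4
        m = compute_metrics(y_true, y_pred)
        assert m.mcc == pytest.approx(12 / math.sqrt(240), abs=1e-12)

    def test_accuracy_49_of_54(self):
        y_true = ["GS"] * 20 + ["GIO"] * 34
        y_pred = ["GIO"] * 5 + ["GS"] * 15 + ["GIO"] * 34
        assert compute_metrics(y_true, y_pred).accuracy == pytest.approx(0.9074, abs=5e-5)

    def test_perfect_prediction(self):
        y = ["GS"] * 5 + ["GIO"] * 5
        score = [1.0] * 5 + [0.0] * 5
        m = compute_metrics(y, y, score)
        assert (m.accuracy, m.f1, m.auc, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_metrics_consistent_with_confusion(self):
        X, y = mixture_table(4)
        clf = StumpForestClassifier(random_state=4).fit(X, y)
        m = compute_metrics(y, clf.predict(X), clf.predict_score(X))
        (tp, fn), (fp, tn) = m.confusion
        n = m.confusion.sum()
        assert m.accuracy == pytest.approx((tp + tn) / n, abs=1e-12)
        denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        assert m.mcc == pytest.approx((tp * tn - fp * fn) / denom, abs=1e-12)
        assert m.f1 == pytest.approx(2 * tp / (2 * tp + fp + fn), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(["GS"], ["GS", "GIO"])


class TestMannWhitney:
    def test_tied_singletons_midrank(self):
        u, p = mann_whitney_u([1.0], [1.0])
        assert u == pytest.approx(0.5)
        assert p == 1.0

    def test_exact_enumeration_example(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)  # 2/20 arrangements as extreme

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_separated_groups_significant(self, rng):
        a = rng.normal(0, 1, size=50)
        b = rng.normal(3, 1, size=50)
        _, p = mann_whitney_u(a, b)
        assert p < 1e-6
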