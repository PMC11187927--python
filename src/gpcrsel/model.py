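"""Coupling-selectivity classification from the three TM5/TM6 descriptors.

Two estimators, both scikit-learn compatible:

:class:`CouplingProjection`
    standardization -> 2-component PCA -> threshold rule on PC1.  The fitted
    model expands to a closed-form affine map of the raw descriptors

        X = pc1 . (x - mu) / s,      predict Gs  iff  X > 0.7

    and can be constructed directly from the published constants
    (:meth:`CouplingProjection.from_reported_constants`) so new receptors
    can be scored without any training data.

:class:`StumpForestClassifier`
    a deliberately weak random forest — bagged depth-1 stumps, one random
    candidate feature per stump, class weights inverting the 24:74 Gs:Gi/o
    training imbalance — matching the constrained ensemble used to validate
    the geometric hypothesis.

Module-level functions are thin wrappers over the estimators plus the
cross-validation, metric, and rank-test helpers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.decomposition import PCA
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    matthews_corrcoef,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from . import constants as C
from .constants import GIO, GS


def _as_features(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("expected (n, 3) array of (tm5_len, tm5_tilt, tm6_outward)")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    return X


class CouplingProjection(BaseEstimator, ClassifierMixin):
    """Standardize, project onto two principal components, threshold PC1.

    Parameters
    ----------
    gs_threshold
        PC1 value above which (strictly) a receptor is called Gs-coupled.
    ddof
        Delta degrees of freedom for the standardization scales.

    Attributes
    ----------
    means_, scales_ : (3,) float arrays
        Per-feature standardization parameters.
    components_ : (2, 3) float array
        Unit row-eigenvectors (PC1, PC2), signs fixed so the TM5-length
        loading of PC1 and the TM6-outward loading of PC2 are positive.
    explained_variance_ratio_ : (2,) float array or None
        Eigenvalue shares (None when built from reported constants).
    """

    def __init__(self, gs_threshold: float = C.GS_THRESHOLD, ddof: int = 0):
        self.gs_threshold = gs_threshold
        self.ddof = ddof

    # -- construction -------------------------------------------------------
    def fit(self, X, y=None) -> "CouplingProjection":
        X = _as_features(X)
        if len(X) < 3:
            raise ValueError("need >= 3 rows to fit standardization + PCA")
        means = X.mean(axis=0)
        scales = X.std(axis=0, ddof=self.ddof)
        if np.any(scales <= 0):
            bad = [C.FEATURE_NAMES[i] for i in np.flatnonzero(scales <= 0)]
            raise ValueError(f"constant feature(s) {bad}: zero standardization scale")
        Z = (X - means) / scales
        pca = PCA(n_components=2, svd_solver="full")
        pca.fit(Z)
        components = pca.components_.copy()
        evr = pca.explained_variance_ratio_.copy()
        self._finalize(means, scales, components, evr)
        return self

    def _finalize(self, means, scales, components, evr) -> None:
        components = np.array(components, dtype=float)
        # sign convention from the published formulas
        if components[0, 0] < 0:
            components[0] *= -1
        if components[1, 2] < 0:
            components[1] *= -1
        self.means_ = np.asarray(means, dtype=float)
        self.scales_ = np.asarray(scales, dtype=float)
        self.components_ = components
        self.explained_variance_ratio_ = None if evr is None else np.asarray(evr, dtype=float)
        self.classes_ = np.array([GIO, GS])

    @classmethod
    def from_reported_constants(cls, gs_threshold: float = C.GS_THRESHOLD) -> "CouplingProjection":
        """The published projection model, ready to predict."""
        model = cls(gs_threshold=gs_threshold)
        model._finalize(C.REPORTED_MEANS, C.REPORTED_SCALES, C.REPORTED_COMPONENTS, None)
        return model

    def to_dict(self) -> dict:
        check_is_fitted(self, "means_")
        return {
            "kind": "coupling_projection",
            "means": self.means_.tolist(),
            "scales": self.scales_.tolist(),
            "components": self.components_.tolist(),
            "explained_variance_ratio": (
                None
                if self.explained_variance_ratio_ is None
                else self.explained_variance_ratio_.tolist()
            ),
            "gs_threshold": self.gs_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CouplingProjection":
        model = cls(gs_threshold=float(d["gs_threshold"]))
        model._finalize(
            np.array(d["means"]),
            np.array(d["scales"]),
            np.array(d["components"]),
            d.get("explained_variance_ratio"),
        )
        return model

    # -- projection ---------------------------------------------------------
    def standardize(self, X) -> np.ndarray:
        check_is_fitted(self, "means_")
        return (_as_features(X) - self.means_) / self.scales_

    def transform(self, X) -> np.ndarray:
        """Project raw descriptor rows to (X, Y) principal-component scores."""
        return self.standardize(X) @ self.components_.T

    def raw_coefficients(self) -> dict[str, np.ndarray | float]:
        """Affine expansion: X = x_coef . f + x_const, Y = y_coef . f + y_const."""
        check_is_fitted(self, "means_")
        w = self.components_ / self.scales_
        consts = -w @ self.means_
        return {
            "x_coef": w[0],
            "x_const": float(consts[0]),
            "y_coef": w[1],
            "y_const": float(consts[1]),
        }

    # -- decision -----------------------------------------------------------
    def decision_function(self, X) -> np.ndarray:
        return self.transform(X)[:, 0] - self.gs_threshold

    def predict(self, X) -> np.ndarray:
        """Gs iff PC1 strictly exceeds the threshold; ties go to Gi/o."""
        return np.where(self.decision_function(X) > 0, GS, GIO)

    def score_rows(self, ids: Sequence[str], X, labels=None):
        """Per-structure prediction table (structure_id, X, Y, predicted, label)."""
        import pandas as pd

        XY = self.transform(X)
        return pd.DataFrame(
            {
                "structure_id": list(ids),
                "X": np.round(XY[:, 0], 4),
                "Y": np.round(XY[:, 1], 4),
                "predicted": self.predict(X),
                "label": list(labels) if labels is not None else [""] * len(XY),
            }
        )


def decide(x_score: float, threshold: float = C.GS_THRESHOLD) -> str:
    """The closed-form rule: Gs iff X > threshold (ties are Gi/o)."""
    if not math.isfinite(x_score):
        raise ValueError("PC1 score must be finite")
    return GS if x_score > threshold else GIO


# thin functional wrappers -------------------------------------------------

def fit_standardization(X, ddof: int = 0) -> tuple[np.ndarray, np.ndarray]:
    X = _as_features(X)
    if len(X) < 2:
        raise ValueError("need >= 2 rows")
    scales = X.std(axis=0, ddof=ddof)
    if np.any(scales <= 0):
        raise ValueError("constant feature: zero standardization scale")
    return X.mean(axis=0), scales


def standardize(x, means, scales) -> np.ndarray:
    return (np.asarray(x, dtype=float) - means) / scales


def fit_pca(Z) -> tuple[np.ndarray, np.ndarray]:
    """Top-2 eigenvectors (sign-fixed) and explained-variance ratios."""
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or len(Z) < 3:
        raise ValueError("need >= 3 standardized rows")
    pca = PCA(n_components=2, svd_solver="full")
    pca.fit(Z)
    components = pca.components_.copy()
    if components[0, 0] < 0:
        components[0] *= -1
    if components[1, 2] < 0:
        components[1] *= -1
    return components, pca.explained_variance_ratio_.copy()


def project(z, components) -> np.ndarray:
    return np.asarray(z, dtype=float) @ np.asarray(components, dtype=float).T


def raw_projection(f, model: CouplingProjection) -> tuple[float, float]:
    """(X, Y) of one raw descriptor triple via the affine expansion."""
    coef = model.raw_coefficients()
    f = np.asarray(f, dtype=float)
    return (
        float(coef["x_coef"] @ f + coef["x_const"]),
        float(coef["y_coef"] @ f + coef["y_const"]),
    )


# ---------------------------------------------------------------------------
# stump forest

@dataclass
class Stump:
    """One depth-1 tree: split on a single feature at a threshold."""

    feature_index: int
    threshold: float
    left_class: str  # predicted when x[feature] <= threshold
    right_class: str


class StumpForestClassifier(BaseEstimator, ClassifierMixin):
    """Bagged depth-1 decision stumps with class-weighted Gini splits.

    Each of the ``n_estimators`` stumps is trained on ``ceil(bagging_fraction
    * n)`` rows drawn with replacement; each stump considers ``max_features``
    randomly chosen candidate features and takes the class-weighted
    Gini-optimal threshold.  Class weights enter both the impurity and the
    leaf majority votes; the prediction score is the fraction of stumps
    voting Gs, with the exact tie going to the majority class Gi/o.
    """

    def __init__(
        self,
        n_estimators: int = C.N_ESTIMATORS,
        max_depth: int = 1,
        max_features: int = C.MAX_FEATURES,
        class_weight: Optional[dict] = None,
        bagging_fraction: float = C.BAGGING_FRACTION,
        random_state: Optional[int] = None,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.max_features = max_features
        self.class_weight = class_weight
        self.bagging_fraction = bagging_fraction
        self.random_state = random_state

    def _weights(self, classes: np.ndarray) -> dict:
        if self.class_weight is not None:
            return dict(self.class_weight)
        if set(classes) == {GS, GIO}:
            return dict(C.CLASS_WEIGHT)
        return {c: 1.0 for c in classes}

    @staticmethod
    def _best_split(x: np.ndarray, y: np.ndarray, w: np.ndarray, classes: np.ndarray):
        """Weighted-Gini-optimal threshold on one feature; None if unsplittable."""
        order = np.argsort(x, kind="stable")
        x, y, w = x[order], y[order], w[order]
        distinct = np.flatnonzero(np.diff(x) > 0)
        if len(distinct) == 0:
            return None
        onehot = (y[:, None] == classes[None, :]).astype(float) * w[:, None]
        cum = np.cumsum(onehot, axis=0)  # class-weight totals left of each cut
        total = cum[-1]
        left = cum[distinct]
        right = total - left
        wl = left.sum(axis=1)
        wr = right.sum(axis=1)
        gini_l = 1.0 - np.sum((left / wl[:, None]) ** 2, axis=1)
        gini_r = 1.0 - np.sum((right / np.where(wr == 0, 1, wr)[:, None]) ** 2, axis=1)
        impurity = (wl * gini_l + wr * gini_r) / (wl + wr)
        best = int(np.argmin(impurity))  # argmin takes the first (lowest threshold) tie
        i = distinct[best]
        threshold = 0.5 * (x[i] + x[i + 1])
        left_class = classes[int(np.argmax(left[best]))]
        right_class = classes[int(np.argmax(right[best]))]
        return float(impurity[best]), threshold, left_class, right_class

    def fit(self, X, y) -> "StumpForestClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be (n, d) with matching y")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data contains a single class")
        self.classes_ = classes
        weights = self._weights(classes)
        w = np.array([weights[c] for c in y], dtype=float)
        rng = np.random.default_rng(self.random_state)
        n, d = X.shape
        m = math.ceil(self.bagging_fraction * n)
        trees: list[Stump] = []
        for _ in range(self.n_estimators):
            bag = rng.integers(0, n, size=m)
            candidates = rng.choice(d, size=min(self.max_features, d), replace=False)
            best = None
            for f in candidates:
                split = self._best_split(X[bag, f], y[bag], w[bag], classes)
                if split is not None and (best is None or split[0] < best[0]):
                    best = (split[0], f, split[1], split[2], split[3])
            if best is None:
                # degenerate bag: vote the weighted-majority class on both sides
                totals = {c: w[bag][y[bag] == c].sum() for c in classes}
                major = max(sorted(totals), key=lambda c: totals[c])
                trees.append(Stump(int(candidates[0]), math.inf, major, major))
            else:
                _, f, thr, lc, rc = best
                trees.append(Stump(int(f), thr, lc, rc))
        self.trees_ = trees
        return self

    def predict_score(self, X) -> np.ndarray:
        """Fraction of stumps voting Gs, in [0, 1]."""
        check_is_fitted(self, "trees_")
        X = np.asarray(X, dtype=float)
        votes = np.zeros(len(X))
        for tree in self.trees_:
            pred_left = X[:, tree.feature_index] <= tree.threshold
            votes += np.where(
                pred_left, tree.left_class == GS, tree.right_class == GS
            ).astype(float)
        return votes / len(self.trees_)

    def predict_proba(self, X) -> np.ndarray:
        score = self.predict_score(X)
        proba = np.column_stack([1 - score, score])  # columns follow self.classes_
        if list(self.classes_) == [GS, GIO]:
            proba = proba[:, ::-1]
        return proba

    def predict(self, X) -> np.ndarray:
        """Majority vote; the exact 50:50 tie goes to the majority class Gi/o."""
        return np.where(self.predict_score(X) > 0.5, GS, GIO)

    def to_dict(self) -> dict:
        check_is_fitted(self, "trees_")
        return {
            "kind": "stump_forest",
            "params": self.get_params(),
            "classes": list(self.classes_),
            "trees": [
                {
                    "feature_index": t.feature_index,
                    "threshold": t.threshold,
                    "left_class": t.left_class,
                    "right_class": t.right_class,
                }
                for t in self.trees_
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StumpForestClassifier":
        model = cls(**d["params"])
        model.classes_ = np.array(d["classes"])
        model.trees_ = [Stump(**t) for t in d["trees"]]
        return model


# ---------------------------------------------------------------------------
# metrics and validation

@dataclass
class ClassifierMetrics:
    """Binary metrics with Gs as the positive class.

    ``confusion`` rows are true labels, columns predicted, ordered (Gs, Gi/o).
    """

    accuracy: float
    f1: float
    auc: float
    mcc: float
    confusion: np.ndarray

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "f1": self.f1,
            "auc": self.auc,
            "mcc": self.mcc,
            "confusion": np.asarray(self.confusion).tolist(),
        }


def compute_metrics(y_true, y_pred, y_score=None) -> ClassifierMetrics:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred length mismatch")
    if len(np.unique(y_true)) < 2:
        raise ValueError("both classes must be represented in y_true")
    auc = float("nan")
    if y_score is not None:
        auc = float(roc_auc_score((y_true == GS).astype(int), np.asarray(y_score, dtype=float)))
    return ClassifierMetrics(
        accuracy=float(accuracy_score(y_true, y_pred)),
        f1=float(f1_score(y_true, y_pred, pos_label=GS)),
        auc=auc,
        mcc=float(matthews_corrcoef(y_true, y_pred)),
        confusion=confusion_matrix(y_true, y_pred, labels=[GS, GIO]),
    )


def stratified_kfold_cv(
    X,
    y,
    estimator: Optional[BaseEstimator] = None,
    k: int = 10,
    seed: Optional[int] = None,
) -> dict:
    """Stratified k-fold cross-validation; every row is tested exactly once.

    When the rarer class has fewer than ``k`` members, ``k`` is reduced to
    that count with a warning.  Returns per-fold metrics, pooled metrics over
    the union of test folds, and the k actually used.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    min_count = int(counts.min())
    if min_count < k:
        warnings.warn(f"reducing k from {k} to {min_count} (smallest class size)")
        k = min_count
    estimator = estimator or StumpForestClassifier(random_state=seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_metrics = []
    pooled_pred = np.empty(len(y), dtype=y.dtype)
    pooled_score = np.empty(len(y), dtype=float)
    for train_idx, test_idx in skf.split(X, y):
        est = clone(estimator)
        est.fit(X[train_idx], y[train_idx])
        pred = est.predict(X[test_idx])
        score = (
            est.predict_score(X[test_idx])
            if hasattr(est, "predict_score")
            else est.predict_proba(X[test_idx])[:, list(est.classes_).index(GS)]
        )
        pooled_pred[test_idx] = pred
        pooled_score[test_idx] = score
        both_present = len(np.unique(y[test_idx])) == 2
        fold_metrics.append(
            compute_metrics(y[test_idx], pred, score if both_present else None)
            if both_present
            else None
        )
    pooled = compute_metrics(y, pooled_pred, pooled_score)
    return {"k": k, "folds": fold_metrics, "pooled": pooled}


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (midrank ties) for two independent samples.

    Exact p for small tie-free samples, normal approximation with tie
    correction otherwise; a fully tied comparison returns p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if math.isnan(p):  # all observations tied: no evidence against the null
        p = 1.0
    return float(res.statistic), p
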