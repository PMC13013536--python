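"""Peak-level classifiers: thresholding, RBF-SVM and 2-means.

All three operate on per-channel min-max normalized features and follow the
scikit-learn estimator protocol (``fit``/``predict``/``get_params``), so
they compose with sklearn model selection.  The decision rules are

* thresholding — locomotor iff the normalized feature strictly exceeds a
  threshold τ; τ is chosen by exhaustive scan over the observed feature
  values (plus a −∞ sentinel) maximizing training F1, ties broken toward
  the smallest τ;
* RBF-SVM — locomotor iff Σᵢ αᵢ cᵢ K(xᵢ, x) + b > 0 with the Gaussian
  kernel K(xᵢ, x) = exp(−γ‖xᵢ − x‖²);
* 2-means — locomotor iff ‖x − μ₁‖² < ‖x − μ₀‖² (strict), where μ₁ is the
  centroid whose member peaks have the higher mean raw prominence.

Normalization is per channel: each continuous feature is min-max scaled to
[0, 1] within its channel (a new channel at predict time is normalized by
its own range); boolean features map to {0, 1}; a constant feature maps
to 0.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import KMeans
from sklearn.svm import SVC

from .config import BOOLEAN_FEATURES, CONTINUOUS_FEATURES, PEAK_FEATURES

logger = logging.getLogger(__name__)

#: default feature subset of the SVM classifier
DEFAULT_SVM_FEATURES: tuple[str, ...] = (
    "Pro",
    "Wid",
    "Time",
    "SynIndex",
    "FreqCK",
    "LocDev",
)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def _channel_keys(table: pd.DataFrame) -> list[str]:
    keys = [k for k in ("recording", "channel") if k in table.columns]
    if not keys:
        raise ValueError("peak table needs a 'channel' column")
    return keys


def normalize_features(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-channel min-max normalization of the 12 features.

    Returns (normalized copy of the feature columns, normalizer mapping
    channel-key -> {feature: (min, max)}).  Constant features map to 0;
    NaNs (e.g. SynIndex on a single-channel recording) map to 0.
    """
    out = table.copy()
    normalizer: dict = {}
    keys = _channel_keys(table)
    groupby = keys[0] if len(keys) == 1 else keys
    for key, g in table.groupby(groupby, sort=False):
        params = {}
        for feat in CONTINUOUS_FEATURES:
            v = g[feat].to_numpy(dtype=float)
            finite = v[np.isfinite(v)]
            if len(finite) == 0:
                mn = mx = 0.0
            else:
                mn, mx = float(finite.min()), float(finite.max())
            params[feat] = (mn, mx)
            if mx > mn:
                scaled = (v - mn) / (mx - mn)
            else:
                scaled = np.zeros_like(v)
            scaled[~np.isfinite(scaled)] = 0.0
            out.loc[g.index, feat] = scaled
        normalizer[key] = params
    for feat in BOOLEAN_FEATURES:
        out[feat] = table[feat].astype(float)
    return out, normalizer


def feature_matrix(
    table: pd.DataFrame, features: tuple[str, ...] | list[str]
) -> np.ndarray:
    """Extract a (n_peaks, n_features) float matrix in the given order."""
    unknown = set(features) - set(PEAK_FEATURES)
    if unknown:
        raise ValueError(f"unknown features: {sorted(unknown)}")
    return table[list(features)].to_numpy(dtype=float)


def _canonical_order(X: np.ndarray, y: np.ndarray | None = None) -> np.ndarray:
    """Row order independent of input permutation (lexicographic)."""
    cols = [X[:, i] for i in range(X.shape[1] - 1, -1, -1)]
    if y is not None:
        cols = [np.asarray(y, dtype=float)] + cols
    return np.lexsort(cols)


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate training labels: only one class present")


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


class ThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Single-feature thresholding classifier.

    Parameters
    ----------
    feature : int
        Column of ``X`` holding the (normalized) feature to threshold.

    Attributes
    ----------
    tau_ : float
        Fitted threshold; predict returns True iff x > tau_ (strict).
    f1_ : float
        Training F1 achieved by the fitted threshold.
    degenerate_ : bool
        True when the training feature was constant.
    """

    def __init__(self, feature: int = 0):
        self.feature = feature

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=bool)
        _check_two_classes(y)
        x = X[:, self.feature]

        grid = np.concatenate([[-np.inf], np.unique(x)])
        best_tau, best_f1 = -np.inf, -1.0
        n_pos = int(y.sum())
        for tau in grid:
            pred = x > tau
            tp = int(np.sum(pred & y))
            fp = int(np.sum(pred & ~y))
            fn = n_pos - tp
            f1 = 2 * tp / (2 * tp + fp + fn) if tp > 0 else 0.0
            if f1 > best_f1:
                best_f1, best_tau = f1, float(tau)
        self.tau_ = best_tau
        self.f1_ = best_f1
        self.degenerate_ = len(np.unique(x)) < 2
        if self.degenerate_:
            logger.warning("threshold fit on a constant feature: tau degenerate")
        if len(np.unique(x)) > 1 and np.corrcoef(x, y.astype(float))[0, 1] < 0:
            logger.warning("feature is anti-correlated with the labels")
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X[:, self.feature] > self.tau_


class RBFPeakClassifier(BaseEstimator, ClassifierMixin):
    """Soft-margin SVM with a Gaussian RBF kernel.

    ``gamma=None`` uses 1 / (n_features · mean feature variance) computed
    on the training matrix.  Training rows are brought to a canonical
    (sorted) order before the solver runs, so fitted parameters do not
    depend on input row order.

    Attributes
    ----------
    support_vectors_, dual_coef_, intercept_, gamma_
        The kernel-expansion parameters; the decision function is
        Σᵢ (αᵢcᵢ) K(xᵢ, x) + b with dual_coef_ = αᵢcᵢ.
    """

    def __init__(self, C: float = 1.0, gamma: float | None = None):
        self.C = C
        self.gamma = gamma

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=bool)
        _check_two_classes(y)
        if self.gamma is None:
            mean_var = float(X.var(axis=0).mean())
            self.gamma_ = 1.0 / (X.shape[1] * mean_var) if mean_var > 0 else 1.0
        else:
            self.gamma_ = float(self.gamma)
        order = _canonical_order(X, y)
        svc = SVC(C=self.C, kernel="rbf", gamma=self.gamma_)
        svc.fit(X[order], y[order])
        self._svc = svc
        self.support_vectors_ = svc.support_vectors_.copy()
        self.dual_coef_ = svc.dual_coef_.ravel().copy()
        self.intercept_ = float(svc.intercept_[0])
        return self

    def decision_function(self, X):
        """Kernel expansion Σᵢ (αᵢcᵢ) K(xᵢ, x) + b, by direct summation."""
        X = np.asarray(X, dtype=float)
        d2 = (
            np.sum(X**2, axis=1)[:, None]
            - 2 * X @ self.support_vectors_.T
            + np.sum(self.support_vectors_**2, axis=1)[None, :]
        )
        K = np.exp(-self.gamma_ * np.maximum(d2, 0.0))
        return K @ self.dual_coef_ + self.intercept_

    def predict(self, X):
        if getattr(self, "_svc", None) is not None:
            return self._svc.decision_function(np.asarray(X, dtype=float)) > 0
        return self.decision_function(X) > 0


class ProminenceKMeans(BaseEstimator, ClassifierMixin):
    """Unsupervised 2-means classifier oriented by raw prominence.

    Lloyd's algorithm with a fixed seed and multiple restarts; rows are
    canonically ordered before fitting so the centroids are permutation
    invariant.  The cluster whose member peaks have the higher mean
    *unnormalized* prominence becomes the locomotor (True) class.

    Attributes
    ----------
    mu0_, mu1_ : ndarray
        Non-locomotor / locomotor centroids.  Predict returns True iff
        ‖x − μ₁‖² < ‖x − μ₀‖² (strict; equidistant points are False).
    """

    def __init__(
        self,
        n_restarts: int = 10,
        random_state: int = 0,
        tol: float = 1e-6,
        max_iter: int = 300,
    ):
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None, prominence=None):
        X = np.asarray(X, dtype=float)
        uniq = np.unique(X, axis=0)
        if len(uniq) < 2:
            raise ValueError("degenerate clustering: fewer than 2 distinct points")
        if prominence is None:
            raise ValueError("fit requires the raw prominence of each peak")
        prominence = np.asarray(prominence, dtype=float)
        order = _canonical_order(X, prominence)
        km = KMeans(
            n_clusters=2,
            n_init=self.n_restarts,
            random_state=self.random_state,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        assign = km.fit_predict(X[order])
        pro_sorted = prominence[order]
        mean_pro = [pro_sorted[assign == k].mean() for k in (0, 1)]
        hi = int(np.argmax(mean_pro))
        self.mu1_ = km.cluster_centers_[hi].copy()
        self.mu0_ = km.cluster_centers_[1 - hi].copy()
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        d1 = np.sum((X - self.mu1_) ** 2, axis=1)
        d0 = np.sum((X - self.mu0_) ** 2, axis=1)
        return d1 < d0


# ---------------------------------------------------------------------------
# table-level fitting / prediction
# ---------------------------------------------------------------------------


def fit_threshold(table: pd.DataFrame, feature: str = "Pro") -> dict:
    """Fit a thresholding model on a labeled peak table (per-channel norm)."""
    labels = _labels_of(table)
    normed, _ = normalize_features(table)
    x = feature_matrix(normed, (feature,))
    clf = ThresholdClassifier(feature=0).fit(x, labels)
    return {
        "kind": "threshold",
        "feature": feature,
        "tau": clf.tau_,
        "train_f1": clf.f1_,
    }


def fit_svm(
    table: pd.DataFrame,
    features: tuple[str, ...] = DEFAULT_SVM_FEATURES,
    C: float = 1.0,
    gamma: float | None = None,
) -> dict:
    labels = _labels_of(table)
    normed, _ = normalize_features(table)
    X = feature_matrix(normed, features)
    clf = RBFPeakClassifier(C=C, gamma=gamma).fit(X, labels)
    return {
        "kind": "svm",
        "features": list(features),
        "C": C,
        "gamma": clf.gamma_,
        "support_vectors": clf.support_vectors_.tolist(),
        "dual_coef": clf.dual_coef_.tolist(),
        "intercept": clf.intercept_,
    }


def fit_kmeans(
    table: pd.DataFrame,
    features: tuple[str, ...] = DEFAULT_SVM_FEATURES,
    n_restarts: int = 10,
    random_state: int = 0,
) -> dict:
    normed, _ = normalize_features(table)
    X = feature_matrix(normed, features)
    clf = ProminenceKMeans(n_restarts=n_restarts, random_state=random_state)
    clf.fit(X, prominence=table["Pro"].to_numpy(dtype=float))
    return {
        "kind": "kmeans",
        "features": list(features),
        "mu0": clf.mu0_.tolist(),
        "mu1": clf.mu1_.tolist(),
    }


def _labels_of(table: pd.DataFrame) -> np.ndarray:
    lab = table["label"]
    if lab.isna().any():
        raise ValueError("peak table has unlabeled rows; cannot train")
    return lab.to_numpy(dtype=bool)


def fit_model(table: pd.DataFrame, approach: str, config=None) -> dict:
    """Train the configured approach on a labeled peak table."""
    from .config import PocaConfig

    cfg = config or PocaConfig()
    if approach == "threshold":
        return fit_threshold(table, cfg.threshold_feature)
    if approach == "svm":
        return fit_svm(table, cfg.svm_features, C=cfg.svm_C, gamma=cfg.svm_gamma)
    if approach == "kmeans":
        return fit_kmeans(
            table,
            cfg.svm_features,
            n_restarts=cfg.kmeans_restarts,
            random_state=cfg.kmeans_seed,
        )
    raise ValueError(f"unknown approach {approach!r}")


def predict_model(model: dict, table: pd.DataFrame) -> np.ndarray:
    """Apply a fitted model to a peak table (each channel self-normalized)."""
    if len(table) == 0:
        return np.zeros(0, dtype=bool)
    normed, _ = normalize_features(table)
    kind = model["kind"]
    if kind == "threshold":
        x = feature_matrix(normed, (model["feature"],))
        return x[:, 0] > model["tau"]
    if kind == "svm":
        X = feature_matrix(normed, tuple(model["features"]))
        clf = RBFPeakClassifier(C=model["C"], gamma=model["gamma"])
        clf.gamma_ = model["gamma"]
        clf.support_vectors_ = np.asarray(model["support_vectors"], dtype=float)
        clf.dual_coef_ = np.asarray(model["dual_coef"], dtype=float)
        clf.intercept_ = float(model["intercept"])
        clf._svc = None
        return clf.predict(X)
    if kind == "kmeans":
        X = feature_matrix(normed, tuple(model["features"]))
        clf = ProminenceKMeans()
        clf.mu0_ = np.asarray(model["mu0"], dtype=float)
        clf.mu1_ = np.asarray(model["mu1"], dtype=float)
        return clf.predict(X)
    raise ValueError(f"unknown model kind {kind!r}")


def save_model(model: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model, fh, indent=1)


def load_model(path: str | Path) -> dict:
    with open(path) as fh:
        model = json.load(fh)
    if model.get("kind") not in ("threshold", "svm", "kmeans"):
        raise ValueError(f"{path}: not a recognized model file")
    return model
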