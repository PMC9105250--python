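"""One-class SVM change detection over handcrafted features.

The detector is fitted on baseline-phase feature vectors only (the target
class) and scores stimulation-phase windows with the signed decision margin:
positive margins mean "still baseline-like", negative margins mean a
behavioral-state change.  The nu parameter upper-bounds the fraction of
training windows treated as outliers and lower-bounds the fraction of
support vectors (the nu-property).

The kernel is RBF with a median-heuristic bandwidth by default: gamma =
1/(2 * median^2) of the pairwise training distances, a standard choice for
one-class novelty detection when nothing is known about the feature scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.preprocessing import StandardScaler
from sklearn.svm import OneClassSVM

from .features import FeatureMatrix
from .preprocess import ValidationError

#: Default outlier-fraction bound.
DEFAULT_NU = 0.1

#: Minimum number of baseline rows required to fit.
MIN_TRAIN_ROWS = 30


class ConfigurationError(ValueError):
    pass


def median_heuristic_gamma(X: np.ndarray, max_rows: int = 500,
                           seed: int = 0) -> float:
    """RBF bandwidth via the median pairwise-distance heuristic."""
    if len(X) > max_rows:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(len(X), max_rows, replace=False)]
    d = pdist(X)
    med = np.median(d[d > 0]) if np.any(d > 0) else 1.0
    return float(1.0 / (2.0 * med ** 2))


@dataclass
class OneClassModel:
    """Fitted one-class model: scaler + kernel machine + nu."""

    svm: OneClassSVM
    scaler: StandardScaler
    nu: float
    gamma: float
    n_features: int
    n_train: int

    @property
    def train_outlier_bound(self) -> float:
        """nu + 2/sqrt(M): the tolerance band of the nu-property."""
        return self.nu + 2.0 / np.sqrt(self.n_train)


def fit_ocsvm(baseline_features: FeatureMatrix | np.ndarray,
              nu: float = DEFAULT_NU,
              kernel: str = "rbf",
              gamma: float | None = None) -> OneClassModel:
    """Fit a nu-parameterized one-class SVM on baseline feature rows.

    Solves the one-class maximum-margin problem: find the hyperplane (in
    kernel space) separating the training mass from the origin with maximum
    offset rho, paying slack for at most ~nu of the rows.
    """
    X = baseline_features.values if isinstance(baseline_features, FeatureMatrix) \
        else np.asarray(baseline_features, dtype=float)
    if not (0 < nu <= 1):
        raise ConfigurationError("nu must be in (0, 1]")
    if len(X) < MIN_TRAIN_ROWS:
        raise ValidationError(
            f"need >= {MIN_TRAIN_ROWS} baseline rows, got {len(X)}")
    if not np.all(np.isfinite(X)):
        raise ValidationError("baseline features contain non-finite values")
    if np.allclose(X, X[0]):
        raise ValidationError(
            "all baseline feature rows are identical; inspect the featurization")
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    if kernel == "rbf" and gamma is None:
        gamma = median_heuristic_gamma(Xs)
    svm = OneClassSVM(kernel=kernel, nu=nu, tol=1e-7,
                      gamma=gamma if kernel == "rbf" else "scale")
    svm.fit(Xs)
    return OneClassModel(svm=svm, scaler=scaler, nu=nu,
                         gamma=float(gamma) if gamma is not None else np.nan,
                         n_features=X.shape[1], n_train=len(X))


def score_windows(model: OneClassModel,
                  features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Signed decision margins per row: + = baseline-like, - = changed."""
    X = features.values if isinstance(features, FeatureMatrix) \
        else np.asarray(features, dtype=float)
    if X.shape[1] != model.n_features:
        raise ValidationError(
            f"feature dimensionality {X.shape[1]} does not match the "
            f"{model.n_features} training features")
    return model.svm.decision_function(model.scaler.transform(X))


def hard_labels(margins: np.ndarray) -> np.ndarray:
    """+1 (unchanged) / -1 (changed) by the sign of the margin."""
    return np.where(np.asarray(margins) >= 0, 1, -1)


def detect_change(margins: np.ndarray, persistence_k: int = 5,
                  start_times: np.ndarray | None = None):
    """Session-level change call: first run of k consecutive negative margins.

    Returns ``(changed, change_time)`` where ``change_time`` is the start
    time (or index when ``start_times`` is None) of the k-th consecutive
    negative window, or ``(False, None)`` if no such run occurs.
    """
    if persistence_k < 1:
        raise ConfigurationError("persistence_k must be >= 1")
    m = np.asarray(margins, dtype=float)
    run = 0
    for i, v in enumerate(m):
        run = run + 1 if v < 0 else 0
        if run >= persistence_k:
            t = i if start_times is None else start_times[i]
            return True, t
    return False, None
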