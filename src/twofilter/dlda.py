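"""Diagonal linear discriminant analysis (DLDA) for two classes.

DLDA is the Gaussian classifier with class-specific means and a shared
*diagonal* covariance: features are treated as independent, and within-class
variances are pooled across the two classes per feature. Its simplicity is a
feature, not a compromise — with few samples and many features there is no
hope of estimating a full covariance, and a simple model keeps the rigorous
(and expensive) cross-validation around it tractable.

The continuous discriminant score of a sample x is

    d(x) = sum_j [(x_j - mu0_j)^2 - (x_j - mu1_j)^2] / s2_j
           + 2 * log(prior1 / prior0)

which is twice the difference of the two diagonal-Gaussian log-likelihoods
plus the prior term; larger values are more class-1-like, and the predicted
class is 1 exactly when d(x) > 0. It is evaluated in the algebraically
identical centered form 2 (mu1 - mu0) (x - (mu0 + mu1)/2) / s2 so that a
sample sitting exactly at the between-centroid midpoint scores exactly zero
in floating point as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

#: variance floor: s2 <- max(s2, VAR_FLOOR_ABS + VAR_FLOOR_REL * median(s2))
VAR_FLOOR_ABS = 1e-8
VAR_FLOOR_REL = 1e-3


def pooled_moments(X0: np.ndarray, X1: np.ndarray,
                   var_floor_abs: float = VAR_FLOOR_ABS,
                   var_floor_rel: float = VAR_FLOOR_REL):
    """Per-feature class means and pooled within-class variance.

    The pooled variance ((n0-1) v0 + (n1-1) v1) / (n0 + n1 - 2) is floored at
    eps = var_floor_abs + var_floor_rel * median(s2) so constant features
    cannot blow up the discriminant.
    """
    n0, n1 = X0.shape[0], X1.shape[0]
    if n0 < 2 or n1 < 2:
        raise ValueError("DLDA needs at least 2 samples per class")
    mu0 = X0.mean(axis=0)
    mu1 = X1.mean(axis=0)
    v0 = X0.var(axis=0, ddof=1)
    v1 = X1.var(axis=0, ddof=1)
    s2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2)
    eps = var_floor_abs + var_floor_rel * float(np.median(s2))
    return mu0, mu1, np.maximum(s2, eps)


class DldaClassifier(ClassifierMixin, BaseEstimator):
    """Two-class diagonal linear discriminant analysis.

    Parameters
    ----------
    priors : {"empirical", "uniform"}
        Class priors from training frequencies (default) or flat 1/2.
    var_floor_abs, var_floor_rel : float
        Pooled-variance floor, see :func:`pooled_moments`.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
    means_ : ndarray of shape (2, n_features)
    var_ : ndarray of shape (n_features,) — floored pooled variances
    priors_ : ndarray of shape (2,)
    """

    def __init__(self, priors: str = "empirical",
                 var_floor_abs: float = VAR_FLOOR_ABS,
                 var_floor_rel: float = VAR_FLOOR_REL):
        self.priors = priors
        self.var_floor_abs = var_floor_abs
        self.var_floor_rel = var_floor_rel

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, yi = np.unique(y, return_inverse=True)
        if self.classes_.size != 2:
            raise ValueError(
                f"DLDA is a two-class model, got {self.classes_.size} classes"
            )
        if X.shape[1] < 1:
            raise ValueError("at least one feature is required")
        X0, X1 = X[yi == 0], X[yi == 1]
        mu0, mu1, s2 = pooled_moments(
            X0, X1, self.var_floor_abs, self.var_floor_rel
        )
        self.means_ = np.vstack([mu0, mu1])
        self.var_ = s2
        if self.priors == "uniform":
            self.priors_ = np.array([0.5, 0.5])
        elif self.priors == "empirical":
            n = X.shape[0]
            self.priors_ = np.array([X0.shape[0] / n, X1.shape[0] / n])
        else:
            raise ValueError("priors must be 'empirical' or 'uniform'")
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        """d(x); larger = more like ``classes_[1]``."""
        check_is_fitted(self, "means_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        mu0, mu1 = self.means_
        w = 2.0 * (mu1 - mu0) / self.var_
        d = ((X - (mu0 + mu1) / 2.0) * w).sum(axis=1)
        return d + 2.0 * np.log(self.priors_[1] / self.priors_[0])

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        # ties at d == 0 go to the larger prior, then to class 0
        tie_hi = self.priors_[1] > self.priors_[0]
        pos = d > 0 if not tie_hi else d >= 0
        return self.classes_[pos.astype(int)]


@dataclass
class DldaModel:
    """Serializable fitted DLDA: per-feature class means, pooled variances,
    and class priors."""

    feature_ids: list
    mu0: np.ndarray
    mu1: np.ndarray
    s2: np.ndarray
    prior0: float
    prior1: float

    def __post_init__(self):
        k = len(self.feature_ids)
        self.mu0 = np.asarray(self.mu0, dtype=float)
        self.mu1 = np.asarray(self.mu1, dtype=float)
        self.s2 = np.asarray(self.s2, dtype=float)
        if not (self.mu0.shape == self.mu1.shape == self.s2.shape == (k,)):
            raise ValueError("model arrays must match feature_ids length")
        if not np.all(self.s2 > 0):
            raise ValueError("pooled variances must be strictly positive")
        if not (0 < self.prior0 < 1 and 0 < self.prior1 < 1):
            raise ValueError("priors must lie in (0, 1)")
        if abs(self.prior0 + self.prior1 - 1.0) > 1e-12:
            raise ValueError("priors must sum to 1")


def dlda_fit(m, labels, priors: str = "empirical") -> DldaModel:
    """Fit DLDA on an expression matrix restricted to selected features.

    ``labels`` is a 0/1 vector aligned with ``m.sample_ids``.
    """
    from .stats import _validate_binary_labels

    y = _validate_binary_labels(labels, len(m.sample_ids))
    if m.shape[0] < 1:
        raise ValueError("at least one feature is required")
    clf = DldaClassifier(priors=priors).fit(m.samples_by_features(), y)
    return DldaModel(
        feature_ids=m.feature_ids,
        mu0=clf.means_[0],
        mu1=clf.means_[1],
        s2=clf.var_,
        prior0=float(clf.priors_[0]),
        prior1=float(clf.priors_[1]),
    )


def _sample_vector(model: DldaModel, sample) -> np.ndarray:
    if isinstance(sample, pd.Series):
        sample = sample.to_dict()
    if isinstance(sample, dict):
        missing = [f for f in model.feature_ids if f not in sample]
        if missing:
            raise ValueError(f"sample is missing features: {missing[:10]}")
        return np.array([float(sample[f]) for f in model.feature_ids])
    x = np.asarray(sample, dtype=float).ravel()
    if x.size != len(model.feature_ids):
        raise ValueError(
            f"sample has {x.size} values, model expects {len(model.feature_ids)}"
        )
    return x


def dlda_score(model: DldaModel, sample) -> float:
    """Continuous discriminant score of one sample; > 0 is class-1-like."""
    x = _sample_vector(model, sample)
    w = 2.0 * (model.mu1 - model.mu0) / model.s2
    d = ((x - (model.mu0 + model.mu1) / 2.0) * w).sum()
    return float(d + 2.0 * np.log(model.prior1 / model.prior0))


def dlda_predict(model: DldaModel, sample) -> int:
    """Predicted class: 1 iff the score is positive; ties go to the class
    with the larger prior, then to class 0."""
    d = dlda_score(model, sample)
    if d > 0:
        return 1
    if d < 0:
        return 0
    return 1 if model.prior1 > model.prior0 else 0


def write_dlda_model(model: DldaModel, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"#priors\t{model.prior0!r}\t{model.prior1!r}\n")
        fh.write("feature_id\tmu0\tmu1\ts2\n")
        for fid, a, b, v in zip(model.feature_ids, model.mu0, model.mu1, model.s2):
            fh.write(f"{fid}\t{float(a)!r}\t{float(b)!r}\t{float(v)!r}\n")


def read_dlda_model(path) -> DldaModel:
    with open(path, "rt", encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n").split("\t")
        if first[0] != "#priors" or len(first) != 3:
            raise ValueError(f"{path} is not a DLDA model file")
        prior0, prior1 = float(first[1]), float(first[2])
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    return DldaModel(
        feature_ids=df["feature_id"].tolist(),
        mu0=df["mu0"].to_numpy(),
        mu1=df["mu1"].to_numpy(),
        s2=df["s2"].to_numpy(),
        prior0=prior0,
        prior1=prior1,
    )
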