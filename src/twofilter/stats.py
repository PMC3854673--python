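"""Per-feature two-class statistics behind the two-way filter.

The filter pairs a signal-strength statistic — the plain difference of class
means of log-scale expression, i.e. a log fold change — with a
signal-to-noise statistic — the two-sided Mann-Whitney U test. The pairing is
deliberate: the mean difference is sensitive to strong shifts regardless of
distributional shape, while the rank test controls the noise level without
assuming normality. A feature passes the filter when its absolute mean
difference is at least ``t1`` and its Mann-Whitney p-value is at most ``t2``.

Directions are carried separately from magnitudes so that selected features
can be split into "high expression -> class 1" and "high expression ->
class 0" lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu, rankdata

UP_IN_CLASS1 = "up_in_class1"
UP_IN_CLASS0 = "up_in_class0"

#: largest min-group-size for which the exact Mann-Whitney null is enumerated
EXACT_MAX_N = 8


@dataclass(frozen=True)
class FeatureStats:
    """The filtering statistics of one feature.

    ``mean_diff`` is mean(class 1) - mean(class 0) in log-scale units;
    ``mw_p`` is the two-sided Mann-Whitney p-value.
    """

    feature_id: str
    mean_diff: float
    mw_p: float

    @property
    def abs_mean_diff(self) -> float:
        return abs(self.mean_diff)

    @property
    def direction(self) -> str:
        # exact ties go to class 1 by convention; any positive t1 threshold
        # excludes such features anyway
        return UP_IN_CLASS1 if self.mean_diff >= 0 else UP_IN_CLASS0


def _as_group(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float).ravel()
    if a.size == 0:
        raise ValueError(f"group {name!r} is empty")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"group {name!r} contains non-finite values")
    return a


def mean_difference(x, y) -> float:
    """mean(y) - mean(x): the signed class-mean difference (class 1 minus
    class 0); on log2 data this is the log2 fold change."""
    x = _as_group(x, "x")
    y = _as_group(y, "y")
    return float(np.mean(y) - np.mean(x))


def mann_whitney_u(x, y) -> float:
    """Mann-Whitney U for class 1 (``y``) over class 0 (``x``): the number of
    (y, x) pairs with y > x, ties counted one half (midranks)."""
    x = _as_group(x, "x")
    y = _as_group(y, "y")
    ranks = rankdata(np.concatenate([x, y]))
    return float(ranks[x.size:].sum() - y.size * (y.size + 1) / 2.0)


def mann_whitney_p(x, y, exact_max_n: int = EXACT_MAX_N) -> float:
    """Two-sided Mann-Whitney p-value between the two groups.

    When the smaller group has at most ``exact_max_n`` values and the pooled
    values carry no ties, the exact permutation null of U is used; otherwise
    the normal approximation with continuity correction and midrank tie
    correction.
    """
    x = _as_group(x, "x")
    y = _as_group(y, "y")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0.0:
        return 1.0  # all values identical: no evidence of separation
    has_ties = np.unique(pooled).size < pooled.size
    if min(x.size, y.size) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(
        y, x, alternative="two-sided", method=method, use_continuity=True
    )
    p = float(res.pvalue)
    return float(min(max(p, np.nextafter(0.0, 1.0)), 1.0))


def welch_t_statistics(X0: np.ndarray, X1: np.ndarray) -> np.ndarray:
    """Per-feature Welch t statistics (class 1 minus class 0).

    Provided as the optional drop-in signal-to-noise statistic and as the
    normality-assuming baseline the two-way filter is compared against on
    subset-effect (non-normal) signal.
    """
    X0 = np.atleast_2d(np.asarray(X0, dtype=float))
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    n0, n1 = X0.shape[0], X1.shape[0]
    if n0 < 2 or n1 < 2:
        raise ValueError("Welch t needs at least 2 samples per class")
    num = X1.mean(axis=0) - X0.mean(axis=0)
    se2 = X0.var(axis=0, ddof=1) / n0 + X1.var(axis=0, ddof=1) / n1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / np.sqrt(se2)
    return np.where(se2 > 0, t, 0.0)


def feature_stats_arrays(X: np.ndarray, y, exact_max_n: int = EXACT_MAX_N):
    """Vectorized per-feature statistics on a samples x features matrix.

    Returns ``(mean_diff, mw_p)`` arrays of length ``n_features``. The
    Mann-Whitney dispatch matches :func:`mann_whitney_p`: per-feature exact
    enumeration at small group sizes, a single vectorized normal-approximation
    call otherwise.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = _validate_binary_labels(y, X.shape[0])
    X0, X1 = X[y == 0], X[y == 1]
    n0, n1 = X0.shape[0], X1.shape[0]
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    md = X1.mean(axis=0) - X0.mean(axis=0)
    if min(n0, n1) <= exact_max_n:
        p = np.array(
            [mann_whitney_p(X0[:, j], X1[:, j], exact_max_n) for j in range(X.shape[1])]
        )
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = mannwhitneyu(
                X1, X0, axis=0, alternative="two-sided",
                method="asymptotic", use_continuity=True,
            )
        p = np.asarray(res.pvalue, dtype=float)
        p = np.where(np.isfinite(p), p, 1.0)  # constant features
        p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    return md, p


def compute_feature_stats(m, labels, exact_max_n: int = EXACT_MAX_N):
    """Per-feature :class:`FeatureStats` for an expression matrix.

    ``labels`` is a 0/1 vector aligned with ``m.sample_ids``; statistics are
    class 1 versus class 0.
    """
    X = m.values.to_numpy(dtype=float).T  # samples x features
    md, p = feature_stats_arrays(X, labels, exact_max_n)
    return [
        FeatureStats(fid, float(d), float(pv))
        for fid, d, pv in zip(m.feature_ids, md, p)
    ]


def _validate_binary_labels(labels, n: int) -> np.ndarray:
    y = np.asarray(labels)
    if y.shape != (n,):
        raise ValueError(f"labels must be a vector of length {n}")
    vals = np.unique(y)
    if not np.isin(vals, [0, 1]).all():
        raise ValueError("labels must be binary 0/1")
    return y.astype(int)
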