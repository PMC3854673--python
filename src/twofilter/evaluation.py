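"""Performance estimation: AUROC, repeated stratified CV, nested CV.

Feature filtering is part of the model, so it is redone inside every training
fold; letting held-out samples influence which features are filtered inflates
the estimate (selection bias). Nested cross-validation goes one step further
and also keeps the *threshold tuning* out of the performance estimate: the
inner CV loop picks the threshold pair on the outer-training portion only,
and the outer loop scores samples the tuning never saw.

Per CV repeat, held-out scores from all folds are pooled into one AUROC;
the reported performance is the mean and SD of the per-repeat AUROCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold

from .dlda import pooled_moments
from .preprocessing import LOG, ExpressionMatrix
from .stats import _validate_binary_labels, feature_stats_arrays


@dataclass(frozen=True)
class CvSpec:
    """Repeated k-fold CV layout: k folds, ``repeats`` shuffles, one seed."""

    k: int = 5
    repeats: int = 5
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.repeats < 1:
            raise ValueError("repeats must be at least 1")


@dataclass(frozen=True)
class CvPerformance:
    """Mean/SD of AUROC over CV repeats plus the average selected-set size."""

    mean_auroc: float
    sd_auroc: float
    per_repeat_aurocs: tuple = field(default_factory=tuple)
    mean_n_features: float = float("nan")

    @classmethod
    def from_repeats(cls, aurocs, mean_n_features=float("nan")) -> "CvPerformance":
        a = np.asarray(aurocs, dtype=float)
        sd = float(a.std(ddof=1)) if a.size > 1 else 0.0
        return cls(float(a.mean()), sd, tuple(float(v) for v in a),
                   float(mean_n_features))


def auroc(scores, labels) -> float:
    """Rank-based AUROC with midrank tie handling.

    Equals U / (n1 * n0) where U counts (positive, negative) pairs with the
    positive scored higher, ties worth one half.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = _validate_binary_labels(labels, s.size)
    n1 = int((y == 1).sum())
    n0 = s.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    r = rankdata(s)
    u = r[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def make_folds(labels, spec: CvSpec):
    """Per-repeat fold assignments (one integer array per repeat).

    Stratified folds preserve the class ratio within one sample; the whole
    layout is deterministic given ``spec.seed``.
    """
    y = np.asarray(labels)
    n = y.size
    if n < spec.k:
        raise ValueError(f"need at least k={spec.k} samples, got {n}")
    if spec.stratified:
        y = _validate_binary_labels(y, n)
        counts = np.bincount(y, minlength=2)
        if counts.min() < spec.k:
            raise ValueError(
                f"stratified CV with k={spec.k} needs >= k samples per class, "
                f"got class counts {counts.tolist()}"
            )
    rng = np.random.default_rng(spec.seed)
    seeds = rng.integers(0, 2**31 - 1, size=spec.repeats)
    assignments = []
    X_dummy = np.zeros((n, 1))
    for s in seeds:
        if spec.stratified:
            splitter = StratifiedKFold(spec.k, shuffle=True, random_state=int(s))
            split = splitter.split(X_dummy, y)
        else:
            splitter = KFold(spec.k, shuffle=True, random_state=int(s))
            split = splitter.split(X_dummy)
        assign = np.empty(n, dtype=int)
        for f, (_, test_idx) in enumerate(split):
            assign[test_idx] = f
        assignments.append(assign)
    return assignments


# ---------------------------------------------------------------------------
# vectorized filter + DLDA engine shared by threshold CV, grid search and
# nested CV: per training fold the per-feature statistics and discriminant
# contributions are computed once, after which each threshold cell is just a
# masked sum.
# ---------------------------------------------------------------------------

def _fold_cell_scores(Xtr, ytr, Xte, t1s, t2s):
    """Held-out DLDA scores for every threshold cell, from one fold.

    Returns ``(scores (n_test, n_cells), n_selected (n_cells,))``. Cells
    through which no feature passes score every held-out sample 0 exactly.
    """
    md, p = feature_stats_arrays(Xtr, ytr)
    amd = np.abs(md)
    X0, X1 = Xtr[ytr == 0], Xtr[ytr == 1]
    mu0, mu1, s2 = pooled_moments(X0, X1)
    contrib = (Xte - (mu0 + mu1) / 2.0) * (2.0 * (mu1 - mu0) / s2)
    mask = (amd[:, None] >= t1s[None, :]) & (p[:, None] <= t2s[None, :])
    n_sel = mask.sum(axis=0)
    scores = contrib @ mask.astype(float)
    prior_term = 2.0 * np.log(X1.shape[0] / X0.shape[0])
    scores = scores + prior_term * (n_sel > 0)
    return scores, n_sel


def _auroc_columns(scores, y) -> np.ndarray:
    """AUROC of each column of a (n_samples, n_cells) score matrix."""
    n1 = int((y == 1).sum())
    n0 = y.size - n1
    r = rankdata(scores, axis=0)
    u = r[y == 1].sum(axis=0) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def evaluate_cells_cv(X, y, t1s, t2s, spec: CvSpec):
    """Repeated CV of filter+DLDA at every threshold cell.

    Returns ``(per_repeat_auroc (repeats, n_cells), mean_n_features
    (n_cells,))``; feature statistics and the classifier are recomputed on
    each training fold only.
    """
    y = _validate_binary_labels(y, X.shape[0])
    t1s = np.asarray(t1s, dtype=float)
    t2s = np.asarray(t2s, dtype=float)
    folds = make_folds(y, spec)
    per_repeat = np.empty((spec.repeats, t1s.size))
    n_sel_all = []
    for r, assign in enumerate(folds):
        scores = np.zeros((y.size, t1s.size))
        for f in range(spec.k):
            te = assign == f
            tr = ~te
            s, n_sel = _fold_cell_scores(X[tr], y[tr], X[te], t1s, t2s)
            scores[te] = s
            n_sel_all.append(n_sel)
        per_repeat[r] = _auroc_columns(scores, y)
    mean_n = np.mean(n_sel_all, axis=0)
    return per_repeat, mean_n


def _require_log(m: ExpressionMatrix) -> None:
    if m.scale != LOG:
        raise ValueError("expression matrix must be on log scale")


def cv_evaluate_thresholds(m: ExpressionMatrix, labels, thresholds,
                           spec: CvSpec) -> CvPerformance:
    """Repeated CV of the two-way filter + DLDA at one threshold pair.

    Filtering happens inside each training fold; folds where no feature
    passes contribute constant (uninformative) held-out scores.
    """
    _require_log(m)
    X = m.samples_by_features()
    per_repeat, mean_n = evaluate_cells_cv(
        X, labels, np.array([thresholds.t1]), np.array([thresholds.t2]), spec
    )
    return CvPerformance.from_repeats(per_repeat[:, 0], mean_n[0])


def cv_evaluate_fixed_features(m: ExpressionMatrix, labels, feature_ids,
                               spec: CvSpec) -> CvPerformance:
    """Repeated CV of DLDA on a *pre-specified* feature set.

    Appropriate for a signature fixed before seeing this data. If the set was
    chosen on the same samples this is run on, the estimate is optimistically
    biased — the selection leaked into every fold.
    """
    _require_log(m)
    sub = m.restrict_features(feature_ids)
    X = sub.samples_by_features()
    y = _validate_binary_labels(labels, X.shape[0])
    folds = make_folds(y, spec)
    aurocs = []
    # vacuous thresholds: every (pre-chosen) feature passes in every fold
    t1s, t2s = np.array([0.0]), np.array([1.0])
    for assign in folds:
        scores = np.zeros(y.size)
        for f in range(spec.k):
            te = assign == f
            s, _ = _fold_cell_scores(X[~te], y[~te], X[te], t1s, t2s)
            scores[te] = s[:, 0]
        aurocs.append(auroc(scores, y))
    return CvPerformance.from_repeats(aurocs, len(feature_ids))


def nested_cv(m: ExpressionMatrix, labels, grid=None,
              outer: CvSpec = CvSpec(), inner: CvSpec = CvSpec(),
              n_t1: int = 20, n_t2: int = 10, return_details: bool = False):
    """Nested CV: inner loop tunes the threshold pair, outer loop scores it.

    For each outer fold the full grid search (inner CV over every cell) runs
    on the outer-training portion alone; the winning pair then filters and
    fits on that portion and scores the outer held-out samples. One AUROC per
    outer repeat from pooled held-out scores.

    With ``grid=None`` (default) the threshold grid is rebuilt from each
    outer-training partition, so not even the grid axes see held-out data; a
    caller-supplied :class:`~twofilter.selection.ThresholdGrid` is used
    verbatim in every fold.
    """
    from .selection import _best_cell, _grid_axes  # deferred: avoids cycle

    _require_log(m)
    X = m.samples_by_features()
    y = _validate_binary_labels(labels, X.shape[0])
    folds = make_folds(y, outer)
    inner_seeds = np.random.default_rng(inner.seed).integers(
        0, 2**31 - 1, size=(outer.repeats, outer.k)
    )
    fixed_cells = None if grid is None else grid.cell_arrays()
    aurocs, n_sel_outer, details = [], [], []
    for r, assign in enumerate(folds):
        scores = np.zeros(y.size)
        for f in range(outer.k):
            te = assign == f
            tr = ~te
            Xtr, ytr = X[tr], y[tr]
            if fixed_cells is None:
                md, p = feature_stats_arrays(Xtr, ytr)
                t1s, t2s = _grid_axes(np.abs(md), p, n_t1, n_t2)
                ct1, ct2 = _cells_from_axes(t1s, t2s)
            else:
                ct1, ct2 = fixed_cells
            fold_spec = CvSpec(inner.k, inner.repeats,
                               int(inner_seeds[r, f]), inner.stratified)
            per_rep, mean_n = evaluate_cells_cv(Xtr, ytr, ct1, ct2, fold_spec)
            best = _best_cell(per_rep.mean(axis=0), mean_n, ct1, ct2)
            s, n_sel = _fold_cell_scores(
                Xtr, ytr, X[te], ct1[[best]], ct2[[best]]
            )
            scores[te] = s[:, 0]
            n_sel_outer.append(n_sel[0])
            details.append({
                "repeat": r, "fold": f,
                "t1": float(ct1[best]), "t2": float(ct2[best]),
                "n_features": int(n_sel[0]),
                "inner_mean_auroc": float(per_rep.mean(axis=0)[best]),
            })
        aurocs.append(auroc(scores, y))
    perf = CvPerformance.from_repeats(aurocs, float(np.mean(n_sel_outer)))
    if return_details:
        return perf, details
    return perf


def _cells_from_axes(t1_values, t2_values):
    t1s = np.repeat(np.asarray(t1_values, dtype=float),
                    len(t2_values))
    t2s = np.tile(np.asarray(t2_values, dtype=float), len(t1_values))
    return t1s, t2s
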