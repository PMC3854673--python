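"""Directional gene-signature scoring and zero-threshold classification.

A signature is two disjoint gene lists: ``up_poor`` (high expression marks
the positive / poor-prognosis class) and ``up_good``. The per-sample score is
the unscaled sum-difference of log expression values,

    score(s) = sum_{g in up_poor} x_gs  -  sum_{g in up_good} x_gs,

classified against a fixed threshold of zero. No scaling, centering or tuning
touches the validation data — the point of the construction is that nothing
can be fitted to the cohort being validated. A one-gene "signature" reduces
to the per-gene AUROC of that gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import auroc
from .preprocessing import LOG, ExpressionMatrix

UP_POOR = "up_poor"
UP_GOOD = "up_good"


@dataclass(frozen=True)
class Signature:
    """Two directional, disjoint gene lists; not both empty."""

    up_poor: tuple
    up_good: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "up_poor", tuple(self.up_poor))
        object.__setattr__(self, "up_good", tuple(self.up_good))
        if not self.up_poor and not self.up_good:
            raise ValueError("signature must name at least one gene")
        overlap = set(self.up_poor) & set(self.up_good)
        if overlap:
            raise ValueError(f"genes in both directions: {sorted(overlap)[:5]}")
        for lst, name in ((self.up_poor, UP_POOR), (self.up_good, UP_GOOD)):
            if len(lst) != len(set(lst)):
                raise ValueError(f"duplicate genes in {name}")


def signature_score(m: ExpressionMatrix, sig: Signature) -> pd.Series:
    """Per-sample sum-difference score on log-scale expression.

    All signature genes must be present; silently dropping missing genes
    would change the score's scale and the meaning of the zero cutoff.
    """
    if m.scale != LOG:
        raise ValueError("signature scoring requires log-scale expression")
    index = set(m.values.index)
    missing = [g for g in (*sig.up_poor, *sig.up_good) if g not in index]
    if missing:
        raise ValueError(f"signature genes missing from matrix: {missing}")
    pos = m.values.loc[list(sig.up_poor)].sum(axis=0) if sig.up_poor else 0.0
    neg = m.values.loc[list(sig.up_good)].sum(axis=0) if sig.up_good else 0.0
    score = pos - neg
    if np.isscalar(score):  # both lists cannot be empty, so unreachable
        raise AssertionError
    score.name = "score"
    return score.astype(float)


def signature_classify(scores, threshold: float = 0.0) -> np.ndarray:
    """Positive (poor-prognosis) class iff score > threshold; a score exactly
    at the threshold goes to the negative class."""
    s = np.asarray(scores, dtype=float).ravel()
    return (s > threshold).astype(int)


def evaluate_signature(m: ExpressionMatrix, sig: Signature, labels) -> float:
    """AUROC of the signature score against binary labels."""
    return auroc(signature_score(m, sig).to_numpy(), labels)


def read_signature(path) -> Signature:
    """Read a two-column TSV (feature_id, direction in {up_poor, up_good})."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"feature_id", "direction"} <= set(df.columns):
        raise ValueError("signature file needs columns feature_id, direction")
    bad = set(df["direction"]) - {UP_POOR, UP_GOOD}
    if bad:
        raise ValueError(f"unknown directions: {sorted(bad)}")
    return Signature(
        tuple(df.loc[df["direction"] == UP_POOR, "feature_id"]),
        tuple(df.loc[df["direction"] == UP_GOOD, "feature_id"]),
    )


def write_signature(sig: Signature, path) -> None:
    rows = [(g, UP_POOR) for g in sig.up_poor] + \
           [(g, UP_GOOD) for g in sig.up_good]
    pd.DataFrame(rows, columns=["feature_id", "direction"]).to_csv(
        path, sep="\t", index=False
    )
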