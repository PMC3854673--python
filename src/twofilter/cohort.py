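"""Phenotype handling: survival-endpoint dichotomization and clinical strata.

The phenotype table is a pandas DataFrame indexed by sample id with (at
least) ``time_years`` and ``event`` columns for survival endpoints, plus
named clinical covariates (``er_status``, ``node_status``, ...).

Two dichotomization rules turn a time-to-event endpoint into the binary
labels the classifier needs:

* extreme groups — poor prognosis = event before ``early`` years, good
  prognosis = event-free beyond ``late`` years; everything in between is
  dropped, trading sample size for cleaner class definitions during
  discovery.
* fixed horizon — positive = event by the horizon, negative = followed past
  the horizon event-free; samples censored before the horizon carry no
  definite label and are dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MISSING = "missing"

#: discovery endpoints: metastasis before 5 years vs disease-free past 10
DEFAULT_EARLY_YEARS = 5.0
DEFAULT_LATE_YEARS = 10.0


def read_phenotype(path) -> pd.DataFrame:
    """Read a phenotype TSV keyed by a ``sample_id`` column."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError("phenotype file needs a sample_id column")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in phenotype file")
    return df.set_index("sample_id")


def write_phenotype(pheno: pd.DataFrame, path) -> None:
    out = pheno.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def _check_survival_columns(pheno: pd.DataFrame) -> None:
    for col in ("time_years", "event"):
        if col not in pheno.columns:
            raise ValueError(f"phenotype table needs a {col!r} column")
    t = pheno["time_years"].to_numpy(dtype=float)
    e = pheno["event"].to_numpy()
    if (t < 0).any():
        raise ValueError("time_years must be nonnegative")
    if not np.isin(np.unique(e), [0, 1]).all():
        raise ValueError("event must be binary 0/1")
    if np.any((e == 1) & ~np.isfinite(t)):
        raise ValueError("events require finite times")


def dichotomize_extreme(pheno: pd.DataFrame,
                        early: float = DEFAULT_EARLY_YEARS,
                        late: float = DEFAULT_LATE_YEARS):
    """Extreme-group labels: poor (1) = event strictly before ``early``,
    good (0) = event-free strictly beyond ``late``; all others dropped.

    Returns ``(labels, retained_ids)`` in phenotype order.
    """
    _check_survival_columns(pheno)
    if not early < late:
        raise ValueError("early cutoff must precede late cutoff")
    t = pheno["time_years"].to_numpy(dtype=float)
    e = pheno["event"].to_numpy(dtype=int)
    poor = (e == 1) & (t < early)
    good = (e == 0) & (t > late)
    keep = poor | good
    labels = poor[keep].astype(int)
    _require_both_classes(labels, "extreme-group dichotomization")
    return labels, pheno.index[keep].tolist()


def dichotomize_at_horizon(pheno: pd.DataFrame, horizon: float):
    """Event-by-horizon labels: positive (1) = event at time <= horizon,
    negative (0) = followed past the horizon; censored before the horizon
    dropped (no definite label).

    Returns ``(labels, retained_ids)`` in phenotype order.
    """
    _check_survival_columns(pheno)
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    t = pheno["time_years"].to_numpy(dtype=float)
    e = pheno["event"].to_numpy(dtype=int)
    pos = (e == 1) & (t <= horizon)
    neg = t > horizon
    keep = pos | neg
    labels = pos[keep].astype(int)
    _require_both_classes(labels, f"dichotomization at {horizon} years")
    return labels, pheno.index[keep].tolist()


def _require_both_classes(labels: np.ndarray, what: str) -> None:
    if labels.size == 0 or labels.min() == labels.max():
        raise ValueError(f"{what} left no samples in one of the classes")


def stratify(pheno: pd.DataFrame, criteria) -> list:
    """Sample ids meeting ALL (covariate, value) criteria.

    ``criteria`` is a mapping or a sequence of pairs. Samples with a missing
    value (NaN or the string "missing") in any cited covariate are excluded
    rather than erroring. Empty criteria return all samples.
    """
    items = list(criteria.items()) if isinstance(criteria, dict) else list(criteria)
    keep = pd.Series(True, index=pheno.index)
    for col, value in items:
        if col not in pheno.columns:
            raise ValueError(f"unknown covariate {col!r}")
        v = pheno[col]
        present = v.notna() & (v.astype(str) != MISSING)
        keep &= present & (v.astype(str) == str(value))
    return pheno.index[keep].tolist()
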