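"""Expression-matrix container, TSV round-tripping, and preprocessing.

Expression files are plain tab-delimited text: the first column holds feature
identifiers, the header row sample identifiers, one feature per row. Matrices
carry a ``scale`` flag distinguishing raw intensities from log2 values so
that log transformation cannot be applied twice by accident. Flooring low
intensities (default floor 40) before the log2 transform is an explicit,
caller-controlled step: some platforms warrant it, others do not.

Probe-to-gene collapsing keeps, for each gene, the probe with the largest
interquartile range across samples — the probe with the most dynamic signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INTENSITY = "intensity"
LOG = "log"
_SCALES = (INTENSITY, LOG)

#: conventional intensity floor applied before log transformation
DEFAULT_FLOOR = 40.0


@dataclass
class ExpressionMatrix:
    """A features x samples expression matrix with a scale flag.

    ``values`` is a DataFrame indexed by feature id with sample ids as
    columns. ``scale`` is ``"intensity"`` (raw, positive after flooring) or
    ``"log"`` (log2, finite).
    """

    values: pd.DataFrame
    scale: str = LOG

    def __post_init__(self):
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        v = self.values
        if v.index.duplicated().any():
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        if v.columns.duplicated().any():
            dupes = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if np.isnan(arr).any():
            raise ValueError("missing values are not supported")
        if self.scale == LOG and not np.isfinite(arr).all():
            raise ValueError("log-scale values must be finite")

    @property
    def feature_ids(self) -> list:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def restrict_features(self, feature_ids) -> "ExpressionMatrix":
        """Sub-matrix with the given features, in the given order."""
        missing = [f for f in feature_ids if f not in self.values.index]
        if missing:
            raise ValueError(f"features not in matrix: {missing[:10]}")
        return ExpressionMatrix(self.values.loc[list(feature_ids)], self.scale)

    def drop_features(self, feature_ids) -> "ExpressionMatrix":
        keep = [f for f in self.feature_ids if f not in set(feature_ids)]
        return ExpressionMatrix(self.values.loc[keep], self.scale)

    def samples_by_features(self) -> np.ndarray:
        """Values as a samples x features float array (estimator layout)."""
        return self.values.to_numpy(dtype=float).T


@dataclass
class ProbeMap:
    """Probe-to-gene relation: each probe maps to at most one gene, a gene
    may own several probes."""

    entries: list = field(default_factory=list)

    def __post_init__(self):
        probes = [p for p, _ in self.entries]
        if len(probes) != len(set(probes)):
            raise ValueError("a probe may map to at most one gene")

    def to_dict(self) -> dict:
        return dict(self.entries)


def read_expression(path, scale: str = INTENSITY) -> ExpressionMatrix:
    """Read a tab-delimited expression file (features in rows)."""
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(sample_ids) != len(set(sample_ids)):
        raise ValueError(f"duplicate sample ids in header of {path}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0,
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed expression file {path}: {exc}") from exc
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression values in {path}: {exc}") from exc
    return ExpressionMatrix(df, scale)


def write_expression(m: ExpressionMatrix, path) -> None:
    df = m.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")  # shortest-repr floats: exact round trip


def read_probe_map(path) -> ProbeMap:
    """Read a two-column TSV (probe_id, gene_id); a header row is expected."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("probe map needs two columns (probe_id, gene_id)")
    return ProbeMap(list(zip(df.iloc[:, 0], df.iloc[:, 1])))


def floor_and_log(m: ExpressionMatrix, floor: float = DEFAULT_FLOOR) -> ExpressionMatrix:
    """Floor intensities at ``floor`` and log2-transform.

    Every value v becomes log2(max(v, floor)). Requires an intensity-scale
    matrix; applying it to log-scale data is a state error.
    """
    if m.scale != INTENSITY:
        raise ValueError("floor_and_log requires an intensity-scale matrix")
    if floor <= 0:
        raise ValueError("floor must be positive")
    out = np.log2(np.maximum(m.values.to_numpy(dtype=float), floor))
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns), LOG
    )


def _iqr(row: np.ndarray) -> float:
    q75, q25 = np.percentile(row, [75, 25])
    return float(q75 - q25)


def collapse_probes_by_iqr(m: ExpressionMatrix, probe_map: ProbeMap) -> ExpressionMatrix:
    """Collapse probes to genes, keeping the max-IQR probe per gene.

    Probes absent from the map are dropped (count logged). Ties in IQR are
    broken by file order of the probes. Gene order follows the first
    appearance of any of its probes.
    """
    mapping = probe_map.to_dict()
    present = [p for p in m.feature_ids if p in mapping]
    dropped = m.shape[0] - len(present)
    if dropped:
        logger.info("collapse_probes_by_iqr: dropped %d unmapped probes", dropped)
    if not present:
        raise ValueError("no probe of the matrix appears in the probe map")

    by_gene: dict = {}
    gene_order: list = []
    for probe in present:  # file order -> deterministic tie-breaking
        gene = mapping[probe]
        if gene not in by_gene:
            by_gene[gene] = []
            gene_order.append(gene)
        by_gene[gene].append(probe)

    arr = m.values
    keep_probes = []
    for gene in gene_order:
        probes = by_gene[gene]
        iqrs = [_iqr(arr.loc[p].to_numpy(dtype=float)) for p in probes]
        keep_probes.append(probes[int(np.argmax(iqrs))])

    out = arr.loc[keep_probes].copy()
    out.index = pd.Index(gene_order, name=arr.index.name)
    return ExpressionMatrix(out, m.scale)
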