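"""Expression-matrix container, file IO, probe collapsing and cohort normalization.

The matrix is the substrate of every analysis stage: features (probe sets or
gene symbols) in rows, samples (arrays or patients) in columns.  Two scales
are distinguished and tracked explicitly:

``raw``
    arbitrary fluorescence intensities, strictly positive;
``normalized``
    log2 ratio of each value to the per-feature median across the cohort
    (or a declared subgroup), so that every feature is centred at 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RAW = "raw"
NORMALIZED = "normalized"
_SCALES = (RAW, NORMALIZED)


class ExpressionMatrix:
    """A features x samples numeric matrix with an explicit intensity scale.

    Parameters
    ----------
    data:
        DataFrame indexed by feature id with one column per sample.
    scale:
        ``"raw"`` (positive intensities) or ``"normalized"``
        (log2 ratio-to-median values).
    """

    def __init__(self, data: pd.DataFrame, scale: str):
        if scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {scale!r}")
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        values = data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if np.isnan(values.astype(float)).any():
            raise ValueError("missing values are not supported")
        if scale == RAW and not (values > 0).all():
            raise ValueError("raw intensities must be strictly positive")
        self.data = data.astype(float)
        self.scale = scale

    # -- basic accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_features(self, features: Sequence[str]) -> "ExpressionMatrix":
        present = [f for f in features if f in self.data.index]
        if not present:
            raise ValueError("none of the requested features are present")
        return ExpressionMatrix(self.data.loc[present], self.scale)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, m = self.shape
        return f"ExpressionMatrix({n} features x {m} samples, scale={self.scale})"


@dataclass
class ProbeAnnotation:
    """Many-to-one mapping from probe set id to gene symbol.

    Probes absent from the mapping are treated as unannotated and are
    dropped when collapsing to gene level.
    """

    mapping: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.mapping = dict(self.mapping)

    def gene_for(self, probe: str) -> str | None:
        return self.mapping.get(probe)

    def __len__(self) -> int:
        return len(self.mapping)

    @classmethod
    def read(cls, path, sep: str = "\t") -> "ProbeAnnotation":
        df = pd.read_csv(path, sep=sep, dtype=str)
        if df.shape[1] < 2:
            raise ValueError("annotation needs two columns: probe_id, gene_symbol")
        probes, genes = df.iloc[:, 0], df.iloc[:, 1]
        if probes.duplicated().any():
            raise ValueError("a probe may map to only one gene symbol")
        return cls(dict(zip(probes, genes)))

    def write(self, path, sep: str = "\t") -> None:
        pd.DataFrame(
            {"probe_id": list(self.mapping), "gene_symbol": list(self.mapping.values())}
        ).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------

def read_expression_matrix(path, scale: str, sep: str = "\t") -> ExpressionMatrix:
    """Read a delimited feature x sample table.

    First column holds feature ids, the header row sample ids.  Non-numeric
    cells, missing cells (including ragged rows) and duplicated feature ids
    are rejected.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids in {path}: {dups[:5]}")
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric expression value in {path}: {exc}") from exc
    if df.isna().any().any():
        raise ValueError(f"missing or ragged values in {path}")
    return ExpressionMatrix(df, scale)


def write_expression_matrix(m: ExpressionMatrix, path, sep: str = "\t") -> None:
    out = m.data.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep=sep, float_format="%.10g")


# ---------------------------------------------------------------------------
# probe -> gene collapsing
# ---------------------------------------------------------------------------

def collapse_probes_to_genes(
    m: ExpressionMatrix, ann: ProbeAnnotation
) -> ExpressionMatrix:
    """Average multiple probe sets per gene into one representative row.

    Each gene's row is the arithmetic mean of its probes' rows on the
    current scale.  Unannotated probes are dropped (count logged).
    """
    genes = pd.Series(
        [ann.gene_for(p) for p in m.feature_ids], index=m.data.index, dtype=object
    )
    annotated = genes.notna()
    n_dropped = int((~annotated).sum())
    if annotated.sum() == 0:
        raise ValueError("no probe in the matrix has a gene annotation")
    if n_dropped:
        logger.info("collapse_probes_to_genes: dropped %d unannotated probes", n_dropped)
    collapsed = m.data.loc[annotated].groupby(genes[annotated]).mean()
    collapsed = collapsed.sort_index()
    collapsed.index.name = "gene_symbol"
    return ExpressionMatrix(collapsed, m.scale)


# ---------------------------------------------------------------------------
# cohort median normalization
# ---------------------------------------------------------------------------

def cohort_median_normalize(
    m: ExpressionMatrix,
    subgroups: Iterable[Sequence[str]] | None = None,
) -> ExpressionMatrix:
    """Normalize each feature to its median across the cohort, then log2.

    Every raw value v of feature f becomes ``log2(v / median_f)`` where the
    median is taken over all samples of the normalization group.  With
    ``subgroups`` given (a partition of the sample ids) the median is taken
    within each subgroup separately.

    The median is the conventional one (for an even sample count, the
    arithmetic mean of the two middle order statistics).  Consequently the
    per-feature median of the *normalized* values is exactly 0 for odd
    group sizes, while for even sizes it equals log2(GM/AM) of the middle
    pair of raw values — 0 only when those two values coincide.
    """
    if m.scale != RAW:
        raise ValueError("cohort_median_normalize expects a raw-scale matrix")
    if subgroups is None:
        groups = [list(m.sample_ids)]
    else:
        groups = [list(g) for g in subgroups]
        seen = [s for g in groups for s in g]
        if sorted(seen) != sorted(m.sample_ids):
            raise ValueError("subgroups must partition the sample ids exactly")
    out = m.data.copy()
    for g in groups:
        if len(g) < 2:
            raise ValueError(f"normalization subgroup of size {len(g)} (< 2 samples)")
        block = m.data[g]
        med = block.median(axis=1)
        if (med <= 0).any():
            bad = med.index[med <= 0][0]
            raise ValueError(f"feature {bad!r} has non-positive median")
        out[g] = np.log2(block.div(med, axis=0))
    return ExpressionMatrix(out, NORMALIZED)
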