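"""In-memory containers shared by every stage of the pipeline.

Expression data travel as a genes x samples table with an explicit unit tag,
sample annotations as a plain :class:`pandas.DataFrame` with the columns
``sample_id, genotype, internode, replicate``, and the replicate-averaged,
centred genotype x gene x internode means as a :class:`ThreeWayArray`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Recognised unit tags for an expression matrix.
UNITS = ("counts", "TPM", "CPM", "log2TPM1", "log2CPM1")

METADATA_COLUMNS = ("sample_id", "genotype", "internode", "replicate")


class ValidationError(ValueError):
    """Raised when an input table violates a documented invariant."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit unit tag.

    Parameters
    ----------
    values
        Numeric table, genes in rows (index = gene ids), samples in columns.
    unit
        One of ``counts``, ``TPM``, ``CPM``, ``log2TPM1``, ``log2CPM1``.
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValidationError(f"unknown unit tag {self.unit!r}; expected one of {UNITS}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("expression values must be finite (no NaN/inf)")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[gene_ids], self.unit)

    def with_values(self, values: pd.DataFrame, unit: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.unit if unit is None else unit)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check a sample-metadata table and return it with canonical column order.

    Requires columns ``sample_id, genotype, internode, replicate`` and a unique
    (genotype, internode, replicate) triple per row.
    """
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    key = meta[["genotype", "internode", "replicate"]]
    if key.duplicated().any():
        raise ValidationError("duplicate (genotype, internode, replicate) in metadata")
    return meta.loc[:, list(METADATA_COLUMNS)]


@dataclass
class ThreeWayArray:
    """Centred I x J x K array of genotype x gene x internode mean expression."""

    values: np.ndarray
    genotype_ids: list = field(default_factory=list)
    gene_ids: list = field(default_factory=list)
    internode_ids: list = field(default_factory=list)
    centering: str = "per-gene grand mean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("ThreeWayArray values must be 3-dimensional")
        i, j, k = self.values.shape
        for labels, n, name in (
            (self.genotype_ids, i, "genotype_ids"),
            (self.gene_ids, j, "gene_ids"),
            (self.internode_ids, k, "internode_ids"),
        ):
            if labels is not None and len(labels) and len(labels) != n:
                raise ValidationError(f"{name} length {len(labels)} != dimension {n}")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def total_ss(self) -> float:
        return float(np.sum(self.values**2))
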