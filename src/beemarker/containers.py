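"""Core data containers and plain-text I/O.

The pipeline operates on three tables: a gene x sample integer count matrix
with per-gene biotype labels, a per-cage sample table (stock, diet, source
colony, mean head+thorax dry mass in mg), and derived expression matrices
(VST values or log-CPM). All files are uncompressed TSV/CSV so fixtures
remain human-readable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BIOTYPES = ("protein_coding", "lncRNA", "viral", "other")

#: columns a featureCounts output carries besides the gene id and counts
_FEATURECOUNTS_META = {"Chr", "Start", "End", "Strand", "Length"}

REQUIRED_SAMPLE_COLUMNS = ("sample_id", "stock", "diet", "colony")


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


@dataclass
class CountMatrix:
    """Integer gene x sample count table plus per-gene biotype labels.

    ``counts`` is a genes-by-samples DataFrame with unique gene ids as the
    index and sample ids as columns. ``biotype`` is a Series aligned to the
    gene index with values in :data:`BIOTYPES`.
    """

    counts: pd.DataFrame
    biotype: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise FormatError(f"duplicate gene ids: {list(dups[:5])}")
        if self.counts.isna().any().any():
            raise FormatError("count matrix contains missing values")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise FormatError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("counts must be non-negative")
        self.biotype = self.biotype.reindex(self.counts.index).fillna("other")
        bad = set(self.biotype.unique()) - set(BIOTYPES)
        if bad:
            raise FormatError(f"unknown biotypes: {sorted(bad)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, gene_ids: Iterable[str]) -> "CountMatrix":
        idx = pd.Index(gene_ids)
        return CountMatrix(self.counts.loc[idx], self.biotype.loc[idx])


@dataclass
class ExprMatrix:
    """Real-valued gene x sample expression matrix (VST or log-CPM)."""

    values: pd.DataFrame
    transform_tag: str = "vst"

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        if self.transform_tag not in ("vst", "logcpm"):
            raise ValueError(f"unknown transform_tag {self.transform_tag!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class SizeFactors:
    """Per-sample median-of-ratios size factors, geometric mean 1."""

    s: pd.Series

    def __post_init__(self) -> None:
        if (self.s <= 0).any():
            raise ValueError("size factors must be positive")
        gm = np.exp(np.mean(np.log(self.s.to_numpy())))
        if abs(gm - 1.0) > 1e-6:
            raise ValueError(f"size factors must have geometric mean 1 (got {gm})")


@dataclass
class DispersionTrend:
    """Parametric NB dispersion-mean trend alpha(mu) = a0 + a1 / mu.

    ``a0`` is the asymptotic dispersion at high expression; ``a1`` captures
    the extra-Poisson spread of low-count genes. Both dimensionless.
    """

    a0: float
    a1: float

    def __post_init__(self) -> None:
        if not self.a0 > 0:
            raise ValueError("a0 must be positive")
        if self.a1 < 0:
            raise ValueError("a1 must be non-negative")

    def alpha(self, mu: np.ndarray) -> np.ndarray:
        return self.a0 + self.a1 / np.asarray(mu, dtype=float)


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Check the per-cage metadata table and normalize its column order.

    Required columns: sample_id, stock, diet, colony; optional weight_mg
    (mean head+thorax dry mass per bee, mg; pool total divided by 8).
    """
    missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise FormatError(f"sample table missing columns: {missing}")
    if samples["sample_id"].duplicated().any():
        raise FormatError("duplicate sample ids in sample table")
    if "weight_mg" in samples.columns:
        w = samples["weight_mg"].dropna()
        if (w <= 0).any():
            raise FormatError("weight_mg must be positive where present")
    return samples.reset_index(drop=True)


def read_counts(tsv: str | Path, annotation: str | Path | None = None) -> CountMatrix:
    """Read a count TSV (plain or featureCounts dialect) plus biotype annotation.

    The plain dialect is a gene-id column followed by one integer column per
    sample. The featureCounts dialect adds a ``#`` program line and the
    Chr/Start/End/Strand/Length columns, which are dropped. Gene ids missing
    from the annotation default to biotype "other".
    """
    df = pd.read_csv(tsv, sep="\t", comment="#", dtype_backend="numpy_nullable")
    if df.shape[1] < 2:
        raise FormatError(f"{tsv}: need a gene-id column and at least one sample column")
    gene_col = df.columns[0]
    drop = [c for c in df.columns if c in _FEATURECOUNTS_META]
    df = df.drop(columns=drop).set_index(gene_col)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    for col in df.columns:
        vals = df[col]
        if not pd.api.types.is_numeric_dtype(vals):
            raise FormatError(f"{tsv}: non-numeric value in column {col!r}")
        as_float = vals.astype(float)
        frac = as_float % 1
        if (frac != 0).any():
            row = df.index[(frac != 0).argmax()]
            raise FormatError(
                f"{tsv}: non-integer count at gene {row!r}, column {col!r}"
            )
    counts = df.astype(np.int64)
    if annotation is not None:
        ann = pd.read_csv(annotation, sep="\t")
        if not {"gene_id", "biotype"} <= set(ann.columns):
            raise FormatError(f"{annotation}: need columns gene_id and biotype")
        biotype = ann.set_index("gene_id")["biotype"].astype(str)
    else:
        biotype = pd.Series("other", index=counts.index)
    return CountMatrix(counts, biotype)


def write_counts(cm: CountMatrix, tsv: str | Path) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(tsv, sep="\t")


def write_annotation(cm: CountMatrix, tsv: str | Path) -> None:
    ann = pd.DataFrame({"gene_id": cm.gene_ids, "biotype": cm.biotype.to_numpy()})
    ann.to_csv(tsv, sep="\t", index=False)


def read_samples(csv: str | Path) -> pd.DataFrame:
    return validate_sample_table(pd.read_csv(csv))


def write_samples(samples: pd.DataFrame, csv: str | Path) -> None:
    validate_sample_table(samples).to_csv(csv, index=False)


def read_expr(tsv: str | Path, transform_tag: str = "vst") -> ExprMatrix:
    df = pd.read_csv(tsv, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExprMatrix(df, transform_tag)


def write_expr(expr: ExprMatrix, tsv: str | Path) -> None:
    out = expr.values.copy()
    out.index.name = "gene_id"
    out.to_csv(tsv, sep="\t")
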