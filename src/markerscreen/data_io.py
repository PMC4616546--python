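"""Tabular input/output and reference-gene normalization.

Expression and methylation matrices are plain TSV/CSV text: one row per
gene (or CpG probe), one column per sample, a header row of sample ids,
and the first column holding the row identifiers.  Sample annotations are
two-column ``sample_id,subtype`` tables.

Normalization divides every gene's value by a housekeeping reference gene
(TBP by default) within each sample, putting cohorts measured in
different processed-RNA-seq units (RSEM, RPKM) on a comparable scale.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "NormalizedMatrix",
    "SampleAnnotation",
    "MethylationTable",
    "read_expression",
    "read_annotation",
    "read_methylation",
    "normalize_by_reference",
    "write_table",
]


def _sep_for(path: str | os.PathLike, dialect: str | None) -> str:
    """Field separator: explicit dialect wins, otherwise file extension."""
    if dialect is not None:
        if dialect not in ("tsv", "csv"):
            raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
        return "\t" if dialect == "tsv" else ","
    ext = os.path.splitext(str(path))[1].lower()
    return "," if ext == ".csv" else "\t"


def _check_unique(ids, what: str) -> None:
    seen: set = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Dense gene x sample matrix of non-negative expression values.

    ``values`` is a DataFrame indexed by gene id with sample ids as
    columns.  Units (RSEM, RPKM, ...) are treated as opaque non-negative
    abundances.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        _check_unique(v.index, "gene")
        _check_unique(v.columns, "sample")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        bad = ~np.isfinite(arr)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite expression value at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )
        neg = arr < 0
        if neg.any():
            g, s = np.argwhere(neg)[0]
            raise ValueError(
                f"negative expression value {arr[g, s]!r} at gene {v.index[g]!r}, "
                f"sample {v.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class NormalizedMatrix(ExpressionMatrix):
    """Expression divided by a reference (housekeeping) gene per sample."""

    reference_gene: str = ""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.reference_gene not in self.values.index:
            raise ValueError(f"reference gene {self.reference_gene!r} missing from matrix")
        ref_row = self.values.loc[self.reference_gene].to_numpy()
        if not np.allclose(ref_row, 1.0):
            raise ValueError("reference gene row is not identically 1 after normalization")


@dataclass(frozen=True)
class SampleAnnotation:
    """Mapping of sample id to subtype label."""

    labels: pd.Series  # index: sample_id, values: subtype label

    def __post_init__(self) -> None:
        _check_unique(self.labels.index, "sample")
        if self.labels.isna().any():
            raise ValueError("annotation contains missing subtype labels")
        if self.labels.nunique() < 2:
            raise ValueError("annotation must contain at least 2 subtype labels")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def subtypes(self) -> list[str]:
        # stable, deterministic order
        return sorted(self.labels.unique())

    def samples_for(self, subtype: str) -> list[str]:
        return list(self.labels.index[self.labels == subtype])

    def counts(self) -> dict[str, int]:
        return {s: int((self.labels == s).sum()) for s in self.subtypes}


@dataclass(frozen=True)
class MethylationTable:
    """CpG probe x sample matrix of beta values in [0, 1]; NaN = missing."""

    beta: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.beta.index, "probe")
        _check_unique(self.beta.columns, "sample")
        arr = self.beta.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (arr < 0) | (arr > 1) | np.isinf(arr)
        if bad.any():
            p, s = np.argwhere(bad)[0]
            raise ValueError(
                f"beta value {arr[p, s]!r} outside [0, 1] at probe "
                f"{self.beta.index[p]!r}, sample {self.beta.columns[s]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)


def _read_matrix_frame(path, dialect) -> pd.DataFrame:
    sep = _sep_for(path, dialect)
    df = pd.read_csv(path, sep=sep, comment="#", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected an id column plus at least one sample column")
    df = df.set_index(df.columns[0])
    df.index.name = None
    return df


def read_expression(path, dialect: str | None = None) -> ExpressionMatrix:
    """Read a gene x sample expression table (genes as rows).

    The first column holds gene ids, the header row sample ids.  TSV/CSV
    auto-detected from the extension unless ``dialect`` is given.
    Duplicate ids, negative, non-numeric or non-finite cells are hard
    errors that name the offending coordinate.
    """
    df = _read_matrix_frame(path, dialect)
    _check_unique(df.index, "gene")
    try:
        df = df.astype(float)
    except (TypeError, ValueError):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad.to_numpy().nonzero()[0][0]]
                raise ValueError(
                    f"non-numeric expression value {df.loc[gene, col]!r} at gene "
                    f"{gene!r}, sample {col!r}"
                ) from None
        df = df.apply(pd.to_numeric)
    if df.isna().to_numpy().any():
        raise ValueError("expression matrix contains missing values")
    m = ExpressionMatrix(df)
    log.info("read expression matrix: %d genes x %d samples from %s", *m.shape, path)
    return m


def read_annotation(path, dialect: str | None = None) -> SampleAnnotation:
    """Read a two-column ``sample_id,subtype`` annotation table."""
    sep = _sep_for(path, dialect if dialect else ("csv" if str(path).endswith(".csv") else None))
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: annotation needs columns sample_id,subtype")
    labels = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy())
    ann = SampleAnnotation(labels)
    log.info("read annotation: %d samples, %d subtypes", len(ann.sample_ids), len(ann.subtypes))
    return ann


def read_methylation(path, dialect: str | None = None) -> MethylationTable:
    """Read a probe x sample beta-value table; empty cells and "NA" are missing."""
    sep = _sep_for(path, dialect)
    df = pd.read_csv(path, sep=sep, comment="#", na_values=["NA", ""], dtype={0: str})
    df = df.set_index(df.columns[0])
    df.index.name = None
    df = df.astype(float)
    t = MethylationTable(df)
    log.info("read methylation table: %d probes x %d samples", *df.shape)
    return t


def normalize_by_reference(m: ExpressionMatrix, reference_gene: str) -> NormalizedMatrix:
    """Divide every gene's value by the reference gene's value per sample.

    Samples where the reference gene reads 0 are dropped with a logged
    warning (keeps downstream percentile summaries finite).  Dropping all
    samples, or a missing reference gene, is a hard error.
    """
    if reference_gene not in m.values.index:
        raise ValueError(f"reference gene {reference_gene!r} not found in expression matrix")
    ref = m.values.loc[reference_gene]
    keep = ref > 0
    dropped = [s for s, k in zip(m.values.columns, keep) if not k]
    if dropped:
        log.warning(
            "dropping %d sample(s) with zero reference (%s) value: %s",
            len(dropped), reference_gene, ", ".join(map(str, dropped)),
        )
    if not keep.any():
        raise ValueError(f"all samples have zero {reference_gene!r} value; nothing to normalize")
    sub = m.values.loc[:, keep.to_numpy()]
    norm = sub.div(sub.loc[reference_gene], axis=1)
    return NormalizedMatrix(norm, reference_gene=reference_gene)


def write_table(df: pd.DataFrame, path, params: dict | None = None, index: bool = True) -> None:
    """Write a CSV with a commented provenance line (tool version + parameters)."""
    items = "" if not params else " " + " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    with open(path, "w") as fh:
        fh.write(f"# markerscreen v{__version__}{items}\n")
        df.to_csv(fh, index=index)
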