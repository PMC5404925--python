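"""Tab-delimited readers and writers for the pipeline's file formats.

Count matrices are genes-as-rows TSV with the gene id in the first column;
allelic tables are long-format TSV with columns gene, sample,
allele1_count, allele2_count.  Readers validate structure and report the
offending 1-based line number for malformed rows; writers use a fixed
float format so that identical inputs serialize byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (ALLELIC_COLUMNS, AllelicCountTable, CountMatrix,
                         SizeFactors, infer_gene_classes)
from .errors import InvalidArgumentError, ParseError

FLOAT_FORMAT = "%.12g"


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", **kwargs)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: file is empty")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    return df


def read_count_matrix(
    path,
    gene_class_path=None,
    sample_meta_path=None,
    markers=None,
    or_prefix: str = "Olfr",
    require_integer: bool = True,
) -> CountMatrix:
    """Read a genes x samples count TSV.

    Gene classes come from a two-column sidecar TSV (gene, class) when
    given, otherwise from naming conventions.  Negative or (by default)
    non-integer values are rejected with the offending line number
    (header = line 1).
    """
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    df.columns.name = "sample"
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        line = int(np.where(df.index == dup)[0][-1]) + 2
        raise ParseError(f"{path}: duplicate gene id {dup!r}", line=line)

    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                line = int(np.where(coerced.isna())[0][0]) + 2
                raise ParseError(f"{path}: non-numeric value in column {col!r}", line=line)
        df = df.apply(pd.to_numeric)
        values = df.to_numpy()
    neg = values < 0
    if neg.any():
        line = int(np.where(neg.any(axis=1))[0][0]) + 2
        raise ParseError(f"{path}: negative count", line=line)
    if require_integer:
        if not np.allclose(values, np.round(values)):
            frac = ~np.isclose(values, np.round(values))
            line = int(np.where(frac.any(axis=1))[0][0]) + 2
            raise ParseError(f"{path}: non-integer count", line=line)
        df = df.round().astype(np.int64)

    if gene_class_path is not None:
        classes = read_gene_classes(gene_class_path)
    else:
        classes = infer_gene_classes(df.index, markers=markers or (), or_prefix=or_prefix) \
            if markers is not None else infer_gene_classes(df.index, or_prefix=or_prefix)
    meta = None
    if sample_meta_path is not None:
        meta = _read_tsv(sample_meta_path, index_col=0)
        meta.index = meta.index.astype(str)
    return CountMatrix(df, classes, meta)


def write_count_matrix(matrix: CountMatrix, path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="gene",
                         float_format=FLOAT_FORMAT)


def read_gene_classes(path) -> pd.Series:
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected columns gene, class")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str).to_numpy(),
                  name="class")
    s.index.name = "gene"
    return s


def write_gene_classes(gene_class: pd.Series, path) -> None:
    gene_class.rename("class").to_csv(path, sep="\t", index_label="gene")


def read_allelic_table(path, allele_labels=("B6", "CAST")) -> AllelicCountTable:
    df = _read_tsv(path)
    missing = [c for c in ALLELIC_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in ("allele1_count", "allele2_count"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            line = int(np.where(coerced.isna())[0][0]) + 2
            raise ParseError(f"{path}: non-numeric {col}", line=line)
        if (coerced < 0).any():
            line = int(np.where((coerced < 0))[0][0]) + 2
            raise ParseError(f"{path}: negative {col}", line=line)
        df[col] = coerced.astype(np.int64)
    dup = df.duplicated(subset=["gene", "sample"])
    if dup.any():
        line = int(np.where(dup)[0][0]) + 2
        raise ParseError(f"{path}: duplicate (gene, sample) pair", line=line)
    return AllelicCountTable(df, allele_labels=tuple(allele_labels))


def write_allelic_table(allelic: AllelicCountTable, path) -> None:
    allelic.table.to_csv(path, sep="\t", index=False)


def read_size_factors(path, kind: str) -> SizeFactors:
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected columns sample, factor")
    s = pd.Series(df.iloc[:, 1].to_numpy(dtype=float),
                  index=df.iloc[:, 0].astype(str).to_numpy(), name="size_factor")
    s.index.name = "sample"
    return SizeFactors(kind, s)


def write_size_factors(factors: SizeFactors, path) -> None:
    factors.values.rename("factor").to_csv(path, sep="\t", index_label="sample",
                                           float_format=FLOAT_FORMAT)


def write_json(payload: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=2)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
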