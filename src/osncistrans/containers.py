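"""Core in-memory containers.

The universal currency of the pipeline is a gene-by-sample count matrix
(:class:`CountMatrix`) whose genes are classified as olfactory-receptor
(``OR``), OSN marker (``marker``) or ``other``.  F1 allele-specific counts
travel in a long-format :class:`AllelicCountTable`; per-sample scaling
constants in :class:`SizeFactors`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

GENE_CLASSES = ("OR", "marker", "other")

#: OSN maturity markers used for cell-content normalization.
DEFAULT_MARKER_GENES = ("Omp", "Adcy3", "Ano2", "Cnga2", "Gnal")


def infer_gene_classes(
    gene_ids,
    markers=DEFAULT_MARKER_GENES,
    or_prefix: str = "Olfr",
) -> pd.Series:
    """Classify genes by naming convention: known markers, ``Olfr*`` receptors, rest other."""
    markers = set(markers)
    classes = [
        "marker" if g in markers else ("OR" if str(g).startswith(or_prefix) else "other")
        for g in gene_ids
    ]
    return pd.Series(classes, index=pd.Index(gene_ids, name="gene"), name="class")


@dataclass
class CountMatrix:
    """Gene x sample expression matrix with gene classes and sample metadata.

    ``counts`` holds raw integers straight from quantification, or reals
    after normalization.  Values must be non-negative and finite.
    """

    counts: pd.DataFrame
    gene_class: pd.Series
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self):
        if not isinstance(self.counts, pd.DataFrame):
            raise InvalidArgumentError("counts must be a pandas DataFrame")
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise InvalidArgumentError(f"duplicate gene ids: {dups[:5]}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise InvalidArgumentError(f"duplicate sample ids: {dups[:5]}")
        vals = self.counts.to_numpy()
        if vals.size and (not np.isfinite(vals).all() or (vals < 0).any()):
            raise InvalidArgumentError("counts must be finite and non-negative")
        self.gene_class = self.gene_class.reindex(self.counts.index)
        if self.gene_class.isna().any():
            missing = self.gene_class.index[self.gene_class.isna()].tolist()
            raise InvalidArgumentError(f"genes without a class: {missing[:5]}")
        bad = set(self.gene_class.unique()) - set(GENE_CLASSES)
        if bad:
            raise InvalidArgumentError(f"unknown gene classes: {sorted(bad)}")
        if self.sample_meta is not None:
            missing = [s for s in self.counts.columns if s not in self.sample_meta.index]
            if missing:
                raise InvalidArgumentError(f"samples without metadata: {missing[:5]}")

    # -- convenience views ------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def or_genes(self) -> pd.Index:
        return self.counts.index[self.gene_class == "OR"]

    @property
    def marker_genes(self) -> pd.Index:
        return self.counts.index[self.gene_class == "marker"]

    def or_totals(self) -> pd.Series:
        """Per-sample total expression over OR-class genes."""
        return self.counts.loc[self.or_genes].sum(axis=0)

    def subset_samples(self, samples) -> "CountMatrix":
        meta = None
        if self.sample_meta is not None:
            meta = self.sample_meta.loc[list(samples)]
        return CountMatrix(self.counts[list(samples)].copy(), self.gene_class.copy(), meta)

    def copy(self) -> "CountMatrix":
        meta = self.sample_meta.copy() if self.sample_meta is not None else None
        return CountMatrix(self.counts.copy(), self.gene_class.copy(), meta)


@dataclass
class SizeFactors:
    """Positive per-sample scalars; ``depth`` factors divide, ``osn_content`` multiply."""

    kind: str
    values: pd.Series

    def __post_init__(self):
        if self.kind not in ("depth", "osn_content"):
            raise InvalidArgumentError(f"unknown size-factor kind: {self.kind!r}")
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals <= 0).any():
            raise InvalidArgumentError("size factors must be finite and > 0")

    def __getitem__(self, sample) -> float:
        return float(self.values[sample])

    def reindex(self, samples) -> "SizeFactors":
        sub = self.values.reindex(samples)
        if sub.isna().any():
            missing = sub.index[sub.isna()].tolist()
            raise InvalidArgumentError(f"missing size factors for samples: {missing[:5]}")
        return SizeFactors(self.kind, sub)


ALLELIC_COLUMNS = ("gene", "sample", "allele1_count", "allele2_count")


@dataclass
class AllelicCountTable:
    """SNP-informative read counts per gene, F1 sample and parental allele.

    ``allele_labels`` names allele 1 and allele 2 (by default the maternal
    B6 and paternal CAST strains of the hybrid cross).
    """

    table: pd.DataFrame
    allele_labels: tuple[str, str] = ("B6", "CAST")

    def __post_init__(self):
        missing = [c for c in ALLELIC_COLUMNS if c not in self.table.columns]
        if missing:
            raise InvalidArgumentError(f"allelic table missing columns: {missing}")
        self.table = self.table.loc[:, list(ALLELIC_COLUMNS)].reset_index(drop=True)
        counts = self.table[["allele1_count", "allele2_count"]].to_numpy()
        if counts.size and ((counts < 0).any() or not np.isfinite(counts.astype(float)).all()):
            raise InvalidArgumentError("allelic counts must be finite and non-negative")
        if self.table.duplicated(subset=["gene", "sample"]).any():
            dup = self.table[self.table.duplicated(subset=["gene", "sample"])]
            pairs = list(dup[["gene", "sample"]].itertuples(index=False, name=None))
            raise InvalidArgumentError(f"duplicate (gene, sample) pairs: {pairs[:5]}")

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.table["gene"].unique(), name="gene")

    @property
    def samples(self) -> pd.Index:
        return pd.Index(self.table["sample"].unique(), name="sample")

    def gene_totals(self) -> pd.Series:
        """Raw informative counts (both alleles, all samples) per gene."""
        tot = self.table["allele1_count"] + self.table["allele2_count"]
        return tot.groupby(self.table["gene"]).sum()

    def informative_fraction(self, total: "CountMatrix") -> pd.Series:
        """Empirical per-gene SNP-informative fraction against matching total counts."""
        inf = self.gene_totals()
        denom = total.counts.loc[:, self.samples].sum(axis=1)
        frac = (inf / denom.reindex(inf.index)).clip(0.0, 1.0)
        return frac.replace([np.inf, -np.inf], np.nan).fillna(0.0)
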