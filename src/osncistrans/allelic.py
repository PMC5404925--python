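"""Allelic ratio estimation and deconvolution of total expression.

Within an F1 hybrid, the share of a gene's SNP-informative fragments
assigned to each parental allele estimates the proportion of OSNs that
chose that allele.  Multiplying a gene's (doubly normalized) total
expression by the ratio and its complement splits it into allele-specific
expression values that sum exactly to the total.

Read-level exclusions (fragments splicing across a SNP, non-unique
mappers) are assumed to have been applied upstream; the allelic table is
taken as pre-filtered.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AllelicCountTable, SizeFactors
from .errors import InvalidArgumentError

log = logging.getLogger(__name__)


@dataclass
class InformativeFilterResult:
    """Genes retained by the lowest-quartile informative-count filter."""

    kept: list[str]
    totals: pd.Series = field(repr=False)
    quartile: float = 0.0

    @property
    def n_total(self) -> int:
        return int(self.totals.size)

    @property
    def fraction_kept(self) -> float:
        return len(self.kept) / max(self.n_total, 1)


def informative_gene_filter(
    allelic: AllelicCountTable,
    depth_factors: SizeFactors,
    osn_factors: SizeFactors | None = None,
) -> InformativeFilterResult:
    """Drop genes whose normalized SNP-informative counts fall in the lowest quartile.

    Per gene, informative counts of both alleles are normalized per sample
    (divided by the depth factor, multiplied by the OSN-content factor when
    given) and summed over all F1 samples.  Genes strictly above the first
    quartile (linear interpolation between order statistics) are kept.
    """
    df = allelic.table
    if df.empty:
        raise InvalidArgumentError("allelic table is empty")
    s = depth_factors.reindex(allelic.samples).values
    w = 1.0 / s
    if osn_factors is not None:
        w = w * osn_factors.reindex(allelic.samples).values
    row_w = df["sample"].map(w).to_numpy(dtype=float)
    normed = (df["allele1_count"] + df["allele2_count"]).to_numpy(dtype=float) * row_w
    totals = pd.Series(normed).groupby(df["gene"]).sum().sort_index()
    q1 = float(np.quantile(totals.to_numpy(), 0.25))
    kept = totals.index[totals > q1].tolist()
    if not kept:
        warnings.warn("all informative totals identical; no gene strictly above Q1")
    log.info("informative filter kept %d/%d genes (Q1 = %.4g)",
             len(kept), totals.size, q1)
    return InformativeFilterResult(kept=kept, totals=totals, quartile=q1)


def allelic_ratio(
    allelic: AllelicCountTable,
    pooling: str = "pooled",
    sample_weights: pd.Series | None = None,
) -> tuple[pd.DataFrame, list]:
    """Allele-1 share of informative counts, per gene.

    ``pooled`` (default) sums counts over all F1 replicates before taking
    the ratio; ``per_sample`` returns one ratio per (gene, sample).
    Optional per-sample weights (e.g. combined size factors) rescale the
    counts before pooling; the reported ``informative_total`` is always the
    raw count backing the estimate.  Entries with zero informative counts
    are omitted and returned in the skipped list.
    """
    if pooling not in ("pooled", "per_sample"):
        raise InvalidArgumentError(f"unknown pooling mode {pooling!r}")
    df = allelic.table.copy()
    if sample_weights is not None:
        w = pd.Series(sample_weights).reindex(df["sample"].unique())
        if w.isna().any():
            missing = w.index[w.isna()].tolist()
            raise InvalidArgumentError(f"missing sample weights: {missing[:5]}")
        row_w = df["sample"].map(w).to_numpy(dtype=float)
    else:
        row_w = np.ones(len(df))
    df["w1"] = df["allele1_count"] * row_w
    df["w2"] = df["allele2_count"] * row_w
    df["raw_total"] = df["allele1_count"] + df["allele2_count"]

    if pooling == "pooled":
        grouped = df.groupby("gene", sort=True)[["w1", "w2", "raw_total"]].sum()
        denom = grouped["w1"] + grouped["w2"]
        ok = denom > 0
        skipped = grouped.index[~ok].tolist()
        out = pd.DataFrame({
            "gene": grouped.index[ok],
            "r": (grouped["w1"][ok] / denom[ok]).to_numpy(),
            "informative_total": grouped["raw_total"][ok].to_numpy(dtype=np.int64),
        }).reset_index(drop=True)
    else:
        denom = df["w1"] + df["w2"]
        ok = denom > 0
        skipped = list(df.loc[~ok, ["gene", "sample"]].itertuples(index=False, name=None))
        out = pd.DataFrame({
            "gene": df.loc[ok, "gene"].to_numpy(),
            "sample": df.loc[ok, "sample"].to_numpy(),
            "r": (df.loc[ok, "w1"] / denom[ok]).to_numpy(),
            "informative_total": df.loc[ok, "raw_total"].to_numpy(dtype=np.int64),
        })
    if skipped:
        log.info("allelic_ratio skipped %d entries with zero informative counts",
                 len(skipped))
    return out, skipped


def deconvolve_alleles(total, ratios: pd.DataFrame) -> pd.DataFrame:
    """Split total normalized expression into allele-specific values.

    ``total`` is a per-gene Series (or a gene x sample DataFrame, which is
    averaged over samples first).  Allele 1 receives total * r and allele 2
    the complement total * (1 - r), so the two always sum to the total.
    """
    if isinstance(total, pd.DataFrame):
        total = total.mean(axis=1)
    total = pd.Series(total, dtype=float)
    r = pd.Series(ratios["r"].to_numpy(), index=ratios["gene"].to_numpy())
    if ((r < 0) | (r > 1)).any():
        raise InvalidArgumentError("allelic ratio outside [0, 1]")
    missing = [g for g in r.index if g not in total.index]
    if missing:
        raise InvalidArgumentError(f"genes without total expression: {missing[:5]}")
    tot = total.reindex(r.index)
    return pd.DataFrame({
        "gene": r.index,
        "allele1_value": (tot * r).to_numpy(),
        "allele2_value": (tot * (1.0 - r)).to_numpy(),
        "total_value": tot.to_numpy(),
    }).reset_index(drop=True)
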