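"""In-silico F1 construction and technical-noise correction.

An in-silico hybrid is assembled by binomially thinning each parental
sample to half the median F1 depth and summing one B6 with one CAST
sample.  Its true allelic fold change equals the parental fold change by
construction, so any deviation of the in-silico allelic estimate from the
x = y line measures technical noise — chiefly the shrinkage and scatter
introduced by low SNP-informative counts.  Subtracting the per-gene mean
deviation from the real F1 allelic fold changes removes that systematic
component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AllelicCountTable, CountMatrix
from .errors import InvalidArgumentError
from .synthetic import _child_rng

log = logging.getLogger(__name__)

_INSILICO_KEY = 29


@dataclass
class DeviationTable:
    """Per-gene mean deviation of in-silico allelic fold changes from parental ones."""

    table: pd.DataFrame  # columns: gene, d, n
    omitted: list

    def as_series(self) -> pd.Series:
        return pd.Series(self.table["d"].to_numpy(),
                         index=self.table["gene"].to_numpy(), name="d")


def build_insilico_f1(
    b6: CountMatrix,
    cast: CountMatrix,
    f1_depths,
    pairing: list[tuple] | None = None,
    seed: int = 0,
    informative_fraction: pd.Series | None = None,
    content_weights: pd.Series | None = None,
) -> tuple[CountMatrix, AllelicCountTable]:
    """Combine thinned parental samples into a 50:50 hybrid with known allele origin.

    Each parental column is thinned to 0.5 x median(f1_depths); paired
    columns are summed into total counts.  Allelic counts are the thinned
    parental contributions themselves (every fragment's strain of origin
    is known), optionally thinned further by a per-gene informative
    fraction to mimic SNP-informative sparsity.

    ``content_weights`` (per parental sample; typically the combined
    normalization multiplier f_j / s_j) balances the two alleles in
    OSN-content terms rather than raw fragments: within a pair, thinning
    fractions are chosen proportional to the weights, so a parent whose
    library under-represents OSN content contributes proportionally more
    fragments.  Without it, parents with unequal OSN fractions would shift
    every gene's in-silico allelic ratio by a common offset that a real F1
    (where both alleles share one tissue) does not have.
    """
    f1_depths = np.asarray(list(f1_depths), dtype=float)
    if f1_depths.size == 0 or (f1_depths <= 0).any():
        raise InvalidArgumentError("f1_depths must be nonempty and positive")
    if not b6.genes.equals(cast.genes):
        raise InvalidArgumentError("parental matrices must share the same gene index")
    if pairing is None:
        k = min(b6.samples.size, cast.samples.size)
        pairing = list(zip(b6.samples[:k], cast.samples[:k]))
    if not pairing:
        raise InvalidArgumentError("pairing must be nonempty")
    for sb, sc in pairing:
        if sb not in b6.samples:
            raise InvalidArgumentError(f"unknown B6 sample in pairing: {sb!r}")
        if sc not in cast.samples:
            raise InvalidArgumentError(f"unknown CAST sample in pairing: {sc!r}")

    target = 0.5 * float(np.median(f1_depths))
    rng = _child_rng(seed, _INSILICO_KEY)
    or_genes = b6.or_genes
    pi = None
    if informative_fraction is not None:
        pi = pd.Series(informative_fraction, dtype=float).reindex(or_genes).fillna(1.0)
        pi = pi.clip(0.0, 1.0).to_numpy()

    totals, rows, ids = [], [], []
    for j, (sb, sc) in enumerate(pairing):
        raw, weight = {}, {}
        for tag, mat, sample in (("b6", b6, sb), ("cast", cast, sc)):
            col = mat.counts[sample].to_numpy()
            raw[tag] = np.asarray(np.round(col), dtype=np.int64)
            if content_weights is not None:
                if sample not in content_weights.index:
                    raise InvalidArgumentError(
                        f"sample {sample!r} missing from content_weights")
                weight[tag] = float(content_weights[sample])
            else:
                weight[tag] = 1.0
        if raw["b6"].sum() == 0 or raw["cast"].sum() == 0:
            raise InvalidArgumentError(f"pair ({sb!r}, {sc!r}) has an empty sample")
        # thinning fractions proportional to the content weights, capped so
        # neither parent exceeds half the median F1 depth (or its own total)
        scale = min(min(1.0, target / raw[tag].sum()) / weight[tag]
                    for tag in ("b6", "cast"))
        cols = {tag: rng.binomial(raw[tag], scale * weight[tag])
                for tag in ("b6", "cast")}
        sample_id = f"insilicoF1_{j + 1}"
        ids.append(sample_id)
        totals.append(cols["b6"] + cols["cast"])
        a1 = cols["b6"][b6.genes.get_indexer(or_genes)]
        a2 = cols["cast"][b6.genes.get_indexer(or_genes)]
        if pi is not None:
            a1 = rng.binomial(a1, pi)
            a2 = rng.binomial(a2, pi)
        rows.append(pd.DataFrame({
            "gene": or_genes,
            "sample": sample_id,
            "allele1_count": a1,
            "allele2_count": a2,
        }))

    counts = pd.DataFrame(np.column_stack(totals), index=b6.genes,
                          columns=pd.Index(ids, name="sample"))
    meta = pd.DataFrame({"strain": "insilico_B6xCAST", "sex": "NA",
                         "condition": "insilico"},
                        index=pd.Index(ids, name="sample"))
    matrix = CountMatrix(counts, b6.gene_class.copy(), meta)
    allelic = AllelicCountTable(pd.concat(rows, ignore_index=True))
    return matrix, allelic


def compute_deviation(insilico_fc, parental_fc: pd.Series) -> DeviationTable:
    """Mean per-gene deviation of in-silico allelic fold changes from parental ones.

    ``insilico_fc`` is a Series, a list of Series (one per in-silico
    replicate set) or a gene x replicate DataFrame.  Genes absent from
    either side are omitted and listed.
    """
    if isinstance(insilico_fc, pd.Series):
        fc = insilico_fc.to_frame("rep1")
    elif isinstance(insilico_fc, pd.DataFrame):
        fc = insilico_fc
    else:
        fc = pd.concat({f"rep{i + 1}": s for i, s in enumerate(insilico_fc)}, axis=1)
    parental_fc = pd.Series(parental_fc, dtype=float)
    common = fc.index.intersection(parental_fc.index)
    omitted = sorted(set(fc.index.symmetric_difference(parental_fc.index)))
    if common.empty:
        raise InvalidArgumentError("no overlapping genes between in-silico and parental sets")
    dev = fc.loc[common].sub(parental_fc.loc[common], axis=0)
    d = dev.mean(axis=1, skipna=True)
    n = dev.notna().sum(axis=1)
    ok = np.isfinite(d) & (n > 0)
    omitted += sorted(common[~ok])
    table = pd.DataFrame({"gene": common[ok], "d": d[ok].to_numpy(),
                          "n": n[ok].to_numpy(dtype=int)}).reset_index(drop=True)
    if omitted:
        log.info("compute_deviation omitted %d genes", len(omitted))
    return DeviationTable(table=table, omitted=omitted)


def correct_allelic_fc(raw: pd.Series, deviation: DeviationTable) -> pd.DataFrame:
    """Subtract the technical deviation: corrected = raw - d.

    Genes without a deviation estimate pass through unchanged, flagged in
    the ``corrected_flag`` column.  Gene membership never changes.
    """
    raw = pd.Series(raw, dtype=float)
    d = deviation.as_series().reindex(raw.index)
    corrected = raw - d.fillna(0.0)
    return pd.DataFrame({
        "gene": raw.index,
        "allelic_log2fc_raw": raw.to_numpy(),
        "allelic_log2fc_corrected": corrected.to_numpy(),
        "deviation": d.to_numpy(),
        "corrected_flag": d.notna().to_numpy(),
    }).reset_index(drop=True)
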