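"""Two-stage normalization of WOM count matrices.

Stage one removes sequencing-depth differences with the median-of-ratios
size-factor estimator.  Stage two removes differences in per-sample OSN
content: OSN marker genes that track the total OR signal are geometrically
averaged per sample, and OR-class counts are rescaled so that marker
expression — hence OSN content — is equalized across samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, SizeFactors
from .errors import (DegenerateInputError, GateFailureError,
                     InvalidArgumentError, UndefinedStatisticError)
from .stats import pearson, rank_correlation

log = logging.getLogger(__name__)


@dataclass
class MarkerGateResult:
    """Which markers tracked total OR expression well enough to normalize with."""

    correlations: dict[str, float]
    kept: list[str]
    threshold: float
    excluded: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "correlations": {k: self.correlations[k] for k in sorted(self.correlations)},
            "kept": sorted(self.kept),
            "threshold": self.threshold,
            "excluded": {k: self.excluded[k] for k in sorted(self.excluded)},
        }


def depth_size_factors(matrix: CountMatrix) -> SizeFactors:
    """Median-of-ratios sequencing-depth size factors.

    The reference for each gene is its geometric mean across samples
    (genes with any zero are excluded); each sample's factor is the median
    ratio of its counts to the reference.  Dividing a column by its factor
    yields depth-normalized expression.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    usable = (counts > 0).all(axis=1)
    if not usable.any():
        raise DegenerateInputError(
            "no gene has nonzero counts in every sample; depth factors undefined")
    sub = counts[usable]
    ref = np.exp(np.mean(np.log(sub), axis=1))
    ratios = sub / ref[:, np.newaxis]
    s = np.median(ratios, axis=0)
    if (s <= 0).any():
        raise DegenerateInputError("median-of-ratios produced a non-positive factor")
    # unit geometric mean keeps the overall expression scale fixed and makes
    # the estimator idempotent
    s = s / np.exp(np.mean(np.log(s)))
    return SizeFactors("depth", pd.Series(s, index=matrix.samples, name="size_factor"))


def apply_depth_normalization(matrix: CountMatrix, factors: SizeFactors) -> CountMatrix:
    """Divide each sample's counts by its depth size factor."""
    factors = factors.reindex(matrix.samples)
    normed = matrix.counts / factors.values
    meta = matrix.sample_meta.copy() if matrix.sample_meta is not None else None
    return CountMatrix(normed, matrix.gene_class.copy(), meta)


def marker_gate(
    normalized: CountMatrix,
    markers=None,
    threshold: float = 0.7,
    method: str = "spearman",
) -> MarkerGateResult:
    """Keep markers whose expression correlates with total OR counts.

    Rank correlation by default (ties averaged); a marker with zero
    variance is excluded with a warning rather than failing the run.  An
    empty kept set is a hard error: OSN-content normalization would be
    meaningless.
    """
    if normalized.samples.size < 3:
        raise InvalidArgumentError("marker gate needs at least 3 samples")
    if markers is None:
        markers = list(normalized.marker_genes)
    missing = [m for m in markers if m not in normalized.genes]
    if missing:
        raise InvalidArgumentError(f"markers absent from matrix: {missing}")
    corr_fn = {"spearman": rank_correlation, "pearson": pearson}.get(method)
    if corr_fn is None:
        raise InvalidArgumentError(f"unknown correlation method {method!r}")

    or_totals = normalized.or_totals().to_numpy(dtype=float)
    correlations: dict[str, float] = {}
    excluded: dict[str, str] = {}
    kept: list[str] = []
    for m in markers:
        expr = normalized.counts.loc[m].to_numpy(dtype=float)
        try:
            rho = corr_fn(expr, or_totals)
        except UndefinedStatisticError:
            excluded[m] = "constant expression; correlation undefined"
            warnings.warn(f"marker {m!r} constant across samples; excluded from gate")
            continue
        correlations[m] = rho
        if rho >= threshold:
            kept.append(m)
        else:
            excluded[m] = f"correlation {rho:.3f} below threshold {threshold}"
    if not kept:
        raise GateFailureError(
            f"no marker passed the correlation gate at threshold {threshold}")
    log.info("marker gate kept %d/%d markers", len(kept), len(markers))
    return MarkerGateResult(correlations=correlations, kept=kept,
                            threshold=threshold, excluded=excluded)


def osn_size_factors(
    normalized: CountMatrix, kept_markers, pseudocount: float = 0.0
) -> SizeFactors:
    """OSN-content size factors from kept markers.

    g_j is the geometric mean of marker expression in sample j; the factor
    is mean(g) / g_j, so multiplying OR counts by it equalizes OSN content.
    Marker genes are abundant by definition, so a zero marker value is a
    hard error unless a pseudocount is supplied.
    """
    kept_markers = list(kept_markers)
    if not kept_markers:
        raise InvalidArgumentError("kept_markers must be nonempty")
    vals = normalized.counts.loc[kept_markers].to_numpy(dtype=float) + pseudocount
    if (vals <= 0).any():
        bad_j = np.where((vals <= 0).any(axis=0))[0][0]
        raise DegenerateInputError(
            f"marker value <= 0 in sample {normalized.samples[bad_j]!r}; "
            "supply a pseudocount or drop the sample")
    g = np.exp(np.mean(np.log(vals), axis=0))
    f = g.mean() / g
    return SizeFactors("osn_content", pd.Series(f, index=normalized.samples,
                                                name="size_factor"))


def apply_osn_normalization(normalized: CountMatrix, factors: SizeFactors) -> CountMatrix:
    """Multiply OR-class rows by the OSN-content factors; other rows untouched."""
    factors = factors.reindex(normalized.samples)
    out = normalized.counts.copy().astype(float)
    or_rows = normalized.gene_class == "OR"
    out.loc[or_rows] = out.loc[or_rows] * factors.values
    meta = normalized.sample_meta.copy() if normalized.sample_meta is not None else None
    return CountMatrix(out, normalized.gene_class.copy(), meta)


def two_stage_normalize(
    matrix: CountMatrix,
    markers=None,
    threshold: float = 0.7,
    method: str = "spearman",
    marker_pseudocount: float = 0.0,
):
    """Depth then OSN-content normalization.

    Returns ``(normalized, depth_factors, osn_factors, gate)``.
    """
    s = depth_size_factors(matrix)
    depth_normed = apply_depth_normalization(matrix, s)
    gate = marker_gate(depth_normed, markers=markers, threshold=threshold, method=method)
    f = osn_size_factors(depth_normed, gate.kept, pseudocount=marker_pseudocount)
    return apply_osn_normalization(depth_normed, f), s, f, gate
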