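"""Lightweight negative-binomial differential-abundance test.

A method-of-moments stand-in for a full shrinkage-based NB framework:
per-gene dispersion is estimated from within-group moments of normalized
counts, a Wald statistic is formed on the log2 fold change with the NB
variance propagated through the delta method, and p-values are referred to
a t distribution with n_A + n_B - 2 degrees of freedom before
Benjamini-Hochberg adjustment.  No dispersion shrinkage is applied — a
documented limitation relative to mature DE packages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps

from .containers import CountMatrix, SizeFactors
from .errors import InvalidArgumentError
from .stats import bh_adjust


@dataclass
class DEResult:
    """Per-gene DE table plus the list of all-zero genes excluded from testing."""

    table: pd.DataFrame  # gene, base_mean, log2fc, alpha, p, q, significant
    fdr: float
    excluded: list = field(default_factory=list)

    @property
    def significant_genes(self) -> list:
        sig = self.table.loc[self.table["significant"], "gene"]
        return sig.tolist()


def _group_moments(normed: np.ndarray):
    """Per-gene mean and unbiased variance of one group's normalized counts."""
    m = normed.mean(axis=1)
    v = normed.var(axis=1, ddof=1)
    return m, v


def estimate_dispersion(groups: list[np.ndarray]) -> np.ndarray:
    """Method-of-moments NB dispersion, pooled across groups.

    Per group g: alpha = (var - mean) / mean^2 from normalized counts; the
    pooled estimate averages groups weighted by their degrees of freedom
    and truncates at zero (sub-Poisson variance maps to alpha = 0).
    Zero-mean genes get NaN.
    """
    if any(g.shape[1] < 2 for g in groups):
        raise InvalidArgumentError("dispersion estimation needs >= 2 replicates per group")
    num = np.zeros(groups[0].shape[0])
    den = np.zeros_like(num)
    any_expressed = np.zeros_like(num, dtype=bool)
    for g in groups:
        m, v = _group_moments(g)
        w = g.shape[1] - 1
        ok = m > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(ok, (v - m) / np.where(ok, m, 1.0) ** 2, 0.0)
        num += np.where(ok, w * a, 0.0)
        den += np.where(ok, w, 0.0)
        any_expressed |= ok
    with np.errstate(invalid="ignore"):
        alpha = np.where(den > 0, num / np.maximum(den, 1.0), np.nan)
    alpha = np.maximum(alpha, 0.0)
    alpha[~any_expressed] = np.nan
    return alpha


def nb_wald_test(
    group_a: CountMatrix,
    group_b: CountMatrix,
    size_factors: SizeFactors | None = None,
    fdr: float = 0.05,
    pseudocount: float = 0.5,
) -> DEResult:
    """Wald test of group B vs group A on the log2 fold change of normalized means.

    Counts are divided by the per-sample size factors, within-group NB
    variances (m + alpha m^2, alpha pooled method-of-moments) are
    propagated to the log scale, and significance is called at the given
    FDR after BH adjustment.  Genes with zero counts in both groups are
    excluded and listed.
    """
    if group_a.samples.size < 2 or group_b.samples.size < 2:
        raise InvalidArgumentError("both groups need >= 2 replicates")
    if not group_a.genes.equals(group_b.genes):
        raise InvalidArgumentError("groups must share the same gene index")
    genes = group_a.genes

    def _normalize(mat: CountMatrix) -> tuple[np.ndarray, np.ndarray]:
        counts = mat.counts.to_numpy(dtype=float)
        if size_factors is None:
            s = np.ones(counts.shape[1])
        else:
            s = size_factors.reindex(mat.samples).values.to_numpy(dtype=float)
        return counts / s[np.newaxis, :], s

    na, sa = _normalize(group_a)
    nb, sb = _normalize(group_b)

    expressed = (na.sum(axis=1) + nb.sum(axis=1)) > 0
    excluded = genes[~expressed].tolist()

    alpha = estimate_dispersion([na, nb])
    m_a = na.mean(axis=1)
    m_b = nb.mean(axis=1)

    # NB variance of each normalized replicate, averaged into the group mean
    def _var_of_mean(m, s, a):
        per_rep = m[:, np.newaxis] / s[np.newaxis, :] + a[:, np.newaxis] * m[:, np.newaxis] ** 2
        return per_rep.sum(axis=1) / s.size ** 2

    a_safe = np.nan_to_num(alpha, nan=0.0)
    v_a = _var_of_mean(m_a, sa, a_safe)
    v_b = _var_of_mean(m_b, sb, a_safe)

    ln2 = np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(m_b + pseudocount) - np.log2(m_a + pseudocount)
        se = np.sqrt(v_a / np.maximum(m_a + pseudocount, 1e-300) ** 2
                     + v_b / np.maximum(m_b + pseudocount, 1e-300) ** 2) / ln2
        stat = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)

    df = group_a.samples.size + group_b.samples.size - 2
    p = 2.0 * sps.t.sf(np.abs(stat), df)
    p = np.clip(p, 0.0, 1.0)

    mask = expressed
    q = np.full_like(p, np.nan)
    if mask.any():
        q[mask] = bh_adjust(p[mask])

    table = pd.DataFrame({
        "gene": genes,
        "base_mean": (m_a + m_b) / 2.0,
        "log2fc": log2fc,
        "alpha": alpha,
        "p": np.where(mask, p, np.nan),
        "q": q,
        "significant": np.where(mask, q <= fdr, False),
    })
    table = table[mask.tolist()].reset_index(drop=True)
    return DEResult(table=table, fdr=fdr, excluded=excluded)
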