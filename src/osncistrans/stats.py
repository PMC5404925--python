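"""Statistical primitives.

Lin's concordance correlation coefficient with its bias-correction factor
C_b (the quantity used to ask whether allelic and parental fold changes
fall on the x = y line), exact hypergeometric upper tails in log space,
rank/linear correlations, log2 fold changes, Benjamini-Hochberg adjustment
and the qPCR relative-quantity transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats as sps
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .errors import InvalidArgumentError, UndefinedStatisticError

__all__ = [
    "ConcordanceReport",
    "EnrichmentResult",
    "QpcrRelQuant",
    "lin_ccc",
    "pearson",
    "rank_correlation",
    "log2_fold_change",
    "hypergeom_upper_tail",
    "bh_adjust",
    "rq_from_delta_ct",
    "abundance_bias_test",
    "least_squares_slope",
]


@dataclass
class ConcordanceReport:
    """Concordance of two fold-change estimates.

    ``ccc = pearson_r * c_b``: the Pearson correlation measures scatter
    around the best-fit line, C_b measures how far that line is from x = y
    (C_b = 1 means no deviation).
    """

    ccc: float
    c_b: float
    pearson_r: float
    n: int
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)


@dataclass
class EnrichmentResult:
    """Exact upper-tail hypergeometric test of overlap with a gene class."""

    population: int
    successes: int
    draws: int
    observed: int
    p_upper_tail: float


@dataclass
class QpcrRelQuant:
    delta_ct: float
    rq: float


def _check_pair(x, y, min_n: int = 3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise InvalidArgumentError("x and y must be 1-D vectors of equal length")
    if x.size < min_n:
        raise InvalidArgumentError(f"need at least {min_n} observations, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InvalidArgumentError("x and y must be finite")
    return x, y


def lin_ccc(x, y) -> ConcordanceReport:
    """Lin's concordance correlation coefficient with bias-correction factor.

    Uses population (1/n) second moments, so the decomposition
    ``ccc = pearson_r * C_b`` is exact:

        ccc = 2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)
        C_b = 2 / (v + 1/v + u^2),  v = s_x/s_y,  u = (mean_x - mean_y)/sqrt(s_x*s_y)
    """
    x, y = _check_pair(x, y)
    mx, my = x.mean(), y.mean()
    sx2 = np.mean((x - mx) ** 2)
    sy2 = np.mean((y - my) ** 2)
    if sx2 == 0.0 or sy2 == 0.0:
        raise UndefinedStatisticError("concordance undefined: zero variance in x or y")
    sxy = np.mean((x - mx) * (y - my))
    denom = sx2 + sy2 + (mx - my) ** 2
    ccc = 2.0 * sxy / denom
    sx, sy = np.sqrt(sx2), np.sqrt(sy2)
    r = sxy / (sx * sy)
    c_b = 2.0 * sx * sy / denom
    return ConcordanceReport(ccc=float(ccc), c_b=float(c_b), pearson_r=float(r),
                             n=int(x.size), x=x, y=y)


def pearson(x, y) -> float:
    x, y = _check_pair(x, y)
    if np.var(x) == 0.0 or np.var(y) == 0.0:
        raise UndefinedStatisticError("Pearson correlation undefined: zero variance")
    return float(sps.pearsonr(x, y).statistic)


def rank_correlation(x, y) -> float:
    """Spearman's rho with average ranks for ties."""
    x, y = _check_pair(x, y)
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise UndefinedStatisticError("rank correlation undefined: constant vector")
    return float(sps.spearmanr(x, y).statistic)


def least_squares_slope(x, y) -> float:
    """Ordinary least-squares slope of y on x (population moments)."""
    x, y = _check_pair(x, y)
    vx = np.var(x)
    if vx == 0.0:
        raise UndefinedStatisticError("slope undefined: zero variance in x")
    return float(np.mean((x - x.mean()) * (y - y.mean())) / vx)


def log2_fold_change(a, b, pseudocount: float = 0.0):
    """log2((a + c) / (b + c)); works elementwise on arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if pseudocount < 0:
        raise InvalidArgumentError("pseudocount must be >= 0")
    if (a < 0).any() or (b < 0).any():
        raise InvalidArgumentError("a and b must be non-negative")
    num = a + pseudocount
    den = b + pseudocount
    if (num <= 0).any() or (den <= 0).any():
        raise InvalidArgumentError(
            "both values zero with zero pseudocount: fold change undefined")
    out = np.log2(num) - np.log2(den)
    return out if out.ndim else float(out)


def hypergeom_upper_tail(N: int, K: int, n: int, x: int) -> EnrichmentResult:
    """Exact P(X >= x) for X ~ Hypergeom(N, K, n), summed in log space.

    Log-space summation keeps tails of order 1e-19 (the magnitudes that
    arise in OR-gene overlap tests) accurate.
    """
    N, K, n, x = int(N), int(K), int(n), int(x)
    if not (0 <= K <= N and 0 <= n <= N):
        raise InvalidArgumentError(f"inconsistent parameters N={N}, K={K}, n={n}")
    lo = max(0, n - (N - K))
    hi = min(K, n)
    if x > hi:
        raise InvalidArgumentError(f"observed x={x} exceeds max attainable {hi}")
    ks = np.arange(max(x, lo), hi + 1)
    if ks.size == 0:
        p = 1.0
    else:
        logp = sps.hypergeom.logpmf(ks, N, K, n)
        p = float(np.exp(logsumexp(logp)))
    p = min(p, 1.0)
    return EnrichmentResult(population=N, successes=K, draws=n, observed=x,
                            p_upper_tail=p)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidArgumentError("p must be a non-empty 1-D vector")
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rq_from_delta_ct(delta_ct: float) -> QpcrRelQuant:
    """qPCR relative quantity, RQ = 2**dCt."""
    if not np.isfinite(delta_ct):
        raise InvalidArgumentError("delta_ct must be finite")
    return QpcrRelQuant(delta_ct=float(delta_ct), rq=float(2.0 ** delta_ct))


def abundance_bias_test(abundance, picked, split: float = 0.5) -> EnrichmentResult:
    """Are picked genes enriched in the high-abundance class of the universe?

    The universe is dichotomized at the ``split`` quantile of ``abundance``
    (default the median); an exact upper-tail hypergeometric test is run on
    the number of picks falling strictly above the cut.
    """
    import pandas as pd

    abundance = pd.Series(abundance, dtype=float)
    missing = [g for g in picked if g not in abundance.index]
    if missing:
        raise InvalidArgumentError(f"picked gene absent from abundance vector: {missing[0]!r}")
    cut = float(np.quantile(abundance.to_numpy(), split))
    high = abundance > cut
    N = int(abundance.size)
    K = int(high.sum())
    n = len(picked)
    x = int(sum(bool(high[g]) for g in picked))
    return hypergeom_upper_tail(N, K, n, x)
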