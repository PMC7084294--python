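"""Shared statistical primitives.

Every stage of the pipeline funnels its inference through this module:
Pearson correlation with the exact two-sided t test (df = n - 2),
Benjamini-Hochberg step-up FDR adjustment, a one-sided hypergeometric
enrichment test for user-supplied gene sets, and the 2^-ddCt relative
quantification formula for qPCR follow-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Set, Tuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "pearson_r",
    "correlation_pvalue",
    "correlation_test",
    "bh_adjust",
    "fisher_enrichment",
    "ddct_relative_expression",
    "ConstantVectorError",
]


class ConstantVectorError(ValueError):
    """Raised when a correlation is requested for a zero-variance vector."""


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its exact two-sided test.

    ``t = r * sqrt((n - 2) / (1 - r^2))`` follows Student's t with ``n - 2``
    degrees of freedom under the null of zero correlation.
    """

    r: float
    n: int
    t_statistic: float
    p_value: float


def _as_float_vector(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length vectors.

    The result is clamped to [-1, 1] to absorb floating-point rounding on
    exactly collinear inputs. Constant vectors have no defined correlation
    and raise :class:`ConstantVectorError`.
    """
    xa = _as_float_vector(x, "x")
    ya = _as_float_vector(y, "y")
    if xa.size != ya.size:
        raise ValueError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.size < 3:
        raise ValueError("need at least 3 observations")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise ConstantVectorError("correlation undefined for a constant vector")
    r = float(xc @ yc) / (sx * sy)
    return max(-1.0, min(1.0, r))


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for an observed Pearson r at sample size n.

    Uses the exact null distribution: t = r*sqrt((n-2)/(1-r^2)) ~ t(n-2).
    |r| = 1 returns p = 0 (the t statistic diverges).
    """
    if n < 3:
        raise ValueError("correlation test requires n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"r must lie in [-1, 1], got {r}")
    if abs(r) == 1.0:
        return 0.0
    df = n - 2
    t = r * math.sqrt(df / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df))


def correlation_test(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Correlation plus its two-sided test, as one immutable record."""
    r = pearson_r(x, y)
    n = len(x)
    if abs(r) == 1.0:
        t = math.inf if r > 0 else -math.inf
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return CorrelationResult(r=r, n=n, t_statistic=t, p_value=correlation_pvalue(r, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Equivalent to sorting ascending, taking q_i = min_{j>=i} (m/j) p_(j)
    capped at 1, and undoing the sort.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrichment(
    target_genes: Set[str] | Iterable[str],
    gene_set: Set[str] | Iterable[str],
    universe: Set[str] | Iterable[str],
) -> Tuple[float, float]:
    """One-sided over-representation test of ``gene_set`` among ``target_genes``.

    Returns ``(odds_ratio, p_value)`` where p is the hypergeometric upper
    tail P(overlap >= observed) for drawing ``len(target_genes)`` genes from
    the universe, and the odds ratio comes from the 2x2 table with a
    Haldane correction of 0.5 added to every cell whenever any cell is zero.
    """
    targets = set(target_genes)
    gset = set(gene_set)
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    if not targets <= uni:
        raise ValueError("target_genes must be a subset of the universe")
    if not gset <= uni:
        raise ValueError("gene_set must be a subset of the universe")
    N = len(uni)
    K = len(gset)
    n = len(targets)
    k = len(targets & gset)
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    a = k
    b = n - k
    c = K - k
    d = N - K - n + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return float(odds), min(1.0, p)


def ddct_relative_expression(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_cal: float,
    ct_ref_cal: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target,test - Ct_ref,test) - (Ct_target,calibrator -
    Ct_ref,calibrator); one cycle difference doubles/halves the estimate.
    """
    for v in (ct_target_test, ct_ref_test, ct_target_cal, ct_ref_cal):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_test - ct_ref_test) - (ct_target_cal - ct_ref_cal)
    return float(2.0 ** (-ddct))
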