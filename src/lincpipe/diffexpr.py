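"""Two-group differential expression on count matrices.

The call criterion is |log2FC| > 1 together with a Benjamini-Hochberg
adjusted p < 0.05. The engine is deliberately transparent: library-size
size factors, a pseudocount-stabilised log2 fold change on normalized group
means, and a two-sided Welch (unequal-variance) test on log2(normalized+1)
per feature. It is not a negative-binomial GLM; the decision rule and its
downstream consumers are the point, and a stricter engine can replace this
one function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import ExpressionMatrix, PipelineConfig, ValidationError
from .stats import bh_adjust

__all__ = ["DEResult", "test_differential_expression", "de_results_frame"]


@dataclass(frozen=True)
class DEResult:
    feature_id: str
    base_mean_a: float
    base_mean_b: float
    log2fc: float
    p_value: float
    padj: float
    is_de: bool
    direction: str  # "up" | "down" | "none"


def _welch_log_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorised two-sided Welch p-values on rows of a and b.

    Degenerate rows (both groups exactly constant) have a 0/0 statistic;
    the limit is defined as p = 1 for equal means and p = 0 otherwise,
    which keeps constructed exact-count examples deterministic.
    """
    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        # near-constant rows trip scipy's precision-loss warning; those rows
        # are overridden by the explicit degenerate limit below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # exactly-constant groups detected via the range: immune to the 1-ulp
    # variance left by mean rounding
    degenerate = (np.ptp(a, axis=1) == 0) & (np.ptp(b, axis=1) == 0)
    if np.any(degenerate):
        equal_means = a[:, 0] == b[:, 0]
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = 0.0
    return p


def test_differential_expression(
    counts: ExpressionMatrix,
    contrast: Tuple[str, str],
    config: Optional[PipelineConfig] = None,
) -> List[DEResult]:
    """Test every feature for differential expression between two groups.

    log2fc is oriented group A over group B: log2((mean_A+1)/(mean_B+1)) on
    size-factor-normalized means. Features with zero counts in every sample
    are excluded from testing and from the BH family entirely (their
    results carry NaN statistics and is_de False).
    """
    config = config or PipelineConfig()
    if counts.kind != "counts":
        raise ValidationError("differential expression requires a counts matrix")
    group_a, group_b = contrast
    samples_a = counts.group_samples(group_a)
    samples_b = counts.group_samples(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValidationError("each group needs >= 2 samples (variance undefined)")

    mat = counts.values.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if np.any(lib <= 0):
        bad = counts.sample_ids[int(np.argmax(lib <= 0))]
        raise ValidationError(f"zero library size for sample {bad!r}")
    size_factors = lib / np.median(lib)
    norm = mat / size_factors[None, :]

    cols = counts.sample_ids
    idx_a = [cols.index(s) for s in samples_a]
    idx_b = [cols.index(s) for s in samples_b]

    tested = mat.sum(axis=1) > 0
    mean_a = norm[:, idx_a].mean(axis=1)
    mean_b = norm[:, idx_b].mean(axis=1)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))

    log_norm = np.log2(norm + 1.0)
    p = np.full(mat.shape[0], np.nan)
    if np.any(tested):
        p[tested] = _welch_log_counts(
            log_norm[np.ix_(tested, idx_a)], log_norm[np.ix_(tested, idx_b)]
        )
    padj = np.full(mat.shape[0], np.nan)
    if np.any(tested):
        padj[tested] = bh_adjust(p[tested])

    results: List[DEResult] = []
    for i, fid in enumerate(counts.feature_ids):
        if not tested[i]:
            results.append(
                DEResult(fid, float(mean_a[i]), float(mean_b[i]), float(log2fc[i]),
                         float("nan"), float("nan"), False, "none")
            )
            continue
        is_de = bool(
            abs(log2fc[i]) > config.de_abs_log2fc_min and padj[i] < config.de_padj_max
        )
        direction = "none" if not is_de else ("up" if log2fc[i] > 0 else "down")
        results.append(
            DEResult(fid, float(mean_a[i]), float(mean_b[i]), float(log2fc[i]),
                     float(p[i]), float(padj[i]), is_de, direction)
        )
    return results


def de_results_frame(results: List[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "base_mean_a": [r.base_mean_a for r in results],
            "base_mean_b": [r.base_mean_b for r in results],
            "log2fc": [r.log2fc for r in results],
            "p_value": [r.p_value for r in results],
            "padj": [r.padj for r in results],
            "is_de": [r.is_de for r in results],
            "direction": [r.direction for r in results],
        }
    )
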