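"""Gene-level expression calls and WT-vs-TG differential expression.

A gene's expression value per condition is the arithmetic mean over its
probesets (a gene can be represented by several probesets on the expression
array); it is called expressed when that mean exceeds 100 (strictly).
Differential expression uses a Welch (unequal-variance) two-sided t-test on
per-sample gene values with an inclusive fold-change gate: up- or
down-regulated when fold >= 1.5 and p <= 0.05.
"""

from __future__ import annotations

from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import io as acio
from .models import Condition, DEStatus, FormatError


def gene_expression_value(probeset_values: Sequence[float]) -> float:
    """Arithmetic mean over a gene's probeset values."""
    values = np.asarray(list(probeset_values), dtype=float)
    if values.size == 0:
        raise FormatError("gene has no probeset values")
    return float(values.mean())


def call_expressed(mean_expression: float, threshold: float = 100.0) -> bool:
    """Expressed iff the mean exceeds the threshold (strict 'greater than')."""
    if threshold <= 0:
        raise FormatError("expression threshold must be > 0")
    return mean_expression > threshold


def welch_test(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided Welch t-test p-value; 1.0 for degenerate zero-variance ties."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise FormatError("Welch test needs at least 2 samples per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def differential_expression(values_wt: Sequence[float],
                            values_tg: Sequence[float],
                            fc_threshold: float = 1.5,
                            p_threshold: float = 0.05
                            ) -> Tuple[float, float, DEStatus]:
    """Fold change, Welch p, and direction call for one gene.

    Fold change is reported as the larger of mean(TG)/mean(WT) and its
    reciprocal; both gates are boundary-inclusive. Returns (fold_change, p,
    status).
    """
    wt = np.asarray(list(values_wt), dtype=float)
    tg = np.asarray(list(values_tg), dtype=float)
    mean_wt, mean_tg = wt.mean(), tg.mean()
    if mean_wt <= 0 or mean_tg <= 0:
        raise FormatError("group means must be positive for a fold change")
    ratio = mean_tg / mean_wt
    fold = max(ratio, 1.0 / ratio)
    p = welch_test(wt, tg)
    status = DEStatus.UNCHANGED
    if fold >= fc_threshold and p <= p_threshold:
        status = DEStatus.UP if ratio > 1 else DEStatus.DOWN
    return float(fold), p, status


def gene_sample_matrix(expression: pd.DataFrame, condition: Condition
                       ) -> pd.DataFrame:
    """Per-gene, per-sample values: probeset rows averaged within each gene."""
    cols = acio.expression_sample_columns(expression, condition)
    if not cols:
        raise FormatError(f"no sample columns for condition {condition.value}")
    return expression.groupby("gene_id")[cols].mean()


def expression_calls(expression: pd.DataFrame,
                     threshold: float = 100.0) -> pd.DataFrame:
    """Per-gene mean expression and expressed flag for both conditions.

    The gene mean averages over probesets and samples; columns
    mean_expression_wt/tg and expressed_wt/tg.
    """
    out = None
    for condition in (Condition.WT, Condition.TG):
        mat = gene_sample_matrix(expression, condition)
        cond = condition.value.lower()
        mean = mat.mean(axis=1)
        part = pd.DataFrame({
            f"mean_expression_{cond}": mean,
            f"expressed_{cond}": mean > threshold,
        })
        out = part if out is None else out.join(part)
    return out.reset_index()


def differential_expression_table(expression: pd.DataFrame,
                                  fc_threshold: float = 1.5,
                                  p_threshold: float = 0.05) -> pd.DataFrame:
    """Vectorized Welch DE over all genes; columns fold_change, de_pvalue,
    de_status."""
    wt = gene_sample_matrix(expression, Condition.WT)
    tg = gene_sample_matrix(expression, Condition.TG).reindex(wt.index)
    a, b = wt.to_numpy(), tg.to_numpy()
    mean_wt, mean_tg = a.mean(axis=1), b.mean(axis=1)
    ratio = mean_tg / mean_wt
    fold = np.maximum(ratio, 1.0 / ratio)

    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    p[degenerate & (mean_wt == mean_tg)] = 1.0
    p[degenerate & (mean_wt != mean_tg)] = 0.0

    passes = (fold >= fc_threshold) & (p <= p_threshold)
    status = np.where(passes & (ratio > 1), DEStatus.UP.value,
                      np.where(passes & (ratio < 1), DEStatus.DOWN.value,
                               DEStatus.UNCHANGED.value))
    return pd.DataFrame({
        "gene_id": wt.index,
        "fold_change": fold,
        "de_pvalue": p,
        "de_status": status,
    }).reset_index(drop=True)
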