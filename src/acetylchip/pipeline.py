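"""End-to-end orchestration: probes + expression in, all summaries out."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Set

import pandas as pd

from . import binding, diffacet, expression as expr_mod, integrate
from .models import Condition, ContingencyResult, RunConfig


@dataclass
class AnalysisResult:
    """Everything the pipeline computes from one probe + expression dataset."""

    config: RunConfig
    bound_probes: Dict[str, Set[str]]
    profiles: Dict[str, pd.DataFrame]
    scores: pd.DataFrame
    expression_calls: pd.DataFrame
    de: pd.DataFrame
    common_genes: list
    contingency: Dict[str, ContingencyResult]
    signature_by_expression: Dict[str, pd.DataFrame]
    de_by_diffacet: pd.DataFrame


def analyze(probes: pd.DataFrame, expression: pd.DataFrame,
            annotation: Optional[pd.DataFrame] = None,
            config: Optional[RunConfig] = None) -> AnalysisResult:
    """Run bound-calling, scoring, expression calls, and integration."""
    config = config or RunConfig()
    bound: Dict[str, Set[str]] = {}
    profiles: Dict[str, pd.DataFrame] = {}
    for condition in (Condition.WT, Condition.TG):
        ids = binding.call_bound_probes(probes, condition, config.p_threshold)
        bound[condition.value] = ids
        profiles[condition.value] = binding.call_bound_genes(
            probes, ids, condition, annotation)

    scores = diffacet.score_table(profiles["WT"], profiles["TG"])
    calls = expr_mod.expression_calls(expression, config.expression_threshold)
    de = expr_mod.differential_expression_table(
        expression, config.fold_threshold, config.de_p_threshold)

    common = integrate.common_gene_set(profiles["WT"]["gene_id"],
                                       calls["gene_id"])
    contingency: Dict[str, ContingencyResult] = {}
    sig_expr: Dict[str, pd.DataFrame] = {}
    for condition in (Condition.WT, Condition.TG):
        table = integrate.bound_by_expressed_table(
            profiles[condition.value], calls, condition, common)
        contingency[condition.value] = integrate.odds_ratio_ci(
            table, config.ci_level)
        sig_expr[condition.value] = integrate.signature_by_expression(
            profiles[condition.value], calls, condition, common)
    de_cat = integrate.de_by_diffacet(de, scores)

    return AnalysisResult(
        config=config, bound_probes=bound, profiles=profiles, scores=scores,
        expression_calls=calls, de=de, common_genes=common,
        contingency=contingency, signature_by_expression=sig_expr,
        de_by_diffacet=de_cat)
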