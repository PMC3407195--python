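"""Bound-probe and bound-gene calling plus descriptive binding statistics.

Decision rules: a probe is bound when its binding p-value is at or below the
threshold (default 0.005, boundary inclusive); a gene is bound when at least
one of its probes is bound. The per-gene binding signature is the set of
probe-location types among its bound probes, and the bound signal sum is the
sum over bound probes of the replicate-mean log2(IP/WCE) ratio — the
per-condition half of the composite differential-acetylation score.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, Iterable, Optional, Set, Tuple

import numpy as np
import pandas as pd

from . import io as acio
from .models import Condition, FormatError, ProbeType, signature_label

logger = logging.getLogger(__name__)

PROFILE_COLUMNS = ["gene_id", "n_bound", "bound_signal_sum", "signature",
                   "bound_probe_ids"]


def call_bound_probes(probes: pd.DataFrame, condition: Condition,
                      threshold: float = 0.005) -> Set[str]:
    """Probe ids bound in a condition: p-value <= threshold (inclusive).

    Probes with a missing p-value are excluded (treated as unbound) with a
    logged count.
    """
    if not 0 < threshold < 1:
        raise FormatError(f"p-value threshold must lie in (0, 1), got {threshold}")
    pv = probes[acio.pvalue_column(condition)]
    missing = pv.isna()
    if missing.any():
        logger.warning("%d probe(s) without a %s p-value treated as unbound",
                       int(missing.sum()), condition.value)
    mask = pv.notna() & (pv <= threshold)
    return set(probes.loc[mask, "probe_id"])


def call_bound_genes(probes: pd.DataFrame, bound_probe_ids: Set[str],
                     condition: Condition,
                     annotation: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Per-gene binding profiles for one condition.

    Returns one row per annotated gene (or per gene present in the probe
    table when no annotation is given) with columns gene_id, n_bound,
    bound_signal_sum, signature (canonical label), bound_probe_ids
    (comma-joined, sorted). Probes referencing a gene absent from the
    annotation are ignored for gene-level statistics with a logged warning.
    """
    probes = probes[probes["gene_id"].notna()]
    if annotation is not None:
        universe = list(annotation["gene_id"])
        known = set(universe)
        orphan = ~probes["gene_id"].isin(known)
        if orphan.any():
            logger.warning("%d probe(s) reference gene_ids absent from the "
                           "annotation; ignored for gene-level statistics",
                           int(orphan.sum()))
            probes = probes[~orphan]
    else:
        universe = list(pd.unique(probes["gene_id"]))

    sig_cols = acio.signal_columns(probes, condition)
    bound = probes[probes["probe_id"].isin(bound_probe_ids)].copy()
    bound["_mean_signal"] = bound[sig_cols].mean(axis=1)

    agg: Dict[str, tuple] = {}
    for gene, grp in bound.groupby("gene_id"):
        ids = sorted(grp["probe_id"])
        types = frozenset(ProbeType(t) for t in grp["probe_type"])
        agg[gene] = (len(ids), float(grp["_mean_signal"].sum()),
                     signature_label(types), ",".join(ids))

    rows = [(g, *agg.get(g, (0, 0.0, signature_label(frozenset()), "")))
            for g in universe]
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def probes_per_gene_distribution(profiles: pd.DataFrame
                                 ) -> Tuple[Dict[int, int], int]:
    """Histogram of bound probes per bound gene (n_bound >= 1) and its max."""
    bound = profiles[profiles["n_bound"] >= 1]
    if bound.empty:
        return {}, 0
    counts = bound["n_bound"].value_counts().sort_index()
    hist = {int(k): int(v) for k, v in counts.items()}
    return hist, int(max(hist))


def chromosome_binding_table(profiles: pd.DataFrame, annotation: pd.DataFrame,
                             profiles_other: Optional[pd.DataFrame] = None
                             ) -> pd.DataFrame:
    """Per-chromosome gene totals, bound counts, and percent bound.

    With a second condition's profiles, adds that condition's columns and the
    ratio of its percent bound to the first's (TG/WT when called that way).
    Chromosomes with zero genes are excluded with a warning.
    """
    ann = annotation[["gene_id", "chromosome"]]
    merged = profiles.merge(ann, on="gene_id", how="inner")
    empty = set(annotation["chromosome"].unique()) - set(merged["chromosome"])
    if empty:
        logger.warning("chromosome(s) with no profiled genes excluded: %s",
                       ", ".join(sorted(empty)))
    grp = merged.groupby("chromosome")
    out = pd.DataFrame({
        "n_genes": grp.size(),
        "n_bound": grp.apply(lambda g: int((g["n_bound"] >= 1).sum()),
                             include_groups=False),
    })
    out["percent_bound"] = 100.0 * out["n_bound"] / out["n_genes"]
    if profiles_other is not None:
        other = chromosome_binding_table(profiles_other, annotation)
        other = other.set_index("chromosome")
        out = out.join(other[["n_bound", "percent_bound"]],
                       rsuffix="_other")
        out["ratio"] = out["percent_bound_other"] / out["percent_bound"]
    out = out.reset_index()
    out["_key"] = out["chromosome"].map(acio.chromosome_sort_key)
    return out.sort_values("_key").drop(columns="_key").reset_index(drop=True)


def probe_type_occupancy(probes: pd.DataFrame,
                         bound_probe_ids: Set[str]) -> pd.DataFrame:
    """Percent of probes bound, per probe type; types absent from the array
    are omitted."""
    df = probes.assign(_bound=probes["probe_id"].isin(bound_probe_ids))
    rows = []
    for ptype in (t.value for t in ProbeType):
        sub = df[df["probe_type"] == ptype]
        if sub.empty:
            continue
        n_total = len(sub)
        n_bound = int(sub["_bound"].sum())
        rows.append((ptype, n_total, n_bound, 100.0 * n_bound / n_total))
    return pd.DataFrame(rows, columns=["probe_type", "n_total", "n_bound",
                                       "percent_bound"])


def signature_census(profiles: pd.DataFrame) -> pd.DataFrame:
    """Counts of bound genes per binding-signature label."""
    bound = profiles[profiles["n_bound"] >= 1]
    counts = bound["signature"].value_counts()
    out = counts.rename_axis("signature").reset_index(name="n_genes")
    return out.sort_values(["n_genes", "signature"],
                           ascending=[False, True]).reset_index(drop=True)


def qpcr_enrichment(ct_ip: float, ct_input: float, *,
                    percent_input: bool = False) -> float:
    """Single-gene ChIP-qPCR enrichment.

    Default: log2(Ct_IP / Ct_input), the ratio-of-cycle-thresholds form.
    With ``percent_input=True``, the conventional 2^(Ct_input - Ct_IP)
    delta-Ct form instead.
    """
    if ct_ip <= 0 or ct_input <= 0:
        raise ValueError("cycle thresholds must be positive")
    if percent_input:
        return float(2.0 ** (ct_input - ct_ip))
    return float(math.log2(ct_ip / ct_input))


def percent_ratio(numerator: float, denominator: float) -> float:
    """100 * numerator / denominator — e.g. TG bound counts as percent of WT."""
    if denominator == 0:
        raise ZeroDivisionError("denominator must be nonzero")
    return 100.0 * numerator / denominator
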