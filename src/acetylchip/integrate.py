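"""Integration of binding and expression calls over the common gene set.

Builds the 2x2 bound-by-expressed contingency table per genotype, computes
the odds ratio with a Wald confidence interval on the log odds ratio and a
two-sided Fisher exact p-value, and cross-tabulates binding signatures and
differential-acetylation categories against expression status.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, Iterable, Optional, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .models import (Category, Condition, ContingencyResult,
                     DECREASED_CATEGORIES, DEStatus, FormatError)

logger = logging.getLogger(__name__)

#: Display floor for exact p-values in reports, mirroring common practice.
P_DISPLAY_FLOOR = 2.2e-16


def common_gene_set(binding_genes: Iterable[str],
                    expression_genes: Iterable[str]) -> list:
    """Sorted intersection of the two platforms' gene lists."""
    binding_genes, expression_genes = set(binding_genes), set(expression_genes)
    if not binding_genes or not expression_genes:
        raise FormatError("both gene sets must be nonempty")
    common = binding_genes & expression_genes
    if not common:
        raise FormatError("binding and expression gene sets do not intersect")
    return sorted(common)


def bound_by_expressed_table(profiles: pd.DataFrame, calls: pd.DataFrame,
                             condition: Condition,
                             genes: Optional[Iterable[str]] = None
                             ) -> ContingencyResult:
    """Count genes into the bound-by-expressed 2x2 table (counts only).

    ``profiles`` is the condition's gene binding profile table; ``calls`` the
    expression-call table with an ``expressed_<cond>`` column. Every gene of
    the common set must carry both calls.
    """
    cond = condition.value.lower()
    prof = profiles.set_index("gene_id")
    expr = calls.set_index("gene_id")
    if genes is None:
        genes = common_gene_set(prof.index, expr.index)
    genes = list(genes)
    missing = [g for g in genes if g not in prof.index or g not in expr.index]
    if missing:
        raise FormatError(
            f"gene(s) missing a binding or expression call: "
            f"{', '.join(missing[:10])}" + ("..." if len(missing) > 10 else ""))
    bound = (prof.loc[genes, "n_bound"] >= 1).to_numpy()
    expressed = expr.loc[genes, f"expressed_{cond}"].to_numpy().astype(bool)
    return ContingencyResult(
        a=int((bound & expressed).sum()),
        b=int((bound & ~expressed).sum()),
        c=int((~bound & expressed).sum()),
        d=int((~bound & ~expressed).sum()),
    )


def odds_ratio_ci(table: ContingencyResult, ci_level: float = 0.99,
                  exact: str = "fisher") -> ContingencyResult:
    """Complete a contingency table with OR, Wald CI, and exact p.

    OR = ad/bc; the CI is Wald on the log odds ratio,
    exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)). When any cell is zero
    the Haldane +0.5 correction is applied to every cell for the OR and CI
    (flagged, never silent); the exact p is computed on the uncorrected
    counts. ``exact`` may be "fisher" (default, two-sided) or "chi2".
    """
    if not 0 < ci_level < 1:
        raise FormatError("ci_level must lie in (0, 1)")
    a, b, c, d = table.a, table.b, table.c, table.d
    haldane = min(a, b, c, d) == 0
    if haldane:
        logger.warning("zero cell in 2x2 table; Haldane +0.5 correction "
                       "applied for OR/CI")
        aa, bb, cc, dd = (a + 0.5, b + 0.5, c + 0.5, d + 0.5)
    else:
        aa, bb, cc, dd = a, b, c, d
    orr = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    ci_low = math.exp(math.log(orr) - z * se)
    ci_high = math.exp(math.log(orr) + z * se)
    if exact == "fisher":
        p = float(stats.fisher_exact([[a, b], [c, d]],
                                     alternative="two-sided")[1])
    elif exact == "chi2":
        p = float(stats.chi2_contingency([[a, b], [c, d]],
                                         correction=False)[1])
    else:
        raise FormatError(f"unknown exact test {exact!r}")
    return ContingencyResult(a=a, b=b, c=c, d=d, odds_ratio=float(orr),
                             ci_level=ci_level, ci_low=float(ci_low),
                             ci_high=float(ci_high), p_exact=p,
                             haldane=haldane)


def fraction_bound_expressed(table: ContingencyResult) -> float:
    """Percent of bound genes that are expressed: 100*a/(a+b), raw value."""
    if table.a + table.b == 0:
        raise FormatError("no bound genes: fraction undefined")
    return 100.0 * table.a / (table.a + table.b)


def signature_by_expression(profiles: pd.DataFrame, calls: pd.DataFrame,
                            condition: Condition,
                            genes: Optional[Iterable[str]] = None
                            ) -> pd.DataFrame:
    """Cross-tab of binding-signature label by expression status (bound genes)."""
    cond = condition.value.lower()
    prof = profiles.set_index("gene_id")
    expr = calls.set_index("gene_id")
    if genes is None:
        genes = common_gene_set(prof.index, expr.index)
    genes = list(genes)
    prof = prof.loc[genes]
    bound = prof[prof["n_bound"] >= 1]
    expressed = expr.loc[bound.index, f"expressed_{cond}"].astype(bool)
    tab = pd.crosstab(bound["signature"], expressed)
    tab.columns = ["not_expressed" if not c else "expressed" for c in tab.columns]
    for col in ("expressed", "not_expressed"):
        if col not in tab.columns:
            tab[col] = 0
    tab = tab[["expressed", "not_expressed"]]
    return tab.rename_axis("signature").reset_index()


def de_by_diffacet(de_records: pd.DataFrame, scores: pd.DataFrame
                   ) -> pd.DataFrame:
    """For each DE direction, counts per differential-acetylation category.

    Returns one row per (de_status in {UP, DOWN}, category) with counts,
    percentages within the direction, and the convenience aggregate
    "decreased acetylation" share (hypoacetylated + not acetylated in TG) in
    ``frame.attrs['decreased_share']``.
    """
    merged = de_records.merge(scores[["gene_id", "category"]], on="gene_id",
                              how="inner")
    rows = []
    decreased_share: Dict[str, float] = {}
    dec_labels = {c.value for c in DECREASED_CATEGORIES}
    for direction in (DEStatus.UP, DEStatus.DOWN):
        sub = merged[merged["de_status"] == direction.value]
        total = len(sub)
        if total == 0:
            logger.warning("no %s-regulated genes", direction.value)
        counts = sub["category"].value_counts()
        for cat in Category:
            n = int(counts.get(cat.value, 0))
            pct = 100.0 * n / total if total else 0.0
            rows.append((direction.value, cat.value, n, pct))
        n_dec = int(counts.reindex(list(dec_labels)).fillna(0).sum())
        decreased_share[direction.value] = 100.0 * n_dec / total if total else 0.0
    out = pd.DataFrame(rows, columns=["de_status", "category", "n_genes",
                                      "percent_of_direction"])
    out.attrs["decreased_share"] = decreased_share
    return out


def format_p(p: float) -> str:
    """Report-display form of an exact p-value, floored at 2.2e-16."""
    if p < P_DISPLAY_FLOOR:
        return f"<{P_DISPLAY_FLOOR:g}"
    return f"{p:.3g}"


def contingency_frame(results: Dict[str, ContingencyResult]) -> pd.DataFrame:
    rows = []
    for name, r in results.items():
        rows.append((name, r.a, r.b, r.c, r.d, r.odds_ratio, r.ci_level,
                     r.ci_low, r.ci_high, r.p_exact, r.haldane))
    return pd.DataFrame(rows, columns=["condition", "a", "b", "c", "d",
                                       "odds_ratio", "ci_level", "ci_low",
                                       "ci_high", "p_exact", "haldane"])


def _md_table(df: pd.DataFrame, floatfmt: str = "{:.2f}") -> str:
    def fmt(v):
        if isinstance(v, float):
            return floatfmt.format(v)
        return str(v)
    header = "| " + " | ".join(df.columns) + " |"
    sep = "|" + "|".join("---" for _ in df.columns) + "|"
    body = "\n".join("| " + " | ".join(fmt(v) for v in row) + " |"
                     for row in df.itertuples(index=False))
    return "\n".join([header, sep, body])


def render_report(pieces: Dict[str, object]) -> str:
    """Assemble the pipeline's human-readable Markdown report.

    ``pieces`` holds the outputs of the earlier stages keyed by section name;
    missing pieces simply omit their section.
    """
    lines = ["# AcH3 ChIP-chip analysis report", ""]
    meta = pieces.get("meta")
    if meta:
        lines += ["## Run configuration", ""]
        lines += [f"- {k} = {v}" for k, v in meta.items()]
        lines.append("")

    summary = pieces.get("binding_summary")
    if summary is not None:
        lines += ["## Binding summary", "", _md_table(summary), ""]

    hist = pieces.get("probes_per_gene")
    if hist is not None:
        lines += ["## Bound probes per gene", "", _md_table(hist), ""]

    chrom = pieces.get("chromosome_table")
    if chrom is not None:
        lines += ["## Per-chromosome binding", "", _md_table(chrom), ""]

    occ = pieces.get("probe_type_occupancy")
    if occ is not None:
        lines += ["## Probe-type occupancy", "", _md_table(occ), ""]

    sig = pieces.get("signature_census")
    if sig is not None:
        lines += ["## Binding signatures", "", _md_table(sig), ""]

    cat = pieces.get("category_census")
    if cat is not None:
        lines += ["## Differential acetylation categories", "",
                  _md_table(cat), ""]

    ranked = pieces.get("ranked_decreased")
    if ranked is not None:
        lines += ["## Top genes with decreased acetylation in TG", "",
                  _md_table(ranked), ""]
    ranked = pieces.get("ranked_increased")
    if ranked is not None:
        lines += ["## Top genes with increased acetylation in TG", "",
                  _md_table(ranked), ""]

    cont = pieces.get("contingency")
    if cont is not None:
        lines += ["## Binding-by-expression association", ""]
        for name, r in cont.items():
            frac = fraction_bound_expressed(r) if r.a + r.b else float("nan")
            lines += [
                f"### {name}",
                "",
                f"- table (a, b, c, d) = ({r.a}, {r.b}, {r.c}, {r.d})",
                f"- odds ratio = {r.odds_ratio:.1f}, "
                f"{100 * r.ci_level:.0f}% CI = "
                f"({r.ci_low:.1f}, {r.ci_high:.1f}), p {format_p(r.p_exact)}"
                + (" [Haldane-corrected]" if r.haldane else ""),
                f"- {frac:.0f}% of AcH3-bound genes are expressed "
                f"({frac:.2f}% raw)",
                "",
            ]

    sig_expr = pieces.get("signature_by_expression")
    if sig_expr is not None:
        for name, tab in sig_expr.items():
            lines += [f"## Signature by expression ({name})", "",
                      _md_table(tab), ""]

    de_tab = pieces.get("de_by_diffacet")
    if de_tab is not None:
        lines += ["## Differential expression by differential acetylation",
                  "", _md_table(de_tab), ""]
        shares = de_tab.attrs.get("decreased_share")
        if shares:
            for direction, share in shares.items():
                lines.append(f"- decreased-acetylation share of "
                             f"{direction}-regulated genes: {share:.0f}%")
            lines.append("")
    return "\n".join(lines)
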