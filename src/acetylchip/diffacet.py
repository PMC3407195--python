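"""Composite differential-acetylation scoring, categorization, and ranking.

The composite score of a gene is the summed bound-probe signal in TG minus
that in WT, so negative scores mean less acetylation in the transgenic
striatum. Genes fall into six categories: the four differential states
(not acetylated in TG, hypoacetylated, hyperacetylated, ectopically
acetylated in TG), unbound in both genotypes, or bound in both with no
score difference.
"""

from __future__ import annotations

import logging
from typing import Iterable, Tuple

import pandas as pd

from .models import (Category, DIFFERENTIAL_CATEGORIES, FormatError,
                     GeneBindingProfile)

logger = logging.getLogger(__name__)

SCORE_COLUMNS = ["gene_id", "n_wt_bound", "n_tg_bound", "score", "category"]


def composite_score(profile_wt: GeneBindingProfile,
                    profile_tg: GeneBindingProfile) -> float:
    """bound_signal_sum(TG) - bound_signal_sum(WT) for one gene."""
    if profile_wt.gene_id != profile_tg.gene_id:
        raise FormatError(
            f"profiles refer to different genes: {profile_wt.gene_id!r} vs "
            f"{profile_tg.gene_id!r}")
    return profile_tg.bound_signal_sum - profile_wt.bound_signal_sum


def classify_differential_acetylation(bound_wt: bool, bound_tg: bool,
                                      score: float,
                                      epsilon: float = 0.0) -> Category:
    """Assign the differential-acetylation category from binding states and
    score sign. ``epsilon`` widens the UNCHANGED band around zero (default 0:
    strict sign rule)."""
    if epsilon < 0:
        raise FormatError("epsilon must be >= 0")
    if bound_wt and not bound_tg:
        return Category.NOT_ACETYLATED_IN_TG
    if bound_tg and not bound_wt:
        return Category.ECTOPICALLY_ACETYLATED_IN_TG
    if not bound_wt and not bound_tg:
        return Category.NOT_ACETYLATED
    if score < -epsilon:
        return Category.HYPOACETYLATED_IN_TG
    if score > epsilon:
        return Category.HYPERACETYLATED_IN_TG
    return Category.UNCHANGED


def score_table(profiles_wt: pd.DataFrame, profiles_tg: pd.DataFrame,
                epsilon: float = 0.0) -> pd.DataFrame:
    """Composite scores and categories for every gene in both profile tables.

    Input frames are per-condition gene binding profiles (columns gene_id,
    n_bound, bound_signal_sum); they must cover the same gene set.
    """
    wt = profiles_wt.set_index("gene_id")
    tg = profiles_tg.set_index("gene_id")
    if set(wt.index) != set(tg.index):
        raise FormatError("WT and TG profiles cover different gene sets")
    tg = tg.reindex(wt.index)
    score = tg["bound_signal_sum"] - wt["bound_signal_sum"]
    # genes unbound on both sides score exactly 0 (empty sums)
    score = score.where((wt["n_bound"] > 0) | (tg["n_bound"] > 0), 0.0)
    out = pd.DataFrame({
        "gene_id": wt.index,
        "n_wt_bound": wt["n_bound"].to_numpy(),
        "n_tg_bound": tg["n_bound"].to_numpy(),
        "score": score.to_numpy(),
    })
    out["category"] = [
        classify_differential_acetylation(nw > 0, nt > 0, s, epsilon).value
        for nw, nt, s in zip(out["n_wt_bound"], out["n_tg_bound"], out["score"])]
    return out


def rank_genes(records: pd.DataFrame, direction: str, k: int) -> pd.DataFrame:
    """Top-k genes by composite score.

    ``direction='decreased'`` ranks ascending (most negative score first),
    ``'increased'`` descending. Ties break by larger |n_wt_bound -
    n_tg_bound| first, then lexicographic gene_id, for determinism.
    """
    if direction not in ("decreased", "increased"):
        raise FormatError("direction must be 'decreased' or 'increased'")
    if k > len(records):
        logger.warning("requested top %d of %d genes; returning all",
                       k, len(records))
        k = len(records)
    df = records.assign(
        _gap=(records["n_wt_bound"] - records["n_tg_bound"]).abs())
    ascending = direction == "decreased"
    df = df.sort_values(["score", "_gap", "gene_id"],
                        ascending=[ascending, False, True], kind="mergesort")
    out = df.drop(columns="_gap").head(k).reset_index(drop=True)
    out.insert(0, "rank", range(1, len(out) + 1))
    return out


def category_census(records: pd.DataFrame) -> pd.DataFrame:
    """Counts per category plus each differential category's share of all
    differentially acetylated genes.

    Fractions are over the four differential categories only; when no gene is
    differential they are reported as 0 with ``degenerate=True``.
    """
    counts = records["category"].value_counts()
    diff_labels = [c.value for c in DIFFERENTIAL_CATEGORIES]
    n_diff = int(counts.reindex(diff_labels).fillna(0).sum())
    rows = []
    for cat in Category:
        n = int(counts.get(cat.value, 0))
        if cat in DIFFERENTIAL_CATEGORIES:
            frac = 100.0 * n / n_diff if n_diff else 0.0
        else:
            frac = float("nan")
        rows.append((cat.value, n, frac))
    out = pd.DataFrame(rows, columns=["category", "n_genes",
                                      "percent_of_differential"])
    out.attrs["n_differential"] = n_diff
    out.attrs["degenerate"] = n_diff == 0
    return out
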