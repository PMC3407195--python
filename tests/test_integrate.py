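import itertools

import numpy as np
import pandas as pd
import pytest

import acetylchip as ac
from acetylchip.integrate import format_p
from acetylchip.models import (Category, Condition, ContingencyResult,
                               DEStatus, FormatError)
from oracles import fisher_two_sided


def test_common_gene_set_intersection():
    assert ac.common_gene_set({"A", "B", "C"}, {"B", "C", "D"}) == ["B", "C"]
    assert ac.common_gene_set({"A"}, {"A"}) == ["A"]


def test_common_gene_set_errors():
    with pytest.raises(FormatError):
        ac.common_gene_set(set(), {"A"})
    with pytest.raises(FormatError):
        ac.common_gene_set({"A"}, {"B"})


def _calls(genes, expressed):
    return pd.DataFrame({
        "gene_id": genes,
        "expressed_wt": expressed,
        "expressed_tg": expressed,
    })


def _profiles(genes, n_bound):
    return pd.DataFrame({
        "gene_id": genes, "n_bound": n_bound,
        "bound_signal_sum": [1.0 * n for n in n_bound],
        "signature": ["Inside Only" if n else "None" for n in n_bound],
    })


def test_contingency_cells_one_each():
    genes = list("abcd")
    prof = _profiles(genes, [1, 1, 0, 0])
    calls = _calls(genes, [True, False, True, False])
    t = ac.bound_by_expressed_table(prof, calls, Condition.WT)
    assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)
    assert t.n == 4


def test_contingency_all_bound_expressed():
    genes = list("abc")
    t = ac.bound_by_expressed_table(_profiles(genes, [1, 2, 3]),
                                    _calls(genes, [True] * 3), Condition.WT)
    assert (t.a, t.b, t.c, t.d) == (3, 0, 0, 0)


def test_contingency_missing_call_listed():
    prof = _profiles(list("ab"), [1, 0])
    calls = _calls(["a"], [True])
    with pytest.raises(FormatError, match="b"):
        ac.bound_by_expressed_table(prof, calls, Condition.WT, genes=["a", "b"])


def test_contingency_matches_hand_enumeration(result):
    """Counts over a 20-gene subset equal a plain loop."""
    genes = result.common_genes[:20]
    prof = result.profiles["WT"].set_index("gene_id")
    calls = result.expression_calls.set_index("gene_id")
    t = ac.bound_by_expressed_table(result.profiles["WT"],
                                    result.expression_calls, Condition.WT,
                                    genes=genes)
    cells = {"a": 0, "b": 0, "c": 0, "d": 0}
    for g in genes:
        bound = prof.loc[g, "n_bound"] >= 1
        expressed = bool(calls.loc[g, "expressed_wt"])
        key = {(True, True): "a", (True, False): "b",
               (False, True): "c", (False, False): "d"}[(bound, expressed)]
        cells[key] += 1
    assert (t.a, t.b, t.c, t.d) == tuple(cells.values())


def test_symmetric_table_or_one_fisher_one():
    res = ac.odds_ratio_ci(ContingencyResult(a=10, b=10, c=10, d=10), 0.99)
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.ci_low < 1.0 < res.ci_high
    assert res.p_exact == pytest.approx(1.0)
    assert res.p_exact == pytest.approx(fisher_two_sided(10, 10, 10, 10))


def test_column_swap_inverts_odds_ratio():
    r1 = ac.odds_ratio_ci(ContingencyResult(a=12, b=5, c=7, d=30))
    r2 = ac.odds_ratio_ci(ContingencyResult(a=5, b=12, c=30, d=7))
    assert r1.odds_ratio * r2.odds_ratio == pytest.approx(1.0)


def test_ci_brackets_or_and_shrinks():
    t = ContingencyResult(a=40, b=10, c=20, d=30)
    wide = ac.odds_ratio_ci(t, 0.99)
    narrow = ac.odds_ratio_ci(t, 0.90)
    for r in (wide, narrow):
        assert r.ci_low <= r.odds_ratio <= r.ci_high
    assert narrow.ci_low > wide.ci_low
    assert narrow.ci_high < wide.ci_high


def test_wald_ci_cross_checked_against_statsmodels():
    sm = pytest.importorskip("statsmodels.stats.contingency_tables")
    for cells in [(40, 10, 20, 30), (4171, 304, 4484, 3860)]:
        a, b, c, d = cells
        res = ac.odds_ratio_ci(ContingencyResult(a=a, b=b, c=c, d=d), 0.99)
        tab = sm.Table2x2(np.array([[a, b], [c, d]]))
        lo, hi = tab.oddsratio_confint(alpha=0.01)
        assert res.odds_ratio == pytest.approx(tab.oddsratio)
        assert res.ci_low == pytest.approx(lo)
        assert res.ci_high == pytest.approx(hi)


def test_zero_cell_haldane_flagged():
    res = ac.odds_ratio_ci(ContingencyResult(a=10, b=0, c=5, d=8))
    assert res.haldane
    assert np.isfinite(res.odds_ratio)
    assert res.odds_ratio == pytest.approx((10.5 * 8.5) / (0.5 * 5.5))


def test_fisher_exact_equals_enumeration_all_small_tables():
    """Two-sided Fisher p matches exhaustive hypergeometric enumeration on
    every 2x2 table with total n <= 20."""
    from scipy.stats import fisher_exact
    checked = 0
    for n in range(1, 21):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    d = n - a - b - c
                    p_impl = fisher_exact([[a, b], [c, d]])[1]
                    p_oracle = fisher_two_sided(a, b, c, d)
                    assert p_impl == pytest.approx(p_oracle, rel=1e-8, abs=1e-12), \
                        (a, b, c, d)
                    checked += 1
    assert checked > 10_000


def test_fraction_bound_expressed():
    assert ac.fraction_bound_expressed(
        ContingencyResult(a=4171, b=304, c=1, d=1)) == pytest.approx(
            100 * 4171 / 4475)
    assert ac.fraction_bound_expressed(
        ContingencyResult(a=0, b=5, c=1, d=1)) == 0.0
    with pytest.raises(FormatError):
        ac.fraction_bound_expressed(ContingencyResult(a=0, b=0, c=1, d=1))


def test_p_display_floor():
    assert format_p(1e-30) == "<2.2e-16"
    assert format_p(0.034) == "0.034"


def test_signature_by_expression_single_gene():
    prof = _profiles(["a"], [1])
    calls = _calls(["a"], [True])
    tab = ac.signature_by_expression(prof, calls, Condition.WT)
    assert tab.set_index("signature").loc["Inside Only", "expressed"] == 1


def test_signature_by_expression_marginals(result):
    tab = ac.signature_by_expression(result.profiles["WT"],
                                     result.expression_calls, Condition.WT,
                                     result.common_genes)
    census = ac.signature_census(result.profiles["WT"]).set_index("signature")
    by_sig = tab.set_index("signature")
    totals = by_sig["expressed"] + by_sig["not_expressed"]
    for sig, n in totals.items():
        assert n == census.loc[sig, "n_genes"]
    prof = result.profiles["WT"].set_index("gene_id")
    calls = result.expression_calls.set_index("gene_id")
    bound = prof[prof["n_bound"] >= 1].index
    assert by_sig["expressed"].sum() == int(
        calls.loc[bound, "expressed_wt"].sum())


def test_de_by_diffacet_shares():
    de = pd.DataFrame({
        "gene_id": ["a", "b"],
        "fold_change": [2.0, 2.0],
        "de_pvalue": [0.01, 0.01],
        "de_status": [DEStatus.DOWN.value] * 2,
    })
    scores = pd.DataFrame({
        "gene_id": ["a", "b"],
        "category": [Category.HYPOACETYLATED_IN_TG.value,
                     Category.NOT_ACETYLATED.value],
    })
    tab = ac.de_by_diffacet(de, scores)
    assert tab.attrs["decreased_share"]["DOWN"] == pytest.approx(50.0)
    down = tab[tab["de_status"] == "DOWN"].set_index("category")
    assert down["n_genes"].sum() == 2


def test_de_by_diffacet_no_de_genes_warns(caplog):
    de = pd.DataFrame({"gene_id": ["a"], "fold_change": [1.0],
                       "de_pvalue": [0.9],
                       "de_status": [DEStatus.UNCHANGED.value]})
    scores = pd.DataFrame({"gene_id": ["a"],
                           "category": [Category.NOT_ACETYLATED.value]})
    with caplog.at_level("WARNING"):
        tab = ac.de_by_diffacet(de, scores)
    assert (tab["n_genes"] == 0).all()


def test_de_decoupled_from_acetylation_changes():
    """With expression changes independent of binding changes, the
    decreased-acetylation share of DOWN genes matches its unconditional
    share to within 3 sigma."""
    study = ac.simulate_study(ac.SimParams(n_genes=4000), seed=21)
    res = ac.analyze(study.probes, study.expression, study.annotation)
    scores = res.scores
    dec = scores["category"].isin([Category.HYPOACETYLATED_IN_TG.value,
                                   Category.NOT_ACETYLATED_IN_TG.value])
    unconditional = dec.mean()
    down = res.de[res.de["de_status"] == DEStatus.DOWN.value]["gene_id"]
    assert len(down) >= 30
    share = dec[scores["gene_id"].isin(down)].mean()
    se = np.sqrt(unconditional * (1 - unconditional) / len(down))
    assert abs(share - unconditional) <= 3 * se


def test_contingency_cells_sum_to_common_set(result):
    for cond in ("WT", "TG"):
        assert result.contingency[cond].n == len(result.common_genes)
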