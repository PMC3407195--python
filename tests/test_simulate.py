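import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import acetylchip as ac
from acetylchip.models import ParameterizationError, ProbeType
from acetylchip.simulate import (SimParams, calibrated_probe_retention,
                                 implied_odds_ratio, simulate_annotation,
                                 simulate_probes, simulate_signals,
                                 solve_joint_probability, stage_rng)


# ---------------------------------------------------------------- joint cells
@settings(max_examples=100, derandomize=True, deadline=None)
@given(pb=st.floats(0.05, 0.95), pe=st.floats(0.05, 0.95),
       orr=st.floats(0.05, 50.0))
def test_cell_solution_reproduces_odds_ratio(pb, pe, orr):
    """Solving then re-multiplying the 2x2 cell probabilities returns the
    requested odds ratio to 1e-9."""
    p11 = solve_joint_probability(pb, pe, orr)
    assert implied_odds_ratio(pb, pe, p11) == pytest.approx(orr, abs=1e-9, rel=1e-9)


def test_or_one_means_independence():
    assert solve_joint_probability(0.3, 0.6, 1.0) == pytest.approx(0.18)


def test_infeasible_marginals_raise():
    with pytest.raises(ParameterizationError):
        solve_joint_probability(1.0, 0.5, 2.0)
    with pytest.raises(ParameterizationError):
        solve_joint_probability(0.5, 0.5, -2.0)


def test_calibrated_probe_retention_in_unit_interval():
    r = calibrated_probe_retention(SimParams())
    assert 0.0 <= r <= 1.0
    with pytest.raises(ParameterizationError):
        calibrated_probe_retention(SimParams(probe_ratio_target_tg=0.99))


# ---------------------------------------------------------------- annotation
def test_single_gene_window_fits():
    params = SimParams(n_genes=1, chrom_lengths={"chr1": 1_000_000})
    ann = simulate_annotation(params, stage_rng(0, "annotation"))
    assert len(ann) == 1
    row = ann.iloc[0]
    if row["strand"] == "+":
        ws = row["tss"] - params.upstream_bp
    else:
        ws = row["tss"] - params.downstream_bp
    assert 0 <= ws and ws + params.window_span <= 1_000_000


def test_chromosome_too_short_raises():
    params = SimParams(n_genes=50, chrom_lengths={"chr1": 100_000})
    with pytest.raises(ParameterizationError, match="too short"):
        simulate_annotation(params, stage_rng(0, "annotation"))


def test_per_chromosome_counts_within_3_sigma(study):
    ann = study.annotation
    n, k = len(ann), len(study.params.chrom_lengths)
    expect = n / k
    sigma = np.sqrt(n * (1 / k) * (1 - 1 / k))
    counts = ann["chromosome"].value_counts()
    assert ((counts - expect).abs() <= 3 * sigma).all()
    assert set(ann["strand"]) == {"+", "-"}


def test_annotation_windows_disjoint(study):
    params = study.params
    for _, grp in study.annotation.groupby("chromosome"):
        ws = np.where(grp["strand"] == "+",
                      grp["tss"] - params.upstream_bp,
                      grp["tss"] - params.downstream_bp)
        ws = np.sort(ws)
        assert (np.diff(ws) >= params.window_span).all()


def test_same_seed_reproduces_everything():
    p = SimParams(n_genes=150)
    s1 = ac.simulate_study(p, seed=5)
    s2 = ac.simulate_study(p, seed=5)
    pd.testing.assert_frame_equal(s1.annotation, s2.annotation)
    pd.testing.assert_frame_equal(s1.probes, s2.probes)
    pd.testing.assert_frame_equal(s1.expression, s2.expression)
    pd.testing.assert_frame_equal(s1.truth, s2.truth)


# ---------------------------------------------------------------- probes
def test_probe_geometry_and_counts(study):
    probes, params = study.probes, study.params
    assert ((probes["end"] - probes["start"]) == params.probe_length).all()
    per_gene = probes.groupby("gene_id").size()
    assert per_gene.mean() == pytest.approx(params.probes_per_gene, rel=0.10)
    assert per_gene.min() >= 1
    # spacing extremes bound the achievable per-window count
    assert per_gene.max() <= params.window_span // (params.probe_length +
                                                    params.spacing_bp[0]) + 1


def test_probe_types_match_classifier(study):
    params = study.params
    sample = study.probes.sample(40, random_state=0)
    for row in sample.itertuples(index=False):
        mid = (row.start + row.end) // 2
        expected = ac.classify_probe_type(mid, row.chromosome, study.annotation,
                                          params, gene_id=row.gene_id)
        assert row.probe_type == expected.value


def _annotation_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "strand",
                                       "tss", "tes"])


def test_classify_probe_type_rules():
    params = SimParams(n_genes=1)
    ann = _annotation_frame([("g1", "chr1", "+", 10_000, 14_000)])
    clf = lambda mid: ac.classify_probe_type(mid, "chr1", ann, params, "g1")
    assert clf(9_900) is ProbeType.PROMOTER
    assert clf(10_000) is ProbeType.INSIDE      # TSS boundary -> Inside
    assert clf(12_000) is ProbeType.INSIDE
    assert clf(14_000) is ProbeType.INSIDE      # TES inclusive
    assert clf(14_500) is ProbeType.DOWNSTREAM
    assert clf(16_000) is ProbeType.UNKNOWN


def test_classify_divergent_promoter():
    params = SimParams(n_genes=1)
    # head-to-head genes: gM transcribes leftward, gP rightward; the region
    # between their TSSs is upstream of both
    ann = _annotation_frame([
        ("gM", "chr1", "-", 20_000, 12_000),
        ("gP", "chr1", "+", 23_000, 30_000),
    ])
    assert ac.classify_probe_type(21_500, "chr1", ann, params,
                                  "gP") is ProbeType.DIVERGENT_PROMOTER
    # same position is upstream of gM too
    assert ac.classify_probe_type(21_500, "chr1", ann, params,
                                  "gM") is ProbeType.DIVERGENT_PROMOTER


def test_classify_no_gene_in_window_is_unknown():
    params = SimParams(n_genes=1)
    ann = _annotation_frame([("g1", "chr1", "+", 10_000, 14_000)])
    assert ac.classify_probe_type(500_000, "chr1", ann,
                                  params) is ProbeType.UNKNOWN


# ---------------------------------------------------------------- signals
def test_truth_marginals_within_3_binomial_se(study):
    truth, params = study.truth, study.params
    n = len(truth)

    def check(observed, target):
        se = np.sqrt(target * (1 - target) / n)
        assert abs(observed - target) <= 3 * se

    check(truth["truly_bound_wt"].mean(), params.frac_bound_wt)
    check(truth["truly_expressed_wt"].mean(), params.frac_expressed_wt)
    retained = truth.loc[truth["truly_bound_wt"], "truly_bound_tg"]
    se = np.sqrt(params.gene_retention_tg * (1 - params.gene_retention_tg)
                 / len(retained))
    assert abs(retained.mean() - params.gene_retention_tg) <= 3 * se


def test_no_effect_case_gives_identical_truth():
    params = SimParams(n_genes=300, gene_retention_tg=1.0,
                       probe_retention_tg=1.0, ectopic_gain_tg=0.0)
    study = ac.simulate_study(params, seed=3)
    t = study.truth
    assert (t["truly_bound_wt"] == t["truly_bound_tg"]).all()
    assert (t["bound_probe_ids_wt"] == t["bound_probe_ids_tg"]).all()


def test_or_target_one_decouples_binding_and_expression():
    params = SimParams(n_genes=4000, target_or_wt=1.0)
    study = ac.simulate_study(params, seed=9)
    t = study.truth
    a = (t.truly_bound_wt & t.truly_expressed_wt).sum()
    b = (t.truly_bound_wt & ~t.truly_expressed_wt).sum()
    c = (~t.truly_bound_wt & t.truly_expressed_wt).sum()
    d = (~t.truly_bound_wt & ~t.truly_expressed_wt).sum()
    res = ac.odds_ratio_ci(ac.ContingencyResult(a=int(a), b=int(b),
                                                c=int(c), d=int(d)), 0.99)
    assert res.ci_low <= 1.0 <= res.ci_high


def test_bound_probe_pvalue_mass_below_threshold(study):
    params = study.params
    truth = study.truth
    bound_ids = set()
    for ids in truth.loc[truth["truly_bound_wt"], "bound_probe_ids_wt"]:
        bound_ids.update(ids.split(","))
    pv = study.probes.loc[study.probes["probe_id"].isin(bound_ids), "pvalue_wt"]
    frac = (pv <= params.p_threshold).mean()
    se = np.sqrt(params.bound_p_mass * (1 - params.bound_p_mass) / len(pv))
    assert abs(frac - params.bound_p_mass) <= 4 * se


def test_tg_bound_probes_subset_of_wt_for_retained_genes(study):
    t = study.truth
    retained = t[t["truly_bound_wt"] & t["truly_bound_tg"]]
    for wt_ids, tg_ids in zip(retained["bound_probe_ids_wt"],
                              retained["bound_probe_ids_tg"]):
        assert set(tg_ids.split(",")) <= set(wt_ids.split(","))
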