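"""Synthetic promoter-array study generator.

Emulates a two-genotype (WT vs transgenic) AcH3 ChIP-chip experiment on an
Agilent-style mouse promoter tiling array — ~25 60-mer probes per gene spaced
every ~100-300 bp over a -5.5 kb..+2.5 kb window around each TSS — together
with a matched expression dataset, and returns a ground-truth table for
parameter-recovery tests.

The generative model works at the gene level first: expression status and
WT binding status are sampled jointly so that the realized bound-by-expressed
odds ratio hits a requested target (the 2x2 cell probabilities are solved in
closed form from the two marginals and the odds ratio — the Plackett
one-unknown quadratic). TG binding is WT binding thinned by a gene-retention
probability plus a small ectopic-gain probability, and within retained genes
the bound-probe set is thinned again so the overall TG/WT bound-probe ratio
lands on its target. Probe-level signals and binding p-values are then drawn
conditional on the truth.

Randomness uses a single seed with named per-stage substreams, so adding a
stage never perturbs the draws of earlier stages.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import betainc, betaincinv

from . import io as acio
from .models import Condition, ParameterizationError, ProbeType, RunConfig

#: Named RNG substreams; fixed ids keep streams stable across code changes.
_STAGES = {
    "annotation": 1,
    "probes": 2,
    "signals": 3,
    "expression": 4,
}

#: Approximate mouse chromosome lengths (bp), the declared genome dictionary.
MOUSE_CHROM_LENGTHS: Dict[str, int] = {
    "chr1": 195_000_000, "chr2": 182_000_000, "chr3": 160_000_000,
    "chr4": 157_000_000, "chr5": 152_000_000, "chr6": 150_000_000,
    "chr7": 145_000_000, "chr8": 129_000_000, "chr9": 124_000_000,
    "chr10": 131_000_000, "chr11": 122_000_000, "chr12": 120_000_000,
    "chr13": 120_000_000, "chr14": 125_000_000, "chr15": 104_000_000,
    "chr16": 98_000_000, "chr17": 95_000_000, "chr18": 91_000_000,
    "chr19": 61_000_000, "chrX": 171_000_000, "chrY": 91_000_000,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for a named simulation stage under one seed."""
    return np.random.default_rng(np.random.SeedSequence(
        entropy=int(seed), spawn_key=(_STAGES[stage],)))


@dataclass
class SimParams:
    """Parameters of the synthetic study.

    Defaults reproduce the printed structure of the source study: 29.6% of
    genes AcH3-bound in WT, TG gene-level retention 71.5%, overall TG/WT
    bound-probe ratio 54.4%, 67.5% of genes expressed, and a bound-by-
    expressed odds ratio of 11.8 in WT. ``n_genes`` defaults to 2,000 for
    fast tests; 12,819 emulates the common ChIP-chip/expression gene set and
    ~18,000 the full promoter array.
    """

    n_genes: int = 2000
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: dict(MOUSE_CHROM_LENGTHS))
    chrom_weights: Optional[Dict[str, float]] = None  # None = uniform

    # array geometry
    probes_per_gene: float = 25.0
    probe_length: int = 60
    spacing_bp: Tuple[int, int] = (100, 300)  # gap between adjacent probes
    upstream_bp: int = 5500
    downstream_bp: int = 2500
    downstream_margin_bp: int = 1000
    gene_length_range: Tuple[int, int] = (1000, 50_000)  # log-uniform

    # gene-level binding structure
    frac_bound_wt: float = 0.296
    gene_retention_tg: float = 0.715
    probe_ratio_target_tg: float = 0.544
    probe_retention_tg: Optional[float] = None  # None = calibrated
    ectopic_gain_tg: float = 0.01
    target_or_wt: float = 11.8
    frac_expressed_wt: float = 8655 / 12819
    bound_probes_lambda: float = 0.817  # bound probes/gene = 1 + Poisson

    # probe-type bias of bound probes (category mass, not per-probe weight)
    type_mass: Dict[str, float] = field(default_factory=lambda: {
        ProbeType.INSIDE.value: 0.7,
        ProbeType.PROMOTER.value: 0.2,
        ProbeType.DOWNSTREAM.value: 0.0333333333,
        ProbeType.DIVERGENT_PROMOTER.value: 0.0333333333,
        ProbeType.UNKNOWN.value: 0.0333333334,
    })

    # probe-level signal and p-value model
    n_replicates: int = 2
    bound_signal_median: float = 1.3
    bound_signal_sigma: float = 0.25
    null_signal_sd: float = 0.3
    replicate_noise_sd: float = 0.15
    p_threshold: float = 0.005
    bound_p_mass: float = 0.97  # P(p <= p_threshold | truly bound probe)
    bound_p_beta: Tuple[float, float] = (0.05, 10.0)
    bound_p_cap: float = 0.05

    # expression model
    n_expr_samples: int = 4
    max_probesets: int = 3
    expr_log_margin: Tuple[float, float] = (0.1, 3.0)
    probeset_log_sd: float = 0.05
    expr_sample_log_sd: float = 0.05
    frac_de: float = 0.05
    de_fold_range: Tuple[float, float] = (1.5, 4.0)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        fracs = {
            "frac_bound_wt": self.frac_bound_wt,
            "gene_retention_tg": self.gene_retention_tg,
            "probe_ratio_target_tg": self.probe_ratio_target_tg,
            "ectopic_gain_tg": self.ectopic_gain_tg,
            "frac_expressed_wt": self.frac_expressed_wt,
            "bound_p_mass": self.bound_p_mass,
            "frac_de": self.frac_de,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ParameterizationError(f"{name} must lie in [0, 1], got {v}")
        if self.target_or_wt <= 0:
            raise ParameterizationError("target_or_wt must be > 0")
        if self.probes_per_gene < 1:
            raise ParameterizationError("probes_per_gene must be >= 1")
        if self.n_genes < 1:
            raise ParameterizationError("n_genes must be >= 1")
        lo, hi = self.spacing_bp
        if not 0 < lo <= hi:
            raise ParameterizationError("spacing_bp must satisfy 0 < lo <= hi")

    @property
    def window_span(self) -> int:
        return self.upstream_bp + self.downstream_bp

    def chrom_list(self) -> list:
        return list(self.chrom_lengths)

    def weights(self) -> np.ndarray:
        chroms = self.chrom_list()
        if self.chrom_weights is None:
            w = np.ones(len(chroms))
        else:
            w = np.array([self.chrom_weights.get(c, 0.0) for c in chroms], float)
        total = w.sum()
        if total <= 0:
            raise ParameterizationError("chromosome weights sum to zero")
        return w / total


def solve_joint_probability(frac_bound: float, frac_expressed: float,
                            odds_ratio: float) -> float:
    """P(bound and expressed) for given marginals and odds ratio.

    Solves OR = p11*p00 / (p10*p01) with p1. = frac_bound, p.1 =
    frac_expressed for p11 — a quadratic with a single admissible root in
    [max(0, p1.+p.1-1), min(p1., p.1)] (the Plackett construction). Raises
    ParameterizationError when the combination admits no valid table.
    """
    pb, pe, orr = frac_bound, frac_expressed, odds_ratio
    if not (0 < pb < 1 and 0 < pe < 1):
        raise ParameterizationError(
            "marginals must lie strictly inside (0, 1) to impose an odds ratio")
    if orr <= 0:
        raise ParameterizationError("odds ratio target must be > 0")
    if orr == 1.0:
        return pb * pe
    a = orr - 1.0
    b = -((orr - 1.0) * (pb + pe) + 1.0)
    c = orr * pb * pe
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise ParameterizationError(
            f"no real solution for OR={orr} with marginals ({pb}, {pe})")
    p11 = (-b - math.sqrt(disc)) / (2.0 * a)
    lo, hi = max(0.0, pb + pe - 1.0), min(pb, pe)
    if not lo - 1e-12 <= p11 <= hi + 1e-12:
        raise ParameterizationError(
            f"solved cell probability {p11:.6f} outside feasible range "
            f"[{lo:.6f}, {hi:.6f}] for OR={orr}, marginals ({pb}, {pe})")
    return float(min(max(p11, lo), hi))


def implied_odds_ratio(frac_bound: float, frac_expressed: float,
                       p11: float) -> float:
    """Recompute the odds ratio from a joint cell probability (self-check)."""
    p10 = frac_bound - p11
    p01 = frac_expressed - p11
    p00 = 1.0 - frac_bound - frac_expressed + p11
    return (p11 * p00) / (p10 * p01)


def calibrated_probe_retention(params: SimParams) -> float:
    """Within-gene bound-probe retention hitting the overall probe-ratio target.

    Retained TG genes keep 1 + Binomial(n_wt - 1, r) of their WT bound
    probes. With mean WT bound probes mu = 1 + lambda, gene retention g,
    ectopic gain e over the unbound fraction, the expected overall TG/WT
    bound-probe ratio is g*(1 + (mu-1)*r)/mu + (1-pb)/pb*e; solve for r.
    """
    mu = 1.0 + params.bound_probes_lambda
    pb = params.frac_bound_wt
    ectopic_share = (1.0 - pb) / pb * params.ectopic_gain_tg
    within = (params.probe_ratio_target_tg - ectopic_share) / params.gene_retention_tg
    if mu <= 1.0:
        return 1.0
    r = (mu * within - 1.0) / (mu - 1.0)
    if not 0.0 <= r <= 1.0:
        raise ParameterizationError(
            f"calibrated probe retention {r:.4f} outside [0, 1]; "
            "probe_ratio_target_tg is infeasible for these parameters")
    return float(r)


def simulate_annotation(params: SimParams, rng: np.random.Generator) -> pd.DataFrame:
    """Place genes on the declared chromosomes with disjoint probe windows.

    Each gene owns an 8 kb probe window (-upstream..+downstream of its TSS,
    strand-oriented); windows never overlap. Gene bodies are log-uniform in
    length and may extend beyond the window. Per-chromosome gene counts
    follow the multinomial weights.
    """
    chroms = params.chrom_list()
    counts = rng.multinomial(params.n_genes, params.weights())
    span = params.window_span
    rows = []
    for chrom, n in zip(chroms, counts):
        if n == 0:
            continue
        length = params.chrom_lengths[chrom]
        gaps = rng.uniform(500.0, 5000.0, size=n)
        window_starts = 10_000 + np.cumsum(gaps + span) - span
        if window_starts[-1] + span + 10_000 > length:
            raise ParameterizationError(
                f"chromosome {chrom} ({length} bp) too short for {n} gene "
                f"windows of {span} bp")
        strands = rng.choice(["+", "-"], size=n)
        lo, hi = params.gene_length_range
        lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)).astype(int)
        for ws, strand, glen in zip(window_starts.astype(int), strands, lengths):
            if strand == "+":
                tss = ws + params.upstream_bp
                tes = tss + int(glen)
            else:
                tss = ws + params.downstream_bp
                tes = tss - int(glen)
            rows.append((chrom, strand, tss, tes))
    df = pd.DataFrame(rows, columns=["chromosome", "strand", "tss", "tes"])
    df.insert(0, "gene_id", [f"g{i:05d}" for i in range(len(df))])
    return df


def _oriented_offset(midpoint: int, tss: int, strand: str) -> int:
    return midpoint - tss if strand == "+" else tss - midpoint


def classify_probe_type(midpoint: int, chromosome: str, annotation: pd.DataFrame,
                        params: SimParams, gene_id: Optional[str] = None) -> ProbeType:
    """Classify a probe position relative to gene annotation.

    Promoter: strictly upstream of the TSS within the upstream window (the
    TSS itself counts as Inside). Inside: between TSS and TES inclusive.
    Downstream: within ``downstream_margin_bp`` past the TES. Divergent
    promoter: simultaneously within the upstream windows of two genes
    transcribed in opposite directions. Unknown: none of the above, or no
    gene within any window.
    """
    genes = annotation[annotation["chromosome"] == chromosome]
    if gene_id is not None:
        sel = genes[genes["gene_id"] == gene_id]
        if sel.empty:
            raise ValueError(f"gene {gene_id!r} not on chromosome {chromosome}")
        gene = sel.iloc[0]
    else:
        gene = None
        best = None
        for row in genes.itertuples(index=False):
            o = _oriented_offset(midpoint, row.tss, row.strand)
            hi = max(abs(row.tes - row.tss) + params.downstream_margin_bp,
                     params.downstream_bp)
            if -params.upstream_bp < o <= hi:
                if best is None or abs(o) < best:
                    best, gene = abs(o), row
        if gene is None:
            return ProbeType.UNKNOWN

    o = _oriented_offset(midpoint, gene.tss, gene.strand)
    glen = abs(gene.tes - gene.tss)
    if -params.upstream_bp < o < 0:
        own = ProbeType.PROMOTER
    elif 0 <= o <= glen:
        own = ProbeType.INSIDE
    elif glen < o <= glen + params.downstream_margin_bp:
        own = ProbeType.DOWNSTREAM
    else:
        own = ProbeType.UNKNOWN

    if own is ProbeType.PROMOTER:
        for row in genes.itertuples(index=False):
            if row.gene_id == gene.gene_id or row.strand == gene.strand:
                continue
            o2 = _oriented_offset(midpoint, row.tss, row.strand)
            if -params.upstream_bp < o2 < 0:
                return ProbeType.DIVERGENT_PROMOTER
    return own


def _classify_offsets(offsets: np.ndarray, gene_length: int,
                      params: SimParams) -> np.ndarray:
    """Vectorized own-gene probe typing by strand-oriented offset from TSS."""
    out = np.full(offsets.shape, ProbeType.UNKNOWN.value, dtype=object)
    out[(offsets > -params.upstream_bp) & (offsets < 0)] = ProbeType.PROMOTER.value
    out[(offsets >= 0) & (offsets <= gene_length)] = ProbeType.INSIDE.value
    out[(offsets > gene_length)
        & (offsets <= gene_length + params.downstream_margin_bp)] = \
        ProbeType.DOWNSTREAM.value
    return out


def simulate_probes(annotation: pd.DataFrame, params: SimParams,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Tile each gene's window with 60-mer probes (positions and types only).

    Candidate probes are laid start-to-start at probe_length plus a uniform
    gap in ``spacing_bp``; candidates are then thinned uniformly at random so
    the expected probe count per gene equals ``probes_per_gene`` (the real
    array tiles its windows incompletely — ~25 probes over 8 kb).
    """
    span = params.window_span
    mean_step = params.probe_length + sum(params.spacing_bp) / 2.0
    expected_candidates = span / mean_step
    keep_p = min(1.0, params.probes_per_gene / expected_candidates)
    lo, hi = params.spacing_bp
    max_steps = int(span / (params.probe_length + lo)) + 2

    records = []
    for row in annotation.itertuples(index=False):
        if row.strand == "+":
            ws = row.tss - params.upstream_bp
        else:
            ws = row.tss - params.downstream_bp
        steps = params.probe_length + rng.uniform(lo, hi, size=max_steps)
        starts = ws + np.concatenate(([0.0], np.cumsum(steps)))
        starts = starts[starts + params.probe_length <= ws + span].astype(int)
        keep = rng.random(starts.size) < keep_p
        if not keep.any():
            keep[rng.integers(starts.size)] = True
        starts = starts[keep]
        mids = starts + params.probe_length // 2
        offsets = np.where(row.strand == "+", mids - row.tss, row.tss - mids)
        glen = abs(row.tes - row.tss)
        types = _classify_offsets(offsets, glen, params)
        for j, (s, t) in enumerate(zip(starts, types)):
            records.append((f"{row.gene_id}_p{j:03d}", row.gene_id,
                            row.chromosome, int(s), int(s) + params.probe_length, t))
    return pd.DataFrame(records, columns=acio.PROBE_KEY_COLUMNS)


def _bound_pvalues(n: int, params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """p-values of truly bound probes: truncated-Beta mixture with exactly
    ``bound_p_mass`` below the binding threshold."""
    a, b = params.bound_p_beta
    f_thr = betainc(a, b, params.p_threshold)
    f_cap = betainc(a, b, params.bound_p_cap)
    u = rng.random(n)
    below = rng.random(n) < params.bound_p_mass
    q = np.where(below, u * f_thr, f_thr + u * (f_cap - f_thr))
    return betaincinv(a, b, q)


def _null_pvalues(n: int, rng: np.random.Generator) -> np.ndarray:
    # Beta(2,1): stochastically larger than uniform, emulating the
    # conservatism of replicate-averaged error-model p-values at unenriched
    # probes (P(p <= 0.005) = 2.5e-5 per probe).
    return np.sqrt(rng.random(n))


def _choose_bound_probes(idx: np.ndarray, types: np.ndarray, n_bound: int,
                         params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Pick bound probes within a gene with the type-bias weights."""
    mass = params.type_mass
    w = np.zeros(idx.size)
    for t in np.unique(types):
        m = types == t
        w[m] = mass.get(t, 0.0) / m.sum()
    if w.sum() <= 0:
        w[:] = 1.0
    w = w / w.sum()
    n_bound = min(n_bound, idx.size)
    return rng.choice(idx, size=n_bound, replace=False, p=w)


def simulate_signals(probes: pd.DataFrame, annotation: pd.DataFrame,
                     params: SimParams, rng: np.random.Generator
                     ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-probe replicate signals and binding p-values for WT and TG.

    Returns (probe table with signal/p-value columns, per-gene truth table).
    Gene-level truth: expression and WT binding are coupled to the target
    odds ratio; TG binding thins WT binding by the gene-retention and adds
    ectopic gains; within retained genes bound probes are thinned by the
    calibrated probe retention.
    """
    genes = annotation["gene_id"].to_numpy()
    ng = genes.size
    pe = params.frac_expressed_wt
    pb = params.frac_bound_wt

    p11 = solve_joint_probability(pb, pe, params.target_or_wt)
    q1 = p11 / pe                  # P(bound | expressed)
    q0 = (pb - p11) / (1.0 - pe)   # P(bound | not expressed)

    expressed = rng.random(ng) < pe
    bound_wt = rng.random(ng) < np.where(expressed, q1, q0)
    bound_tg = np.where(bound_wt,
                        rng.random(ng) < params.gene_retention_tg,
                        rng.random(ng) < params.ectopic_gain_tg)

    probe_retention = (params.probe_retention_tg
                       if params.probe_retention_tg is not None
                       else calibrated_probe_retention(params))

    n_probes = len(probes)
    gene_of_probe = probes["gene_id"].to_numpy()
    type_of_probe = probes["probe_type"].to_numpy()
    order = {g: i for i, g in enumerate(genes)}
    probe_groups: Dict[str, np.ndarray] = {
        g: np.asarray(idx) for g, idx in probes.groupby("gene_id").indices.items()}

    tb_probe = {c: np.zeros(n_probes, dtype=bool) for c in ("wt", "tg")}
    for gi, g in enumerate(genes):
        idx = probe_groups.get(g)
        if idx is None:
            continue
        types = type_of_probe[idx]
        wt_sel = np.array([], dtype=int)
        if bound_wt[gi]:
            n_b = 1 + rng.poisson(params.bound_probes_lambda)
            wt_sel = _choose_bound_probes(idx, types, n_b, params, rng)
            tb_probe["wt"][wt_sel] = True
        if bound_tg[gi]:
            if bound_wt[gi]:
                n_tg = 1 + rng.binomial(wt_sel.size - 1, probe_retention)
                tg_sel = rng.choice(wt_sel, size=n_tg, replace=False)
            else:
                n_b = 1 + rng.poisson(params.bound_probes_lambda)
                tg_sel = _choose_bound_probes(idx, types, n_b, params, rng)
            tb_probe["tg"][tg_sel] = True

    out = probes.copy()
    mu_log = math.log(params.bound_signal_median)
    for cond in ("wt", "tg"):
        mask = tb_probe[cond]
        base = rng.normal(0.0, params.null_signal_sd, size=n_probes)
        base[mask] = rng.lognormal(mu_log, params.bound_signal_sigma,
                                   size=int(mask.sum()))
        for r in range(1, params.n_replicates + 1):
            out[f"signal_{cond}_{r}"] = base + rng.normal(
                0.0, params.replicate_noise_sd, size=n_probes)
        pv = _null_pvalues(n_probes, rng)
        pv[mask] = _bound_pvalues(int(mask.sum()), params, rng)
        out[f"pvalue_{cond}"] = pv

    def _ids(cond: str) -> list:
        sel = pd.Series(probes["probe_id"].to_numpy()[tb_probe[cond]])
        by_gene = sel.groupby(
            pd.Series(gene_of_probe[tb_probe[cond]])).apply(
                lambda s: ",".join(sorted(s)))
        return [by_gene.get(g, "") for g in genes]

    truth = pd.DataFrame({
        "gene_id": genes,
        "truly_expressed_wt": expressed,
        "truly_bound_wt": bound_wt,
        "truly_bound_tg": bound_tg,
        "bound_probe_ids_wt": _ids("wt"),
        "bound_probe_ids_tg": _ids("tg"),
    })
    return out, truth


def simulate_expression(truth: pd.DataFrame, params: SimParams,
                        rng: np.random.Generator
                        ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Probeset-level expression values for both genotypes.

    Expressed genes sit log-uniformly above the detection threshold (100),
    unexpressed genes below it; a small fraction of genes receive a true
    fold change in TG, independent of binding changes. Returns (expression
    table, truth augmented with TG expression status and true fold change).
    """
    genes = truth["gene_id"].to_numpy()
    ng = genes.size
    expressed = truth["truly_expressed_wt"].to_numpy()
    lo, hi = params.expr_log_margin
    mag = rng.uniform(lo, hi, size=ng)
    base_wt = 100.0 * np.exp(np.where(expressed, mag, -mag))

    de = rng.random(ng) < params.frac_de
    direction = np.where(rng.random(ng) < 0.5, 1.0, -1.0)
    f_lo, f_hi = params.de_fold_range
    fold = rng.uniform(f_lo, f_hi, size=ng)
    true_fold = np.where(de, fold ** direction, 1.0)
    base_tg = base_wt * true_fold

    n_ps = rng.integers(1, params.max_probesets + 1, size=ng)
    gene_idx = np.repeat(np.arange(ng), n_ps)
    ps_rank = np.concatenate([np.arange(k) for k in n_ps])
    n_rows = gene_idx.size
    ps_mult = np.exp(rng.normal(0.0, params.probeset_log_sd, size=n_rows))

    data = {
        "gene_id": genes[gene_idx],
        "probeset_id": [f"{genes[i]}_ps{j}" for i, j in zip(gene_idx, ps_rank)],
    }
    for cond, base in (("wt", base_wt), ("tg", base_tg)):
        for s in range(1, params.n_expr_samples + 1):
            noise = np.exp(rng.normal(0.0, params.expr_sample_log_sd, size=n_rows))
            data[f"{cond}_{s}"] = base[gene_idx] * ps_mult * noise
    expr = pd.DataFrame(data)

    truth = truth.copy()
    truth["truly_expressed_tg"] = base_tg > 100.0
    truth["true_fold_tg_vs_wt"] = true_fold
    return expr, truth


@dataclass
class SimulatedStudy:
    annotation: pd.DataFrame
    probes: pd.DataFrame
    expression: pd.DataFrame
    truth: pd.DataFrame
    params: SimParams
    seed: int


def simulate_study(params: SimParams, seed: int) -> SimulatedStudy:
    """Run every generator stage under named substreams of one seed."""
    annotation = simulate_annotation(params, stage_rng(seed, "annotation"))
    probes = simulate_probes(annotation, params, stage_rng(seed, "probes"))
    probes, truth = simulate_signals(probes, annotation, params,
                                     stage_rng(seed, "signals"))
    expression, truth = simulate_expression(truth, params,
                                            stage_rng(seed, "expression"))
    return SimulatedStudy(annotation=annotation, probes=probes,
                          expression=expression, truth=truth,
                          params=params, seed=seed)


def write_study(study: SimulatedStudy, outdir, config: Optional[RunConfig] = None
                ) -> Dict[str, Path]:
    """Write annotation/probe/expression/truth TSVs with config headers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig(seed=study.seed)
    meta = dict(config.meta())
    meta["seed"] = study.seed
    meta["n_genes"] = study.params.n_genes
    paths = {
        "annotation": outdir / "annotation.tsv",
        "probes": outdir / "probes.tsv",
        "expression": outdir / "expression.tsv",
        "truth": outdir / "truth.tsv",
    }
    acio.write_annotation(study.annotation, paths["annotation"], meta)
    acio.write_probe_table(study.probes, paths["probes"], meta)
    acio.write_table(study.expression, paths["expression"], meta)
    acio.write_table(study.truth, paths["truth"], meta)
    return paths
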