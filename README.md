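# acetylchip

Analysis of genome-wide histone H3 acetylation (AcH3, H3K9K14ac) measured by
ChIP-chip on promoter tiling arrays, comparing wild-type (WT) with R6/2
transgenic (TG) Huntington's-disease mouse striatum, and integration of the
binding calls with gene-expression data. The package is aimed at anyone
analysing probe-level promoter-array ChIP results: it takes per-probe
log2(IP/WCE) enrichment ratios and binding p-values (the output of standard
two-colour array processing) plus a gene-level expression table, and
produces bound-probe/bound-gene calls, binding-location signatures,
differential-acetylation scores and categories, and binding-by-expression
association statistics.

## The statistics at the core

- **Bound calls.** A probe is bound when its binding p-value satisfies
  p ≤ 0.005; a gene is bound when ≥ 1 of its probes is bound. A gene's
  *binding signature* is the set of probe-location types (Promoter, Inside,
  Downstream, Divergent Promoter, Unknown) among its bound probes.
- **Composite differential-acetylation score.** Per gene,

  `score = Σ_{TG bound probes} mean_r log2(IP/WCE) − Σ_{WT bound probes} mean_r log2(IP/WCE)`

  (mean over replicates r). Negative scores mean less acetylation in TG.
  Genes are categorized as *not acetylated in TG* (bound in WT only),
  *ectopically acetylated in TG* (TG only), *hypo-/hyperacetylated in TG*
  (bound in both, score sign), *not acetylated* (neither), and ranked by
  score.
- **Expression calls.** Gene expression is the mean over its probesets;
  expressed ⇔ mean > 100. Differential expression: Welch two-sided t-test,
  fold ≥ 1.5 and p ≤ 0.05.
- **Binding–expression association.** Over the common gene set, the 2×2
  bound-by-expressed table with odds ratio OR = ad/bc, a Wald confidence
  interval on log OR at 99%, `exp(ln OR ± z·√(1/a+1/b+1/c+1/d))`, and a
  two-sided Fisher exact p.

Because no public accession exists for arrays of this design, the package
includes a first-class synthetic generator emulating an Agilent-style mouse
promoter array (~25 probes/gene, 60-mers spaced 100–300 bp over
−5.5 kb..+2.5 kb around each TSS) with genotype-dependent binding loss,
a closed-form odds-ratio-targeted coupling between binding and expression,
and a ground-truth table for recovery tests. See `docs/methods.md` for the
full model.

## Worked example

```sh
acetylchip simulate --seed 7 --n-genes 2000 --out demo
acetylchip call demo
acetylchip score demo
acetylchip expression demo
acetylchip integrate demo
acetylchip report demo
```

prints (abridged):

```
WT: 1041 bound probes, 577 bound genes
TG: 558 bound probes, 423 bound genes
scored 2000 genes; 599 differentially acetylated
1330 genes expressed in WT, 1326 in TG; 57 up / 65 down
WT: OR=14.4 CI=(8.8, 23.6) p<2.2e-16; 95% of bound genes expressed
TG: OR=8.1 CI=(5.0, 13.1) p<2.2e-16; 92% of bound genes expressed
```

Reading this: 28.9% of the 2,000 simulated genes are AcH3-bound in WT; the
TG striatum retains 53.6% of the WT bound probes and 73.3% of the WT bound
genes (the generator's targets are 54.4% and ~73%, i.e. 71.5% gene
retention plus a small ectopic gain). Among bound WT genes, 95% are
expressed, and the bound-by-expressed odds ratio of 14.4 (99% CI 8.8–23.6,
Fisher p < 2.2e-16) says a bound gene has ~14-fold higher odds of being
expressed than an unbound one — at n = 2,000 the interval is wide; at the
full common-set size of 12,819 genes the recovered OR concentrates near the
11.8 target. `demo/report.md` assembles per-chromosome binding, probe-type
occupancy (Inside probes dominate binding), signature and category censuses,
ranked gene tables, and the expression cross-tabs; every output TSV header
records the thresholds and seed, and identical config + seed reproduces
every file byte-identically.

The same analyses are available as a library:

```python
import acetylchip as ac

study = ac.simulate_study(ac.SimParams(n_genes=2000), seed=7)
result = ac.analyze(study.probes, study.expression, study.annotation)
result.contingency["WT"].odds_ratio     # 14.4...
ac.category_census(result.scores)       # five-category table
```

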