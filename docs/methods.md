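# Methods

## The analysis

`acetylchip` analyses promoter tiling-array ChIP-chip data for acetylated
histone H3 (AcH3, H3K9K14ac) in two genotypes — wild-type (WT) and R6/2
transgenic (TG) mouse striatum — and integrates the binding calls with gene
expression. The pipeline's inputs are probe-level results as produced by
standard two-colour array processing: per-probe log2(IP/WCE) enrichment
ratios (replicates) and a per-probe binding p-value per condition. Upstream
normalization and error modelling (LOWESS, replicate-combining error models,
peak detection) are treated as already done; their outputs are this
package's inputs, and the synthetic generator fabricates them directly.

Decision rules, all exposed in `RunConfig`:

- **Bound probe**: binding p-value ≤ 0.005 (boundary inclusive).
- **Bound gene**: at least one bound probe among the gene's probes.
- **Binding signature**: the set of probe-location types (Promoter, Inside,
  Downstream, Divergent Promoter, Unknown) among a gene's bound probes.
- **Composite differential-acetylation score**: per gene,
  `sum over TG bound probes of the replicate-mean log2 ratio` minus the same
  sum over WT bound probes. Negative = less acetylation in TG. The
  replicate-mean convention (arithmetic mean of the biological replicates'
  log2 ratios) is this package's declared choice; only bound probes enter
  either sum.
- **Categories**: bound in WT only → *not acetylated in TG*; bound in TG
  only → *ectopically acetylated in TG*; bound in both with negative /
  positive score → *hypo-* / *hyperacetylated in TG*; bound in neither →
  *not acetylated*. A gene bound in both with |score| ≤ ε is labelled
  *unchanged*; ε defaults to 0 (strict sign rule), so with continuous
  signals the label appears only for degenerate input.
- **Expressed gene**: mean over the gene's probesets (and samples) strictly
  greater than 100.
- **Differential expression**: Welch (unequal-variance) two-sided t-test on
  per-sample gene values with an inclusive gate, fold ≥ 1.5 and p ≤ 0.05.
  The t-test is used as the operational significance rule; permutation-based
  FDR machinery is deliberately out of scope.
- **Association**: over the common gene set (intersection of the binding and
  expression platforms' gene lists), the 2×2 bound-by-expressed table per
  condition; OR = ad/bc; CI by the Wald interval on the log odds ratio,
  `exp(ln OR ± z·sqrt(1/a+1/b+1/c+1/d))` at 99% by default; p by the
  two-sided Fisher exact test (chi-square available behind a flag). The Wald
  form was chosen because it reproduces the reference interval for tables of
  this size; exact conditional intervals are wider. When a cell is zero the
  Haldane +0.5 correction is applied to all four cells for the OR/CI only,
  and flagged. Exact p-values below 2.2e-16 are displayed as "<2.2e-16" in
  reports; the raw value is always stored.

Ranking ties (equal composite scores) break by larger |n_WT − n_TG| bound
probes, then lexicographic gene id — an invented but deterministic rule.

## The synthetic study generator

No public accession exists for arrays of this design, so the package ships a
first-class generator (`simulate`) that emulates an Agilent-style mouse
promoter array: ~25 probes per gene on average, 60-mers, spaced every
100–300 bp across a −5.5 kb..+2.5 kb window around each TSS. Genes are
placed with disjoint probe windows on a declared chromosome dictionary
(approximate mouse lengths), both strands, log-uniform gene lengths
(1–50 kb). Because laying probes end-to-start at the stated spacing would
overfill the window (~31 probes), candidate positions are tiled at that
spacing and then thinned uniformly at random to the target mean of 25 —
mirroring the real array's incomplete tiling. A consequence of the disjoint
windows is that divergent-promoter probes cannot arise in simulated data;
the classifier supports them and is tested on crafted annotation.

Gene-level truth is sampled first:

1. `expressed ~ Bernoulli(frac_expressed)` (default 8655/12819 ≈ 0.675).
2. WT binding is sampled conditionally on expression so the *joint* 2×2 cell
   probabilities hit the target odds ratio (default 11.8) with marginal
   `frac_bound_wt` (default 0.296): the joint cell is the single admissible
   root of the Plackett quadratic, solved in closed form
   (`solve_joint_probability`), not by rejection sampling. Re-multiplying
   the solved cells returns the requested OR to 1e-9.
3. TG binding retains each WT-bound gene with `gene_retention_tg`
   (default 0.715) and adds ectopic gains with probability 0.01 among
   WT-unbound genes so all four differential categories are populated.
4. WT-bound genes get `1 + Poisson(0.817)` bound probes (mean 1.82, the
   ratio of bound probes to bound genes in the emulated design), drawn with
   type-biased weights (category mass: Inside 0.7, Promoter 0.2, rest 0.1)
   so inside probes dominate binding. Retained TG genes keep
   `1 + Binomial(n−1, r)` of them, a subset; `r` is calibrated in closed
   form (`calibrated_probe_retention`) so the overall TG/WT bound-probe
   ratio lands on its 0.544 target after accounting for ectopic genes.

Probe-level observables are then drawn conditional on truth. Bound probes:
log2 ratios log-normal with median 1.3 (σ = 0.25); p-values from a
two-piece truncated Beta(0.05, 10) with exactly `bound_p_mass` = 0.97 of
the mass below the 0.005 threshold (so a truly bound gene is almost always
called, but ~3% of single-probe genes are missed — realistic attenuation).
Unbound probes: log2 ratios Normal(0, 0.3); p-values Beta(2, 1)
(`p = sqrt(U)`). The mildly conservative null emulates replicate-averaged
error-model p-values at unenriched probes; a Uniform(0, 1) null would give
each 25-probe unbound gene an ≈12% chance of a false bound call under the
≥1-probe rule, which no array analysis of this design exhibits and which
would swamp the gene-level marginals. Replicates (2 per condition) add
Normal(0, 0.15) noise around the per-probe value.

Expression values (4 samples per condition, 1–3 probesets per gene, chosen
as typical for a two-genotype array comparison): expressed genes sit
log-uniformly in (100·e^0.1, 100·e^3), unexpressed genes mirrored below
100, with 5% log-sd probeset and sample noise. 5% of genes receive a true
fold change (1.5–4×, either direction) in TG, *independent of binding
changes* — so the cross-tab of differential expression against differential
acetylation has no built-in coupling, and the pipeline's independence
properties can be tested.

All randomness derives from a single seed through named per-stage
substreams (`SeedSequence(seed, spawn_key=(stage,))`), so the whole dataset
is byte-for-byte reproducible and adding a stage never perturbs earlier
draws.

### What the generator does not emulate

Raw two-colour intensities, dye bias, spatial artifacts, sequence content,
probe-specific affinity, correlated probe noise along the tiling path, and
the long-tailed probes-per-gene distribution of a real design. Passing the
recovery tests therefore shows that the *pipeline logic* is faithful and
well-calibrated under the declared generative model — not that the model
captures every failure mode of real arrays.

## Numerical choices and degenerate inputs

- Threshold comparisons are inclusive (≤ for p-values and fold, strict >
  for the expression level), matching the stated decision rules.
- Probes missing a p-value in one condition are unbound there, with a
  logged count; probes referencing unannotated genes are dropped from
  gene-level statistics with a warning.
- A probe midpoint exactly at the TSS classifies as Inside; the TES is
  Inside-inclusive; "downstream" extends 1 kb past the TES by default.
- Zero-variance, equal-mean expression groups get p = 1 (UNCHANGED).
- TSV writers render floats with shortest round-trip `repr`, so
  write-then-read reproduces every table bit-exactly; every output header
  records the thresholds and seed.
- Welch rather than pooled t: group variances are not assumed equal.

## Problem sizes

Unit and property tests run on a 2,000-gene study (~50k probes);
parameter-recovery checks and the acceptance script use the 12,819-gene
common-set scale (~320k probes), which simulates and analyses in a few
seconds. Full-array emulation (18,000 genes) is a parameter away
(`SimParams(n_genes=18000)`).

## Known limitations

- The composite score weights all bound probes equally (plain summed
  signal); no per-probe variance weighting.
- The bound/unbound p-value distributions are stylized; only their mass
  around the 0.005 threshold matters downstream, and recovery results are
  insensitive to their shapes beyond that.
- The Wald CI is asymptotic; for tables with small cells the Haldane
  correction keeps it defined but not exact.
- The gene-level TG/WT bound ratio recovered from defaults is expected
  around 0.73, not exactly the 0.715 retention parameter, because ectopic
  gains add TG-only bound genes; the analytic expectation is
  `retention + ectopic·(1−p_bound)/p_bound`.
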