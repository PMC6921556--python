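# Methods

This note documents the models, statistics and design choices behind the
package, what the synthetic generator does and does not emulate, and the
numerical conventions used throughout.

## Study design and coordinates

Three conditions are modelled: untreated (UT), sampled during chronic
exposure (Ni-E) and sampled after the termination of exposure (Ni-W),
with at least two biological replicates each. All genomic intervals are
0-based half-open (BED convention); the annotation's TSS column is a
0-based coordinate. Promoter windows are `[TSS − flank, TSS + flank)`
with `flank = 2000` bp by default, independent of gene strand.

## Expression quantification and differential expression

RPKM is the classical `count / (exonic_kb × library_millions)` with the
library size taken as the raw column sum — no robust size factors, since
the quantity is used descriptively (heatmaps) and the DE test normalizes
separately.

The built-in differential test is a per-gene negative-binomial Wald test
designed to honour the contract (log2FC, raw *p*, BH-adjusted *p*) that
the temporal classifier consumes; externally computed tables (e.g. from a
full DE package) can be substituted via `method="external"`.

* Counts are scaled to a common library size (column sum / mean column
  sum).
* Group means and variances are estimated by moments; the NB dispersion
  α (Var = μ + αμ²) is estimated per gene pooled across both groups.
* Per-gene moment estimates of α at 2–3 replicates are extremely noisy,
  so they are shrunk toward the across-gene median with a prior weight of
  10 df against the residual df — the same empirical-Bayes sharing idea
  used by the established count-model packages (common/trended dispersion,
  variance moderation).
* The Wald statistic uses the moderated variance, and is referred to a
  Student *t* whose df is residual + prior df, reflecting the information
  actually contributing to the variance estimate. With a plain normal
  reference the test is anticonservative at *n* = 3 (empirical size ≈ 0.07
  at nominal 0.05); with a *t* on the residual df alone it is so heavy-
  tailed that genuine 4-fold changes cannot survive BH correction. The
  moderated reference gives an empirical size of ≈ 0.047 under the null
  simulation (NB mean 100, α = 0.05, 3 vs 3) while retaining essentially
  full power for 4-fold effects.
* log2FC is `log2((mean_t + 0.5)/(mean_c + 0.5))` on the normalized
  scale; the 0.5 offset keeps zero-count groups finite. Genes with zero
  counts in every sample of both groups are reported with log2FC 0 and
  *p* = 1.
* BH adjustment is the standard step-up procedure (statsmodels), applied
  over all tested genes.

The 1.5-fold rule is applied to the DE table's log2FC
(`|log2FC| ≥ log2(1.5)`), and both the fold threshold and α are
parameters, since different upstream estimators (shrunken or not) can
legitimately be plugged in.

## Temporal classification

The classifier is a total function over the nine (status_A, status_B)
cells (table in the README). Two conventions are deliberate:

* "Reverted to basal levels" (TU/TD) is operationalized as *not
  significant* in the Ni-W vs UT contrast at the same thresholds — no
  additional test against the Ni-E level is required.
* Genes significant in opposite directions across the two contrasts are
  labelled `discordant` and excluded from all six categories rather than
  silently binned; they are rare under the simulated designs but a
  nonempty possibility on real data.

Summary shares are quoted per group (PU-A and PU-B over all PU, PD-A and
PD-B over all PD, post-exposure share over all persistent genes), rounded
half-up to one decimal.

## Promoter signal and the chromatin dynamic score

Reads are deduplicated on (chrom, start, strand) — the standard
single-end redundancy key — and assigned to promoters by 5′ position only
(start on +, end−1 on −), with no fragment extension or shift: this is
the simplest convention that is exactly testable against a linear-scan
oracle. Window RPKM uses the 4-kb window length and the genome-wide
deduplicated read total of the sample.

The chromatin dynamic score
`CDS_i = √(RPKM_i^t / median^t) − √(RPKM_i^c / median^c)` divides each
gene's promoter signal by the per-sample median over **all** annotated
promoters (zeros included) before the square root; this makes the score
exactly antisymmetric under swapping treatment and control, and exactly
invariant to rescaling the depth of one sample (both verified to 1e−12
in tests). Replicates are averaged at the RPKM level before the formula —
the score is defined on one treatment and one control value per gene, and
averaging is the minimal aggregation. A zero median raises an explicit
error (the promoter universe is then too sparse for the score).

Gene-set comparisons use one-tailed two-sample Student *t*-tests (equal
variance by default, Welch via a flag), with the direction always chosen
by the caller *a priori*. A one-sample against-zero mode is provided for
users who prefer testing the set's CDS against no-change directly. The
degenerate identical-sample case is reported as *t* = 0, *p* = 0.5.

## TF enrichment

The 2×2 table per TF is bound/unbound × foreground/background where the
background is the all-genes promoter-UDHS universe **minus** the
foreground — Fisher's exact test requires disjoint cells. The one-sided
(enrichment) *p* is computed as the hypergeometric upper tail
(vectorized); tests verify it against both `scipy.stats.fisher_exact` and
an exact integer tail-sum oracle over every table with margins ≤ 50.
Peak–UDHS and promoter–UDHS overlap is "≥ 1 bp on half-open intervals".
Ranking is by ascending raw *p* (ties: descending odds ratio, then TF
id), matching how candidate-binder lists are conventionally reported; a
BH column is emitted as supplementary output but does not affect ranks.

## Synthetic data generator

The generator plants known structure at the scale of the real study
design so every downstream stage can be validated against truth labels:

* **Counts**: NB(μ, α) with Var = μ + αμ², baseline mean 100, dispersion
  0.05, two replicates per condition by default, and per-category
  condition means scaled by `fold_change` (default 4) according to the
  category sign pattern.
* **ChIP reads**: 50-bp single-end reads; per-gene promoter pileups are
  Poisson with a condition-independent base rate times per-category,
  per-condition multipliers (TU 4/4/1, PU-A 4/4/4, PU-B 1/1/4, TD 2/2/2,
  PD-A 4/4/4, PD-B 4/4/1, unplanted 1/1/1 for UT/Ni-E/Ni-W), plus a
  uniform genome-wide background (30% of depth). The base rate is
  condition-independent so expected between-condition promoter count
  ratios equal the planted multiplier ratios exactly. Reads at chromosome
  edges are clipped to bounds. Real ChIP depth per sample is not known
  for the motivating design, so the default (200k reads on a 5-Mb toy
  genome) is an exposed, arbitrary choice.
* **Genome layout**: one chromosome, TSSs on a regular grid so promoter
  windows never overlap — promoter attribution is then unambiguous and
  statistic testing is isolated from overlap-resolution policy. An
  explicit sizing error is raised when the genome cannot hold the
  windows.
* **UDHS/TF catalog**: one UDHS per promoter (±300 bp) plus optional
  intergenic distractors; target TFs overlap planted-category promoter
  UDHS at rate 0.8 and everything else at 0.1; null TFs bind uniformly
  at 0.2.
* **qPCR**: log-normal multiplicative noise around per-category true
  fold-enrichment means (persistently upregulated promoters 4 → 1 from
  UT to Ni-W, i.e. loss of the repressive mark; others flat), at least
  two replicates.
* **Seeding**: one master seed; each generator draws from a sub-stream
  derived with a fixed labelled spawn key, so adding a generator never
  perturbs the others and every generator is a pure function of
  (config, seed).

What the generator does **not** emulate: GC/mappability bias, fragment
size distributions, library-composition effects, correlated genes,
baseline expression heterogeneity, multi-chromosome genomes (supported
via config but not defaulted), or peak-shaped ChIP pileups (reads are
uniform within the window). Passing tests therefore demonstrate that the
statistics recover planted structure under idealized noise, not that
they are robust to every artefact of real sequencing data.

## Problem sizes

The shipped tests and the acceptance script run the pipeline at 120–1000
genes, 20k–200k ChIP reads per sample and 200 replications for the
Monte-Carlo calibration checks; these sizes give stable estimates (type-I
error to ±0.003, rank-1 fractions to ±2%) while keeping a full run in
tens of seconds.

## Known limitations

* The built-in DE test is a calibrated stand-in, not a reimplementation
  of a full count-model package (no trended dispersion, no LFC
  shrinkage); external DE tables are first-class inputs for real
  analyses.
* The orchestrator's ChIP stage runs on synthetic reads; file-based ChIP
  analyses go through the library or the `nidyn chip`/`cds` subcommands.
* A single shared annotation is assumed for expression and ChIP
  quantification; cross-assembly gene matching is out of scope.
* The TF enrichment implements the promoter-restricted Fisher ranking
  only, with a toy catalog — not a genome-wide scoring pipeline or a
  curated multi-thousand-dataset TF compendium.
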