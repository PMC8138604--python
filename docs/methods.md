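# Methods

`crossmeth` implements a cross-species DNA-methylation analysis for
tumour/control bisulfite-sequencing studies with a companion human
bead-array comparison: per-CpG differential methylation, region (DMR)
detection, sample clustering, ortholog-level concordance between species,
and a clinical risk-group concordance test. This note describes the
models, the defaults and why they were chosen, what the synthetic data
generator does and does not emulate, and the numerical details.

## Methylation quantities

For a CpG with `n_meth` methylated of `n_total` reads the methylation
level is the beta value `beta = n_meth / n_total` in [0, 1]. Linear
modelling uses the M value

    M = log2((beta + c) / (1 - beta + c)),   c = 0.01,

a logit-like transform with a stabilising constant that keeps M finite at
beta = 0 and 1 and gives approximately homoscedastic residuals. The
transform is inverted exactly by `m_to_beta`, and the package reports all
effect sizes on the beta scale (differences of methylation fractions),
where thresholds like "a 30% difference" live.

Quality filters for sequencing data: a locus is kept when (i) its
minimum coverage across samples is >= 8x and (ii) its methylated reads
summed over all samples reach 6. Rule (i) is read as the across-sample
minimum so that every sample contributes an informative beta; rule (ii)
as the across-sample sum, i.e. at least some methylation must be present
somewhere. The two rules commute and the filter is idempotent. Array
probes are instead dropped when their detection p-value exceeds 0.01
(the usual bead-array convention; configurable) in any sample. No
between-sample normalisation is applied: beta and M are already
scale-free per sample.

Technical replicates are merged by summing counts per locus before any
analysis; loci covered in only one replicate keep their counts.

## Per-CpG differential methylation

Each locus gets an ordinary least-squares fit of M on an intercept plus
a two-group indicator; the coefficient is the group difference on the M
scale, with residual variance s² on d = n − 2 degrees of freedom.
Variances are then shrunk by empirical Bayes: the prior
s² ~ s0²·χ²(d0)/d0 is estimated by matching the first two moments of
log s² to its theoretical scaled-F form (using the digamma/trigamma
identities), and the posterior variance is

    s²_post = (d0·s0² + d·s²) / (d0 + d).

The moderated t is the coefficient over its posterior standard error,
referred to a t distribution with d0 + d degrees of freedom. When the
moment equation has no finite solution (observed spread of log s² at or
below its pure-sampling component) d0 is capped at 10⁶, which behaves as
full shrinkage with a normal reference; when fewer than 10 loci are
usable the function falls back to d0 = 0 (ordinary t-tests) with a
warning. The trigamma inverse is solved by Newton iteration. With all
sample variances exactly identical the common value itself is taken as
the prior and the posterior is constant — the no-information degenerate
case.

Benjamini–Hochberg step-up controls the FDR over the tested loci
(untestable loci — fewer than two non-missing values in a group — are
excluded from the denominator). Tests are two-sided; significance
thresholds are FDR < 0.10 for sequencing data and FDR < 0.05 for the
better-powered array comparisons. Per-locus direction (hyper/hypo) is
the sign of the beta-scale difference.

## DMR detection

Candidate regions are agglomerated deterministically: per chromosome,
CpGs covered (>= 1 read) in at least 75% of samples are scanned left to
right; from each anchor the window grows to the rightmost CpG within
200 bp (1-based inclusive width), and a maximal window with >= 15
members is emitted, the scan resuming after it, so regions never
overlap. The thresholds (15 CpGs / 200 bp / 75% presence) are the
classical clusterSites-style rule; the greedy maximal-window scan was
chosen because it is deterministic and testable against exhaustive
enumeration.

Each candidate is tested with a beta-binomial regression over its
(CpG, sample) count observations: methylated counts follow a
beta-binomial with logit-linear mean (intercept + group) and a single
region-level dispersion rho, fitted by maximum likelihood; the p-value is
the likelihood-ratio test of the group coefficient against chi-squared
with 1 df. One dispersion per region is the smallest model that captures
extra-binomial variation between samples; at rho -> 0 the test reduces to
a logistic-binomial GLM LRT (verified against statsmodels to 1e-3).

Region summaries follow the top-DMR-table convention: the control and
tumour medians are medians over member CpGs of the per-CpG group-mean
beta, and the reported difference is the median over member CpGs of the
per-CpG group difference — deliberately *not* the difference of the two
medians, which is a different number once CpG effects are heterogeneous.
Regions are BH-adjusted over the converged tests (FDR < 0.10, matching
the CpG-level sequencing threshold) and ranked by |median difference|
descending, ties broken by (chrom, start). Gene context is `genic` when
the region overlaps a gene body, `promoter` when it only overlaps the
1,500 bp window upstream of a TSS, else `intergenic`.

Coordinates are 1-based inclusive everywhere internally — so a region
spanning positions 57,391,482–57,391,657 has width 176 bp — and are
converted to 0-based half-open only inside the BED/BedGraph writers.

## Clustering and global methylation

Sample clustering uses the 10,000 most variable loci (across-sample
variance of beta; ties broken by position; fewer loci = keep all with a
warning), Euclidean distances between sample beta profiles, and average
linkage by default (the paper-style figure's linkage is not
reconstructible; single/complete/ward are available, as is an optional
covariance-whitened distance mode). Group-level methylation is compared
on one number per sample — the sample's mean beta over retained loci —
with one-way ANOVA and Tukey HSD contrasts (> 2 groups); the two-group
case equals the pooled two-sided t-test exactly.

## Orthologs and cross-species concordance

Mouse -> human ortholog candidates (confidence flag plus homology
percentage) are resolved by a fixed cascade: restrict to high-confidence
candidates when any exist; keep the maximal homology (compared at 4
decimal places to avoid float-noise nondeterminism); prefer
case-insensitively identical gene symbols among ties (FILIP1L vs
Filip1l); keep all survivors otherwise. The result is independent of
input row order.

Loci map to every gene whose body or 1,500 bp upstream promoter window
contains them (a locus over two opposite-strand genes counts for both);
per gene and dataset the package records the number of tested and
significant loci, the maximal |delta beta| among significant loci, and
the direction at that strongest locus — a deterministic per-gene
direction dominated by the strongest signal. A gene "has DM" with >= 1
significant locus and "has clear DM" when the maximal |delta beta| is
also >= 0.30.

Three cross-species questions are asked through the ortholog map:
enrichment (2x2 Pearson chi-squared, no continuity correction,
Bonferroni across human subtypes) of human DM among orthologs of
mouse-DM genes versus all other tested human genes; direction
concordance per subtype among genes DM in both species, with a 2x2
chi-squared comparing subtypes; and the major-relevance list — genes
clearly DM in both species, sorted by the smaller of the two maximal
|delta beta| values. Continuity correction is off because the intended
comparisons involve large counts; the helper warns when an expected cell
is below 5.

The clinical check restricts two contrasts to one gene's loci: the
high-vs-low-risk contrast (significant at FDR < 0.05) and the
tumour-vs-control contrast (significant and |delta beta| > 0.30). Over
the n shared loci, the count k whose signs agree is tested one-sided
against Binomial(n, 1/2) with the exact tail sum — one-sided because the
direction is pre-specified by the tumour contrast; for the canonical
8-of-9 case p = 10/512 ≈ 0.0195.

## BS vs oxBS (5hmC) noise check

Standard bisulfite conversion reads 5mC + 5hmC, the oxidative protocol
5mC only, so the per-locus difference of paired beta matrices estimates
hydroxymethylation (possibly negative through noise). The dataset-level
verdict is "indistinguishable from noise" when the mean estimate's
magnitude does not exceed 2 standard errors of the mean (configurable);
under a simulated null the verdict is "noise" in >= 95% of seeds. No
joint maximum-likelihood BS/oxBS model is attempted.

## Synthetic data generator

The generator produces the study conditions every test runs under:

* 500 genes laid out deterministically over 19 chromosomes, each with
  one dense cluster of 20 CpGs at 9 bp spacing (so every cluster is a
  valid region candidate), 10,000 loci in total;
* baseline beta per CpG from a bimodal mixture — 60% Beta(2, 18) (low
  mode, mean 0.1) and 40% Beta(18, 2) (high mode, mean 0.9) — the
  hallmark shape of CpG methylation;
* coverage per locus and sample from a negative binomial with mean 30
  and size 8; methylated reads from a beta-binomial with intra-class
  correlation rho = 0.02 (biological overdispersion between samples);
  zero-coverage records are dropped at read time;
* 6 control and 6 tumour samples;
* DMRs planted in 5% of genes: cluster baselines drawn from
  U(0.15, 0.45) and tumour methylation shifted by the per-CpG logit
  offset that maps baseline to baseline + 0.40 exactly in expectation —
  effects are injected on the logit scale so beta stays in [0, 1]
  without clipping, but the target is stated on the beta scale where
  every downstream threshold lives;
* an optional global tumour shift (`global_shift_beta`, e.g. +0.03 mean
  beta) injected the same way at every locus, emulating a globally
  hypermethylated subtype;
* a companion array per human subtype: probes per ortholog gene with
  logit-normal noise (sd 0.25) around group means, planted human DM in
  genes shared with the mouse truth whose direction agrees with the
  mouse direction with a configurable probability (defaults 0.825 and
  0.657 for the stem-like and keratinocyte-like subtypes in the
  orchestrated study), and a 5% fraction of probes failing detection in
  one sample;
* an ortholog candidate table with controlled ambiguity: every gene has
  a correct high-confidence candidate, ~10% get a lower-homology decoy
  and ~10% an equal-homology tie that only the symbol rule can break.

Everything is deterministic under the configured seed, and the
orchestrated run writes and re-reads all inputs through the real file
writers/readers, so synthetic runs exercise the I/O paths.

What the generator does **not** emulate: read-level artefacts (mapping
bias, bisulfite conversion failure, strand effects), genome-realistic
CpG density and gene structure, correlated methylation along the genome
beyond the planted cluster structure, batch or age/sex covariates, and
array probe-type chemistry differences. Passing tests therefore show the
statistical machinery is correct and calibrated under the stated
generative model, not that real-data artefacts are handled.

The defaults are sized for a desk-scale study (full pipeline in well
under a minute for the per-CpG stages, a few seconds for the
beta-binomial stage per ~500 regions); they are the package's chosen
study conditions, not tuned per dataset.

## Numerical choices and degenerate inputs

* Beta-binomial fits use the log-likelihood written directly in
  gammaln/betaln form and L-BFGS-B from two starts (pooled and
  group-split initial logits; dispersion started at rho ≈ 0.018 via its
  logit); non-convergence flags the region, which is excluded from the
  BH denominator with a warning.
* rho and fitted means are clipped to [1e-9, 1 − 1e-9]; linear
  predictors to ±30.
* Zero residual variance with zero effect gives p = 1 (no evidence);
  zero residual variance with a non-zero effect gives p = 0 (infinite
  t); both only arise in toy data.
* The d0 cap of 10⁶ stands in for an infinite prior df so no code path
  special-cases infinity.
* BedGraph emission: significant loci as +beta, non-significant as
  −beta; a non-significant beta of exactly 0 is emitted as the literal
  `-0` so the significance flag survives the round trip except at the
  unavoidable |beta| = 0 ambiguity for parsers that normalise −0.
* Empty inputs: empty coverage file -> empty table with a warning; empty
  p-vector -> empty q-vector; empty region list -> header-only table.

## Known limitations

* The BiSeq-style smoothing of methylation levels along the genome is
  not implemented; regions are tested on raw counts.
* Array analysis is unpaired; matched designs are not modelled.
* The beta-binomial LRT's chi-squared reference is asymptotic; for very
  few (CpG, sample) observations the regional p is approximate.
* Enrichment/concordance chi-squared tests are asymptotic and the
  helper only warns (does not switch to an exact test) on small expected
  counts.
* Gene direction summarised at the single strongest locus ignores
  within-gene heterogeneity by design.
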