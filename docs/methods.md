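# Methods

## Model and test

At a biallelic SNP locus observed across a cohort, let *p* be the
reference-allele frequency and *q* = 1 − *p*. Under panmixia, genotypes AA,
Aa, aa occur at Hardy–Weinberg proportions *p*², 2*pq*, *q*². An
enrichment-based methylation assay captures only methylated fragments, so
genotype calling is presence/absence: a sample is called heterozygous iff
its reads show both alleles, homozygous iff they show one, missing iff it
has no reads (for this assay, usually an unmethylated locus rather than a
failed measurement). Stable monoallelic methylation hides one allele of
every heterozygote and shifts heterozygotes into the homozygote classes;
the test statistic is the count of called heterozygotes among the samples
with non-zero coverage.

The null distribution conditions on the observed per-locus allele
frequency estimate and the observed per-sample coverages. Allele
frequencies are estimated from genotypes, p̂ = (2·n_AA + n_Aa)/(2·n_typed),
not from read abundances — this makes the estimate insensitive to residual
reference-alignment bias in read counts. A typed sample with coverage *c*
is called heterozygous under the null with probability
h(c) = 2p̂q̂·(1 − 2·(1/2)^c); the null heterozygote count is the sum of
independent Bernoulli(h(cᵢ)) draws (a Poisson-binomial). Sampling groups
samples by unique coverage and sums Binomial(n_c, h(c)) draws, which is
distributionally identical to simulating genotypes and reads per sample
(`simulate_null_het_count` implements the literal generative version, and
the test suite checks both against exhaustive enumeration of the
genotype × read outcome space).

Monte-Carlo P-values use the add-one estimator P = (1 + #{null ≤
observed})/(1 + B), so P is never 0 and the minimum attainable stage-2 P
(10⁻⁶ at B₂ = 10⁶) sits well below the operating BH threshold. The screen
runs two stages — B₁ = 1,000 for all testable loci, then B₂ = 10⁶ for
loci with stage-1 P ≤ 0.005 — purely as a compute-saving device; the
stage-1 P is kept as the final P for gated-out loci. Significance is
called by Benjamini–Hochberg over the final P-values of **all** tested
loci at q = 0.1. With m = 486,090 tests and 80 rejections the BH critical
value is 80·0.1/486,090 ≈ 1.6·10⁻⁵, which is the reproduction check for
the bundled discovery summary. Loci with p̂ ∈ {0, 1} or no typed samples
are untestable and reported with a reason. Per-locus RNG substreams are
keyed by (seed, chromosome, position), so results are independent of
processing order and safely parallelisable.

A reference-bias quality control compares pooled per-sample coverages of
hom-ref versus hom-alt calls at significant loci with a two-sided Wilcoxon
rank-sum test (exact for small groups). It is reported, never used to
filter: a small P would flag alignment bias toward the reference allele.

## Pre-processing

**SNP tracing** keeps candidate mismatch positions that are catalogued
SNVs with compatible alleles and at least one alternative read anywhere in
the cohort. **Filtering** keeps loci with major-allele frequency < 0.9 and
total coverage ≥ 350 on autosomes; on the X chromosome only female samples
contribute (both to the frequency and the coverage sum) and the threshold
relaxes to 250, roughly 1× per contributing sample. Male counts at
retained X loci are zeroed. The MAF filter is re-applied implicitly by the
screen's untestability rule after correction; corrected frequencies
crossing 0.9 are rare but possible, and re-filtering is the stricter
choice.

**Sequencing-error correction** is an iterative empirical-Bayes cleanup.
For each (locus, sample) profile with both alleles present, with n = total
reads and per-locus p̂ from the current genotype calls, it compares

* posterior(het) ∝ 2p̂q̂ · Binom(n, ½) at the ref count,
* posterior(hom-ref) ∝ p̂² · Binom(n, ε) at the alt count,
* posterior(hom-alt) ∝ q̂² · Binom(n, ε) at the ref count,

with ε = 0.0025 the per-read probability of miscalling toward the other
retained allele (a single scalar, not ε/3 per alternative base — the
conservative reading). If a homozygous hypothesis strictly wins, the
minority reads are deleted; ties keep the heterozygote, again the side
that disfavours calling monoallelic methylation. Frequencies are
re-estimated between rounds; two rounds are applied. Both the low ε and
the small round count deliberately under-correct: deleting genuine
heterozygote reads would manufacture heterozygote deficit, while leaving a
few error-induced false heterozygotes only masks signal.

## Downstream analyses

**Functional enrichment.** Each significant locus distributes one unit of
weight equally over the *distinct* functional classes (promoter, exon,
intron) of the intervals overlapping it on either strand; no overlap means
intergenic = 1. "Distinct classes" rather than distinct intervals: a gene
with ten transcripts sharing an exon should not dilute its own class. The
promoter is the 2,000 bp upstream of a transcription start through the TSS,
strand-aware. The null resamples, per chromosome and without replacement,
as many universe loci as that chromosome has significant loci (1,000
draws), applies the same fractional classification to the sampled loci,
and doubles the smaller add-one tail for a two-sided empirical P capped at
1.

**Bisulfite validation.** Per candidate locus and heterozygous WGBS
sample, CpG calls partitioned by SNP allele form a 2×2 table; the Pearson
chi-square (no continuity correction) measures allele-dependent
methylation. The permutation null fixes both margins — the conditional
hypergeometric null — with B = 2,000 replicates per sample; the global
locus statistic sums the usable per-sample chi-squares, with each null
replicate summing one permuted value per sample. Uncovered or homozygous
samples and degenerate tables (a zero margin) are excluded with a recorded
reason. C/T and G/A SNPs are confounded with bisulfite conversion; they
are flagged in the output but still tested so results stay comparable.
Because the conditional statistic is discrete, the Monte-Carlo P is exactly
calibrated only in the deep-coverage limit; at realistic depths it is
conservative (P(P ≤ α) ≤ α), never anticonservative. The test suite checks
uniformity at high call depth and conservativeness at moderate depth.

**ASE validation.** Each variant site with read depth ≥ 10 (bases of
quality ≥ 13 counted upstream) gets an exact two-sided binomial test at
0.5, using the minimum-likelihood two-sided convention (the sum of
probabilities of all outcomes no more likely than the observed one). BH at
q = 0.01 runs within each tissue — the FDR scope is configurable, but
per-tissue matches testing on a per-site per-tissue basis. A gene in a
tissue is ASE with ≥ 2 significant sites, biallelic with ≥ 2 tested but
< 2 significant, and not assessable otherwise; requiring two sites guards
against single-site artefacts from residual mapping bias or genotype
error.

## The simulator

`simulate_methylcap` draws, per locus: an allele frequency (fixed or
uniform on [0.2, 0.8] by default); HWE genotypes for each sample; a
per-sample, locus-level methylation event with probability `meth_prob`
(default 0.8) — unmethylated samples are uncovered, reproducing
enrichment dropout. At biallelic loci a methylated sample has **both**
carried alleles captured (that is what biallelic methylation means; each
methylated copy contributes an independent read depth). At monoallelic
loci every methylated sample carries exactly one methylated copy; for
heterozygotes the side is chosen once per sample and is stable, so the
sample reads as homozygous. A `mosaic` mode instead mixes both alleles
into the heterozygote's reads (X-inactivation-like random-per-cell
choice), which the screen should — and does — fail to detect. Read depth
per methylated copy is negative-binomial with mean 10 and dispersion 10
(Poisson as the infinite-dispersion limit); each read flips to the other
allele with probability ε = 0.0025; X loci yield no reads in males.

Defaults (300 samples, 500 loci, depth 10, meth_prob 0.8) describe a
cohort of the scale where a ~1× per-sample coverage filter is meaningful.
What the simulator does **not** model: capture-efficiency variation with
CpG density or fragment GC content, read-level artefacts (duplicates,
mapping ambiguity), linkage between nearby SNPs, population substructure
(the HWE assumption is exact in the generator, whereas real cohorts
deviate from panmixia), and allele-specific capture bias. Passing
calibration and recovery tests on these cohorts therefore demonstrate
correctness of the statistical machinery under the model's assumptions,
not robustness to every failure mode of real enrichment data — which is
why the bisulfite and expression validations exist as orthogonal checks.

## Numerical and design choices

* Monte-Carlo P-values always use the add-one rule; empirical two-sided
  P-values double the smaller add-one tail and cap at 1.
* BH is computed directly from the step function (sort, largest rank k
  with p(k) ≤ kq/m); the critical value is kq/m, 0 when nothing passes.
  The implementation is cross-checked against statsmodels in the tests.
* Error-correction ties (including the degenerate p̂ ∈ {0,1} prior) keep
  the heterozygote; an exact tie between the two homozygote hypotheses
  resolves to the majority allele.
* The null does not re-inject sequencing errors: the screen's input is
  corrected data, in which error-induced heterozygotes have already been
  removed, and the simulator-based calibration study confirms type-I
  control for the corrected-data pipeline.
* Zero-coverage samples are excluded from both the observed statistic and
  the null; in enrichment data they are expected (methylation-negative),
  so treating them as missing genotypes would be wrong and treating them
  as homozygotes worse.
* Reported study sizes: null calibration uses 500 loci × 300 samples with
  B₂ = 2·10⁴ for the ~0.5% of loci passing the gate; the power study uses
  400 loci (5% monoallelic) × 300 samples with B₂ = 10⁵. These are the
  package's default reproduction-study sizes and complete in seconds.

## Known limitations

* The two-allele model drops third alleles at multi-allelic catalogue
  entries (keeping the two most abundant); truly tri-allelic loci are not
  handled.
* The screen detects *stable* monoallelic methylation only; mosaic
  (random-per-cell) methylation is invisible by design, and the X
  chromosome in females is expected to yield nothing for exactly this
  reason.
* Power depends on cohort size and allele frequency through 2pq·n_typed;
  loci with MAF near the 0.9 filter boundary carry little information.
* The bisulfite validation consumes per-allele call counts; read
  alignment, methylation calling and conversion-efficiency estimation are
  upstream concerns.
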