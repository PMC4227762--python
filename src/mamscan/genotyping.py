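"""From allele counts to genotype calls.

In enrichment-based methylation sequencing only methylated fragments are
captured, so genotype calling is purely presence/absence: a sample showing
reads for both alleles is heterozygous, a sample showing one allele is
homozygous for it, and an uncovered sample is missing (which for a
methylation-enriched library usually means the locus is unmethylated in
that sample, not that the assay failed).

The module covers the four pre-processing steps upstream of the
Hardy-Weinberg screen:

1. ``trace_snps`` — keep only candidate mismatch positions that are known
   SNVs with compatible alleles and at least one alternative read.
2. ``call_genotypes`` / ``estimate_allele_frequencies`` — presence/absence
   genotypes and genotype-based allele-frequency estimates
   p̂ = (2·n_hom_ref + n_het) / (2·n_typed); estimating p from genotypes
   rather than read abundances minimises reference-alignment bias.
3. ``filter_loci`` — major-allele-frequency < 0.9 and total-coverage
   thresholds (350 autosomes, 250 on X, where only female samples count).
4. ``correct_sequencing_errors`` — an iterative empirical-Bayes cleanup:
   per (locus, sample) profile with both alleles present, compare the
   posterior of true heterozygosity against homozygosity-plus-sequencing-
   error and delete the minority reads when a homozygous explanation wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import (
    AlleleCountTable,
    ConfigurationError,
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    GT_MISSING,
    SnpCatalogue,
)

__all__ = [
    "ErrorModel",
    "GenotypeMatrix",
    "LocusSummary",
    "trace_snps",
    "call_genotypes",
    "estimate_allele_frequencies",
    "filter_loci",
    "correct_sequencing_errors",
    "locus_summaries",
]


@dataclass(frozen=True)
class ErrorModel:
    """Sequencing-error model for the Bayesian correction.

    epsilon is the per-read probability of reporting the opposite retained
    allele (default 0.25%, a deliberately low estimate so the correction
    stays conservative); n_rounds is how many correction/re-estimation
    iterations are applied (default 2).
    """

    epsilon: float = 0.0025
    n_rounds: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon < 0.5:
            raise ConfigurationError(f"epsilon must be in [0, 0.5), got {self.epsilon}")
        if self.n_rounds < 1:
            raise ConfigurationError("n_rounds must be >= 1")


@dataclass
class GenotypeMatrix:
    """Presence/absence genotype calls plus per-cell coverage.

    ``calls`` uses the integer codes from :mod:`mamscan.datamodel`
    (missing=0, hom_ref=1, het=2, hom_alt=3); shape (n_loci, n_samples).
    """

    calls: np.ndarray
    coverage: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        if self.calls.shape != self.coverage.shape:
            raise ValueError("calls/coverage shape mismatch")
        if ((self.calls == GT_MISSING) != (self.coverage == 0)).any():
            raise ValueError("missing call must coincide with zero coverage")


@dataclass
class LocusSummary:
    """Everything the Hardy-Weinberg null needs for one locus."""

    chrom: str
    pos: int
    p_hat: float          # ref-allele frequency from genotype calls
    het_observed: int
    coverages: np.ndarray  # per typed sample (coverage > 0 only)

    @property
    def q_hat(self) -> float:
        return 1.0 - self.p_hat

    @property
    def n_typed(self) -> int:
        return len(self.coverages)

    @property
    def total_coverage(self) -> int:
        return int(self.coverages.sum())

    @property
    def testable(self) -> bool:
        return self.n_typed > 0 and 0.0 < self.p_hat < 1.0


def trace_snps(observed: AlleleCountTable, catalogue: SnpCatalogue) -> AlleleCountTable:
    """Intersect candidate mismatch positions with the known-SNV catalogue.

    A locus is retained iff (chrom, pos) is catalogued, both its alleles are
    among the catalogued alleles, and at least one sample carries >= 1
    alternative read (a position never showing a mismatch carries no SNP
    evidence).
    """
    keep = np.zeros(observed.n_loci, dtype=bool)
    any_alt = observed.alt.sum(axis=1) > 0
    for i in range(observed.n_loci):
        if not any_alt[i]:
            continue
        row = observed.loci.iloc[i]
        allowed = catalogue.alleles(str(row["chrom"]), int(row["pos"]))
        if allowed is None:
            continue
        keep[i] = row["ref"] in allowed and row["alt"] in allowed
    return observed.subset_loci(keep)


def call_genotypes(table: AlleleCountTable) -> GenotypeMatrix:
    """Presence/absence genotype calls from ref/alt counts."""
    calls = np.full(table.ref.shape, GT_MISSING, dtype=np.int8)
    has_ref = table.ref > 0
    has_alt = table.alt > 0
    calls[has_ref & ~has_alt] = GT_HOM_REF
    calls[~has_ref & has_alt] = GT_HOM_ALT
    calls[has_ref & has_alt] = GT_HET
    return GenotypeMatrix(calls, table.coverage)


def estimate_allele_frequencies(
    genotypes: GenotypeMatrix, sample_mask: np.ndarray | None = None
) -> np.ndarray:
    """Per-locus ref-allele frequency p̂ = (2 n_RR + n_het) / (2 n_typed).

    Missing calls are excluded; loci with zero typed samples get NaN
    (flagged unusable downstream). ``sample_mask`` restricts the estimate
    to a sample subset (females for X-linked loci).
    """
    calls = genotypes.calls
    if sample_mask is not None:
        calls = calls[:, np.asarray(sample_mask, dtype=bool)]
    n_rr = (calls == GT_HOM_REF).sum(axis=1)
    n_het = (calls == GT_HET).sum(axis=1)
    n_typed = (calls != GT_MISSING).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_hat = np.where(n_typed > 0, (2.0 * n_rr + n_het) / (2.0 * n_typed), np.nan)
    return p_hat


def filter_loci(
    table: AlleleCountTable,
    maf_max: float = 0.90,
    min_cov_autosome: int = 350,
    min_cov_x: int = 250,
) -> AlleleCountTable:
    """Retain informative loci: MAF < maf_max and total coverage above the
    chromosome-class threshold.

    X-linked loci are evaluated on the female subset only (both the
    frequency and the coverage sum), and male counts at retained X loci are
    zeroed so downstream stages never see them. Raises
    :class:`ConfigurationError` if X loci are present but no sample has sex
    metadata.
    """
    x_loci = table.x_mask()
    female = table.female_mask()
    if x_loci.any() and not (table.samples["sex"] != "unknown").any():
        raise ConfigurationError(
            "X-chromosome loci present but sample sheet carries no sex metadata"
        )

    genotypes = call_genotypes(table)
    p_auto = estimate_allele_frequencies(genotypes)
    coverage = table.coverage
    total_auto = coverage.sum(axis=1)

    maf = np.maximum(p_auto, 1.0 - p_auto)
    keep = (~np.isnan(p_auto)) & (maf < maf_max) & (total_auto >= min_cov_autosome)

    if x_loci.any():
        p_x = estimate_allele_frequencies(genotypes, sample_mask=female)
        total_x = coverage[:, female].sum(axis=1)
        maf_x = np.maximum(p_x, 1.0 - p_x)
        keep_x = (~np.isnan(p_x)) & (maf_x < maf_max) & (total_x >= min_cov_x)
        keep = np.where(x_loci, keep_x, keep)

    out = table.subset_loci(keep)
    out_x = out.x_mask()
    if out_x.any():
        male_or_unknown = ~out.female_mask()
        out.ref[np.ix_(out_x, male_or_unknown)] = 0
        out.alt[np.ix_(out_x, male_or_unknown)] = 0
    return out


def _hom_beats_het(ref, alt, p, epsilon):
    """Vectorised posterior comparison for profiles with both alleles seen.

    Returns (hom_wins, majority_is_ref): hom_wins marks cells where the
    best homozygous hypothesis has strictly larger posterior than
    heterozygosity (ties keep the heterozygote — the conservative side).
    """
    n = ref + alt
    q = 1.0 - p
    with np.errstate(divide="ignore"):
        log_het = np.log(2.0 * p * q) + stats.binom.logpmf(ref, n, 0.5)
        log_rr = 2.0 * np.log(p) + stats.binom.logpmf(alt, n, epsilon)
        log_aa = 2.0 * np.log(q) + stats.binom.logpmf(ref, n, epsilon)
    # best homozygote; exact tie between the two homs -> side of the majority allele
    rr_best = (log_rr > log_aa) | ((log_rr == log_aa) & (ref >= alt))
    log_hom = np.where(rr_best, log_rr, log_aa)
    hom_wins = log_hom > log_het
    return hom_wins, rr_best


def correct_sequencing_errors(
    table: AlleleCountTable, model: ErrorModel = ErrorModel()
) -> AlleleCountTable:
    """Iterative Bayesian sequencing-error correction.

    Per round: estimate p̂ per locus from current genotype calls; for each
    (locus, sample) with both alleles observed compare

    * posterior(het)     ∝ 2p̂q̂ · Binom(n, 1/2) at the ref count,
    * posterior(hom_ref) ∝ p̂²  · Binom(n, ε) at the alt count,
    * posterior(hom_alt) ∝ q̂²  · Binom(n, ε) at the ref count,

    and where a homozygous hypothesis strictly wins, delete the minority
    reads. Frequencies are re-estimated from the corrected genotypes between
    rounds. Counts never increase and no new allele is ever created.
    """
    ref = table.ref.copy()
    alt = table.alt.copy()
    for _ in range(model.n_rounds):
        work = AlleleCountTable(table.loci.copy(), table.samples.copy(), ref, alt)
        genotypes = call_genotypes(work)
        p_hat = estimate_allele_frequencies(genotypes)
        both = (ref > 0) & (alt > 0)
        if not both.any():
            break
        li, sj = np.nonzero(both)
        p_cell = np.clip(p_hat[li], 0.0, 1.0)
        hom_wins, rr_best = _hom_beats_het(ref[both], alt[both], p_cell, model.epsilon)
        to_rr = both.copy()
        to_rr[li, sj] = hom_wins & rr_best
        to_aa = both.copy()
        to_aa[li, sj] = hom_wins & ~rr_best
        alt[to_rr] = 0
        ref[to_aa] = 0
    return AlleleCountTable(table.loci.copy(), table.samples.copy(), ref, alt)


def locus_summaries(
    table: AlleleCountTable, genotypes: GenotypeMatrix | None = None
) -> list[LocusSummary]:
    """Per-locus summaries for the screen (typed samples only)."""
    if genotypes is None:
        genotypes = call_genotypes(table)
    p_hat = estimate_allele_frequencies(genotypes)
    coverage = table.coverage
    out = []
    for i in range(table.n_loci):
        typed = coverage[i] > 0
        row = table.loci.iloc[i]
        out.append(
            LocusSummary(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                p_hat=float(p_hat[i]) if typed.any() else float("nan"),
                het_observed=int((genotypes.calls[i] == GT_HET).sum()),
                coverages=coverage[i, typed].copy(),
            )
        )
    return out
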