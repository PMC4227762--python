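"""Coverage-conditioned Hardy-Weinberg heterozygote-deficit screen.

The detector's premise: at a biallelically methylated SNP locus, samples
behave like a Hardy-Weinberg population — genotypes AA/Aa/aa occur at
p², 2pq, q² — and a heterozygote is *observed* as such only if its reads
happen to show both alleles. Monoallelic methylation hides one allele of
every heterozygote from the enrichment assay, so heterozygotes vanish and
the locus shows a heterozygote deficit beyond what low coverage alone
explains.

The null distribution for a locus conditions on exactly what was observed:
the genotype-based allele frequency p̂ and the per-sample coverages. For a
typed sample with coverage c the chance of being *called* heterozygous is

    h(c) = 2·p̂·q̂ · (1 − 2·(1/2)^c)

(the genotype must be Aa and the c reads, each picking an allele with
probability 1/2, must show both). The null heterozygote count is the sum of
independent Bernoulli(h(c_i)) over typed samples; Monte-Carlo P-values use
the add-one estimator P = (1 + #{null ≤ observed}) / (1 + B), so P is never
zero. The screen runs in two stages — a cheap pass at B1 iterations gating
loci with P ≤ stage1_alpha into an expensive pass at B2 — followed by
Benjamini-Hochberg significance calling over all tested loci.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    AlleleCountTable,
    ConfigurationError,
    GT_HOM_ALT,
    GT_HOM_REF,
)
from .genotyping import GenotypeMatrix, LocusSummary, call_genotypes, locus_summaries

__all__ = [
    "ScreenConfig",
    "HweTestResult",
    "het_call_probability",
    "simulate_null_het_count",
    "het_deficit_pvalue",
    "two_stage_screen",
    "bh_threshold",
    "reference_bias_qc",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Two-stage screen settings (defaults follow the published pipeline)."""

    b1: int = 1_000
    stage1_alpha: float = 0.005
    b2: int = 1_000_000
    fdr_q: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.b1 < 1 or self.b2 < 1:
            raise ConfigurationError("iteration counts must be >= 1")
        if not 0.0 < self.stage1_alpha < 1.0:
            raise ConfigurationError("stage1_alpha must be in (0, 1)")
        if not 0.0 < self.fdr_q < 1.0:
            raise ConfigurationError("fdr_q must be in (0, 1)")


@dataclass
class HweTestResult:
    chrom: str
    pos: int
    het_observed: int
    n_typed: int
    p_hat: float
    p_stage1: float | None
    p_stage2: float | None
    significant: bool = False
    reason: str | None = None  # set when the locus is untestable

    @property
    def p_final(self) -> float | None:
        return self.p_stage2 if self.p_stage2 is not None else self.p_stage1


def locus_rng(seed: int, chrom: str, pos: int, stage: int = 1) -> np.random.Generator:
    """Deterministic per-locus RNG substream keyed by (seed, chrom, pos).

    Processing order and parallelism therefore never change results.
    """
    key = (zlib.crc32(chrom.encode()), pos & 0xFFFFFFFF, stage)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def het_call_probability(p_hat: float, coverages: np.ndarray) -> np.ndarray:
    """Per-sample probability of being called heterozygous under the null."""
    c = np.asarray(coverages, dtype=np.float64)
    return 2.0 * p_hat * (1.0 - p_hat) * (1.0 - np.exp2(1.0 - c))


def simulate_null_het_count(summary: LocusSummary, rng: np.random.Generator) -> int:
    """One null replicate, simulated at the generative level.

    Draw a genotype per typed sample at (p̂², 2p̂q̂, q̂²); homozygotes emit
    only their allele; a heterozygote with coverage c splits c reads
    Bernoulli(1/2) between alleles and is counted heterozygous only if both
    appear. Used for transparency and as a cross-check of the grouped
    binomial sampler inside :func:`het_deficit_pvalue`.
    """
    if not summary.testable:
        raise ValueError("locus untestable (p_hat degenerate or no typed sample)")
    p = summary.p_hat
    u = rng.random(summary.n_typed)
    is_het = (u >= p * p) & (u < p * p + 2 * p * (1 - p))
    het_calls = 0
    for c in summary.coverages[is_het]:
        ref_reads = rng.binomial(int(c), 0.5)
        if 0 < ref_reads < c:
            het_calls += 1
    return het_calls


def _null_het_counts(
    summary: LocusSummary, B: int, rng: np.random.Generator
) -> np.ndarray:
    """B null heterozygote counts, drawn by grouping equal-coverage samples.

    Samples sharing coverage c share h(c), so the Poisson-binomial total is
    a sum of Binomial(n_c, h(c)) draws — identical in distribution to
    simulating every sample, but O(#unique coverages) per replicate.
    """
    unique_c, counts = np.unique(summary.coverages, return_counts=True)
    h = het_call_probability(summary.p_hat, unique_c)
    total = np.zeros(B, dtype=np.int64)
    for n_c, h_c in zip(counts, h):
        if h_c > 0.0:
            total += rng.binomial(int(n_c), h_c, size=B)
    return total


def het_deficit_pvalue(
    summary: LocusSummary, B: int, rng: np.random.Generator
) -> float:
    """One-sided Monte-Carlo P for a heterozygote deficit at one locus."""
    if not summary.testable:
        raise ValueError("locus untestable")
    null_counts = _null_het_counts(summary, B, rng)
    hits = int((null_counts <= summary.het_observed).sum())
    return (1 + hits) / (1 + B)


def two_stage_screen(
    table: AlleleCountTable,
    cfg: ScreenConfig = ScreenConfig(),
    genotypes: GenotypeMatrix | None = None,
) -> tuple[list[HweTestResult], float]:
    """Run the full two-stage screen and BH significance call.

    Returns (results, bh_critical_value). Every testable locus gets a
    stage-1 P at ``cfg.b1``; loci passing the ``stage1_alpha`` gate are
    re-measured at ``cfg.b2``; BH at ``cfg.fdr_q`` runs over the final
    P-values of all tested loci (gated-out loci contribute their stage-1 P).
    """
    summaries = locus_summaries(table, genotypes)
    results: list[HweTestResult] = []
    for s in summaries:
        res = HweTestResult(
            chrom=s.chrom,
            pos=s.pos,
            het_observed=s.het_observed,
            n_typed=s.n_typed,
            p_hat=s.p_hat,
            p_stage1=None,
            p_stage2=None,
        )
        if not s.testable:
            res.reason = (
                "no_typed_samples" if s.n_typed == 0 else "monomorphic_p_hat"
            )
        else:
            res.p_stage1 = het_deficit_pvalue(
                s, cfg.b1, locus_rng(cfg.seed, s.chrom, s.pos, stage=1)
            )
            if res.p_stage1 <= cfg.stage1_alpha:
                res.p_stage2 = het_deficit_pvalue(
                    s, cfg.b2, locus_rng(cfg.seed, s.chrom, s.pos, stage=2)
                )
        results.append(res)

    tested = [r for r in results if r.p_final is not None]
    crit = 0.0
    if tested:
        pvals = np.array([r.p_final for r in tested])
        crit, flags = bh_threshold(pvals, cfg.fdr_q)
        for r, sig in zip(tested, flags):
            r.significant = bool(sig)
    return results, crit


def results_frame(results: list[HweTestResult]) -> pd.DataFrame:
    """Flatten screen results into the output table layout."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in results],
            "pos": [r.pos for r in results],
            "het_observed": [r.het_observed for r in results],
            "n_typed": [r.n_typed for r in results],
            "p_hat": [r.p_hat for r in results],
            "p_stage1": [r.p_stage1 for r in results],
            "p_stage2": [r.p_stage2 for r in results],
            "p_final": [r.p_final for r in results],
            "significant": [r.significant for r in results],
            "reason": [r.reason for r in results],
        }
    )


def bh_threshold(p_values: np.ndarray, q: float) -> tuple[float, np.ndarray]:
    """Benjamini-Hochberg step-up over m P-values at FDR level q.

    Returns (critical value, boolean flags). The critical value is
    k*·q/m where k* is the largest rank k with p(k) ≤ k·q/m, or 0 when no
    rank qualifies; flags mark p ≤ critical value.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        raise ValueError("need at least one P-value")
    m = p.size
    order = np.sort(p)
    ranks = np.arange(1, m + 1)
    ok = order <= ranks * q / m
    if not ok.any():
        return 0.0, np.zeros(m, dtype=bool)
    k_star = int(ranks[ok][-1])
    crit = k_star * q / m
    return crit, p <= crit


@dataclass
class ReferenceBiasQc:
    """Wilcoxon rank-sum comparison of coverages at significant loci.

    Compares per-sample coverage between hom-ref and hom-alt calls; a small
    P would indicate alignment bias toward the reference allele. Reported
    only, never used for filtering.
    """

    assessable: bool
    p_value: float | None = None
    n_hom_ref: int = 0
    n_hom_alt: int = 0
    reason: str | None = None


def reference_bias_qc(
    results: list[HweTestResult],
    genotypes: GenotypeMatrix,
    table: AlleleCountTable,
) -> ReferenceBiasQc:
    """Two-sided Wilcoxon rank-sum on pooled hom-ref vs hom-alt coverages
    at significant loci."""
    pos_index = {
        (str(row["chrom"]), int(row["pos"])): i
        for i, row in table.loci.iterrows()
    }
    cov_ref: list[int] = []
    cov_alt: list[int] = []
    for r in results:
        if not r.significant:
            continue
        i = pos_index.get((r.chrom, r.pos))
        if i is None:
            continue
        calls = genotypes.calls[i]
        cov = table.coverage[i]
        cov_ref.extend(cov[calls == GT_HOM_REF].tolist())
        cov_alt.extend(cov[calls == GT_HOM_ALT].tolist())
    if not cov_ref or not cov_alt:
        return ReferenceBiasQc(
            assessable=False,
            reason="no significant locus with both homozygote classes",
        )
    stat = stats.mannwhitneyu(cov_ref, cov_alt, alternative="two-sided", method="auto")
    return ReferenceBiasQc(
        assessable=True,
        p_value=float(stat.pvalue),
        n_hom_ref=len(cov_ref),
        n_hom_alt=len(cov_alt),
    )
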