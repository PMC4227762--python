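"""Bisulfite (WGBS) validation of candidate monoallelically methylated loci.

For each candidate locus and each heterozygous bisulfite sample, CpG
methylation calls are partitioned by the SNP allele of the covering read,
giving a 2x2 table (allele x methylated/unmethylated). A Pearson chi-square
statistic measures whether the degree of methylation is allele-dependent;
its null distribution is generated by Monte-Carlo permutation with both
margins fixed (the conditional hypergeometric null), so no large-sample
approximation is involved. Summing the per-sample statistics across all
usable heterozygous samples gives a locus-level global statistic with its
own permutation null.

Samples that are uncovered or homozygous at the locus carry no allele
contrast and are excluded with a reason, as are degenerate tables (a zero
allele row or a zero methylation-state column). Loci whose alleles are
confounded with bisulfite conversion (C/T, or G/A on the opposite strand)
are flagged but still tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import AlleleMethylationTable, SnpLocus

__all__ = [
    "SampleTestOutcome",
    "ChiSquareResult",
    "sample_chisq",
    "sample_p",
    "global_test",
    "locus_tables",
]

EXCLUSION_REASONS = ("uncovered", "homozygous", "degenerate_table")


def sample_chisq(counts: np.ndarray) -> float:
    """Pearson chi-square for a 2x2 allele x {meth, unmeth} table.

    No continuity correction (the Monte-Carlo null makes it immaterial).
    Raises ValueError for degenerate tables (any zero margin).
    """
    t = np.asarray(counts, dtype=np.float64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    n = t.sum()
    if (r == 0).any() or (c == 0).any():
        raise ValueError("degenerate_table")
    # n (ad - bc)^2 / (r1 r2 c1 c2)
    det = t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0]
    return float(n * det * det / (r[0] * r[1] * c[0] * c[1]))


def _chisq_over_support(r1: int, r2: int, c1: int):
    """chi-square value for every attainable count a = table[0,0] given
    fixed margins; returns (support values a, chi2 per a)."""
    n = r1 + r2
    c2 = n - c1
    a = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    b = r1 - a
    c = c1 - a
    d = r2 - c
    det = a * d - b * c
    chi2 = n * det.astype(np.float64) ** 2 / (r1 * r2 * c1 * c2)
    return a, chi2


def sample_p(
    counts: np.ndarray, B: int = 2000, rng: np.random.Generator | None = None
) -> tuple[float, float]:
    """Monte-Carlo P for one 2x2 table; returns (chi2_observed, p).

    Null replicates permute methylation labels among the table's calls with
    both margins fixed, i.e. draw the a-cell from the hypergeometric
    distribution; P = (1 + #{null chi2 >= observed}) / (1 + B).
    """
    if rng is None:
        rng = np.random.default_rng()
    t = np.asarray(counts, dtype=np.int64)
    obs = sample_chisq(t)  # raises on degenerate tables
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1 = int(t[:, 0].sum())
    support, chi2_of = _chisq_over_support(r1, r2, c1)
    draws = rng.hypergeometric(c1, r1 + r2 - c1, r1, size=B)
    null_chi2 = chi2_of[draws - support[0]]
    hits = int((null_chi2 >= obs - 1e-12).sum())
    return obs, (1 + hits) / (1 + B)


@dataclass
class SampleTestOutcome:
    usable: bool
    chi2: float | None = None
    p: float | None = None
    reason: str | None = None


@dataclass
class ChiSquareResult:
    """Locus-level bisulfite validation outcome."""

    locus: SnpLocus
    per_sample: dict[str, SampleTestOutcome] = field(default_factory=dict)
    global_chi2: float | None = None
    global_p: float | None = None
    n_usable: int = 0
    bisulfite_ambiguous: bool = False

    @property
    def assessable(self) -> bool:
        return self.n_usable > 0


def global_test(
    locus: SnpLocus,
    tables: dict[str, np.ndarray | str],
    B: int = 2000,
    rng: np.random.Generator | None = None,
) -> ChiSquareResult:
    """Per-sample and global allele-dependence test for one locus.

    ``tables`` maps sample_id to either a 2x2 count table (rows ref/alt
    allele, columns meth/unmeth) or an exclusion reason string
    ('uncovered' / 'homozygous'). The global statistic sums the usable
    per-sample chi-squares; each null replicate sums one margin-preserving
    permuted chi-square per usable sample.
    """
    if rng is None:
        rng = np.random.default_rng()
    result = ChiSquareResult(
        locus=locus, bisulfite_ambiguous=locus.is_bisulfite_ambiguous
    )
    usable: list[tuple[str, np.ndarray]] = []
    for sid, entry in tables.items():
        if isinstance(entry, str):
            if entry not in EXCLUSION_REASONS:
                raise ValueError(f"unknown exclusion reason {entry!r}")
            result.per_sample[sid] = SampleTestOutcome(usable=False, reason=entry)
            continue
        t = np.asarray(entry, dtype=np.int64)
        try:
            chi2, p = sample_p(t, B=B, rng=rng)
        except ValueError:
            result.per_sample[sid] = SampleTestOutcome(
                usable=False, reason="degenerate_table"
            )
            continue
        result.per_sample[sid] = SampleTestOutcome(usable=True, chi2=chi2, p=p)
        usable.append((sid, t))

    result.n_usable = len(usable)
    if not usable:
        return result

    global_obs = 0.0
    null_sum = np.zeros(B)
    for _, t in usable:
        global_obs += sample_chisq(t)
        r1, r2 = int(t[0].sum()), int(t[1].sum())
        c1 = int(t[:, 0].sum())
        support, chi2_of = _chisq_over_support(r1, r2, c1)
        draws = rng.hypergeometric(c1, r1 + r2 - c1, r1, size=B)
        null_sum += chi2_of[draws - support[0]]
    hits = int((null_sum >= global_obs - 1e-12).sum())
    result.global_chi2 = global_obs
    result.global_p = (1 + hits) / (1 + B)
    return result


def locus_tables(
    table: AlleleMethylationTable, chrom: str, pos: int
) -> dict[str, np.ndarray]:
    """Collect per-sample 2x2 tables for one locus from a methylation-call
    table. Samples with calls on only one allele are homozygous (or only
    one allele was covered) and map to the 'homozygous' exclusion."""
    sub = table.rows[(table.rows["chrom"] == chrom) & (table.rows["pos"] == pos)]
    out: dict[str, np.ndarray | str] = {}
    for sid, grp in sub.groupby("sample_id"):
        alleles = set(grp["allele"])
        if alleles != {"ref", "alt"}:
            out[str(sid)] = "homozygous"
            continue
        ref_row = grp[grp["allele"] == "ref"].iloc[0]
        alt_row = grp[grp["allele"] == "alt"].iloc[0]
        out[str(sid)] = np.array(
            [
                [ref_row["meth"], ref_row["unmeth"]],
                [alt_row["meth"], alt_row["unmeth"]],
            ],
            dtype=np.int64,
        )
    return out
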