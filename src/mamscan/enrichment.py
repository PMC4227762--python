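"""Functional classification and chromosome-matched enrichment testing.

Each significant locus receives fractional weights over the functional
classes {promoter, exon, intron, intergenic}: the distinct classes of all
annotation intervals overlapping the position (either strand) share one
unit of weight equally; a position overlapping nothing is intergenic with
weight 1. A locus in an exon on one strand and an intron of an antisense
gene thus scores 0.5 exon + 0.5 intron, and the weights of any locus sum
to exactly 1.

The enrichment null matches the chromosomal composition of the significant
set: each of ``n_draws`` replicates samples, per chromosome and without
replacement, as many universe loci as that chromosome has significant
loci, and sums their class weights. Two-sided empirical P-values double
the smaller tail (add-one corrected) and are capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    AnnotationSet,
    ConfigurationError,
    FUNCTIONAL_CLASSES,
    SnpLocus,
)

__all__ = ["FunctionalWeights", "EnrichmentResult", "classify_snp", "enrichment_test"]


@dataclass(frozen=True)
class FunctionalWeights:
    promoter: float = 0.0
    exon: float = 0.0
    intron: float = 0.0
    intergenic: float = 0.0

    def __post_init__(self) -> None:
        total = self.promoter + self.exon + self.intron + self.intergenic
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {total}")

    def as_array(self) -> np.ndarray:
        return np.array([self.promoter, self.exon, self.intron, self.intergenic])


@dataclass
class EnrichmentResult:
    """Per-class observed weight sums against the chromosome-matched null."""

    observed: dict[str, float]
    null_mean: dict[str, float]
    null_sd: dict[str, float]
    p_two_sided: dict[str, float]
    n_draws: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cls": list(FUNCTIONAL_CLASSES),
                "observed": [self.observed[c] for c in FUNCTIONAL_CLASSES],
                "null_mean": [self.null_mean[c] for c in FUNCTIONAL_CLASSES],
                "null_sd": [self.null_sd[c] for c in FUNCTIONAL_CLASSES],
                "p_two_sided": [self.p_two_sided[c] for c in FUNCTIONAL_CLASSES],
            }
        )


def classify_snp(locus: SnpLocus, ann: AnnotationSet) -> FunctionalWeights:
    """Fractional functional weights for one position (see module docs)."""
    classes = ann.classes_at(locus.chrom, locus.pos)
    if not classes:
        return FunctionalWeights(intergenic=1.0)
    w = 1.0 / len(classes)
    return FunctionalWeights(
        promoter=w if "promoter" in classes else 0.0,
        exon=w if "exon" in classes else 0.0,
        intron=w if "intron" in classes else 0.0,
    )


def _weight_matrix(loci: pd.DataFrame, ann: AnnotationSet) -> np.ndarray:
    out = np.zeros((len(loci), len(FUNCTIONAL_CLASSES)))
    for i, (chrom, pos) in enumerate(zip(loci["chrom"], loci["pos"])):
        classes = ann.classes_at(str(chrom), int(pos))
        if not classes:
            out[i, 3] = 1.0
        else:
            w = 1.0 / len(classes)
            for j, cls in enumerate(FUNCTIONAL_CLASSES[:3]):
                if cls in classes:
                    out[i, j] = w
    return out


def enrichment_test(
    significant: pd.DataFrame,
    universe: pd.DataFrame,
    ann: AnnotationSet,
    n_draws: int = 1000,
    rng: np.random.Generator | None = None,
) -> EnrichmentResult:
    """Chromosome-matched random-sampling enrichment test.

    ``significant`` and ``universe`` are locus tables with ``chrom``/``pos``
    columns; the significant set must be a subset of the universe (the
    post-filter loci the screen actually tested).
    """
    if rng is None:
        rng = np.random.default_rng()
    weights = _weight_matrix(universe, ann)
    observed = _weight_matrix(significant, ann).sum(axis=0)

    uni_chrom = universe["chrom"].astype(str).to_numpy()
    sig_counts = significant["chrom"].astype(str).value_counts()
    chrom_idx: list[tuple[np.ndarray, int]] = []
    for chrom, k in sig_counts.items():
        idx = np.nonzero(uni_chrom == chrom)[0]
        if len(idx) < k:
            raise ConfigurationError(
                f"chromosome {chrom}: {k} significant loci but only "
                f"{len(idx)} universe loci"
            )
        chrom_idx.append((idx, int(k)))

    null = np.zeros((n_draws, len(FUNCTIONAL_CLASSES)))
    for b in range(n_draws):
        total = np.zeros(len(FUNCTIONAL_CLASSES))
        for idx, k in chrom_idx:
            take = rng.choice(idx, size=k, replace=False)
            total += weights[take].sum(axis=0)
        null[b] = total

    p = {}
    for j, cls in enumerate(FUNCTIONAL_CLASSES):
        ge = int((null[:, j] >= observed[j] - 1e-12).sum())
        le = int((null[:, j] <= observed[j] + 1e-12).sum())
        p[cls] = min(1.0, 2.0 * min(ge + 1, le + 1) / (n_draws + 1))
    return EnrichmentResult(
        observed={c: float(observed[j]) for j, c in enumerate(FUNCTIONAL_CLASSES)},
        null_mean={c: float(null[:, j].mean()) for j, c in enumerate(FUNCTIONAL_CLASSES)},
        null_sd={c: float(null[:, j].std(ddof=1)) for j, c in enumerate(FUNCTIONAL_CLASSES)},
        p_two_sided=p,
        n_draws=n_draws,
    )
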