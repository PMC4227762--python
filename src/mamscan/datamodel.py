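"""Shared genomic data model for the monoallelic-methylation screen.

All coordinates are 1-based inclusive (dbSNP/VCF convention). BED input is
converted on read; see :mod:`mamscan.io`.

The central container is :class:`AlleleCountTable`: a dense (locus x sample)
matrix of reference/alternative read counts at known SNV positions, as
produced by counting mismatch pileups from enrichment-based sequencing
(MethylCap-seq / MBD-seq). Zero coverage (ref == alt == 0) and an absent
entry are the same state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

NUCLEOTIDES = frozenset("ACGT")

#: chromosome names treated as the X chromosome
X_CHROM_NAMES = frozenset({"X", "chrX", "x", "chrx"})

# genotype codes used throughout (int8 matrices)
GT_MISSING = 0
GT_HOM_REF = 1
GT_HET = 2
GT_HOM_ALT = 3

GENOTYPE_LABELS = {
    GT_MISSING: "missing",
    GT_HOM_REF: "hom_ref",
    GT_HET: "het",
    GT_HOM_ALT: "hom_alt",
}


class DataModelError(ValueError):
    """Invariant violation in a typed table."""


class ConfigurationError(ValueError):
    """Inconsistent or missing run configuration / metadata."""


@dataclass(frozen=True)
class SnpLocus:
    """A biallelic SNV position.

    Parameters
    ----------
    chrom, pos
        Chromosome name and 1-based coordinate.
    ref_allele, alt_allele
        The two observed nucleotides; must differ.
    snp_id
        Optional catalogue identifier (e.g. an rs number).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    snp_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataModelError(f"position must be >= 1, got {self.pos}")
        for a in (self.ref_allele, self.alt_allele):
            if a not in NUCLEOTIDES:
                raise DataModelError(f"invalid allele {a!r}")
        if self.ref_allele == self.alt_allele:
            raise DataModelError("ref and alt allele must differ")

    @property
    def is_x(self) -> bool:
        return self.chrom in X_CHROM_NAMES

    @property
    def is_bisulfite_ambiguous(self) -> bool:
        """C/T (read strand) or G/A (opposite strand) pairs are confounded
        with bisulfite conversion and are flagged in validation output."""
        pair = frozenset((self.ref_allele, self.alt_allele))
        return pair == frozenset("CT") or pair == frozenset("GA")


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if self.sex not in {"female", "male", "unknown"}:
            raise DataModelError(f"invalid sex {self.sex!r}")


LOCUS_COLUMNS = ["chrom", "pos", "snp_id", "ref", "alt"]


@dataclass
class AlleleCountTable:
    """Per (SNP locus x sample) ref/alt read counts.

    Attributes
    ----------
    loci
        DataFrame with columns ``chrom, pos, snp_id, ref, alt``; (chrom, pos)
        unique, one row per locus in matrix order.
    samples
        DataFrame with columns ``sample_id, sex``, one row per matrix column.
    ref, alt
        Integer arrays of shape (n_loci, n_samples).
    """

    loci: pd.DataFrame
    samples: pd.DataFrame
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.loci = self.loci.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.ref = np.asarray(self.ref, dtype=np.int64)
        self.alt = np.asarray(self.alt, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        n, m = len(self.loci), len(self.samples)
        if self.ref.shape != (n, m) or self.alt.shape != (n, m):
            raise DataModelError(
                f"count matrices {self.ref.shape}/{self.alt.shape} do not "
                f"match {n} loci x {m} samples"
            )
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise DataModelError("negative read count")
        missing = [c for c in LOCUS_COLUMNS if c not in self.loci.columns]
        if missing:
            raise DataModelError(f"loci table missing columns {missing}")
        dup = self.loci.duplicated(subset=["chrom", "pos"])
        if dup.any():
            row = self.loci[dup].iloc[0]
            raise DataModelError(f"duplicate locus {row.chrom}:{row.pos}")
        if self.samples["sample_id"].duplicated().any():
            raise DataModelError("duplicate sample_id")
        bad = ~self.loci["ref"].isin(NUCLEOTIDES) | ~self.loci["alt"].isin(NUCLEOTIDES)
        if bad.any():
            raise DataModelError("unknown allele in loci table")
        if (self.loci["ref"] == self.loci["alt"]).any():
            raise DataModelError("ref allele equals alt allele")
        if (self.loci["pos"] < 1).any():
            raise DataModelError("position must be >= 1")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def coverage(self) -> np.ndarray:
        return self.ref + self.alt

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    def locus_at(self, i: int) -> SnpLocus:
        row = self.loci.iloc[i]
        snp_id = row["snp_id"]
        if pd.isna(snp_id) or snp_id in ("", "."):
            snp_id = None
        return SnpLocus(str(row["chrom"]), int(row["pos"]), str(row["ref"]),
                        str(row["alt"]), snp_id)

    def x_mask(self) -> np.ndarray:
        """Boolean mask over loci on the X chromosome."""
        return self.loci["chrom"].isin(X_CHROM_NAMES).to_numpy()

    def female_mask(self) -> np.ndarray:
        return (self.samples["sex"] == "female").to_numpy()

    def subset_loci(self, mask: np.ndarray) -> "AlleleCountTable":
        mask = np.asarray(mask)
        return AlleleCountTable(
            loci=self.loci.loc[mask].copy(),
            samples=self.samples.copy(),
            ref=self.ref[mask].copy(),
            alt=self.alt[mask].copy(),
        )

    def sorted(self) -> "AlleleCountTable":
        """Deterministic order: by (chrom, pos); sample order untouched."""
        order = self.loci.sort_values(["chrom", "pos"], kind="mergesort").index
        idx = order.to_numpy()
        return AlleleCountTable(
            loci=self.loci.loc[order].copy(),
            samples=self.samples.copy(),
            ref=self.ref[idx].copy(),
            alt=self.alt[idx].copy(),
        )

    def equals(self, other: "AlleleCountTable") -> bool:
        return (
            self.loci.fillna(".").reset_index(drop=True)
            .equals(other.loci.fillna(".").reset_index(drop=True))
            and self.samples.reset_index(drop=True)
            .equals(other.samples.reset_index(drop=True))
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
        )

    @classmethod
    def from_counts(
        cls,
        loci: Iterable[SnpLocus],
        samples: Iterable[SampleInfo],
        counts: Mapping[tuple[tuple[str, int], str], tuple[int, int]],
    ) -> "AlleleCountTable":
        """Build from a sparse mapping ((chrom,pos), sample_id) -> (ref, alt).

        Absent entries mean zero coverage.
        """
        loci = list(loci)
        samples = list(samples)
        loci_df = pd.DataFrame(
            {
                "chrom": [l.chrom for l in loci],
                "pos": [l.pos for l in loci],
                "snp_id": [l.snp_id for l in loci],
                "ref": [l.ref_allele for l in loci],
                "alt": [l.alt_allele for l in loci],
            }
        )
        samples_df = pd.DataFrame(
            {"sample_id": [s.sample_id for s in samples],
             "sex": [s.sex for s in samples]}
        )
        ref = np.zeros((len(loci), len(samples)), dtype=np.int64)
        alt = np.zeros_like(ref)
        locus_idx = {(l.chrom, l.pos): i for i, l in enumerate(loci)}
        sample_idx = {s.sample_id: j for j, s in enumerate(samples)}
        for (lkey, sid), (r, a) in counts.items():
            ref[locus_idx[lkey], sample_idx[sid]] = r
            alt[locus_idx[lkey], sample_idx[sid]] = a
        return cls(loci_df, samples_df, ref, alt)


@dataclass
class SnpCatalogue:
    """Known-SNV catalogue: (chrom, pos) -> allowed alleles."""

    entries: dict[tuple[str, int], frozenset[str]]
    n_skipped: int = 0  # indel / multi-nucleotide records dropped on read

    def __post_init__(self) -> None:
        for key, alleles in self.entries.items():
            if len(alleles) < 2:
                raise DataModelError(f"catalogue entry {key} has <2 alleles")
            if not alleles <= NUCLEOTIDES:
                raise DataModelError(f"catalogue entry {key} has invalid allele")

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.entries

    def alleles(self, chrom: str, pos: int) -> frozenset[str] | None:
        return self.entries.get((chrom, pos))

    def __len__(self) -> int:
        return len(self.entries)


ANNOTATION_CLASSES = ("promoter", "exon", "intron")
FUNCTIONAL_CLASSES = ANNOTATION_CLASSES + ("intergenic",)


@dataclass
class AnnotationSet:
    """Genomic intervals with a functional class.

    ``intervals`` columns: chrom, start, end (1-based inclusive), strand,
    cls in {promoter, exon, intron}, feature_id. Positions not covered by
    any interval are implicitly intergenic.
    """

    intervals: pd.DataFrame

    _by_chrom: dict = field(default_factory=dict, init=False, repr=False)

    def __post_init__(self) -> None:
        df = self.intervals.reset_index(drop=True)
        required = ["chrom", "start", "end", "strand", "cls", "feature_id"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise DataModelError(f"annotation missing columns {missing}")
        if (df["start"] > df["end"]).any():
            raise DataModelError("interval start > end")
        bad = ~df["cls"].isin(ANNOTATION_CLASSES)
        if bad.any():
            raise DataModelError(
                f"invalid annotation class {df.loc[bad, 'cls'].iloc[0]!r}"
            )
        self.intervals = df
        # per-chromosome arrays for fast point overlap
        for chrom, sub in df.groupby("chrom", sort=False):
            self._by_chrom[chrom] = (
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                sub["cls"].to_numpy(),
            )

    def classes_at(self, chrom: str, pos: int) -> frozenset[str]:
        """Distinct annotation classes overlapping a position (both strands)."""
        rec = self._by_chrom.get(chrom)
        if rec is None:
            return frozenset()
        start, end, cls = rec
        hit = (start <= pos) & (pos <= end)
        return frozenset(cls[hit])


def promoter_interval(tss: int, strand: str) -> tuple[int, int]:
    """1-based inclusive promoter window: 2000 bp upstream through the TSS."""
    if strand == "+":
        return max(1, tss - 2000), tss
    if strand == "-":
        return tss, tss + 2000
    raise DataModelError(f"invalid strand {strand!r}")


@dataclass
class AlleleMethylationTable:
    """Per-allele methylated/unmethylated CpG call counts (bisulfite data).

    ``rows`` columns: chrom, pos, sample_id, allele in {ref, alt},
    meth, unmeth (non-negative call counts).
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.rows.reset_index(drop=True)
        required = ["chrom", "pos", "sample_id", "allele", "meth", "unmeth"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise DataModelError(f"methylation table missing columns {missing}")
        if not df["allele"].isin(["ref", "alt"]).all():
            raise DataModelError("allele must be 'ref' or 'alt'")
        if (df[["meth", "unmeth"]] < 0).any().any():
            raise DataModelError("negative call count")
        if df.duplicated(subset=["chrom", "pos", "sample_id", "allele"]).any():
            raise DataModelError("duplicate (locus, sample, allele) row")
        self.rows = df


@dataclass
class AseSiteTable:
    """Per-site ref/alt expression read counts for ASE testing.

    ``rows`` columns: chrom, pos, tissue, gene_ids (tuple of str, may be
    empty for intergenic sites), ref_count, alt_count.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.rows.reset_index(drop=True)
        required = ["chrom", "pos", "tissue", "gene_ids", "ref_count", "alt_count"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise DataModelError(f"ASE table missing columns {missing}")
        if (df[["ref_count", "alt_count"]] < 0).any().any():
            raise DataModelError("negative read count")
        df["gene_ids"] = df["gene_ids"].map(tuple)
        self.rows = df

    @property
    def depth(self) -> np.ndarray:
        return (self.rows["ref_count"] + self.rows["alt_count"]).to_numpy()
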