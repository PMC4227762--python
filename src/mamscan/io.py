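"""Readers and writers for every external table the pipeline touches.

Formats (all tab-separated, plain text):

* **allele-count TSV** — ``#chrom pos snp_id ref alt <id>_ref <id>_alt ...``
  ('#'-prefixed header, one column pair per sample). Zero coverage may be
  written as ``0``/``0``, ``.`` or an empty field; all read back as zero.
* **sample sheet TSV** — ``sample_id sex``.
* **SNP catalogue** — standard VCF (via pysam) or a TSV with columns
  ``chrom pos ref alts`` (alts comma-separated).
* **annotation BED** — BED 0-based half-open, converted to 1-based
  inclusive on read; functional class and feature id in the two columns
  after the strand (BED6+2), or a compact 6-column variant
  ``chrom start end strand class feature_id``.
* **methylation-call TSV** — ``chrom pos sample_id allele meth unmeth``.
* **ASE TSV** — ``chrom pos tissue gene_ids ref_count alt_count``.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    ANNOTATION_CLASSES,
    AlleleCountTable,
    AlleleMethylationTable,
    AnnotationSet,
    AseSiteTable,
    ConfigurationError,
    NUCLEOTIDES,
    SnpCatalogue,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file; message names the file and line number."""


ALLELE_COUNT_FIXED = ["chrom", "pos", "snp_id", "ref", "alt"]


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment=None, dtype=str)
    df.columns = [c.lstrip("#") for c in df.columns]
    if "sample_id" not in df.columns or "sex" not in df.columns:
        raise ParseError(f"{path}: sample sheet needs columns sample_id, sex")
    bad = ~df["sex"].isin(["female", "male", "unknown"])
    if bad.any():
        raise ParseError(
            f"{path}: invalid sex value {df.loc[bad, 'sex'].iloc[0]!r}"
        )
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample_id")
    return df[["sample_id", "sex"]].reset_index(drop=True)


def _parse_count(field: str, path, lineno: int) -> int:
    if field in ("", "."):
        return 0
    try:
        value = int(field)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer count {field!r}") from None
    if value < 0:
        raise ParseError(f"{path}:{lineno}: negative count {value}")
    return value


def read_allele_counts(
    path: str | os.PathLike, sample_sheet: str | os.PathLike | pd.DataFrame
) -> AlleleCountTable:
    """Read the canonical allele-count TSV against a sample sheet.

    Every ``<id>_ref``/``<id>_alt`` column pair must correspond to a sample
    listed in the sheet, else a :class:`ConfigurationError` is raised.
    """
    if isinstance(sample_sheet, pd.DataFrame):
        sheet = sample_sheet
    else:
        sheet = read_sample_sheet(sample_sheet)
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}:1: empty file")
        columns = header.lstrip("#").split("\t")
        if columns[: len(ALLELE_COUNT_FIXED)] != ALLELE_COUNT_FIXED:
            raise ParseError(
                f"{path}:1: header must start with {ALLELE_COUNT_FIXED}"
            )
        pair_cols = columns[len(ALLELE_COUNT_FIXED):]
        if len(pair_cols) % 2:
            raise ParseError(f"{path}:1: odd number of sample count columns")
        sample_ids: list[str] = []
        for i in range(0, len(pair_cols), 2):
            rcol, acol = pair_cols[i], pair_cols[i + 1]
            if not (rcol.endswith("_ref") and acol.endswith("_alt")):
                raise ParseError(f"{path}:1: bad column pair {rcol!r}/{acol!r}")
            if rcol[:-4] != acol[:-4]:
                raise ParseError(f"{path}:1: mismatched pair {rcol!r}/{acol!r}")
            sample_ids.append(rcol[:-4])
        known = set(sheet["sample_id"])
        unknown = [s for s in sample_ids if s not in known]
        if unknown:
            raise ConfigurationError(
                f"{path}: sample column(s) {unknown} absent from sample sheet"
            )
        rows, refs, alts = [], [], []
        n_fields = len(columns)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != n_fields:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_fields} fields, got {len(fields)}"
                )
            chrom, pos_s, snp_id, ref, alt = fields[:5]
            try:
                pos = int(pos_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad position {pos_s!r}") from None
            if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
                raise ParseError(f"{path}:{lineno}: unknown allele {ref!r}/{alt!r}")
            rows.append((chrom, pos, None if snp_id in (".", "") else snp_id, ref, alt))
            counts = [_parse_count(f, path, lineno) for f in fields[5:]]
            refs.append(counts[0::2])
            alts.append(counts[1::2])
    loci = pd.DataFrame(rows, columns=ALLELE_COUNT_FIXED)
    samples = (
        sheet.set_index("sample_id").loc[sample_ids].reset_index()
        [["sample_id", "sex"]]
    )
    shape = (len(loci), len(sample_ids))
    ref_m = np.array(refs, dtype=np.int64).reshape(shape)
    alt_m = np.array(alts, dtype=np.int64).reshape(shape)
    try:
        return AlleleCountTable(loci, samples, ref_m, alt_m)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_allele_counts(table: AlleleCountTable, path: str | os.PathLike) -> None:
    """Write the canonical TSV, deterministically ordered by (chrom, pos)."""
    table = table.sorted()
    header = list(ALLELE_COUNT_FIXED)
    for sid in table.sample_ids:
        header += [f"{sid}_ref", f"{sid}_alt"]
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(header) + "\n")
        for i in range(table.n_loci):
            row = table.loci.iloc[i]
            snp_id = row["snp_id"]
            fields = [
                str(row["chrom"]),
                str(int(row["pos"])),
                "." if snp_id is None or pd.isna(snp_id) else str(snp_id),
                row["ref"],
                row["alt"],
            ]
            for j in range(table.n_samples):
                fields += [str(table.ref[i, j]), str(table.alt[i, j])]
            fh.write("\t".join(fields) + "\n")


def write_sample_sheet(samples: pd.DataFrame, path: str | os.PathLike) -> None:
    samples[["sample_id", "sex"]].to_csv(path, sep="\t", index=False)


def read_snp_catalogue(path: str | os.PathLike) -> SnpCatalogue:
    """Read a known-SNV catalogue from VCF or 4-column TSV.

    Indel and multi-nucleotide records are skipped (counted on the returned
    catalogue); multi-allelic SNVs keep their full allele set.
    """
    path = Path(path)
    if path.suffix in (".vcf", ".gz", ".bcf") or path.name.endswith(".vcf.gz"):
        return _read_catalogue_vcf(path)
    return _read_catalogue_tsv(path)


def _read_catalogue_vcf(path: Path) -> SnpCatalogue:
    import pysam

    entries: dict[tuple[str, int], frozenset[str]] = {}
    n_skipped = 0
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"{path}: unreadable VCF header: {exc}") from exc
    with vcf:
        for rec in vcf:
            alts = rec.alts or ()
            alleles = [rec.ref, *alts]
            if any(a is None or len(a) != 1 or a not in NUCLEOTIDES for a in alleles):
                n_skipped += 1
                continue
            key = (rec.chrom, rec.pos)  # pysam .pos is 1-based
            merged = frozenset(alleles) | entries.get(key, frozenset())
            entries[key] = merged
    if n_skipped:
        logger.info("catalogue %s: skipped %d non-SNV records", path, n_skipped)
    return SnpCatalogue(entries, n_skipped=n_skipped)


def _read_catalogue_tsv(path: Path) -> SnpCatalogue:
    entries: dict[tuple[str, int], frozenset[str]] = {}
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            chrom, pos_s, ref, alts_s = fields[:4]
            try:
                pos = int(pos_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad position {pos_s!r}") from None
            alleles = [ref] + alts_s.split(",")
            if any(len(a) != 1 or a not in NUCLEOTIDES for a in alleles):
                n_skipped += 1
                continue
            key = (chrom, pos)
            entries[key] = frozenset(alleles) | entries.get(key, frozenset())
    if n_skipped:
        logger.info("catalogue %s: skipped %d non-SNV records", path, n_skipped)
    return SnpCatalogue(entries, n_skipped=n_skipped)


def read_annotation_intervals(path: str | os.PathLike) -> AnnotationSet:
    """Read BED-like functional intervals (0-based half-open on disk).

    Accepts BED6+2 (class, feature_id after the strand) or the compact
    6-column layout ``chrom start end strand class feature_id``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) >= 8:
                chrom, start_s, end_s = fields[0], fields[1], fields[2]
                strand, cls, feature = fields[5], fields[6], fields[7]
            elif len(fields) == 6:
                chrom, start_s, end_s, strand, cls, feature = fields
            else:
                raise ParseError(
                    f"{path}:{lineno}: expected 6 or >=8 columns, got {len(fields)}"
                )
            if cls not in ANNOTATION_CLASSES:
                raise ParseError(
                    f"{path}:{lineno}: class {cls!r} not in {ANNOTATION_CLASSES}"
                )
            try:
                start0, end0 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from None
            if strand not in ("+", "-", "."):
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            # BED half-open [start0, end0) -> 1-based inclusive [start0+1, end0]
            rows.append((chrom, start0 + 1, end0, strand, cls, feature))
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "cls", "feature_id"]
    )
    return AnnotationSet(df)


def write_annotation_intervals(ann: AnnotationSet, path: str | os.PathLike) -> None:
    """Write intervals back out as BED6+2 (exact inverse of the reader)."""
    with open(path, "w") as fh:
        for row in ann.intervals.itertuples(index=False):
            fh.write(
                "\t".join(
                    [
                        str(row.chrom),
                        str(row.start - 1),
                        str(row.end),
                        row.feature_id,
                        "0",
                        row.strand,
                        row.cls,
                        row.feature_id,
                    ]
                )
                + "\n"
            )


def read_methylation_calls(path: str | os.PathLike) -> AlleleMethylationTable:
    """Read per-allele methylation-call counts.

    Rows where both call counts are zero carry no information and are
    dropped with a warning.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "pos", "sample_id", "allele", "meth", "unmeth"],
        header=0,
        dtype={"chrom": str, "sample_id": str, "allele": str},
    )
    empty = (df["meth"] + df["unmeth"]) == 0
    if empty.any():
        logger.warning(
            "%s: dropped %d zero-call rows", path, int(empty.sum())
        )
        df = df[~empty]
    try:
        return AlleleMethylationTable(df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_methylation_calls(
    table: AlleleMethylationTable, path: str | os.PathLike
) -> None:
    table.rows.to_csv(path, sep="\t", index=False)


def read_ase_counts(path: str | os.PathLike) -> AseSiteTable:
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "pos", "tissue", "gene_ids", "ref_count", "alt_count"],
        header=0,
        dtype={"chrom": str, "tissue": str, "gene_ids": str},
    )
    df["gene_ids"] = [
        tuple(g for g in str(v).split(",") if g) if pd.notna(v) else ()
        for v in df["gene_ids"]
    ]
    try:
        return AseSiteTable(df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_ase_counts(table: AseSiteTable, path: str | os.PathLike) -> None:
    df = table.rows.copy()
    df["gene_ids"] = df["gene_ids"].map(",".join)
    df.to_csv(path, sep="\t", index=False)
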