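"""Allele-specific expression (ASE) validation from RNA-seq allele counts.

Each heterozygous variant site in a tissue is tested with an exact
two-sided binomial test against equal expression of the two alleles
(success probability 0.5; the two-sided P sums the probabilities of all
outcomes no more likely than the observed one). Sites below the minimum
read depth (default 10) are excluded. Benjamini-Hochberg FDR control
(default 1%) is applied within each tissue, and a gene in a tissue is
called allele-specifically expressed only when at least two of its sites
are significant — a single imbalanced site is too easily produced by
residual mapping bias or a genotyping error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AseSiteTable
from .hwe_screen import bh_threshold

__all__ = [
    "AseGeneCall",
    "site_binomial_test",
    "test_sites",
    "call_gene_ase",
]

MIN_DEPTH = 10


def site_binomial_test(ref_count: int, alt_count: int) -> float:
    """Exact two-sided binomial P at p=0.5; symmetric in the two counts."""
    if ref_count < 0 or alt_count < 0:
        raise ValueError("counts must be non-negative")
    n = ref_count + alt_count
    if n == 0:
        raise ValueError("empty site")
    return float(stats.binomtest(ref_count, n, 0.5, alternative="two-sided").pvalue)


def test_sites(table: AseSiteTable, min_depth: int = MIN_DEPTH) -> pd.DataFrame:
    """Site-level tests for every row of an :class:`AseSiteTable`.

    Returns the rows with added columns ``depth``, ``tested`` (depth >=
    min_depth), ``p`` (NaN for untested sites) and ``reason``.
    """
    df = table.rows.copy()
    df["depth"] = df["ref_count"] + df["alt_count"]
    df["tested"] = df["depth"] >= min_depth
    df["reason"] = np.where(df["tested"], None, "low_depth")
    p = np.full(len(df), np.nan)
    for i, (r, a, ok) in enumerate(
        zip(df["ref_count"], df["alt_count"], df["tested"])
    ):
        if ok:
            p[i] = site_binomial_test(int(r), int(a))
    df["p"] = p
    return df


@dataclass(frozen=True)
class AseGeneCall:
    gene_id: str
    tissue_id: str
    classification: str  # ASE | BE | not_assessable
    n_sites_tested: int
    n_sites_significant: int


def call_gene_ase(
    table: AseSiteTable,
    fdr_q: float = 0.01,
    min_sites: int = 2,
    min_depth: int = MIN_DEPTH,
) -> tuple[pd.DataFrame, list[AseGeneCall]]:
    """Site tests, per-tissue BH correction, and gene-level classification.

    A gene/tissue pair is ASE when >= ``min_sites`` of its tested sites are
    BH-significant, biallelically expressed (BE) when it has >= min_sites
    tested sites but fewer significant ones, and not_assessable otherwise.
    Returns (site-level frame with ``bh_significant``, gene calls).
    """
    sites = test_sites(table, min_depth=min_depth)
    sites["bh_significant"] = False
    for tissue, grp in sites.groupby("tissue"):
        tested = grp[grp["tested"]]
        if tested.empty:
            continue
        _, flags = bh_threshold(tested["p"].to_numpy(), fdr_q)
        sites.loc[tested.index, "bh_significant"] = flags

    calls: list[AseGeneCall] = []
    exploded = sites[sites["tested"]].explode("gene_ids").dropna(subset=["gene_ids"])
    exploded = exploded[exploded["gene_ids"] != ""]
    for (gene, tissue), grp in exploded.groupby(["gene_ids", "tissue"]):
        n_tested = len(grp)
        n_sig = int(grp["bh_significant"].sum())
        if n_sig >= min_sites:
            cls = "ASE"
        elif n_tested >= min_sites:
            cls = "BE"
        else:
            cls = "not_assessable"
        calls.append(AseGeneCall(str(gene), str(tissue), cls, n_tested, n_sig))
    return sites, calls


def summarize_gene_tissue_calls(calls: pd.DataFrame) -> dict[str, int]:
    """Aggregate per-(gene, tissue) ASE/BE labels to gene-level categories.

    ``calls`` needs columns ``gene_id`` and ``classification`` (one row per
    gene x expression type or per gene x tissue). Returns counts of genes
    with ASE in at least one tissue, genes showing both ASE and biallelic
    expression across tissues ("mixed"), genes exclusively ASE, and genes
    exclusively BE.
    """
    has_ase = calls[calls["classification"] == "ASE"]["gene_id"].unique()
    has_be = calls[calls["classification"] == "BE"]["gene_id"].unique()
    ase, be = set(has_ase), set(has_be)
    return {
        "n_genes_assessed": calls["gene_id"].nunique(),
        "n_genes_ase": len(ase),
        "n_genes_mixed": len(ase & be),
        "n_genes_exclusive_ase": len(ase - be),
        "n_genes_exclusive_be": len(be - ase),
    }


def gene_calls_frame(calls: list[AseGeneCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "tissue": [c.tissue_id for c in calls],
            "classification": [c.classification for c in calls],
            "n_tested": [c.n_sites_tested for c in calls],
            "n_significant": [c.n_sites_significant for c in calls],
        }
    )
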