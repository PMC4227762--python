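"""Bundled reference tables from the original discovery cohort.

Three small summaries of the 334-sample MethylCap-seq discovery screen and
its external validations ship with the package so that the downstream
decision rules can be exercised and re-checked without the (unavailable)
raw sequencing data:

* ``load_discovery_summary`` — locus counts through the pipeline stages
  (traced, filtered, stage-1 pass, significant) plus the screen settings;
* ``load_wgbs_global_p`` — locus-level global permutation P-values for the
  44 candidate loci covered by at least one heterozygous bisulfite sample;
* ``load_ase_gene_tissue_calls`` — per-gene, per-tissue allele-specific /
  biallelic expression labels for the 21 candidate genes assessable in the
  16 normal-tissue RNA-seq panel.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

__all__ = [
    "load_discovery_summary",
    "load_wgbs_global_p",
    "load_ase_gene_tissue_calls",
]


def _data_path(name: str):
    return resources.files("mamscan.data").joinpath(name)


def load_discovery_summary() -> dict:
    with _data_path("discovery_summary.json").open() as fh:
        return json.load(fh)


def load_wgbs_global_p() -> pd.DataFrame:
    with _data_path("wgbs_validation_global_p.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


def load_ase_gene_tissue_calls() -> pd.DataFrame:
    with _data_path("ase_gene_tissue_calls.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
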