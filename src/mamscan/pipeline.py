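"""End-to-end pipeline: trace -> filter -> correct -> screen -> (enrich).

Stage outputs are persisted between steps so the validation subcommands can
run independently, and a JSON manifest records the configuration, seed,
package versions and per-stage record counts for reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datamodel import ConfigurationError
from .genotyping import (
    ErrorModel,
    call_genotypes,
    correct_sequencing_errors,
    filter_loci,
    trace_snps,
)
from .hwe_screen import (
    ScreenConfig,
    reference_bias_qc,
    results_frame,
    two_stage_screen,
)
from . import io as mio

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full pipeline configuration; defaults are the published settings."""

    counts: str = ""
    sample_sheet: str = ""
    catalogue: str = ""
    annotation: str | None = None
    out_dir: str = "mam_run"

    maf_max: float = 0.90
    min_cov_autosome: int = 350
    min_cov_x: int = 250
    epsilon: float = 0.0025
    correction_rounds: int = 2

    b1: int = 1_000
    stage1_alpha: float = 0.005
    b2: int = 1_000_000
    fdr_q: float = 0.1

    enrichment_draws: int = 1000
    wgbs_permutations: int = 2000
    ase_min_depth: int = 10   # bases of quality >= 13 counted upstream
    ase_fdr_q: float = 0.01
    ase_min_sites: int = 2

    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def screen_config(self) -> ScreenConfig:
        return ScreenConfig(
            b1=self.b1,
            stage1_alpha=self.stage1_alpha,
            b2=self.b2,
            fdr_q=self.fdr_q,
            seed=self.seed,
        )

    def error_model(self) -> ErrorModel:
        return ErrorModel(epsilon=self.epsilon, n_rounds=self.correction_rounds)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the discovery pipeline; returns the manifest dict.

    Writes corrected counts, the screen results table, the optional
    enrichment table and ``manifest.json`` into ``config.out_dir``.
    """
    for name in ("counts", "sample_sheet", "catalogue"):
        path = getattr(config, name)
        if not path or not Path(path).exists():
            raise ConfigurationError(f"input {name!r} missing: {path!r}")
    if config.annotation and not Path(config.annotation).exists():
        raise ConfigurationError(f"annotation file missing: {config.annotation!r}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "mamscan",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    def record(stage: str, n_in: int, n_out: int) -> None:
        manifest["stages"][stage] = {
            "input": n_in,
            "retained": n_out,
            "dropped": n_in - n_out,
        }
        logger.info("%s: %d -> %d loci", stage, n_in, n_out)

    table = mio.read_allele_counts(config.counts, config.sample_sheet)
    catalogue = mio.read_snp_catalogue(config.catalogue)
    n0 = table.n_loci

    traced = trace_snps(table, catalogue)
    record("trace", n0, traced.n_loci)

    filtered = filter_loci(
        traced,
        maf_max=config.maf_max,
        min_cov_autosome=config.min_cov_autosome,
        min_cov_x=config.min_cov_x,
    )
    record("filter", traced.n_loci, filtered.n_loci)

    corrected = correct_sequencing_errors(filtered, config.error_model())
    record("correct", filtered.n_loci, corrected.n_loci)
    mio.write_allele_counts(corrected, out / "corrected_counts.tsv")

    genotypes = call_genotypes(corrected)
    results, crit = two_stage_screen(corrected, config.screen_config(), genotypes)
    frame = results_frame(results)
    frame.to_csv(out / "screen_results.tsv", sep="\t", index=False)
    n_sig = int(frame["significant"].sum())
    record("screen", corrected.n_loci, n_sig)
    manifest["bh_critical_value"] = crit
    manifest["n_significant"] = n_sig

    qc = reference_bias_qc(results, genotypes, corrected)
    manifest["reference_bias_qc"] = {
        "assessable": qc.assessable,
        "p_value": qc.p_value,
        "n_hom_ref": qc.n_hom_ref,
        "n_hom_alt": qc.n_hom_alt,
        "reason": qc.reason,
    }

    if config.annotation:
        from .enrichment import enrichment_test

        ann = mio.read_annotation_intervals(config.annotation)
        sig = frame[frame["significant"]]
        if len(sig):
            rng = np.random.default_rng(config.seed)
            enr = enrichment_test(
                sig, frame, ann, n_draws=config.enrichment_draws, rng=rng
            )
            enr.to_frame().to_csv(out / "enrichment.tsv", sep="\t", index=False)
            manifest["stages"]["enrich"] = {
                "input": len(sig),
                "retained": len(sig),
                "dropped": 0,
            }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
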