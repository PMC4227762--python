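"""Self-contained simulation studies: null calibration and power/recovery.

These run the full discovery chain (simulate -> filter -> correct ->
two-stage screen -> BH) on synthetic cohorts and summarise how the screen
behaves when the truth is known. They back both the test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .genotyping import correct_sequencing_errors, filter_loci
from .hwe_screen import ScreenConfig, two_stage_screen
from .simulate import SimulationParams, simulate_methylcap

__all__ = ["null_calibration_study", "power_recovery_study"]


def null_calibration_study(
    seed: int = 0,
    n_loci: int = 500,
    n_samples: int = 300,
    b1: int = 1000,
    b2: int = 20_000,
) -> dict:
    """Screen a fully biallelic cohort and summarise P-value calibration.

    Returns the empirical type-I error at nominal 0.05 and the
    Kolmogorov-Smirnov distance of the final P-values from Uniform(0,1).
    """
    params = SimulationParams(
        n_loci=n_loci, n_samples=n_samples, frac_monoallelic=0.0, seed=seed
    )
    table, _ = simulate_methylcap(params)
    corrected = correct_sequencing_errors(filter_loci(table))
    results, _ = two_stage_screen(
        corrected, ScreenConfig(b1=b1, b2=b2, seed=seed + 1)
    )
    p = np.array([r.p_final for r in results if r.p_final is not None])
    return {
        "n_tested": int(len(p)),
        "type1_at_005": float((p <= 0.05).mean()),
        "ks_statistic": float(stats.kstest(p, "uniform").statistic),
        "ks_critical_1pct": float(1.628 / np.sqrt(len(p))),
    }


def power_recovery_study(
    seed: int = 0,
    n_loci: int = 400,
    n_samples: int = 300,
    frac_monoallelic: float = 0.05,
    b1: int = 1000,
    b2: int = 100_000,
    fdr_q: float = 0.1,
) -> dict:
    """Mixed cohort: recover monoallelic loci at BH FDR ``fdr_q``.

    Returns sensitivity over the simulated monoallelic loci and the
    empirical false-discovery proportion among BH rejections.
    """
    params = SimulationParams(
        n_loci=n_loci,
        n_samples=n_samples,
        frac_monoallelic=frac_monoallelic,
        seed=seed,
    )
    table, truth = simulate_methylcap(params)
    corrected = correct_sequencing_errors(filter_loci(table))
    results, _ = two_stage_screen(
        corrected, ScreenConfig(b1=b1, b2=b2, fdr_q=fdr_q, seed=seed + 1)
    )
    mono = {
        (str(row.chrom), int(row.pos))
        for row in truth.loci.itertuples(index=False)
        if row.monoallelic
    }
    rejected = {(r.chrom, r.pos) for r in results if r.significant}
    n_true = len(mono)
    tp = len(rejected & mono)
    fp = len(rejected - mono)
    return {
        "n_monoallelic": n_true,
        "n_rejected": len(rejected),
        "sensitivity": tp / n_true if n_true else float("nan"),
        "empirical_fdr": fp / len(rejected) if rejected else 0.0,
    }
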