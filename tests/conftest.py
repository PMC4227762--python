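import numpy as np
import pandas as pd
import pytest

from mamscan.datamodel import AlleleCountTable


@pytest.fixture
def small_table() -> AlleleCountTable:
    """2 loci x 3 samples with a zero-coverage entry and a het profile."""
    loci = pd.DataFrame(
        {
            "chrom": ["1", "2"],
            "pos": [100, 200],
            "snp_id": ["rs1", None],
            "ref": ["A", "C"],
            "alt": ["G", "T"],
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "sex": ["female", "male", "female"],
        }
    )
    ref = np.array([[7, 3, 0], [0, 5, 2]])
    alt = np.array([[0, 1, 0], [4, 0, 3]])
    return AlleleCountTable(loci, samples, ref, alt)


def make_table(entries, samples=None):
    """Compact builder: entries = list of (chrom, pos, ref, alt, ref_row, alt_row)."""
    if samples is None:
        n = len(entries[0][4])
        samples = pd.DataFrame(
            {"sample_id": [f"s{j}" for j in range(n)], "sex": ["female"] * n}
        )
    loci = pd.DataFrame(
        {
            "chrom": [e[0] for e in entries],
            "pos": [e[1] for e in entries],
            "snp_id": [None] * len(entries),
            "ref": [e[2] for e in entries],
            "alt": [e[3] for e in entries],
        }
    )
    ref = np.array([e[4] for e in entries])
    alt = np.array([e[5] for e in entries])
    return AlleleCountTable(loci, samples, ref, alt)
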