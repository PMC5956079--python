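import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adipoclass.synthetic import ArchitectureSpec


def make_giant_file(path, rows, header=None):
    """Write a GIANT-dialect summary-statistics file from (id, chrom, pos,
    a1, a2, eaf, beta, se, n) tuples; P is computed consistently from
    beta/se unless a 10th element overrides it."""
    header = header or [
        "MarkerName", "Chr", "Pos", "Allele1", "Allele2",
        "FreqAllele1HapMapCEU", "b", "se", "p", "N",
    ]
    recs = []
    for row in rows:
        vid, chrom, pos, a1, a2, eaf, beta, se, n = row[:9]
        p = row[9] if len(row) > 9 else 2 * stats.norm.sf(abs(beta / se))
        recs.append([vid, chrom, pos, a1, a2, eaf, beta, se, p, n])
    pd.DataFrame(recs, columns=header).to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def giant_file(tmp_path):
    return make_giant_file(
        tmp_path / "bmi.tsv",
        [
            ("rs1", "1", 1_000_000, "A", "G", 0.30, 0.05, 0.01, 50_000),
            ("rs2", "2", 2_000_000, "C", "T", 0.45, -0.02, 0.008, 48_000),
            ("rs3", "3", 3_000_000, "G", "A", 0.12, 0.001, 0.012, 51_000),
        ],
    )


@pytest.fixture
def null_spec():
    """All true effects zero; moderate cohort for calibration checks."""
    return ArchitectureSpec(
        effect_size_bmi=0.0,
        effect_size_whr=0.0,
        r_target=0.5,
        n_individuals=20_000,
        causal_disease_beta=0.0,
        seed=11,
    )


@pytest.fixture
def default_spec():
    return ArchitectureSpec(seed=7)
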