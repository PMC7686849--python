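"""Shared fixtures: the study SNP panel and a haplotype panel whose
chromosome counts match the published haplotype table (84 TGCG of 198
chromosomes, one hemoglobin-missing TGCG/CACA man, etc.)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from haploscan import EGLN1_PANEL, HaplotypePanel, PhenotypeTable

# Chromosome counts among the 48 hemoglobin-measured men (96 chromosomes)
MEN_MEASURED = {
    "TGCG": 46, "TGGA": 13, "CACA": 12, "TACG": 8,
    "TGCA": 7, "CACG": 7, "CAGA": 3,
}
# ... and among all 50 women (100 chromosomes)
WOMEN = {
    "TGCG": 37, "CACA": 16, "TACG": 11, "TGCA": 8, "CAGA": 7, "CACG": 6,
    "TGGA": 5, "TACA": 3, "TGGG": 2, "TAGA": 2, "TAGG": 2, "CGCA": 1,
}
# The one hemoglobin-missing individual is a TGCG/CACA man, bringing the
# entire-cohort chromosome totals to 198 with 84 TGCG.
MISSING_MAN_PAIR = ("TGCG", "CACA")


def _pair_up(counts: dict[str, int]) -> list[tuple[str, str]]:
    chroms: list[str] = []
    for hap in sorted(counts):
        chroms.extend([hap] * counts[hap])
    assert len(chroms) % 2 == 0
    # deterministic interleaved pairing so most pairs are heterozygous
    half = len(chroms) // 2
    return list(zip(chroms[:half], chroms[half:]))


@pytest.fixture(scope="session")
def study_snps():
    return list(EGLN1_PANEL)


@pytest.fixture(scope="session")
def table_panel(study_snps):
    """99-individual phased panel + phenotype table matching the published
    chromosome counts; returns (panel, phenotypes, sample metadata frame)."""
    rng = np.random.default_rng(20161201)
    haplotypes, carriers, rows = [], [], []

    def add(sid, sex, pair, hb):
        haplotypes.extend(pair)
        carriers.extend([sid, sid])
        rows.append({"sample_id": sid, "sex": sex, "hb": hb})

    i = 0
    for pair in _pair_up(MEN_MEASURED):
        i += 1
        add(f"M{i:03d}", "male", pair, round(float(rng.normal(15.4, 0.8)), 2))
    i += 1
    add(f"M{i:03d}", "male", MISSING_MAN_PAIR, np.nan)
    j = 0
    for pair in _pair_up(WOMEN):
        j += 1
        add(f"F{j:03d}", "female", pair, round(float(rng.normal(13.3, 1.0)), 2))

    panel = HaplotypePanel(study_snps, haplotypes, carriers)
    pheno = PhenotypeTable(pd.DataFrame(rows))
    return panel, pheno
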