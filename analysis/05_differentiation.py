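#!/usr/bin/env python
"""Differentiation statistics: windowed F_ST/PBS/PBS' and haplotype F_ST.

Scans the Balding-Nichols frequency table (drifted focal population HNA)
with 5 kb windows / 5 kb steps, reporting mean PBS' per population, and
runs the haplotype-level Weir-Cockerham F_ST permutation test between the
two synthetic cohorts (expected: no differentiation, as in the study's
La Paz vs El Alto comparison).
"""

from pathlib import Path

import numpy as np

from haploscan import RunConfig, read_genotype_vcf, read_phenotypes_tsv
from haploscan.phasing import em_phase, panel_from_phasing
from haploscan.pipeline import (
    _attach_metadata,
    load_pop_freq_table,
    stage_fst,
    stage_pbs_scan,
)

ROOT = Path(__file__).resolve().parents[1]
FIX = ROOT / "results" / "fixtures"
OUT = ROOT / "results"

cfg = RunConfig(
    vcf=str(FIX / "cohort.vcf"),
    phenotypes=str(FIX / "phenotypes.tsv"),
    out_dir=str(OUT),
    freqs_tsv=str(FIX / "drift_freqs.tsv"),
    sizes_tsv=str(FIX / "drift_sizes.tsv"),
    triplet=["HNA", "CLM", "CEU"],
    n_permutations=2000,
    seed=1,
)
path = stage_pbs_scan(cfg, OUT)
print(f"wrote {path}")
import pandas as pd

wins = pd.read_csv(path, sep="\t")
for pop in ("HNA", "CLM", "CEU"):
    col = wins.loc[wins["complete"], f"pbs_prime_{pop}"]
    print(f"mean PBS' {pop}: {col.mean():+.3f} +/- {col.std(ddof=1):.3f}")

pheno = read_phenotypes_tsv(FIX / "phenotypes.tsv")
gm = _attach_metadata(read_genotype_vcf(FIX / "cohort.vcf"), pheno)
panel = panel_from_phasing(em_phase(gm, seed=1), gm)
fst_path = stage_fst(panel, gm, cfg, OUT)
res = pd.read_csv(fst_path, sep="\t").iloc[0]
print(
    f"haplotype F_ST {res['pop_a']} vs {res['pop_b']}: {res['fst']:.4f} "
    f"(p = {res['p_value']:.3f}, {int(res['n_permutations'])} permutations)"
)
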