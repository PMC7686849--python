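#!/usr/bin/env python
"""Haplotype bifurcation around the rs1769792 G (cohort-major) allele.

Builds upstream and downstream bifurcation trees on the EM-phased panel
and prints the extended-homozygosity decay per depth.
"""

from pathlib import Path

from haploscan import RunConfig, read_genotype_vcf, read_phenotypes_tsv
from haploscan.bifurcation import build_bifurcation, extended_homozygosity
from haploscan.phasing import em_phase, panel_from_phasing
from haploscan.pipeline import _attach_metadata, stage_bifurcate

ROOT = Path(__file__).resolve().parents[1]
FIX = ROOT / "results" / "fixtures"
OUT = ROOT / "results"

pheno = read_phenotypes_tsv(FIX / "phenotypes.tsv")
gm = _attach_metadata(read_genotype_vcf(FIX / "cohort.vcf"), pheno)
panel = panel_from_phasing(em_phase(gm, seed=1), gm)

cfg = RunConfig(
    vcf=str(FIX / "cohort.vcf"), phenotypes=str(FIX / "phenotypes.tsv"),
    out_dir=str(OUT), core_snp="rs1769792", core_allele="G",
)
for p in stage_bifurcate(panel, cfg, OUT):
    print(f"wrote {p}")

for direction in ("upstream", "downstream"):
    tree = build_bifurcation(panel, "rs1769792", "G", direction)
    ehh = extended_homozygosity(tree)
    decay = " ".join(f"{v:.3f}" for v in ehh)
    print(f"{direction}: root {tree.root_count} chromosomes, EHH by depth: {decay}")
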