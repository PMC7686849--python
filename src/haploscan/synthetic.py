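"""Synthetic cohorts and multi-population frequency tables.

Two generators cover every input the pipeline needs so that all stages are
testable without any external download:

* :func:`gen_cohort` draws a two-cohort diploid study population by random
  union of gametes from a declared haplotype frequency spectrum, then
  simulates hemoglobin as a sex-specific Gaussian baseline plus optional
  additive per-haplotype effects.  The defaults mirror the Andean study
  this package models: 99 individuals (48 at ~3700 m, 51 at ~4000 m), the
  published 12-haplotype spectrum over the four EGLN1 tag SNPs, and Hb
  baselines of 15.4 +/- 0.8 g/dL (men) and 13.3 +/- 1.0 g/dL (women).
* :func:`gen_drift_populations` draws per-population allele frequencies
  around a shared ancestral frequency under the Balding-Nichols model, for
  exercising the F_ST / PBS machinery at known differentiation.

All randomness flows through one ``numpy`` Generator constructed from the
spec's seed; fixed seed means byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import (
    GenotypeMatrix,
    HaplotypePanel,
    PhenotypeTable,
    SampleRecord,
    SnpRecord,
    write_genotype_vcf,
)

__all__ = [
    "EGLN1_PANEL",
    "STUDY_SPECTRUM",
    "CohortSpec",
    "DriftSpec",
    "gen_cohort",
    "gen_drift_populations",
    "write_fixture_set",
]

# The four EGLN1-region tag SNPs (GRCh37 positions; GRCh38 as alternate),
# with the major/minor designation observed in the Bolivian cohort.
EGLN1_PANEL: tuple[SnpRecord, ...] = (
    SnpRecord("rs2486740", "1", 231517552, "T", "C", pos_alt=231381806),
    SnpRecord("rs508618", "1", 231532312, "G", "A", pos_alt=231396566),
    SnpRecord("rs12097901", "1", 231557255, "C", "G", pos_alt=231421509),
    SnpRecord("rs1769792", "1", 231598618, "G", "A", pos_alt=231462872),
)

# Published 12-haplotype frequency spectrum over the panel (alleles in SNP
# order rs2486740, rs508618, rs12097901, rs1769792); sums to 1.
STUDY_SPECTRUM: dict[str, float] = {
    "TGCG": 0.424,
    "CACA": 0.146,
    "TACG": 0.096,
    "TGGA": 0.091,
    "TGCA": 0.076,
    "CACG": 0.066,
    "CAGA": 0.051,
    "TACA": 0.015,
    "TGGG": 0.010,
    "TAGA": 0.010,
    "TAGG": 0.010,
    "CGCA": 0.005,
}


@dataclass
class CohortSpec:
    """Study-cohort generator settings (defaults = the modelled study)."""

    # cohort label -> (n individuals, n men, altitude m)
    cohorts: Mapping[str, tuple[int, int, float]] = field(
        default_factory=lambda: {
            "LaPaz": (48, 24, 3700.0),
            "ElAlto": (51, 25, 4000.0),
        }
    )
    spectrum: Mapping[str, float] = field(
        default_factory=lambda: dict(STUDY_SPECTRUM)
    )
    snps: Sequence[SnpRecord] = EGLN1_PANEL
    hb_mean_male: float = 15.4
    hb_sd_male: float = 0.8
    hb_mean_female: float = 13.3
    hb_sd_female: float = 1.0
    # additive Hb effect (g/dL per copy) of carrying a haplotype; default
    # null.  Keys are haplotype strings.
    hb_effects: Mapping[str, float] = field(default_factory=dict)
    age_mean: float = 25.1
    age_sd: float = 3.2
    age_min: float = 20.0
    spo2_mean: float = 90.5
    spo2_sd: float = 2.6
    n_hb_missing: int = 0  # individuals with hemoglobin left unmeasured
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.spectrum.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"spectrum frequencies sum to {total}, not 1")
        if min(self.hb_sd_male, self.hb_sd_female, self.age_sd, self.spo2_sd) <= 0:
            raise ValueError("standard deviations must be positive")
        n = len(self.snps)
        for h in self.spectrum:
            if len(h) != n:
                raise ValueError(
                    f"haplotype {h!r} length does not match the {n}-SNP panel"
                )


def egln1_like_spec(effect_tgcg: float = 0.35, **kwargs) -> CohortSpec:
    """Preset with a synthetic +effect on the TGCG haplotype.

    The effect size is a synthetic choice for power/recovery exercises, not
    an estimate from any dataset.
    """
    return CohortSpec(hb_effects={"TGCG": effect_tgcg}, **kwargs)


def gen_cohort(
    spec: CohortSpec | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, PhenotypeTable, dict]:
    """Draw a diploid cohort by random union of gametes from the spectrum.

    Each individual receives two haplotypes drawn i.i.d. from the spectrum,
    so Hardy-Weinberg proportions hold by construction.  Hemoglobin is
    sex baseline + sum of per-haplotype additive effects + Gaussian noise
    at the baseline SD.  Returns (genotypes, phenotypes, truth), where the
    truth record carries the drawn haplotype pair per sample for
    phasing-accuracy checks, plus the generating spectrum.
    """
    spec = spec or CohortSpec()
    if seed is None:
        seed = spec.seed
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    haps = list(spec.spectrum)
    probs = np.array([spec.spectrum[h] for h in haps])
    probs = probs / probs.sum()
    snps = list(spec.snps)

    samples: list[SampleRecord] = []
    rows = []
    truth_pairs: dict[str, tuple[str, str]] = {}
    for cohort, (n, n_men, altitude) in spec.cohorts.items():
        sexes = ["male"] * n_men + ["female"] * (n - n_men)
        for i, sex in enumerate(sexes):
            sid = f"{cohort}_{i + 1:03d}"
            age = float(
                np.clip(rng.normal(spec.age_mean, spec.age_sd), spec.age_min, None)
            )
            samples.append(
                SampleRecord(sid, cohort=cohort, sex=sex, age=round(age, 1),
                             altitude=altitude)
            )
            pair = tuple(np.array(haps)[rng.choice(len(haps), 2, p=probs)])
            truth_pairs[sid] = pair
            base, sd = (
                (spec.hb_mean_male, spec.hb_sd_male)
                if sex == "male"
                else (spec.hb_mean_female, spec.hb_sd_female)
            )
            hb = base + rng.normal(0.0, sd)
            for h in pair:
                hb += spec.hb_effects.get(h, 0.0)
            spo2 = float(np.clip(rng.normal(spec.spo2_mean, spec.spo2_sd), 50, 100))
            rows.append(
                {
                    "sample_id": sid,
                    "cohort": cohort,
                    "sex": sex,
                    "age": round(age, 1),
                    "altitude": altitude,
                    "hb": round(float(hb), 2),
                    "spo2": round(spo2, 1),
                }
            )
    # blank out hemoglobin for a random subset if requested
    if spec.n_hb_missing:
        idx = rng.choice(len(rows), size=spec.n_hb_missing, replace=False)
        for i in idx:
            rows[i]["hb"] = np.nan

    dosage = np.zeros((len(samples), len(snps)), dtype=np.int16)
    for i, s in enumerate(samples):
        h1, h2 = truth_pairs[s.sample_id]
        for j, snp in enumerate(snps):
            dosage[i, j] = (h1[j] == snp.allele_b) + (h2[j] == snp.allele_b)
    gm = GenotypeMatrix(samples, snps, dosage)
    pheno = PhenotypeTable(pd.DataFrame(rows))
    truth = {
        "spectrum": dict(spec.spectrum),
        "hb_effects": dict(spec.hb_effects),
        "pairs": truth_pairs,
        "seed": seed if isinstance(seed, int) else None,
    }
    return gm, pheno, truth


def truth_panel(gm: GenotypeMatrix, truth: dict) -> HaplotypePanel:
    """The generator's true phased panel, for phasing-accuracy checks."""
    haps, carriers = [], []
    for s in gm.samples:
        h1, h2 = truth["pairs"][s.sample_id]
        haps.extend([h1, h2])
        carriers.extend([s.sample_id, s.sample_id])
    return HaplotypePanel(gm.snps, haps, carriers)


@dataclass
class DriftSpec:
    """Balding-Nichols multi-population frequency generator settings."""

    n_sites: int = 500
    region_length: int = 436_300  # bp; matches the scanned region scale
    # population label -> drift parameter F (0 <= F < 1)
    drift: Mapping[str, float] = field(
        default_factory=lambda: {"HNA": 0.10, "CLM": 0.01, "CEU": 0.01}
    )
    # haploid sample sizes per population
    sizes: Mapping[str, int] = field(
        default_factory=lambda: {"HNA": 84, "CLM": 100, "CEU": 100}
    )
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        for pop, f in self.drift.items():
            if not 0.0 <= f < 1.0:
                raise ValueError(f"drift F for {pop} must be in [0, 1)")
        if set(self.drift) != set(self.sizes):
            raise ValueError("drift and sizes must name the same populations")


def gen_drift_populations(
    spec: DriftSpec | None = None,
    seed: int | np.random.Generator | None = None,
):
    """Sampled per-population allele frequencies under Balding-Nichols.

    Per site, an ancestral frequency p is drawn uniformly on
    [ancestral_low, ancestral_high]; each population's true frequency is
    Beta(p(1-F)/F, (1-p)(1-F)/F) (F = 0 copies p exactly), and the
    reported frequency is a binomial sample at the population's haploid
    size — the sampling noise a real cohort would add.
    """
    from .differentiation import PopFreqTable

    spec = spec or DriftSpec()
    if seed is None:
        seed = spec.seed
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    pops = list(spec.drift)
    positions = np.sort(
        rng.choice(spec.region_length, size=spec.n_sites, replace=False)
    )
    anc = rng.uniform(spec.ancestral_low, spec.ancestral_high, spec.n_sites)
    freqs = np.zeros((len(pops), spec.n_sites))
    for i, pop in enumerate(pops):
        f = spec.drift[pop]
        n = spec.sizes[pop]
        if f == 0.0:
            true = anc
        else:
            c = (1.0 - f) / f
            true = rng.beta(anc * c, (1.0 - anc) * c)
        freqs[i] = rng.binomial(n, true) / n
    return PopFreqTable(
        pops=pops,
        positions=positions,
        freqs=freqs,
        sizes=np.array([spec.sizes[p] for p in pops]),
        region_length=spec.region_length,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_set(
    outdir: str | Path,
    cohort_spec: CohortSpec | None = None,
    drift_spec: DriftSpec | None = None,
    seed: int = 0,
) -> dict:
    """Write a complete fixture set (VCF + phenotype TSV + truth JSON +
    drift frequency TSV) and return a manifest with sha256 checksums."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    gm, pheno, truth = gen_cohort(cohort_spec, seed=rng)
    vcf = outdir / "cohort.vcf"
    write_genotype_vcf(gm, vcf)
    pheno_path = outdir / "phenotypes.tsv"
    pheno.to_tsv(pheno_path)
    truth_path = outdir / "truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "spectrum": truth["spectrum"],
                "hb_effects": truth["hb_effects"],
                "pairs": {k: list(v) for k, v in truth["pairs"].items()},
                "seed": seed,
            },
            indent=1,
            sort_keys=True,
        )
    )
    pft = gen_drift_populations(drift_spec, seed=rng)
    drift_path = outdir / "drift_freqs.tsv"
    frame = pft.to_frame()
    frame.to_csv(drift_path, sep="\t", index=False)
    sizes_path = outdir / "drift_sizes.tsv"
    pd.DataFrame({"population": pft.pops, "haploid_n": pft.sizes}).to_csv(
        sizes_path, sep="\t", index=False
    )
    files = [vcf, pheno_path, truth_path, drift_path, sizes_path]
    return {
        "seed": seed,
        "files": {f.name: _sha256(f) for f in files},
        "outdir": str(outdir),
    }
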