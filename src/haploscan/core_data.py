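"""Data model and I/O for small SNP-panel genotype studies.

The study design this package targets is a cohort of ~100 diploid
individuals typed at a handful of tag SNPs (here, four SNPs spanning the
EGLN1 region), with a per-sample phenotype table (hemoglobin, SpO2, blood
pressure, anthropometrics) and, for the comparative analyses, externally
phased haplotype panels.  Everything downstream — per-SNP summary
statistics, LD, EM phasing, association models, differentiation scans —
consumes the containers defined here.

Coordinate convention: SNP positions are 1-based physical coordinates as in
VCF.  Window arithmetic elsewhere in the package uses 0-based half-open
intervals; each site of conversion is documented where it happens.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "SnpRecord",
    "SampleRecord",
    "GenotypeMatrix",
    "PhenotypeTable",
    "HaplotypePanel",
    "read_genotype_vcf",
    "read_phased_vcf",
    "read_phenotypes_tsv",
    "write_genotype_vcf",
    "write_phased_vcf",
    "genotype_counts",
]

MISSING = -1  # internal sentinel inside the raw array; exposed via the mask

SEXES = ("male", "female")


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic SNP.  ``allele_a`` is the designated major allele.

    ``pos`` is the 1-based GRCh37 coordinate; an optional alternate-build
    coordinate may be carried in ``pos_alt`` (e.g. GRCh38) but is never used
    in computation.
    """

    snp_id: str
    chrom: str
    pos: int
    allele_a: str
    allele_b: str
    pos_alt: int | None = None

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.snp_id}: alleles must differ")
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1 (1-based)")


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    cohort: str | None = None
    sex: str | None = None
    age: float | None = None
    altitude: float | None = None

    def __post_init__(self) -> None:
        if self.sex is not None and self.sex not in SEXES:
            raise ValueError(f"{self.sample_id}: sex must be one of {SEXES}")
        if self.age is not None and not self.age > 0:
            raise ValueError(f"{self.sample_id}: age must be positive")


class GenotypeMatrix:
    """Samples x SNPs diploid minor-allele dosage with explicit missingness.

    ``dosage[i, j]`` counts copies of ``snps[j].allele_b`` carried by
    ``samples[i]`` (0, 1 or 2).  Missing calls are flagged in ``missing``
    and the corresponding dosage entry is undefined (never read).
    """

    def __init__(
        self,
        samples: Sequence[SampleRecord],
        snps: Sequence[SnpRecord],
        dosage: np.ndarray,
        missing: np.ndarray | None = None,
        phased_input: bool = False,
    ) -> None:
        dosage = np.asarray(dosage, dtype=np.int16)
        if dosage.shape != (len(samples), len(snps)):
            raise ValueError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(samples)} samples x {len(snps)} snps"
            )
        if missing is None:
            missing = np.zeros(dosage.shape, dtype=bool)
        missing = np.asarray(missing, dtype=bool)
        if missing.shape != dosage.shape:
            raise ValueError("missing mask shape mismatch")
        ok = missing | ((dosage >= 0) & (dosage <= 2))
        if not ok.all():
            raise ValueError("dosage values must be in {0,1,2} where not missing")
        ids = [s.snp_id for s in snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids in panel")
        self.samples = list(samples)
        self.snps = list(snps)
        self.dosage = dosage
        self.missing = missing
        self.phased_input = phased_input
        self._snp_index = {s.snp_id: j for j, s in enumerate(self.snps)}
        self._sample_index = {s.sample_id: i for i, s in enumerate(self.samples)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_index(self, snp_id: str) -> int:
        try:
            return self._snp_index[snp_id]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} not in panel") from None

    def snp(self, snp_id: str) -> SnpRecord:
        return self.snps[self.snp_index(snp_id)]

    def column(self, snp_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Dosage column and its missing mask for one SNP."""
        j = self.snp_index(snp_id)
        return self.dosage[:, j], self.missing[:, j]

    def sample_mask(self, stratum: Mapping[str, str] | None) -> np.ndarray:
        """Boolean mask of samples matching a {field: value} filter."""
        mask = np.ones(self.n_samples, dtype=bool)
        if stratum:
            for key, value in stratum.items():
                mask &= np.array(
                    [getattr(s, key, None) == value for s in self.samples]
                )
        return mask

    def subset(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self._sample_index[s] for s in sample_ids]
        return GenotypeMatrix(
            [self.samples[i] for i in idx],
            self.snps,
            self.dosage[idx],
            self.missing[idx],
            phased_input=self.phased_input,
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            [s.snp_id for s in self.snps] == [s.snp_id for s in other.snps]
            and [s.sample_id for s in self.samples]
            == [s.sample_id for s in other.samples]
            and np.array_equal(self.missing, other.missing)
            and np.array_equal(
                np.where(self.missing, 0, self.dosage),
                np.where(other.missing, 0, other.dosage),
            )
        )


# Typed phenotype columns with the admissible range used for unit checks.
# hb is g/dL, spo2 percent, heart_rate bpm, sbp/dbp mmHg, height cm,
# weight kg, bmi kg/m^2.
_PHENO_NUMERIC = {
    "hb": (5.0, 25.0),
    "spo2": (50.0, 100.0),
    "heart_rate": (20.0, 250.0),
    "sbp": (60.0, 260.0),
    "dbp": (30.0, 160.0),
    "height": (100.0, 230.0),
    "weight": (25.0, 250.0),
    "bmi": (10.0, 60.0),
    "age": (0.0, 120.0),
    "altitude": (0.0, 6000.0),
}
_PHENO_BOOL = ("smoking", "alcohol", "exercise")


class PhenotypeTable:
    """Per-sample phenotype/covariate table backed by a pandas DataFrame.

    Known numeric columns are range-checked at construction; unknown columns
    are carried through untouched so callers can stratify on them.
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        if "sample_id" in frame.columns:
            frame = frame.set_index("sample_id")
        if frame.index.name != "sample_id":
            raise ValueError("phenotype table requires a sample_id column")
        frame = frame.copy()
        for col, (lo, hi) in _PHENO_NUMERIC.items():
            if col in frame.columns:
                vals = pd.to_numeric(frame[col], errors="coerce")
                bad_parse = vals.isna() & frame[col].notna()
                if bad_parse.any():
                    row = frame.index[bad_parse][0]
                    raise ValueError(
                        f"unparseable numeric in column {col!r}, sample {row!r}"
                    )
                out = vals.dropna()
                if ((out < lo) | (out > hi)).any():
                    bad = out[(out < lo) | (out > hi)].index[0]
                    raise ValueError(
                        f"{col} out of admissible range ({lo}, {hi}) "
                        f"for sample {bad!r}"
                    )
                frame[col] = vals
        for col in _PHENO_BOOL:
            if col in frame.columns:
                frame[col] = frame[col].astype("boolean")
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    def value(self, sample_id: str, column: str) -> float | None:
        v = self.frame.at[sample_id, column]
        return None if pd.isna(v) else float(v)

    def column(self, name: str) -> pd.Series:
        return self.frame[name]

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t")


class HaplotypePanel:
    """Phased chromosomes over an ordered SNP panel.

    ``haplotypes[k]`` is a string with one allele character per SNP, in SNP
    position order; ``carriers[k]`` is the sample id owning chromosome k.
    Diploid panels carry exactly two chromosomes per sample, consecutively.
    """

    def __init__(
        self,
        snps: Sequence[SnpRecord],
        haplotypes: Sequence[str],
        carriers: Sequence[str],
    ) -> None:
        if len(haplotypes) != len(carriers):
            raise ValueError("one carrier id per chromosome required")
        n = len(snps)
        for h in haplotypes:
            if len(h) != n:
                raise ValueError(
                    f"haplotype {h!r} has {len(h)} alleles, panel has {n} SNPs"
                )
        self.snps = list(snps)
        self.haplotypes = list(haplotypes)
        self.carriers = list(carriers)
        self._snp_index = {s.snp_id: j for j, s in enumerate(self.snps)}

    @property
    def n_chrom(self) -> int:
        return len(self.haplotypes)

    @property
    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.carriers:
            seen.setdefault(c, None)
        return list(seen)

    def snp_index(self, snp_id: str) -> int:
        try:
            return self._snp_index[snp_id]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} not in panel") from None

    def alleles_at(self, snp_id: str) -> list[str]:
        j = self.snp_index(snp_id)
        return [h[j] for h in self.haplotypes]

    def subset_samples(self, sample_ids: Iterable[str]) -> "HaplotypePanel":
        keep = set(sample_ids)
        haps, carr = [], []
        for h, c in zip(self.haplotypes, self.carriers):
            if c in keep:
                haps.append(h)
                carr.append(c)
        return HaplotypePanel(self.snps, haps, carr)

    def to_genotype_matrix(
        self, samples: Sequence[SampleRecord] | None = None
    ) -> GenotypeMatrix:
        """Collapse phase: dosage of allele_b per sample per SNP."""
        by_sample: dict[str, list[str]] = {}
        for h, c in zip(self.haplotypes, self.carriers):
            by_sample.setdefault(c, []).append(h)
        ids = list(by_sample)
        for sid, haps in by_sample.items():
            if len(haps) != 2:
                raise ValueError(f"sample {sid} has {len(haps)} chromosomes")
        if samples is None:
            samples = [SampleRecord(sample_id=sid) for sid in ids]
        else:
            if [s.sample_id for s in samples] != ids:
                raise ValueError("sample records do not match panel carriers")
        dosage = np.zeros((len(ids), len(self.snps)), dtype=np.int16)
        for i, sid in enumerate(ids):
            h1, h2 = by_sample[sid]
            for j, snp in enumerate(self.snps):
                dosage[i, j] = (h1[j] == snp.allele_b) + (h2[j] == snp.allele_b)
        return GenotypeMatrix(samples, self.snps, dosage)


# ---------------------------------------------------------------------------
# VCF I/O (pysam; VCF 4.2, GT only; plain or bgzipped input)
# ---------------------------------------------------------------------------


def _designate_alleles(
    ref: str, alt: str, n_ref: int, n_alt: int
) -> tuple[str, str]:
    """Major/minor designation by cohort frequency, ties alphabetical."""
    if n_alt > n_ref or (n_alt == n_ref and alt < ref):
        return alt, ref
    return ref, alt


def read_genotype_vcf(
    path: str | Path,
    panel_snp_ids: Sequence[str] | None = None,
    samples: Sequence[SampleRecord] | None = None,
) -> GenotypeMatrix:
    """Read diploid genotypes for a SNP panel from a VCF.

    Dosage counts the designated minor allele, where major/minor are
    assigned by allele frequency among the loaded samples (ties broken
    alphabetically, the lexically smaller allele becoming major).  If
    ``panel_snp_ids`` is given, records are matched by ID or ``chrom:pos``
    and every requested SNP must be present and biallelic.  Phased
    separators are recorded in ``phased_input`` so the same file can also
    feed :func:`read_phased_vcf`.
    """
    requested = list(panel_snp_ids) if panel_snp_ids is not None else None
    with pysam.VariantFile(str(path)) as vf:
        sample_ids = list(vf.header.samples)
        rows: list[tuple[SnpRecord, np.ndarray, np.ndarray]] = []
        seen: dict[str, int] = {}
        all_phased = True
        for rec in vf:
            keys = {rec.id, f"{rec.chrom}:{rec.pos}"}
            if requested is not None and not keys & set(requested):
                continue
            if rec.alts is None or len(rec.alts) != 1:
                if requested is not None:
                    raise ValueError(
                        f"SNP {rec.id or rec.chrom + ':' + str(rec.pos)} "
                        "is not biallelic"
                    )
                continue
            ref, alt = rec.ref, rec.alts[0]
            n = len(sample_ids)
            alt_count = np.zeros(n, dtype=np.int16)
            miss = np.zeros(n, dtype=bool)
            n_ref = n_alt = 0
            for i, sid in enumerate(sample_ids):
                gt = rec.samples[sid]["GT"]
                if gt is None or len(gt) != 2:
                    raise ValueError(
                        f"non-diploid genotype for sample {sid} at "
                        f"{rec.chrom}:{rec.pos}"
                    )
                if not rec.samples[sid].phased:
                    all_phased = False
                if gt[0] is None or gt[1] is None:
                    miss[i] = True
                    continue
                alt_count[i] = sum(gt)
                n_alt += sum(gt)
                n_ref += 2 - sum(gt)
            snp_id = rec.id or f"{rec.chrom}:{rec.pos}"
            major, minor = _designate_alleles(ref, alt, n_ref, n_alt)
            dosage = alt_count if minor == alt else 2 - alt_count
            dosage[miss] = 0
            if snp_id in seen:
                raise ValueError(f"duplicate SNP id {snp_id} in VCF")
            seen[snp_id] = len(rows)
            rows.append(
                (
                    SnpRecord(snp_id, rec.chrom, rec.pos, major, minor),
                    dosage,
                    miss,
                )
            )
    if requested is not None:
        missing_snps = [
            r
            for r in requested
            if r not in seen
            and r not in {f"{s.chrom}:{s.pos}" for s, _, _ in rows}
        ]
        if missing_snps:
            raise ValueError(f"requested SNP(s) not found in VCF: {missing_snps}")
        order = []
        for r in requested:
            if r in seen:
                order.append(seen[r])
            else:
                order.append(
                    next(
                        k
                        for k, (s, _, _) in enumerate(rows)
                        if f"{s.chrom}:{s.pos}" == r
                    )
                )
        rows = [rows[k] for k in order]
    if samples is None:
        samples = [SampleRecord(sample_id=sid) for sid in sample_ids]
    elif [s.sample_id for s in samples] != sample_ids:
        raise ValueError("sample records do not match VCF sample order")
    snps = [r[0] for r in rows]
    dosage = np.stack([r[1] for r in rows], axis=1) if rows else np.zeros((len(samples), 0), dtype=np.int16)
    miss = np.stack([r[2] for r in rows], axis=1) if rows else np.zeros((len(samples), 0), dtype=bool)
    return GenotypeMatrix(samples, snps, dosage, miss, phased_input=all_phased)


def read_phased_vcf(path: str | Path) -> HaplotypePanel:
    """Read a fully phased VCF into a haplotype panel.

    Every GT must use the phased ``|`` separator; otherwise the caller is
    told to run phasing first.  Allele strings are ordered by SNP position.
    """
    with pysam.VariantFile(str(path)) as vf:
        sample_ids = list(vf.header.samples)
        recs = []
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"record at {rec.chrom}:{rec.pos} is not biallelic"
                )
            alleles_per_sample = []
            n_ref = n_alt = 0
            for sid in sample_ids:
                call = rec.samples[sid]
                gt = call["GT"]
                if gt is None or len(gt) != 2 or gt[0] is None or gt[1] is None:
                    raise ValueError(
                        f"missing genotype at {rec.chrom}:{rec.pos} "
                        f"sample {sid}: phased panels must be complete"
                    )
                if not call.phased:
                    raise ValueError(
                        f"unphased genotype at {rec.chrom}:{rec.pos} sample "
                        f"{sid}: run phasing (em_phase) first"
                    )
                pair = (rec.alleles[gt[0]], rec.alleles[gt[1]])
                n_alt += sum(g == 1 for g in gt)
                n_ref += sum(g == 0 for g in gt)
                alleles_per_sample.append(pair)
            major, minor = _designate_alleles(rec.ref, rec.alts[0], n_ref, n_alt)
            snp_id = rec.id or f"{rec.chrom}:{rec.pos}"
            recs.append(
                (
                    SnpRecord(snp_id, rec.chrom, rec.pos, major, minor),
                    alleles_per_sample,
                )
            )
    recs.sort(key=lambda r: r[0].pos)
    snps = [r[0] for r in recs]
    haplotypes, carriers = [], []
    for i, sid in enumerate(sample_ids):
        for k in range(2):
            haplotypes.append("".join(r[1][i][k] for r in recs))
            carriers.append(sid)
    return HaplotypePanel(snps, haplotypes, carriers)


def read_phenotypes_tsv(path: str | Path) -> PhenotypeTable:
    """Read a header-named TSV phenotype table (gzip transparently)."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in frame.columns:
        raise ValueError("phenotype TSV must have a sample_id column")
    return PhenotypeTable(frame)


def _vcf_header(snps: Sequence[SnpRecord], sample_ids: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for chrom in dict.fromkeys(s.chrom for s in snps):
        maxpos = max(s.pos for s in snps if s.chrom == chrom)
        header.contigs.add(chrom, length=maxpos + 10_000_000)
    header.formats.add("GT", 1, "String", "Genotype")
    for sid in sample_ids:
        header.add_sample(sid)
    return header


def write_genotype_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write unphased genotypes as VCF 4.2 with REF=major, ALT=minor."""
    sample_ids = [s.sample_id for s in gm.samples]
    header = _vcf_header(gm.snps, sample_ids)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, snp in enumerate(sorted(gm.snps, key=lambda s: (s.chrom, s.pos))):
            col = gm.snp_index(snp.snp_id)
            rec = out.new_record(
                contig=snp.chrom,
                start=snp.pos - 1,  # pysam start is 0-based
                alleles=(snp.allele_a, snp.allele_b),
                id=snp.snp_id,
            )
            for i, sid in enumerate(sample_ids):
                if gm.missing[i, col]:
                    rec.samples[sid]["GT"] = (None, None)
                else:
                    d = int(gm.dosage[i, col])
                    rec.samples[sid]["GT"] = ((0, 0), (0, 1), (1, 1))[d]
                rec.samples[sid].phased = False
            out.write(rec)


def write_phased_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a haplotype panel as a phased VCF (two chromosomes per sample)."""
    by_sample: dict[str, list[str]] = {}
    for h, c in zip(panel.haplotypes, panel.carriers):
        by_sample.setdefault(c, []).append(h)
    sample_ids = list(by_sample)
    header = _vcf_header(panel.snps, sample_ids)
    order = sorted(range(len(panel.snps)), key=lambda j: panel.snps[j].pos)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in order:
            snp = panel.snps[j]
            rec = out.new_record(
                contig=snp.chrom,
                start=snp.pos - 1,
                alleles=(snp.allele_a, snp.allele_b),
                id=snp.snp_id,
            )
            for sid in sample_ids:
                h1, h2 = by_sample[sid]
                rec.samples[sid]["GT"] = (
                    int(h1[j] == snp.allele_b),
                    int(h2[j] == snp.allele_b),
                )
                rec.samples[sid].phased = True
            out.write(rec)


def genotype_counts(
    gm: GenotypeMatrix,
    snp_id: str,
    stratum: Mapping[str, str] | None = None,
) -> tuple[int, int, int, int]:
    """Genotype counts (n_AA, n_AB, n_BB, n_missing) for one SNP.

    n_AA counts homozygotes for the designated major allele (dosage 0).
    The stratum filter matches SampleRecord fields, e.g.
    ``{"cohort": "LaPaz"}`` or ``{"sex": "male"}``.
    """
    mask = gm.sample_mask(stratum)
    if not mask.any():
        raise ValueError(f"empty stratum {stratum!r}")
    dos, miss = gm.column(snp_id)
    dos, miss = dos[mask], miss[mask]
    n_missing = int(miss.sum())
    dos = dos[~miss]
    return (
        int((dos == 0).sum()),
        int((dos == 1).sum()),
        int((dos == 2).sum()),
        n_missing,
    )
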