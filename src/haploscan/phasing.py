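"""Multi-locus EM haplotype phasing for small SNP panels.

Maximum-likelihood haplotype frequencies under random union of gametes
(Excoffier-Slatkin EM): the E-step weights each ordered haplotype pair
compatible with an individual's multilocus genotype by the product of the
current frequency estimates; the M-step re-estimates frequencies from the
expected gamete counts.  Suited to panels of up to ~12 SNPs, where the
2**(h-1) phase resolutions per individual stay enumerable.

Also builds the haplotype/phenotype summary table (distinct haplotypes with
chromosome counts, frequencies and per-carrier-chromosome phenotype
mean +/- SD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import GenotypeMatrix, HaplotypePanel, PhenotypeTable

__all__ = ["PhasingResult", "em_phase", "haplotype_table", "panel_from_phasing"]

LOGLIK_TOL = 1e-8
MAX_ITER = 2000
N_RESTARTS = 10
MAX_HET = 20  # refuse samples whose phase ambiguity cannot be enumerated


@dataclass
class PhasingResult:
    """EM phasing output for one genotype matrix.

    ``hap_freqs`` maps haplotype strings (alleles in panel SNP order) to
    maximum-likelihood frequencies.  ``posteriors`` holds, per sample, the
    posterior over compatible unordered haplotype pairs; ``best_pair`` is
    the maximum-posterior pair.  ``loglik_trace`` is from the winning
    restart.
    """

    snp_ids: list[str]
    hap_freqs: dict[str, float]
    posteriors: list[dict[tuple[str, str], float]]
    best_pair: list[tuple[str, str]]
    sample_ids: list[str]
    loglik: float
    loglik_trace: list[float] = field(repr=False, default_factory=list)

    def frequency(self, haplotype: str) -> float:
        return self.hap_freqs.get(haplotype, 0.0)


def _compatible_pairs(
    genotype: Sequence[int], alleles: Sequence[tuple[str, str]]
) -> list[tuple[str, str]]:
    """All unordered haplotype pairs consistent with a multilocus genotype.

    ``genotype`` holds minor-allele dosages; ``alleles[j]`` is the
    (major, minor) pair at SNP j.  Heterozygous sites each contribute a
    binary choice on the first haplotype; fixing the first het site breaks
    the (h1, h2) <-> (h2, h1) symmetry so each unordered pair appears once.
    """
    het = [j for j, d in enumerate(genotype) if d == 1]
    if len(het) > MAX_HET:
        raise ValueError(
            f"{len(het)} heterozygous sites: phase enumeration intractable"
        )
    base1 = [alleles[j][0] if d == 0 else alleles[j][1] for j, d in enumerate(genotype)]
    base2 = list(base1)
    for j, d in enumerate(genotype):
        if d == 1:
            base1[j] = alleles[j][0]
            base2[j] = alleles[j][1]
    if not het:
        h = "".join(base1)
        return [(h, h)]
    free = het[1:]  # first het site pinned to break ordering symmetry
    pairs = []
    for flips in product((False, True), repeat=len(free)):
        h1, h2 = list(base1), list(base2)
        for j, flip in zip(free, flips):
            if flip:
                h1[j], h2[j] = h2[j], h1[j]
        pairs.append(("".join(h1), "".join(h2)))
    return pairs


def em_phase(
    gm: GenotypeMatrix,
    snps: Sequence[str] | None = None,
    seed: int | np.random.Generator = 0,
    n_restarts: int = N_RESTARTS,
) -> PhasingResult:
    """EM haplotype-frequency estimation with seeded random restarts.

    Restart 0 initialises uniformly over all observed-compatible haplotypes;
    the remaining restarts draw Dirichlet(1) starting points.  The restart
    with the best converged log-likelihood wins.  Haplotypes with estimated
    frequency below 1/(4 * chromosomes) — less than half a chromosome — are
    pruned after convergence as EM noise.

    Samples with missing genotypes at panel SNPs are not accepted; exclude
    them first (the study panel this models has complete genotypes).
    """
    snp_ids = list(snps) if snps is not None else [s.snp_id for s in gm.snps]
    cols = [gm.snp_index(sid) for sid in snp_ids]
    if gm.missing[:, cols].any():
        bad = [
            gm.samples[i].sample_id
            for i in np.flatnonzero(gm.missing[:, cols].any(axis=1))
        ]
        raise ValueError(
            f"missing genotypes at panel SNPs for samples {bad}; "
            "drop them before phasing"
        )
    alleles = [(gm.snps[c].allele_a, gm.snps[c].allele_b) for c in cols]
    genos = gm.dosage[:, cols]
    pairs_per_sample = [
        _compatible_pairs(genos[i], alleles) for i in range(gm.n_samples)
    ]
    hap_ids: dict[str, int] = {}
    for pairs in pairs_per_sample:
        for h1, h2 in pairs:
            hap_ids.setdefault(h1, len(hap_ids))
            hap_ids.setdefault(h2, len(hap_ids))
    haps = list(hap_ids)
    k = len(haps)
    n_chrom = 2 * gm.n_samples
    sample_pairs = [
        [(hap_ids[h1], hap_ids[h2]) for h1, h2 in pairs]
        for pairs in pairs_per_sample
    ]

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    def run(f0: np.ndarray) -> tuple[np.ndarray, list[float]]:
        f = f0.copy()
        trace: list[float] = []
        for _ in range(MAX_ITER):
            counts = np.zeros(k)
            ll = 0.0
            for pairs in sample_pairs:
                w = np.array(
                    [
                        (2.0 if i != j else 1.0) * f[i] * f[j]
                        for i, j in pairs
                    ]
                )
                tot = w.sum()
                if tot <= 0:
                    w = np.ones(len(pairs))
                    tot = w.sum()
                    ll += -745.0  # log of ~5e-324; degenerate start
                else:
                    ll += np.log(tot)
                w /= tot
                for (i, j), wij in zip(pairs, w):
                    counts[i] += wij
                    counts[j] += wij
            if trace:
                assert ll >= trace[-1] - 1e-9, "EM log-likelihood decreased"
            converged = bool(trace) and ll - trace[-1] < LOGLIK_TOL
            trace.append(ll)
            f = counts / n_chrom
            if converged:
                return f, trace
        return f, trace

    best_f, best_trace = None, [-np.inf]
    for r in range(max(1, n_restarts)):
        if r == 0:
            f0 = np.full(k, 1.0 / k)
        else:
            f0 = rng.dirichlet(np.ones(k))
        f, trace = run(f0)
        if trace[-1] > best_trace[-1]:
            best_f, best_trace = f, trace
    f = best_f
    # prune EM noise below half a chromosome and renormalise
    floor = 1.0 / (4 * n_chrom)
    f = np.where(f < floor, 0.0, f)
    f = f / f.sum()

    posteriors: list[dict[tuple[str, str], float]] = []
    best_pair: list[tuple[str, str]] = []
    for pairs in sample_pairs:
        w = np.array(
            [(2.0 if i != j else 1.0) * f[i] * f[j] for i, j in pairs]
        )
        if w.sum() <= 0:  # all compatible pairs pruned; fall back to uniform
            w = np.ones(len(pairs))
        w /= w.sum()
        post = {
            (haps[i], haps[j]): float(wij)
            for (i, j), wij in zip(pairs, w)
        }
        posteriors.append(post)
        best_pair.append(max(post, key=post.get))

    order = np.argsort(-f)
    hap_freqs = {haps[i]: float(f[i]) for i in order if f[i] > 0}
    return PhasingResult(
        snp_ids=snp_ids,
        hap_freqs=hap_freqs,
        posteriors=posteriors,
        best_pair=best_pair,
        sample_ids=[s.sample_id for s in gm.samples],
        loglik=float(best_trace[-1]),
        loglik_trace=[float(x) for x in best_trace],
    )


def panel_from_phasing(pr: PhasingResult, gm: GenotypeMatrix) -> HaplotypePanel:
    """Best-pair phased panel (two chromosomes per sample) from EM output."""
    cols = [gm.snp_index(sid) for sid in pr.snp_ids]
    snps = [gm.snps[c] for c in cols]
    haplotypes, carriers = [], []
    for sid, (h1, h2) in zip(pr.sample_ids, pr.best_pair):
        haplotypes.extend([h1, h2])
        carriers.extend([sid, sid])
    return HaplotypePanel(snps, haplotypes, carriers)


def haplotype_table(
    phased: PhasingResult | HaplotypePanel,
    pheno: PhenotypeTable | None = None,
    phenotype_field: str = "hb",
    gm: GenotypeMatrix | None = None,
) -> pd.DataFrame:
    """Distinct-haplotype summary with per-haplotype phenotype mean +/- SD.

    Each chromosome contributes its carrier's phenotype value (homozygous
    carriers contribute twice).  Chromosomes whose carrier lacks the
    phenotype are excluded from the mean/SD (and from ``count_pheno``) but
    kept in ``count`` and in the frequency denominator, so both the
    all-chromosome frequency column and the phenotype-measured chromosome
    count of the study tables are reproduced.  Rows sort by descending
    count.  Singleton SD is reported as 0.0 (sample SD with n-1 denominator
    otherwise).
    """
    if isinstance(phased, PhasingResult):
        if gm is None:
            raise ValueError(
                "haplotype_table from a PhasingResult needs the genotype "
                "matrix to materialise best-pair chromosomes"
            )
        panel = panel_from_phasing(phased, gm)
    else:
        panel = phased
    if panel.n_chrom == 0:
        raise ValueError("empty haplotype panel")
    values: dict[str, list[float]] = {}
    counts: dict[str, int] = {}
    for hap, carrier in zip(panel.haplotypes, panel.carriers):
        counts[hap] = counts.get(hap, 0) + 1
        if pheno is not None:
            v = (
                pheno.value(carrier, phenotype_field)
                if carrier in pheno.frame.index
                else None
            )
            if v is not None:
                values.setdefault(hap, []).append(v)
    total = panel.n_chrom
    rows = []
    for hap, c in counts.items():
        row = {
            "haplotype": hap,
            "count": c,
            "frequency": c / total,
        }
        if pheno is not None:
            vals = values.get(hap, [])
            row["count_pheno"] = len(vals)
            if vals:
                row["pheno_mean"] = float(np.mean(vals))
                row["pheno_sd"] = (
                    float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
                )
            else:
                row["pheno_mean"] = np.nan
                row["pheno_sd"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows).sort_values(
        ["count", "haplotype"], ascending=[False, True], kind="mergesort"
    )
    return out.reset_index(drop=True)
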