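"""Two-locus haplotype frequencies and linkage disequilibrium (D, D', r2).

From phased panels the four gamete frequencies are counted directly.  From
unphased genotypes they are estimated by the classic two-locus EM over the
double-heterozygote phase ambiguity (the Haploview approach), initialised at
linkage equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_data import GenotypeMatrix, HaplotypePanel

__all__ = ["LdResult", "ld_from_phased", "ld_from_genotypes"]

EM_TOL = 1e-8          # max absolute change in any haplotype frequency
EM_MAX_ITER = 1000


@dataclass(frozen=True)
class LdResult:
    """Pairwise LD summary.  Haplotype order: AB, Ab, aB, ab where A/a are
    the major/minor alleles of snp1 and B/b of snp2."""

    snp1: str
    snp2: str
    hap_freqs: tuple[float, float, float, float]
    d: float
    d_prime: float
    r2: float
    n_chrom: int
    chi2_p: float  # approximate: chi-square on r2 * n_chrom, 1 df
    loglik_trace: tuple[float, ...] = field(default=(), repr=False)


def _coefficients(f: np.ndarray) -> tuple[float, float, float]:
    """(D, D', r2) from gamete frequencies [f_AB, f_Ab, f_aB, f_ab]."""
    p_a = f[0] + f[1]  # major allele at locus 1
    p_b = f[0] + f[2]  # major allele at locus 2
    q_a, q_b = 1.0 - p_a, 1.0 - p_b
    if min(p_a, q_a, p_b, q_b) <= 0.0:
        raise ValueError("monomorphic locus: D' and r2 undefined")
    d = f[0] - p_a * p_b
    if d > 0:
        d_max = min(p_a * q_b, q_a * p_b)
    else:
        d_max = min(p_a * p_b, q_a * q_b)
    d_prime = 0.0 if d == 0 else abs(d) / d_max
    r2 = d * d / (p_a * q_a * p_b * q_b)
    return d, min(d_prime, 1.0), min(r2, 1.0)


def _result(snp1, snp2, f, n_chrom, trace=()) -> LdResult:
    d, d_prime, r2 = _coefficients(f)
    chi2 = r2 * n_chrom
    p = float(stats.chi2.sf(chi2, df=1))
    return LdResult(
        snp1=snp1,
        snp2=snp2,
        hap_freqs=tuple(float(x) for x in f),
        d=float(d),
        d_prime=float(d_prime),
        r2=float(r2),
        n_chrom=int(n_chrom),
        chi2_p=p,
        loglik_trace=tuple(trace),
    )


def ld_from_phased(panel: HaplotypePanel, snp1: str, snp2: str) -> LdResult:
    """LD by direct gamete counting on a phased panel."""
    j1, j2 = panel.snp_index(snp1), panel.snp_index(snp2)
    s1, s2 = panel.snps[j1], panel.snps[j2]
    counts = np.zeros(4)
    for h in panel.haplotypes:
        i = (h[j1] == s1.allele_b) * 2 + (h[j2] == s2.allele_b)
        counts[i] += 1
    f = counts / counts.sum()
    return _result(snp1, snp2, f, int(counts.sum()))


def ld_from_genotypes(gm: GenotypeMatrix, snp1: str, snp2: str) -> LdResult:
    """LD by two-locus EM on unphased genotypes.

    Individuals missing either genotype are dropped pairwise.  The only
    phase-ambiguous class is the double heterozygote, which may be
    AB/ab (coupling) or Ab/aB (repulsion); the E-step splits its gametes by
    the current estimate, f_AB f_ab versus f_Ab f_aB.  Initialisation is at
    linkage equilibrium; the per-iteration log-likelihood is recorded and
    asserted non-decreasing.
    """
    d1, m1 = gm.column(snp1)
    d2, m2 = gm.column(snp2)
    keep = ~(m1 | m2)
    if keep.sum() < 2:
        raise ValueError("need >= 2 jointly genotyped individuals")
    d1, d2 = d1[keep].astype(int), d2[keep].astype(int)
    n_ind = len(d1)
    n_chrom = 2 * n_ind
    # genotype class counts: g[i, j] = # individuals with i copies of minor1
    # and j copies of minor2
    g = np.zeros((3, 3))
    for a, b in zip(d1, d2):
        g[a, b] += 1
    # known gamete counts (everything except the double het); gametes indexed
    # AB, Ab, aB, ab with A/B major
    known = np.zeros(4)
    for i in range(3):
        for j in range(3):
            if i == 1 and j == 1:
                continue
            c = g[i, j]
            if c == 0:
                continue
            # each individual contributes two gametes; with at most one het
            # locus the allele pairing across loci is forced
            g1 = [1] * (2 - i) + [0] * i  # 1 = major allele on that gamete
            g2 = [1] * (2 - j) + [0] * j
            for k in range(2):
                idx = (0 if g1[k] else 2) + (0 if g2[k] else 1)
                known[idx] += c
    n_dh = g[1, 1]
    p_a = (2 * (g[0, :].sum()) + g[1, :].sum()) / n_chrom  # freq major at 1
    p_b = (2 * (g[:, 0].sum()) + g[:, 1].sum()) / n_chrom
    f = np.array(
        [p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b, (1 - p_a) * (1 - p_b)]
    )
    f = np.clip(f, 1e-12, None)
    f /= f.sum()

    def loglik(f: np.ndarray) -> float:
        ll = float(np.dot(known, np.log(np.clip(f, 1e-300, None))))
        if n_dh:
            ll += n_dh * np.log(
                max(2 * f[0] * f[3] + 2 * f[1] * f[2], 1e-300)
            )
        return ll

    trace = [loglik(f)]
    for _ in range(EM_MAX_ITER):
        if n_dh:
            coup = f[0] * f[3]
            rep = f[1] * f[2]
            w = coup / (coup + rep) if coup + rep > 0 else 0.5
        else:
            w = 0.0
        expected = known.copy()
        expected[0] += n_dh * w
        expected[3] += n_dh * w
        expected[1] += n_dh * (1 - w)
        expected[2] += n_dh * (1 - w)
        f_new = expected / n_chrom
        ll = loglik(f_new)
        assert ll >= trace[-1] - 1e-9, "EM log-likelihood decreased"
        trace.append(ll)
        if np.max(np.abs(f_new - f)) < EM_TOL:
            f = f_new
            break
        f = f_new
    else:
        raise RuntimeError(
            f"two-locus EM did not converge in {EM_MAX_ITER} iterations; "
            f"log-likelihood trace tail: {trace[-5:]}"
        )
    return _result(snp1, snp2, f, n_chrom, trace)


def ld_matrix(source, snp_ids=None, phased: bool | None = None):
    """All-pairs D'/r2 table.  ``source`` is a HaplotypePanel or a
    GenotypeMatrix; returns a list of LdResult in upper-triangle order."""
    if phased is None:
        phased = isinstance(source, HaplotypePanel)
    ids = snp_ids or [s.snp_id for s in source.snps]
    out = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if phased:
                out.append(ld_from_phased(source, ids[i], ids[j]))
            else:
                out.append(ld_from_genotypes(source, ids[i], ids[j]))
    return out
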