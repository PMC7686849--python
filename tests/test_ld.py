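"""Two-locus LD: direct counting, EM estimation, and their agreement."""

import numpy as np
import pytest

from haploscan import (
    GenotypeMatrix,
    HaplotypePanel,
    SampleRecord,
    SnpRecord,
    ld_from_genotypes,
    ld_from_phased,
)
from oracles import two_locus_ml_oracle

SNPS = [
    SnpRecord("s1", "1", 1000, "A", "G"),
    SnpRecord("s2", "1", 2000, "C", "T"),
]


def panel_from_hap_counts(counts: dict[str, int]) -> HaplotypePanel:
    """counts keyed by two-character haplotypes, e.g. 'AC' (major-major)."""
    chroms = [h for h, c in sorted(counts.items()) for _ in range(c)]
    if len(chroms) % 2:
        chroms.append(chroms[0])
    carriers = [f"S{i // 2}" for i in range(len(chroms))]
    return HaplotypePanel(SNPS, chroms, carriers)


def gm_from_hap_freqs(freqs, n_ind, seed) -> GenotypeMatrix:
    """Unphased genotypes drawn by random union of gametes."""
    rng = np.random.default_rng(seed)
    haps = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])  # minor-allele dosage
    draws = rng.choice(4, size=(n_ind, 2), p=np.asarray(freqs))
    dosage = haps[draws[:, 0]] + haps[draws[:, 1]]
    samples = [SampleRecord(f"S{i}") for i in range(n_ind)]
    return GenotypeMatrix(samples, SNPS, dosage)


def test_perfect_coupling():
    res = ld_from_phased(panel_from_hap_counts({"AC": 50, "GT": 50}), "s1", "s2")
    assert res.hap_freqs == pytest.approx((0.5, 0.0, 0.0, 0.5))
    assert (res.d, res.d_prime, res.r2) == pytest.approx((0.25, 1.0, 1.0))


def test_independent_loci():
    # frequencies are exact products of the marginals -> D = 0
    res = ld_from_phased(
        panel_from_hap_counts({"AC": 36, "AT": 24, "GC": 24, "GT": 16}),
        "s1",
        "s2",
    )
    assert res.d == pytest.approx(0.0, abs=1e-12)
    assert res.r2 == pytest.approx(0.0, abs=1e-12)


def test_monomorphic_locus_rejected():
    with pytest.raises(ValueError, match="monomorphic"):
        ld_from_phased(panel_from_hap_counts({"AC": 60, "AT": 40}), "s1", "s2")


def test_em_equals_counting_without_double_heterozygotes():
    # genotypes: one double-hom and singly-het individuals only
    samples = [SampleRecord(f"S{i}") for i in range(4)]
    dosage = np.array([[0, 0], [1, 0], [0, 1], [2, 2]])
    gm = GenotypeMatrix(samples, SNPS, dosage)
    res = ld_from_genotypes(gm, "s1", "s2")
    # direct gamete counting: AB x2, (AB+aB), (AB+Ab), ab x2
    assert res.hap_freqs == pytest.approx((4 / 8, 1 / 8, 1 / 8, 2 / 8))


def test_em_matches_grid_search_oracle():
    gm = gm_from_hap_freqs([0.4, 0.1, 0.1, 0.4], n_ind=20, seed=5)
    res = ld_from_genotypes(gm, "s1", "s2")
    g = np.zeros((3, 3))
    d1, _ = gm.column("s1")
    d2, _ = gm.column("s2")
    for a, b in zip(d1, d2):
        g[a, b] += 1
    oracle = two_locus_ml_oracle(g)
    assert np.max(np.abs(np.array(res.hap_freqs) - oracle)) < 1e-5


def test_em_consistent_with_phased_counting():
    rng = np.random.default_rng(8)
    freqs = [0.45, 0.05, 0.05, 0.45]
    haps2 = ["AC", "AT", "GC", "GT"]
    chroms = [haps2[i] for i in rng.choice(4, 400, p=freqs)]
    carriers = [f"S{i // 2}" for i in range(400)]
    panel = HaplotypePanel(SNPS, chroms, carriers)
    phased = ld_from_phased(panel, "s1", "s2")
    unphased = ld_from_genotypes(panel.to_genotype_matrix(), "s1", "s2")
    assert unphased.r2 == pytest.approx(phased.r2, abs=0.02)
    assert unphased.d_prime == pytest.approx(phased.d_prime, abs=0.02)


def test_em_preserves_marginals_and_monotone_loglik():
    gm = gm_from_hap_freqs([0.3, 0.2, 0.3, 0.2], n_ind=50, seed=9)
    res = ld_from_genotypes(gm, "s1", "s2")
    f = np.array(res.hap_freqs)
    d1, _ = gm.column("s1")
    d2, _ = gm.column("s2")
    assert f[0] + f[1] == pytest.approx(1 - d1.mean() / 2, abs=1e-9)
    assert f[0] + f[2] == pytest.approx(1 - d2.mean() / 2, abs=1e-9)
    assert np.all(np.diff(res.loglik_trace) >= -1e-9)


def test_dprime_recovery_large_panel():
    # gamete frequencies with D' = 0.8: pA=pB=0.5, f_AB = 0.25 + 0.2
    target = [0.45, 0.05, 0.05, 0.45]
    rng = np.random.default_rng(10)
    haps2 = ["AC", "AT", "GC", "GT"]
    chroms = [haps2[i] for i in rng.choice(4, 1200, p=target)]
    carriers = [f"S{i // 2}" for i in range(1200)]
    res = ld_from_phased(HaplotypePanel(SNPS, chroms, carriers), "s1", "s2")
    assert res.d_prime == pytest.approx(0.8, abs=0.05)
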