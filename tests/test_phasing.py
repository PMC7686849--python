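"""Multi-locus EM phasing and the haplotype/phenotype summary table."""

import numpy as np
import pandas as pd
import pytest

from haploscan import (
    GenotypeMatrix,
    PhenotypeTable,
    SampleRecord,
    SnpRecord,
    em_phase,
    gen_cohort,
    haplotype_table,
)
from haploscan.phasing import panel_from_phasing
from haploscan.synthetic import STUDY_SPECTRUM
from oracles import phasing_ml_oracle

SNPS2 = [
    SnpRecord("a", "1", 100, "A", "G"),
    SnpRecord("b", "1", 200, "C", "T"),
]


def small_gm(dosage):
    dosage = np.asarray(dosage)
    samples = [SampleRecord(f"S{i}") for i in range(len(dosage))]
    return GenotypeMatrix(samples, SNPS2[: dosage.shape[1]], dosage)


def test_all_homozygous_sample_has_forced_phase():
    pr = em_phase(small_gm([[0, 2], [0, 2]]), seed=0)
    assert pr.posteriors[0] == {("AT", "AT"): 1.0}
    assert pr.best_pair[0] == ("AT", "AT")


def test_single_heterozygote_phase_forced():
    pr = em_phase(small_gm([[1, 0], [1, 0]]), seed=0)
    assert set(pr.best_pair[0]) == {"AC", "GC"}
    assert pr.posteriors[0][("AC", "GC")] == pytest.approx(1.0)


def test_em_matches_simplex_grid_oracle():
    """3 individuals x 2 SNPs: EM frequencies equal the dense-grid ML."""
    dosage = [[1, 1], [1, 0], [0, 1]]
    pr = em_phase(small_gm(dosage), seed=0)
    haps01 = [(0, 0), (0, 1), (1, 0), (1, 1)]
    labels = ["AC", "AT", "GC", "GT"]
    oracle = phasing_ml_oracle([tuple(g) for g in dosage], haps01)
    est = np.array([pr.hap_freqs.get(l, 0.0) for l in labels])
    assert np.max(np.abs(est - oracle)) < 1e-4


def test_loglik_monotone_and_order_invariant():
    gm, _, _ = gen_cohort(seed=21)
    pr = em_phase(gm, seed=2)
    assert np.all(np.diff(pr.loglik_trace) >= -1e-9)
    # reverse the sample order: same frequency estimates
    rev = GenotypeMatrix(gm.samples[::-1], gm.snps, gm.dosage[::-1])
    pr_rev = em_phase(rev, seed=2)
    for h, f in pr.hap_freqs.items():
        assert pr_rev.hap_freqs.get(h, 0.0) == pytest.approx(f, abs=1e-6)


def test_no_double_het_equals_gamete_counting():
    # every individual heterozygous at most once -> phase unambiguous
    dosage = [[0, 0], [1, 0], [0, 1], [2, 0], [0, 2], [1, 0]]
    pr = em_phase(small_gm(dosage), seed=0)
    # chromosomes: (AC,AC),(AC,GC),(AC,AT),(GC,GC),(AT,AT),(AC,GC)
    counting = {"AC": 5 / 12, "GC": 4 / 12, "AT": 3 / 12, "GT": 0.0}
    for h, f in counting.items():
        assert pr.hap_freqs.get(h, 0.0) == pytest.approx(f, abs=1e-9)


def test_spectrum_recovery_at_n500():
    from haploscan import CohortSpec

    spec = CohortSpec(cohorts={"A": (250, 125, 3700.0), "B": (250, 125, 4000.0)})
    gm, _, truth = gen_cohort(spec, seed=42)
    pr = em_phase(gm, seed=42)
    err = max(
        abs(pr.hap_freqs.get(h, 0.0) - f) for h, f in truth["spectrum"].items()
    )
    assert err < 0.03


def test_missing_genotypes_refused():
    gm = small_gm([[1, 1], [0, 0]])
    gm.missing[0, 0] = True
    with pytest.raises(ValueError, match="missing genotypes"):
        em_phase(gm, seed=0)


def test_haplotype_table_single_homozygote_cohort():
    gm = small_gm([[0, 0], [0, 0], [0, 0]])
    pr = em_phase(gm, seed=0)
    pheno = PhenotypeTable(
        pd.DataFrame(
            {"sample_id": ["S0", "S1", "S2"], "hb": [14.0, 15.0, 16.0]}
        )
    )
    tab = haplotype_table(pr, pheno, "hb", gm=gm)
    assert len(tab) == 1
    assert tab.loc[0, "frequency"] == 1.0
    assert tab.loc[0, "pheno_mean"] == pytest.approx(15.0)


def test_haplotype_table_counts_and_singleton_sd(table_panel):
    panel, pheno = table_panel
    tab = haplotype_table(panel, pheno, "hb").set_index("haplotype")
    assert tab["count"].sum() == 198
    assert tab["frequency"].sum() == pytest.approx(1.0)
    assert tab.loc["TGCG", "count"] == 84
    assert tab.loc["TGCG", "count_pheno"] == 83  # Hb-missing carrier excluded
    assert tab.loc["CGCA", "count"] == 1
    assert tab.loc["CGCA", "pheno_sd"] == 0.0
    # rows sorted by descending count
    assert list(tab["count"]) == sorted(tab["count"], reverse=True)


def test_haplotype_table_recovers_generator_frequencies():
    gm, pheno, truth = gen_cohort(seed=33)
    pr = em_phase(gm, seed=33)
    tab = haplotype_table(pr, pheno, "hb", gm=gm).set_index("haplotype")
    for hap, f in truth["spectrum"].items():
        est = tab["frequency"].get(hap, 0.0)
        se = np.sqrt(f * (1 - f) / 198)
        assert abs(est - f) < 4 * se + 0.01


def test_empty_panel_rejected():
    from haploscan import HaplotypePanel

    with pytest.raises(ValueError, match="empty"):
        haplotype_table(HaplotypePanel(SNPS2, [], []), None)
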