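"""F_ST estimators, PBS/PBS', sliding windows and the permutation test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haploscan import (
    DriftSpec,
    PopFreqTable,
    fst_permutation_p,
    gen_drift_populations,
    haplotype_fst,
    hudson_fst_site,
    pbs,
    pbs_prime,
    sliding_windows,
    weighted_fst,
)

freq = st.floats(min_value=0.01, max_value=0.99)


def test_hudson_site_equal_freqs_near_zero():
    num, den, fst = hudson_fst_site(0.4, 1000, 0.4, 1000)
    # the sampling correction makes the estimator slightly negative at
    # identical frequencies: -2 p(1-p)/(n-1) in the numerator
    assert fst == pytest.approx(0.0, abs=2e-3)
    assert fst < 0


def test_hudson_site_hand_value():
    num, den, fst = hudson_fst_site(0.8, 50, 0.2, 50)
    assert num == pytest.approx(0.35347, abs=1e-5)
    assert den == pytest.approx(0.68, abs=1e-12)
    assert fst == pytest.approx(0.5198, abs=1e-4)


@given(freq, freq)
@settings(max_examples=100, derandomize=True)
def test_hudson_site_symmetric(p1, p2):
    a = hudson_fst_site(p1, 40, p2, 60)
    b = hudson_fst_site(p2, 60, p1, 40)
    assert a[0] == pytest.approx(b[0], abs=1e-12)
    assert a[1] == pytest.approx(b[1], abs=1e-12)


def test_weighted_fst_single_and_duplicated_site():
    single = hudson_fst_site(0.7, 50, 0.3, 50)[2]
    assert weighted_fst([0.7], 50, [0.3], 50) == pytest.approx(single)
    assert weighted_fst([0.7, 0.7], 50, [0.3, 0.3], 50) == pytest.approx(single)


def test_ratio_of_averages_differs_from_average_of_ratios():
    # one informative site plus one noisy rare site: the rare site drags an
    # average-of-ratios down (its negative sampling-corrected ratio), while
    # the ratio of averages down-weights it
    p1, p2 = [0.8, 0.02], [0.2, 0.02]
    roa = weighted_fst(p1, 50, p2, 50)
    ratios = [hudson_fst_site(a, 50, b, 50)[2] for a, b in zip(p1, p2)]
    aor = np.mean(ratios)
    assert roa > aor


def test_pbs_closed_forms_and_symmetry():
    assert pbs(0.0, 0.0, 0.0) == (0.0, 0.0, 0.0)
    a, b, c = pbs(0.1, 0.1, 0.0)
    assert a == pytest.approx(0.10536, abs=1e-5)
    assert b == pytest.approx(0.0, abs=1e-12)
    assert c == pytest.approx(0.0, abs=1e-12)
    # permuting populations permutes outputs: swapping b and c swaps the
    # (ab, ac) inputs and the (b, c) outputs
    r1 = pbs(0.1, 0.2, 0.05)
    r2 = pbs(0.2, 0.1, 0.05)
    assert r2 == pytest.approx((r1[0], r1[2], r1[1]))


@given(
    st.floats(-0.05, 0.95), st.floats(-0.05, 0.95), st.floats(-0.05, 0.95)
)
@settings(max_examples=200, derandomize=True)
def test_pbs_branch_sum_conservation(f_ab, f_ac, f_bc):
    t = [-np.log(1 - f) for f in (f_ab, f_ac, f_bc)]
    total = sum(pbs(f_ab, f_ac, f_bc))
    assert total == pytest.approx(sum(t) / 2, abs=1e-12)


def test_pbs_prime_normalisation():
    assert pbs_prime(0.0, 0.0, 0.0) == (0.0, 0.0, 0.0)
    out = pbs_prime(0.10536, 0.0, 0.0)
    assert out[0] == pytest.approx(0.0953, abs=1e-4)
    # small negative components stay finite and negative
    out = pbs_prime(-0.01, 0.2, 0.05)
    assert out[0] < 0 and np.isfinite(out).all()


def test_sliding_windows_tile_and_count_sites():
    pft = PopFreqTable(
        pops=["X", "Y", "Z"],
        positions=[100, 4900, 5100, 14_000],
        freqs=[[0.5, 0.6, 0.4, 0.3]] * 3,
        sizes=[50, 50, 50],
        region_length=15_000,
    )
    wins = sliding_windows(pft, ["X", "Y", "Z"], 5000, 5000)
    assert [(w.start, w.end) for w in wins] == [
        (0, 5000), (5000, 10_000), (10_000, 15_000)
    ]
    assert [w.n_sites for w in wins] == [2, 1, 1]
    # identical populations -> near-zero F_ST, finite PBS
    assert all(np.isfinite(w.pbs).all() for w in wins if w.complete)


def test_sliding_windows_empty_window_flagged():
    pft = PopFreqTable(
        pops=["X", "Y", "Z"],
        positions=[100],
        freqs=[[0.5], [0.6], [0.4]],
        sizes=[50, 50, 50],
        region_length=10_000,
    )
    wins = sliding_windows(pft, ["X", "Y", "Z"], 5000, 5000)
    assert wins[1].n_sites == 0 and not wins[1].complete


def test_weighted_fst_recovers_balding_nichols_f():
    spec = DriftSpec(
        n_sites=2000,
        drift={"P": 0.1, "Q": 0.1},
        sizes={"P": 500, "Q": 500},
    )
    pft = gen_drift_populations(spec, seed=1)
    est = weighted_fst(pft.freqs[0], 500, pft.freqs[1], 500)
    # both populations drift by F from the shared ancestor, so the pairwise
    # Hudson numerator is 2F p(1-p) against a 2 p(1-p) denominator -> ~F
    assert est == pytest.approx(0.1, rel=0.10)


def test_haplotype_fst_extremes_and_relabel_invariance():
    # identical frequency vectors: near zero (WC theta is unbiased, so the
    # point estimate at identical sample frequencies is slightly negative)
    same = {"A": {"h1": 50, "h2": 50}, "B": {"h1": 50, "h2": 50}}
    assert haplotype_fst(same).fst == pytest.approx(0.0, abs=0.02)
    fixed = {"A": {"h1": 60}, "B": {"h2": 40}}
    assert haplotype_fst(fixed).fst == pytest.approx(1.0)
    t1 = {"A": {"x": 30, "y": 10, "z": 20}, "B": {"x": 5, "y": 40, "z": 15}}
    t2 = {"A": {"q": 30, "r": 10, "s": 20}, "B": {"q": 5, "r": 40, "s": 15}}
    assert haplotype_fst(t1).fst == pytest.approx(haplotype_fst(t2).fst)


def test_haplotype_fst_hand_worked_components():
    """3-haplotype, 2-population toy against longhand Weir-Cockerham sums."""
    tables = {"A": {"h1": 6, "h2": 2, "h3": 2}, "B": {"h1": 2, "h2": 6, "h3": 2}}
    n = np.array([10.0, 10.0])
    n_tot, r = 20.0, 2
    n_c = (n_tot - (100 + 100) / n_tot) / (r - 1)
    a_sum = tot_sum = 0.0
    for pA, pB in [(0.6, 0.2), (0.2, 0.6), (0.2, 0.2)]:
        p_bar = (10 * pA + 10 * pB) / 20
        msp = (10 * (pA - p_bar) ** 2 + 10 * (pB - p_bar) ** 2) / (r - 1)
        msg = (10 * pA * (1 - pA) + 10 * pB * (1 - pB)) / (9 + 9)
        a = (msp - msg) / n_c
        a_sum += a
        tot_sum += a + msg
    assert haplotype_fst(tables).fst == pytest.approx(a_sum / tot_sum, abs=1e-12)


def test_permutation_floor_for_disjoint_populations():
    pairs = [("h1", "h1")] * 12 + [("h2", "h2")] * 12
    labels = ["A"] * 12 + ["B"] * 12
    res = fst_permutation_p(pairs, labels, n_perm=1999, seed=0)
    assert res.fst == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1 / 2000)
    assert res.p_value >= 1 / (res.n_permutations + 1)


def test_permutation_p_null_behaviour():
    rng = np.random.default_rng(17)
    haps = ["h1", "h2", "h3"]
    ps = []
    for _ in range(40):
        pairs = [tuple(rng.choice(haps, 2, p=[0.5, 0.3, 0.2])) for _ in range(30)]
        labels = ["A"] * 15 + ["B"] * 15
        ps.append(fst_permutation_p(pairs, labels, n_perm=99, seed=rng).p_value)
    ps = np.array(ps)
    assert 0.3 < ps.mean() < 0.7
    assert (ps < 0.2).mean() < 0.5


def test_permutation_requires_permutations():
    with pytest.raises(ValueError):
        fst_permutation_p([("h1", "h1")], ["A"], n_perm=0)
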