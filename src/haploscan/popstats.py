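"""Per-SNP summary statistics and exact tests.

Implements the QC layer of the pipeline: allele frequencies, observed and
expected heterozygosity, the conditional exact Hardy-Weinberg test, plus the
generic two-group comparisons used for cohort tables (Fisher's exact test on
2x2 contingency tables, Welch's unequal-variance t-test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SnpSummary",
    "snp_summary",
    "hwe_exact",
    "fisher_exact_2x2",
    "welch_t",
    "welch_t_samples",
]


@dataclass(frozen=True)
class SnpSummary:
    """Single-SNP summary for one stratum (one row of a QC table)."""

    snp_id: str
    stratum: str
    n: int
    freq_a: float
    freq_b: float
    count_a: int
    count_b: int
    h_obs: float
    h_exp: float
    hwe_p: float


def snp_summary(
    counts: tuple[int, int, int],
    snp_id: str = "",
    stratum: str = "all",
) -> SnpSummary:
    """Summarise a genotype triple (n_AA, n_AB, n_BB).

    freq_a = (2 n_AA + n_AB) / 2n; h_obs = n_AB / n; h_exp = 2 p q with no
    small-sample correction (plain 2pq; at the panel sizes involved the
    2n/(2n-1) correction does not change two-decimal rounding).
    """
    n_aa, n_ab, n_bb = counts
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    count_a = 2 * n_aa + n_ab
    count_b = 2 * n_bb + n_ab
    p = count_a / (2 * n)
    q = 1.0 - p
    return SnpSummary(
        snp_id=snp_id,
        stratum=stratum,
        n=n,
        freq_a=p,
        freq_b=q,
        count_a=count_a,
        count_b=count_b,
        h_obs=n_ab / n,
        h_exp=2.0 * p * q,
        hwe_p=hwe_exact(n_aa, n_ab, n_bb),
    )


def hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test conditional on the allele counts.

    Enumerates every heterozygote count compatible with the observed allele
    counts; the probability of a configuration is proportional to
    n! / (n_AA! n_AB! n_BB!) * 2**n_AB.  The two-sided p-value is the sum of
    configuration probabilities not exceeding that of the observed
    configuration (the standard exact test, not mid-p).  Monomorphic samples
    have a single configuration and p = 1.
    """
    for c in (n_aa, n_ab, n_bb):
        if c < 0:
            raise ValueError("genotype counts must be nonnegative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one individual")
    n_a = 2 * n_aa + n_ab  # minor-or-major allele count; test is symmetric
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0
    # log-weight of each admissible heterozygote count (same parity as rare)
    lgamma = math.lgamma
    hets = np.arange(rare % 2, rare + 1, 2)
    logw = np.array(
        [
            -lgamma((rare - h) / 2 + 1)
            - lgamma(h + 1)
            - lgamma((2 * n - rare - h) / 2 + 1)
            + h * math.log(2.0)
            for h in hets
        ]
    )
    w = np.exp(logw - logw.max())
    probs = w / w.sum()
    assert abs(probs.sum() - 1.0) < 1e-12
    obs = np.flatnonzero(hets == n_ab)
    if obs.size == 0:  # parity violation cannot occur with valid counts
        raise ValueError("inconsistent genotype counts")
    p_obs = probs[obs[0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for a 2x2 table [[a, b], [c, d]]."""
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be nonnegative integers")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def welch_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's t from group summaries: (t, Welch-Satterthwaite df, two-sided p)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if v1 + v2 == 0:
        return 0.0, float(n1 + n2 - 2), 1.0
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def welch_t_samples(x, y) -> tuple[float, float, float]:
    """Welch's t from raw samples (NaNs dropped)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    return welch_t(
        float(x.mean()), float(x.std(ddof=1)), len(x),
        float(y.mean()), float(y.std(ddof=1)), len(y),
    )
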