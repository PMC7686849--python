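"""Independent oracles for cross-checking the package's estimators.

Everything here is deliberately written from first principles (enumeration,
dense search, closed-form textbook formulas) and shares no code with the
implementations under test.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
from scipy import optimize, special


def two_locus_loglik(class_counts: np.ndarray, f: np.ndarray) -> float:
    """Multinomial log-likelihood of 3x3 two-locus genotype class counts
    given gamete frequencies f = [f_AB, f_Ab, f_aB, f_ab]."""
    f_ab_, f_aB, f_Ab, f_AB = f[3], f[2], f[1], f[0]
    # genotype-class probabilities under random union of gametes
    probs = np.zeros((3, 3))
    gametes = {(0, 0): f_AB, (0, 1): f_Ab, (1, 0): f_aB, (1, 1): f_ab_}
    for (a1, b1), p1 in gametes.items():
        for (a2, b2), p2 in gametes.items():
            probs[a1 + a2, b1 + b2] += p1 * p2
    ll = 0.0
    for i in range(3):
        for j in range(3):
            if class_counts[i, j]:
                ll += class_counts[i, j] * math.log(max(probs[i, j], 1e-300))
    return ll


def two_locus_ml_oracle(class_counts: np.ndarray) -> np.ndarray:
    """ML gamete frequencies by dense 1-D search over f_AB.

    The observed allele counts pin the marginals, leaving one free
    parameter; the search is a fine grid followed by bounded refinement,
    entirely independent of any EM iteration.
    """
    class_counts = np.asarray(class_counts, dtype=float)
    n_ind = class_counts.sum()
    p_minor1 = (
        class_counts[1, :].sum() + 2 * class_counts[2, :].sum()
    ) / (2 * n_ind)
    p_minor2 = (
        class_counts[:, 1].sum() + 2 * class_counts[:, 2].sum()
    ) / (2 * n_ind)
    p_a, p_b = 1 - p_minor1, 1 - p_minor2  # major-allele marginals

    def freqs(f_ab: float) -> np.ndarray:
        return np.array(
            [f_ab, p_a - f_ab, p_b - f_ab, 1 - p_a - p_b + f_ab]
        )

    lo = max(0.0, p_a + p_b - 1.0)
    hi = min(p_a, p_b)
    grid = np.linspace(lo + 1e-9, hi - 1e-9, 2001)
    lls = [two_locus_loglik(class_counts, freqs(g)) for g in grid]
    g0 = grid[int(np.argmax(lls))]
    span = (hi - lo) / 2000
    res = optimize.minimize_scalar(
        lambda g: -two_locus_loglik(class_counts, freqs(g)),
        bounds=(max(lo, g0 - 2 * span), min(hi, g0 + 2 * span)),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return freqs(float(res.x))


def phasing_loglik(genotypes, haplotypes, freqs) -> float:
    """Log-likelihood of multilocus genotypes (minor-dosage tuples) under
    random union of gametes from ``haplotypes`` at ``freqs``.

    ``haplotypes`` are 0/1 minor-indicator tuples.
    """
    ll = 0.0
    for g in genotypes:
        p = 0.0
        for i, h1 in enumerate(haplotypes):
            for j, h2 in enumerate(haplotypes):
                if all(a + b == d for a, b, d in zip(h1, h2, g)):
                    p += freqs[i] * freqs[j]
        ll += math.log(max(p, 1e-300))
    return ll


def phasing_ml_oracle(genotypes, haplotypes) -> np.ndarray:
    """ML haplotype frequencies by dense simplex grid + local refinement.

    Grid step 0.02 over the (k-1)-simplex locates the basin; Nelder-Mead on
    softmax-parameterised frequencies polishes to ~1e-8.  Only usable for
    k <= 4 haplotypes / a handful of individuals.
    """
    k = len(haplotypes)
    step = 50  # grid resolution: 1/50
    best, best_ll = None, -np.inf
    for combo in _compositions(step, k):
        f = np.array(combo, dtype=float) / step
        ll = phasing_loglik(genotypes, haplotypes, f)
        if ll > best_ll:
            best, best_ll = f, ll

    def neg(z: np.ndarray) -> float:
        f = special.softmax(np.concatenate([[0.0], z]))
        return -phasing_loglik(genotypes, haplotypes, f)

    z0 = np.log(np.clip(best[1:], 1e-6, None)) - np.log(max(best[0], 1e-6))
    res = optimize.minimize(neg, z0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 20000})
    return special.softmax(np.concatenate([[0.0], res.x]))


def _compositions(total: int, parts: int):
    if parts == 1:
        yield (total,)
        return
    for head in range(total + 1):
        for tail in _compositions(total - head, parts - 1):
            yield (head,) + tail


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by brute force over all tables with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        return math.exp(
            math.lgamma(r1 + 1) + math.lgamma(r2 + 1)
            + math.lgamma(c1 + 1) + math.lgamma(n - c1 + 1)
            - math.lgamma(n + 1) - math.lgamma(x + 1)
            - math.lgamma(r1 - x + 1) - math.lgamma(c1 - x + 1)
            - math.lgamma(r2 - c1 + x + 1)
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12))


def welch_formula(x, y) -> tuple[float, float, float]:
    """Textbook Welch t, df and two-sided p, written out longhand."""
    from scipy.stats import t as t_dist

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    m1, m2 = x.mean(), y.mean()
    v1 = x.var(ddof=1) / len(x)
    v2 = y.var(ddof=1) / len(y)
    t = (m1 - m2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (len(x) - 1) + v2**2 / (len(y) - 1))
    return t, df, 2 * t_dist.sf(abs(t), df)
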