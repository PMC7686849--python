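"""Population-differentiation statistics.

Per-site Hudson F_ST combined over windows as a ratio of averages
("weighted" F_ST), the population branch statistic PBS with branch lengths
T = -ln(1 - F_ST), its normalised form PBS' (PBSn1: each branch divided by
one plus the sum of the three branches), sliding-window scans over a
multi-population allele-frequency table, and a haplotype-level
Weir-Cockerham F_ST (each distinct haplotype treated as an allele) with a
permutation null over individuals.

Window coordinates are 0-based half-open [start, end) in bp; SNP positions
entering a window table are 0-based offsets within the scanned region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PopFreqTable",
    "WindowStat",
    "HapFstResult",
    "hudson_fst_site",
    "weighted_fst",
    "pbs",
    "pbs_prime",
    "sliding_windows",
    "haplotype_fst",
    "fst_permutation_p",
]

FST_CAP = 1.0 - 1e-12  # keeps T = -ln(1 - F) finite at fixed differences


@dataclass
class PopFreqTable:
    """Per-site allele frequencies for several populations over one region.

    positions are 0-based offsets within the region; ``freqs`` is
    (n_pops, n_sites); ``sizes`` are haploid sample sizes per population.
    """

    pops: list[str]
    positions: np.ndarray
    freqs: np.ndarray
    sizes: np.ndarray
    region_length: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=int)
        if self.freqs.shape != (len(self.pops), len(self.positions)):
            raise ValueError("freqs must be (n_pops, n_sites)")
        if np.any((self.freqs < 0) | (self.freqs > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        if np.any(self.sizes < 2):
            raise ValueError("haploid sample sizes must be >= 2")
        if self.region_length is None:
            self.region_length = int(self.positions.max()) + 1 if len(self.positions) else 0

    def index(self, pop: str) -> int:
        try:
            return self.pops.index(pop)
        except ValueError:
            raise KeyError(f"population {pop!r} not in table") from None

    def to_frame(self) -> pd.DataFrame:
        data = {"position": self.positions}
        for i, p in enumerate(self.pops):
            data[p] = self.freqs[i]
        return pd.DataFrame(data)


@dataclass(frozen=True)
class WindowStat:
    """Per-window differentiation summary for one population triplet."""

    start: int
    end: int
    n_sites: int
    fst_ab: float
    fst_ac: float
    fst_bc: float
    pbs: tuple[float, float, float]
    pbs_prime: tuple[float, float, float]
    complete: bool  # False when the window held no usable site


@dataclass(frozen=True)
class HapFstResult:
    pop_a: str
    pop_b: str
    fst: float
    p_value: float | None = None
    n_permutations: int = 0


def hudson_fst_site(
    p1: float, n1: int, p2: float, n2: int
) -> tuple[float, float, float]:
    """Hudson's F_ST estimator at one site: (numerator, denominator, fst).

    numerator = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1);
    denominator = p1(1-p2) + p2(1-p1).  A zero denominator (both
    populations fixed) makes the ratio undefined; callers skip such sites.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("haploid sample sizes must be >= 2")
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / (n1 - 1)
        - p2 * (1 - p2) / (n2 - 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    fst = num / den if den > 0 else np.nan
    return float(num), float(den), float(fst)


def weighted_fst(
    p1: Sequence[float], n1: int, p2: Sequence[float], n2: int
) -> float:
    """Multi-site Hudson F_ST as a ratio of averages.

    Site numerators and denominators are summed separately and the ratio
    taken once (never an average of per-site ratios), so uninformative
    low-frequency sites are down-weighted naturally.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    nums, dens = [], []
    for a, b in zip(p1, p2):
        num, den, _ = hudson_fst_site(a, n1, b, n2)
        if den > 0:
            nums.append(num)
            dens.append(den)
    if not dens:
        return np.nan
    return float(np.sum(nums) / np.sum(dens))


def pbs(
    fst_ab: float, fst_ac: float, fst_bc: float
) -> tuple[float, float, float]:
    """Population branch statistics for populations (a, b, c).

    Branch lengths T_xy = -ln(1 - F_ST,xy); pbs_a = (T_ab + T_ac - T_bc)/2
    and cyclically.  Negative F_ST estimates pass through (T < 0 allowed);
    F_ST is capped just below 1 to keep T finite.
    """
    t = [-np.log(1.0 - min(f, FST_CAP)) for f in (fst_ab, fst_ac, fst_bc)]
    t_ab, t_ac, t_bc = t
    return (
        float((t_ab + t_ac - t_bc) / 2),
        float((t_ab + t_bc - t_ac) / 2),
        float((t_ac + t_bc - t_ab) / 2),
    )


def pbs_prime(
    pbs_a: float, pbs_b: float, pbs_c: float
) -> tuple[float, float, float]:
    """Normalised PBS (PBSn1): pbs_x / (1 + pbs_a + pbs_b + pbs_c).

    Damps windows where every branch is long; small negative components
    stay finite (and possibly negative).
    """
    denom = 1.0 + pbs_a + pbs_b + pbs_c
    return (
        float(pbs_a / denom),
        float(pbs_b / denom),
        float(pbs_c / denom),
    )


def sliding_windows(
    pft: PopFreqTable,
    triplet: Sequence[str],
    window_bp: int = 5000,
    step_bp: int = 5000,
) -> list[WindowStat]:
    """Windowed weighted F_ST, PBS and PBS' for a population triplet.

    Windows are 0-based half-open, anchored at the region start; the final
    partial window is kept.  Windows with no usable site are emitted with
    ``complete=False`` and NaN statistics.
    """
    if not (window_bp >= step_bp > 0):
        raise ValueError("require window >= step > 0")
    ia, ib, ic = (pft.index(p) for p in triplet)
    na, nb, nc = (int(pft.sizes[i]) for i in (ia, ib, ic))
    length = pft.region_length or 0
    out: list[WindowStat] = []
    start = 0
    while start < length:
        end = min(start + window_bp, length)
        in_win = (pft.positions >= start) & (pft.positions < end)
        fa = pft.freqs[ia, in_win]
        fb = pft.freqs[ib, in_win]
        fc = pft.freqs[ic, in_win]
        f_ab = weighted_fst(fa, na, fb, nb)
        f_ac = weighted_fst(fa, na, fc, nc)
        f_bc = weighted_fst(fb, nb, fc, nc)
        usable = not any(np.isnan(f) for f in (f_ab, f_ac, f_bc))
        if usable:
            p = pbs(f_ab, f_ac, f_bc)
            pp = pbs_prime(*p)
        else:
            p = (np.nan,) * 3
            pp = (np.nan,) * 3
        out.append(
            WindowStat(
                start=start,
                end=end,
                n_sites=int(in_win.sum()),
                fst_ab=f_ab,
                fst_ac=f_ac,
                fst_bc=f_bc,
                pbs=p,
                pbs_prime=pp,
                complete=usable,
            )
        )
        start += step_bp
    return out


def windows_frame(stats: Sequence[WindowStat], triplet: Sequence[str]) -> pd.DataFrame:
    a, b, c = triplet
    return pd.DataFrame(
        {
            "start": [w.start for w in stats],
            "end": [w.end for w in stats],
            "n_sites": [w.n_sites for w in stats],
            f"fst_{a}_{b}": [w.fst_ab for w in stats],
            f"fst_{a}_{c}": [w.fst_ac for w in stats],
            f"fst_{b}_{c}": [w.fst_bc for w in stats],
            f"pbs_{a}": [w.pbs[0] for w in stats],
            f"pbs_{b}": [w.pbs[1] for w in stats],
            f"pbs_{c}": [w.pbs[2] for w in stats],
            f"pbs_prime_{a}": [w.pbs_prime[0] for w in stats],
            f"pbs_prime_{b}": [w.pbs_prime[1] for w in stats],
            f"pbs_prime_{c}": [w.pbs_prime[2] for w in stats],
            "complete": [w.complete for w in stats],
        }
    )


def _wc_theta(counts: np.ndarray, sizes: np.ndarray) -> float:
    """Weir-Cockerham theta for haploid samples, multi-allelic.

    ``counts`` is (n_pops, n_alleles) haplotype counts; variance components
    are summed over alleles before the ratio is taken.
    """
    r = counts.shape[0]
    if r < 2:
        raise ValueError("need >= 2 populations")
    n_i = sizes.astype(float)
    n_tot = n_i.sum()
    n_c = (n_tot - np.sum(n_i**2) / n_tot) / (r - 1)
    freqs = counts / n_i[:, None]
    a_sum = 0.0
    tot_sum = 0.0
    for k in range(counts.shape[1]):
        p_i = freqs[:, k]
        p_bar = np.sum(n_i * p_i) / n_tot
        msp = np.sum(n_i * (p_i - p_bar) ** 2) / (r - 1)
        msg = np.sum(n_i * p_i * (1 - p_i)) / np.sum(n_i - 1)
        a = (msp - msg) / n_c
        a_sum += a
        tot_sum += a + msg
    if tot_sum == 0:
        return 0.0
    return float(a_sum / tot_sum)


def _count_matrix(
    tables: Mapping[str, Mapping[str, int]]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    pops = list(tables)
    alleles = sorted({h for t in tables.values() for h in t})
    counts = np.array(
        [[tables[p].get(h, 0) for h in alleles] for p in pops], dtype=float
    )
    sizes = counts.sum(axis=1)
    return pops, counts, sizes


def haplotype_fst(tables: Mapping[str, Mapping[str, int]]) -> HapFstResult:
    """Weir-Cockerham theta over distinct haplotypes treated as alleles.

    ``tables`` maps population label -> {haplotype: chromosome count}.
    """
    pops, counts, sizes = _count_matrix(tables)
    if len(pops) != 2:
        raise ValueError("haplotype_fst compares exactly two populations")
    theta = _wc_theta(counts, sizes)
    return HapFstResult(pop_a=pops[0], pop_b=pops[1], fst=theta)


def fst_permutation_p(
    hap_pairs: Sequence[tuple[str, str]],
    pop_labels: Sequence[str],
    n_perm: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> HapFstResult:
    """Permutation test of haplotype F_ST between two populations.

    Individuals (their two chromosomes together) are shuffled between the
    populations; p = (# permuted theta >= observed + 1) / (n_perm + 1), so
    the attainable floor is 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    labels = np.asarray(pop_labels)
    pops = sorted(set(labels.tolist()))
    if len(pops) != 2:
        raise ValueError("permutation F_ST compares exactly two populations")
    alleles = sorted({h for pair in hap_pairs for h in pair})
    a_idx = {h: k for k, h in enumerate(alleles)}
    # per-individual allele count vector (2 chromosomes)
    ind = np.zeros((len(hap_pairs), len(alleles)))
    for i, (h1, h2) in enumerate(hap_pairs):
        ind[i, a_idx[h1]] += 1
        ind[i, a_idx[h2]] += 1

    def theta_for(lab: np.ndarray) -> float:
        counts = np.stack([ind[lab == p].sum(axis=0) for p in pops])
        return _wc_theta(counts, counts.sum(axis=1))

    observed = theta_for(labels)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    hits = 0
    perm = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if theta_for(perm) >= observed - 1e-15:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return HapFstResult(
        pop_a=pops[0],
        pop_b=pops[1],
        fst=float(observed),
        p_value=float(p),
        n_permutations=int(n_perm),
    )
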