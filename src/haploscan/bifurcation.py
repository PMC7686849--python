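"""Haplotype bifurcation trees around a core allele.

Starting from the set of chromosomes carrying a chosen allele at a core
SNP, the tree splits marker by marker moving away from the core (upstream
toward smaller positions or downstream toward larger ones).  Node counts
record how many chromosomes share each allele path; the decay of
``extended_homozygosity`` with depth summarises how quickly haplotype
identity around the core breaks down (the EHH idea behind bifurcation
diagrams).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .core_data import HaplotypePanel

__all__ = ["BifurcationTree", "build_bifurcation", "extended_homozygosity"]

MISSING_ALLELES = {".", "N", "-"}


@dataclass
class BifurcationTree:
    """Nodes are keyed by allele path (tuple of alleles from the core
    outward); the empty path is the root.  Counts at each depth sum to the
    root count minus chromosomes terminated by missing alleles."""

    core_snp: str
    core_allele: str
    direction: str
    markers: list[str]
    nodes: dict[tuple[str, ...], int]

    @property
    def root_count(self) -> int:
        return self.nodes[()]

    def depth_counts(self, depth: int) -> dict[tuple[str, ...], int]:
        return {p: c for p, c in self.nodes.items() if len(p) == depth}

    def children(self, path: tuple[str, ...]) -> dict[str, int]:
        return {
            p[-1]: c
            for p, c in self.nodes.items()
            if len(p) == len(path) + 1 and p[: len(path)] == path
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "depth": len(path),
                "marker": self.markers[len(path) - 1] if path else self.core_snp,
                "path": "".join(path),
                "count": count,
            }
            for path, count in sorted(self.nodes.items(), key=lambda kv: (len(kv[0]), kv[0]))
        ]
        return pd.DataFrame(rows)


def build_bifurcation(
    panel: HaplotypePanel,
    core_snp: str,
    core_allele: str,
    direction: str = "downstream",
    max_markers: int | None = None,
    max_bp: int | None = None,
) -> BifurcationTree:
    """Build the bifurcation tree from chromosomes carrying ``core_allele``.

    Markers are the panel's polymorphic SNPs on the chosen side of the core
    (monomorphic sites cannot bifurcate and are skipped), ordered by
    increasing distance, optionally truncated at ``max_markers`` markers or
    ``max_bp`` base pairs from the core.  A chromosome with a missing
    allele at a marker leaves the tree at that depth.
    """
    if direction not in ("upstream", "downstream"):
        raise ValueError("direction must be 'upstream' or 'downstream'")
    j_core = panel.snp_index(core_snp)
    core_pos = panel.snps[j_core].pos
    carriers = [
        h for h in panel.haplotypes if h[j_core] == core_allele
    ]
    if not carriers:
        raise ValueError(
            f"allele {core_allele!r} absent at {core_snp}: no core chromosomes"
        )
    side = []
    for j, snp in enumerate(panel.snps):
        if j == j_core:
            continue
        if direction == "downstream" and snp.pos <= core_pos:
            continue
        if direction == "upstream" and snp.pos >= core_pos:
            continue
        if max_bp is not None and abs(snp.pos - core_pos) > max_bp:
            continue
        observed = {
            h[j] for h in panel.haplotypes if h[j] not in MISSING_ALLELES
        }
        if len(observed) < 2:
            continue  # monomorphic in the panel
        side.append((abs(snp.pos - core_pos), j))
    side.sort()
    if max_markers is not None:
        side = side[:max_markers]
    marker_cols = [j for _, j in side]
    markers = [panel.snps[j].snp_id for j in marker_cols]

    nodes: dict[tuple[str, ...], int] = {(): len(carriers)}
    alive = [(h, ()) for h in carriers]
    for depth, j in enumerate(marker_cols, start=1):
        nxt = []
        for h, path in alive:
            allele = h[j]
            if allele in MISSING_ALLELES:
                continue  # chromosome terminates here
            new_path = path + (allele,)
            nodes[new_path] = nodes.get(new_path, 0) + 1
            nxt.append((h, new_path))
        alive = nxt
        if not alive:
            break
    return BifurcationTree(
        core_snp=core_snp,
        core_allele=core_allele,
        direction=direction,
        markers=markers,
        nodes=nodes,
    )


def extended_homozygosity(tree: BifurcationTree) -> list[float]:
    """Fraction of core-chromosome pairs still on a shared path per depth.

    At depth d the value is sum over nodes of c(c-1) divided by r(r-1) for
    root count r; depth 0 is 1 by construction and the sequence is
    non-increasing.  With a single core chromosome (r = 1) no pair exists
    and the summary is reported as 1.0 at the root only.
    """
    r = tree.root_count
    if r < 2:
        return [1.0]
    max_depth = max(len(p) for p in tree.nodes)
    out = []
    for d in range(max_depth + 1):
        num = sum(c * (c - 1) for p, c in tree.nodes.items() if len(p) == d)
        out.append(num / (r * (r - 1)))
    return out
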