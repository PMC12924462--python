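"""Temporal persistence of DMRs and pairwise sharedness between conditions.

Overlap is defined on member CpG identity by default: a DMR from set A
"persists" in set B when it shares at least one member cytosine position
with a same-direction DMR of B.  CpG identity is the natural unit for
array-derived DMRs (the probe set is fixed) and is immune to interval-edge
artifacts; base-pair interval overlap is available via ``by="bp"``.
Direction must match — a region hypermethylated early and hypomethylated
later is not stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dmr import DMR

__all__ = [
    "OverlapResult",
    "overlap_dmr_sets",
    "persistence_fraction",
    "format_percent",
    "pairwise_sharedness",
]


@dataclass(frozen=True)
class OverlapResult:
    n_early: int
    n_late: int
    n_overlap: int

    @property
    def persistence_pct(self) -> float:
        return persistence_fraction(self.n_early, self.n_overlap)


def _overlaps(a: DMR, b: DMR, by: str) -> bool:
    if a.chrom != b.chrom or a.direction != b.direction:
        return False
    if by == "cpg":
        return bool(set(a.cpg_positions) & set(b.cpg_positions))
    if by == "bp":
        return a.start < b.end and b.start < a.end
    raise ValueError(f"unknown overlap mode {by!r} (use 'cpg' or 'bp')")


def overlap_dmr_sets(a: list[DMR], b: list[DMR], by: str = "cpg") -> OverlapResult:
    """Count DMRs of ``a`` that recur (same direction) in ``b``."""
    # index b's CpG positions by (chrom, direction) for linear-time lookup
    if by == "cpg":
        index: dict[tuple[str, str], set[int]] = {}
        for d in b:
            index.setdefault((d.chrom, d.direction), set()).update(d.cpg_positions)
        n_overlap = sum(
            1
            for d in a
            if index.get((d.chrom, d.direction), set()) & set(d.cpg_positions)
        )
    else:
        n_overlap = sum(1 for d in a if any(_overlaps(d, x, by) for x in b))
    return OverlapResult(n_early=len(a), n_late=len(b), n_overlap=n_overlap)


def persistence_fraction(n_early: int, n_overlap: int) -> float:
    """Percent of early DMRs recurring later: 100 * n_overlap / n_early."""
    if n_early <= 0:
        raise ValueError("n_early must be positive")
    if not 0 <= n_overlap <= n_early:
        raise ValueError("n_overlap must be between 0 and n_early")
    return 100.0 * n_overlap / n_early


def format_percent(pct: float) -> str:
    """Display convention: integer percent when >= 1%, one decimal below."""
    if pct >= 1.0:
        return f"{pct:.0f}%"
    return f"{pct:.1f}%"


def pairwise_sharedness(sets: dict[str, list[DMR]], by: str = "cpg") -> pd.DataFrame:
    """Asymmetric matrix: entry (i, j) = % of set i's DMRs recurring in set j."""
    if len(sets) < 2:
        raise ValueError("need at least two DMR sets")
    names = list(sets)
    mat = np.full((len(names), len(names)), np.nan)
    for i, ni in enumerate(names):
        for j, nj in enumerate(names):
            if i == j:
                mat[i, j] = 100.0 if sets[ni] else np.nan
                continue
            if not sets[ni]:
                continue
            res = overlap_dmr_sets(sets[ni], sets[nj], by=by)
            mat[i, j] = res.persistence_pct
    return pd.DataFrame(mat, index=names, columns=names)
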