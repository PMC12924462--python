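"""Per-CpG differential methylation (Δβ) and effect-size DMR calling.

The caller is purely effect-size based: a DMR is a maximal run, within one
chromosome and one direction, of at least ``min_cpgs`` CpGs whose |Δβ|
strictly exceeds ``min_abs_delta`` with the same sign, where successive
qualifying CpGs lie strictly closer than ``max_gap`` bp.  Hyper- and
hypomethylation are called symmetrically by applying the identical rule to
each sign.  Gaps are measured between successive qualifying cytosines, so a
measured sub-threshold CpG sitting between two qualifying ones is
transparent; a CpG whose Δβ is *missing*, however, breaks the run —
evidence absent is treated conservatively.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import BetaMatrix, CpGSite, resolve_selector

__all__ = [
    "DeltaTrack",
    "DMR",
    "DMRSummary",
    "compute_delta",
    "call_dmrs",
    "summarize_dmrs",
    "round_half_up",
]


@dataclass
class DeltaTrack:
    """Per-CpG Δβ = mean(treatment) - mean(control), NaN where undefined."""

    sites: list[CpGSite]
    delta: np.ndarray
    n_used: np.ndarray  # per-site (n_treatment, n_control) non-missing counts

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        if len(self.sites) != self.delta.shape[0]:
            raise ValueError("sites and delta lengths differ")


@dataclass(frozen=True)
class DMR:
    """A called differentially methylated region (0-based half-open)."""

    chrom: str
    start: int
    end: int
    cpg_positions: tuple[int, ...]
    direction: str  # "hyper" | "hypo"
    mean_delta: float

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)


@dataclass(frozen=True)
class DMRSummary:
    total: int
    n_hyper: int
    n_hypo: int
    pct_hyper: int
    pct_hypo: int


def round_half_up(x: float) -> int:
    """Round to nearest integer with .5 going up (0.5 -> 1, 1.5 -> 2)."""
    return int(math.floor(x + 0.5))


def compute_delta(beta: BetaMatrix, treatment, control) -> DeltaTrack:
    """Group-mean Δβ per CpG over non-missing replicates.

    A site's Δβ is missing when either group has no non-missing replicate
    there.  ``treatment`` and ``control`` are sample selectors (ids, field
    dict, or predicate) and must be non-empty and disjoint.
    """
    t_idx = resolve_selector(beta.samples, treatment)
    c_idx = resolve_selector(beta.samples, control)
    if set(t_idx) & set(c_idx):
        shared = [beta.samples[j].sample_id for j in set(t_idx) & set(c_idx)]
        raise ValueError(f"treatment and control selectors overlap: {shared}")
    t_vals = beta.values[:, t_idx]
    c_vals = beta.values[:, c_idx]
    with warnings.catch_warnings():
        # all-NaN rows legitimately yield NaN group means (missing site)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        t_mean = np.nanmean(t_vals, axis=1)
        c_mean = np.nanmean(c_vals, axis=1)
    delta = t_mean - c_mean
    n_used = np.stack(
        [np.sum(~np.isnan(t_vals), axis=1), np.sum(~np.isnan(c_vals), axis=1)],
        axis=1,
    )
    return DeltaTrack(sites=list(beta.sites), delta=delta, n_used=n_used)


def call_dmrs(
    track: DeltaTrack,
    min_cpgs: int = 2,
    min_abs_delta: float = 0.1,
    max_gap: int = 2000,
) -> list[DMR]:
    """Call maximal same-direction runs of qualifying CpGs as DMRs.

    Sites must be sorted by (chrom, pos).  Thresholds are strict:
    |Δβ| > min_abs_delta and successive-qualifying-CpG gap < max_gap.
    """
    if min_abs_delta <= 0 or max_gap <= 0 or min_cpgs < 1:
        raise ValueError("thresholds must be positive")
    keys = [(s.chrom, s.pos) for s in track.sites]
    if any(keys[i] >= keys[i + 1] for i in range(len(keys) - 1)):
        raise ValueError("DeltaTrack sites must be sorted by (chrom, pos) and unique")

    dmrs: list[DMR] = []
    for sign, direction in ((+1, "hyper"), (-1, "hypo")):
        run_pos: list[int] = []
        run_delta: list[float] = []
        run_chrom: str | None = None

        def flush() -> None:
            if len(run_pos) >= min_cpgs:
                dmrs.append(
                    DMR(
                        chrom=run_chrom,
                        start=run_pos[0],
                        end=run_pos[-1] + 1,
                        cpg_positions=tuple(run_pos),
                        direction=direction,
                        mean_delta=float(np.mean(run_delta)),
                    )
                )

        for site, d in zip(track.sites, track.delta):
            if np.isnan(d):  # missing evidence breaks the run
                flush()
                run_pos, run_delta, run_chrom = [], [], None
                continue
            if sign * d <= min_abs_delta:  # not qualifying for this direction
                continue
            if (
                run_chrom != site.chrom
                or (run_pos and site.pos - run_pos[-1] >= max_gap)
            ):
                flush()
                run_pos, run_delta = [], []
            run_chrom = site.chrom
            run_pos.append(site.pos)
            run_delta.append(float(d))
        flush()

    dmrs.sort(key=lambda r: (r.chrom, r.start, r.direction))
    return dmrs


def summarize_dmrs(dmrs: list[DMR]) -> DMRSummary:
    """Hyper/hypo counts with independently rounded integer percentages."""
    n_hyper = sum(1 for d in dmrs if d.direction == "hyper")
    n_hypo = len(dmrs) - n_hyper
    total = len(dmrs)
    if total == 0:
        return DMRSummary(0, 0, 0, 0, 0)
    return DMRSummary(
        total=total,
        n_hyper=n_hyper,
        n_hypo=n_hypo,
        pct_hyper=round_half_up(100.0 * n_hyper / total),
        pct_hypo=round_half_up(100.0 * n_hypo / total),
    )
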