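"""Count filtering, TMM/CPM normalisation and differential-expression screening.

TMM (trimmed mean of M-values) follows the canonical algorithm: the
reference sample is the one whose 75th-percentile count fraction is closest
to the mean across samples; per sample, gene-wise log ratios M and average
log abundances A versus the reference are computed over genes expressed in
both; M is trimmed 30% each side and A 5% each side; the scale factor is
the precision-weighted mean of the surviving M values; factors are
renormalised to geometric mean 1.  CPM uses the effective library size
(library size x factor).

DEG screening is effect-size based by default: |log2FC| > 1 on group-mean
CPM with a 0.5 pseudocount.  An optional Welch t-test on log2(CPM + 0.5)
with Benjamini-Hochberg adjustment adds the adjusted-p < 0.05 criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import CountMatrix, resolve_selector

__all__ = [
    "NormalizedCounts",
    "DEGRecord",
    "filter_low_expressed",
    "tmm_normalize",
    "call_degs",
]


@dataclass
class NormalizedCounts:
    """TMM-scaled counts-per-million plus the per-sample scaling metadata."""

    genes: list[str]
    samples: list  # SampleMeta
    cpm: np.ndarray  # genes x samples
    tmm_factors: np.ndarray
    lib_sizes: np.ndarray

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cpm, index=self.genes, columns=self.sample_ids)

    def select_columns(self, selector) -> np.ndarray:
        idx = resolve_selector(self.samples, selector)
        return self.cpm[:, idx]


@dataclass(frozen=True)
class DEGRecord:
    gene: str
    log2fc: float
    mean_cpm_treatment: float
    mean_cpm_control: float
    p: float | None
    p_adj: float | None
    is_deg: bool


def filter_low_expressed(
    counts: CountMatrix, min_count: int = 5, min_frac: float = 0.25
) -> CountMatrix:
    """Keep genes with >= min_count reads in >= ceil(min_frac * n_samples) samples."""
    need = math.ceil(min_frac * counts.n_samples)
    keep = (counts.counts >= min_count).sum(axis=1) >= need
    return CountMatrix(
        genes=[g for g, k in zip(counts.genes, keep) if k],
        samples=counts.samples,
        counts=counts.counts[keep, :],
    )


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
    weighted: bool = True,
) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2**f)."""
    obs = obs.astype(float)
    ref = ref.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / lib_obs) / (ref / lib_ref))
        abs_e = (np.log2(obs / lib_obs) + np.log2(ref / lib_ref)) / 2.0
        v = (lib_obs - obs) / lib_obs / obs + (lib_ref - ref) / lib_ref / ref
    finite = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
    log_r, abs_e, v = log_r[finite], abs_e[finite], v[finite]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = math.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = stats.rankdata(log_r)
    rank_e = stats.rankdata(abs_e)
    keep = (
        (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    )
    if not np.any(keep):
        return 1.0
    if weighted:
        f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    else:
        f = np.mean(log_r[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_normalize(counts: CountMatrix) -> NormalizedCounts:
    """TMM scale factors and CPM on effective library sizes."""
    if counts.n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    x = counts.counts.astype(float)
    lib = x.sum(axis=0)
    if np.any(lib == 0):
        bad = [s.sample_id for s, l in zip(counts.samples, lib) if l == 0]
        raise ValueError(f"samples with zero library size: {bad}")
    # reference: sample whose upper-quartile count fraction is closest to the mean
    f75 = np.percentile(x, 75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair_factor(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx])
            for j in range(counts.n_samples)
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))  # geometric mean 1
    eff_lib = lib * factors
    cpm = x / eff_lib[None, :] * 1e6
    return NormalizedCounts(
        genes=list(counts.genes),
        samples=list(counts.samples),
        cpm=cpm,
        tmm_factors=factors,
        lib_sizes=lib,
    )


def call_degs(
    norm: NormalizedCounts,
    treatment,
    control,
    logfc_thresh: float = 1.0,
    alpha: float = 0.05,
    test: bool = False,
    pseudocount: float = 0.5,
) -> list[DEGRecord]:
    """Screen genes by |log2FC| (and optionally Welch t + BH adjusted p).

    log2FC = log2((mean treatment CPM + pseudocount) / (mean control CPM +
    pseudocount)).  With ``test=True`` a two-sided Welch t-test on
    log2(CPM + pseudocount) is BH-adjusted across all genes and
    ``is_deg`` additionally requires p_adj < alpha.
    """
    t_cpm = norm.select_columns(treatment)
    c_cpm = norm.select_columns(control)
    if test and (t_cpm.shape[1] < 2 or c_cpm.shape[1] < 2):
        raise ValueError(
            "test=True needs >= 2 replicates per group; use test=False for singletons"
        )
    mean_t = t_cpm.mean(axis=1)
    mean_c = c_cpm.mean(axis=1)
    log2fc = np.log2(mean_t + pseudocount) - np.log2(mean_c + pseudocount)

    p = p_adj = None
    if test:
        lt = np.log2(t_cpm + pseudocount)
        lc = np.log2(c_cpm + pseudocount)
        p = stats.ttest_ind(lt, lc, axis=1, equal_var=False).pvalue
        p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical groups
        p_adj = multipletests(p, method="fdr_bh")[1]

    records = []
    for i, gene in enumerate(norm.genes):
        passes = abs(log2fc[i]) > logfc_thresh
        if test:
            passes = passes and p_adj[i] < alpha
        records.append(
            DEGRecord(
                gene=gene,
                log2fc=float(log2fc[i]),
                mean_cpm_treatment=float(mean_t[i]),
                mean_cpm_control=float(mean_c[i]),
                p=float(p[i]) if test else None,
                p_adj=float(p_adj[i]) if test else None,
                is_deg=bool(passes),
            )
        )
    return records


def degs_to_frame(records: list[DEGRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
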