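"""Methylome-transcriptome integration and genomic-context profiling.

Brings the called DMRs together with expression, chromatin state and
sequence: CpG-gene correlation (Spearman with an exact permutation null at
small n, or Pearson), DMR-DEG intersection through a promoter/gene-body
mapping, chromatin-state enrichment by Fisher's exact test on
midpoint-assigned states, predicted-off-target overlap fractions,
hypergeometric gene-set overrepresentation with BH adjustment, and
sequence-preference profiling (position frequency matrix and motif
enrichment) around DMR CpGs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import BetaMatrix, CpGSite, RegionAnnotation
from .dmr import DMR, DeltaTrack
from .expression import DEGRecord, NormalizedCounts

__all__ = [
    "CpGGeneCorr",
    "DmrDeg",
    "StateEnrichment",
    "SeqPreference",
    "cpg_gene_correlation",
    "intersect_dmr_deg",
    "chromhmm_enrichment",
    "predicted_offtarget_overlap",
    "ora",
    "sequence_preference",
    "spearman_exact",
]


@dataclass(frozen=True)
class CpGGeneCorr:
    site: CpGSite
    gene: str
    method: str
    r: float
    p: float
    n: int
    significant: bool


@dataclass(frozen=True)
class DmrDeg:
    gene: str
    dmr: DMR
    deg: DEGRecord
    mapping_rule: str  # "promoter" | "body"


@dataclass(frozen=True)
class StateEnrichment:
    state: str
    n_in_query: int
    n_query: int
    n_in_background: int
    n_background: int
    odds_ratio: float
    p: float
    direction: str  # "enriched" | "depleted"


@dataclass
class SeqPreference:
    window_k: int
    pfm: pd.DataFrame          # rows A,C,G,T x window positions; column sums = n windows
    n_windows: int
    n_skipped: int
    motif: str
    motif_query: int           # query windows containing the motif
    motif_background: int
    n_background: int
    odds_ratio: float
    p: float


# -- CpG-gene correlation -----------------------------------------------------


@lru_cache(maxsize=8)
def _exact_spearman_null(n: int) -> np.ndarray:
    """Null distribution of rho over all n! rank permutations (no ties)."""
    perms = np.array(list(itertools.permutations(range(1, n + 1))), dtype=float)
    base = np.arange(1, n + 1, dtype=float)
    d2 = ((perms - base[None, :]) ** 2).sum(axis=1)
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))


def spearman_exact(x: np.ndarray, y: np.ndarray, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rho with a two-sided exact permutation p for small n.

    For n <= exact_max_n without ties, p is the fraction of the n! rank
    permutations at least as extreme in |rho|; otherwise the usual
    t-approximation is used.
    """
    n = len(x)
    rho, p_t = stats.spearmanr(x, y)
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    has_ties = len(set(rx)) < n or len(set(ry)) < n
    if n <= exact_max_n and not has_ties:
        null = _exact_spearman_null(n)
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
        return float(rho), p
    return float(rho), float(p_t)


def cpg_gene_correlation(
    beta: BetaMatrix,
    expr: NormalizedCounts,
    pairs: list[tuple[CpGSite, str]],
    method: str = "spearman",
    alpha: float = 0.05,
    min_n: int = 3,
) -> tuple[list[CpGGeneCorr], list[tuple[CpGSite, str, str]]]:
    """Correlate CpG β with gene CPM across shared samples, per declared pair.

    Samples are matched pairwise-complete by sample_id.  Pairs with fewer
    than ``min_n`` complete observations, or zero variance in either
    variable, are skipped with a reason; the second return value lists the
    skipped (site, gene, reason) triples.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    shared = [s for s in beta.sample_ids if s in set(expr.sample_ids)]
    if not shared:
        raise ValueError("no shared sample ids between beta and expression")
    b_idx = [beta.sample_ids.index(s) for s in shared]
    e_idx = [expr.sample_ids.index(s) for s in shared]
    site_row = {(s.chrom, s.pos): i for i, s in enumerate(beta.sites)}
    gene_row = {g: i for i, g in enumerate(expr.genes)}

    results: list[CpGGeneCorr] = []
    skipped: list[tuple[CpGSite, str, str]] = []
    for site, gene in pairs:
        i = site_row.get((site.chrom, site.pos))
        j = gene_row.get(gene)
        if i is None or j is None:
            skipped.append((site, gene, "site or gene absent"))
            continue
        x = beta.values[i, b_idx]
        y = expr.cpm[j, e_idx]
        ok = ~np.isnan(x) & ~np.isnan(y)
        x, y = x[ok], y[ok]
        if len(x) < min_n:
            skipped.append((site, gene, f"only {len(x)} complete pairs"))
            continue
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            skipped.append((site, gene, "zero variance"))
            continue
        if method == "spearman":
            r, p = spearman_exact(x, y)
        else:
            r, p = stats.pearsonr(x, y)
        results.append(
            CpGGeneCorr(
                site=site, gene=gene, method=method,
                r=float(r), p=float(p), n=len(x), significant=bool(p < alpha),
            )
        )
    return results, skipped


# -- DMR-DEG intersection -----------------------------------------------------


def map_dmrs_to_genes(
    dmrs: list[DMR],
    gene_regions: list[RegionAnnotation],
    promoter_upstream: int = 1500,
    promoter_downstream: int = 500,
) -> list[tuple[DMR, str, str]]:
    """(dmr, gene, rule) for every DMR overlapping a gene body or promoter.

    The promoter window spans [start - upstream, start + downstream) around
    the annotated gene start (category "gene" regions; strand-less, start
    taken as the 5' end).  A DMR overlapping several genes maps to each.
    """
    hits: list[tuple[DMR, str, str]] = []
    by_chrom: dict[str, list[RegionAnnotation]] = {}
    for g in gene_regions:
        by_chrom.setdefault(g.chrom, []).append(g)
    for dmr in dmrs:
        seen: set[tuple[str, str]] = set()
        for g in by_chrom.get(dmr.chrom, []):
            prom_start = max(0, g.start - promoter_upstream)
            prom_end = g.start + promoter_downstream
            if dmr.start < prom_end and prom_start < dmr.end:
                key = (g.label, "promoter")
                if key not in seen:
                    hits.append((dmr, g.label, "promoter"))
                    seen.add(key)
            if dmr.start < g.end and g.start < dmr.end:
                key = (g.label, "body")
                if key not in seen:
                    hits.append((dmr, g.label, "body"))
                    seen.add(key)
    return hits


def intersect_dmr_deg(
    dmrs: list[DMR],
    degs: list[DEGRecord],
    gene_regions: list[RegionAnnotation],
    promoter_upstream: int = 1500,
    promoter_downstream: int = 500,
) -> list[DmrDeg]:
    """Genes with both a mapped DMR and DEG status (DMR-DEGs)."""
    deg_by_gene = {d.gene: d for d in degs if d.is_deg}
    out: list[DmrDeg] = []
    for dmr, gene, rule in map_dmrs_to_genes(
        dmrs, gene_regions, promoter_upstream, promoter_downstream
    ):
        deg = deg_by_gene.get(gene)
        if deg is not None:
            out.append(DmrDeg(gene=gene, dmr=dmr, deg=deg, mapping_rule=rule))
    return out


# -- chromatin-state enrichment -----------------------------------------------


def assign_state(
    chrom: str, pos: int, states: list[RegionAnnotation]
) -> str:
    for s in states:
        if s.contains(chrom, pos):
            return s.label
    return "Unannotated"


def _midpoint(r) -> tuple[str, int]:
    if isinstance(r, DMR) or hasattr(r, "direction"):
        return r.chrom, (r.start + r.end) // 2
    if isinstance(r, RegionAnnotation):
        return r.chrom, (r.start + r.end) // 2
    if isinstance(r, CpGSite):
        return r.chrom, r.pos
    chrom, start, end = r[:3]
    return chrom, (int(start) + int(end)) // 2


class _StateIndex:
    """Sorted-interval lookup per chromosome (states must not overlap)."""

    def __init__(self, states: list[RegionAnnotation]):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        tmp: dict[str, list[RegionAnnotation]] = {}
        for s in states:
            tmp.setdefault(s.chrom, []).append(s)
        for chrom, regs in tmp.items():
            regs = sorted(regs, key=lambda r: r.start)
            for a, b in zip(regs, regs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"chromatin states overlap on {chrom}: "
                        f"{a.label!r} and {b.label!r}"
                    )
            self.by_chrom[chrom] = (
                np.array([r.start for r in regs]),
                np.array([r.end for r in regs]),
                [r.label for r in regs],
            )

    def lookup(self, chrom: str, pos: int) -> str:
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return "Unannotated"
        starts, ends, labels = entry
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return labels[i]
        return "Unannotated"


def chromhmm_enrichment(
    query: list,
    states: list[RegionAnnotation],
    background: list,
) -> list[StateEnrichment]:
    """Per-state 2x2 Fisher exact enrichment of query vs background.

    Each query item (DMR, region or CpG site) is assigned the state at its
    midpoint; background items likewise.  Items given as plain strings are
    taken as already-assigned state labels (useful when the background
    assignment is precomputed once and reused).  For each state the table
    [[query in, query out], [background in, background out]] yields an odds
    ratio and a two-sided Fisher exact p; midpoints in annotation gaps
    count under "Unannotated".
    """
    index = _StateIndex(states)

    def assign(r):
        return r if isinstance(r, str) else index.lookup(*_midpoint(r))

    q_states = [assign(r) for r in query]
    b_states = [assign(r) for r in background]
    n_q, n_b = len(q_states), len(b_states)
    out: list[StateEnrichment] = []
    labels = sorted(set(q_states) | set(b_states))
    q_counts = pd.Series(q_states).value_counts()
    b_counts = pd.Series(b_states).value_counts()
    for state in labels:
        a = int(q_counts.get(state, 0))
        c = int(b_counts.get(state, 0))
        table = [[a, n_q - a], [c, n_b - c]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        out.append(
            StateEnrichment(
                state=state,
                n_in_query=a,
                n_query=n_q,
                n_in_background=c,
                n_background=n_b,
                odds_ratio=float(odds),
                p=float(p),
                direction="enriched" if odds >= 1 else "depleted",
            )
        )
    return out


# -- predicted off-target overlap ---------------------------------------------


def predicted_offtarget_overlap(
    predicted: list[RegionAnnotation],
    delta: DeltaTrack,
    degs: list[DEGRecord] | None = None,
    locus_genes: dict[str, str] | None = None,
    beta_thresh: float = 0.05,
    logfc_thresh: float = 0.05,
) -> dict:
    """Fractions of predicted off-target loci with methylome/transcriptome change.

    A locus qualifies on methylation when it contains >= 1 CpG with
    |Δβ| > beta_thresh; on expression when its associated gene (via
    ``locus_genes``: locus label -> gene) has |log2FC| > logfc_thresh.
    Percentages are reported on the 0-100 scale.
    """
    if not predicted:
        return {"n_predicted": 0, "empty": True}
    chroms = np.array([s.chrom for s in delta.sites])
    poss = np.array([s.pos for s in delta.sites], dtype=np.int64)
    d = delta.delta
    n_meth = 0
    for locus in predicted:
        mask = (
            (chroms == locus.chrom) & (poss >= locus.start) & (poss < locus.end)
        )
        vals = d[mask]
        vals = vals[~np.isnan(vals)]
        if vals.size and np.max(np.abs(vals)) > beta_thresh:
            n_meth += 1
    result = {
        "n_predicted": len(predicted),
        "n_methylation": n_meth,
        "pct_methylation": 100.0 * n_meth / len(predicted),
        "empty": False,
    }
    if degs is not None and locus_genes is not None:
        lfc_by_gene = {r.gene: r.log2fc for r in degs}
        n_expr = 0
        for locus in predicted:
            gene = locus_genes.get(locus.label)
            if gene is None:
                continue
            lfc = lfc_by_gene.get(gene)
            if lfc is not None and abs(lfc) > logfc_thresh:
                n_expr += 1
        result["n_expression"] = n_expr
        result["pct_expression"] = 100.0 * n_expr / len(predicted)
    return result


# -- over-representation analysis ---------------------------------------------


def ora(
    gene_sets: dict[str, list[str]],
    query_genes: list[str],
    universe: list[str],
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of the query in each gene set.

    One-sided upper-tail p per set (overlap at least as large as observed),
    BH-adjusted across tested sets.  Sets disjoint from the universe are
    skipped with a reason column.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe must be non-empty")
    query = set(query_genes) & uni
    if set(query_genes) - uni:
        extra = sorted(set(query_genes) - uni)
        raise ValueError(f"query genes outside the universe: {extra[:5]}")
    rows = []
    for name, genes in gene_sets.items():
        in_uni = set(genes) & uni
        if not in_uni:
            rows.append(
                {
                    "set": name, "n_set": 0, "n_overlap": 0,
                    "odds_ratio": np.nan, "p": np.nan,
                    "skipped": "set disjoint from universe",
                }
            )
            continue
        k = len(in_uni & query)
        K = len(in_uni)
        N = len(uni)
        n = len(query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        a, b = k, n - k
        c, d = K - k, N - K - (n - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append(
            {
                "set": name, "n_set": K, "n_overlap": k,
                "odds_ratio": odds, "p": p, "skipped": "",
            }
        )
    df = pd.DataFrame(rows)
    tested = df["skipped"] == ""
    df["p_adj"] = np.nan
    if tested.any():
        df.loc[tested, "p_adj"] = multipletests(
            df.loc[tested, "p"].to_numpy(), method="fdr_bh"
        )[1]
    return df


# -- sequence preference ------------------------------------------------------


def _window_sequences(
    cpg_list: list[tuple[str, int]],
    genome_sequences: dict[tuple[str, int, int], str],
    window_k: int,
) -> tuple[list[str], int]:
    """Extract ±k windows centred on each CpG from per-region sequences."""
    windows: list[str] = []
    skipped = 0
    regions = list(genome_sequences.items())
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for (chrom, start, end), seq in regions:
        by_chrom.setdefault(chrom, []).append((start, end, seq))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    for chrom, pos in cpg_list:
        entry = None
        for start, end, seq in by_chrom.get(chrom, []):
            if start <= pos < end:
                entry = (start, end, seq)
                break
        if entry is None:
            skipped += 1
            continue
        start, end, seq = entry
        off = pos - start
        lo, hi = off - window_k, off + window_k + 1
        if lo < 0 or hi > len(seq):
            skipped += 1  # window truncated at the sequence edge
            continue
        windows.append(seq[lo:hi])
    return windows, skipped


def sequence_preference(
    dmrs: list[DMR],
    genome_sequences: dict[tuple[str, int, int], str],
    background_cpgs: list[tuple[str, int]],
    window_k: int = 5,
    motif: str = "GCGC",
) -> SeqPreference:
    """Sequence composition around DMR CpGs vs background CpGs.

    Builds the position frequency matrix over the 2k+1 window centred on
    every DMR member CpG, counts windows containing the motif in query and
    background, and tests motif enrichment by Fisher's exact test.
    """
    query_cpgs = [(d.chrom, p) for d in dmrs for p in d.cpg_positions]
    q_windows, q_skipped = _window_sequences(query_cpgs, genome_sequences, window_k)
    b_windows, b_skipped = _window_sequences(
        background_cpgs, genome_sequences, window_k
    )
    width = 2 * window_k + 1
    pfm = np.zeros((4, width), dtype=int)
    alphabet = "ACGT"
    idx = {c: i for i, c in enumerate(alphabet)}
    for w in q_windows:
        for j, c in enumerate(w):
            if c in idx:
                pfm[idx[c], j] += 1
    pfm_df = pd.DataFrame(
        pfm, index=list(alphabet), columns=range(-window_k, window_k + 1)
    )
    mq = sum(1 for w in q_windows if motif in w)
    mb = sum(1 for w in b_windows if motif in w)
    table = [
        [mq, len(q_windows) - mq],
        [mb, len(b_windows) - mb],
    ]
    if len(q_windows) and len(b_windows):
        odds, p = stats.fisher_exact(table, alternative="two-sided")
    else:
        odds, p = float("nan"), float("nan")
    return SeqPreference(
        window_k=window_k,
        pfm=pfm_df,
        n_windows=len(q_windows),
        n_skipped=q_skipped + b_skipped,
        motif=motif,
        motif_query=mq,
        motif_background=mb,
        n_background=len(b_windows),
        odds_ratio=float(odds),
        p=float(p),
    )
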