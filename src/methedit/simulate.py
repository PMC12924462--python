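"""Synthetic methylome + transcriptome generator with ground truth.

The generator emulates the statistical structure of a dCas9
methylation-editing experiment so every downstream stage can be exercised
and checked against known truth:

* a region-based genome whose chromatin states carry a bimodal baseline —
  promoter-like states sit near β ≈ 0.05, closed states near β ≈ 0.85;
* a single on-target locus receiving a fixed deposition (default Δβ = 0.5)
  in targeting samples, with CpGs under the gRNA footprint attenuated
  (binding-site protection);
* region-wise off-target deposition in all epimodifier samples (targeting
  and NTC alike — the construct, not the guide, drives it), drawn per
  region with probability off_target_rate x state susceptibility and a
  magnitude that *decreases* with baseline methylation (default
  delta_max x (1 − β0)), reproducing the preference for low-to-medium
  methylated promoter-like regions;
* temporal decay: each deposited region survives to a later timepoint with
  a configured probability, nested so survival is monotone in time; the
  on-target deposition persists;
* negative-binomial expression counts for the genes whose promoters are
  the simulated regions, with a configurable fraction of deposited
  promoters repressing their gene (methylation-expression coupling) plus
  guide-independent expression changes present in both targeting and NTC
  samples;
* GC-rich sequence composition (with planted GCGC motifs) for
  deposition-prone promoter-like states, for sequence-preference profiling.

All randomness flows from ``SimConfig.seed``; the same config yields
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core_io import (
    BetaMatrix,
    CountMatrix,
    CpGSite,
    RegionAnnotation,
    SampleMeta,
    write_beta_matrix,
    write_count_matrix,
    write_regions_bed,
    write_sample_sheet,
)

__all__ = ["SimConfig", "SimulatedDataset", "simulate_dataset", "truth_expected_dmrs"]

# chromatin-state vocabulary: prior weight (genome composition) and
# deposition susceptibility (multiplier on off_target_rate, capped at p=1)
DEFAULT_STATE_VOCAB = {
    #               prior, susceptibility, promoter-like
    "Active TSS": (0.12, 2.5, True),
    "Bivalent TSS": (0.06, 2.0, True),
    "Active enhancer": (0.14, 1.0, False),
    "Transcribed": (0.22, 0.5, False),
    "Repressed Polycomb": (0.10, 0.5, False),
    "Heterochromatin": (0.20, 0.2, False),
    "Quiescent": (0.16, 0.2, False),
}


@dataclass
class SimConfig:
    """Study conditions for the simulated editing experiment."""

    n_regions: int = 2000
    cpgs_per_region: tuple[int, int] = (4, 10)  # inclusive range
    cpg_spacing: tuple[int, int] = (40, 220)    # bp between CpGs within a region
    region_gap: int = 5000                      # bp between regions (> max_gap)
    n_chroms: int = 5
    state_vocab: dict = field(default_factory=lambda: dict(DEFAULT_STATE_VOCAB))
    # baseline β mixture: promoter-like states draw mostly from the low mode
    baseline_low: tuple[float, float] = (2.0, 38.0)   # Beta(a,b), mean ~0.05
    baseline_high: tuple[float, float] = (17.0, 3.0)  # Beta(a,b), mean ~0.85
    p_low_promoter: float = 0.9   # P(low mode | promoter-like state)
    p_low_other: float = 0.15
    # deposition
    on_target_delta: float = 0.5
    off_target_rate: float = 0.1
    delta_max: float = 0.35       # off-target magnitude = delta_max * (1 - baseline)
    dep_jitter_sd: float = 0.02   # per-CpG jitter on off-target deposition
    footprint_protection: float = 0.8  # fraction of on-target delta removed in footprint
    # temporal decay (on-target persists; off-target survives with these probs)
    timepoints: tuple[int, ...] = (3, 7, 30)
    persistence: dict = field(default_factory=lambda: {3: 1.0, 7: 0.5, 30: 0.1})
    noise_sd: float = 0.03        # replicate-level β noise (approx. β-scale sd)
    n_replicates: int = 4
    construct: str = "CRISPRoff"
    control_construct: str = "d3A"
    # expression
    nb_mean_log: tuple[float, float] = (5.3, 1.0)  # log base-mean ~ N(mu, sd)
    nb_dispersion: float = 0.1
    coupling_fraction: float = 0.3
    coupling_slope: float = 4.0   # |log2FC| per unit Δβ for coupled promoters
    grna_independent_degs: int = 100
    grna_independent_lfc: float = 2.0
    # sequences
    seq_gc_promoter: float = 0.65
    seq_gc_other: float = 0.40
    motif: str = "GCGC"
    motif_rate_promoter: float = 0.06   # planted motifs per bp in promoter-like regions
    motif_rate_other: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions <= 0:
            raise ValueError("n_regions must be positive")
        for name, p in (
            ("off_target_rate", self.off_target_rate),
            ("footprint_protection", self.footprint_protection),
            ("coupling_fraction", self.coupling_fraction),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if not 0.0 <= self.on_target_delta <= 1.0:
            raise ValueError("on_target_delta must be in [0,1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for t in self.timepoints:
            if t not in self.persistence:
                raise ValueError(f"persistence probability missing for day {t}")


@dataclass
class SimulatedDataset:
    """Everything the pipeline consumes, plus the generating truth."""

    betas: dict[int, BetaMatrix]          # timepoint -> matrix
    counts: dict[int, CountMatrix]
    regions: dict[str, list[RegionAnnotation]]  # by category
    truth: pd.DataFrame
    sequences: dict[tuple[str, int, int], str]  # (chrom, start, end) -> sequence
    config: SimConfig

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        for day, beta in self.betas.items():
            write_beta_matrix(beta, os.path.join(outdir, f"beta_day{day}.tsv"))
            write_sample_sheet(
                beta.samples, os.path.join(outdir, f"samples_day{day}.tsv")
            )
        for day, cm in self.counts.items():
            write_count_matrix(cm, os.path.join(outdir, f"counts_day{day}.tsv"))
        for category, regs in self.regions.items():
            if regs:
                write_regions_bed(regs, os.path.join(outdir, f"{category}.bed"))
        self.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
        with open(os.path.join(outdir, "sequences.tsv"), "w") as fh:
            fh.write("chrom\tstart\tend\tsequence\n")
            for (chrom, start, end), seq in self.sequences.items():
                fh.write(f"{chrom}\t{start}\t{end}\t{seq}\n")


def _beta_noise(rng, beta: np.ndarray, sd: float) -> np.ndarray:
    """Replicate noise on the logit scale, scaled so the β-scale sd ≈ sd.

    The logit-scale sd is sd / (p(1-p)) (delta method) with p clamped away
    from the boundary, so mid-range and extreme CpGs receive comparable
    β-scale perturbation while β stays in (0,1) by construction.
    """
    if sd == 0:
        return beta
    p = np.clip(beta, 1e-4, 1 - 1e-4)
    p_eff = np.clip(p, 0.02, 0.98)
    scale = sd / (p_eff * (1 - p_eff))
    return expit(logit(p) + rng.normal(0.0, 1.0, size=beta.shape) * scale)


def _random_sequence(rng, length: int, gc: float, motif: str, motif_rate: float) -> str:
    at = (1 - gc) / 2
    gcp = gc / 2
    seq = rng.choice(list("ACGT"), size=length, p=[at, gcp, gcp, at])
    n_motifs = rng.binomial(length, motif_rate)
    for _ in range(n_motifs):
        start = rng.integers(0, max(1, length - len(motif)))
        seq[start : start + len(motif)] = list(motif)
    return "".join(seq)


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Generate the full multi-timepoint methylome + transcriptome dataset."""
    rng = np.random.default_rng(cfg.seed)
    states = list(cfg.state_vocab)
    priors = np.array([cfg.state_vocab[s][0] for s in states], dtype=float)
    priors = priors / priors.sum()
    susc = {s: cfg.state_vocab[s][1] for s in states}
    promoter_like = {s: cfg.state_vocab[s][2] for s in states}

    # ---- genome layout: regions laid consecutively along chromosomes ----
    n = cfg.n_regions
    region_state = rng.choice(states, size=n, p=priors)
    lo, hi = cfg.cpgs_per_region
    n_cpgs = rng.integers(lo, hi + 1, size=n)
    chrom_of = np.array(
        [f"chr{1 + (i * cfg.n_chroms) // n}" for i in range(n)]
    )
    rows = []
    cpg_chrom: list[str] = []
    cpg_pos: list[int] = []
    cpg_region: list[int] = []
    cursor: dict[str, int] = {}
    for i in range(n):
        chrom = chrom_of[i]
        pos = cursor.get(chrom, 10_000)
        start = pos
        for _ in range(int(n_cpgs[i])):
            cpg_chrom.append(chrom)
            cpg_pos.append(pos)
            cpg_region.append(i)
            pos += int(rng.integers(cfg.cpg_spacing[0], cfg.cpg_spacing[1] + 1))
        end = cpg_pos[-1] + 2  # half-open, covering the last CpG dinucleotide
        cursor[chrom] = end + cfg.region_gap
        rows.append({"region_id": i, "chrom": chrom, "start": start, "end": end})
    layout = pd.DataFrame(rows)
    layout["state"] = region_state
    layout["n_cpgs"] = n_cpgs
    cpg_region_arr = np.array(cpg_region)
    cpg_pos_arr = np.array(cpg_pos, dtype=np.int64)
    n_cpg_total = len(cpg_pos)

    # ---- baseline β: bimodal mixture conditioned on state ----
    p_low = np.array(
        [
            cfg.p_low_promoter if promoter_like[s] else cfg.p_low_other
            for s in region_state
        ]
    )
    low = rng.random(n) < p_low
    a_lo, b_lo = cfg.baseline_low
    a_hi, b_hi = cfg.baseline_high
    base_region = np.where(
        low, rng.beta(a_lo, b_lo, size=n), rng.beta(a_hi, b_hi, size=n)
    )
    # per-CpG baseline = region baseline + small jitter (shared by all samples)
    jitter = (
        rng.normal(0.0, 0.01, size=n_cpg_total) if cfg.noise_sd > 0 else np.zeros(n_cpg_total)
    )
    base_cpg = np.clip(base_region[cpg_region_arr] + jitter, 0.0, 1.0)

    # ---- target locus & gRNA footprint: first promoter-like region ----
    promoter_mask = np.array([promoter_like[s] for s in region_state])
    target_candidates = np.flatnonzero(promoter_mask)
    if target_candidates.size == 0:
        raise ValueError("no promoter-like region available for the target locus")
    target_region = int(target_candidates[0])
    t_row = layout.iloc[target_region]
    target_cpgs = np.flatnonzero(cpg_region_arr == target_region)
    # footprint: ~20 bp around the middle CpGs of the target locus
    mid = target_cpgs[len(target_cpgs) // 2]
    fp_start = int(cpg_pos_arr[mid]) - 10
    fp_end = int(cpg_pos_arr[mid]) + 12
    footprint = RegionAnnotation(
        chrom=t_row["chrom"],
        start=max(0, fp_start),
        end=fp_end,
        label="g_footprint",
        category="grna_footprint",
    )
    in_footprint = np.zeros(n_cpg_total, dtype=bool)
    in_footprint[target_cpgs] = (cpg_pos_arr[target_cpgs] >= footprint.start) & (
        cpg_pos_arr[target_cpgs] < footprint.end
    )

    # ---- off-target deposition: per-region Bernoulli, magnitude decreasing in β0 ----
    p_dep = np.minimum(
        1.0, cfg.off_target_rate * np.array([susc[s] for s in region_state])
    )
    p_dep[target_region] = 0.0  # the target locus is handled separately
    deposited = rng.random(n) < p_dep
    dep_delta = np.where(deposited, cfg.delta_max * (1.0 - base_region), 0.0)
    # nested survival: one uniform per region; survives day t iff u < persistence[t]
    u_surv = rng.random(n)
    survive = {
        t: deposited & (u_surv < cfg.persistence[t]) for t in cfg.timepoints
    }

    # ---- predicted off-target loci: deposited regions + background decoys ----
    decoy_pool = np.flatnonzero(~deposited & (np.arange(n) != target_region))
    decoys = rng.choice(decoy_pool, size=min(40, decoy_pool.size), replace=False)
    predicted_ids = sorted(set(np.flatnonzero(deposited)[:10]) | set(decoys))

    # ---- per-CpG deposition jitter (fixed per CpG, shared across replicates) ----
    dep_jitter = (
        rng.normal(0.0, cfg.dep_jitter_sd, size=n_cpg_total)
        if cfg.noise_sd > 0
        else np.zeros(n_cpg_total)
    )

    # ---- samples ----
    def make_samples(day: int) -> list[SampleMeta]:
        samples = []
        for guide, construct in (
            ("targeting", cfg.construct),
            ("NTC", cfg.construct),
            ("NTC", cfg.control_construct),
        ):
            for r in range(1, cfg.n_replicates + 1):
                samples.append(
                    SampleMeta(
                        sample_id=f"{construct}_{guide}_d{day}_r{r}",
                        construct=construct,
                        guide=guide,
                        timepoint_days=day,
                        replicate=r,
                    )
                )
        return samples

    sites = [CpGSite(chrom=c, pos=int(p)) for c, p in zip(cpg_chrom, cpg_pos_arr)]

    # ---- β matrices per timepoint ----
    betas: dict[int, BetaMatrix] = {}
    for day in cfg.timepoints:
        samples = make_samples(day)
        cols = []
        for s in samples:
            mean = base_cpg.copy()
            if s.construct == cfg.construct:
                # off-target deposition: construct-driven, guide-independent
                region_d = np.where(survive[day], dep_delta, 0.0)
                d = region_d[cpg_region_arr]
                d = np.where(d > 0, np.clip(d + dep_jitter, 0.0, 1.0), 0.0)
                mean = mean + d
                if s.guide == "targeting":
                    on = np.zeros(n_cpg_total)
                    on[target_cpgs] = cfg.on_target_delta
                    on[in_footprint] *= 1.0 - cfg.footprint_protection
                    mean = mean + on
            mean = np.clip(mean, 0.0, 1.0)
            cols.append(_beta_noise(rng, mean, cfg.noise_sd))
        betas[day] = BetaMatrix(sites, samples, np.column_stack(cols))

    # ---- genes: one per promoter-like region ----
    gene_region = np.flatnonzero(promoter_mask)
    gene_ids = {int(i): f"gene_{i}" for i in gene_region}
    mu_log, sd_log = cfg.nb_mean_log
    base_mean = {}
    for i in gene_region:
        base_mean[int(i)] = float(np.exp(rng.normal(mu_log, sd_log)))
    coupled = {
        int(i): bool(deposited[i]) and (rng.random() < cfg.coupling_fraction)
        for i in gene_region
    }
    target_gene = gene_ids.get(target_region)
    # guide-independent DEGs: construct-driven expression changes, both guides
    indep_pool = [int(i) for i in gene_region if not coupled[int(i)] and int(i) != target_region]
    n_indep = min(cfg.grna_independent_degs, len(indep_pool))
    indep_ids = set(
        rng.choice(indep_pool, size=n_indep, replace=False).tolist()
    ) if n_indep else set()
    indep_lfc = {
        i: float(rng.choice([-1.0, 1.0]) * cfg.grna_independent_lfc) for i in indep_ids
    }

    disp = cfg.nb_dispersion

    def nb_draw(mu: np.ndarray) -> np.ndarray:
        if disp <= 0:
            return rng.poisson(mu)
        r = 1.0 / disp
        p = r / (r + mu)
        return rng.negative_binomial(r, p)

    counts: dict[int, CountMatrix] = {}
    truth_lfc: dict[tuple[int, int], float] = {}  # (region, day) -> true log2FC
    for day in cfg.timepoints:
        samples = make_samples(day)
        genes = [gene_ids[int(i)] for i in gene_region]
        mat = np.zeros((len(genes), len(samples)), dtype=np.int64)
        for j, s in enumerate(samples):
            mu = np.empty(len(genes))
            for k, i in enumerate(gene_region):
                i = int(i)
                lfc = 0.0
                if s.construct == cfg.construct:
                    if coupled[i] and survive[day][i]:
                        lfc += -cfg.coupling_slope * dep_delta[i]
                    if i == target_region and s.guide == "targeting":
                        lfc += -cfg.coupling_slope * cfg.on_target_delta
                    if i in indep_ids:
                        lfc += indep_lfc[i]
                mu[k] = base_mean[i] * 2.0**lfc
            mat[:, j] = nb_draw(mu)
        counts[day] = CountMatrix(genes, samples, mat)
    for day in cfg.timepoints:
        for i in gene_region:
            i = int(i)
            lfc = 0.0
            if coupled[i] and survive[day][i]:
                lfc += -cfg.coupling_slope * dep_delta[i]
            if i in indep_ids:
                lfc += indep_lfc[i]
            truth_lfc[(i, day)] = lfc

    # ---- region annotations ----
    state_regions = [
        RegionAnnotation(
            chrom=r.chrom, start=int(r.start), end=int(r.end),
            label=str(r.state), category="chromatin_state",
        )
        for r in layout.itertuples()
    ]
    target_locus = [
        RegionAnnotation(
            chrom=t_row["chrom"], start=int(t_row["start"]), end=int(t_row["end"]),
            label="target_locus", category="target_locus",
        )
    ]
    offtarget_loci = [
        RegionAnnotation(
            chrom=layout.at[i, "chrom"],
            start=int(layout.at[i, "start"]),
            end=int(layout.at[i, "end"]),
            label=f"predicted_ot_{i}",
            category="offtarget_locus",
        )
        for i in predicted_ids
    ]
    promoters = [
        RegionAnnotation(
            chrom=layout.at[int(i), "chrom"],
            start=int(layout.at[int(i), "start"]),
            end=int(layout.at[int(i), "end"]),
            label=gene_ids[int(i)],
            category="promoter",
        )
        for i in gene_region
    ]
    # gene body: interval immediately downstream of the promoter region
    gene_bodies = [
        RegionAnnotation(
            chrom=layout.at[int(i), "chrom"],
            start=int(layout.at[int(i), "end"]),
            end=int(layout.at[int(i), "end"]) + 2000,
            label=gene_ids[int(i)],
            category="gene",
        )
        for i in gene_region
    ]

    # ---- sequences per region ----
    sequences: dict[tuple[str, int, int], str] = {}
    for r in layout.itertuples():
        prom = promoter_like[r.state]
        gc = cfg.seq_gc_promoter if prom else cfg.seq_gc_other
        rate = cfg.motif_rate_promoter if prom else cfg.motif_rate_other
        sequences[(r.chrom, int(r.start), int(r.end))] = _random_sequence(
            rng, int(r.end) - int(r.start), gc, cfg.motif, rate
        )

    # ---- truth table ----
    truth = layout.copy()
    truth["baseline_beta"] = base_region
    truth["is_target"] = np.arange(n) == target_region
    truth["deposited"] = deposited
    truth["dep_delta"] = dep_delta
    for t in cfg.timepoints:
        truth[f"survive_d{t}"] = survive[t]
    truth["gene"] = [gene_ids.get(int(i), "") for i in range(n)]
    truth["coupled"] = [coupled.get(int(i), False) for i in range(n)]
    truth["predicted_offtarget"] = [int(i) in set(predicted_ids) for i in range(n)]
    for t in cfg.timepoints:
        truth[f"true_lfc_d{t}"] = [
            truth_lfc.get((int(i), t), 0.0) for i in range(n)
        ]

    return SimulatedDataset(
        betas=betas,
        counts=counts,
        regions={
            "chromatin_state": state_regions,
            "target_locus": target_locus,
            "offtarget_locus": offtarget_loci,
            "grna_footprint": [footprint],
            "promoter": promoters,
            "gene": gene_bodies,
        },
        truth=truth,
        sequences=sequences,
        config=cfg,
    )


def truth_expected_dmrs(
    truth: pd.DataFrame,
    timepoint: int,
    min_abs_delta: float = 0.1,
    min_cpgs: int = 2,
) -> list[tuple[str, int, int]]:
    """Regions whose deposited change should be called as a DMR at a timepoint.

    A region is expected when its deposit survives to the timepoint, its
    magnitude exceeds the calling threshold and it carries at least
    ``min_cpgs`` CpGs.  Returns (chrom, start, end) intervals.
    """
    col = f"survive_d{timepoint}"
    if col not in truth.columns:
        raise ValueError(f"truth has no column {col!r}")
    sel = (
        truth[col]
        & (truth["dep_delta"].abs() > min_abs_delta)
        & (truth["n_cpgs"] >= min_cpgs)
    )
    return [
        (r.chrom, int(r.start), int(r.end)) for r in truth[sel].itertuples()
    ]
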