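# methedit

Analysis toolkit for profiling the **on-target and off-target effects of
dCas9 DNA-methylation editors** (CRISPRoff, dCas9-DNMT3A fusions and
related epimodifiers). Starting from beta-value matrices (EPIC-array or
targeted methyl-seq style), Bismark-style cytosine coverage files and raw
RNA-seq count matrices, it provides:

- **Effect-size DMR calling** — a differentially methylated region is a
  maximal run of ≥ 2 consecutive qualifying CpGs with same-direction
  |Δβ| > 0.1 and successive gaps < 2 kb, where
  Δβ = mean β(treatment) − mean β(control); hyper- and hypomethylation are
  called symmetrically, and direction splits are summarised as integer
  percentages.
- **Targeted-panel quantification** — coverage masking (β set missing
  below 10×), per-locus per-CpG profiles, the net specific effect
  Δβ(targeting) − Δβ(NTC), gRNA-footprint annotation, and the enzymatic
  methyl-seq differential filter (≥ 10× in both conditions, |Δβ| ≥ 0.10).
- **Temporal stability** — persistence of DMRs across harvest days
  (100 · n_overlap / n_early, overlap by shared member CpG and matching
  direction) and the asymmetric pairwise-sharedness matrix.
- **Expression screening** — low-count filtering (≥ 5 reads in ≥ 25 % of
  samples), TMM/CPM normalisation (edgeR-compatible scale factors), and
  DEG screening at |log₂FC| > 1, optionally with Welch t + BH-adjusted
  p < 0.05.
- **Integration** — CpG–gene Spearman/Pearson correlation (exact
  permutation p at small n), DMR–DEG intersection via a promoter
  (−1500/+500) + gene-body mapping, chromatin-state enrichment (Fisher
  exact on midpoint-assigned states), predicted-off-target overlap
  fractions, hypergeometric gene-set overrepresentation with BH
  correction, and sequence-preference profiling (position frequency
  matrix, GCGC-motif enrichment) around DMR CpGs.
- **A ground-truthed simulator** — generates methylome + transcriptome
  datasets with the statistical structure such experiments show: bimodal
  baseline methylation, deposition concentrated at low-methylated
  promoter-like regions, gRNA-footprint protection, day 3→7→30 decay and
  negative-binomial counts partially coupled to promoter methylation — so
  every stage can be validated against known truth without external data.

## Worked example

```python
from methedit import SimConfig, simulate_dataset, compute_delta, call_dmrs, summarize_dmrs
from methedit.stability import overlap_dmr_sets

data = simulate_dataset(SimConfig(n_regions=2000, seed=1))
dmrs = {}
for day in (3, 7):
    track = compute_delta(
        data.betas[day],
        {"construct": "CRISPRoff", "guide": "NTC"},   # construct-driven changes
        {"construct": "d3A"},                         # catalytically dead control
    )
    dmrs[day] = call_dmrs(track, min_cpgs=2, min_abs_delta=0.1, max_gap=2000)

s = summarize_dmrs(dmrs[3])
print(s.total, s.pct_hyper, s.pct_hypo)   # -> 93 100 0
res = overlap_dmr_sets(dmrs[3], dmrs[7])
print(round(res.persistence_pct, 1))      # -> 43.0
```

93 off-target DMRs are called at day 3 (all hypermethylated, as expected
for a methyltransferase payload), and 43 % of them persist to day 7 —
consistent with the simulated 50 % region-survival probability (the truth
table in `data.truth` lets you verify this directly). The same stages are
available from the shell:

```bash
methedit simulate --seed 1 --out sim/
methedit call-dmrs --beta sim/beta_day3.tsv --sheet sim/samples_day3.tsv \
    --treat construct=CRISPRoff,guide=NTC --control construct=d3A --out dmrs_d3.bed
methedit run-all --seed 1 --out run/     # every stage + reproducibility manifest
```

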