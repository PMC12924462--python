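# Methods

## Coordinates, missingness, strands

All in-memory intervals are 0-based half-open (BED-compatible). Bismark
coverage files and beta-matrix TSVs use 1-based positions and are
converted at the read boundary; writers convert back, so read/write pairs
are the identity on valid data. Missing β is carried as NaN, never 0: a
sub-10× CpG is *absent evidence*, and every downstream mean is
pairwise-complete. CpGs are keyed by the + strand cytosine; symmetric CpG
methylation is assumed to have been merged upstream (the readers do not
merge strands).

## DMR calling

Δβ at a CpG is the difference of group means over non-missing replicates;
it is missing when either group is entirely missing there. A DMR is a
maximal run of qualifying CpGs — |Δβ| strictly > `delta_beta` (default
0.1) with one sign — within one chromosome, where successive *qualifying*
CpGs lie strictly closer than `max_gap` (default 2000 bp), with at least
`min_cpgs` (default 2) members. Three deliberate reading choices:

- the identical rule is applied to each sign, giving symmetric hyper/hypo
  calls;
- a measured sub-threshold CpG between two qualifying CpGs is transparent
  (the gap is measured between qualifying cytosines), whereas a CpG with
  *missing* Δβ breaks the run — measured weak evidence and absent
  evidence are treated differently, absent evidence conservatively;
- both thresholds are strict inequalities (a Δβ of exactly 0.1, or a gap
  of exactly 2000 bp, does not qualify).

Direction percentages in summaries use round-half-up to integers,
independently per direction, so the two percentages may sum to 99–101.
No p-value is attached: the rule is purely effect-size based; replication
enters through the group means.

An independent brute-force enumerator of maximal qualifying runs (in the
test suite) is held equal to the caller on thousands of random tracks.

## Targeted panel

Coverage masking keeps a CpG at exactly 10× and masks strictly below —
and the enzymatic methyl-seq differential filter keeps |Δβ| ≥ 0.10
*inclusive* while the genome-wide caller is strict at > 0.1; the two
stages intentionally follow their own conventions. The net specific
effect of a guide is computed per CpG as
Δβ(targeting vs control) − Δβ(NTC vs control); the shared control cancels
algebraically, so any common reference yields the same net effect (a
property test asserts this). Locus means are reported overall and split
by gRNA-footprint membership, since footprint CpGs are physically
protected from deposition. Coverage is interpreted per-CpG (not
per-amplicon). A panel locus with no covered CpG yields a flagged, empty
profile rather than an error.

## Stability

Persistence of a DMR set is the fraction of early DMRs sharing ≥ 1 member
CpG with a same-direction later DMR. CpG identity (rather than base-pair
intersection) is the default overlap unit because array-derived DMRs are
built from a fixed probe set, making CpG sharing edge-artifact-free;
base-pair overlap is available via `by="bp"` (and is the CLI default for
BED inputs, which carry no member CpGs). Direction must match: a region
hyper early and hypo late is not stable. The pairwise-sharedness matrix
is row-normalised and therefore asymmetric by construction. Display
formatting is integer percent at ≥ 1 % and one decimal below.

## Expression

Gene filtering keeps a gene with ≥ `count_min` (5) reads in at least
⌈`count_frac` · n_samples⌉ (25 %) samples. TMM follows the canonical
algorithm — reference sample by closest 75th-percentile count fraction,
log-ratio trim 0.30, abundance trim 0.05, precision-weighted mean,
factors renormalised to geometric mean 1 — and reproduces
edgeR::calcNormFactors to 1e-6 on a frozen oracle matrix. CPM uses
effective library sizes (library × factor). DEG screening defaults to the
effect-size rule |log₂FC| > 1 on group-mean CPM with pseudocount 0.5
(finite ratios at zero counts; configurable). The optional test mode adds
a two-sided Welch t on log₂(CPM + 0.5) with Benjamini–Hochberg
adjustment, p_adj < 0.05; it is off by default because a dispersion-aware
count test is out of scope and the effect-size rule alone defines the
default screening surface.

## Integration

- **CpG–gene correlation**: pairwise-complete matching by sample id;
  Spearman p is an exact permutation tail for n ≤ 9 without ties (the n!
  null is enumerated and cached), t-approximate otherwise — the exact
  branch matters because per-condition sample counts are small. Pairs
  with < 3 complete observations or zero variance are skipped with a
  recorded reason.
- **DMR→gene mapping**: a DMR maps to a gene when it overlaps the gene
  body or the promoter window −1500/+500 bp around the annotated start
  (configurable); a DMR spanning several genes maps to each. A DMR-DEG is
  a mapped gene that also passes the DEG screen.
- **Chromatin-state enrichment**: each query element is assigned the
  state at its midpoint (deterministic and tie-free; midpoints in
  annotation gaps count as "Unannotated"), then a per-state 2×2 Fisher
  exact test (two-sided, since both enrichment and depletion are of
  interest) against a caller-supplied background. The background choice
  is explicit and surfaced in the result object; pre-assigned labels may
  be passed directly when the assignment is precomputed.
- **ORA**: one-sided hypergeometric upper tail per gene set, BH across
  sets; the query must lie within the declared universe.
- **Sequence preference**: position frequency matrix over ±k bp (default
  ±5) windows centred on DMR CpGs; windows truncated at a sequence edge
  are skipped and tallied; motif (default GCGC) enrichment vs background
  windows by Fisher exact test.

## The simulator

The generator emulates the statistical structure of a methylation-editing
experiment; its defaults are the study conditions under which the test
suite validates the pipeline.

- **Genome**: 2000 regions of 4–10 CpGs (spacing 40–220 bp) on 5
  chromosomes, separated by 5 kb gaps (larger than `max_gap`, so regions
  are independent calling units). Each region carries a chromatin state
  drawn from a seven-state vocabulary with genome-like priors.
- **Baseline**: a two-component Beta mixture — Beta(2, 38) (mode ≈ 0.05)
  with probability 0.9 for promoter-like states, Beta(17, 3) (mode ≈
  0.85) otherwise — giving the bimodal genome-wide β distribution real
  methylomes show.
- **Deposition**: one on-target promoter locus gains Δβ = 0.5 exactly in
  targeting samples, attenuated by the footprint-protection factor (0.8)
  at CpGs under the gRNA binding site. Off-target deposition is
  *construct-driven* (applied to targeting and NTC samples alike, as
  non-targeting constructs also deposit genome-wide): each region
  deposits with probability `off_target_rate` × state susceptibility
  (promoter-like states up to 2.5×, closed chromatin 0.2×), with
  magnitude `delta_max` · (1 − β₀) — a simple decreasing function of
  baseline chosen because the true functional form of the baseline bias
  is not known; it is a config field.
- **Decay**: one survival uniform per region makes persistence nested and
  monotone over time (default survival 1.0/0.5/0.1 at days 3/7/30); the
  on-target deposition persists throughout.
- **Noise**: replicate noise is added on the logit scale with the scale
  chosen by the delta method so the β-scale standard deviation is
  approximately `noise_sd` (0.03) across the range; β stays in (0, 1) by
  construction. With `noise_sd=0` every stochastic perturbation is off
  and deposition is exact, which pins down the arithmetic in tests.
- **Expression**: one gene per promoter-like region, negative-binomial
  counts (log-normal base means, dispersion 0.1). A fraction
  `coupling_fraction` (0.3) of deposited promoters represses its gene by
  `coupling_slope` (4) log₂ units per unit Δβ while the deposit survives;
  100 further genes receive guide-independent ±2 log₂FC shifts in both
  targeting and NTC samples, emulating the pervasive
  methylation-independent transcriptional response to the construct.
- **Sequences**: promoter-like regions are GC-rich (65 %) with planted
  GCGC motifs, other states AT-richer, so deposition-prone regions carry
  the motif signal the sequence-preference stage should detect.

What the simulator does **not** model: probe-level array chemistry and
normalisation artifacts, read-level sampling (β noise is not
coverage-dependent), linkage between neighbouring regions, secondary
(expression-driven) methylation changes, and cell-population
heterogeneity. Passing tests therefore demonstrate correctness of the
analysis logic under the stated generative assumptions, not performance
on any particular real dataset.

## Problem sizes and numerical choices

Validation runs use 2000 simulated regions (≈ 14 000 CpGs, 12 samples per
timepoint) for parameter recovery, 20 seeds × 200 regions for the
footprint-protection contrast, 1000 random tracks (≤ 300 CpGs) for
caller–oracle equivalence, and 1000 resampling draws for the
null-calibration of the exact tests — sizes at which every statistical
check has ample power while the whole suite runs in well under a minute
per module. Null calibration uses pools large enough (≈ 50 000 labelled
items; universe 20 000 genes with a 5000-gene set and 5000-gene queries)
that the discrete support of the exact hypergeometric/Fisher p-values is
finer than the Kolmogorov–Smirnov resolution at 1000 draws; at smaller
table sizes an exact test's p-value is *not* uniform (it is discrete and
conservative), and uniformity should not be expected.

The EM-seq inclusive boundary (|Δβ| ≥ 0.10) is checked with a 1e-12
tolerance because count-ratio differences such as 0.5 − 0.4 are not exact
in binary floating point. TMM reproduces edgeR's tie-handling by using
average ranks in the trimming windows. Fisher exact and hypergeometric
tails come from scipy; BH adjustment from statsmodels.
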