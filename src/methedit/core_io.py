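"""Data model, coordinate conventions and file I/O.

All genomic intervals held in memory are 0-based half-open (BED-compatible).
Positions arriving in 1-based inclusive conventions — Bismark cytosine
coverage files and array-manifest style beta-matrix TSVs — are converted at
the read boundary and converted back on write, so a round trip is the
identity.

Missing methylation values are first-class: they are carried as NaN, never
as 0, and every downstream mean is pairwise-complete.  CpG strands are
assumed pre-merged to the + strand cytosine (symmetric CpG methylation);
readers do not merge strands themselves.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CpGSite",
    "SampleMeta",
    "BetaMatrix",
    "CoverageRecord",
    "RegionAnnotation",
    "CountMatrix",
    "read_sample_sheet",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_bismark_coverage",
    "read_regions_bed",
    "write_regions_bed",
    "read_count_matrix",
    "write_count_matrix",
    "read_config",
    "write_config",
    "DEFAULT_THRESHOLDS",
    "resolve_selector",
]

# Analysis thresholds used throughout the pipeline; every stage takes these
# as explicit keyword arguments, this dict only centralises the defaults.
DEFAULT_THRESHOLDS = {
    "delta_beta": 0.1,     # per-CpG |Δβ| must exceed this (strict) for DMR membership
    "max_gap": 2000,       # successive qualifying CpGs must be closer than this (strict), bp
    "min_cpgs": 2,         # minimum CpGs per DMR
    "coverage_min": 10,    # minimum read coverage, below which β is set missing
    "logfc": 1.0,          # |log2FC| DEG threshold (strict)
    "count_min": 5,        # expression filter: minimum raw count ...
    "count_frac": 0.25,    # ... in at least this fraction of samples
}

REGION_CATEGORIES = (
    "chromatin_state",
    "target_locus",
    "offtarget_locus",
    "grna_footprint",
    "gene",
    "promoter",
)

GUIDE_VOCAB = ("targeting", "NTC", "scaffold", "empty")


@dataclass(frozen=True, order=True)
class CpGSite:
    """A CpG cytosine, keyed by the + strand position (0-based)."""

    chrom: str
    pos: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("CpGSite.chrom must be non-empty")
        if self.pos < 0:
            raise ValueError(f"CpGSite.pos must be >= 0, got {self.pos}")


@dataclass(frozen=True)
class SampleMeta:
    """One sample: which epimodifier construct, which guide, when, which replicate."""

    sample_id: str
    construct: str
    guide: str
    timepoint_days: int
    replicate: int

    def __post_init__(self) -> None:
        if self.guide not in GUIDE_VOCAB:
            raise ValueError(
                f"sample {self.sample_id!r}: guide {self.guide!r} not in {GUIDE_VOCAB}"
            )
        if self.timepoint_days <= 0:
            raise ValueError(
                f"sample {self.sample_id!r}: timepoint_days must be positive"
            )


@dataclass(frozen=True)
class CoverageRecord:
    """Per-CpG methylated/unmethylated read counts (Bismark coverage style)."""

    site: CpGSite
    count_methylated: int
    count_unmethylated: int

    def __post_init__(self) -> None:
        if self.count_methylated < 0 or self.count_unmethylated < 0:
            raise ValueError(f"negative counts at {self.site.chrom}:{self.site.pos}")

    @property
    def coverage(self) -> int:
        return self.count_methylated + self.count_unmethylated

    @property
    def beta(self) -> float:
        """Methylation fraction from counts; NaN when coverage is zero."""
        if self.coverage == 0:
            return float("nan")
        return self.count_methylated / self.coverage


@dataclass(frozen=True)
class RegionAnnotation:
    """A labelled genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    label: str
    category: str = "chromatin_state"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"region {self.label!r}: start must be < end "
                f"({self.chrom}:{self.start}-{self.end})"
            )
        if self.category not in REGION_CATEGORIES:
            raise ValueError(f"unknown region category {self.category!r}")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    @property
    def length(self) -> int:
        return self.end - self.start


class BetaMatrix:
    """CpG sites x samples methylation fractions, with NaN as the missing marker.

    Sites are kept sorted by (chrom, pos) and unique; all non-missing values
    lie in [0, 1].
    """

    def __init__(
        self,
        sites: Sequence[CpGSite],
        samples: Sequence[SampleMeta],
        values: np.ndarray,
    ):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(sites), len(samples)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(sites)} sites x {len(samples)} samples"
            )
        order = sorted(range(len(sites)), key=lambda i: (sites[i].chrom, sites[i].pos))
        self.sites: list[CpGSite] = [sites[i] for i in order]
        self.values: np.ndarray = values[order, :]
        self.samples: list[SampleMeta] = list(samples)
        keys = [(s.chrom, s.pos) for s in self.sites]
        if len(set(keys)) != len(keys):
            seen: set[tuple[str, int]] = set()
            for k in keys:
                if k in seen:
                    raise ValueError(f"duplicate CpG site {k[0]}:{k[1]}")
                seen.add(k)
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            bad = np.argwhere((self.values < 0) | (self.values > 1))
            i, j = bad[0]
            raise ValueError(
                f"beta value {self.values[i, j]} out of [0,1] at "
                f"{self.sites[i].chrom}:{self.sites[i].pos}, "
                f"sample {self.samples[j].sample_id!r}"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def positions(self) -> tuple[np.ndarray, np.ndarray]:
        """(chrom array, pos array) aligned with rows."""
        return (
            np.array([s.chrom for s in self.sites]),
            np.array([s.pos for s in self.sites], dtype=np.int64),
        )

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]

    def select_samples(self, selector) -> "BetaMatrix":
        idx = resolve_selector(self.samples, selector)
        return BetaMatrix(
            self.sites, [self.samples[j] for j in idx], self.values[:, idx]
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.sample_ids)
        df.insert(0, "pos", [s.pos for s in self.sites])
        df.insert(0, "chrom", [s.chrom for s in self.sites])
        return df


class CountMatrix:
    """Gene x sample raw RNA-seq counts."""

    def __init__(
        self,
        genes: Sequence[str],
        samples: Sequence[SampleMeta],
        counts: np.ndarray,
    ):
        counts = np.asarray(counts)
        if counts.shape != (len(genes), len(samples)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        if len(set(genes)) != len(genes):
            raise ValueError("gene identifiers must be unique")
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be non-negative")
        self.genes: list[str] = list(genes)
        self.samples: list[SampleMeta] = list(samples)
        self.counts: np.ndarray = counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def select_samples(self, selector) -> "CountMatrix":
        idx = resolve_selector(self.samples, selector)
        return CountMatrix(
            self.genes, [self.samples[j] for j in idx], self.counts[:, idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.sample_ids)


# -- sample selectors ---------------------------------------------------------


def resolve_selector(samples: Sequence[SampleMeta], selector) -> list[int]:
    """Resolve a sample selector to column indices.

    A selector may be a list of sample_ids, a dict of SampleMeta field ->
    value (or collection of values), or a callable SampleMeta -> bool.
    """
    if callable(selector):
        idx = [j for j, s in enumerate(samples) if selector(s)]
    elif isinstance(selector, dict):
        def match(s: SampleMeta) -> bool:
            for key, want in selector.items():
                got = getattr(s, key)
                if isinstance(want, (list, tuple, set, frozenset)):
                    if got not in want:
                        return False
                elif got != want:
                    return False
            return True

        idx = [j for j, s in enumerate(samples) if match(s)]
    else:
        ids = list(selector)
        by_id = {s.sample_id: j for j, s in enumerate(samples)}
        missing = [i for i in ids if i not in by_id]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        idx = [by_id[i] for i in ids]
    if not idx:
        raise ValueError(f"selector {selector!r} matched no samples")
    return idx


# -- readers / writers --------------------------------------------------------


def read_sample_sheet(path) -> list[SampleMeta]:
    """TSV with columns sample_id, construct, guide, timepoint_days, replicate."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["sample_id", "construct", "guide", "timepoint_days", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path}: missing columns {missing}")
    samples = [
        SampleMeta(
            sample_id=row.sample_id,
            construct=row.construct,
            guide=row.guide,
            timepoint_days=int(row.timepoint_days),
            replicate=int(row.replicate),
        )
        for row in df.itertuples()
    ]
    keys = [(s.construct, s.guide, s.timepoint_days, s.replicate) for s in samples]
    if len(set(keys)) != len(keys):
        raise ValueError(f"sample sheet {path}: duplicate (construct, guide, timepoint, replicate)")
    return samples


def write_sample_sheet(samples: Sequence[SampleMeta], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "construct": [s.construct for s in samples],
            "guide": [s.guide for s in samples],
            "timepoint_days": [s.timepoint_days for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def read_beta_matrix(path, sample_sheet) -> BetaMatrix:
    """Read a beta-value TSV (chrom, pos, one column per sample_id).

    ``pos`` is the 1-based cytosine position (array-manifest convention);
    it is converted to the internal 0-based convention.  Missing values are
    "NA" or empty cells.  Sample columns must all be declared in the sheet.
    """
    samples = read_sample_sheet(sample_sheet)
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""], comment="#")
    if "chrom" not in df.columns or "pos" not in df.columns:
        raise ValueError(f"{path}: beta matrix needs 'chrom' and 'pos' columns")
    sample_cols = [c for c in df.columns if c not in ("chrom", "pos")]
    known = {s.sample_id for s in samples}
    unknown = [c for c in sample_cols if c not in known]
    if unknown:
        raise ValueError(f"{path}: sample columns not in sample sheet: {unknown}")
    by_id = {s.sample_id: s for s in samples}
    metas = [by_id[c] for c in sample_cols]

    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(f"{path}: duplicate CpG site {row['chrom']}:{int(row['pos'])}")
    values = df[sample_cols].to_numpy(dtype=float)
    bad = np.argwhere((values < 0) | (values > 1))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{path}: beta value {values[i, j]} out of [0,1] at "
            f"{df['chrom'].iloc[i]}:{int(df['pos'].iloc[i])}, column {sample_cols[j]!r}"
        )
    sites = [
        CpGSite(chrom=str(c), pos=int(p) - 1)  # 1-based -> 0-based
        for c, p in zip(df["chrom"], df["pos"])
    ]
    return BetaMatrix(sites, metas, values)


def write_beta_matrix(beta: BetaMatrix, path) -> None:
    """Write back in the 1-based TSV dialect read_beta_matrix expects."""
    df = beta.to_frame()
    df["pos"] = df["pos"] + 1  # 0-based -> 1-based
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_bismark_coverage(path) -> list[CoverageRecord]:
    """Parse a Bismark coverage file.

    Columns: chrom, start (1-based), end, percent methylation, count
    methylated, count unmethylated.  β is recomputed from the counts; the
    percent column is ignored.
    """
    records: list[CoverageRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) != 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 columns, got {len(fields)}"
                )
            chrom, start, _end, _pct, n_meth, n_unmeth = fields
            n_m, n_u = int(n_meth), int(n_unmeth)
            if n_m < 0 or n_u < 0:
                raise ValueError(f"{path}:{lineno}: negative counts")
            records.append(
                CoverageRecord(
                    site=CpGSite(chrom=chrom, pos=int(start) - 1),  # 1-based -> 0-based
                    count_methylated=n_m,
                    count_unmethylated=n_u,
                )
            )
    return records


def write_bismark_coverage(records: Iterable[CoverageRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            pct = 0.0 if r.coverage == 0 else 100.0 * r.count_methylated / r.coverage
            fh.write(
                f"{r.site.chrom}\t{r.site.pos + 1}\t{r.site.pos + 1}\t"
                f"{pct:.6g}\t{r.count_methylated}\t{r.count_unmethylated}\n"
            )


_BED_SCORE_SCALE = 1000.0  # score column = round(|effect| * 1000), BED-style 0-1000


def write_regions_bed(regions: Sequence, path) -> None:
    """Write RegionAnnotations or DMRs as sorted BED (0-based half-open).

    Name column carries the region label (or DMR direction); score carries
    the scaled effect size for DMRs, 0 otherwise; column 7 carries the
    category (or DMR mean Δβ) so the matching reader can round-trip.
    """
    rows = []
    for r in regions:
        if hasattr(r, "category"):  # RegionAnnotation
            rows.append((r.chrom, r.start, r.end, r.label, 0, ".", r.category))
        else:  # DMR-like: chrom/start/end/direction/mean_delta
            score = int(round(min(abs(r.mean_delta), 1.0) * _BED_SCORE_SCALE))
            rows.append(
                (r.chrom, r.start, r.end, r.direction, score, ".", f"{r.mean_delta:.6g}")
            )
    rows.sort(key=lambda t: (t[0], t[1], t[2]))
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tinfo\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_regions_bed(path, default_category: str = "chromatin_state") -> list[RegionAnnotation]:
    """Read a BED written by write_regions_bed (or any >=4 column BED)."""
    regions: list[RegionAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            label = fields[3] if len(fields) > 3 else f"region_{lineno}"
            category = default_category
            if len(fields) > 6 and fields[6] in REGION_CATEGORIES:
                category = fields[6]
            regions.append(
                RegionAnnotation(
                    chrom=chrom, start=start, end=end, label=label, category=category
                )
            )
    return regions


def read_count_matrix(path, sample_sheet) -> CountMatrix:
    """TSV with a 'gene' column then one raw-count column per sample_id."""
    samples = read_sample_sheet(sample_sheet)
    df = pd.read_csv(path, sep="\t", comment="#")
    gene_col = df.columns[0]
    sample_cols = list(df.columns[1:])
    known = {s.sample_id for s in samples}
    unknown = [c for c in sample_cols if c not in known]
    if unknown:
        raise ValueError(f"{path}: sample columns not in sample sheet: {unknown}")
    by_id = {s.sample_id: s for s in samples}
    metas = [by_id[c] for c in sample_cols]
    return CountMatrix(
        genes=[str(g) for g in df[gene_col]],
        samples=metas,
        counts=df[sample_cols].to_numpy(),
    )


def write_count_matrix(counts: CountMatrix, path) -> None:
    df = counts.to_frame()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


# -- plain key=value config ---------------------------------------------------


def read_config(path) -> dict:
    """Read a plain key=value config; numbers are coerced where possible."""
    cfg: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("["):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            for caster in (int, float):
                try:
                    cfg[key] = caster(value)
                    break
                except ValueError:
                    continue
            else:
                cfg[key] = value
    return cfg


def write_config(cfg: dict, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for key, value in cfg.items():
            fh.write(f"{key} = {value}\n")
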