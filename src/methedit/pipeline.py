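"""End-to-end orchestration: simulate -> DMRs -> stability -> DEGs -> integrate.

Runs the whole analysis on a simulated dataset (or, stage by stage, on user
files via the CLI) and writes every intermediate as TSV/BED plus a
reproducibility manifest (config snapshot, input digests, seed, version,
per-stage row counts).
"""

from __future__ import annotations

import hashlib
import json
import os

import numpy as np
import pandas as pd

from . import __version__
from .core_io import DEFAULT_THRESHOLDS, write_regions_bed
from .dmr import call_dmrs, compute_delta, summarize_dmrs
from .expression import call_degs, degs_to_frame, filter_low_expressed, tmm_normalize
from .integration import (
    chromhmm_enrichment,
    intersect_dmr_deg,
    predicted_offtarget_overlap,
    sequence_preference,
)
from .simulate import SimConfig, simulate_dataset
from .stability import pairwise_sharedness, overlap_dmr_sets

__all__ = ["run_all", "sim_config_from_dict"]

_SIM_KEYS = {
    "n_regions", "on_target_delta", "off_target_rate", "delta_max",
    "footprint_protection", "noise_sd", "n_replicates", "coupling_fraction",
    "coupling_slope", "grna_independent_degs", "seed",
}


def sim_config_from_dict(cfg: dict) -> SimConfig:
    kwargs = {k: v for k, v in cfg.items() if k in _SIM_KEYS}
    if "n_regions" in kwargs:
        kwargs["n_regions"] = int(kwargs["n_regions"])
    for key in ("n_replicates", "grna_independent_degs", "seed"):
        if key in kwargs:
            kwargs[key] = int(kwargs[key])
    return SimConfig(**kwargs)


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_all(config: dict, outdir: str) -> dict:
    """Execute the full pipeline per the config; returns the manifest dict.

    Config keys: simulator parameters (seed, n_regions, noise_sd, ...) and
    threshold overrides (delta_beta, max_gap, min_cpgs, logfc, count_min,
    count_frac).  Any stage failure raises with the stage name.
    """
    thresholds = dict(DEFAULT_THRESHOLDS)
    for key in thresholds:
        if key in config:
            thresholds[key] = config[key]
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: v for k, v in config.items()},
        "thresholds": thresholds,
        "stages": {},
        "digests": {},
    }

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    # ---- simulate ----
    sim_cfg = sim_config_from_dict(config)
    data = stage("simulate")(lambda: simulate_dataset(sim_cfg))
    sim_dir = os.path.join(outdir, "simulated")
    data.write(sim_dir)
    manifest["stages"]["simulate"] = {
        "n_regions": sim_cfg.n_regions,
        "timepoints": list(sim_cfg.timepoints),
        "seed": sim_cfg.seed,
    }

    construct = sim_cfg.construct
    control = sim_cfg.control_construct
    contrasts = {
        "g_vs_control": (
            {"construct": construct, "guide": "targeting"},
            {"construct": control},
        ),
        "ntc_vs_control": (
            {"construct": construct, "guide": "NTC"},
            {"construct": control},
        ),
        "g_vs_ntc": (
            {"construct": construct, "guide": "targeting"},
            {"construct": construct, "guide": "NTC"},
        ),
    }

    # ---- DMRs per timepoint and contrast ----
    dmr_sets: dict[str, list] = {}
    delta_tracks: dict[str, object] = {}
    summary_rows = []
    for day, beta in data.betas.items():
        for cname, (treat, ctrl) in contrasts.items():
            key = f"d{day}_{cname}"
            track = stage(f"call-dmrs:{key}")(
                lambda b=beta, t=treat, c=ctrl: compute_delta(b, t, c)
            )
            dmrs = call_dmrs(
                track,
                min_cpgs=int(thresholds["min_cpgs"]),
                min_abs_delta=float(thresholds["delta_beta"]),
                max_gap=int(thresholds["max_gap"]),
            )
            delta_tracks[key] = track
            dmr_sets[key] = dmrs
            write_regions_bed(dmrs, os.path.join(outdir, f"dmrs_{key}.bed"))
            s = summarize_dmrs(dmrs)
            summary_rows.append(
                {
                    "contrast": key, "total": s.total,
                    "hyper": s.n_hyper, "pct_hyper": s.pct_hyper,
                    "hypo": s.n_hypo, "pct_hypo": s.pct_hypo,
                }
            )
    pd.DataFrame(summary_rows).to_csv(
        os.path.join(outdir, "dmr_summary.tsv"), sep="\t", index=False
    )
    manifest["stages"]["call-dmrs"] = {k: len(v) for k, v in dmr_sets.items()}

    # ---- stability across timepoints (construct-driven off-target DMRs) ----
    days = sorted(data.betas)
    named = {f"d{day}": dmr_sets[f"d{day}_ntc_vs_control"] for day in days}
    shared = stage("stability")(lambda: pairwise_sharedness(named))
    shared.to_csv(os.path.join(outdir, "sharedness.tsv"), sep="\t")
    persistence = {}
    d0 = days[0]
    for day in days[1:]:
        res = overlap_dmr_sets(named[f"d{d0}"], named[f"d{day}"])
        persistence[f"d{d0}_to_d{day}"] = {
            "n_early": res.n_early,
            "n_overlap": res.n_overlap,
            "pct": res.persistence_pct if res.n_early else None,
        }
    manifest["stages"]["stability"] = persistence

    # ---- expression ----
    deg_sets: dict[str, list] = {}
    for day, cm in data.counts.items():
        filtered = stage(f"degs:d{day}")(
            lambda c=cm: filter_low_expressed(
                c,
                min_count=int(thresholds["count_min"]),
                min_frac=float(thresholds["count_frac"]),
            )
        )
        norm = tmm_normalize(filtered)
        degs = call_degs(
            norm,
            treatment={"construct": construct, "guide": "targeting"},
            control={"construct": control},
            logfc_thresh=float(thresholds["logfc"]),
        )
        deg_sets[day] = degs
        degs_to_frame(degs).to_csv(
            os.path.join(outdir, f"degs_d{day}.tsv"), sep="\t", index=False
        )
    manifest["stages"]["degs"] = {
        f"d{day}": int(sum(r.is_deg for r in degs)) for day, degs in deg_sets.items()
    }

    # ---- integration at the first timepoint ----
    day = days[0]
    dmrs_day = dmr_sets[f"d{day}_ntc_vs_control"]
    states = data.regions["chromatin_state"]
    background = [
        (r.chrom, r.start, r.end) for r in states
    ]  # all simulated regions as the background universe
    enrich = stage("integrate:chromhmm")(
        lambda: chromhmm_enrichment(dmrs_day, states, background)
    )
    pd.DataFrame([e.__dict__ for e in enrich]).to_csv(
        os.path.join(outdir, "state_enrichment.tsv"), sep="\t", index=False
    )
    dmr_degs = stage("integrate:dmr-deg")(
        lambda: intersect_dmr_deg(
            dmr_sets[f"d{day}_g_vs_control"],
            deg_sets[day],
            data.regions["gene"],
        )
    )
    pd.DataFrame(
        [
            {
                "gene": x.gene, "rule": x.mapping_rule,
                "dmr": f"{x.dmr.chrom}:{x.dmr.start}-{x.dmr.end}",
                "mean_delta": x.dmr.mean_delta, "log2fc": x.deg.log2fc,
            }
            for x in dmr_degs
        ]
    ).to_csv(os.path.join(outdir, "dmr_degs.tsv"), sep="\t", index=False)

    locus_genes = {
        f"predicted_ot_{r.region_id}": r.gene
        for r in data.truth.itertuples()
        if r.predicted_offtarget and r.gene
    }
    ot = stage("integrate:offtarget")(
        lambda: predicted_offtarget_overlap(
            data.regions["offtarget_locus"],
            delta_tracks[f"d{day}_ntc_vs_control"],
            degs=deg_sets[day],
            locus_genes=locus_genes,
        )
    )
    seqpref = stage("integrate:seqpref")(
        lambda: sequence_preference(
            dmrs_day,
            data.sequences,
            background_cpgs=[
                (s.chrom, s.pos)
                for s in data.betas[day].sites
            ][:: max(1, len(data.betas[day].sites) // 2000)],
        )
    )
    manifest["stages"]["integrate"] = {
        "n_dmr_degs": len(dmr_degs),
        "offtarget_overlap": {
            k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in ot.items()
        },
        "seq_motif_odds_ratio": seqpref.odds_ratio,
        "seq_motif_p": seqpref.p,
        "top_enriched_state": max(enrich, key=lambda e: e.odds_ratio).state
        if enrich
        else None,
    }

    for fname in sorted(os.listdir(outdir)):
        path = os.path.join(outdir, fname)
        if os.path.isfile(path):
            manifest["digests"][fname] = _digest(path)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
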