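"""CpG-gene correlation, DMR-DEG intersection, state enrichment, ORA, sequences."""

import numpy as np
import pytest
from scipy import stats

from methedit.core_io import CpGSite, RegionAnnotation
from methedit.expression import DEGRecord, NormalizedCounts
from methedit.integration import (
    chromhmm_enrichment,
    cpg_gene_correlation,
    intersect_dmr_deg,
    map_dmrs_to_genes,
    ora,
    predicted_offtarget_overlap,
    sequence_preference,
    spearman_exact,
)
from methedit.dmr import DeltaTrack
from methedit.simulate import SimConfig, simulate_dataset

from conftest import make_beta, make_dmr, make_samples


def norm_counts(genes, cpm, samples):
    cpm = np.asarray(cpm, dtype=float)
    return NormalizedCounts(
        genes=list(genes),
        samples=samples,
        cpm=cpm,
        tmm_factors=np.ones(cpm.shape[1]),
        lib_sizes=np.full(cpm.shape[1], 1e6),
    )


def deg(gene, log2fc, is_deg=None):
    if is_deg is None:
        is_deg = abs(log2fc) > 1
    return DEGRecord(
        gene=gene, log2fc=log2fc, mean_cpm_treatment=0.0, mean_cpm_control=0.0,
        p=None, p_adj=None, is_deg=is_deg,
    )


class TestCpgGeneCorrelation:
    def samples(self, n=6):
        return make_samples([("CRISPRoff", "targeting", 3, r + 1) for r in range(n)])

    def test_perfect_monotone_spearman(self):
        samples = self.samples()
        beta = make_beta([100], [np.linspace(0.1, 0.6, 6)], samples)
        expr = norm_counts(["gA"], [np.exp(np.linspace(1, 3, 6))], samples)
        results, skipped = cpg_gene_correlation(
            beta, expr, [(CpGSite("chr1", 100), "gA")]
        )
        assert not skipped
        assert results[0].r == pytest.approx(1.0)

    def test_constant_beta_skipped(self):
        samples = self.samples()
        beta = make_beta([100], [[0.5] * 6], samples)
        expr = norm_counts(["gA"], [np.arange(1.0, 7.0)], samples)
        results, skipped = cpg_gene_correlation(
            beta, expr, [(CpGSite("chr1", 100), "gA")]
        )
        assert results == [] and "zero variance" in skipped[0][2]

    def test_too_few_complete_pairs_skipped(self):
        samples = self.samples(4)
        beta = make_beta([100], [[0.1, 0.2, np.nan, np.nan]], samples)
        expr = norm_counts(["gA"], [[1.0, 2.0, 3.0, 4.0]], samples)
        _, skipped = cpg_gene_correlation(beta, expr, [(CpGSite("chr1", 100), "gA")])
        assert "2 complete pairs" in skipped[0][2]

    def test_exact_permutation_p_antimonotone_n5(self):
        """n=5 anti-monotone: rho=-1, p = 2/5! (both perfect orderings)."""
        samples = self.samples(5)
        beta = make_beta([100], [np.linspace(0.5, 0.1, 5)], samples)
        expr = norm_counts(["gA"], [np.arange(1.0, 6.0)], samples)
        results, _ = cpg_gene_correlation(beta, expr, [(CpGSite("chr1", 100), "gA")])
        assert results[0].r == pytest.approx(-1.0)
        assert results[0].p == pytest.approx(2 / 120)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        x = rng.random(8)
        y = rng.random(8)
        r1, p1 = spearman_exact(x, y)
        r2, p2 = spearman_exact(np.exp(5 * x), y**3 + 1)
        assert r1 == pytest.approx(r2)
        assert p1 == pytest.approx(p2)

    def test_pearson_mode(self):
        samples = self.samples()
        x = np.linspace(0.1, 0.6, 6)
        beta = make_beta([100], [x], samples)
        expr = norm_counts(["gA"], [2 * x + 1], samples)
        results, _ = cpg_gene_correlation(
            beta, expr, [(CpGSite("chr1", 100), "gA")], method="pearson"
        )
        assert results[0].r == pytest.approx(1.0)


class TestDmrDegIntersection:
    GENES = [
        RegionAnnotation("chr1", 10_000, 15_000, "gA", "gene"),
        RegionAnnotation("chr1", 10_500, 18_000, "gB", "gene"),
    ]

    def test_promoter_hit(self):
        dmr = make_dmr(positions=(9_000, 9_100), mean_delta=0.2)
        hits = intersect_dmr_deg([dmr], [deg("gA", -1.5)], self.GENES[:1])
        assert len(hits) == 1
        assert hits[0].mapping_rule == "promoter"

    def test_non_deg_gene_excluded(self):
        dmr = make_dmr(positions=(9_000, 9_100), mean_delta=0.2)
        assert intersect_dmr_deg([dmr], [deg("gA", 0.5)], self.GENES[:1]) == []

    def test_dmr_spanning_two_promoters_maps_to_both(self):
        dmr = make_dmr(positions=(9_300, 10_200), mean_delta=0.2)
        hits = intersect_dmr_deg(
            [dmr], [deg("gA", -1.5), deg("gB", 2.0)], self.GENES
        )
        assert sorted(h.gene for h in hits if h.mapping_rule == "promoter") == ["gA", "gB"]

    def test_body_mapping(self):
        dmr = make_dmr(positions=(14_000, 14_200), mean_delta=0.2)
        hits = map_dmrs_to_genes([dmr], self.GENES[:1])
        assert [(g, rule) for _, g, rule in hits] == [("gA", "body")]

    def test_count_bounded_by_mapped_and_degs(self):
        rng = np.random.default_rng(1)
        dmrs = [
            make_dmr(positions=(int(p), int(p) + 100), mean_delta=0.2)
            for p in rng.integers(0, 50_000, 30)
        ]
        degs = [deg(f"g{i}", rng.uniform(-3, 3)) for i in range(10)]
        genes = [
            RegionAnnotation("chr1", i * 5_000, i * 5_000 + 2_000, f"g{i}", "gene")
            for i in range(10)
        ]
        hits = intersect_dmr_deg(dmrs, degs, genes)
        n_mapped = len(map_dmrs_to_genes(dmrs, genes))
        n_degs = sum(d.is_deg for d in degs)
        assert len(hits) <= min(n_mapped, 30 * n_degs)


class TestChromhmmEnrichment:
    STATES = [
        RegionAnnotation("chr1", 0, 1_000, "Active TSS"),
        RegionAnnotation("chr1", 1_000, 10_000, "Quiescent"),
    ]

    def test_midpoint_assignment(self):
        dmr = make_dmr(positions=(100, 200))  # midpoint 150
        res = chromhmm_enrichment([dmr], self.STATES, [("chr1", 5_000, 6_000)])
        by_state = {e.state: e for e in res}
        assert by_state["Active TSS"].n_in_query == 1

    def test_unannotated_gap(self):
        dmr = make_dmr(positions=(50_000, 50_100))
        res = chromhmm_enrichment([dmr], self.STATES, [("chr1", 500, 600)])
        assert {e.state for e in res} == {"Active TSS", "Unannotated"}

    def test_overlapping_states_rejected(self):
        bad = self.STATES + [RegionAnnotation("chr1", 500, 1_500, "X")]
        with pytest.raises(ValueError, match="overlap"):
            chromhmm_enrichment([make_dmr()], bad, [])

    def test_odds_ratio_and_exact_p(self):
        """OR from the cross-product; p equals the hypergeometric tail sum."""
        query = ["S"] * 10 + ["other"] * 90
        background = ["S"] * 100 + ["other"] * 9_900
        res = {e.state: e for e in chromhmm_enrichment(query, self.STATES, background)}
        e = res["S"]
        assert e.odds_ratio == pytest.approx((10 * 9_900) / (90 * 100))
        # oracle: sum of hypergeometric point probabilities <= P(observed)
        N, K, n, k = 10_100, 110, 100, 10
        pmf = stats.hypergeom.pmf(np.arange(0, min(K, n) + 1), N, K, n)
        p_oracle = pmf[pmf <= pmf[k] * (1 + 1e-7)].sum()
        assert e.p == pytest.approx(p_oracle, rel=1e-6)

    def test_counts_sum_to_totals(self):
        rng = np.random.default_rng(3)
        dmrs = [
            make_dmr(positions=(int(p), int(p) + 10))
            for p in rng.integers(0, 60_000, 50)
        ]
        res = chromhmm_enrichment(dmrs, self.STATES, [("chr1", 100, 200)])
        assert sum(e.n_in_query for e in res) == 50


class TestPredictedOfftargetOverlap:
    def track(self, positions, deltas):
        sites = [CpGSite("chr1", p) for p in positions]
        return DeltaTrack(sites, np.asarray(deltas, float), np.ones((len(sites), 2)))

    def predicted(self, n):
        return [
            RegionAnnotation("chr1", i * 1_000, i * 1_000 + 500, f"ot{i}", "offtarget_locus")
            for i in range(n)
        ]

    def test_fraction_of_qualifying_loci(self):
        preds = self.predicted(10)
        # loci 0 and 1 contain a CpG above threshold
        trk = self.track([100, 1_100, 2_100], [0.2, -0.08, 0.01])
        rep = predicted_offtarget_overlap(preds, trk)
        assert rep["n_methylation"] == 2
        assert rep["pct_methylation"] == pytest.approx(20.0)

    def test_empty_predicted_flagged(self):
        trk = self.track([100], [0.2])
        rep = predicted_offtarget_overlap([], trk)
        assert rep["empty"] and rep["n_predicted"] == 0

    def test_threshold_monotonicity(self):
        preds = self.predicted(20)
        rng = np.random.default_rng(4)
        trk = self.track(
            sorted(rng.choice(20_000, 200, replace=False).tolist()),
            rng.uniform(-0.3, 0.3, 200),
        )
        fracs = [
            predicted_offtarget_overlap(preds, trk, beta_thresh=t)["pct_methylation"]
            for t in (0.02, 0.05, 0.1, 0.2)
        ]
        assert fracs == sorted(fracs, reverse=True)

    def test_expression_fraction(self):
        preds = self.predicted(4)
        trk = self.track([100], [0.0])
        degs = [deg("gA", 1.2), deg("gB", 0.01)]
        rep = predicted_offtarget_overlap(
            preds, trk, degs=degs,
            locus_genes={"ot0": "gA", "ot1": "gB"},
        )
        assert rep["n_expression"] == 1
        assert rep["pct_expression"] == pytest.approx(25.0)


class TestOra:
    def test_query_equals_set_is_minimal(self):
        universe = [f"g{i}" for i in range(200)]
        sets = {"hit": universe[:20], "other": universe[100:120]}
        df = ora(sets, universe[:20], universe).set_index("set")
        assert df.loc["hit", "p"] < 1e-10
        assert df.loc["hit", "p"] < df.loc["other", "p"]

    def test_disjoint_set_skipped(self):
        universe = [f"g{i}" for i in range(50)]
        df = ora({"alien": ["x1", "x2"]}, universe[:5], universe)
        assert df["skipped"].iloc[0] == "set disjoint from universe"

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            ora({"s": ["a"]}, [], [])

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ora({"s": ["g1"]}, ["zz"], ["g1", "g2"])

    def test_p_matches_hypergeom_oracle(self):
        universe = [f"g{i}" for i in range(1_000)]
        gene_set = universe[:100]
        query = universe[50:250]  # overlap 50
        df = ora({"s": gene_set}, query, universe)
        expected = stats.hypergeom.sf(49, 1_000, 100, 200)
        assert df["p"].iloc[0] == pytest.approx(expected, rel=1e-12)


class TestSequencePreference:
    def test_constructed_windows(self):
        # CpGs at offsets 5 within an 11-mer region sequence "AAGCGCAAAAA"
        seqs = {("chr1", 0, 11): "AAGCGCAAAAA", ("chr1", 1_000, 1_011): "AAGCGCAAAAA"}
        dmrs = [
            make_dmr(positions=(5, 6)),
        ]
        dmrs[0] = make_dmr(positions=(5,))
        bg = [("chr1", 1_005)]
        pref = sequence_preference(dmrs, seqs, bg, window_k=5, motif="GCGC")
        assert pref.n_windows == 1
        # centre column (offset 0) is the base at position 5: 'C'
        assert pref.pfm.loc["C", 0] == 1
        assert pref.pfm.sum(axis=0).eq(1).all()
        assert pref.motif_query == 1 and pref.motif_background == 1

    def test_truncated_window_skipped(self):
        seqs = {("chr1", 0, 11): "AAGCGCAAAAA"}
        dmrs = [make_dmr(positions=(1,))]  # window would start at -4
        pref = sequence_preference(dmrs, seqs, [], window_k=5)
        assert pref.n_windows == 0 and pref.n_skipped == 1

    def test_null_no_enrichment(self):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), size=20_000))
        seqs = {("chr1", 0, 20_000): seq}
        pos = rng.choice(np.arange(10, 19_990), size=600, replace=False)
        q_pos, b_pos = pos[:300], pos[300:]
        dmrs = [make_dmr(positions=(int(p),)) for p in q_pos]
        pref = sequence_preference(
            dmrs, seqs, [("chr1", int(p)) for p in b_pos], motif="GCGC"
        )
        assert pref.p > 0.01  # same generator: no detectable preference

    def test_planted_enrichment_detected(self):
        """GC-rich deposition targets yield motif enrichment vs background."""
        data = simulate_dataset(SimConfig(n_regions=400, seed=7))
        from methedit.dmr import call_dmrs, compute_delta

        trk = compute_delta(
            data.betas[3],
            {"construct": "CRISPRoff", "guide": "NTC"},
            {"construct": "d3A"},
        )
        dmrs = call_dmrs(trk)
        bg = [(s.chrom, s.pos) for s in data.betas[3].sites]
        pref = sequence_preference(dmrs, data.sequences, bg)
        assert pref.odds_ratio > 1.0
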