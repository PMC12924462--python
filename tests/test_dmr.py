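"""Δβ computation, the effect-size DMR rule, and hyper/hypo summarisation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from methedit.core_io import CpGSite
from methedit.dmr import (
    DMR,
    DeltaTrack,
    call_dmrs,
    compute_delta,
    round_half_up,
    summarize_dmrs,
)

from conftest import make_beta, make_dmr, make_samples


def track(positions, deltas, chroms=None):
    if chroms is None:
        chroms = ["chr1"] * len(positions)
    sites = [CpGSite(chrom=c, pos=p) for c, p in zip(chroms, positions)]
    return DeltaTrack(
        sites=sites,
        delta=np.asarray(deltas, dtype=float),
        n_used=np.ones((len(positions), 2), dtype=int),
    )


# -- independent oracle: brute-force enumeration of maximal qualifying runs --


def brute_force_dmrs(trk, min_cpgs=2, min_abs_delta=0.1, max_gap=2000):
    """Enumerate every candidate run and keep the valid, maximal ones.

    Written independently of the caller: candidate runs are all windows of
    the per-direction qualifying-CpG list; validity and maximality are
    checked through an explicit link predicate (same chromosome, gap
    strictly below max_gap, no missing-Δβ site strictly between).
    """
    out = []
    n = len(trk.sites)
    for sign, direction in ((1, "hyper"), (-1, "hypo")):
        qual = [
            i
            for i in range(n)
            if not np.isnan(trk.delta[i]) and sign * trk.delta[i] > min_abs_delta
        ]

        def linked(i, j):  # i, j are site indices of consecutive qualifying CpGs
            if trk.sites[i].chrom != trk.sites[j].chrom:
                return False
            if trk.sites[j].pos - trk.sites[i].pos >= max_gap:
                return False
            return not any(
                np.isnan(trk.delta[k]) for k in range(i + 1, j)
            )

        for a in range(len(qual)):
            for b in range(a, len(qual)):
                members = qual[a : b + 1]
                if len(members) < min_cpgs:
                    continue
                if not all(
                    linked(members[k], members[k + 1])
                    for k in range(len(members) - 1)
                ):
                    continue
                if a > 0 and linked(qual[a - 1], qual[a]):
                    continue  # extendable left
                if b < len(qual) - 1 and linked(qual[b], qual[b + 1]):
                    continue  # extendable right
                out.append(
                    DMR(
                        chrom=trk.sites[members[0]].chrom,
                        start=trk.sites[members[0]].pos,
                        end=trk.sites[members[-1]].pos + 1,
                        cpg_positions=tuple(trk.sites[k].pos for k in members),
                        direction=direction,
                        mean_delta=float(
                            np.mean([trk.delta[k] for k in members])
                        ),
                    )
                )
    out.sort(key=lambda r: (r.chrom, r.start, r.direction))
    return out


def random_track(rng, max_cpgs=300):
    n = int(rng.integers(2, max_cpgs + 1))
    gaps = rng.integers(50, 5001, size=n)
    pos = np.cumsum(gaps)
    deltas = rng.uniform(-0.3, 0.3, size=n)
    miss = rng.random(n) < 0.05
    deltas[miss] = np.nan
    chroms = np.where(rng.random(n).cumsum() < 0, "chr1", "chr1")  # single chrom
    return track(pos.tolist(), deltas)


class TestComputeDelta:
    def test_mean_difference(self, two_group_samples):
        bm = make_beta([10], [[0.6, 0.7, 0.1, 0.1]], two_group_samples)
        trk = compute_delta(bm, {"construct": "CRISPRoff"}, {"construct": "d3A"})
        assert trk.delta[0] == pytest.approx(0.55)
        assert tuple(trk.n_used[0]) == (2, 2)

    def test_identical_groups_zero(self, two_group_samples):
        bm = make_beta([10, 20], [[0.3, 0.3, 0.3, 0.3], [0.8, 0.8, 0.8, 0.8]], two_group_samples)
        trk = compute_delta(bm, {"construct": "CRISPRoff"}, {"construct": "d3A"})
        np.testing.assert_allclose(trk.delta, 0.0)

    def test_fully_missing_control_propagates(self, two_group_samples):
        bm = make_beta([10], [[0.6, 0.7, np.nan, np.nan]], two_group_samples)
        trk = compute_delta(bm, {"construct": "CRISPRoff"}, {"construct": "d3A"})
        assert np.isnan(trk.delta[0])

    def test_partial_missing_uses_available(self, two_group_samples):
        bm = make_beta([10], [[0.6, np.nan, 0.1, 0.3]], two_group_samples)
        trk = compute_delta(bm, {"construct": "CRISPRoff"}, {"construct": "d3A"})
        assert trk.delta[0] == pytest.approx(0.6 - 0.2)
        assert tuple(trk.n_used[0]) == (1, 2)

    def test_overlapping_selectors_rejected(self, two_group_samples):
        bm = make_beta([10], [[0.6, 0.7, 0.1, 0.1]], two_group_samples)
        with pytest.raises(ValueError, match="overlap"):
            compute_delta(bm, {"construct": "CRISPRoff"}, {"guide": "targeting"})

    def test_empty_selector_rejected(self, two_group_samples):
        bm = make_beta([10], [[0.6, 0.7, 0.1, 0.1]], two_group_samples)
        with pytest.raises(ValueError):
            compute_delta(bm, {"construct": "none"}, {"construct": "d3A"})


class TestCallDmrs:
    def test_worked_example(self):
        trk = track([100, 500, 3000, 3400, 3800], [0.15, 0.20, -0.15, -0.12, 0.05])
        dmrs = call_dmrs(trk)
        assert len(dmrs) == 2
        hyper, hypo = dmrs[0], dmrs[1]
        assert hyper.direction == "hyper"
        assert hyper.cpg_positions == (100, 500)
        assert hyper.mean_delta == pytest.approx(0.175)
        assert hypo.direction == "hypo"
        assert hypo.cpg_positions == (3000, 3400)
        assert hypo.mean_delta == pytest.approx(-0.135)

    def test_all_zero_no_dmrs(self):
        trk = track([100, 200, 300], [0.0, 0.0, 0.0])
        assert call_dmrs(trk) == []

    def test_gap_exactly_max_is_excluded(self):
        # strict "less than 2 kb": a 2000 bp gap does not join the CpGs
        trk = track([1000, 3000], [0.2, 0.2])
        assert call_dmrs(trk) == []
        trk2 = track([1000, 2999], [0.2, 0.2])
        assert len(call_dmrs(trk2)) == 1

    def test_delta_exactly_threshold_is_excluded(self):
        trk = track([100, 200], [0.1, 0.1])
        assert call_dmrs(trk) == []

    def test_missing_breaks_run(self):
        trk = track([100, 200, 300], [0.2, np.nan, 0.2])
        assert call_dmrs(trk) == []

    def test_subthreshold_cpg_is_transparent(self):
        # gap measured between successive *qualifying* CpGs
        trk = track([100, 200, 300], [0.2, 0.05, 0.2])
        dmrs = call_dmrs(trk)
        assert len(dmrs) == 1
        assert dmrs[0].cpg_positions == (100, 300)

    def test_chromosome_boundary_breaks_run(self):
        trk = track([100, 200], [0.2, 0.2], chroms=["chr1", "chr2"])
        assert call_dmrs(trk) == []

    def test_unsorted_rejected(self):
        sites = [CpGSite("chr1", 200), CpGSite("chr1", 100)]
        trk = DeltaTrack(sites, np.array([0.2, 0.2]), np.ones((2, 2)))
        with pytest.raises(ValueError, match="sorted"):
            call_dmrs(trk)

    def test_oracle_equivalence_random_tracks(self):
        rng = np.random.default_rng(2024)
        for _ in range(150):
            trk = random_track(rng, max_cpgs=120)
            assert call_dmrs(trk) == brute_force_dmrs(trk)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        deltas=st.lists(
            st.one_of(st.none(), st.floats(-0.5, 0.5, allow_nan=False)),
            min_size=2,
            max_size=40,
        ),
        gaps=st.lists(st.integers(1, 4000), min_size=1, max_size=39),
    )
    def test_oracle_equivalence_property(self, deltas, gaps):
        n = min(len(deltas), len(gaps) + 1)
        pos = np.cumsum([100] + list(gaps[: n - 1])).tolist()
        d = [np.nan if x is None else x for x in deltas[:n]]
        trk = track(pos, d)
        assert call_dmrs(trk) == brute_force_dmrs(trk)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        trk = random_track(rng)
        counts = [
            len(call_dmrs(trk, min_abs_delta=t)) for t in (0.05, 0.1, 0.15, 0.2)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_direction_symmetry(self):
        rng = np.random.default_rng(6)
        trk = random_track(rng)
        flipped = DeltaTrack(trk.sites, -trk.delta, trk.n_used)
        a = summarize_dmrs(call_dmrs(trk))
        b = summarize_dmrs(call_dmrs(flipped))
        assert (a.n_hyper, a.n_hypo) == (b.n_hypo, b.n_hyper)

    def test_same_direction_dmrs_disjoint(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            trk = random_track(rng, max_cpgs=150)
            for direction in ("hyper", "hypo"):
                ds = [d for d in call_dmrs(trk) if d.direction == direction]
                seen = set()
                for d in ds:
                    assert not (seen & set(d.cpg_positions))
                    seen.update(d.cpg_positions)


class TestSummarize:
    @pytest.mark.parametrize(
        "n_hyper,n_hypo,pct_hyper,pct_hypo",
        [
            (21282, 195, 99, 1),     # 99.09 / 0.91
            (16, 493, 3, 97),        # 3.14 / 96.86
            (259, 43, 86, 14),       # 85.76 / 14.24
            (963, 153, 86, 14),      # 86.29 / 13.71
            (1, 0, 100, 0),
        ],
    )
    def test_direction_percentages(self, n_hyper, n_hypo, pct_hyper, pct_hypo):
        dmrs = [make_dmr(positions=(i * 10, i * 10 + 2)) for i in range(n_hyper)]
        dmrs += [
            make_dmr(positions=(i * 10 + 5, i * 10 + 7), direction="hypo", mean_delta=-0.2)
            for i in range(n_hypo)
        ]
        s = summarize_dmrs(dmrs)
        assert (s.total, s.n_hyper, s.n_hypo) == (n_hyper + n_hypo, n_hyper, n_hypo)
        assert (s.pct_hyper, s.pct_hypo) == (pct_hyper, pct_hypo)

    def test_empty(self):
        s = summarize_dmrs([])
        assert s.total == 0 and s.pct_hyper == 0

    def test_round_half_up(self):
        assert round_half_up(0.5) == 1
        assert round_half_up(1.5) == 2
        assert round_half_up(2.4999) == 2
        assert round_half_up(99.09) == 99
        assert round_half_up(96.86) == 97
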