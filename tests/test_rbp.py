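"""Binding-region geometry, motif scanning, background sampling, enrichment."""

import math
from fractions import Fraction

import numpy as np
import pytest

from dosetrx import rbp
from dosetrx.types import Motif, SpliceEvent


def _se_event(exon=(1000, 1100), strand="+", chrom="chr1", eid="e1"):
    return SpliceEvent(event_id=eid, event_type="SE", gene_id="g", chrom=chrom,
                       strand=strand, exon=exon, upstream=(400, 550),
                       downstream=(1500, 1650))


@pytest.fixture()
def genome():
    rng = np.random.default_rng(0)
    return {"chr1": "".join(rng.choice(list("ACGT"), size=10000))}


class TestBindingRegions:
    def test_se_interval_arithmetic(self, genome):
        """250 bp flanks with 10 bp trims around exon [1000,1100)."""
        (r,) = rbp.build_binding_regions(_se_event(), genome, 250, 10)
        assert r.intervals == [(750, 990), (1000, 1100), (1110, 1350)]
        assert len(r.sequence) == 240 + 100 + 240 == 580

    def test_degenerate_no_flanks(self, genome):
        (r,) = rbp.build_binding_regions(_se_event(), genome, 0, 0)
        assert r.intervals == [(1000, 1100)]
        assert r.sequence == genome["chr1"][1000:1100]

    def test_minus_strand_reverse_complement(self, genome):
        (plus,) = rbp.build_binding_regions(_se_event(strand="+"), genome)
        (minus,) = rbp.build_binding_regions(_se_event(strand="-"), genome)
        assert minus.intervals == plus.intervals
        assert minus.sequence == rbp.reverse_complement(plus.sequence)
        assert minus.pieces == [rbp.reverse_complement(p)
                                for p in reversed(plus.pieces)]

    def test_trim_zone_never_included(self, genome):
        (r,) = rbp.build_binding_regions(_se_event(), genome, 250, 10)
        s, e = 1000, 1100
        excluded = set(range(s - 10, s)) | set(range(e, e + 10))
        covered = {p for a, b in r.intervals for p in range(a, b)}
        assert not (covered & excluded)

    def test_flank_clipped_at_chromosome_start(self, genome):
        (r,) = rbp.build_binding_regions(_se_event(exon=(100, 200)), genome)
        assert r.intervals[0] == (0, 90)

    def test_body_outside_chromosome_error(self, genome):
        with pytest.raises(ValueError, match="outside"):
            rbp.build_binding_regions(_se_event(exon=(9990, 10200)), genome)

    def test_mxe_two_regions(self, genome):
        ev = SpliceEvent(event_id="m1", event_type="MXE", gene_id="g",
                         chrom="chr1", strand="+", exon=(1000, 1100),
                         exon2=(2000, 2100), upstream=(400, 550),
                         downstream=(3000, 3150))
        regions = rbp.build_binding_regions(ev, genome)
        assert len(regions) == 2
        assert regions[0].event_id == "m1:1" and regions[1].event_id == "m1:2"

    def test_zero_trim_merges_flank_into_body(self, genome):
        (r,) = rbp.build_binding_regions(_se_event(), genome, 250, 0)
        assert r.intervals == [(750, 1350)]  # one contiguous run


class TestScan:
    def _region(self, seq):
        return rbp.BindingRegion("e", "chr1", "+", [(0, len(seq))], [seq])

    def test_exact_consensus_hit(self):
        hits = rbp.scan_motif(self._region("AAGGAGGAAA"),
                              Motif("x", "m", consensus="GGAGGA"))
        assert hits == [2]

    def test_fully_degenerate_hits_everywhere(self):
        hits = rbp.scan_motif(self._region("ACGTACGTAC"),
                              Motif("x", "m", consensus="NNNN"))
        assert hits == list(range(7))  # length - 3 positions

    def test_overlapping_hits_reported(self):
        hits = rbp.scan_motif(self._region("AAAA"), Motif("x", "m", consensus="AA"))
        assert hits == [0, 1, 2]

    def test_motif_wider_than_sequence(self):
        assert rbp.scan_motif(self._region("ACG"),
                              Motif("x", "m", consensus="ACGTACGT")) == []

    def test_match_never_spans_piece_gap(self):
        region = rbp.BindingRegion("e", "chr1", "+", [(0, 3), (10, 13)],
                                   ["GGA", "GGA"])
        assert rbp.scan_motif(region, Motif("x", "m", consensus="GGAGGA")) == []
        assert region.sequence == "GGAGGA"  # concatenation alone would match

    def test_pfm_threshold_one_only_best_word(self):
        pfm = np.array([[8, 1, 1],   # A
                        [1, 8, 1],   # C
                        [0, 0, 0],   # G
                        [1, 1, 8]])  # T: best word ACT
        m = Motif("x", "m", pfm=pfm, score_threshold=1.0)
        assert rbp.scan_motif(self._region("GGACTGG"), m) == [2]
        assert rbp.scan_motif(self._region("GGACCGG"), m) == []

    def test_pfm_lower_threshold_admits_near_words(self):
        pfm = np.array([[8, 1, 1], [1, 8, 1], [0, 0, 0], [1, 1, 8]])
        m = Motif("x", "m", pfm=pfm, score_threshold=0.35)
        assert 2 in rbp.scan_motif(self._region("GGACTGG"), m)
        assert rbp.scan_motif(self._region("GGACCGG"), m)  # 2/3 columns strong


class TestBackground:
    def _events(self, n):
        return [_se_event(exon=(1000 + 2000 * i, 1100 + 2000 * i), eid=f"e{i}")
                for i in range(n)]

    def test_deterministic_given_rng_seed(self, genome):
        big = {"chr1": genome["chr1"] * 30}
        evs = self._events(100)
        a = rbp.sample_background(evs, 5, big, np.random.default_rng(1))
        b = rbp.sample_background(evs, 5, big, np.random.default_rng(1))
        assert [r.event_id for r in a] == [r.event_id for r in b]

    def test_over_request_rejected(self, genome):
        with pytest.raises(ValueError, match="multiplier"):
            rbp.sample_background(self._events(50), 100, genome,
                                  np.random.default_rng(0))

    def test_different_seeds_differ(self, genome):
        big = {"chr1": genome["chr1"] * 30}
        evs = self._events(100)
        a = rbp.sample_background(evs, 5, big, np.random.default_rng(1))
        b = rbp.sample_background(evs, 5, big, np.random.default_rng(2))
        assert [r.event_id for r in a] != [r.event_id for r in b]


class TestEnrichment:
    def _regions(self, seqs):
        return [rbp.BindingRegion(f"e{i}", "chr1", "+", [(0, len(s))], [s])
                for i, s in enumerate(seqs)]

    def test_extreme_table_closed_form(self):
        """a=10,b=0,c=0,d=10 gives p = 1/C(20,10)."""
        motif = Motif("R", "m", consensus="GGAGGA")
        diff = self._regions(["AAGGAGGAAA"] * 10)
        bg = self._regions(["ACACACACAC"] * 10)
        res = rbp.enrich(diff, bg, [motif])
        assert res.p_one_sided.iloc[0] == pytest.approx(1 / math.comb(20, 10),
                                                        rel=1e-9)
        assert (res.a.iloc[0], res.d.iloc[0]) == (10, 10)
        assert res.significant.iloc[0]

    def test_balanced_table_not_significant(self):
        motif = Motif("R", "m", consensus="GGAGGA")
        diff = self._regions(["AAGGAGGAAA"] * 5 + ["ACACACACAC"] * 5)
        bg = self._regions(["AAGGAGGAAA"] * 5 + ["ACACACACAC"] * 5)
        res = rbp.enrich(diff, bg, [motif])
        assert res.p_one_sided.iloc[0] > 0.5
        assert not res.significant.iloc[0]

    def test_min_p_motif_selected_per_rbp(self):
        strong = Motif("R", "m_strong", consensus="GGAGGA")
        weak = Motif("R", "m_weak", consensus="TTTTTT")
        diff = self._regions(["AAGGAGGAAA"] * 8 + ["CCCCCCCCCC"] * 2)
        bg = self._regions(["CCCCCCCCCC"] * 10)
        res = rbp.enrich(diff, bg, [weak, strong]).set_index("motif_id")
        assert bool(res.loc["m_strong", "selected"])
        assert not bool(res.loc["m_weak", "selected"])
        assert bool(res.loc["m_strong", "significant"])

    def test_duplicate_motif_rejected(self):
        m = Motif("R", "m", consensus="ACGT")
        regions = self._regions(["ACGTACGT"])
        with pytest.raises(ValueError, match="duplicate"):
            rbp.enrich(regions, regions, [m, m])

    def test_empty_region_set_rejected(self):
        m = Motif("R", "m", consensus="ACGT")
        with pytest.raises(ValueError, match="non-empty"):
            rbp.enrich([], self._regions(["ACGT"]), [m])


class TestFisherOneSided:
    def test_matches_rational_enumeration_sample(self):
        """Spot-check the hypergeometric tail against exact rationals."""
        for (a, b, c, d) in [(10, 0, 0, 10), (5, 5, 5, 5), (3, 7, 1, 9),
                             (0, 10, 10, 0), (12, 3, 4, 11), (1, 1, 1, 1)]:
            N, r1, c1 = a + b + c + d, a + b, a + c
            exact = sum(
                Fraction(math.comb(c1, x) * math.comb(N - c1, r1 - x),
                         math.comb(N, r1))
                for x in range(a, min(r1, c1) + 1))
            assert rbp.fisher_one_sided(a, b, c, d) == \
                pytest.approx(float(exact), abs=1e-12)

    def test_matches_scipy_fisher(self):
        from scipy.stats import fisher_exact
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 30, 4)
            assert rbp.fisher_one_sided(a, b, c, d) == pytest.approx(
                fisher_exact([[a, b], [c, d]], alternative="greater")[1],
                rel=1e-9, abs=1e-12)
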