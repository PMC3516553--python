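import numpy as np
import pytest

from autozygome import (HET, HOM_ALT, HOM_REF, MISSING, RELAXED, STRINGENT,
                        ROHSegment, RohParams, SharedRegion, detect_roh,
                        exclude_unaffected, segment_size,
                        shared_autozygous_regions, summarize_regions)
from autozygome.datasets import (index_family_shared_regions,
                                 index_family_unaffected_roh)

from util import make_matrix, oracle_detect_roh, oracle_shared_regions


def test_presets_match_the_published_definitions():
    assert (RELAXED.min_snp, RELAXED.min_span_bp) == (50, 500_000)
    assert (STRINGENT.min_snp, STRINGENT.min_span_bp) == (500, 5_000_000)
    assert STRINGENT.max_het == STRINGENT.max_missing == 0


class TestDetectRoh:
    def test_all_het_sample_yields_nothing(self):
        gm = make_matrix(range(1000, 61_000, 100), {"s": [HET] * 600})
        assert detect_roh(gm, "s", RohParams(5, 100)) == []

    def test_span_must_strictly_exceed_threshold(self):
        # 50 homozygous markers spanning exactly 500 kb fail; one extra bp passes
        pos = list(np.linspace(10_000, 505_000, 49).astype(int)) + [510_000]
        calls = [HOM_REF] * 50
        params = RohParams(min_snp=50, min_span_bp=500_000)
        gm_exact = make_matrix(pos[:-1] + [pos[0] + 500_000], {"s": calls})
        assert detect_roh(gm_exact, "s", params) == []
        gm_over = make_matrix(pos[:-1] + [pos[0] + 500_001], {"s": calls})
        segs = detect_roh(gm_over, "s", params)
        assert len(segs) == 1
        assert segs[0].size == 500_001 and segs[0].n_snp == 50

    def test_unknown_sample_raises_and_empty_matrix_is_empty(self):
        gm = make_matrix([100], {"s": [HOM_REF]})
        with pytest.raises(KeyError):
            detect_roh(gm, "nope", RELAXED)
        empty = make_matrix([], {"s": []})
        assert detect_roh(empty, "s", RELAXED) == []

    def test_emitted_segments_respect_thresholds_and_boundaries(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(200_000, size=500, replace=False)) + 1
        calls = rng.choice([HOM_REF, HOM_ALT, HET, MISSING], size=500,
                           p=[0.55, 0.3, 0.1, 0.05])
        gm = make_matrix(pos, {"s": calls})
        params = RohParams(min_snp=8, min_span_bp=3_000, max_het=1, max_missing=1)
        segs = detect_roh(gm, "s", params)
        assert segs, "expected at least one run in this fixture"
        for seg in segs:
            assert seg.n_snp >= params.min_snp
            assert seg.size > params.min_span_bp
            assert seg.n_het <= params.max_het
            assert seg.n_missing <= params.max_missing
            for bp in (seg.start_bp, seg.end_bp):  # boundaries are homozygous
                assert calls[np.flatnonzero(pos == bp)[0]] in (HOM_REF, HOM_ALT)

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_exhaustive_enumeration_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = 200
        pos = np.sort(rng.choice(50_000, size=n, replace=False)) + 1
        p_hom = rng.uniform(0.5, 0.95)
        rest = 1 - p_hom
        calls = rng.choice([HOM_REF, HOM_ALT, HET, MISSING], size=n,
                           p=[p_hom * 0.6, p_hom * 0.4, rest * 0.7, rest * 0.3])
        params = RohParams(
            min_snp=int(rng.integers(3, 15)),
            min_span_bp=int(rng.integers(0, 8_000)),
            max_het=int(rng.integers(0, 3)),
            max_missing=int(rng.integers(0, 3)),
        )
        gm = make_matrix(pos, {"s": calls})
        got = [(int(np.flatnonzero(pos == s.start_bp)[0]),
                int(np.flatnonzero(pos == s.end_bp)[0]),
                s.n_snp, s.n_het, s.n_missing)
               for s in detect_roh(gm, "s", params)]
        assert got == oracle_detect_roh(pos, calls, params)

    def test_invariant_to_markers_on_other_chromosomes(self):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(30_000, size=120, replace=False)) + 1
        calls = rng.choice([HOM_REF, HET], size=120, p=[0.9, 0.1])
        params = RohParams(5, 1_000, max_het=1)
        gm1 = make_matrix(pos, {"s": calls})
        chroms = ["chr1"] * 120 + ["chr9"] * 40
        pos2 = np.concatenate([pos, np.arange(1, 41) * 100])
        calls2 = np.concatenate([calls, [HET] * 40])
        gm2 = make_matrix(pos2, {"s": calls2}, chrom=chroms)
        one = [(s.chrom, s.start_bp, s.end_bp) for s in detect_roh(gm1, "s", params)]
        two = [(s.chrom, s.start_bp, s.end_bp) for s in detect_roh(gm2, "s", params)
               if s.chrom == "chr1"]
        assert one == two


class TestSegmentSize:
    @pytest.mark.parametrize("start,end,size", [
        (11_008_695, 11_512_411, 503_716),
        (21_155_324, 21_264_965, 109_641),
        (5, 5, 0),
    ])
    def test_end_minus_start_convention(self, start, end, size):
        assert segment_size((start, end)) == size

    def test_accepts_segment_objects(self):
        seg = ROHSegment("s", "chr1", 100, 350, n_snp=10)
        assert segment_size(seg) == 250


class TestSharedRegions:
    def test_single_affected_returns_own_segments(self):
        pos = np.arange(1, 101) * 1000
        calls = np.full(100, HOM_REF)
        gm = make_matrix(pos, {"a": calls})
        segs = detect_roh(gm, "a", RohParams(5, 10_000))
        shared = shared_autozygous_regions({"a": segs}, gm)
        assert [(r.start_bp, r.end_bp) for r in shared] == \
            [(s.start_bp, s.end_bp) for s in segs]

    def test_disjoint_roh_share_nothing(self):
        pos = np.arange(1, 201) * 1000
        a = np.where(np.arange(200) < 90, HOM_REF, HET)
        b = np.where(np.arange(200) >= 110, HOM_REF, HET)
        gm = make_matrix(pos, {"a": a, "b": b})
        params = RohParams(5, 10_000)
        shared = shared_autozygous_regions(
            {"a": detect_roh(gm, "a", params), "b": detect_roh(gm, "b", params)}, gm)
        assert shared == []

    def test_allele_mismatch_drops_interval(self):
        pos = np.arange(1, 51) * 1000
        a = np.full(50, HOM_REF)
        b = np.full(50, HOM_ALT)  # homozygous for the other allele throughout
        gm = make_matrix(pos, {"a": a, "b": b})
        params = RohParams(5, 10_000)
        roh = {s: detect_roh(gm, s, params) for s in "ab"}
        kept, dropped = shared_autozygous_regions(roh, gm, return_diagnostics=True)
        assert kept == []
        assert dropped and not dropped[0].allele_matched

    def test_missing_and_het_calls_do_not_break_matching(self):
        pos = np.arange(1, 51) * 1000
        a = np.full(50, HOM_REF)
        a[10] = HET
        b = np.full(50, HOM_REF)
        b[20] = MISSING
        gm = make_matrix(pos, {"a": a, "b": b})
        params = RohParams(5, 10_000, max_het=1, max_missing=1)
        roh = {s: detect_roh(gm, s, params) for s in "ab"}
        shared = shared_autozygous_regions(roh, gm)
        assert len(shared) == 1 and shared[0].allele_matched

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_marker_level_oracle(self, trial):
        rng = np.random.default_rng(7000 + trial)
        n = 200
        pos = np.sort(rng.choice(60_000, size=n, replace=False)) + 1
        samples = {}
        for s in ("x", "y", "z"):
            p_hom = rng.uniform(0.6, 0.95)
            samples[s] = rng.choice(
                [HOM_REF, HOM_ALT, HET, MISSING], size=n,
                p=[p_hom * 0.8, p_hom * 0.2, (1 - p_hom) * 0.8, (1 - p_hom) * 0.2])
        gm = make_matrix(pos, samples)
        params = RohParams(min_snp=int(rng.integers(3, 10)),
                           min_span_bp=int(rng.integers(0, 5_000)),
                           max_het=int(rng.integers(0, 2)),
                           max_missing=int(rng.integers(0, 2)))
        roh = {s: detect_roh(gm, s, params) for s in samples}
        got = [(r.start_bp, r.end_bp) for r in shared_autozygous_regions(roh, gm)]
        want = [(s, e) for s, e, matched in
                oracle_shared_regions(roh, pos, samples) if matched]
        assert got == want

    def test_shared_coverage_contained_in_every_affecteds_roh(self, family_sim):
        gm = family_sim.genotypes
        roh = {s: detect_roh(gm, s, RELAXED) for s in ("V1", "V2", "V3")}
        shared = shared_autozygous_regions(roh, gm)
        for region in shared:
            for sample, segs in roh.items():
                assert any(seg.chrom == region.chrom
                           and seg.start_bp <= region.start_bp
                           and seg.end_bp >= region.end_bp for seg in segs)


class TestExclusionAndSummary:
    def test_published_survey_exclusion_and_totals(self):
        shared = index_family_shared_regions()
        retained = exclude_unaffected(shared, index_family_unaffected_roh())
        summary = summarize_regions(retained)
        assert summary["count"] == 20
        assert summary["total_bp"] == 17_108_575
        largest = summary["largest_region"]
        assert (largest.chrom, largest.start_bp, largest.end_bp) == \
            ("chr11", 66_108_660, 68_097_826)
        assert segment_size(largest) == 1_989_166

    def test_no_unaffected_roh_keeps_everything(self):
        shared = index_family_shared_regions()
        assert exclude_unaffected(shared, {}) == shared

    def test_contained_region_removed_with_excluding_sample_recorded(self):
        region = SharedRegion("chr5", 1_000_000, 2_000_000, ["V1"])
        unaff = {"IV3": [ROHSegment("IV3", "chr5", 500_000, 9_000_000, n_snp=500)]}
        retained = exclude_unaffected([region], unaff)
        assert retained == []
        assert region.excluded_by == "IV3"

    def test_empty_summary(self):
        assert summarize_regions([]) == {"count": 0, "total_bp": 0,
                                         "largest_region": None}
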