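from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from autozygome import (FilterConfig, FunctionalCall, GeneModel, HET, HOM_ALT,
                        HOM_REF, MISSING, ReferenceMismatchError, VariantRecord,
                        apply_recessive_filters, cds_to_codon, classify_variant,
                        tally_classes)
from autozygome.datasets import (candidate_functional_calls, nphp1_like_fixture,
                                 sptbn2_like_fixture)
from autozygome.variants import FILTER_STAGES


class TestCodonArithmetic:
    @pytest.mark.parametrize("cdna,codon,within", [
        (1881, 627, 3),  # the premature-stop position: third base of codon 627
        (1, 1, 1),
        (3, 1, 3),
        (4, 2, 1),
        (1653, 551, 3),  # the synonymous L551L position
    ])
    def test_examples(self, cdna, codon, within):
        assert cds_to_codon(cdna) == (codon, within)

    @pytest.mark.parametrize("bad", [0, -5])
    def test_non_positive_rejected(self, bad):
        with pytest.raises(ValueError):
            cds_to_codon(bad)

    @given(st.integers(min_value=1, max_value=10**9))
    @settings(max_examples=50, derandomize=True)
    def test_inverse_relation(self, pos):
        codon, within = cds_to_codon(pos)
        assert 1 <= within <= 3
        assert 3 * (codon - 1) + within == pos


AFF = ["V1", "V2", "V3"]
REGION = [("chr1", 1_000_000, 2_000_000)]


def _variant(vid, pos=1_500_000, chrom="chr1", gts=None, af=None,
             segdup=False, cohort=0):
    gts = gts if gts is not None else {s: HOM_ALT for s in AFF}
    return VariantRecord(chrom=chrom, pos=pos, ref="A", alt="G", vid=vid,
                         genotypes=gts, population_af=af, in_segdup=segdup,
                         cohort_hom_count=cohort)


class TestRecessiveCascade:
    def test_hand_enumerated_twelve_variant_table(self):
        # expected outcomes enumerated by hand from the five rules in order
        table = [
            (_variant("v01"), "survivor"),
            (_variant("v02", chrom="chr9"), "shared_region"),
            (_variant("v03", pos=2_000_001), "shared_region"),
            (_variant("v04", gts={"V1": HOM_ALT, "V2": HET, "V3": HOM_ALT}),
             "homozygous_affected"),
            (_variant("v05", gts={"V1": HOM_ALT, "V2": HOM_ALT}),
             "homozygous_affected"),  # V3 missing counts as not homozygous
            (_variant("v06", af=0.05), "allele_frequency"),
            (_variant("v07", af=0.01), "survivor"),  # boundary: strictly >1%
            (_variant("v08", af=0.0101), "allele_frequency"),
            (_variant("v09", af=None), "survivor"),  # unknown AF kept as rare
            (_variant("v10", segdup=True), "segmental_duplication"),
            (_variant("v11", cohort=2), "cohort_homozygote"),
            (_variant("v12", af=0.05, segdup=True), "allele_frequency"),  # first stage wins
        ]
        survivors, trace = apply_recessive_filters(
            [v for v, _ in table], REGION, AFF)
        assert {v.vid for v in survivors} == \
            {v.vid for v, want in table if want == "survivor"}
        for v, want in table:
            assert trace.outcome[v.vid] == want, v.vid
        counts = trace.counts()
        assert sum(counts.values()) == len(table)

    def test_empty_region_list_removes_everything_without_error(self):
        survivors, trace = apply_recessive_filters([_variant("v")], [], AFF)
        assert survivors == []
        assert trace.outcome["v"] == "shared_region"

    def test_cascade_monotone_and_counts_conserved_on_random_tables(self):
        import numpy as np

        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(1, 40))
            variants = []
            for i in range(n):
                gts = {s: int(rng.choice([HOM_REF, HET, HOM_ALT, MISSING],
                                         p=[.2, .2, .5, .1])) for s in AFF}
                variants.append(_variant(
                    f"v{i}", pos=int(rng.integers(1, 3_000_000)),
                    chrom=str(rng.choice(["chr1", "chr2"])), gts=gts,
                    af=None if rng.random() < .3 else float(rng.random() * 0.1),
                    segdup=bool(rng.random() < .2),
                    cohort=int(rng.integers(0, 3))))
            survivors, trace = apply_recessive_filters(variants, REGION, AFF)
            counts = trace.counts()
            assert sum(counts.values()) == n
            assert counts["survivor"] == len(survivors)
            # monotonicity: the set alive after stage k contains the set
            # alive after stage k+1
            rank = {s: i for i, s in enumerate(FILTER_STAGES)}
            rank["survivor"] = len(FILTER_STAGES)

            def alive_after(k):
                return {v.vid for v in variants if rank[trace.outcome[v.vid]] > k}

            for k in range(len(FILTER_STAGES) - 1):
                assert alive_after(k) >= alive_after(k + 1)


class TestClassification:
    def test_stop_gain_fixture_produces_C627X(self):
        model, cds, variant = sptbn2_like_fixture()
        call = classify_variant(variant, [model], {model.gene_id: cds})
        assert call.klass == "exonic"
        assert call.exonic_effect == "stop_gained"
        assert call.aa_change == "C627X"
        assert call.cdna_pos == 1881 and call.codon_index == 627
        # the reference codon is TGC and the alternate TGA
        assert cds[3 * 626: 3 * 627] == "TGC"

    def test_synonymous_minus_strand_fixture_produces_L551L(self):
        model, cds, variant = nphp1_like_fixture()
        call = classify_variant(variant, [model], {model.gene_id: cds})
        assert call.klass == "exonic"
        assert call.exonic_effect == "synonymous"
        assert call.aa_change == "L551L"
        assert call.codon_index == 551
        assert not call.splice_proximal

    def test_missense_call(self):
        model, cds, variant = sptbn2_like_fixture()
        # codon 627 TGC -> AGC is Cys -> Ser
        v = VariantRecord(chrom=model.chrom, pos=model.cds_start + 1878,
                          ref=cds[1878], alt="A", vid="m")
        call = classify_variant(v, [model], {model.gene_id: cds})
        assert call.exonic_effect == "missense"
        assert call.aa_change == "C627S"

    def test_reference_mismatch_is_an_error(self):
        model, cds, variant = sptbn2_like_fixture()
        bad = VariantRecord(chrom=model.chrom, pos=variant.pos,
                            ref="T" if cds[1880] != "T" else "G", alt="A", vid="bad")
        with pytest.raises(ReferenceMismatchError):
            classify_variant(bad, [model], {model.gene_id: cds})

    def test_strand_symmetry_of_amino_acid_calls(self):
        # the same physical substitution annotated against a plus-strand
        # model and its mirrored minus-strand model gives the same aa change
        import numpy as np

        from autozygome.simulate import random_cds

        rng = np.random.default_rng(4)
        cds = random_cds(40, rng, overrides={10: "TGC"})
        start = 10_001
        end = start + len(cds) - 1
        plus = GeneModel("plus", "chrX", "+", [(start, end)], start, end, True)
        minus = GeneModel("minus", "chrX", "-", [(start, end)], start, end, True)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        cdna = 28  # first base of the pinned TGC codon
        # plus-strand gene: the genome slice IS the CDS
        v_plus = VariantRecord("chrX", start + cdna - 1, cds[cdna - 1], "A", vid="p")
        call_plus = classify_variant(v_plus, [plus], {"plus": cds})
        # minus-strand gene with the same protein: the genome slice is the
        # reverse complement, so the same coding change sits at the mirrored
        # genomic position with complemented alleles
        v_minus = VariantRecord("chrX", end - cdna + 1, comp[cds[cdna - 1]],
                                comp["A"], vid="m")
        call_minus = classify_variant(v_minus, [minus], {"minus": cds})
        assert call_plus.aa_change == call_minus.aa_change
        assert call_plus.exonic_effect == call_minus.exonic_effect
        assert call_plus.exonic_effect == "missense"

    def test_non_exonic_classes_and_precedence(self):
        coding = GeneModel("g", "chr3", "+", [(1000, 1199), (1400, 1799)],
                           cds_start=1100, cds_end=1701, coding=True)
        nc = GeneModel("nc", "chr3", "+", [(900, 2000)], coding=False)
        models = [coding, nc]

        def klass(pos):
            return classify_variant(
                VariantRecord("chr3", pos, "A", "G", vid=str(pos)), models).klass

        assert klass(1050) == "5'UTR"      # beats the ncRNA exon underneath
        assert klass(1750) == "3'UTR"
        assert klass(1300) == "ncRNA"      # exon of nc beats intron of coding
        assert klass(2100) == "intergenic"
        only = [coding]
        call = classify_variant(VariantRecord("chr3", 1300, "A", "G", vid="i"), only)
        assert call.klass == "intronic"
        up = classify_variant(VariantRecord("chr3", 500, "A", "G", vid="u"), only)
        assert up.klass == "upstream"
        far = classify_variant(VariantRecord("chr3", 100_000, "A", "G", vid="f"), only)
        assert far.klass == "intergenic"

    def test_splice_proximity_window(self):
        model = GeneModel("g", "chr3", "+", [(1000, 1199), (1400, 1799)],
                          cds_start=1000, cds_end=1799, coding=True)
        near = classify_variant(VariantRecord("chr3", 1201, "A", "G", vid="n"), [model])
        assert near.klass == "intronic" and near.splice_proximal
        deep = classify_variant(VariantRecord("chr3", 1300, "A", "G", vid="d"), [model])
        assert not deep.splice_proximal


class TestTally:
    def test_published_68_candidate_fixture(self):
        calls = candidate_functional_calls()
        counts = tally_classes(calls)
        assert counts["total"] == 68
        assert counts["exonic"] == 2
        assert counts["exonic_effects"] == {"stop_gained": 1, "synonymous": 1}
        assert counts["5'UTR"] == 1
        assert counts["ncRNA"] == 3
        assert counts["intronic"] == 39
        assert counts["upstream"] == 2
        assert counts["intergenic"] == 21

    def test_empty_input_all_zero(self):
        counts = tally_classes([])
        assert counts["total"] == 0
        assert all(v == 0 for k, v in counts.items()
                   if k not in ("total", "exonic_effects"))

    def test_random_labels_match_counter_oracle(self):
        import numpy as np

        from autozygome.variants import CLASSES

        rng = np.random.default_rng(3)
        labels = [str(rng.choice(CLASSES)) for _ in range(57)]
        calls = [FunctionalCall(k) for k in labels]
        counts = tally_classes(calls)
        oracle = Counter(labels)
        for k in CLASSES:
            assert counts[k] == oracle.get(k, 0)
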