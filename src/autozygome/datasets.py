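"""Bundled reference data for the SPARCA1 index family.

The homozygosity survey of the discovery family — 23 autosomal regions of
homozygosity shared by the three affecteds (V1, V2, V3), three of which are
also homozygous in an unaffected parent (IV3 or IV4) and are therefore
excluded from the recessive search — plus the functional-class breakdown of
the 68 candidate variants that survived the filter cascade, and synthetic
coding-sequence fixtures reproducing the two exonic candidates: the
SPTBN2 stop codon C627X (c.1881C>A, TGC->TGA in the third spectrin repeat)
and the synonymous NPHP1 L551L.

The CDS fixtures are synthetic: random sense codons with only the
functionally relevant codons pinned, not the real transcript sequences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .roh import ROHSegment, SharedRegion
from .simulate import random_cds
from .variants import GeneModel, FunctionalCall, VariantRecord

# (chrom, start_bp, end_bp, published size, unaffected sample the region is
# homozygous in, or None)
INDEX_FAMILY_ROH: list[tuple[str, int, int, int, str | None]] = [
    ("chr1", 11_008_695, 11_512_411, 503_716, None),
    ("chr1", 152_466_882, 152_773_905, 307_023, None),
    ("chr2", 110_432_886, 111_586_214, 1_153_328, None),  # contains NPHP1 L551L
    ("chr4", 1_755_491, 2_268_126, 512_635, None),
    ("chr5", 42_431_016, 42_911_014, 479_998, None),
    ("chr6", 42_231_419, 43_196_182, 964_763, None),
    ("chr7", 73_889_810, 75_160_045, 1_270_235, None),
    ("chr8", 92_965_409, 93_493_424, 528_015, None),
    ("chr11", 44_874_510, 51_372_036, 6_497_526, "IV4"),
    ("chr11", 55_091_268, 59_054_448, 3_963_180, "IV4"),
    ("chr11", 66_108_660, 68_097_826, 1_989_166, None),  # contains SPTBN2 C627X
    ("chr11", 72_937_274, 74_146_105, 1_208_831, None),
    ("chr12", 825_782, 1_583_962, 758_180, None),
    ("chr12", 88_356_316, 89_340_293, 983_977, None),
    ("chr14", 105_777_094, 106_863_833, 1_086_739, None),
    ("chr15", 48_369_485, 48_889_188, 519_703, None),
    ("chr16", 47_239_089, 48_179_983, 940_894, None),
    ("chr16", 50_034_680, 50_641_988, 607_308, None),
    ("chr16", 61_713_393, 63_225_217, 1_511_824, None),
    ("chr17", 17_544_704, 18_634_672, 1_089_968, "IV3"),
    ("chr17", 27_935_688, 28_543_044, 607_356, None),
    ("chr17", 39_993_771, 41_059_014, 1_065_243, None),
    ("chr18", 21_155_324, 21_264_965, 109_641, None),
]

AFFECTEDS = ["V1", "V2", "V3"]


def index_family_roh_table() -> pd.DataFrame:
    """The published 23-region homozygosity survey as a frame."""
    return pd.DataFrame(
        INDEX_FAMILY_ROH,
        columns=["chrom", "start_bp", "end_bp", "published_size_bp", "homozygous_in"],
    )


def index_family_shared_regions() -> list[SharedRegion]:
    """The 23 shared regions, before parental exclusion."""
    return [
        SharedRegion(chrom=c, start_bp=s, end_bp=e, supporting_affecteds=list(AFFECTEDS))
        for c, s, e, _, _ in INDEX_FAMILY_ROH
    ]


def index_family_unaffected_roh() -> dict[str, list[ROHSegment]]:
    """Stringent parental ROH reconstructed from the survey's flags.

    Only the intervals flagged homozygous in IV3 or IV4 can be recovered
    from the published survey; they are encoded as stringent runs covering
    exactly those intervals.
    """
    out: dict[str, list[ROHSegment]] = {"IV3": [], "IV4": []}
    for c, s, e, _, flag in INDEX_FAMILY_ROH:
        if flag is not None:
            out[flag].append(
                ROHSegment(sample=flag, chrom=c, start_bp=s, end_bp=e, n_snp=500)
            )
    return out


#: Functional classes of the 68 candidate variants surviving the cascade.
CANDIDATE_CLASS_COUNTS: dict[str, int] = {
    "exonic": 2,  # 1 stop-gained (SPTBN2 C627X), 1 synonymous (NPHP1 L551L)
    "5'UTR": 1,
    "ncRNA": 3,
    "intronic": 39,
    "upstream": 2,
    "intergenic": 21,
}


def candidate_functional_calls() -> list[FunctionalCall]:
    """The 68 surviving candidates as labelled functional calls."""
    calls = [
        FunctionalCall("exonic", gene_id="SPTBN2", exonic_effect="stop_gained",
                       cdna_pos=1881, codon_index=627, aa_change="C627X"),
        FunctionalCall("exonic", gene_id="NPHP1", exonic_effect="synonymous",
                       cdna_pos=1653, codon_index=551, aa_change="L551L"),
    ]
    for klass, n in CANDIDATE_CLASS_COUNTS.items():
        if klass == "exonic":
            continue
        calls.extend(FunctionalCall(klass) for _ in range(n))
    return calls


# --------------------------------------------------------------------------
# Synthetic CDS fixtures for the two exonic candidates
# --------------------------------------------------------------------------

def sptbn2_like_fixture(seed: int = 2012) -> tuple[GeneModel, str, VariantRecord]:
    """Synthetic single-exon stand-in for the SPTBN2 stop-gain.

    A 2,390-codon plus-strand CDS (the beta-III spectrin protein length)
    with codon 627 pinned to TGC, placed inside the largest shared region on
    chr11; the returned variant is the C>A substitution at coding position
    1881 producing the premature stop C627X (TGC -> TGA).
    """
    rng = np.random.default_rng(seed)
    n_codons = 2391  # 2390 residues + terminator
    cds = random_cds(n_codons, rng, overrides={627: "TGC"})
    cds_start = 66_452_000
    cds_end = cds_start + 3 * n_codons - 1
    model = GeneModel(
        gene_id="SPTBN2_like", chrom="chr11", strand="+",
        exons=[(cds_start - 150, cds_end + 150)],
        cds_start=cds_start, cds_end=cds_end, coding=True,
    )
    variant = VariantRecord(chrom="chr11", pos=cds_start + 1880, ref="C", alt="A",
                            vid="SPTBN2_like_c1881CtoA")
    return model, cds, variant


def nphp1_like_fixture(seed: int = 551) -> tuple[GeneModel, str, VariantRecord]:
    """Synthetic minus-strand stand-in for the synonymous NPHP1 L551L.

    A 700-codon CDS with codon 551 pinned to CTG on the coding strand; the
    returned variant is the genomic substitution corresponding to the
    silent CTG -> CTA change at coding position 1653 (third base of codon
    551). The model is minus-strand, exercising reverse-complement codon
    arithmetic; the variant sits mid-exon, away from any splice site.
    """
    rng = np.random.default_rng(seed)
    n_codons = 701  # 700 residues + terminator
    cds = random_cds(n_codons, rng, overrides={551: "CTG"})
    cds_len = 3 * n_codons
    cds_start = 110_900_000
    cds_end = cds_start + cds_len - 1
    model = GeneModel(
        gene_id="NPHP1_like", chrom="chr2", strand="-",
        exons=[(cds_start - 150, cds_end + 150)],
        cds_start=cds_start, cds_end=cds_end, coding=True,
    )
    # coding position 1653 on the minus strand maps to this genomic base
    genomic_pos = cds_end - 1653 + 1
    variant = VariantRecord(chrom="chr2", pos=genomic_pos, ref="C", alt="T",
                            vid="NPHP1_like_L551L")
    return model, cds, variant
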