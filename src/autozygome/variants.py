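"""Recessive filter cascade and functional classification of variants.

The cascade mirrors the homozygous-recessive search used in autozygosity
mapping studies: restrict to the shared autozygous regions, require the
variant homozygous-alternate in every affected, then discard variants that
are common in a reference population (allele frequency strictly above 1%),
fall in segmental duplications, or were seen homozygous in other samples of
the sequencing cohort. Survivors are classified into functional classes
(exonic with stop-gain/synonymous/missense effect, UTRs, ncRNA, intronic,
upstream, intergenic) using strand-aware codon arithmetic on supplied CDS
sequences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .genotypes import HET, HOM_ALT, HOM_REF, MISSING

logger = logging.getLogger(__name__)


class ReferenceMismatchError(ValueError):
    """Variant REF allele disagrees with the supplied CDS sequence."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class VariantRecord:
    """One called variant with per-sample genotype codes and annotations."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vid: str = "."
    genotypes: dict[str, int] = field(default_factory=dict)
    population_af: float | None = None  # None: absent from the panel
    in_segdup: bool = False
    cohort_hom_count: int = 0
    annotations: dict = field(default_factory=dict)  # pass-through (scores etc.)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.population_af is not None and not 0.0 <= self.population_af <= 1.0:
            raise ValueError("population AF out of range")
        if self.cohort_hom_count < 0:
            raise ValueError("cohort homozygote count must be >= 0")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware single-transcript gene model.

    Exons are 1-based inclusive, sorted and non-overlapping; for coding
    models the CDS bounds lie inside the exon union and the spliced CDS
    length is divisible by three.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...] | list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None
    coding: bool = False
    upstream_window_bp: int = 1000

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        prev_end = -1
        for s, e in self.exons:
            if s > e or s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons must be sorted and non-overlapping")
            prev_end = e
        if self.coding:
            if self.cds_start is None or self.cds_end is None:
                raise ValueError("coding model requires CDS bounds")
            for bound in (self.cds_start, self.cds_end):
                if not any(s <= bound <= e for s, e in self.exons):
                    raise ValueError("CDS bounds must lie inside the exon union")
            if self.cds_length % 3 != 0:
                raise ValueError("spliced CDS length must be divisible by 3")

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    def _cds_parts(self) -> list[tuple[int, int]]:
        assert self.cds_start is not None and self.cds_end is not None
        parts = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                parts.append((lo, hi))
        return parts

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self._cds_parts())

    def genomic_to_cds(self, pos: int) -> int | None:
        """1-based coding position of a genomic coordinate, or None."""
        if not self.coding:
            return None
        offset = 0
        fwd = None
        for s, e in self._cds_parts():
            if s <= pos <= e:
                fwd = offset + (pos - s) + 1
                break
            offset += e - s + 1
        if fwd is None:
            return None
        return fwd if self.strand == "+" else self.cds_length - fwd + 1


@dataclass(frozen=True)
class FunctionalCall:
    klass: str  # exonic / 5'UTR / 3'UTR / ncRNA / intronic / upstream / intergenic
    gene_id: str | None = None
    exonic_effect: str | None = None  # stop_gained / synonymous / missense / other
    cdna_pos: int | None = None
    codon_index: int | None = None
    aa_change: str | None = None
    splice_proximal: bool = False


CLASSES = ("exonic", "5'UTR", "3'UTR", "ncRNA", "intronic", "upstream", "intergenic")
_PRECEDENCE = {"exonic": 0, "5'UTR": 1, "3'UTR": 1, "ncRNA": 2,
               "intronic": 3, "upstream": 4, "intergenic": 5}

#: Ordered stages of the recessive cascade.
FILTER_STAGES = (
    "shared_region",
    "homozygous_affected",
    "allele_frequency",
    "segmental_duplication",
    "cohort_homozygote",
)


@dataclass
class FilterTrace:
    """Per-variant first removing stage, or 'survivor'."""

    stages: tuple[str, ...]
    outcome: dict[str, str] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        c = {stage: 0 for stage in self.stages}
        c["survivor"] = 0
        for o in self.outcome.values():
            c[o] += 1
        return c


@dataclass(frozen=True)
class FilterConfig:
    af_max: float = 0.01   # drop strictly above (">1%")
    segdup: bool = True
    cohort: bool = True


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------

def cds_to_codon(cdna_pos: int) -> tuple[int, int]:
    """(codon index, position within codon), both 1-based.

    E.g. coding position 1881 is the third base of codon 627.
    """
    if cdna_pos < 1:
        raise ValueError("coding positions are 1-based and positive")
    return math.ceil(cdna_pos / 3), (cdna_pos - 1) % 3 + 1


def apply_recessive_filters(
    variants: Sequence[VariantRecord],
    regions: Sequence,
    affected: Sequence[str],
    config: FilterConfig = FilterConfig(),
) -> tuple[list[VariantRecord], FilterTrace]:
    """The five-stage homozygous-recessive cascade.

    Stage order is fixed for reproducible trace semantics; the filters are
    independent predicates, so order does not change the survivor set.
    Unknown population AF is treated as rare (absence from the reference
    panel is itself evidence of rarity).
    """
    if not regions:
        logger.warning("empty shared-region list: no variant can survive the cascade")
    trace = FilterTrace(stages=FILTER_STAGES)
    survivors: list[VariantRecord] = []

    def in_regions(v: VariantRecord) -> bool:
        for r in regions:
            chrom = getattr(r, "chrom", None) or r[0]
            start = getattr(r, "start_bp", None) or r[1]
            end = getattr(r, "end_bp", None) or r[2]
            if v.chrom == chrom and start <= v.pos <= end:
                return True
        return False

    for v in variants:
        if not in_regions(v):
            trace.outcome[v.vid] = "shared_region"
        elif not all(v.genotypes.get(s, MISSING) == HOM_ALT for s in affected):
            trace.outcome[v.vid] = "homozygous_affected"
        elif v.population_af is not None and v.population_af > config.af_max:
            trace.outcome[v.vid] = "allele_frequency"
        elif config.segdup and v.in_segdup:
            trace.outcome[v.vid] = "segmental_duplication"
        elif config.cohort and v.cohort_hom_count > 0:
            trace.outcome[v.vid] = "cohort_homozygote"
        else:
            trace.outcome[v.vid] = "survivor"
            survivors.append(v)
    return survivors, trace


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _splice_proximal(model: GeneModel, pos: int, window: int = 2) -> bool:
    if len(model.exons) < 2:
        return False
    boundaries = []
    for i, (s, e) in enumerate(model.exons):
        if i > 0:
            boundaries.append(s)
        if i < len(model.exons) - 1:
            boundaries.append(e)
    return any(abs(pos - b) <= window for b in boundaries)


def _classify_against_model(
    variant: VariantRecord,
    model: GeneModel,
    cds_seq: str | None,
) -> FunctionalCall | None:
    pos = variant.pos
    if variant.chrom != model.chrom:
        return None
    if model.tx_start <= pos <= model.tx_end:
        in_exon = any(s <= pos <= e for s, e in model.exons)
        splice = _splice_proximal(model, pos)
        if not in_exon:
            return FunctionalCall("intronic", model.gene_id, splice_proximal=splice)
        if not model.coding:
            return FunctionalCall("ncRNA", model.gene_id, splice_proximal=splice)
        assert model.cds_start is not None and model.cds_end is not None
        if pos < model.cds_start:
            klass = "5'UTR" if model.strand == "+" else "3'UTR"
            return FunctionalCall(klass, model.gene_id, splice_proximal=splice)
        if pos > model.cds_end:
            klass = "3'UTR" if model.strand == "+" else "5'UTR"
            return FunctionalCall(klass, model.gene_id, splice_proximal=splice)
        cdna = model.genomic_to_cds(pos)
        assert cdna is not None
        effect = None
        codon_index = None
        aa_change = None
        if variant.is_snv and cds_seq is not None:
            codon_index, in_codon = cds_to_codon(cdna)
            ref_c = variant.ref if model.strand == "+" else _revcomp(variant.ref)
            alt_c = variant.alt if model.strand == "+" else _revcomp(variant.alt)
            if cds_seq[cdna - 1] != ref_c:
                raise ReferenceMismatchError(
                    f"{variant.vid}: CDS base {cds_seq[cdna - 1]!r} at coding position "
                    f"{cdna} of {model.gene_id} does not match REF {variant.ref!r}"
                )
            codon = cds_seq[3 * (codon_index - 1): 3 * codon_index]
            alt_codon = codon[: in_codon - 1] + alt_c + codon[in_codon:]
            ref_aa = str(Seq(codon).translate())
            alt_aa = str(Seq(alt_codon).translate())
            if alt_aa == "*" and ref_aa != "*":
                effect = "stop_gained"
            elif ref_aa == alt_aa:
                effect = "synonymous"
            elif "*" not in (ref_aa, alt_aa):
                effect = "missense"
            else:
                effect = "other"
            sym = lambda aa: "X" if aa == "*" else aa
            aa_change = f"{sym(ref_aa)}{codon_index}{sym(alt_aa)}"
        elif cds_seq is not None:
            # indels: frame classification only
            effect = "other"
            shift = abs(len(variant.ref) - len(variant.alt)) % 3
            codon_index = cds_to_codon(cdna)[0]
            aa_change = None if shift else f"inframe@{codon_index}"
        return FunctionalCall(
            "exonic", model.gene_id, exonic_effect=effect, cdna_pos=cdna,
            codon_index=codon_index, aa_change=aa_change, splice_proximal=splice,
        )
    window = model.upstream_window_bp
    if model.strand == "+" and model.tx_start - window <= pos < model.tx_start:
        return FunctionalCall("upstream", model.gene_id)
    if model.strand == "-" and model.tx_end < pos <= model.tx_end + window:
        return FunctionalCall("upstream", model.gene_id)
    return None


def classify_variant(
    variant: VariantRecord,
    gene_models: Sequence[GeneModel],
    cds_sequences: Mapping[str, str] | None = None,
) -> FunctionalCall:
    """Highest-precedence functional call across all gene models.

    Precedence when a position hits several features:
    exonic > UTR > ncRNA > intronic > upstream > intergenic. Ties are broken
    by gene id for determinism. For coding exonic SNVs the reference and
    alternate codons are built on the coding strand (reverse-complemented
    for minus-strand models) and translated with the standard genetic code.
    """
    cds_sequences = cds_sequences or {}
    calls = []
    for model in gene_models:
        call = _classify_against_model(variant, model, cds_sequences.get(model.gene_id))
        if call is not None:
            calls.append(call)
    if not calls:
        return FunctionalCall("intergenic")
    return min(calls, key=lambda c: (_PRECEDENCE[c.klass], c.gene_id or ""))


def tally_classes(calls: Sequence[FunctionalCall]) -> dict:
    """Counts per functional class; exonic sub-effects reported separately."""
    counts = {k: 0 for k in CLASSES}
    effects: dict[str, int] = {}
    for call in calls:
        counts[call.klass] += 1
        if call.klass == "exonic" and call.exonic_effect is not None:
            effects[call.exonic_effect] = effects.get(call.exonic_effect, 0) + 1
    counts["total"] = len(calls)
    counts["exonic_effects"] = effects
    return counts
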