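"""Compound-heterozygote candidate search and parental trans/cis phasing.

A gene is a compound-het candidate when an affected carries two different
heterozygous variants in it. Phasing uses parental carriage only — exactly
the criterion usable in a sequenced trio without read-backed phasing: the
pair is *trans* when each parent carries exactly one of the two variants
(both gene copies hit), *cis* when one parent carries both and the other
neither (one copy hit, not disease-causing under a recessive model), and
*unknown* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

from .genotypes import HET, HOM_ALT, MISSING
from .pedigree import Pedigree
from .variants import FunctionalCall, VariantRecord


@dataclass
class CompHetPair:
    gene_id: str
    variant_a: VariantRecord
    variant_b: VariantRecord
    affecteds_supporting: list[str]
    phase: str = "unknown"  # trans / cis / unknown
    phasing_parents: dict[str, list[str]] = field(default_factory=dict)
    phase_conflict: bool = False

    def __post_init__(self) -> None:
        if self.variant_a.vid == self.variant_b.vid:
            raise ValueError("a compound-het pair needs two different variants")


def _is_coding(call: FunctionalCall) -> bool:
    return call.klass == "exonic" or call.splice_proximal


def find_comphet_candidates(
    variants: Sequence[VariantRecord],
    annotations: Mapping[str, FunctionalCall],
    affecteds: Sequence[str],
    coding_only: bool = True,
) -> list[CompHetPair]:
    """Every unordered pair of distinct coding variants in one gene that is
    heterozygous together in at least one affected; ``affecteds_supporting``
    lists every affected carrying both variants het."""
    by_gene: dict[str, list[VariantRecord]] = {}
    for v in variants:
        call = annotations.get(v.vid)
        if call is None or call.gene_id is None:
            continue
        if coding_only and not _is_coding(call):
            continue
        by_gene.setdefault(call.gene_id, []).append(v)
    pairs: list[CompHetPair] = []
    for gene_id in sorted(by_gene):
        for va, vb in combinations(by_gene[gene_id], 2):
            support = [
                s for s in affecteds
                if va.genotypes.get(s) == HET and vb.genotypes.get(s) == HET
            ]
            if support:
                pairs.append(CompHetPair(gene_id, va, vb, support))
    return pairs


def _carries(variant: VariantRecord, sample: str) -> bool | None:
    g = variant.genotypes.get(sample, MISSING)
    if g == MISSING:
        return None
    return g in (HET, HOM_ALT)


def phase_by_parents(
    pair: CompHetPair, pedigree: Pedigree, record_parents: bool = True
) -> CompHetPair:
    """Set ``pair.phase`` from parental carriage in fully genotyped trios.

    Verdicts from every usable affected-parent trio are collected; if they
    disagree the phase is ``unknown`` with a conflict flag (refusing to
    guess when trios contradict each other).
    """
    verdicts: set[str] = set()
    for aff in pair.affecteds_supporting:
        if aff not in pedigree:
            continue
        parents = pedigree.parents_of(aff)
        if parents is None:
            continue
        carriage = {}
        usable = True
        for parent in parents:
            ca = _carries(pair.variant_a, parent)
            cb = _carries(pair.variant_b, parent)
            if ca is None or cb is None:
                usable = False
                break
            carriage[parent] = [
                v.vid for v, c in ((pair.variant_a, ca), (pair.variant_b, cb)) if c
            ]
        if not usable:
            continue
        if record_parents:
            pair.phasing_parents.update(carriage)
        sets = [set(v) for v in carriage.values()]
        both = {pair.variant_a.vid, pair.variant_b.vid}
        if all(len(s) == 1 for s in sets) and sets[0] != sets[1]:
            verdicts.add("trans")
        elif (sets[0] == both and not sets[1]) or (sets[1] == both and not sets[0]):
            verdicts.add("cis")
        else:
            verdicts.add("unknown")
    if len(verdicts) == 1:
        pair.phase = verdicts.pop()
    elif verdicts:
        pair.phase = "unknown"
        pair.phase_conflict = True
    else:
        pair.phase = "unknown"
    return pair


def report_loci(
    pairs: Sequence[CompHetPair],
    affecteds: Sequence[str],
    require_all_affecteds: bool = True,
    require_trans: bool = True,
) -> tuple[list[CompHetPair], dict[str, int]]:
    """Apply the all-affecteds and trans gates in order, with per-gate counts.

    Counts are numbers of distinct loci (genes), monotone non-increasing
    across the gates.
    """
    def n_loci(ps: Sequence[CompHetPair]) -> int:
        return len({p.gene_id for p in ps})

    kept = list(pairs)
    counts = {"loci_candidate": n_loci(kept)}
    if require_all_affecteds:
        kept = [p for p in kept if set(affecteds) <= set(p.affecteds_supporting)]
    counts["loci_all_affecteds"] = n_loci(kept)
    if require_trans:
        kept = [p for p in kept if p.phase == "trans"]
    counts["loci_trans"] = n_loci(kept)
    return kept, counts
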