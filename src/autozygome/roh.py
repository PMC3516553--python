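"""Runs of homozygosity: detection, sharing across affecteds, exclusion.

A homozygous region is a maximal run of consecutive markers on one
chromosome containing at least ``min_snp`` homozygous calls and spanning
strictly more than ``min_span_bp`` (last position minus first), with at most
``max_het`` heterozygous and ``max_missing`` missing calls inside and
homozygous markers at both boundaries. Two presets mirror standard mapping
practice in consanguineous families: a *relaxed* set (50 SNPs / 500 kb,
tolerating a het call) applied to affecteds to minimise false negatives,
and a *stringent* set (500 SNPs / 5 Mb, uninterrupted) applied to unaffected
relatives so that only confident parental homozygosity excludes a region.

This is a deliberate departure from PLINK's windowed vote heuristic: the
region definition itself is implemented as an explicit maximal-run scanner,
which is exactly testable against an enumerate-all-windows oracle. Runs are
selected greedily left to right, so per-sample per-chromosome output is
non-overlapping.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genotypes import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING


@dataclass(frozen=True)
class RohParams:
    min_snp: int
    min_span_bp: int
    max_het: int = 0
    max_missing: int = 0

    def __post_init__(self) -> None:
        if self.min_snp < 1:
            raise ValueError("min_snp must be >= 1")
        if self.min_span_bp < 0 or self.max_het < 0 or self.max_missing < 0:
            raise ValueError("thresholds must be non-negative")


#: Relaxed preset for affecteds: >=50 homozygous SNPs spanning more than
#: 500 kb, allowing for some heterozygous calls within the run. The het
#: allowance is not quantified by the mapping protocol; one het and two
#: missing calls per run is the overridable default here.
RELAXED = RohParams(min_snp=50, min_span_bp=500_000, max_het=1, max_missing=2)
#: Stringent preset for unaffecteds: an uninterrupted run of >=500
#: homozygous SNPs spanning more than 5 Mb.
STRINGENT = RohParams(min_snp=500, min_span_bp=5_000_000, max_het=0, max_missing=0)

PRESETS: dict[str, RohParams] = {"relaxed": RELAXED, "stringent": STRINGENT}


@dataclass(frozen=True)
class ROHSegment:
    sample: str
    chrom: str
    start_bp: int  # position of first marker in the run, 1-based
    end_bp: int    # position of last marker in the run, 1-based
    n_snp: int     # homozygous calls in the run
    n_het: int = 0
    n_missing: int = 0

    @property
    def size(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class SharedRegion:
    chrom: str
    start_bp: int
    end_bp: int
    supporting_affecteds: list[str]
    allele_matched: bool = True
    excluded_by: str | None = None

    @property
    def size(self) -> int:
        return self.end_bp - self.start_bp


def segment_size(segment) -> int:
    """Region size in bp under the ``end - start`` convention.

    Accepts an :class:`ROHSegment`/:class:`SharedRegion` or a
    ``(start_bp, end_bp)`` pair. This convention (not end-start+1) is the
    one that reproduces the published per-region sizes exactly.
    """
    if hasattr(segment, "start_bp"):
        return segment.end_bp - segment.start_bp
    start, end = segment
    return end - start


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    m = re.fullmatch(r"(?:chr)?(\d+)", chrom)
    return (int(m.group(1)), "") if m else (10**9, chrom)


def detect_roh(genotypes: GenotypeMatrix, sample: str, params: RohParams) -> list[ROHSegment]:
    """All maximal qualifying homozygous runs for one sample.

    Runs are grown from each candidate homozygous start to the furthest
    homozygous marker reachable within the het/missing allowances and
    emitted when they satisfy the marker-count and span thresholds; scanning
    resumes after an emitted run, so segments never overlap.
    """
    col = genotypes.calls_for(sample)
    out: list[ROHSegment] = []
    for chrom in genotypes.chromosomes():
        idx, pos = genotypes.chrom_block(chrom)
        calls = col[idx]
        n = len(calls)
        hom_idx = np.flatnonzero((calls == HOM_REF) | (calls == HOM_ALT))
        k = 0
        while k < len(hom_idx):
            i = int(hom_idx[k])
            nhet = nmiss = 0
            best = (i, 1, 0, 0)  # (last hom idx, n_hom, n_het, n_missing)
            nhom = 1
            t = i + 1
            while t < n:
                c = calls[t]
                if c == HET:
                    nhet += 1
                    if nhet > params.max_het:
                        break
                elif c == MISSING:
                    nmiss += 1
                    if nmiss > params.max_missing:
                        break
                else:
                    nhom += 1
                    best = (t, nhom, nhet, nmiss)
                t += 1
            j, n_hom, n_het, n_missing = best
            if n_hom >= params.min_snp and pos[j] - pos[i] > params.min_span_bp:
                out.append(ROHSegment(
                    sample=sample, chrom=chrom,
                    start_bp=int(pos[i]), end_bp=int(pos[j]),
                    n_snp=n_hom, n_het=n_het, n_missing=n_missing,
                ))
                while k < len(hom_idx) and hom_idx[k] <= j:
                    k += 1
            else:
                k += 1
    return out


def _intersect_intervals(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s <= e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def shared_autozygous_regions(
    roh_by_affected: Mapping[str, Sequence[ROHSegment]],
    genotypes: GenotypeMatrix,
    return_diagnostics: bool = False,
) -> list[SharedRegion] | tuple[list[SharedRegion], list[SharedRegion]]:
    """Allele-matched intersection of per-affected ROH.

    Returns maximal intervals covered by a run of every affected where, at
    every marker inside the interval, all non-missing homozygous calls agree
    across affecteds. Heterozygous and missing calls never break matching
    (arrays miscall; the sharing criterion is genotype identity, not
    completeness). Intervals failing allele matching are dropped from the
    main return and available via ``return_diagnostics``.
    """
    affecteds = list(roh_by_affected)
    if not affecteds:
        raise ValueError("need at least one affected sample with detected ROH")
    for s in affecteds:
        genotypes.sample_index(s)  # raises for unknown samples
    chroms = genotypes.chromosomes()
    kept: list[SharedRegion] = []
    dropped: list[SharedRegion] = []
    cols = {s: genotypes.calls_for(s) for s in affecteds}
    for chrom in chroms:
        per_sample = [
            sorted((seg.start_bp, seg.end_bp) for seg in roh_by_affected[s] if seg.chrom == chrom)
            for s in affecteds
        ]
        shared = per_sample[0]
        for other in per_sample[1:]:
            shared = _intersect_intervals(shared, other)
        for start, end in shared:
            rows = genotypes.subset_region(chrom, start, end)
            sub = np.stack([cols[s][rows] for s in affecteds], axis=1)
            hom = (sub == HOM_REF) | (sub == HOM_ALT)
            has_ref = ((sub == HOM_REF) & hom).any(axis=1)
            has_alt = ((sub == HOM_ALT) & hom).any(axis=1)
            region = SharedRegion(
                chrom=chrom, start_bp=int(start), end_bp=int(end),
                supporting_affecteds=list(affecteds),
                allele_matched=not bool((has_ref & has_alt).any()),
            )
            (kept if region.allele_matched else dropped).append(region)
    if return_diagnostics:
        return kept, dropped
    return kept


def exclude_unaffected(
    shared: Sequence[SharedRegion],
    unaffected_roh_by_sample: Mapping[str, Sequence[ROHSegment]],
) -> list[SharedRegion]:
    """Drop shared regions overlapping any stringent ROH of an unaffected.

    Removed regions get ``excluded_by`` set to the first excluding sample;
    retained regions are returned.
    """
    retained: list[SharedRegion] = []
    for region in shared:
        for sample, segs in unaffected_roh_by_sample.items():
            hit = any(
                seg.chrom == region.chrom
                and seg.start_bp <= region.end_bp
                and seg.end_bp >= region.start_bp
                for seg in segs
            )
            if hit:
                region.excluded_by = sample
                break
        else:
            retained.append(region)
    return retained


def summarize_regions(regions: Sequence[SharedRegion]) -> dict:
    """Count, total size and largest region (ties: lowest chrom, then start)."""
    if not regions:
        return {"count": 0, "total_bp": 0, "largest_region": None}
    largest = min(
        regions,
        key=lambda r: (-segment_size(r), _chrom_sort_key(r.chrom), r.start_bp),
    )
    return {
        "count": len(regions),
        "total_bp": sum(segment_size(r) for r in regions),
        "largest_region": largest,
    }
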