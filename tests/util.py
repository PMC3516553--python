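"""Shared test helpers: matrix builders and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd

from autozygome import GenotypeMatrix, RohParams


def make_matrix(pos, calls_by_sample, chrom="chr1") -> GenotypeMatrix:
    """GenotypeMatrix from a position list and {sample: calls} mapping."""
    pos = np.asarray(pos, dtype=np.int64)
    samples = list(calls_by_sample)
    calls = np.stack([np.asarray(calls_by_sample[s], dtype=np.int8) for s in samples], axis=1)
    markers = pd.DataFrame({
        "chrom": chrom if isinstance(chrom, str) else list(chrom),
        "pos": pos,
        "id": [f"m{i}" for i in range(len(pos))],
    })
    return GenotypeMatrix(markers=markers, samples=samples, calls=calls)


def oracle_detect_roh(pos, calls, params: RohParams):
    """Exhaustive-enumeration ROH oracle.

    Enumerates every marker sub-interval with homozygous boundaries, keeps
    those satisfying the thresholds, then selects greedily left to right
    (minimal start, then maximal end, discarding overlaps). Returns
    (start_idx, end_idx, n_hom, n_het, n_missing) tuples.
    """
    pos = np.asarray(pos)
    calls = np.asarray(calls)
    n = len(calls)
    is_hom = (calls == 0) | (calls == 2)
    c_hom = np.concatenate([[0], np.cumsum(is_hom)])
    c_het = np.concatenate([[0], np.cumsum(calls == 1)])
    c_mis = np.concatenate([[0], np.cumsum(calls == -1)])
    qualifying = []
    for i in range(n):
        if not is_hom[i]:
            continue
        for j in range(i, n):
            if not is_hom[j]:
                continue
            nhet = int(c_het[j + 1] - c_het[i])
            nmis = int(c_mis[j + 1] - c_mis[i])
            nhom = int(c_hom[j + 1] - c_hom[i])
            if (nhet <= params.max_het and nmis <= params.max_missing
                    and nhom >= params.min_snp
                    and pos[j] - pos[i] > params.min_span_bp):
                qualifying.append((i, j, nhom, nhet, nmis))
    qualifying.sort(key=lambda t: (t[0], -t[1]))
    chosen, cursor = [], -1
    for tup in qualifying:
        if tup[0] > cursor:
            chosen.append(tup)
            cursor = tup[1]
    return chosen


def oracle_shared_regions(roh_by_sample, pos, calls_by_sample):
    """Marker-level sharing oracle: a marker is shared-covered when inside a
    run of every affected; maximal covered runs are then checked for
    homozygous-genotype identity across affecteds marker by marker."""
    pos = np.asarray(pos)
    n = len(pos)
    covered = np.ones(n, dtype=bool)
    for sample, segs in roh_by_sample.items():
        cov = np.zeros(n, dtype=bool)
        for seg in segs:
            cov |= (pos >= seg.start_bp) & (pos <= seg.end_bp)
        covered &= cov
    out = []
    i = 0
    samples = list(roh_by_sample)
    while i < n:
        if not covered[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and covered[j + 1]:
            j += 1
        homs = []
        matched = True
        for m in range(i, j + 1):
            vals = {calls_by_sample[s][m] for s in samples
                    if calls_by_sample[s][m] in (0, 2)}
            if len(vals) > 1:
                matched = False
        out.append((int(pos[i]), int(pos[j]), matched))
        i = j + 1
    return out
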