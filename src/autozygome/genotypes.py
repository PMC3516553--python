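"""Genotype matrix container for SNP-array style marker panels.

Calls are stored as small integers counting alternate alleles:
``0`` hom-ref, ``1`` het, ``2`` hom-alt, ``-1`` missing. Markers are kept in
a pandas frame sorted by (chromosome, position); positions are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

_VALID_CALLS = frozenset({HOM_REF, HET, HOM_ALT, MISSING})


@dataclass
class GenotypeMatrix:
    """Per-sample biallelic calls at ordered genomic markers.

    Parameters
    ----------
    markers : pandas.DataFrame
        Columns ``chrom`` (str), ``pos`` (int, 1-based), ``id`` (str) and
        optionally ``ref``/``alt`` allele columns. Positions must be strictly
        increasing within each chromosome.
    samples : list of str
    calls : numpy.ndarray of shape (n_markers, n_samples), int8
    """

    markers: pd.DataFrame
    samples: list[str]
    calls: np.ndarray
    _sample_idx: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "id"}
        if not required.issubset(self.markers.columns):
            raise ValueError(f"markers frame needs columns {sorted(required)}")
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.markers), len(self.samples)):
            raise ValueError("calls shape does not match markers x samples")
        bad = set(np.unique(self.calls)) - _VALID_CALLS
        if bad:
            raise ValueError(f"invalid call codes {sorted(bad)}")
        for _, block in self.markers.groupby("chrom", sort=False):
            pos = block["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("marker positions must be strictly increasing per chromosome")
        self._sample_idx = {s: i for i, s in enumerate(self.samples)}

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sample_index(self, sample: str) -> int:
        try:
            return self._sample_idx[sample]
        except KeyError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def calls_for(self, sample: str) -> np.ndarray:
        return self.calls[:, self.sample_index(sample)]

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chrom"]))

    def chrom_block(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(row indices, positions) of the markers on ``chrom``."""
        idx = np.flatnonzero((self.markers["chrom"] == chrom).to_numpy())
        return idx, self.markers["pos"].to_numpy()[idx]

    def subset_region(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Row indices of markers in the closed interval [start, end]."""
        idx, pos = self.chrom_block(chrom)
        return idx[(pos >= start) & (pos <= end)]
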