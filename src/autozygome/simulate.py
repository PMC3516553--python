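"""Pedigree gene-dropping simulator with a planted recessive stop-gain.

Founder chromosomes receive distinct haplotype labels which are then
transmitted down the pedigree through recombinant meioses (Haldane model:
Poisson crossover count with mean equal to the genetic length in Morgans,
uniform crossover positions, no interference). The resulting identity-by-
descent mosaic drives both marker-genotype synthesis (autozygous tracts are
homozygous up to genotyping error) and a variant table carrying one causal
stop-gain — homozygous in all affecteds, heterozygous in the four carrier
parents — plus decoy variants that the recessive filter cascade and the
compound-heterozygote analysis are expected to reject.

Planting: transmitting one founder haplotype homozygously to all three
affecteds requires thirteen specific meioses to cooperate, so the default
``plant_mode="conditional"`` draws each constrained meiosis conditionally on
carrying the required founder label at the planted locus. The crossover
process is drawn unconditionally and only the uniform starting-phase bit is
conditioned, which is an exact draw from the conditional law; a
``"rejection"`` mode that redraws unconstrained realizations until the
condition holds is also provided.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genotypes import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING
from .pedigree import FAMILY_AFFECTEDS, FAMILY_PARENTS, Pedigree, build_family_pedigree
from .variants import GeneModel, VariantRecord

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_SENSE_CODONS = [c for c in _CODONS if c not in _STOPS and c != "ATG"]


class SimulationError(RuntimeError):
    pass


class PlantingError(SimulationError):
    """Raised when the requested IBD transmission cannot be realized."""


# --------------------------------------------------------------------------
# Recombination map
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    length_cm: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("physical length must be > 0")
        if self.length_cm < 0:
            raise ValueError("genetic length must be >= 0")


@dataclass(frozen=True)
class RecombinationMap:
    """Uniform-rate genetic map over a set of autosomes."""

    chromosomes: tuple[Chromosome, ...]

    @classmethod
    def uniform(cls, spec: Iterable[tuple[str, int, float]]) -> "RecombinationMap":
        return cls(tuple(Chromosome(*c) for c in spec))

    def __getitem__(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def total_bp(self) -> int:
        return sum(c.length_bp for c in self.chromosomes)


# --------------------------------------------------------------------------
# Haplotypes and gene dropping
# --------------------------------------------------------------------------

# A haplotype is a list of (start, end, founder_label) segments, 1-based
# inclusive, tiling [1, chromosome length] without gaps or overlaps.
Hap = list[tuple[int, int, str]]


def label_at(hap: Hap, pos: int) -> str:
    ends = [seg[1] for seg in hap]
    i = bisect.bisect_left(ends, pos)
    start, end, lab = hap[i]
    if not start <= pos <= end:  # pragma: no cover - construction invariant
        raise AssertionError("haplotype segments do not tile the chromosome")
    return lab


def _slice_hap(hap: Hap, start: int, end: int) -> Hap:
    out: Hap = []
    for s, e, lab in hap:
        if e < start or s > end:
            continue
        out.append((max(s, start), min(e, end), lab))
    return out


def _merge_adjacent(hap: Hap) -> Hap:
    out: Hap = []
    for seg in hap:
        if out and out[-1][2] == seg[2] and out[-1][1] + 1 == seg[0]:
            out[-1] = (out[-1][0], seg[1], seg[2])
        else:
            out.append(seg)
    return out


def _gamete(
    h0: Hap,
    h1: Hap,
    chrom: Chromosome,
    rng: np.random.Generator,
    anchors: Sequence[tuple[int, str]] = (),
) -> Hap:
    """One recombinant gamete; ``anchors`` force founder labels at loci."""
    for _ in range(64):
        k = int(rng.poisson(chrom.length_cm / 100.0))
        xs = np.unique(rng.integers(1, chrom.length_bp, size=k)) if k else np.empty(0, int)
        allowed = [True, True]
        for pos, want in anchors:
            parity = int(np.searchsorted(xs, pos, side="left")) % 2
            for phase0 in (0, 1):
                src = h0 if (phase0 ^ parity) == 0 else h1
                if label_at(src, pos) != want:
                    allowed[phase0] = False
        if allowed[0] and allowed[1]:
            phase0 = int(rng.integers(2))
        elif allowed[0]:
            phase0 = 0
        elif allowed[1]:
            phase0 = 1
        else:
            if not anchors or not any(
                label_at(h, p) == w for p, w in anchors for h in (h0, h1)
            ):
                raise PlantingError("required founder label absent from transmitting parent")
            continue  # incompatible crossover realization; redraw
        bounds = [0, *xs.tolist(), chrom.length_bp]
        gam: Hap = []
        for i in range(len(bounds) - 1):
            src = h0 if ((phase0 + i) % 2) == 0 else h1
            gam.extend(_slice_hap(src, bounds[i] + 1, bounds[i + 1]))
        return _merge_adjacent(gam)
    raise PlantingError("could not satisfy transmission constraints in 64 crossover draws")


# constraints: (parent_id, child_id) -> [(chrom_name, pos, founder_label), ...]
Constraints = dict[tuple[str, str], list[tuple[str, int, str]]]


@dataclass
class PedigreeGenome:
    """Founder-labelled diplotypes for every pedigree member."""

    rmap: RecombinationMap
    haplotypes: dict[str, dict[str, tuple[Hap, Hap]]]

    def _ind(self, individual: str) -> dict[str, tuple[Hap, Hap]]:
        try:
            return self.haplotypes[individual]
        except KeyError:
            raise ValueError(f"unknown individual {individual!r}") from None

    def labels_at(self, individual: str, chrom: str, pos: int) -> tuple[str, str]:
        h0, h1 = self._ind(individual)[chrom]
        return label_at(h0, pos), label_at(h1, pos)

    def carrier_count(self, individual: str, chrom: str, pos: int, lab: str) -> int:
        return sum(x == lab for x in self.labels_at(individual, chrom, pos))

    def autozygous_segments(self, individual: str, chrom: str) -> list[tuple[int, int]]:
        """Maximal intervals where both haplotypes share a founder label."""
        h0, h1 = self._ind(individual)[chrom]
        out: list[tuple[int, int]] = []
        i = j = 0
        while i < len(h0) and j < len(h1):
            s = max(h0[i][0], h1[j][0])
            e = min(h0[i][1], h1[j][1])
            if s <= e and h0[i][2] == h1[j][2]:
                if out and out[-1][1] + 1 == s:
                    out[-1] = (out[-1][0], e)
                else:
                    out.append((s, e))
            if h0[i][1] < h1[j][1]:
                i += 1
            else:
                j += 1
        return out


def gene_drop(
    pedigree: Pedigree,
    rmap: RecombinationMap,
    seed: int | np.random.Generator,
    constraints: Constraints | None = None,
) -> PedigreeGenome:
    """Drop founder haplotypes through the pedigree with recombination.

    Founders receive labels ``"<id>.0"`` (paternal slot) and ``"<id>.1"``;
    every non-founder haplotype is a mosaic of the corresponding parent's
    two labels. Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    constraints = constraints or {}
    haps: dict[str, dict[str, tuple[Hap, Hap]]] = {}
    for member in pedigree.topological_order():
        per_chrom: dict[str, tuple[Hap, Hap]] = {}
        for chrom in rmap.chromosomes:
            if member.is_founder:
                whole0: Hap = [(1, chrom.length_bp, f"{member.id}.0")]
                whole1: Hap = [(1, chrom.length_bp, f"{member.id}.1")]
                per_chrom[chrom.name] = (whole0, whole1)
            else:
                gams = []
                for parent_id in (member.father_id, member.mother_id):
                    anchors = [
                        (pos, lab)
                        for (c, pos, lab) in constraints.get((parent_id, member.id), [])
                        if c == chrom.name
                    ]
                    h0, h1 = haps[parent_id][chrom.name]
                    gams.append(_gamete(h0, h1, chrom, rng, anchors))
                per_chrom[chrom.name] = (gams[0], gams[1])
        haps[member.id] = per_chrom
    return PedigreeGenome(rmap=rmap, haplotypes=haps)


def autozygosity_fraction(genome: PedigreeGenome, individual: str) -> float:
    """Fraction of the genome where both haplotypes are identical by descent."""
    total = genome.rmap.total_bp
    auto = 0
    for chrom in genome.rmap.names:
        for s, e in genome.autozygous_segments(individual, chrom):
            auto += e - s + 1
    return auto / total


def rejection_plant(
    pedigree: Pedigree,
    rmap: RecombinationMap,
    predicate: Callable[[PedigreeGenome], bool],
    seed: int,
    max_attempts: int = 1000,
) -> tuple[PedigreeGenome, int]:
    """Redraw unconstrained gene drops until ``predicate`` holds."""
    rng = np.random.default_rng(seed)
    for attempt in range(1, max_attempts + 1):
        genome = gene_drop(pedigree, rmap, rng)
        if predicate(genome):
            return genome, attempt
    raise PlantingError(f"no qualifying IBD realization in {max_attempts} attempts")


# --------------------------------------------------------------------------
# Transmission constraints
# --------------------------------------------------------------------------

def homozygous_transmission_constraints(
    pedigree: Pedigree,
    founder_id: str,
    hap_label: str,
    chrom: str,
    pos: int,
    affecteds: Sequence[str],
) -> Constraints:
    """Constraints forcing ``hap_label`` to reach every affected via both parents."""
    cons: Constraints = {}
    for aff in affecteds:
        parents = pedigree.parents_of(aff)
        if parents is None:
            raise PlantingError(f"affected {aff} has no parents to transmit through")
        for parent in parents:
            path = pedigree.lineage_path(founder_id, parent)
            if path is None:
                raise PlantingError(f"founder {founder_id} is not an ancestor of {parent}")
            chain = path + [aff]
            for a, b in zip(chain, chain[1:]):
                cons.setdefault((a, b), [])
                entry = (chrom, pos, hap_label)
                if entry not in cons[(a, b)]:
                    cons[(a, b)].append(entry)
    return cons


def carrier_transmission_constraints(
    pedigree: Pedigree,
    founder_id: str,
    hap_label: str,
    chrom: str,
    pos: int,
    via: dict[str, str],
) -> Constraints:
    """Constraints delivering one copy of ``hap_label`` to each carrier.

    ``via`` maps each carrier to the parent through which the copy must come
    (fixing cis/trans structure for compound-het plantings).
    """
    cons: Constraints = {}
    for carrier, parent in via.items():
        path = pedigree.lineage_path(founder_id, parent)
        if path is None:
            raise PlantingError(f"founder {founder_id} is not an ancestor of {parent}")
        chain = path + [carrier]
        for a, b in zip(chain, chain[1:]):
            cons.setdefault((a, b), [])
            entry = (chrom, pos, hap_label)
            if entry not in cons[(a, b)]:
                cons[(a, b)].append(entry)
    return cons


def merge_constraints(*parts: Constraints) -> Constraints:
    out: Constraints = {}
    for part in parts:
        for key, entries in part.items():
            out.setdefault(key, [])
            for e in entries:
                if e not in out[key]:
                    out[key].append(e)
    return out


# --------------------------------------------------------------------------
# Simulation configuration
# --------------------------------------------------------------------------

_DEFAULT_DECOYS = {
    "common": 1,            # population AF above the 1% cutoff
    "segdup": 1,            # inside a segmental-duplication mask
    "cohort_homozygous": 1, # homozygous elsewhere in the sequencing cohort
    "comphet_cis_pair": 1,  # two hets on the same parental haplotype
    "comphet_trans_pair": 1,  # two hets on opposite haplotypes
    "neutral": 5,           # rare variants outside the shared autozygome
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic consanguineous family.

    Defaults are a scaled-down rendering of a genome-wide SNP-array study:
    two 100-Mb autosomes at 1 cM/Mb with 10,000 markers each (one marker per
    10 kb, the density of a ~300k genome-wide array), uniform marker allele
    frequencies in [0.05, 0.5], a 0.1% symmetric genotyping-error rate and no
    missing calls (emulating a panel already stripped of markers with missing
    genotypes).
    """

    seed: int = 0
    chromosomes: tuple[tuple[str, int, float], ...] = (
        ("chr1", 100_000_000, 100.0),
        ("chr2", 100_000_000, 100.0),
    )
    n_markers: int = 10_000  # per chromosome
    af_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    error_rate: float = 0.001
    causal_chrom: str = "chr1"
    causal_pos: int = 62_500_000
    causal_founder_hap: str = "F1.0"
    comphet_chrom: str = "chr2"
    decoys: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_DECOYS))
    plant_mode: str = "conditional"  # or "rejection"
    max_plant_attempts: int = 100

    def __post_init__(self) -> None:
        for rate in (self.missing_rate, self.error_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.plant_mode not in ("conditional", "rejection"):
            raise ValueError(f"unknown plant_mode {self.plant_mode!r}")
        names = [c[0] for c in self.chromosomes]
        if self.causal_chrom not in names:
            raise SimulationError(f"causal chromosome {self.causal_chrom!r} not simulated")
        length = dict((c[0], c[1]) for c in self.chromosomes)[self.causal_chrom]
        if not 1 <= self.causal_pos <= length:
            raise SimulationError("planted locus outside chromosome bounds")

    @property
    def rmap(self) -> RecombinationMap:
        return RecombinationMap.uniform(self.chromosomes)


# --------------------------------------------------------------------------
# Marker genotypes
# --------------------------------------------------------------------------

def _draw_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length + 1, size=int(n * 1.1) + 16))
    while len(pos) < n:
        pos = np.unique(np.concatenate([pos, rng.integers(1, length + 1, size=n)]))
    if len(pos) > n:
        pos = np.sort(rng.choice(pos, size=n, replace=False))
    return pos


def synthesize_genotypes(
    genome: PedigreeGenome,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    marker_positions: dict[str, np.ndarray] | None = None,
    samples: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Array-style genotypes from the founder-labelled diplotypes.

    Founder haplotypes are assigned alleles marker-by-marker from the
    configured frequency distribution; a genotype is the sum of the two
    founder-haplotype alleles, then perturbed by symmetric genotyping error
    (hom -> het and het -> hom at equal rate) and missingness.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    samples = list(samples) if samples is not None else list(genome.haplotypes)
    frames = []
    call_blocks = []
    founder_labels = sorted(
        {seg[2] for ind in genome.haplotypes.values() for ch in ind.values() for h in ch for seg in h}
    )
    for chrom in genome.rmap.chromosomes:
        if marker_positions is not None and chrom.name in marker_positions:
            pos = np.asarray(sorted(marker_positions[chrom.name]), dtype=np.int64)
            if len(pos) and (pos[0] < 1 or pos[-1] > chrom.length_bp):
                raise ValueError(f"marker outside bounds of {chrom.name}")
        else:
            pos = _draw_positions(rng, chrom.length_bp, config.n_markers)
        n = len(pos)
        afs = rng.uniform(*config.af_range, size=n)
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        founder_alleles = {
            lab: (rng.random(n) < afs).astype(np.int8) for lab in founder_labels
        }
        block = np.empty((n, len(samples)), dtype=np.int8)
        for si, sample in enumerate(samples):
            dosage = np.zeros(n, dtype=np.int8)
            for hap in genome.haplotypes[sample][chrom.name]:
                alleles = np.empty(n, dtype=np.int8)
                for s, e, lab in hap:
                    i0 = np.searchsorted(pos, s, side="left")
                    i1 = np.searchsorted(pos, e, side="right")
                    alleles[i0:i1] = founder_alleles[lab][i0:i1]
                dosage += alleles
            block[:, si] = dosage
        # symmetric genotype error
        if config.error_rate > 0:
            err = rng.random(block.shape) < config.error_rate
            hom = err & ((block == HOM_REF) | (block == HOM_ALT))
            het = err & (block == HET)
            block[hom] = HET
            block[het] = rng.integers(0, 2, size=int(het.sum())).astype(np.int8) * 2
        if config.missing_rate > 0:
            block[rng.random(block.shape) < config.missing_rate] = MISSING
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom.name,
                    "pos": pos,
                    "id": [f"{chrom.name}_m{i}" for i in range(n)],
                    "ref": [_BASES[i] for i in ref_idx],
                    "alt": [_BASES[i] for i in alt_idx],
                }
            )
        )
        call_blocks.append(block)
    markers = pd.concat(frames, ignore_index=True)
    return GenotypeMatrix(markers=markers, samples=list(samples), calls=np.vstack(call_blocks))


# --------------------------------------------------------------------------
# CDS / gene-model synthesis helpers
# --------------------------------------------------------------------------

def random_cds(n_codons: int, rng: np.random.Generator, overrides: dict[int, str] | None = None) -> str:
    """Random coding sequence: ATG start, no internal stops, TAA terminator.

    ``overrides`` maps 1-based codon indices to fixed triplets.
    """
    if n_codons < 3:
        raise ValueError("need at least start, one sense codon and stop")
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)
    codons = ["ATG"] + [_SENSE_CODONS[i] for i in idx] + ["TAA"]
    for ci, triplet in (overrides or {}).items():
        if not 1 <= ci <= n_codons:
            raise ValueError("override codon outside CDS")
        codons[ci - 1] = triplet
    return "".join(codons)


_AA = {c: str(Seq(c).translate()) for c in _CODONS}


def missense_alt(cds: str, cds_pos: int) -> tuple[str, str]:
    """(ref_base, alt_base) at a CDS position such that the change is missense."""
    ci = (cds_pos - 1) // 3
    off = (cds_pos - 1) % 3
    codon = cds[3 * ci : 3 * ci + 3]
    ref_aa = _AA[codon]
    for alt in _BASES:
        if alt == codon[off]:
            continue
        mutated = codon[:off] + alt + codon[off + 1 :]
        if _AA[mutated] not in ("*", ref_aa):
            return codon[off], alt
    raise ValueError("no missense substitution available at this position")


# --------------------------------------------------------------------------
# Family simulation
# --------------------------------------------------------------------------

@dataclass
class SimResult:
    config: SimConfig
    pedigree: Pedigree
    genome: PedigreeGenome
    genotypes: GenotypeMatrix
    variants: list[VariantRecord]
    truth: pd.DataFrame
    gene_models: list[GeneModel]
    cds_sequences: dict[str, str]
    causal_tract: tuple[int, int]
    plant_attempts: int


def _comphet_layout(config: SimConfig) -> dict:
    length = dict((c[0], c[1]) for c in config.chromosomes)[config.comphet_chrom]
    base = length // 2
    return {
        "chrom": config.comphet_chrom,
        "trans_exons": [(base + 19_901, base + 20_200), (base + 79_801, base + 80_100)],
        "trans_pos": (base + 20_000, base + 80_000),
        "cis_exons": [(base + 319_901, base + 320_200), (base + 379_801, base + 380_100)],
        "cis_pos": (base + 320_000, base + 380_000),
        "maternal_anchor": base + 200_000,
    }


def _family_constraints(ped: Pedigree, config: SimConfig) -> Constraints:
    cons = homozygous_transmission_constraints(
        ped, config.causal_founder_hap.split(".")[0], config.causal_founder_hap,
        config.causal_chrom, config.causal_pos, FAMILY_AFFECTEDS,
    )
    lay = _comphet_layout(config)
    want_trans = config.decoys.get("comphet_trans_pair", 0) > 0
    want_cis = config.decoys.get("comphet_cis_pair", 0) > 0
    if want_trans:
        cons = merge_constraints(
            cons,
            carrier_transmission_constraints(
                ped, "S1", "S1.0", lay["chrom"], lay["trans_pos"][0],
                via={"V1": "IV1", "V2": "IV1", "V3": "IV3"},
            ),
        )
    if want_trans or want_cis:
        cons = merge_constraints(
            cons,
            carrier_transmission_constraints(
                ped, "F2", "F2.0", lay["chrom"], lay["maternal_anchor"],
                via={"V1": "IV2", "V2": "IV2", "V3": "IV4"},
            ),
        )
    return cons


def _plant_ok(genome: PedigreeGenome, config: SimConfig) -> bool:
    lab, chrom, pos = config.causal_founder_hap, config.causal_chrom, config.causal_pos
    for aff in FAMILY_AFFECTEDS:
        if genome.carrier_count(aff, chrom, pos, lab) != 2:
            return False
    for parent in FAMILY_PARENTS:
        if genome.carrier_count(parent, chrom, pos, lab) != 1:
            return False
    lay = _comphet_layout(config)
    fathers, mothers = ("IV1", "IV3"), ("IV2", "IV4")
    if config.decoys.get("comphet_trans_pair", 0) > 0:
        pa, pb = lay["trans_pos"]
        for aff in FAMILY_AFFECTEDS:
            if genome.carrier_count(aff, lay["chrom"], pa, "S1.0") != 1:
                return False
            if genome.carrier_count(aff, lay["chrom"], pb, "F2.0") != 1:
                return False
        for f in fathers:
            if genome.carrier_count(f, lay["chrom"], pb, "F2.0") != 0:
                return False
    if config.decoys.get("comphet_cis_pair", 0) > 0:
        for p in lay["cis_pos"]:
            for aff in FAMILY_AFFECTEDS:
                if genome.carrier_count(aff, lay["chrom"], p, "F2.0") != 1:
                    return False
            for f in fathers:
                if genome.carrier_count(f, lay["chrom"], p, "F2.0") != 0:
                    return False
            for m in mothers:
                if genome.carrier_count(m, lay["chrom"], p, "F2.0") != 1:
                    return False
    return True


def _genotype_from_carriage(genome: PedigreeGenome, samples: Sequence[str],
                            chrom: str, pos: int, lab: str) -> dict[str, int]:
    codes = {0: HOM_REF, 1: HET, 2: HOM_ALT}
    return {s: codes[genome.carrier_count(s, chrom, pos, lab)] for s in samples}


def shared_causal_tract(genome: PedigreeGenome, config: SimConfig) -> tuple[int, int]:
    """Intersection over affecteds of the autozygous segment at the planted locus."""
    lo, hi = 1, config.rmap[config.causal_chrom].length_bp
    for aff in FAMILY_AFFECTEDS:
        for s, e in genome.autozygous_segments(aff, config.causal_chrom):
            if s <= config.causal_pos <= e:
                lo, hi = max(lo, s), min(hi, e)
                break
        else:
            raise PlantingError("planted locus not autozygous in all affecteds")
    return lo, hi


def synthesize_variant_table(
    genome: PedigreeGenome, config: SimConfig, rng: np.random.Generator,
    samples: Sequence[str] | None = None,
) -> tuple[list[VariantRecord], pd.DataFrame, list[GeneModel], dict[str, str]]:
    """The VCF-style table: planted stop-gain, decoys and comphet pairs.

    Truth labels (the stage of the recessive cascade expected to remove each
    decoy, or the expected comphet phase) are returned as a sidecar frame.
    """
    samples = list(samples) if samples is not None else list(genome.haplotypes)
    chrom, pos, lab = config.causal_chrom, config.causal_pos, config.causal_founder_hap
    lo, hi = shared_causal_tract(genome, config)
    records: list[VariantRecord] = []
    truth_rows: list[dict] = []
    gene_models: list[GeneModel] = []
    cds_seqs: dict[str, str] = {}

    # causal stop-gain: CDS arranged so the variant hits coding position 1881,
    # i.e. the third base of codon 627 (TGC -> TGA).
    n_codons = 2391  # 2390 residues + terminator
    cds = random_cds(n_codons, rng, overrides={627: "TGC"})
    cds_start = pos - 1880
    cds_end = cds_start + 3 * n_codons - 1
    gene_a = GeneModel(
        gene_id="GENE_A", chrom=chrom, strand="+",
        exons=[(cds_start - 200, cds_end + 200)],
        cds_start=cds_start, cds_end=cds_end, coding=True,
    )
    gene_models.append(gene_a)
    cds_seqs["GENE_A"] = cds
    records.append(VariantRecord(
        chrom=chrom, pos=pos, ref="C", alt="A", vid="causal_stopgain",
        genotypes=_genotype_from_carriage(genome, samples, chrom, pos, lab),
        population_af=None, in_segdup=False, cohort_hom_count=0,
    ))
    truth_rows.append({"variant_id": "causal_stopgain", "category": "causal",
                       "expected_outcome": "survivor"})

    # in-tract decoys ride the same founder haplotype (hom in affecteds) but
    # carry a disqualifying annotation.
    span = hi - lo
    frac_cycle = [0.30, 0.45, 0.60, 0.75, 0.20, 0.85]
    fi = 0

    def _next_pos() -> int:
        nonlocal fi
        p = lo + int(span * frac_cycle[fi % len(frac_cycle)]) + fi // len(frac_cycle)
        fi += 1
        return p if p != pos else p + 1

    decoy_specs = [
        ("common", dict(population_af=0.05, in_segdup=False, cohort_hom_count=0),
         "allele_frequency"),
        ("segdup", dict(population_af=0.001, in_segdup=True, cohort_hom_count=0),
         "segmental_duplication"),
        ("cohort_homozygous", dict(population_af=0.001, in_segdup=False, cohort_hom_count=3),
         "cohort_homozygote"),
    ]
    for cat, info, stage in decoy_specs:
        for k in range(config.decoys.get(cat, 0)):
            dpos = _next_pos()
            vid = f"decoy_{cat}_{k}"
            ref_i = int(rng.integers(0, 4))
            records.append(VariantRecord(
                chrom=chrom, pos=dpos, ref=_BASES[ref_i], alt=_BASES[(ref_i + 1) % 4],
                vid=vid,
                genotypes=_genotype_from_carriage(genome, samples, chrom, dpos, lab),
                **info,
            ))
            truth_rows.append({"variant_id": vid, "category": cat,
                               "expected_outcome": f"removed:{stage}"})

    # neutral rare decoys on the other chromosome: outside the shared autozygome
    other = config.comphet_chrom
    other_len = genome.rmap[other].length_bp
    founder_haps = sorted({seg[2] for ind in genome.haplotypes.values()
                           for ch in ind.values() for h in ch for seg in h})
    for k in range(config.decoys.get("neutral", 0)):
        dpos = int(other_len * (0.04 + 0.04 * k)) + 1
        carrier = founder_haps[int(rng.integers(0, len(founder_haps)))]
        ref_i = int(rng.integers(0, 4))
        vid = f"decoy_neutral_{k}"
        records.append(VariantRecord(
            chrom=other, pos=dpos, ref=_BASES[ref_i], alt=_BASES[(ref_i + 2) % 4],
            vid=vid,
            genotypes=_genotype_from_carriage(genome, samples, other, dpos, carrier),
            population_af=0.001, in_segdup=False, cohort_hom_count=0,
        ))
        truth_rows.append({"variant_id": vid, "category": "neutral",
                           "expected_outcome": "removed:shared_region"})

    # compound-het genes
    lay = _comphet_layout(config)
    if config.decoys.get("comphet_trans_pair", 0) > 0:
        cds_t = random_cds(200, rng)
        gene_t = GeneModel(
            gene_id="GENE_T", chrom=lay["chrom"], strand="+", exons=lay["trans_exons"],
            cds_start=lay["trans_exons"][0][0], cds_end=lay["trans_exons"][1][1], coding=True,
        )
        gene_models.append(gene_t)
        cds_seqs["GENE_T"] = cds_t
        for tag, vpos, carrier in (("a", lay["trans_pos"][0], "S1.0"),
                                   ("b", lay["trans_pos"][1], "F2.0")):
            cpos = gene_t.genomic_to_cds(vpos)
            ref, alt = missense_alt(cds_t, cpos)
            vid = f"comphet_trans_{tag}"
            records.append(VariantRecord(
                chrom=lay["chrom"], pos=vpos, ref=ref, alt=alt, vid=vid,
                genotypes=_genotype_from_carriage(genome, samples, lay["chrom"], vpos, carrier),
                population_af=0.002, in_segdup=False, cohort_hom_count=0,
            ))
            truth_rows.append({"variant_id": vid, "category": "comphet_trans_pair",
                               "expected_outcome": "phase:trans"})
    if config.decoys.get("comphet_cis_pair", 0) > 0:
        cds_c = random_cds(200, rng)
        gene_c = GeneModel(
            gene_id="GENE_C", chrom=lay["chrom"], strand="+", exons=lay["cis_exons"],
            cds_start=lay["cis_exons"][0][0], cds_end=lay["cis_exons"][1][1], coding=True,
        )
        gene_models.append(gene_c)
        cds_seqs["GENE_C"] = cds_c
        for tag, vpos in (("a", lay["cis_pos"][0]), ("b", lay["cis_pos"][1])):
            cpos = gene_c.genomic_to_cds(vpos)
            ref, alt = missense_alt(cds_c, cpos)
            vid = f"comphet_cis_{tag}"
            records.append(VariantRecord(
                chrom=lay["chrom"], pos=vpos, ref=ref, alt=alt, vid=vid,
                genotypes=_genotype_from_carriage(genome, samples, lay["chrom"], vpos, "F2.0"),
                population_af=0.002, in_segdup=False, cohort_hom_count=0,
            ))
            truth_rows.append({"variant_id": vid, "category": "comphet_cis_pair",
                               "expected_outcome": "phase:cis"})

    records.sort(key=lambda r: (r.chrom, r.pos))
    return records, pd.DataFrame(truth_rows), gene_models, cds_seqs


def simulate_family(config: SimConfig | None = None) -> SimResult:
    """End-to-end synthetic dataset for the index-family analysis."""
    config = config if config is not None else SimConfig()
    ped = build_family_pedigree()
    rmap = config.rmap
    rng = np.random.default_rng(config.seed)
    if config.plant_mode == "conditional":
        cons = _family_constraints(ped, config)
        for attempt in range(1, config.max_plant_attempts + 1):
            genome = gene_drop(ped, rmap, rng, constraints=cons)
            if _plant_ok(genome, config):
                break
        else:
            raise PlantingError(
                f"planting failed in {config.max_plant_attempts} conditional draws"
            )
    else:
        genome, attempt = rejection_plant(
            ped, rmap, lambda g: _plant_ok(g, config), config.seed,
            max_attempts=config.max_plant_attempts,
        )
    genotypes = synthesize_genotypes(genome, config, rng, samples=[m.id for m in ped.members])
    variants, truth, gene_models, cds_seqs = synthesize_variant_table(
        genome, config, rng, samples=[m.id for m in ped.members]
    )
    return SimResult(
        config=config, pedigree=ped, genome=genome, genotypes=genotypes,
        variants=variants, truth=truth, gene_models=gene_models,
        cds_sequences=cds_seqs, causal_tract=shared_causal_tract(genome, config),
        plant_attempts=attempt,
    )
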