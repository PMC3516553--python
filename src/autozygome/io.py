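"""Readers and writers for the formats the pipeline touches.

VCF (a v4.2 subset with AF/SEGDUP/COHORT_HOM INFO keys and GT genotypes) is
parsed with cyvcf2 after a light line-numbered validation pass; gene models
travel as a GFF3 subset parsed with gffutils; pedigrees as 6-column PED;
genotype matrices as TSV with 0/1/2/NA alternate-allele counts; regions as
BED3 (0-based half-open on disk, converted exactly to the 1-based inclusive
convention used internally).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotypes import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING
from .pedigree import PedMember, Pedigree
from .roh import ROHSegment, SharedRegion
from .variants import GeneModel, VariantRecord


class ParseError(ValueError):
    pass


# --------------------------------------------------------------------------
# Genotype TSV: marker_id, chrom, pos, then one column per sample (0/1/2/NA)
# --------------------------------------------------------------------------

_META_COLS = ["marker_id", "chrom", "pos"]


def write_genotype_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame({
        "marker_id": genotypes.markers["id"],
        "chrom": genotypes.markers["chrom"],
        "pos": genotypes.markers["pos"],
    })
    for i, sample in enumerate(genotypes.samples):
        col = genotypes.calls[:, i].astype(object)
        df[sample] = ["NA" if c == MISSING else str(c) for c in col]
    df.to_csv(path, sep="\t", index=False)


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA"])
    samples = [c for c in df.columns if c not in _META_COLS]
    calls = df[samples].to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    markers = pd.DataFrame({
        "chrom": df["chrom"], "pos": df["pos"].astype(int), "id": df["marker_id"],
    })
    return GenotypeMatrix(markers=markers, samples=samples, calls=calls)


# --------------------------------------------------------------------------
# PED 6-column
# --------------------------------------------------------------------------

_SEX_OUT = {"M": "1", "F": "2", "U": "0"}
_SEX_IN = {"1": "M", "2": "F", "0": "U"}


def write_ped(pedigree: Pedigree, path: str | Path) -> None:
    lines = []
    for m in pedigree.members:
        lines.append("\t".join([
            pedigree.family_id, m.id, m.father_id or "0", m.mother_id or "0",
            _SEX_OUT.get(m.sex, "0"), "2" if m.affected else "1",
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ped(path: str | Path) -> Pedigree:
    members = []
    family_id = "FAM1"
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 6:
            raise ParseError(f"{path}:{ln}: expected 6 PED columns, got {len(fields)}")
        family_id, iid, fid, mid, sex, phen = fields
        members.append(PedMember(
            id=iid,
            father_id=None if fid == "0" else fid,
            mother_id=None if mid == "0" else mid,
            sex=_SEX_IN.get(sex, "U"),
            affected=phen == "2",
        ))
    return Pedigree(members, family_id=family_id)


# --------------------------------------------------------------------------
# BED3 (0-based half-open on disk <-> 1-based inclusive internally)
# --------------------------------------------------------------------------

def write_bed(regions: Sequence, path: str | Path) -> None:
    lines = []
    for r in regions:
        if hasattr(r, "start_bp"):
            chrom, start, end = r.chrom, r.start_bp, r.end_bp
        else:
            chrom, start, end = r
        lines.append(f"{chrom}\t{start - 1}\t{end}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{ln}: expected >=3 BED columns")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        if start >= end:
            raise ParseError(f"{path}:{ln}: BED start must be < end")
        out.append((chrom, start + 1, end))
    return out


# --------------------------------------------------------------------------
# VCF v4.2 subset
# --------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AF,Number=A,Type=Float,Description="Population allele frequency">
##INFO=<ID=SEGDUP,Number=0,Type=Flag,Description="In a segmental duplication">
##INFO=<ID=COHORT_HOM,Number=1,Type=Integer,Description="Homozygote count in the sequencing cohort">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT_OUT = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
_GT_RE = re.compile(r"^(\.|\d+)([/|](\.|\d+))?$")


def write_vcf(variants: Sequence[VariantRecord], samples: Sequence[str],
              path: str | Path) -> None:
    lines = [_VCF_HEADER.rstrip("\n")]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    for v in sorted(variants, key=lambda x: (x.chrom, x.pos)):
        info = []
        if v.population_af is not None:
            info.append(f"AF={v.population_af:g}")
        if v.in_segdup:
            info.append("SEGDUP")
        if v.cohort_hom_count:
            info.append(f"COHORT_HOM={v.cohort_hom_count}")
        gts = "\t".join(_GT_OUT[v.genotypes.get(s, MISSING)] for s in samples)
        lines.append("\t".join([
            v.chrom, str(v.pos), v.vid, v.ref, v.alt, ".", ".",
            ";".join(info) or ".", "GT", gts,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def _prevalidate_vcf(path: str | Path) -> list[str]:
    """Cheap structural pass so malformed POS/GT name their line number."""
    samples: list[str] = []
    n_fixed = 9
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.startswith("##") or not line.strip():
            continue
        if line.startswith("#CHROM"):
            cols = line.lstrip("#").split("\t")
            samples = cols[n_fixed:]
            continue
        fields = line.split("\t")
        if len(fields) < 8:
            raise ParseError(f"{path}:{ln}: expected >=8 VCF columns")
        if not fields[1].isdigit():
            raise ParseError(f"{path}:{ln}: malformed POS {fields[1]!r}")
        if len(fields) > n_fixed:
            fmt = fields[8].split(":")
            if "GT" in fmt:
                gt_i = fmt.index("GT")
                for s_i, cell in enumerate(fields[n_fixed:]):
                    gt = cell.split(":")[gt_i]
                    if not _GT_RE.match(gt):
                        raise ParseError(f"{path}:{ln}: malformed GT {gt!r}")
    if not samples:
        raise ParseError(f"{path}: missing #CHROM header line declaring samples")
    return samples


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    """Parse the VCF subset; multi-allelic records are split into biallelic
    records with per-alternate AF. GT separators / and | are both accepted
    (phase is ignored); the FILTER column is ignored (call-level quality
    filtering belongs to the upstream caller)."""
    from cyvcf2 import VCF

    samples = _prevalidate_vcf(path)
    vcf = VCF(str(path))
    known_info = {"AF", "SEGDUP", "COHORT_HOM"}
    out: list[VariantRecord] = []
    for v in vcf:
        afs = v.INFO.get("AF")
        if afs is not None and not isinstance(afs, tuple):
            afs = (afs,)
        extra = {k: val for k, val in v.INFO if k not in known_info}
        gts = v.genotypes if len(samples) else []
        for ai, alt in enumerate(v.ALT):
            genotypes: dict[str, int] = {}
            for s, g in zip(samples, gts):
                alleles = [a for a in g[:-1] if a is not None]
                if not alleles or any(a < 0 for a in alleles):
                    genotypes[s] = MISSING
                else:
                    genotypes[s] = sum(a == ai + 1 for a in alleles)
            out.append(VariantRecord(
                chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt,
                vid=v.ID or f"{v.CHROM}:{v.POS}:{v.REF}:{alt}",
                genotypes=genotypes,
                population_af=float(afs[ai]) if afs is not None else None,
                in_segdup=bool(v.INFO.get("SEGDUP")),
                cohort_hom_count=int(v.INFO.get("COHORT_HOM") or 0),
                annotations=extra,
            ))
    vcf.close()
    return out, samples


# --------------------------------------------------------------------------
# GFF3 subset for gene models
# --------------------------------------------------------------------------

def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for m in models:
        attrs = f"ID=gene:{m.gene_id}"
        lines.append("\t".join([
            m.chrom, "autozygome", "gene", str(m.tx_start), str(m.tx_end),
            ".", m.strand, ".", attrs,
        ]))
        ttype = "mRNA" if m.coding else "ncRNA"
        tid = f"transcript:{m.gene_id}"
        lines.append("\t".join([
            m.chrom, "autozygome", ttype, str(m.tx_start), str(m.tx_end),
            ".", m.strand, ".", f"ID={tid};Parent=gene:{m.gene_id}",
        ]))
        for i, (s, e) in enumerate(m.exons):
            lines.append("\t".join([
                m.chrom, "autozygome", "exon", str(s), str(e), ".", m.strand,
                ".", f"ID=exon:{m.gene_id}.{i + 1};Parent={tid}",
            ]))
        if m.coding:
            phase = 0
            parts = []
            for s, e in m.exons:
                lo, hi = max(s, m.cds_start), min(e, m.cds_end)
                if lo <= hi:
                    parts.append((lo, hi))
            ordered = parts if m.strand == "+" else parts[::-1]
            for j, (lo, hi) in enumerate(ordered):
                lines.append("\t".join([
                    m.chrom, "autozygome", "CDS", str(lo), str(hi), ".",
                    m.strand, str(phase), f"ID=cds:{m.gene_id};Parent={tid}",
                ]))
                phase = (3 - ((hi - lo + 1 - phase) % 3)) % 3
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path, upstream_window_bp: int = 1000) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    models = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.id.split(":", 1)[-1]
        exons = sorted(
            (f.start, f.end) for f in db.children(gene, featuretype="exon")
        )
        cds = sorted(
            (f.start, f.end) for f in db.children(gene, featuretype="CDS")
        )
        if not exons:
            exons = [(gene.start, gene.end)]
        models.append(GeneModel(
            gene_id=gene_id, chrom=gene.seqid, strand=gene.strand,
            exons=exons,
            cds_start=cds[0][0] if cds else None,
            cds_end=cds[-1][1] if cds else None,
            coding=bool(cds),
            upstream_window_bp=upstream_window_bp,
        ))
    return models


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# --------------------------------------------------------------------------
# Report tables
# --------------------------------------------------------------------------

def regions_table(regions: Sequence[SharedRegion]) -> pd.DataFrame:
    """Region report in the style of a published ROH survey (1-based, size)."""
    return pd.DataFrame([
        {
            "region": f"{r.chrom}:{r.start_bp}-{r.end_bp}",
            "chrom": r.chrom, "start_bp": r.start_bp, "end_bp": r.end_bp,
            "size_bp": r.size,
            "excluded_by": r.excluded_by or "",
        }
        for r in regions
    ])


def roh_table(segments: Sequence[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "sample": s.sample, "chrom": s.chrom, "start_bp": s.start_bp,
            "end_bp": s.end_bp, "size_bp": s.size, "n_snp": s.n_snp,
            "n_het": s.n_het, "n_missing": s.n_missing,
        }
        for s in segments
    ])


# --------------------------------------------------------------------------
# YAML config round-trip
# --------------------------------------------------------------------------

def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def dump_yaml(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
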