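"""End-to-end orchestration: simulate -> ROH -> share/exclude -> filter -> comphet.

`run_analysis` performs the whole mapping in memory and `run_pipeline`
additionally writes the report artifacts (region survey TSV + BED,
functional class counts, survivor VCF, filter trace, comphet report and a
run manifest). Identical configuration and seed produce byte-identical
artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .comphet import CompHetPair, find_comphet_candidates, phase_by_parents, report_loci
from .genotypes import GenotypeMatrix
from .io import (dump_yaml, load_yaml, read_fasta, read_genotype_tsv, read_gff3,
                 read_ped, read_vcf, regions_table, roh_table, write_bed,
                 write_fasta, write_genotype_tsv, write_gff3, write_ped, write_vcf)
from .pedigree import Pedigree
from .roh import (PRESETS, RELAXED, STRINGENT, RohParams, SharedRegion,
                  detect_roh, exclude_unaffected, shared_autozygous_regions,
                  summarize_regions)
from .simulate import SimConfig, SimResult, simulate_family
from .variants import (FilterConfig, FilterTrace, FunctionalCall, GeneModel,
                       VariantRecord, apply_recessive_filters, classify_variant,
                       tally_classes)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


_ROH_FIELDS = {f.name for f in dataclasses.fields(RohParams)}
_SIM_FIELDS = {f.name for f in dataclasses.fields(SimConfig)}
_FILTER_FIELDS = {f.name for f in dataclasses.fields(FilterConfig)}


def _from_mapping(cls, data: Mapping, known: set[str], label: str):
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown {label} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; round-trips through YAML."""

    seed: int = 0
    simulate: bool = True
    affected: list[str] = field(default_factory=lambda: ["V1", "V2", "V3"])
    unaffected: list[str] = field(default_factory=lambda: ["IV1", "IV2", "IV3", "IV4"])
    sim: SimConfig = field(default_factory=SimConfig)
    roh_affected: RohParams = RELAXED
    roh_unaffected: RohParams = STRINGENT
    filter: FilterConfig = field(default_factory=FilterConfig)
    require_all_affecteds: bool = True
    require_trans: bool = True
    inputs: dict = field(default_factory=dict)  # genotypes/vcf/ped/gff3/cds paths
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.affected:
            raise ConfigError("affected sample list must not be empty")

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "sim" in data and isinstance(data["sim"], Mapping):
            sim = dict(data["sim"])
            if "chromosomes" in sim:
                sim["chromosomes"] = tuple(tuple(c) for c in sim["chromosomes"])
            if "af_range" in sim:
                sim["af_range"] = tuple(sim["af_range"])
            data["sim"] = _from_mapping(SimConfig, sim, _SIM_FIELDS, "sim")
        for key, klass, fields in (("roh_affected", RohParams, _ROH_FIELDS),
                                   ("roh_unaffected", RohParams, _ROH_FIELDS)):
            if key in data:
                if isinstance(data[key], str):
                    data[key] = PRESETS[data[key]]
                elif isinstance(data[key], Mapping):
                    data[key] = _from_mapping(klass, data[key], fields, key)
        if "filter" in data and isinstance(data["filter"], Mapping):
            data["filter"] = _from_mapping(FilterConfig, data["filter"],
                                           _FILTER_FIELDS, "filter")
        return cls(**data)

    def to_dict(self) -> dict:
        def plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [plain(x) for x in obj]
            if isinstance(obj, list):
                return [plain(x) for x in obj]
            return obj

        return {f.name: plain(getattr(self, f.name))
                for f in dataclasses.fields(self)}

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(load_yaml(path))


@dataclass
class AnalysisResult:
    roh_affected: dict[str, list]
    roh_unaffected: dict[str, list]
    shared: list[SharedRegion]
    retained: list[SharedRegion]
    summary: dict
    survivors: list[VariantRecord]
    trace: FilterTrace
    survivor_calls: dict[str, FunctionalCall]
    class_counts: dict
    comphet_pairs: list[CompHetPair]
    comphet_report: tuple[list[CompHetPair], dict[str, int]]


def run_analysis(
    genotypes: GenotypeMatrix,
    variants: Sequence[VariantRecord],
    pedigree: Pedigree,
    gene_models: Sequence[GeneModel],
    cds_sequences: Mapping[str, str],
    affected: Sequence[str],
    unaffected: Sequence[str],
    roh_affected: RohParams = RELAXED,
    roh_unaffected: RohParams = STRINGENT,
    filter_config: FilterConfig = FilterConfig(),
    require_all_affecteds: bool = True,
    require_trans: bool = True,
) -> AnalysisResult:
    """The full recessive-mapping analysis, in memory."""
    roh_aff = {s: detect_roh(genotypes, s, roh_affected) for s in affected}
    roh_unaff = {s: detect_roh(genotypes, s, roh_unaffected) for s in unaffected}
    shared = shared_autozygous_regions(roh_aff, genotypes)
    retained = exclude_unaffected(shared, roh_unaff)
    summary = summarize_regions(retained)
    survivors, trace = apply_recessive_filters(variants, retained, affected, filter_config)
    survivor_calls = {
        v.vid: classify_variant(v, gene_models, cds_sequences) for v in survivors
    }
    class_counts = tally_classes(list(survivor_calls.values()))
    all_calls = {v.vid: classify_variant(v, gene_models, cds_sequences) for v in variants}
    pairs = find_comphet_candidates(variants, all_calls, affected)
    pairs = [phase_by_parents(p, pedigree) for p in pairs]
    report = report_loci(pairs, affected, require_all_affecteds, require_trans)
    return AnalysisResult(
        roh_affected=roh_aff, roh_unaffected=roh_unaff, shared=shared,
        retained=retained, summary=summary, survivors=survivors, trace=trace,
        survivor_calls=survivor_calls, class_counts=class_counts,
        comphet_pairs=pairs, comphet_report=report,
    )


def _comphet_table(pairs: Sequence[CompHetPair]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "gene": p.gene_id, "variant_a": p.variant_a.vid,
            "variant_b": p.variant_b.vid,
            "affecteds": ",".join(p.affecteds_supporting),
            "phase": p.phase,
            "phasing_parents": ";".join(
                f"{k}:{'|'.join(v) or '-'}" for k, v in sorted(p.phasing_parents.items())
            ),
        }
        for p in pairs
    ])


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> AnalysisResult:
    """Run the analysis and write all artifacts under ``out_dir``."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.simulate:
        sim_config = dataclasses.replace(config.sim, seed=config.seed)
        sim = simulate_family(sim_config)
        pedigree, genotypes, variants = sim.pedigree, sim.genotypes, sim.variants
        gene_models, cds = sim.gene_models, sim.cds_sequences
        write_ped(pedigree, out / "family.ped")
        write_genotype_tsv(genotypes, out / "genotypes.tsv")
        write_vcf(variants, genotypes.samples, out / "variants.vcf")
        write_gff3(gene_models, out / "genes.gff3")
        write_fasta(cds, out / "cds.fasta")
        sim.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    else:
        required = {"genotypes", "vcf", "ped", "gff3", "cds"}
        missing = required - set(config.inputs)
        if missing:
            raise ConfigError(f"missing input paths: {sorted(missing)}")
        genotypes = read_genotype_tsv(config.inputs["genotypes"])
        variants, _ = read_vcf(config.inputs["vcf"])
        pedigree = read_ped(config.inputs["ped"])
        gene_models = read_gff3(config.inputs["gff3"])
        cds = read_fasta(config.inputs["cds"])
    for s in config.affected + config.unaffected:
        if s not in genotypes.samples:
            raise ConfigError(f"sample {s!r} not present in genotypes")

    result = run_analysis(
        genotypes, variants, pedigree, gene_models, cds,
        config.affected, config.unaffected,
        config.roh_affected, config.roh_unaffected, config.filter,
        config.require_all_affecteds, config.require_trans,
    )

    regions_table(result.retained).to_csv(out / "shared_regions.tsv", sep="\t", index=False)
    write_bed(result.retained, out / "shared_regions.bed")
    roh_table([seg for segs in result.roh_affected.values() for seg in segs]).to_csv(
        out / "roh_affected.tsv", sep="\t", index=False)
    write_vcf(result.survivors, genotypes.samples, out / "survivors.vcf")
    pd.DataFrame(
        [{"variant_id": vid, "outcome": stage}
         for vid, stage in sorted(result.trace.outcome.items())]
    ).to_csv(out / "filter_trace.tsv", sep="\t", index=False)
    counts = {k: v for k, v in result.class_counts.items() if k != "exonic_effects"}
    class_df = pd.DataFrame(sorted(counts.items()), columns=["functional_class", "n"])
    class_df.to_csv(out / "class_counts.tsv", sep="\t", index=False)
    _comphet_table(result.comphet_pairs).to_csv(out / "comphet.tsv", sep="\t", index=False)

    largest = result.summary["largest_region"]
    manifest = {
        "package": "autozygome",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "shared_regions": {
            "count": result.summary["count"],
            "total_bp": result.summary["total_bp"],
            "largest": None if largest is None else
            f"{largest.chrom}:{largest.start_bp}-{largest.end_bp}",
        },
        "filter_counts": result.trace.counts(),
        "comphet_gates": result.comphet_report[1],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return result
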