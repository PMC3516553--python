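# Methods

## Model and assumptions

The package targets the classical autozygosity-mapping setting: a fully
penetrant autosomal recessive disorder in a consanguineous family, with the
causal allele transmitted identical by descent (IBD) from a shared ancestor
to every affected individual. Two inheritance models are implemented: a
homozygous model (the causal variant is homozygous-alternate in every
affected and inside a region of shared autozygosity absent from unaffected
relatives) and a compound-heterozygous model (two different variants in one
gene, present in all affecteds and in trans). Autosomes only; X-linked
inheritance is out of scope.

## ROH detection

A homozygous region is defined directly — a run of at least `min_snp`
homozygous calls whose span (last marker position minus first) strictly
exceeds `min_span_bp`, containing at most `max_het` heterozygous and
`max_missing` missing calls, with homozygous markers at both boundaries —
rather than through PLINK's sliding-window vote heuristic. This is a
deliberate design choice: the run definition is the scientific object, and
an explicit maximal-run scanner can be verified exactly against a
brute-force oracle that enumerates every marker sub-interval, which the
test suite does on random instances. Runs are selected greedily left to
right (smallest qualifying start, then furthest reachable homozygous end),
making per-sample, per-chromosome output non-overlapping and deterministic.

Parameter presets:

| preset | min_snp | min_span_bp | max_het | max_missing | applied to |
|---|---|---|---|---|---|
| relaxed | 50 | 500,000 | 1 | 2 | affecteds |
| stringent | 500 | 5,000,000 | 0 | 0 | unaffecteds |

The relaxed run definition tolerates "some" heterozygous calls without a
published count; one heterozygous plus two missing calls per run is this
package's default and is configurable. Asymmetric presets encode the
asymmetric error costs: missing a true region in an affected loses the
disease locus, while a false parental region wrongly excludes one.

Region size is `end − start` (not `end − start + 1`); this is the
convention that reproduces the published per-region sizes exactly
(e.g. chr1:11,008,695–11,512,411 → 503,716 bp). Coordinates are 1-based
inclusive internally; BED export converts to 0-based half-open exactly.

## Sharing, allele matching, exclusion

Shared regions are maximal intervals covered by a run of every affected.
Inside each interval, allele matching requires every marker's non-missing
homozygous calls to agree across affecteds; heterozygous and missing calls
never break matching, since array data contain miscalls and the sharing
criterion is genotype identity, not completeness. Intervals failing
matching are dropped (kept only in diagnostic output). Shared regions
overlapping any stringent ROH of any unaffected relative are excluded, with
the excluding sample recorded. The summary reports count, total size and
the largest region, ties broken by (chromosome, start) for determinism.

## Recessive filter cascade

Five predicates in fixed order: (1) inside a retained shared region;
(2) homozygous-alternate in all affecteds; (3) population allele frequency
strictly greater than 1 % removes the variant (a frequency of exactly 1 %
is kept); (4) segmental-duplication flag; (5) homozygous occurrence in
other cohort samples (any count above zero). The predicates are independent,
so the order does not change the survivor set; it fixes the semantics of
the trace, which records each variant's first removing stage and whose
stage counts always sum to the input count. Unknown population frequency is
treated as rare and kept: absence from the reference panel is itself
evidence of rarity, and the filter's purpose is to remove *common*
variation. An empty region list yields an empty survivor set with a
warning, not an error.

## Functional classification

Each variant receives exactly one class with precedence
exonic > UTR > ncRNA > intronic > upstream > intergenic across overlapping
single-transcript gene models (multi-transcript collapsing is out of
scope). The upstream window defaults to 1,000 bp from the strand-aware
transcription start (an annotation-tool convention; configurable); there is
no downstream class, matching the class set used for reporting, and a 3'UTR
class is carried for totality even where reports contain none. For coding
SNVs, the coding position maps to codon ⌈pos/3⌉ and offset
((pos−1) mod 3)+1; reference and alternate codons are built on the coding
strand (reverse-complemented for minus-strand models), translated with the
standard code, and reported as stop-gained / synonymous / missense with an
HGVS-like amino-acid change (stop written `X`, as in C627X). A reference
allele disagreeing with the supplied CDS is an integrity error, not a
silent mismatch. Splice proximity is flagged within ±2 bp of an internal
exon boundary (the canonical splice dinucleotides). Indels get a
frame-based classification only (length difference mod 3); full protein
consequences for indels are out of scope.

## Compound-heterozygote phasing

Candidates are unordered pairs of distinct coding variants (exonic, or
splice-proximal; configurable) in one gene, heterozygous together in at
least one affected. Phasing uses parental carriage only: in a fully
genotyped trio, each parent carrying exactly one distinct variant of the
pair means trans; one parent carrying both and the other neither means cis;
anything else (missing genotypes, de novo patterns, both parents carrying
both) is unknown. When several trios are available and disagree, the phase
is unknown with a conflict flag — the package refuses to guess. Gates are
applied in order (all-affecteds, then trans) with per-gate locus counts,
which are monotone non-increasing.

## The simulator

Gene dropping assigns every founder two labelled haplotypes per chromosome
and transmits recombinant gametes down the pedigree under the Haldane
model: crossover count Poisson with mean equal to the genetic length in
Morgans, uniform positions, no interference, at a uniform 1 cM/Mb by
default. Child haplotypes are exact mosaics of the corresponding parent's
labels, so Mendelian consistency holds at every position by construction,
and the expected autozygous fraction of first-cousin offspring is the
kinship-theory value F = 1/16, which the tests verify to within 0.01 over
500 replicates.

The bundled family fixture has two affected siblings (V1, V2) and their
affected first cousin (V3); the fathers IV1 and IV3 are brothers, and both
mothers descend from the same founder couple as the fathers, so one founder
haplotype can reach all three affecteds homozygously. The real family's
consanguinity loops are not fully enumerable from the published
description; this is the minimal structure consistent with the stated
sibship and first-cousin relations, and results on it should be read as
structure-level validation, not as a reconstruction of the actual family.

Default study conditions (all configurable): two 100-Mb autosomes at
1 cM/Mb; 10,000 markers per chromosome (one per 10 kb, the genome-wide
density of a ~300k SNP array); marker alternate-allele frequencies uniform
on [0.05, 0.5], independent across markers (no linkage-disequilibrium
structure); symmetric genotyping error 0.001 (hom→het and het→hom at equal
rate, so the expected heterozygous-call count inside an autozygous tract is
Binomial(n, 0.001)); missing rate 0 (emulating a panel already stripped of
markers with missing calls, as array QC does). The scaled-down genome keeps
the default test and acceptance runs fast while preserving every structural
property the algorithms depend on; because it is 15× smaller than a real
genome, per-run region counts and total shared sizes are not comparable to
the published family's 20 regions / 17.1 Mb — those are checked exactly
from the bundled published survey instead.

**Planting.** Transmitting one founder haplotype homozygously to all three
affecteds requires thirteen specific meioses to cooperate
(probability 2⁻¹³ per unconstrained realization), so the default
`plant_mode="conditional"` draws each constrained meiosis conditionally on
carrying the required founder label at the planted locus: the crossover
process is drawn unconditionally and only the uniform starting-phase bit is
conditioned, an exact draw from the conditional law, since phase is
independent of crossover positions. The compound-het plantings (trans pair:
one variant through the paternal line, one through the maternal; cis pair:
both maternal) are anchored the same way, with a bounded redraw loop for
the residual conditions conditioning cannot guarantee (e.g. a father
independently inheriting the maternal-line haplotype, which would confound
phasing). A `plant_mode="rejection"` that simply redraws unconstrained
realizations is provided and tested; it is impractical for the full family
but matches the conditional sampler's target distribution by construction.
Decoy variants are placed truthfully: in-tract decoys ride the causal
founder haplotype (hence homozygous in affecteds) and carry the
disqualifying annotation for their stage; neutral decoys sit on the other
chromosome; a truth sidecar records each variant's expected outcome.

What passing simulated tests does *not* show: performance on real array
data with linkage disequilibrium, population-level allele sharing between
unrelated haplotypes (which lengthens chance ROH), genotyping artefacts
beyond symmetric error, or PLINK's exact windowed behaviour.

## Numerical and degenerate-input choices

Same seed, byte-identical outputs, end to end (the manifest records seed
and parameters, no timestamps). Empty marker sets, empty region lists and
empty candidate lists return empty results or zero counts rather than
erroring. A single affected's "shared" regions are its own runs. Largest-
region ties break by (chromosome, start). The VCF FILTER column is ignored
on read — call-level quality filtering belongs to the upstream caller.
Chromosome names are compared as given; the bundled survey uses `chr`
prefixes.

## Known limitations

Single transcript per gene; no LD-structured haplotypes; no read-backed or
statistical phasing (parental carriage only, as in the trio criterion
implemented); conservation and pathogenicity scores are pass-through
annotations, never computed; sex chromosomes unsupported. The published
13-locus compound-het count depended on a private cohort's frequency data
and is therefore not a reproducible quantity; the phasing logic itself is
validated on simulated truth instead.
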