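# Methods

## Scope and model

`famprio` analyses one nuclear family at a time under a fully penetrant
autosomal recessive model: every affected individual carries two defective
alleles of the causal gene (homozygous, or two different variants in
trans), every unaffected individual does not. Sex chromosomes are accepted
in input but excluded from recessive calling; X-linked, imprinting and
mosaic models are out of scope, as are read-level steps (mapping, variant
calling, CNV analysis) and the computation of in-silico predictor scores,
which are consumed as an opaque input table.

Coordinates are 1-based inclusive everywhere internally (the VCF
convention); only BED output is 0-based half-open. Variant identity is
`(contig, pos, REF, ALT)` after uppercasing and stripping a leading `chr`;
indels are required to arrive left-normalized and biallelic records are
produced by decomposing multi-allelic input, so set subtraction and
intersection are well-defined string operations. No indel
re-normalization is attempted.

## Filtering funnel

Stages run in a fixed order: site mapping quality (MQ ≥ 20, the only
site-level quality filter; QUAL/FILTER are parsed but unused), impact
class, database subtraction in the configured order, then panel
restriction. Two descriptive pre-stage counts (raw variants,
gene-overlapping variants) are reported but filter nothing. Design points:

* **Missing MQ** retains the variant and increments a warning counter:
  absence of an annotation is not evidence of poor mapping, but it must be
  auditable.
* **Database semantics.** A frequency catalogue stores MAFs; a small
  control-exome set stores membership only (`PRESENT`), because with a few
  dozen individuals presence is meaningful while a frequency estimate is
  not. The default `maf_exclusion_threshold = 0.0` makes any catalogued
  frequency exclusionary — the strict "novel variants only" screen.  It is
  configurable because a variant catalogued at very low frequency can
  still be pathogenic for a recessive gene.
* Subtraction is genotype-blind (site/allele presence), matching how
  variant lists, not genotypes, are filtered in practice.
* The final sets are order-invariant across database orderings (set
  difference commutes); the intermediate funnel counts follow whatever
  order is configured. `run_pipeline` also accepts `late_dbs`, applied
  after sibling intersection, for catalogues consulted only when vetting
  the final shared candidates.

## Annotation

One transcript per gene. A gene model carries exons (genomic order), a
CDS interval and the spliced, strand-corrected CDS sequence; coding SNVs
are classified by translating the affected codon before and after the
change (stop-gain and stop-loss are both reported as NONSENSE to keep the
class set small), indels by length modulo 3. Intronic positions within
`splice_window` (default 2, the canonical donor/acceptor dinucleotide) of
an exon boundary are SPLICE; ties between donor and acceptor distance
resolve to the donor side. cDNA labels follow HGVS conventions
(`c.6437G>A`, `c.4320+1G>A`) with the legacy IVS alias numbered by the
preceding exon in transcript order (`IVS11+1`). A REF allele that
contradicts the CDS sequence raises an error rather than annotating:
that always means mismatched inputs. Protein-domain labels come from a
residue-interval map; splice variants are mapped through their nearest
CDS base.

## Family logic

Sharing intersects the affected siblings' final variant-key sets
(presence-based); genotype requirements are then applied per gene by
`call_recessive`. A missing genotype counts as non-carrier wherever
presence is required, but every affected call carries a missingness flag
so the decision is auditable. Genes with ≥ 3 shared heterozygous variants
emit all pairs, flagged, ranked with trans-confirmed pairs first.

Trans confirmation demands each parent heterozygous for exactly one
distinct member of the pair: a homozygous parent could have transmitted
either haplotype, so such configurations stay `PHASE_UNKNOWN` rather than
confirmed. A pair carried entirely by one parent (the other parent
carrying neither) is `CIS_REJECTED` and excluded from the causative
report, though retained in audit output. Under full penetrance an
unaffected sampled individual carrying the complete causal genotype marks
the call `INCONSISTENT`. A lone shared heterozygote is reported as
`SINGLE_HET_UNCERTAIN` with unknown phase — the second allele may sit in
an unsequenced region, which is why the coverage audit exists.

Control carrier counting is presence-based (het or hom counts as a
carrier); a cohort never genotyped at a key counts zero carriers by
convention.

## Coverage audit

A gap is a maximal run of bases with depth strictly below
`depth_gap_threshold` (default 5). Gene-level audits scan exons padded by
the splice window, so donor/acceptor sites — where a causal splice variant
would sit — are always audited; deeper intronic holes are ignored.
Coverage summaries use ≥ t semantics uniformly for every threshold
(default t ∈ {1, 10}) and are reported per sample, with pooling across
tracks.

## Synthetic data generator

`simulate_family` produces a family exome whose statistical structure
matches what the pipeline assumes, with a truth set for every planted
feature. Defaults are the study conditions the package is tested under:

| parameter | default | rationale |
|---|---|---|
| background sites per family | 300 | a post-triage protein-affecting exome at toy scale |
| background MAF | uniform(0.01, 0.5) | common-to-low-frequency polymorphism background |
| catalogue membership | 0.9 (1.0 in panel genes) | most standing variation is catalogued; curated disease genes are the best-studied regions, and forcing full catalogue coverage there keeps the planted variants the only novel panel alleles |
| control-exome membership | 0.5 | a small control set catches population-specific alleles the catalogue misses, independently of it |
| low-MQ decoy fraction | 0.05 | exercises the quality stage |
| control cohort | 409 individuals | the carrier-screen size the report format is built around |
| depth | Poisson(56) with 10 planted low regions of 90 bp | mid-50s mean coverage with ~10% of bases under 10× |

Founders draw haplotypes per site under Hardy–Weinberg; children inherit
one allele per parent. Sites are transmitted independently (no linkage
structure) *except* inside the causal gene, where each parent contributes
a single haplotype per child — no intra-gene recombination — which is what
makes the planted cis decoy pair co-segregate and lets segregation logic
be exercised honestly. Phase is tracked internally but the VCF is emitted
unphased, so the pipeline must re-infer trans configuration from parents.
Affection status is part of the pedigree specification (an ascertained
family), not simulated from genotypes: transmissions at the causal gene
are rejection-sampled (capped at 10⁴ draws) until affected children carry
the causal genotype and unaffected children do not.

The compound-het plant places a splice-donor +1 variant on one maternal
haplotype and a missense variant on one paternal haplotype of a 17-exon
toy gene whose first 11 exons carry 4320 coding bases (so the donor site
is c.4320+1/IVS11+1). Decoys ride the two causal haplotypes: a catalogued
MAF-0.002 missense (removed by catalogue subtraction), a
control-exome-present missense (removed at the control stage), and a cis
pair on the paternal causal haplotype (reaches candidate calling, must be
rejected as cis). Mixed pairs of one maternal and one paternal planted
allele are genuinely in trans and are confirmed as such; recovery tests
therefore assert that the planted pair is confirmed and that every
trans-confirmed call falls in the planted gene. Planted alleles are absent
from both databases and from all simulated controls (family-private).
Identical configurations (including the seed) give byte-identical output
files.

What the generator does **not** emulate: sequencing error and genotype
miscalls, linkage disequilibrium among background sites, indel background
variation, population stratification between family and controls, and
realistic exome-wide variant counts (tens of thousands of raw sites) — the
funnel's *shape* is reproduced at a few-hundred-site scale so the full
test suite runs in seconds. Passing tests therefore demonstrate the
correctness of the filtering, sharing, phasing and audit logic under clean
genotypes, not robustness to caller noise.

## Numerical and degenerate-input choices

* Funnel counts are asserted non-increasing across filtering stages at
  record time; descriptive pre-stages are exempt.
* `find_gaps` with threshold 0 is empty by construction; an all-zero track
  is one whole-interval gap. Coverage summaries on empty track sets raise.
* An empty affected-sample list yields an empty analysis with a warning
  rather than an error; an affected sample missing from the VCF is an
  error.
* Exit codes 0/3/4 (confirmed / uncertain only / none) map the three
  possible family outcomes so batch screens can triage on exit status.
* Worked-example inputs with unpublished coordinates use synthetic
  positions, marked as such in `famprio.examples`; published positions are
  used verbatim.
* The acceptance script derives all replicate seeds from `--seed` via
  `numpy.random.SeedSequence` and runs 20 recovery replicates — enough to
  detect any systematic phasing failure while keeping runtime in seconds.
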