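"""Seeded simulator for family exomes with known ground truth.

The generator emulates the statistical structure a family-based recessive
variant-prioritization analysis assumes, without any external reference
data:

* a toy genome of single-transcript gene models (one large deafness-panel
  gene with 17 coding exons, a few smaller panel genes, and background
  genes), each with a deterministic coding sequence;
* background variation: sites with minor allele frequencies drawn from a
  declared distribution, mostly present in a frequency catalogue and/or a
  small control-exome membership set, plus a configurable fraction of
  low-mapping-quality decoy sites;
* Mendelian transmission: founders draw genotypes from per-site MAFs under
  Hardy–Weinberg; children inherit one allele per parent.  Haplotype phase
  is tracked internally but the VCF is emitted unphased, so downstream
  phasing must be re-inferred from parental genotypes;
* a planted causal genotype in a panel gene, absent from every database
  and from all simulated controls: by default a compound-heterozygous pair
  (one splice-donor +1 variant, one missense) on opposite parental
  haplotypes, heterozygous in every affected child;
* decoy features that each later pipeline stage must remove: a shared
  panel-gene variant catalogued at MAF 0.002, a control-exome-present
  variant, and a cis-configured pair riding the same parental haplotype as
  the causal missense allele;
* per-base depth tracks over the causal gene with planted low-coverage
  regions (read depth below the gap threshold).

Within the causal gene, transmission uses a single haplotype choice per
parent per child (no intra-gene recombination), which is what makes the
cis decoy co-segregate; all other sites are transmitted independently.
Identical configurations (including the seed) produce byte-identical
output files.
"""

from __future__ import annotations

import itertools
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .annotate import classify_variant
from .core import (
    GeneModel,
    ImpactClass,
    Individual,
    Pedigree,
    PipelineConfig,
    Variant,
    VariantKey,
    normalize_contig,
)
from .coverage import DepthTrack
from .inheritance import ControlCohort
from .io import PopulationDB

_STOPS = {"TAA", "TAG", "TGA"}
NON_STOP_CODONS = sorted(
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in _STOPS
)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


# ---------------------------------------------------------------------------
# Toy genome
# ---------------------------------------------------------------------------

def _filler_codons(symbol: str, n_codons: int) -> list[str]:
    """Deterministic non-stop filler codons, seeded from the gene symbol."""
    rng = np.random.default_rng(zlib.crc32(symbol.encode()) & 0x7FFFFFFF)
    return [NON_STOP_CODONS[i] for i in rng.integers(0, len(NON_STOP_CODONS), n_codons)]


def toy_gene(
    symbol: str,
    contig: str,
    start: int,
    exon_lengths: Sequence[int],
    strand: str = "+",
    intron_length: int = 150,
    special_codons: Optional[dict[int, str]] = None,
) -> GeneModel:
    """Build a gene model whose CDS covers its exons exactly.

    ``special_codons`` pins selected codon numbers (1-based) to fixed
    triplets; everything else is deterministic filler without in-frame
    stops.  The total exon length must be a multiple of 3.
    """
    cds_len = sum(exon_lengths)
    if cds_len % 3:
        raise ValueError("exon lengths must sum to a multiple of 3")
    codons = _filler_codons(symbol, cds_len // 3)
    for number, triplet in (special_codons or {}).items():
        codons[number - 1] = triplet
    exons = []
    pos = start
    for length in exon_lengths:
        exons.append((pos, pos + length - 1))
        pos += length + intron_length
    return GeneModel(
        symbol=symbol,
        contig=contig,
        strand=strand,
        exons=tuple(exons),
        cds_interval=(exons[0][0], exons[-1][1]),
        cds_sequence="".join(codons),
    )


def causal_panel_gene(symbol: str = "MYO15A") -> GeneModel:
    """The large 17-exon toy deafness gene used as the default causal gene.

    Its first 11 exons carry 4320 coding bases, so the donor +1 site after
    exon 11 is c.4320+1 (IVS11+1); codon 2146 is arginine (CGG) and codon
    2161 serine (TCC), mirroring the reference positions the worked
    examples use.  Total CDS: 2162 codons ending in a stop.
    """
    return toy_gene(
        symbol,
        contig="17",
        start=18_030_000,
        exon_lengths=[393] * 10 + [390] + [361] * 6,
        special_codons={2146: "CGG", 2161: "TCC", 2162: "TAA"},
    )


DEFAULT_PANEL = ("MYO15A", "GJB2", "SLC26A4", "OTOF", "TECTA", "GRHL2")


def toy_genome(
    panel_genes: Sequence[str] = DEFAULT_PANEL,
    n_background_genes: int = 20,
    causal_gene: str = "MYO15A",
) -> dict[str, GeneModel]:
    """Panel genes plus background genes on non-overlapping toy loci."""
    models: dict[str, GeneModel] = {}
    slot = 0

    def place(symbol: str, exon_lengths: Sequence[int], strand: str = "+") -> None:
        nonlocal slot
        contig = str(slot % 22 + 1)
        start = 1_000_000 + (slot // 22) * 200_000
        models[symbol] = toy_gene(symbol, contig, start, exon_lengths, strand=strand)
        slot += 1

    for symbol in panel_genes:
        if symbol == causal_gene:
            models[symbol] = causal_panel_gene(symbol)
        else:
            place(symbol, [150] * 4)
    for i in range(n_background_genes):
        # a sprinkling of minus-strand genes keeps strand handling honest
        place(f"BG{i + 1:03d}", [150] * 4, strand="-" if i % 5 == 4 else "+")
    return models


# ---------------------------------------------------------------------------
# Configuration and truth
# ---------------------------------------------------------------------------

class IndividualSpec(BaseModel):
    id: str
    father: Optional[str] = None
    mother: Optional[str] = None
    sex: str = "0"
    affected: bool = False
    sample_available: bool = True


def quartet_pedigree(prefix: str = "SIM-903") -> list[IndividualSpec]:
    """Two unaffected parents, two affected siblings, all sampled."""
    return [
        IndividualSpec(id=f"{prefix}F", sex="1"),
        IndividualSpec(id=f"{prefix}M", sex="2"),
        IndividualSpec(id=prefix, father=f"{prefix}F", mother=f"{prefix}M", sex="1", affected=True),
        IndividualSpec(id=f"{prefix}B", father=f"{prefix}F", mother=f"{prefix}M", sex="2", affected=True),
    ]


def sib_pair_pedigree(prefix: str = "SIM-285") -> list[IndividualSpec]:
    """Affected sib pair whose parents are in the pedigree but unsampled."""
    return [
        IndividualSpec(id=f"{prefix}F", sex="1", sample_available=False),
        IndividualSpec(id=f"{prefix}M", sex="2", sample_available=False),
        IndividualSpec(id=prefix, father=f"{prefix}F", mother=f"{prefix}M", sex="1", affected=True),
        IndividualSpec(id=f"{prefix}S", father=f"{prefix}F", mother=f"{prefix}M", sex="2", affected=True),
    ]


class SimulationConfig(BaseModel):
    """Study conditions for one simulated family.

    Defaults emulate the structure of a small exome study of an ascertained
    recessive family: a few hundred protein-affecting background sites per
    exome (after upstream triage), most of them catalogued, a planted
    compound-het pair in a panel gene private to the family, 409 unrelated
    controls, and depth tracks averaging 56x with planted dropouts.
    """

    family_id: str = "SIM-903"
    individuals: list[IndividualSpec] = Field(default_factory=quartet_pedigree)
    panel_genes: tuple[str, ...] = DEFAULT_PANEL
    n_background_genes: int = 20
    n_background_variants: int = 300
    catalogue_fraction: float = Field(default=0.9, ge=0.0, le=1.0)
    control_exome_fraction: float = Field(default=0.5, ge=0.0, le=1.0)
    maf_range: tuple[float, float] = (0.01, 0.5)
    low_mq_fraction: float = Field(default=0.05, ge=0.0, le=1.0)
    causal_model: Literal["COMPOUND_HET", "HOMOZYGOUS", "SINGLE_HET", "NONE"] = "COMPOUND_HET"
    causal_gene: str = "MYO15A"
    with_decoys: bool = True
    control_cohort_size: int = Field(default=409, ge=0)
    mean_depth: float = 56.0
    low_depth_region_count: int = 10
    low_depth_region_length: int = 90
    random_seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.causal_model != "NONE" and self.causal_gene not in self.panel_genes:
            raise ValueError("causal gene must be on the panel when a causal model is set")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 1")
        return self


@dataclass
class TruthSet:
    """Ground truth for one simulated family, the oracle for every test."""

    causal_gene: Optional[str]
    causal_keys: list[VariantKey]
    planted_genotypes: dict[str, dict[str, int]]  # individual -> key-string -> count
    maf_decoy_key: Optional[VariantKey] = None
    cis_decoy_keys: Optional[tuple[VariantKey, VariantKey]] = None
    control_decoy_key: Optional[VariantKey] = None
    background_keys: list[VariantKey] = field(default_factory=list)
    background_mafs: dict[VariantKey, float] = field(default_factory=dict)

    def to_json(self) -> str:
        def k2s(key: Optional[VariantKey]) -> Optional[str]:
            return None if key is None else ":".join(map(str, key))

        payload = {
            "causal_gene": self.causal_gene,
            "causal_keys": [k2s(k) for k in self.causal_keys],
            "planted_genotypes": self.planted_genotypes,
            "maf_decoy_key": k2s(self.maf_decoy_key),
            "cis_decoy_keys": (
                None
                if self.cis_decoy_keys is None
                else [k2s(k) for k in self.cis_decoy_keys]
            ),
            "control_decoy_key": k2s(self.control_decoy_key),
            "background_keys": [k2s(k) for k in self.background_keys],
        }
        return json.dumps(payload, indent=1)


@dataclass
class _Site:
    contig: str
    pos: int
    ref: str
    alt: str
    gene: str
    role: str  # background / causal_* / *_decoy
    maf: Optional[float]  # population MAF used for founder draws (None: private)
    catalogue_maf: Optional[float]  # None = not catalogued; value may be 0-freq sentinel
    in_catalogue: bool = False
    in_control: bool = False
    mq: float = 45.0

    @property
    def key(self) -> VariantKey:
        return (normalize_contig(self.contig), self.pos, self.ref, self.alt)


def _contig_sort_key(contig: str) -> tuple[int, str]:
    c = normalize_contig(contig)
    return (0, f"{int(c):03d}") if c.isdigit() else (1, c)


def _genomic_allele(base: str, strand: str) -> str:
    return base if strand == "+" else base.translate(_COMPLEMENT)


def _cds_site(
    gene: GeneModel, cds_index: int, alt_cds_base: str
) -> tuple[int, str, str]:
    """(genomic pos, genomic ref, genomic alt) for a CDS substitution."""
    positions = gene.cds_genomic_positions()
    pos = positions[cds_index - 1]
    ref = _genomic_allele(gene.cds_sequence[cds_index - 1], gene.strand)
    alt = _genomic_allele(alt_cds_base, gene.strand)
    return pos, ref, alt


def _pick_coding_change(
    gene: GeneModel,
    codon_number: int,
    wanted: ImpactClass,
    cfg: PipelineConfig,
) -> tuple[int, str, str]:
    """Deterministically find a substitution in a codon with the wanted
    impact class, by scanning positions and alternate bases in order."""
    for offset in range(3):
        cds_index = (codon_number - 1) * 3 + offset + 1
        ref_base = gene.cds_sequence[cds_index - 1]
        for alt_base in "ACGT":
            if alt_base == ref_base:
                continue
            pos, ref, alt = _cds_site(gene, cds_index, alt_base)
            v = Variant(contig=gene.contig, pos=pos, ref=ref, alt=alt)
            if classify_variant(v, gene, cfg).impact_class is wanted:
                return pos, ref, alt
    raise ValueError(f"no {wanted.value} substitution found in codon {codon_number}")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class FamilySimulation:
    """In-memory result of one family simulation, with file writers."""

    config: SimulationConfig
    pedigree: Pedigree
    gene_models: dict[str, GeneModel]
    variants: list[Variant]
    samples: list[str]
    catalogue_db: PopulationDB
    control_db: PopulationDB
    depth_tracks: list[DepthTrack]
    controls: ControlCohort
    truth: TruthSet

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        from . import io as fio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out / "family.vcf",
            "ped": out / "family.ped",
            "catalogue": out / "catalogue.tsv",
            "control_exome": out / "control_exome.tsv",
            "panel": out / "panel.tsv",
            "gene_models": out / "gene_models.json",
            "depth": out / "depth.tsv",
            "controls": out / "controls.tsv",
            "truth": out / "truth.json",
        }
        fio.write_vcf(self.variants, self.samples, paths["vcf"])
        fio.write_ped(self.pedigree, self.config.family_id, paths["ped"])
        fio.write_population_db(self.catalogue_db, paths["catalogue"])
        fio.write_population_db(self.control_db, paths["control_exome"])
        paths["panel"].write_text("".join(f"{g}\n" for g in self.config.panel_genes))
        fio.write_gene_models(self.gene_models, paths["gene_models"])
        fio.write_depth_track(self.depth_tracks, paths["depth"])
        write_control_cohort(self.controls, paths["controls"])
        paths["truth"].write_text(self.truth.to_json() + "\n")
        return paths


def write_control_cohort(cohort: ControlCohort, path: str | Path) -> None:
    """TSV ``contig pos ref alt genotypes`` with comma-separated allele
    counts, one column value per control individual."""
    with open(path, "w") as fh:
        fh.write(f"#n_individuals={cohort.n_individuals}\n")
        for key in sorted(cohort.genotypes):
            counts = ",".join(str(int(g)) for g in cohort.genotypes[key])
            contig, pos, ref, alt = key
            fh.write(f"{contig}\t{pos}\t{ref}\t{alt}\t{counts}\n")


def read_control_cohort(path: str | Path) -> ControlCohort:
    n = None
    genotypes: dict[VariantKey, np.ndarray] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#n_individuals="):
                n = int(line.split("=", 1)[1])
                continue
            if not line or line.startswith("#"):
                continue
            contig, pos, ref, alt, counts = line.split("\t")
            arr = np.array([int(x) for x in counts.split(",")] if counts else [], dtype=np.int8)
            genotypes[(normalize_contig(contig), int(pos), ref, alt)] = arr
    if n is None:
        n = len(next(iter(genotypes.values()))) if genotypes else 0
    return ControlCohort(n_individuals=n, genotypes=genotypes)


class SimulationError(RuntimeError):
    pass


def _build_pedigree(specs: Sequence[IndividualSpec]) -> Pedigree:
    individuals = [
        Individual(
            id=s.id,
            father=s.father,
            mother=s.mother,
            sex=s.sex,
            affected=s.affected,
            sample_available=s.sample_available,
        )
        for s in specs
    ]
    ped = Pedigree(individuals)
    for ind in individuals:
        if (ind.father is None) != (ind.mother is None):
            raise SimulationError(f"{ind.id}: both parents or neither must be specified")
    return ped


def _plant_causal_and_decoys(
    cfg: SimulationConfig, gene: GeneModel, pipeline_cfg: PipelineConfig
) -> tuple[list[_Site], dict[str, str]]:
    """Sites for the causal model plus the decoy features.

    Returns the planted sites and a role → parental-haplotype assignment
    ('father'/'mother'), used when seeding founder haplotypes.  The cis
    decoy pair and the control decoy ride the father's causal haplotype;
    the MAF decoy rides the mother's, so every planted site is
    automatically co-inherited with the causal alleles by each affected
    child.
    """
    sites: list[_Site] = []
    parent_of: dict[str, str] = {}
    n_codons = len(gene.cds_sequence) // 3

    def missense(codon: int, role: str) -> _Site:
        pos, ref, alt = _pick_coding_change(gene, codon, ImpactClass.MISSENSE, pipeline_cfg)
        return _Site(gene.contig, pos, ref, alt, gene.symbol, role, None, None)

    if cfg.causal_model == "COMPOUND_HET":
        # splice-donor +1 after an interior exon (exon 11 on the big toy gene)
        donor_exon = 10 if len(gene.exons) >= 12 else 0
        if gene.strand == "+":
            splice_pos = gene.exons[donor_exon][1] + 1
        else:
            splice_pos = gene.exons[len(gene.exons) - 1 - donor_exon][0] - 1
        sites.append(
            _Site(gene.contig, splice_pos, "G", "A", gene.symbol, "causal_splice", None, None)
        )
        parent_of["causal_splice"] = "mother"
        codon = min(2146, n_codons - 1)
        sites.append(missense(codon, "causal_missense"))
        parent_of["causal_missense"] = "father"
    elif cfg.causal_model == "HOMOZYGOUS":
        sites.append(missense(min(2146, n_codons - 1), "causal_hom"))
        parent_of["causal_hom"] = "both"
    elif cfg.causal_model == "SINGLE_HET":
        codon = min(2161, n_codons - 1)
        sites.append(missense(codon, "causal_single"))
        parent_of["causal_single"] = "mother"

    if cfg.with_decoys and cfg.causal_model != "NONE":
        maf_decoy = missense(min(1800, n_codons - 2), "maf_decoy")
        maf_decoy.catalogue_maf = 0.002
        maf_decoy.in_catalogue = True
        sites.append(maf_decoy)
        parent_of["maf_decoy"] = "mother"

        control_decoy = missense(min(900, n_codons - 3), "control_decoy")
        control_decoy.in_control = True
        sites.append(control_decoy)
        parent_of["control_decoy"] = "father"

        cis1 = missense(min(400, n_codons - 4), "cis_decoy_1")
        cis2 = missense(min(600, n_codons - 5), "cis_decoy_2")
        sites.extend([cis1, cis2])
        parent_of["cis_decoy_1"] = "father"
        parent_of["cis_decoy_2"] = "father"
    return sites, parent_of


def simulate_family(cfg: SimulationConfig) -> FamilySimulation:
    """Generate one family exome with truth set, databases, controls and
    depth tracks.  Deterministic given the config (including its seed)."""
    rng = np.random.default_rng(cfg.random_seed)
    pipeline_cfg = PipelineConfig()
    pedigree = _build_pedigree(cfg.individuals)
    models = toy_genome(cfg.panel_genes, cfg.n_background_genes, cfg.causal_gene)
    gene_list = list(models.values())
    causal = models[cfg.causal_gene] if cfg.causal_model != "NONE" else None

    # ---- background sites -------------------------------------------------
    sites: list[_Site] = []
    used_positions: set[tuple[str, int]] = set()
    planted: list[_Site] = []
    parent_of: dict[str, str] = {}
    if causal is not None:
        planted, parent_of = _plant_causal_and_decoys(cfg, causal, pipeline_cfg)
        used_positions.update((s.contig, s.pos) for s in planted)

    panel_set = set(cfg.panel_genes)
    attempts = 0
    while len(sites) < cfg.n_background_variants:
        attempts += 1
        if attempts > cfg.n_background_variants * 50:
            raise SimulationError("could not place background variants without collisions")
        gene = gene_list[rng.integers(len(gene_list))]
        cds_index = int(rng.integers(1, len(gene.cds_sequence) + 1))
        ref_base = gene.cds_sequence[cds_index - 1]
        alt_base = "ACGT".replace(ref_base, "")[rng.integers(3)]
        pos, ref, alt = _cds_site(gene, cds_index, alt_base)
        if (gene.contig, pos) in used_positions:
            continue
        used_positions.add((gene.contig, pos))
        maf = float(rng.uniform(*cfg.maf_range))
        # Background variation in panel genes is kept fully catalogued, the
        # regime a curated disease-gene panel sits in; elsewhere catalogue
        # membership is Bernoulli.
        in_catalogue = gene.symbol in panel_set or rng.random() < cfg.catalogue_fraction
        in_control = rng.random() < cfg.control_exome_fraction
        mq = (
            float(rng.uniform(5.0, 19.5))
            if rng.random() < cfg.low_mq_fraction
            else float(rng.uniform(30.0, 60.0))
        )
        sites.append(
            _Site(
                gene.contig, pos, ref, alt, gene.symbol, "background",
                maf, maf if in_catalogue else None,
                in_catalogue=in_catalogue, in_control=in_control, mq=mq,
            )
        )
    sites.extend(planted)
    sites.sort(key=lambda s: (_contig_sort_key(s.contig), s.pos, s.alt))
    n_sites = len(sites)
    site_index = {s.key: i for i, s in enumerate(sites)}
    causal_indices = (
        [i for i, s in enumerate(sites) if causal is not None and s.gene == cfg.causal_gene]
    )
    causal_index_set = set(causal_indices)

    # ---- founder haplotypes ----------------------------------------------
    founders = [ind for ind in pedigree.individuals if ind.father is None]
    children = [ind for ind in pedigree.individuals if ind.father is not None]
    mafs = np.array([s.maf if s.maf is not None else 0.0 for s in sites])
    haplotypes: dict[str, np.ndarray] = {}
    for ind in founders:
        haplotypes[ind.id] = (rng.random((2, n_sites)) < mafs).astype(np.int8)

    # plant the causal/decoy alleles on dedicated founder haplotypes
    father_id = mother_id = None
    if children:
        father_id, mother_id = children[0].father, children[0].mother
    for s in planted:
        carriers = parent_of[s.role]
        idx = site_index[s.key]
        targets = []
        if carriers in ("father", "both") and father_id is not None:
            targets.append(father_id)
        if carriers in ("mother", "both") and mother_id is not None:
            targets.append(mother_id)
        if not targets:
            raise SimulationError(
                f"causal model {cfg.causal_model} needs sampled-or-not parents "
                "in the pedigree to place planted alleles"
            )
        for parent in targets:
            haplotypes[parent][0, idx] = 1  # haplotype 0 carries the plant

    # ---- transmission ------------------------------------------------------
    affected_children = [c.id for c in children if c.affected]
    unaffected_children = [c.id for c in children if c.affected is False]

    def child_ok(child_haps: dict[str, np.ndarray]) -> bool:
        if causal is None:
            return True
        gts = {
            cid: {sites[i].role: int(h[:, i].sum()) for i in causal_indices}
            for cid, h in child_haps.items()
        }
        if cfg.causal_model == "COMPOUND_HET":
            for cid in affected_children:
                if gts[cid]["causal_splice"] != 1 or gts[cid]["causal_missense"] != 1:
                    return False
            for cid in unaffected_children:
                if gts[cid]["causal_splice"] >= 1 and gts[cid]["causal_missense"] >= 1:
                    return False
        elif cfg.causal_model == "HOMOZYGOUS":
            for cid in affected_children:
                if gts[cid]["causal_hom"] != 2:
                    return False
            for cid in unaffected_children:
                if gts[cid]["causal_hom"] == 2:
                    return False
        elif cfg.causal_model == "SINGLE_HET":
            for cid in affected_children:
                if gts[cid]["causal_single"] < 1:
                    return False
        return True

    for _attempt in range(10_000):
        trial: dict[str, np.ndarray] = {}
        for child in children:
            pat_choice = rng.integers(0, 2, n_sites)
            mat_choice = rng.integers(0, 2, n_sites)
            if causal_indices:
                # one haplotype per parent across the whole causal gene:
                # no intra-gene recombination
                pat_gene = rng.integers(0, 2)
                mat_gene = rng.integers(0, 2)
                for i in causal_indices:
                    pat_choice[i] = pat_gene
                    mat_choice[i] = mat_gene
            pat = haplotypes[child.father][pat_choice, np.arange(n_sites)]
            mat = haplotypes[child.mother][mat_choice, np.arange(n_sites)]
            trial[child.id] = np.stack([pat, mat])
        if child_ok(trial):
            haplotypes.update(trial)
            break
    else:
        raise SimulationError(
            "could not satisfy the configured affection pattern in 10000 draws; "
            "the causal model is inconsistent with the pedigree"
        )

    # ---- assemble outputs ---------------------------------------------------
    samples = [ind.id for ind in pedigree.individuals if ind.sample_available]
    variants: list[Variant] = []
    for i, s in enumerate(sites):
        genotypes = {sid: int(haplotypes[sid][:, i].sum()) for sid in samples}
        variants.append(
            Variant(
                contig=s.contig, pos=s.pos, ref=s.ref, alt=s.alt,
                mapping_quality=round(s.mq, 2), genotypes=genotypes,
            )
        )

    catalogue = PopulationDB(
        "catalogue",
        {s.key: s.catalogue_maf for s in sites if s.in_catalogue},
    )
    control = PopulationDB(
        "control_exome", {s.key: None for s in sites if s.in_control}
    )

    causal_keys = [s.key for s in planted if s.role.startswith("causal")]
    background = [s for s in sites if s.role == "background"]
    truth = TruthSet(
        causal_gene=cfg.causal_gene if causal is not None else None,
        causal_keys=causal_keys,
        planted_genotypes={
            ind.id: {
                ":".join(map(str, s.key)): int(haplotypes[ind.id][:, site_index[s.key]].sum())
                for s in planted
            }
            for ind in pedigree.individuals
        },
        maf_decoy_key=next((s.key for s in planted if s.role == "maf_decoy"), None),
        cis_decoy_keys=(
            tuple(s.key for s in planted if s.role.startswith("cis_decoy")) or None  # type: ignore[arg-type]
        ),
        control_decoy_key=next((s.key for s in planted if s.role == "control_decoy"), None),
        background_keys=[s.key for s in background],
        background_mafs={s.key: s.maf for s in background},
    )
    if truth.cis_decoy_keys is not None and len(truth.cis_decoy_keys) != 2:
        truth.cis_decoy_keys = None

    private_keys = [s.key for s in planted]
    controls = simulate_controls(
        private_keys,
        cfg.control_cohort_size,
        truth.background_mafs,
        seed=int(rng.integers(2**31 - 1)),
    )
    depth_tracks = (
        [_depth_track(causal, cfg, rng)] if causal is not None else []
    )
    return FamilySimulation(
        config=cfg,
        pedigree=pedigree,
        gene_models=models,
        variants=variants,
        samples=samples,
        catalogue_db=catalogue,
        control_db=control,
        depth_tracks=depth_tracks,
        controls=controls,
        truth=truth,
    )


def simulate_controls(
    private_keys: Sequence[VariantKey],
    n: int,
    background_mafs: dict[VariantKey, float],
    seed: int,
) -> ControlCohort:
    """Genotype an unrelated control cohort.

    Family-private keys (the planted causal and decoy alleles) are never
    carried by controls; background sites draw Hardy–Weinberg genotypes at
    their stated MAFs.
    """
    rng = np.random.default_rng(seed)
    genotypes: dict[VariantKey, np.ndarray] = {}
    for key in private_keys:
        genotypes[key] = np.zeros(n, dtype=np.int8)
    for key in sorted(background_mafs):
        genotypes[key] = rng.binomial(2, background_mafs[key], size=n).astype(np.int8)
    return ControlCohort(n_individuals=n, genotypes=genotypes)


def _depth_track(
    gene: GeneModel, cfg: SimulationConfig, rng: np.random.Generator
) -> DepthTrack:
    """Poisson depth over the gene span with planted low-coverage regions."""
    lo, hi = gene.span
    lo, hi = lo - 10, hi + 10
    depths = rng.poisson(cfg.mean_depth, hi - lo + 1)
    span = hi - lo + 1
    for _ in range(cfg.low_depth_region_count):
        start = int(rng.integers(0, max(1, span - cfg.low_depth_region_length)))
        length = cfg.low_depth_region_length
        depths[start : start + length] = rng.integers(0, 10, length)
    return DepthTrack(contig=gene.contig, start=lo, depths=depths)
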