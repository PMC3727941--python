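"""Core domain types shared by every pipeline stage.

The pipeline reasons about biallelic variants carried by members of a
nuclear family, classified against single-transcript gene models, and
filtered by a small set of configurable thresholds.  Coordinates are
1-based inclusive everywhere internally (the VCF convention); only BED
output switches to 0-based half-open.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from pydantic import BaseModel, Field, field_validator

#: A genotype call is the number of alternate alleles carried (0, 1 or 2);
#: ``None`` marks a missing call and is distinct from 0.
GenotypeCall = Optional[int]

#: Variant identity: (normalized contig, pos, REF, ALT), uppercased alleles.
VariantKey = tuple[str, int, str, str]

_SEX_CONTIGS = {"X", "Y", "M", "MT", "W", "Z"}


def normalize_contig(contig: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix so dialects compare equal."""
    low = contig.lower()
    return contig[3:] if low.startswith("chr") else contig


def is_autosome(contig: str) -> bool:
    return normalize_contig(contig).upper() not in _SEX_CONTIGS


def is_carrier(gt: GenotypeCall) -> bool:
    """Carrier status; missing genotypes are conservatively non-carriers."""
    return gt is not None and gt >= 1


class ImpactClass(enum.Enum):
    MISSENSE = "MISSENSE"
    NONSENSE = "NONSENSE"
    SYNONYMOUS = "SYNONYMOUS"
    SPLICE = "SPLICE"
    FRAMESHIFT_INDEL = "FRAMESHIFT_INDEL"
    INFRAME_INDEL = "INFRAME_INDEL"
    INTRONIC = "INTRONIC"
    UTR = "UTR"
    INTERGENIC = "INTERGENIC"


#: Classes retained by the impact filter under default configuration:
#: protein-changing or splice-disrupting variants.
DEFAULT_RETAINED_IMPACTS = frozenset(
    {
        ImpactClass.MISSENSE,
        ImpactClass.NONSENSE,
        ImpactClass.SPLICE,
        ImpactClass.FRAMESHIFT_INDEL,
        ImpactClass.INFRAME_INDEL,
    }
)


@dataclass(frozen=True)
class Variant:
    """A biallelic variant with per-sample genotype calls.

    Multi-allelic records are decomposed upstream (see
    :func:`famprio.io.read_vcf`), so ``alt`` is always a single allele.
    ``mapping_quality`` is the site-level MQ when the caller reported one.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    mapping_quality: Optional[float] = None
    genotypes: Mapping[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.contig}:{self.pos}")
        for sample, gt in self.genotypes.items():
            if gt is not None and gt not in (0, 1, 2):
                raise ValueError(f"bad allele count {gt!r} for sample {sample}")

    @property
    def key(self) -> VariantKey:
        return (normalize_contig(self.contig), self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def carriers(self) -> list[str]:
        return [s for s, gt in self.genotypes.items() if is_carrier(gt)]


@dataclass(frozen=True)
class GeneModel:
    """Single-transcript gene model: exons, CDS span and CDS sequence.

    ``exons`` are 1-based closed genomic intervals, non-overlapping and
    sorted by genomic start regardless of strand.  ``cds_sequence`` is the
    spliced coding sequence in translation order (already
    reverse-complemented for minus-strand genes) and must be a whole number
    of codons.
    """

    symbol: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_interval: tuple[int, int]
    cds_sequence: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "cds_interval", tuple(self.cds_interval))
        object.__setattr__(self, "cds_sequence", self.cds_sequence.upper())
        prev_end = 0
        for s, e in exons:
            if s > e:
                raise ValueError(f"{self.symbol}: exon ({s},{e}) reversed")
            if s <= prev_end:
                raise ValueError(f"{self.symbol}: exons overlap or unsorted at ({s},{e})")
            prev_end = e
        if len(self.cds_sequence) % 3 != 0:
            raise ValueError(
                f"{self.symbol}: CDS length {len(self.cds_sequence)} not a multiple of 3"
            )
        cs, ce = self.cds_interval
        if not any(s <= cs <= e for s, e in exons) or not any(
            s <= ce <= e for s, e in exons
        ):
            raise ValueError(f"{self.symbol}: CDS endpoints fall outside exons")
        covered = sum(max(0, min(e, ce) - max(s, cs) + 1) for s, e in exons)
        if covered != len(self.cds_sequence):
            raise ValueError(
                f"{self.symbol}: CDS sequence length {len(self.cds_sequence)} "
                f"does not match {covered} exonic bases in the CDS interval"
            )

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    def cds_genomic_positions(self) -> list[int]:
        """Genomic positions of CDS bases, in translation (5'→3' mRNA) order."""
        cs, ce = self.cds_interval
        positions: list[int] = []
        for s, e in self.exons:
            lo, hi = max(s, cs), min(e, ce)
            if lo <= hi:
                positions.extend(range(lo, hi + 1))
        if self.strand == "-":
            positions.reverse()
        return positions


@dataclass(frozen=True)
class Individual:
    id: str
    father: Optional[str]
    mother: Optional[str]
    sex: str  # "1" male, "2" female, "0" unknown
    affected: Optional[bool]  # None = unknown phenotype
    sample_available: bool = True


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """A family: individuals, parental links and affection status.

    Validation rejects dangling parental references, self-ancestry cycles
    and pedigrees with no affected member.
    """

    individuals: list[Individual]

    def __post_init__(self) -> None:
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise PedigreeError("duplicate individual ids")
        self._by_id = {ind.id: ind for ind in self.individuals}
        for ind in self.individuals:
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in self._by_id:
                    raise PedigreeError(
                        f"{ind.id}: parent {parent!r} not in pedigree"
                    )
        self._check_acyclic()
        if not any(ind.affected for ind in self.individuals):
            raise PedigreeError("pedigree has no affected individual")

    def _check_acyclic(self) -> None:
        # DFS over parent links; a back-edge means someone is their own ancestor.
        WHITE, GREY, BLACK = 0, 1, 2
        color = {i.id: WHITE for i in self.individuals}

        def visit(node: str) -> None:
            color[node] = GREY
            ind = self._by_id[node]
            for parent in (ind.father, ind.mother):
                if parent is None:
                    continue
                if color[parent] == GREY:
                    raise PedigreeError(f"pedigree cycle through {parent}")
                if color[parent] == WHITE:
                    visit(parent)
            color[node] = BLACK

        for ind in self.individuals:
            if color[ind.id] == WHITE:
                visit(ind.id)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    def __getitem__(self, individual_id: str) -> Individual:
        return self._by_id[individual_id]

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]


def affected_samples(pedigree: Pedigree) -> list[str]:
    """Ids of affected individuals with a DNA sample available, in pedigree order.

    An empty result is legal (nobody both affected and sampled) but callers
    should treat it as a warning condition: the family cannot be analyzed.
    """
    return [
        ind.id
        for ind in pedigree.individuals
        if ind.affected and ind.sample_available
    ]


def parent_pair(pedigree: Pedigree, child_id: str) -> tuple[Optional[str], Optional[str]]:
    """(father, mother) ids for ``child_id``; ``None`` where the parent is
    unknown or has no sample available (an unsampled parent contributes no
    genotypes, so downstream phase logic must treat them as absent)."""
    if child_id not in pedigree:
        raise PedigreeError(f"unknown individual {child_id!r}")
    child = pedigree[child_id]

    def usable(parent_id: Optional[str]) -> Optional[str]:
        if parent_id is None:
            return None
        return parent_id if pedigree[parent_id].sample_available else None

    return usable(child.father), usable(child.mother)


class PipelineConfig(BaseModel):
    """Thresholds and conventions for the whole pipeline.

    ``maf_exclusion_threshold`` is the frequency at or above which database
    presence excludes a variant; the default 0.0 makes *any* database
    presence exclusionary, which is the behaviour of a strict
    novel-variants-only screen.
    """

    min_mapping_quality: float = 20.0
    retained_impact_classes: frozenset[ImpactClass] = DEFAULT_RETAINED_IMPACTS
    maf_exclusion_threshold: float = Field(default=0.0, ge=0.0, le=1.0)
    splice_window: int = Field(default=2, ge=0)
    depth_gap_threshold: int = Field(default=5, ge=0)
    coverage_thresholds: tuple[int, ...] = (1, 10)
    random_seed: int = 0

    model_config = {"frozen": True}

    @field_validator("min_mapping_quality")
    @classmethod
    def _non_negative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("min_mapping_quality must be non-negative")
        return v

    @field_validator("coverage_thresholds")
    @classmethod
    def _thresholds_ok(cls, v: Sequence[int]) -> tuple[int, ...]:
        vv = tuple(int(t) for t in v)
        if any(t < 0 for t in vv):
            raise ValueError("coverage thresholds must be non-negative")
        return vv

    @field_validator("retained_impact_classes", mode="before")
    @classmethod
    def _coerce_impacts(cls, v: Iterable) -> frozenset[ImpactClass]:
        return frozenset(
            ImpactClass(x) if not isinstance(x, ImpactClass) else x for x in v
        )
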