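"""Family logic for recessive-disease candidate calling.

After the per-sample filtering funnel, candidacy is decided by pedigree
reasoning: variants must be shared by every affected sibling, satisfy an
autosomal recessive genotype model (homozygous, or two heterozygous
variants in the same gene), and — where parents are sampled — segregate in
*trans*: one variant inherited from each parent.  Two heterozygous variants
inherited from the same parent sit on one haplotype (*cis*) and leave the
other haplotype intact, so a cis pair is rejected as a compound
heterozygote.  Phase is inferred purely from parental genotypes; when no
parent is sampled it stays unknown.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import (
    GenotypeCall,
    Pedigree,
    Variant,
    VariantKey,
    affected_samples,
    is_autosome,
    is_carrier,
    parent_pair,
)
from .annotate import Annotation


class InheritanceModel(enum.Enum):
    HOMOZYGOUS = "HOMOZYGOUS"
    COMPOUND_HET = "COMPOUND_HET"
    SINGLE_HET_UNCERTAIN = "SINGLE_HET_UNCERTAIN"


class PhaseStatus(enum.Enum):
    TRANS_CONFIRMED = "TRANS_CONFIRMED"
    CIS_REJECTED = "CIS_REJECTED"
    PHASE_UNKNOWN = "PHASE_UNKNOWN"
    NOT_APPLICABLE = "NOT_APPLICABLE"


class SegregationStatus(enum.Enum):
    CONSISTENT = "CONSISTENT"
    INCONSISTENT = "INCONSISTENT"
    UNTESTABLE = "UNTESTABLE"


@dataclass
class CandidateCall:
    """A per-gene recessive candidate: one homozygous variant, a
    compound-het pair, or a lone heterozygous variant of uncertain status.

    ``CIS_REJECTED`` calls are excluded from the causative report but kept
    in audit output so the rejection is traceable.
    """

    gene: str
    variants: list[Variant]
    model: InheritanceModel
    phase_status: PhaseStatus = PhaseStatus.NOT_APPLICABLE
    segregation_status: SegregationStatus = SegregationStatus.UNTESTABLE
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = 2 if self.model is InheritanceModel.COMPOUND_HET else 1
        if len(self.variants) != expected:
            raise ValueError(
                f"{self.model.value} call must have {expected} variant(s), "
                f"got {len(self.variants)}"
            )

    @property
    def reportable(self) -> bool:
        return self.phase_status is not PhaseStatus.CIS_REJECTED


@dataclass
class ControlCohort:
    """Genotypes of unrelated, ethnically matched control individuals."""

    n_individuals: int
    genotypes: dict[VariantKey, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, arr in self.genotypes.items():
            arr = np.asarray(arr)
            if len(arr) != self.n_individuals:
                raise ValueError(f"{key}: {len(arr)} genotypes for {self.n_individuals} controls")
            self.genotypes[key] = arr


def shared_variants(per_sample_sets: Sequence[Sequence[Variant]]) -> list[Variant]:
    """Variants present in every affected sibling's candidate set.

    Intersection is by identity key; the survivors are returned in the
    first sample's order (so a single affected sample passes through
    unchanged).
    """
    if not per_sample_sets:
        raise ValueError("at least one affected sample set required")
    common = set(v.key for v in per_sample_sets[0])
    for other in per_sample_sets[1:]:
        common &= {v.key for v in other}
    return [v for v in per_sample_sets[0] if v.key in common]


def _genotype_in_all(
    v: Variant, sample_ids: Sequence[str], value: int
) -> tuple[bool, bool]:
    """(all samples have this allele count, any genotype was missing)."""
    missing = any(v.genotypes.get(s) is None for s in sample_ids)
    ok = all(v.genotypes.get(s) == value for s in sample_ids)
    return ok, missing


def call_recessive(
    variants: Sequence[Variant],
    annotations: Mapping[VariantKey, Annotation],
    pedigree: Pedigree,
) -> list[CandidateCall]:
    """Group shared variants by gene and call recessive candidates.

    Per gene: any variant homozygous-alternate in every affected sampled
    sibling is a HOMOZYGOUS call; otherwise two or more variants
    heterozygous in every affected sibling yield COMPOUND_HET calls over
    each pair (three or more are all emitted, flagged); a lone
    heterozygous variant is SINGLE_HET_UNCERTAIN.  Sex chromosomes are
    skipped — the model here is strictly autosomal recessive.
    """
    affected = affected_samples(pedigree)
    if not affected:
        return []
    by_gene: dict[str, list[Variant]] = {}
    for v in variants:
        if not is_autosome(v.contig):
            continue
        ann = annotations.get(v.key)
        if ann is None or ann.gene is None:
            continue
        by_gene.setdefault(ann.gene, []).append(v)

    calls: list[CandidateCall] = []
    for gene, gene_variants in by_gene.items():
        homs, hets, any_missing = [], [], False
        for v in gene_variants:
            hom_ok, miss1 = _genotype_in_all(v, affected, 2)
            het_ok, miss2 = _genotype_in_all(v, affected, 1)
            any_missing = any_missing or miss1 or miss2
            if hom_ok:
                homs.append(v)
            elif het_ok:
                hets.append(v)
        flags = ["missing_genotype"] if any_missing else []
        if homs:
            for v in homs:
                calls.append(
                    CandidateCall(gene, [v], InheritanceModel.HOMOZYGOUS, flags=list(flags))
                )
            continue
        if len(hets) >= 2:
            pair_flags = list(flags)
            if len(hets) > 2:
                pair_flags.append("multiple_het_pairs")
            for a, b in combinations(hets, 2):
                calls.append(
                    CandidateCall(
                        gene, [a, b], InheritanceModel.COMPOUND_HET, flags=list(pair_flags)
                    )
                )
        elif len(hets) == 1:
            calls.append(
                CandidateCall(
                    gene, hets, InheritanceModel.SINGLE_HET_UNCERTAIN, flags=list(flags)
                )
            )
    return calls


def classify_pair_phase(
    father_a: GenotypeCall,
    father_b: GenotypeCall,
    mother_a: GenotypeCall,
    mother_b: GenotypeCall,
) -> PhaseStatus:
    """Phase of a het/het pair in the children given parental genotypes.

    TRANS_CONFIRMED requires each parent to carry exactly one *distinct*
    member of the pair, heterozygously (a homozygous parent could have
    transmitted either haplotype, so nothing is confirmed).  Both variants
    carried by one parent with the other parent carrying neither is a cis
    configuration and is rejected.  Every other combination — including
    any missing parental genotype — leaves the phase unknown.
    """
    if any(g is None for g in (father_a, father_b, mother_a, mother_b)):
        return PhaseStatus.PHASE_UNKNOWN
    if (father_a == 1 and father_b == 0 and mother_a == 0 and mother_b == 1) or (
        father_a == 0 and father_b == 1 and mother_a == 1 and mother_b == 0
    ):
        return PhaseStatus.TRANS_CONFIRMED
    if (father_a >= 1 and father_b >= 1 and mother_a == 0 and mother_b == 0) or (
        mother_a >= 1 and mother_b >= 1 and father_a == 0 and father_b == 0
    ):
        return PhaseStatus.CIS_REJECTED
    return PhaseStatus.PHASE_UNKNOWN


def _unaffected_sampled(pedigree: Pedigree) -> list[str]:
    return [
        ind.id
        for ind in pedigree.individuals
        if ind.affected is False and ind.sample_available
    ]


def check_segregation(call: CandidateCall, pedigree: Pedigree) -> CandidateCall:
    """Annotate a candidate call with phase and segregation status.

    Parental genotypes come from the variants' own multi-sample genotype
    maps.  Under the full-penetrance recessive model an unaffected sampled
    individual carrying the complete causal genotype (both members of a
    pair, or homozygous for a HOMOZYGOUS call) marks the call
    INCONSISTENT.
    """
    affected = affected_samples(pedigree)
    father = mother = None
    if affected:
        father, mother = parent_pair(pedigree, affected[0])
    unaffected = _unaffected_sampled(pedigree)

    if call.model is InheritanceModel.COMPOUND_HET:
        va, vb = call.variants
        if father is None or mother is None:
            call.phase_status = PhaseStatus.PHASE_UNKNOWN
            call.segregation_status = SegregationStatus.UNTESTABLE
            if father is None and mother is None:
                call.flags.append("parents_unsampled")
            return call
        call.phase_status = classify_pair_phase(
            va.genotypes.get(father),
            vb.genotypes.get(father),
            va.genotypes.get(mother),
            vb.genotypes.get(mother),
        )
        if call.phase_status is PhaseStatus.TRANS_CONFIRMED:
            double_carrier = any(
                is_carrier(va.genotypes.get(s)) and is_carrier(vb.genotypes.get(s))
                for s in unaffected
            )
            call.segregation_status = (
                SegregationStatus.INCONSISTENT
                if double_carrier
                else SegregationStatus.CONSISTENT
            )
        elif call.phase_status is PhaseStatus.CIS_REJECTED:
            call.segregation_status = SegregationStatus.INCONSISTENT
        else:
            call.segregation_status = SegregationStatus.UNTESTABLE
        return call

    if call.model is InheritanceModel.HOMOZYGOUS:
        v = call.variants[0]
        call.phase_status = PhaseStatus.NOT_APPLICABLE
        parents = [p for p in (father, mother) if p is not None]
        if not parents:
            call.segregation_status = SegregationStatus.UNTESTABLE
            call.flags.append("parents_unsampled")
            return call
        genotypes = [v.genotypes.get(p) for p in parents]
        if any(g is None for g in genotypes):
            call.segregation_status = SegregationStatus.UNTESTABLE
            call.flags.append("missing_parent_genotype")
            return call
        hom_unaffected = any(v.genotypes.get(s) == 2 for s in unaffected)
        all_carriers = all(g >= 1 for g in genotypes)
        call.segregation_status = (
            SegregationStatus.CONSISTENT
            if all_carriers and not hom_unaffected
            else SegregationStatus.INCONSISTENT
        )
        return call

    # A lone heterozygous variant: no second allele observed, so neither
    # phase nor recessive segregation can be established.
    call.phase_status = PhaseStatus.PHASE_UNKNOWN
    call.segregation_status = SegregationStatus.UNTESTABLE
    return call


def count_carriers(
    key: VariantKey, cohort: ControlCohort
) -> tuple[int, int]:
    """(carrier count, cohort size) for a variant in the control cohort.

    Carrier means at least one alternate allele.  A key the cohort was
    never genotyped at counts 0 carriers by convention.
    """
    genotypes = cohort.genotypes.get(key)
    if genotypes is None or cohort.n_individuals == 0:
        return (0, cohort.n_individuals)
    carriers = sum(1 for g in genotypes.tolist() if g is not None and g >= 1)
    return (int(carriers), cohort.n_individuals)
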