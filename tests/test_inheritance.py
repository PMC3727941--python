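from itertools import product

import numpy as np
import pytest

from famprio.annotate import Annotation
from famprio.core import ImpactClass, Individual, Pedigree, Variant
from famprio.examples import (
    genomes_catalogue,
    sr285_annotations,
    sr285_pedigree,
    sr285_variants,
    sr903_annotations,
    sr903_pedigree,
    sr903_variants,
)
from famprio.inheritance import (
    CandidateCall,
    ControlCohort,
    InheritanceModel,
    PhaseStatus,
    SegregationStatus,
    call_recessive,
    check_segregation,
    classify_pair_phase,
    count_carriers,
    shared_variants,
)
from famprio.simulate import simulate_controls


def _affected_sets(variants, samples):
    from famprio.cascade import sample_variants

    return [sample_variants(variants, s) for s in samples]


class TestSharedVariants:
    def test_sibling_intersection_three_of_five(self):
        sets = _affected_sets(sr903_variants(), ["SR-903", "SR-903B"])
        assert [len(s) for s in sets] == [5, 3]
        shared = shared_variants(sets)
        assert len(shared) == 3

    def test_single_sample_is_identity(self):
        sets = _affected_sets(sr903_variants(), ["SR-903"])
        assert shared_variants(sets) == sets[0]

    def test_disjoint_sets_empty(self):
        a = [Variant("1", 1, "A", "C")]
        b = [Variant("1", 2, "A", "C")]
        assert shared_variants([a, b]) == []


def _quartet(gts_by_pos):
    """Pedigree + variants with genotypes (father, mother, sib1, sib2)."""
    ped = Pedigree(
        [
            Individual("F", None, None, "1", affected=False),
            Individual("M", None, None, "2", affected=False),
            Individual("C1", "F", "M", "1", affected=True),
            Individual("C2", "F", "M", "2", affected=True),
        ]
    )
    variants = [
        Variant("1", pos, "A", "C", genotypes=dict(zip(("F", "M", "C1", "C2"), gts)))
        for pos, gts in gts_by_pos.items()
    ]
    anns = {v.key: Annotation(gene="G1", impact_class=ImpactClass.MISSENSE) for v in variants}
    return ped, variants, anns


class TestCallRecessive:
    def test_two_shared_hets_make_compound_pair(self):
        ped, variants, anns = _quartet({10: (1, 0, 1, 1), 20: (0, 1, 1, 1)})
        (call,) = call_recessive(variants, anns, ped)
        assert call.model is InheritanceModel.COMPOUND_HET
        assert len(call.variants) == 2

    def test_homozygous_in_all_affected(self):
        ped, variants, anns = _quartet({10: (1, 1, 2, 2)})
        (call,) = call_recessive(variants, anns, ped)
        assert call.model is InheritanceModel.HOMOZYGOUS

    def test_lone_het_is_uncertain(self):
        ped, variants, anns = _quartet({10: (1, 0, 1, 1)})
        (call,) = call_recessive(variants, anns, ped)
        assert call.model is InheritanceModel.SINGLE_HET_UNCERTAIN

    def test_three_hets_emit_all_pairs_flagged(self):
        ped, variants, anns = _quartet(
            {10: (1, 0, 1, 1), 20: (0, 1, 1, 1), 30: (1, 0, 1, 1)}
        )
        calls = call_recessive(variants, anns, ped)
        assert len(calls) == 3
        assert all("multiple_het_pairs" in c.flags for c in calls)

    def test_missing_genotype_flagged_and_treated_noncarrier(self):
        ped, variants, anns = _quartet({10: (1, 0, 1, None), 20: (0, 1, 1, 1)})
        calls = call_recessive(variants, anns, ped)
        # site 10 is not het in all affected, so only the lone het at 20 remains
        (call,) = calls
        assert call.model is InheritanceModel.SINGLE_HET_UNCERTAIN
        assert "missing_genotype" in call.flags

    def test_sex_chromosome_variants_skipped(self):
        ped = _quartet({})[0]
        v = Variant("X", 5, "A", "C", genotypes={"F": 0, "M": 1, "C1": 1, "C2": 1})
        anns = {v.key: Annotation(gene="G1", impact_class=ImpactClass.MISSENSE)}
        assert call_recessive([v], anns, ped) == []


class TestSegregation:
    def test_trans_confirmed_one_variant_per_parent(self):
        ped, variants, anns = _quartet({10: (1, 0, 1, 1), 20: (0, 1, 1, 1)})
        (call,) = call_recessive(variants, anns, ped)
        call = check_segregation(call, ped)
        assert call.phase_status is PhaseStatus.TRANS_CONFIRMED
        assert call.segregation_status is SegregationStatus.CONSISTENT

    def test_cis_pair_rejected(self):
        ped, variants, anns = _quartet({10: (1, 0, 1, 1), 20: (1, 0, 1, 1)})
        (call,) = call_recessive(variants, anns, ped)
        call = check_segregation(call, ped)
        assert call.phase_status is PhaseStatus.CIS_REJECTED
        assert not call.reportable

    def test_unsampled_parents_leave_phase_unknown(self):
        ped = sr285_pedigree()
        v1 = Variant("1", 10, "A", "C", genotypes={"SR-285": 1, "SR-285S": 1})
        v2 = Variant("1", 20, "A", "C", genotypes={"SR-285": 1, "SR-285S": 1})
        anns = {v.key: Annotation(gene="G1", impact_class=ImpactClass.MISSENSE) for v in (v1, v2)}
        (call,) = call_recessive([v1, v2], anns, ped)
        call = check_segregation(call, ped)
        assert call.phase_status is PhaseStatus.PHASE_UNKNOWN
        assert call.segregation_status is SegregationStatus.UNTESTABLE

    def test_unaffected_sib_with_both_variants_is_inconsistent(self):
        ped = Pedigree(
            [
                Individual("F", None, None, "1", affected=False),
                Individual("M", None, None, "2", affected=False),
                Individual("C1", "F", "M", "1", affected=True),
                Individual("U", "F", "M", "2", affected=False),
            ]
        )
        variants = [
            Variant("1", 10, "A", "C", genotypes={"F": 1, "M": 0, "C1": 1, "U": 1}),
            Variant("1", 20, "A", "C", genotypes={"F": 0, "M": 1, "C1": 1, "U": 1}),
        ]
        anns = {v.key: Annotation(gene="G1", impact_class=ImpactClass.MISSENSE) for v in variants}
        (call,) = call_recessive(variants, anns, ped)
        call = check_segregation(call, ped)
        assert call.phase_status is PhaseStatus.TRANS_CONFIRMED
        assert call.segregation_status is SegregationStatus.INCONSISTENT

    def test_homozygous_needs_both_parents_carriers(self):
        ped, variants, anns = _quartet({10: (1, 1, 2, 2)})
        (call,) = call_recessive(variants, anns, ped)
        assert check_segregation(call, ped).segregation_status is SegregationStatus.CONSISTENT

        ped2, variants2, anns2 = _quartet({10: (0, 1, 2, 2)})
        (call2,) = call_recessive(variants2, anns2, ped2)
        assert check_segregation(call2, ped2).segregation_status is SegregationStatus.INCONSISTENT


def _phase_oracle(fa, fb, ma, mb):
    """Independent enumeration oracle over parental carrier sets.

    Builds each parent's carried-variant multiset from the genotype pair
    and applies the documented decision rule for the het/het sib pair.
    """
    if None in (fa, fb, ma, mb):
        return PhaseStatus.PHASE_UNKNOWN
    father = {"A": fa, "B": fb}
    mother = {"A": ma, "B": mb}
    carried_f = {v for v, n in father.items() if n > 0}
    carried_m = {v for v, n in mother.items() if n > 0}
    exactly_one_each = (
        carried_f in ({"A"}, {"B"})
        and carried_m in ({"A"}, {"B"})
        and carried_f != carried_m
    )
    no_hom = all(n < 2 for n in list(father.values()) + list(mother.values()))
    if exactly_one_each and no_hom:
        return PhaseStatus.TRANS_CONFIRMED
    if (carried_f == {"A", "B"} and not carried_m) or (
        carried_m == {"A", "B"} and not carried_f
    ):
        return PhaseStatus.CIS_REJECTED
    return PhaseStatus.PHASE_UNKNOWN


def test_phase_matches_exhaustive_81_case_oracle():
    """All 3^4 parental genotype combinations agree with the enumeration
    oracle, and missing genotypes always leave phase unknown."""
    for fa, fb, ma, mb in product((0, 1, 2), repeat=4):
        assert classify_pair_phase(fa, fb, ma, mb) is _phase_oracle(fa, fb, ma, mb), (
            fa, fb, ma, mb,
        )
    assert classify_pair_phase(None, 1, 0, 1) is PhaseStatus.PHASE_UNKNOWN


class TestControls:
    def test_private_variant_absent_from_409_controls(self):
        keys = [("17", 18035881, "G", "A"), ("17", 18049349, "G", "A")]
        cohort = simulate_controls(keys, 409, {}, seed=3)
        for key in keys:
            assert count_carriers(key, cohort) == (0, 409)

    def test_carrier_fraction_tracks_hardy_weinberg(self):
        key = ("1", 100, "A", "C")
        cohort = simulate_controls([], 2000, {key: 0.5}, seed=5)
        carriers, n = count_carriers(key, cohort)
        # expectation 1-(1-0.5)^2 = 0.75; allow 3 binomial SE
        se = np.sqrt(0.75 * 0.25 / n)
        assert abs(carriers / n - 0.75) < 3 * se

    def test_empty_cohort(self):
        cohort = ControlCohort(n_individuals=0)
        assert count_carriers(("1", 1, "A", "C"), cohort) == (0, 0)

    def test_cohort_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ControlCohort(n_individuals=3, genotypes={("1", 1, "A", "C"): np.zeros(2)})


class TestWorkedExamples:
    """The two published families, run through the family-logic stages."""

    def test_sr903_pair_survives_exclusion_and_phases_in_trans(self):
        from famprio.cascade import subtract_database
        from famprio.core import PipelineConfig

        shared = shared_variants(_affected_sets(sr903_variants(), ["SR-903", "SR-903B"]))
        retained = subtract_database(shared, genomes_catalogue(), PipelineConfig())
        assert len(retained) == 2
        (call,) = call_recessive(retained, sr903_annotations(), sr903_pedigree())
        call = check_segregation(call, sr903_pedigree())
        assert call.model is InheritanceModel.COMPOUND_HET
        assert call.phase_status is PhaseStatus.TRANS_CONFIRMED

    def test_sr285_lone_het_uncertain(self):
        shared = shared_variants(_affected_sets(sr285_variants(), ["SR-285", "SR-285S"]))
        assert len(shared) == 1
        (call,) = call_recessive(shared, sr285_annotations(), sr285_pedigree())
        call = check_segregation(call, sr285_pedigree())
        assert call.model is InheritanceModel.SINGLE_HET_UNCERTAIN
        assert call.phase_status is PhaseStatus.PHASE_UNKNOWN
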