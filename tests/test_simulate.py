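import filecmp

import numpy as np
import pytest

from famprio.core import is_carrier
from famprio.simulate import (
    IndividualSpec,
    SimulationConfig,
    SimulationError,
    causal_panel_gene,
    quartet_pedigree,
    sib_pair_pedigree,
    simulate_family,
    toy_genome,
)


class TestToyGenome:
    def test_big_gene_structure(self, big_gene):
        assert len(big_gene.exons) == 17
        # 4320 coding bases through exon 11
        assert sum(e - s + 1 for s, e in big_gene.exons[:11]) == 4320
        assert len(big_gene.cds_sequence) % 3 == 0
        assert big_gene.cds_sequence[-3:] == "TAA"
        # pinned codons
        assert big_gene.cds_sequence[6435:6438] == "CGG"
        assert big_gene.cds_sequence[6480:6483] == "TCC"

    def test_gene_models_validate_and_do_not_overlap(self):
        models = toy_genome()
        spans = {}
        for g in models.values():
            for other_span in spans.get(g.contig, []):
                assert g.span[1] < other_span[0] or g.span[0] > other_span[1]
            spans.setdefault(g.contig, []).append(g.span)

    def test_deterministic_sequences(self):
        assert causal_panel_gene().cds_sequence == causal_panel_gene().cds_sequence


class TestDeterminism:
    def test_identical_seed_gives_byte_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(random_seed=9)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        paths1 = simulate_family(cfg).write(d1)
        paths2 = simulate_family(cfg).write(d2)
        for name in paths1:
            assert filecmp.cmp(paths1[name], paths2[name], shallow=False), name

    def test_different_seed_changes_genotypes(self):
        a = simulate_family(SimulationConfig(random_seed=1))
        b = simulate_family(SimulationConfig(random_seed=2))
        assert [v.key for v in a.variants] != [v.key for v in b.variants] or any(
            va.genotypes != vb.genotypes for va, vb in zip(a.variants, b.variants)
        )


class TestPlanting:
    def test_quartet_compound_het_layout(self, quartet_sim):
        sim = quartet_sim
        splice_key, missense_key = sim.truth.causal_keys
        by_key = {v.key: v for v in sim.variants}
        father, mother = "SIM-903F", "SIM-903M"
        for child in ("SIM-903", "SIM-903B"):
            assert by_key[splice_key].genotypes[child] == 1
            assert by_key[missense_key].genotypes[child] == 1
        assert by_key[splice_key].genotypes[mother] == 1
        assert by_key[splice_key].genotypes[father] == 0
        assert by_key[missense_key].genotypes[father] == 1
        assert by_key[missense_key].genotypes[mother] == 0

    def test_causal_keys_absent_from_all_databases(self, quartet_sim):
        for key in quartet_sim.truth.causal_keys:
            assert key not in quartet_sim.catalogue_db
            assert key not in quartet_sim.control_db

    def test_causal_model_none_has_no_truth_keys(self):
        sim = simulate_family(SimulationConfig(causal_model="NONE", random_seed=4))
        assert sim.truth.causal_keys == [] and sim.truth.causal_gene is None

    def test_unsampled_parents_absent_from_vcf(self):
        cfg = SimulationConfig(
            family_id="SIM-285",
            individuals=sib_pair_pedigree(),
            causal_model="SINGLE_HET",
            random_seed=5,
        )
        sim = simulate_family(cfg)
        assert sim.samples == ["SIM-285", "SIM-285S"]
        (causal_key,) = sim.truth.causal_keys
        by_key = {v.key: v for v in sim.variants}
        assert by_key[causal_key].genotypes["SIM-285"] == 1
        assert by_key[causal_key].genotypes["SIM-285S"] == 1

    def test_homozygous_model_plants_hom_in_affected(self):
        sim = simulate_family(SimulationConfig(causal_model="HOMOZYGOUS", random_seed=6))
        (key,) = sim.truth.causal_keys
        by_key = {v.key: v for v in sim.variants}
        assert by_key[key].genotypes["SIM-903"] == 2
        assert by_key[key].genotypes["SIM-903B"] == 2
        assert by_key[key].genotypes["SIM-903F"] == 1
        assert by_key[key].genotypes["SIM-903M"] == 1

    def test_impossible_config_raises(self):
        inds = [IndividualSpec(id="solo", affected=True)]
        cfg = SimulationConfig(individuals=inds, causal_model="HOMOZYGOUS", random_seed=1)
        with pytest.raises(SimulationError):
            simulate_family(cfg)


def _mendelian_ok(child, father, mother):
    if None in (child, father, mother):
        return True
    pat = {0: {0}, 1: {0, 1}, 2: {1}}[father]
    mat = {0: {0}, 1: {0, 1}, 2: {1}}[mother]
    return any(p + m == child for p in pat for m in mat)


def test_every_child_genotype_is_mendelian(quartet_sim):
    """Exhaustive per-site check: each child genotype is derivable from
    one allele of each parent."""
    for v in quartet_sim.variants:
        for child in ("SIM-903", "SIM-903B"):
            assert _mendelian_ok(
                v.genotypes[child], v.genotypes["SIM-903F"], v.genotypes["SIM-903M"]
            ), v.key


def test_offspring_hom_alt_fraction_from_het_x_het_parents():
    """1000 offspring of het x het parents: hom-alt fraction within 3
    binomial standard errors of the Mendelian 1/4."""
    inds = [IndividualSpec(id="F", sex="1"), IndividualSpec(id="M", sex="2")] + [
        IndividualSpec(id=f"C{i}", father="F", mother="M", affected=(i == 0))
        for i in range(1000)
    ]
    cfg = SimulationConfig(
        individuals=inds, causal_model="NONE", n_background_variants=30,
        maf_range=(0.4, 0.5), n_background_genes=3, control_cohort_size=0,
        random_seed=7,
    )
    sim = simulate_family(cfg)
    het_sites = [
        v for v in sim.variants if v.genotypes["F"] == 1 and v.genotypes["M"] == 1
    ]
    assert het_sites, "expected at least one het x het site at these MAFs"
    v = het_sites[0]
    gts = np.array([v.genotypes[f"C{i}"] for i in range(1000)])
    frac = float(np.mean(gts == 2))
    se = np.sqrt(0.25 * 0.75 / 1000)
    assert abs(frac - 0.25) < 3 * se


def test_background_survival_matches_independent_db_membership(quartet_sim):
    """Background sites in non-panel genes escape both databases at rate
    (1 - catalogue fraction)(1 - control fraction), within 3 SE."""
    sim = quartet_sim
    panel = set(sim.config.panel_genes)
    panel_contigs = {g.contig for s, g in sim.gene_models.items() if s in panel}
    non_panel_keys = [
        k for k in sim.truth.background_keys if k[0] not in panel_contigs
    ]
    n = len(non_panel_keys)
    assert n > 50
    survived = sum(
        1
        for k in non_panel_keys
        if k not in sim.catalogue_db and k not in sim.control_db
    )
    expected = (1 - sim.config.catalogue_fraction) * (1 - sim.config.control_exome_fraction)
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(survived / n - expected) < 3 * se


def test_controls_never_carry_planted_alleles(quartet_sim):
    truth = quartet_sim.truth
    planted = list(truth.causal_keys)
    planted += [truth.maf_decoy_key, truth.control_decoy_key]
    planted += list(truth.cis_decoy_keys or ())
    for key in planted:
        assert not any(
            is_carrier(int(g)) for g in quartet_sim.controls.genotypes[key]
        ), key
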