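import numpy as np
import pytest
from Bio.Seq import Seq

from famprio.annotate import (
    Annotation,
    AnnotationError,
    assign_domain,
    classify_variant,
    join_scores,
)
from famprio.core import ImpactClass, Variant
from famprio.io import ScoreTable
from famprio.simulate import _cds_site, causal_panel_gene, toy_gene


def _variant_at_cds(gene, cds_index, alt_base):
    pos, ref, alt = _cds_site(gene, cds_index, alt_base)
    return Variant(contig=gene.contig, pos=pos, ref=ref, alt=alt)


class TestCodingSnv:
    def test_arginine_to_glutamine_missense(self, big_gene, cfg):
        # codon 2146 is CGG; G>A at its second base (c.6437) gives CAG = Gln
        v = _variant_at_cds(big_gene, 6437, "A")
        ann = classify_variant(v, big_gene, cfg)
        assert ann.impact_class is ImpactClass.MISSENSE
        assert ann.protein_label == "p.R2146Q"
        assert ann.cdna_label == "c.6437G>A"
        assert ann.protein_position == 2146

    def test_serine_to_phenylalanine_missense(self, big_gene, cfg):
        # codon 2161 is TCC; C>T at c.6482 gives TTC = Phe
        v = _variant_at_cds(big_gene, 6482, "T")
        ann = classify_variant(v, big_gene, cfg)
        assert ann.protein_label == "p.S2161F"
        assert ann.cdna_label == "c.6482C>T"

    def test_third_base_wobble_synonymous(self, big_gene, cfg):
        # CGG -> CGA, both arginine
        v = _variant_at_cds(big_gene, 6438, "A")
        ann = classify_variant(v, big_gene, cfg)
        assert ann.impact_class is ImpactClass.SYNONYMOUS
        assert ann.protein_label == "p.R2146R"

    def test_stop_gain_is_nonsense(self, cfg):
        gene = toy_gene("TGLN", "5", 1000, [9], special_codons={1: "ATG", 2: "CGA", 3: "TAA"})
        # CGA -> TGA at codon 2 first base
        v = _variant_at_cds(gene, 4, "T")
        ann = classify_variant(v, gene, cfg)
        assert ann.impact_class is ImpactClass.NONSENSE
        assert ann.protein_label == "p.R2*"

    def test_ref_mismatch_raises(self, big_gene, cfg):
        pos, ref, _ = _cds_site(big_gene, 6437, "A")
        wrong_ref = "ACGT".replace(ref, "")[0]
        v = Variant(contig=big_gene.contig, pos=pos, ref=wrong_ref, alt="T" if wrong_ref != "T" else "C")
        with pytest.raises(AnnotationError, match="CDS"):
            classify_variant(v, big_gene, cfg)

    def test_classification_is_pure(self, big_gene, cfg):
        v = _variant_at_cds(big_gene, 6437, "A")
        assert classify_variant(v, big_gene, cfg) == classify_variant(v, big_gene, cfg)


class TestSpliceAndIntron:
    def test_donor_plus_one_after_exon_11(self, big_gene, cfg):
        v = Variant(big_gene.contig, big_gene.exons[10][1] + 1, "G", "A")
        ann = classify_variant(v, big_gene, cfg)
        assert ann.impact_class is ImpactClass.SPLICE
        assert ann.cdna_label == "c.4320+1G>A"
        assert ann.ivs_label == "IVS11+1"
        assert ann.location == "Intron"

    def test_acceptor_minus_one_before_exon_12(self, big_gene, cfg):
        v = Variant(big_gene.contig, big_gene.exons[11][0] - 1, "G", "C")
        ann = classify_variant(v, big_gene, cfg)
        assert ann.impact_class is ImpactClass.SPLICE
        assert ann.cdna_label == "c.4321-1G>C"
        assert ann.ivs_label == "IVS11-1"

    def test_deep_intronic_beyond_window(self, big_gene, cfg):
        v = Variant(big_gene.contig, big_gene.exons[10][1] + 3, "G", "A")
        ann = classify_variant(v, big_gene, cfg)
        assert ann.impact_class is ImpactClass.INTRONIC
        assert ann.ivs_label == "IVS11+3"

    def test_outside_gene_span_is_intergenic(self, big_gene, cfg):
        v = Variant(big_gene.contig, big_gene.span[1] + 1000, "G", "A")
        ann = classify_variant(v, big_gene, cfg)
        assert ann.impact_class is ImpactClass.INTERGENIC and ann.gene is None


class TestIndels:
    def test_two_base_deletion_is_frameshift(self, big_gene, cfg):
        pos, ref, _ = _cds_site(big_gene, 100, "A")
        nxt = big_gene.cds_sequence[100:102]
        v = Variant(big_gene.contig, pos, ref + nxt, ref)
        ann = classify_variant(v, big_gene, cfg)
        assert ann.impact_class is ImpactClass.FRAMESHIFT_INDEL

    def test_three_base_deletion_is_inframe(self, big_gene, cfg):
        pos, ref, _ = _cds_site(big_gene, 100, "A")
        nxt = big_gene.cds_sequence[100:103]
        v = Variant(big_gene.contig, pos, ref + nxt, ref)
        ann = classify_variant(v, big_gene, cfg)
        assert ann.impact_class is ImpactClass.INFRAME_INDEL


def _brute_force_class(gene, cds_index, alt_base):
    """Independent oracle: retranslate the whole mutant CDS and diff."""
    cds = gene.cds_sequence
    mutant = cds[: cds_index - 1] + alt_base + cds[cds_index:]
    wt_protein = str(Seq(cds).translate())
    mut_protein = str(Seq(mutant).translate())
    codon = (cds_index - 1) // 3
    if wt_protein == mut_protein:
        return ImpactClass.SYNONYMOUS
    if mut_protein[codon] == "*" or wt_protein[codon] == "*":
        return ImpactClass.NONSENSE
    return ImpactClass.MISSENSE


def test_every_cds_snv_matches_full_retranslation_oracle(big_gene, cfg):
    """Sampled CDS substitutions: the single-codon classification agrees
    with brute-force full-CDS retranslation, and exactly one of the three
    coding classes is assigned."""
    rng = np.random.default_rng(42)
    coding = {ImpactClass.MISSENSE, ImpactClass.NONSENSE, ImpactClass.SYNONYMOUS}
    for cds_index in rng.integers(1, len(big_gene.cds_sequence) + 1, size=300):
        cds_index = int(cds_index)
        ref_base = big_gene.cds_sequence[cds_index - 1]
        for alt_base in "ACGT".replace(ref_base, ""):
            v = _variant_at_cds(big_gene, cds_index, alt_base)
            ann = classify_variant(v, big_gene, cfg)
            assert ann.impact_class in coding
            assert ann.impact_class is _brute_force_class(big_gene, cds_index, alt_base)


def test_minus_strand_gene_gives_same_protein_labels(cfg):
    """A minus-strand gene with the same CDS yields identical protein
    labels as its plus-strand twin for every sampled substitution."""
    plus = toy_gene("TWINP", "3", 50_000, [150] * 4, strand="+")
    minus = toy_gene("TWINP", "3", 90_000, [150] * 4, strand="-")
    assert plus.cds_sequence == minus.cds_sequence  # same symbol, same filler
    rng = np.random.default_rng(7)
    for cds_index in rng.integers(1, 601, size=50):
        cds_index = int(cds_index)
        ref_base = plus.cds_sequence[cds_index - 1]
        alt_base = "ACGT".replace(ref_base, "")[0]
        ann_p = classify_variant(_variant_at_cds(plus, cds_index, alt_base), plus, cfg)
        ann_m = classify_variant(_variant_at_cds(minus, cds_index, alt_base), minus, cfg)
        assert ann_p.protein_label == ann_m.protein_label
        assert ann_p.cdna_label == ann_m.cdna_label


class TestScoresAndDomains:
    def test_scores_attached_verbatim(self):
        key = ("17", 18049349, "G", "A")
        anns = {key: Annotation(gene="MYO15A", impact_class=ImpactClass.MISSENSE)}
        table = ScoreTable({key: {"conserved": 1.0, "sift": 0.0, "polyphen2": 0.99, "mupro": -0.743}})
        joined = join_scores(anns, table)
        assert joined[key].scores["mupro"] == -0.743

    def test_absent_key_scores_none(self):
        key = ("17", 1, "G", "A")
        anns = {key: Annotation(gene="X", impact_class=ImpactClass.MISSENSE)}
        assert join_scores(anns, ScoreTable({}))[key].scores is None

    def test_domain_from_residue(self):
        domains = {"MYO15A": [((1, 1700), "Motor"), ((2000, 2400), "MyTH4")]}
        ann = Annotation(gene="MYO15A", impact_class=ImpactClass.MISSENSE,
                         protein_position=2146)
        assert assign_domain(ann, domains).domain_label == "MyTH4"

    def test_residue_outside_all_domains(self):
        domains = {"MYO15A": [((2000, 2400), "MyTH4")]}
        ann = Annotation(gene="MYO15A", impact_class=ImpactClass.MISSENSE,
                         protein_position=3474)
        assert assign_domain(ann, domains).domain_label is None

    def test_splice_variant_maps_through_cds_anchor(self):
        # donor +1 after c.4320 anchors to residue 1440, inside the motor domain
        domains = {"MYO15A": [((1, 1700), "Motor")]}
        ann = Annotation(gene="MYO15A", impact_class=ImpactClass.SPLICE, cds_anchor=4320)
        assert assign_domain(ann, domains).domain_label == "Motor"
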