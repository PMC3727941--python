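"""Gene-model-based functional classification and HGVS-like naming.

Each variant is classified against a single-transcript gene model into one
impact class (missense/nonsense/synonymous, splice, in-frame or frameshift
indel, intronic, UTR, intergenic) and given a c.-style cDNA label.  Splice
classification follows the clinical convention: the first ``splice_window``
intronic bases past an exon boundary (default 2, the canonical GT/AG
dinucleotides) count as splice-site.  Intronic variants also get the legacy
IVS alias, with intron *k* numbered after exon *k* in transcript order, so
a donor +1 change after the 11th exon reads ``IVS11+1``.

Amino-acid changes are named on the one-letter scale (``p.R2146Q``).
External predictor scores are pass-through annotations joined from a table;
nothing here computes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq, reverse_complement

from .core import GeneModel, ImpactClass, PipelineConfig, Variant, VariantKey


class AnnotationError(ValueError):
    """Variant/model disagreement, e.g. REF not matching the CDS sequence."""


@dataclass
class Annotation:
    """Functional annotation of one variant against one gene model."""

    gene: Optional[str]
    impact_class: ImpactClass
    cdna_label: Optional[str] = None
    ivs_label: Optional[str] = None
    protein_label: Optional[str] = None
    protein_position: Optional[int] = None
    #: nearest CDS base (1-based transcript coordinate); set for coding and
    #: near-exon intronic variants, used to map splice hits onto protein domains
    cds_anchor: Optional[int] = None
    domain_label: Optional[str] = None
    scores: Optional[dict[str, Optional[float]]] = None
    #: human-readable transcript location, e.g. "Exon 29" or "Intron"
    location: Optional[str] = None


@lru_cache(maxsize=256)
def _cds_index_by_genomic_pos(gene: GeneModel) -> dict[int, int]:
    """Map genomic position → 1-based CDS coordinate (translation order)."""
    return {pos: i + 1 for i, pos in enumerate(gene.cds_genomic_positions())}


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon, ``*`` for stop."""
    codon = codon.upper()
    if codon in standard_dna_table.stop_codons:
        return "*"
    return str(Seq(codon).translate())


def _tx_allele(allele: str, strand: str) -> str:
    return allele if strand == "+" else reverse_complement(allele)


def _exon_number(gene: GeneModel, pos: int) -> Optional[int]:
    """1-based exon number in transcript order for an exonic position."""
    for i, (s, e) in enumerate(gene.exons):
        if s <= pos <= e:
            return i + 1 if gene.strand == "+" else len(gene.exons) - i
    return None


def _classify_coding_snv(
    v: Variant, gene: GeneModel, cds_index: int
) -> Annotation:
    ref_t = _tx_allele(v.ref, gene.strand)
    alt_t = _tx_allele(v.alt, gene.strand)
    cds = gene.cds_sequence
    if cds[cds_index - 1] != ref_t:
        raise AnnotationError(
            f"{gene.symbol}: REF {v.ref} at {v.contig}:{v.pos} maps to CDS "
            f"position {cds_index} but the model has {cds[cds_index - 1]}"
        )
    codon_number = (cds_index - 1) // 3 + 1
    codon_start = (codon_number - 1) * 3
    codon = cds[codon_start : codon_start + 3]
    offset = (cds_index - 1) % 3
    mutant = codon[:offset] + alt_t + codon[offset + 1 :]
    aa_ref, aa_alt = translate_codon(codon), translate_codon(mutant)
    if aa_ref == aa_alt:
        impact = ImpactClass.SYNONYMOUS
    elif aa_alt == "*" or aa_ref == "*":
        # premature stop gain, and stop-loss folded into the same class
        impact = ImpactClass.NONSENSE
    else:
        impact = ImpactClass.MISSENSE
    return Annotation(
        gene=gene.symbol,
        impact_class=impact,
        cdna_label=f"c.{cds_index}{ref_t}>{alt_t}",
        protein_label=f"p.{aa_ref}{codon_number}{aa_alt}",
        protein_position=codon_number,
        cds_anchor=cds_index,
        location=f"Exon {_exon_number(gene, v.pos)}",
    )


def _classify_indel(v: Variant, gene: GeneModel, cds_index: int) -> Annotation:
    delta = abs(len(v.ref) - len(v.alt))
    impact = (
        ImpactClass.FRAMESHIFT_INDEL if delta % 3 else ImpactClass.INFRAME_INDEL
    )
    if len(v.ref) > len(v.alt):
        label = f"c.{cds_index + 1}_{cds_index + delta}del" if delta > 1 else f"c.{cds_index + 1}del"
    elif len(v.alt) > len(v.ref):
        inserted = _tx_allele(v.alt[len(v.ref):], gene.strand)
        label = f"c.{cds_index}_{cds_index + 1}ins{inserted}"
    else:
        label = f"c.{cds_index}delins"
    return Annotation(
        gene=gene.symbol,
        impact_class=impact,
        cdna_label=label,
        protein_position=(cds_index - 1) // 3 + 1,
        cds_anchor=cds_index,
        location=f"Exon {_exon_number(gene, v.pos)}",
    )


def _classify_intronic(
    v: Variant, gene: GeneModel, cfg: PipelineConfig
) -> Annotation:
    exons = gene.exons
    n = len(exons)
    left = max(i for i, (_s, e) in enumerate(exons) if e < v.pos)  # 0-based
    right = left + 1
    cds_map = _cds_index_by_genomic_pos(gene)
    if gene.strand == "+":
        k_donor = v.pos - exons[left][1]
        k_acceptor = exons[right][0] - v.pos
        donor_anchor_pos, acceptor_anchor_pos = exons[left][1], exons[right][0]
        intron_number = left + 1
    else:
        k_donor = exons[right][0] - v.pos
        k_acceptor = v.pos - exons[left][1]
        donor_anchor_pos, acceptor_anchor_pos = exons[right][0], exons[left][1]
        intron_number = n - right + 1  # intron follows transcript exon n-right+1
    ref_t, alt_t = _tx_allele(v.ref, gene.strand), _tx_allele(v.alt, gene.strand)
    if k_donor <= k_acceptor:
        k, anchor_pos, sign = k_donor, donor_anchor_pos, "+"
    else:
        k, anchor_pos, sign = k_acceptor, acceptor_anchor_pos, "-"
    anchor = cds_map.get(anchor_pos)
    if anchor is not None and v.is_snv:
        cdna = f"c.{anchor}{sign}{k}{ref_t}>{alt_t}"
    elif anchor is not None:
        cdna = f"c.{anchor}{sign}{k}"
    else:
        cdna = None
    impact = ImpactClass.SPLICE if k <= cfg.splice_window else ImpactClass.INTRONIC
    return Annotation(
        gene=gene.symbol,
        impact_class=impact,
        cdna_label=cdna,
        ivs_label=f"IVS{intron_number}{sign}{k}",
        cds_anchor=anchor,
        location="Intron",
    )


def classify_variant(
    v: Variant, gene: GeneModel, cfg: Optional[PipelineConfig] = None
) -> Annotation:
    """Classify one biallelic variant against one gene model.

    Coding SNVs are resolved by translating the affected codon before and
    after the change; indels touching the CDS are frameshift when the
    length change is not a multiple of 3; intronic positions within
    ``splice_window`` of an exon boundary are splice-site.  Raises
    :class:`AnnotationError` when the VCF REF contradicts the model's CDS
    sequence — that always signals mismatched inputs.
    """
    cfg = cfg or PipelineConfig()
    from .core import normalize_contig

    if normalize_contig(v.contig) != normalize_contig(gene.contig):
        return Annotation(gene=None, impact_class=ImpactClass.INTERGENIC)
    span_lo, span_hi = gene.span
    if not (span_lo <= v.pos <= span_hi):
        return Annotation(gene=None, impact_class=ImpactClass.INTERGENIC)
    cds_map = _cds_index_by_genomic_pos(gene)
    in_exon = any(s <= v.pos <= e for s, e in gene.exons)
    if in_exon:
        cds_index = cds_map.get(v.pos)
        if cds_index is None:
            return Annotation(
                gene=gene.symbol,
                impact_class=ImpactClass.UTR,
                location=f"Exon {_exon_number(gene, v.pos)}",
            )
        if v.is_snv:
            return _classify_coding_snv(v, gene, cds_index)
        return _classify_indel(v, gene, cds_index)
    return _classify_intronic(v, gene, cfg)


def annotate_variants(
    variants: Sequence[Variant],
    gene_models: Mapping[str, GeneModel],
    cfg: Optional[PipelineConfig] = None,
) -> dict[VariantKey, Annotation]:
    """Classify each variant against the gene model whose span contains it.

    With single-transcript, non-overlapping toy gene models at most one
    gene matches; a variant outside every model is INTERGENIC.
    """
    cfg = cfg or PipelineConfig()
    annotations: dict[VariantKey, Annotation] = {}
    for v in variants:
        ann = Annotation(gene=None, impact_class=ImpactClass.INTERGENIC)
        for gene in gene_models.values():
            candidate = classify_variant(v, gene, cfg)
            if candidate.impact_class is not ImpactClass.INTERGENIC:
                ann = candidate
                break
        annotations[v.key] = ann
    return annotations


def join_scores(
    annotations: Mapping[VariantKey, Annotation], scores
) -> dict[VariantKey, Annotation]:
    """Attach external in-silico scores (conservation, predictor outputs)
    where the variant key matches; variants absent from the table keep
    ``scores=None``.  Values are passed through verbatim."""
    out = {}
    for key, ann in annotations.items():
        entry = scores.get(key) if scores is not None else None
        out[key] = replace(ann, scores=dict(entry) if entry else None)
    return out


def assign_domain(
    annotation: Annotation,
    domain_map: Mapping[str, list[tuple[tuple[int, int], str]]],
) -> Annotation:
    """Tag the annotation with the protein domain containing its residue.

    Missense/nonsense/synonymous variants use their codon number directly;
    splice and intronic variants are mapped through the nearest CDS base.
    Returns the annotation unchanged when no residue can be derived or no
    domain interval covers it.
    """
    if annotation.gene is None:
        return annotation
    residue = annotation.protein_position
    if residue is None and annotation.cds_anchor is not None:
        residue = (annotation.cds_anchor - 1) // 3 + 1
    if residue is None:
        return annotation
    for (start, end), label in domain_map.get(annotation.gene.upper(), []):
        if start <= residue <= end:
            return replace(annotation, domain_label=label)
    return annotation
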