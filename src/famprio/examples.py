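"""Published worked-example inputs for two deafness families.

These builders encode, as program inputs, the genotypes and candidate
variant lists of two small families with autosomal recessive
nonsyndromic hearing loss in which exome sequencing implicated *MYO15A*:

* **SR-903**: two affected siblings and both parents sampled.  Five
  deafness-panel candidate variants survived filtering in the proband and
  three in the sibling; three were shared, all in *MYO15A* (a splice-donor
  change IVS11+1 / c.4320+1G>A, the missense p.R2146Q, and p.S3474G).
  p.S3474G is catalogued at MAF 0.002 and is excluded; the remaining pair
  segregates in trans — the missense from the father, the splice variant
  from the mother.
* **SR-285**: two affected siblings, parents without DNA samples.  The
  proband carried three panel candidates (p.Q445R in *GRHL2*, p.T1321S in
  *TECTA*, p.S2161F in *MYO15A*); only p.S2161F was shared with the
  sibling, a lone heterozygote whose phase cannot be established.

Genomic positions of the three *MYO15A* variants are the published hg19
coordinates.  Variants whose coordinates were not published (the excluded
p.S3474G, the proband-private candidates, and the *GRHL2*/*TECTA*
variants) are placed at synthetic positions; their counts, genes and
genotype patterns follow the published tables.
"""

from __future__ import annotations

from .annotate import Annotation
from .core import ImpactClass, Individual, Pedigree, Variant
from .io import GenePanel, PopulationDB, ScoreTable

# Published hg19 positions of the three MYO15A variants.
SPLICE_KEY = ("17", 18035881, "G", "A")  # c.4320+1G>A, IVS11+1
R2146Q_KEY = ("17", 18049349, "G", "A")  # c.6437G>A, p.R2146Q
S2161F_KEY = ("17", 18049394, "C", "T")  # c.6482C>T, p.S2161F
# Synthetic position for the excluded p.S3474G (coordinates unpublished).
S3474G_KEY = ("17", 18057000, "A", "G")

DEAFNESS_PANEL = GenePanel(("MYO15A", "GJB2", "SLC26A4", "OTOF", "TECTA", "GRHL2", "CDH23"))


def sr903_pedigree() -> Pedigree:
    return Pedigree(
        [
            Individual("SR-903F", None, None, "1", affected=False),
            Individual("SR-903M", None, None, "2", affected=False),
            Individual("SR-903", "SR-903F", "SR-903M", "1", affected=True),
            Individual("SR-903B", "SR-903F", "SR-903M", "2", affected=True),
        ]
    )


def sr285_pedigree() -> Pedigree:
    return Pedigree(
        [
            Individual("SR-285F", None, None, "1", affected=False, sample_available=False),
            Individual("SR-285M", None, None, "2", affected=False, sample_available=False),
            Individual("SR-285", "SR-285F", "SR-285M", "1", affected=True),
            Individual("SR-285S", "SR-285F", "SR-285M", "2", affected=True),
        ]
    )


def sr903_variants() -> list[Variant]:
    """The SR-903 family's post-funnel panel candidates with genotypes.

    Both siblings are heterozygous for the three shared variants; the
    father carries only the missense, the mother only the splice variant.
    Two further proband-private candidates (synthetic positions in other
    panel genes) bring the proband's list to five.
    """
    shared_gts = {"SR-903": 1, "SR-903B": 1}
    return [
        Variant(*SPLICE_KEY, mapping_quality=58.0,
                genotypes={**shared_gts, "SR-903F": 0, "SR-903M": 1}),
        Variant(*R2146Q_KEY, mapping_quality=59.0,
                genotypes={**shared_gts, "SR-903F": 1, "SR-903M": 0}),
        Variant(*S3474G_KEY, mapping_quality=55.0,
                genotypes={**shared_gts, "SR-903F": 0, "SR-903M": 1}),
        # proband-private panel candidates (sibling non-carrier)
        Variant("13", 20_763_000, "C", "T", mapping_quality=50.0,
                genotypes={"SR-903": 1, "SR-903B": 0, "SR-903F": 1, "SR-903M": 0}),
        Variant("10", 73_550_000, "G", "A", mapping_quality=51.0,
                genotypes={"SR-903": 1, "SR-903B": 0, "SR-903F": 0, "SR-903M": 1}),
    ]


def sr903_annotations() -> dict[tuple, Annotation]:
    """Functional annotations of the SR-903 candidates as published."""
    return {
        SPLICE_KEY: Annotation(
            gene="MYO15A", impact_class=ImpactClass.SPLICE,
            cdna_label="c.4320+1G>A", ivs_label="IVS11+1",
            domain_label="Motor", cds_anchor=4320, location="Intron",
        ),
        R2146Q_KEY: Annotation(
            gene="MYO15A", impact_class=ImpactClass.MISSENSE,
            cdna_label="c.6437G>A", protein_label="p.R2146Q",
            protein_position=2146, cds_anchor=6437, domain_label="MyTH4",
            location="Exon 29",
        ),
        S3474G_KEY: Annotation(
            gene="MYO15A", impact_class=ImpactClass.MISSENSE,
            protein_label="p.S3474G", protein_position=3474,
        ),
        ("13", 20_763_000, "C", "T"): Annotation(
            gene="GJB2", impact_class=ImpactClass.MISSENSE, protein_label="p.A10V",
            protein_position=10,
        ),
        ("10", 73_550_000, "G", "A"): Annotation(
            gene="CDH23", impact_class=ImpactClass.MISSENSE, protein_label="p.R500Q",
            protein_position=500,
        ),
    }


def genomes_catalogue() -> PopulationDB:
    """The late-stage frequency catalogue that excludes p.S3474G (MAF 0.002)."""
    return PopulationDB("genomes1k", {S3474G_KEY: 0.002})


def sr285_variants() -> list[Variant]:
    """SR-285 proband's three panel candidates; only p.S2161F in MYO15A is
    carried by the affected sibling."""
    return [
        Variant("8", 102_505_000, "A", "G", mapping_quality=48.0,
                genotypes={"SR-285": 1, "SR-285S": 0}),
        Variant("11", 121_060_000, "A", "T", mapping_quality=52.0,
                genotypes={"SR-285": 1, "SR-285S": 0}),
        Variant(*S2161F_KEY, mapping_quality=57.0,
                genotypes={"SR-285": 1, "SR-285S": 1}),
    ]


def sr285_annotations() -> dict[tuple, Annotation]:
    return {
        ("8", 102_505_000, "A", "G"): Annotation(
            gene="GRHL2", impact_class=ImpactClass.MISSENSE, protein_label="p.Q445R",
            protein_position=445,
        ),
        ("11", 121_060_000, "A", "T"): Annotation(
            gene="TECTA", impact_class=ImpactClass.MISSENSE, protein_label="p.T1321S",
            protein_position=1321,
        ),
        S2161F_KEY: Annotation(
            gene="MYO15A", impact_class=ImpactClass.MISSENSE,
            cdna_label="c.6482C>T", protein_label="p.S2161F",
            protein_position=2161, cds_anchor=6482, domain_label="MyTH4",
            location="Exon 29",
        ),
    }


def published_scores() -> ScoreTable:
    """In-silico predictor scores as printed for the two missense variants."""
    return ScoreTable(
        {
            R2146Q_KEY: {"conserved": 1.0, "sift": 0.0, "polyphen2": 0.99, "mupro": -0.743},
            S2161F_KEY: {"conserved": 1.0, "sift": 0.0, "polyphen2": 1.0, "mupro": -0.543},
        }
    )
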