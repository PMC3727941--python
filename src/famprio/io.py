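"""Readers and writers for every external format the pipeline touches.

VCF handling delegates to :mod:`pysam`; everything else is a small
tab-separated or JSON format documented in the function that reads it.
Contig naming dialects (``chr17`` vs ``17``) are normalized for identity
purposes only — files are re-emitted in the dialect they arrived in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam

from .core import (
    GeneModel,
    GenotypeCall,
    Individual,
    Pedigree,
    Variant,
    VariantKey,
    normalize_contig,
)
from .coverage import DepthTrack

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: PathLike) -> tuple[list[Variant], list[str]]:
    """Read a multi-sample VCF into decomposed biallelic :class:`Variant` rows.

    Multi-allelic records are split into one ``Variant`` per ALT allele; a
    sample's allele count for each split variant is the number of its called
    alleles equal to that ALT, so the per-sample counts sum back to the
    original alternate-allele dosage.  Site mapping quality is taken from
    ``INFO/MQ`` when present.  A genotype with any uncalled allele is
    treated as missing.  QUAL and FILTER are parsed but deliberately unused.
    """
    path = str(path)
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise FormatError(f"{path}: malformed VCF header: {exc}") from exc
    samples = list(vcf.header.samples)
    variants: list[Variant] = []
    for n, rec in enumerate(vcf, start=1):
        try:
            alts = rec.alts or ()
            mq = rec.info.get("MQ")
            mq = float(mq) if mq is not None else None
            for alt_index, alt in enumerate(alts, start=1):
                genotypes: dict[str, GenotypeCall] = {}
                for sample in samples:
                    gt = rec.samples[sample].get("GT")
                    if gt is None or any(a is None for a in gt):
                        genotypes[sample] = None
                    else:
                        genotypes[sample] = sum(1 for a in gt if a == alt_index)
                variants.append(
                    Variant(
                        contig=rec.contig,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        mapping_quality=mq,
                        genotypes=genotypes,
                    )
                )
        except (ValueError, KeyError) as exc:
            raise FormatError(f"{path}: bad VCF record #{n} at line ~{n}: {exc}") from exc
    return variants, samples


def write_vcf(variants: Sequence[Variant], samples: Sequence[str], path: PathLike) -> None:
    """Write biallelic variants as an uncompressed VCF (GT only, INFO/MQ)."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for contig in dict.fromkeys(v.contig for v in variants):
        header.contigs.add(contig)
    for sample in samples:
        header.add_sample(sample)
    out = pysam.VariantFile(str(path), "w", header=header)
    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1), None: (None, None)}
    try:
        for v in variants:
            rec = out.new_record(
                contig=v.contig,
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            if v.mapping_quality is not None:
                rec.info["MQ"] = float(v.mapping_quality)
            for sample in samples:
                rec.samples[sample]["GT"] = gt_map[v.genotypes.get(sample)]
            out.write(rec)
    finally:
        out.close()


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

def read_ped(path: PathLike) -> Pedigree:
    """Read a 6-column PED file (family, id, father, mother, sex, phenotype).

    Phenotype coding: 2 = affected, 1 = unaffected, 0 or -9 = unknown.
    An optional 7th column ``sample_available`` in {0,1} marks whether DNA
    was available for the individual (default 1).  A single family per file.
    """
    individuals: list[Individual] = []
    families = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected >=6 PED columns")
            fam, iid, father, mother, sex, pheno = fields[:6]
            families.add(fam)
            available = True
            if len(fields) >= 7:
                available = fields[6] == "1"
            affected: Optional[bool]
            if pheno == "2":
                affected = True
            elif pheno == "1":
                affected = False
            elif pheno in ("0", "-9"):
                affected = None
            else:
                raise FormatError(f"{path}:{lineno}: bad phenotype code {pheno!r}")
            individuals.append(
                Individual(
                    id=iid,
                    father=None if father == "0" else father,
                    mother=None if mother == "0" else mother,
                    sex=sex,
                    affected=affected,
                    sample_available=available,
                )
            )
    if len(families) > 1:
        raise FormatError(f"{path}: multiple families {sorted(families)}; one per run")
    return Pedigree(individuals)


def write_ped(pedigree: Pedigree, family_id: str, path: PathLike) -> None:
    with open(path, "w") as fh:
        for ind in pedigree.individuals:
            pheno = {True: "2", False: "1", None: "0"}[ind.affected]
            fh.write(
                "\t".join(
                    [
                        family_id,
                        ind.id,
                        ind.father or "0",
                        ind.mother or "0",
                        ind.sex,
                        pheno,
                        "1" if ind.sample_available else "0",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Population databases
# ---------------------------------------------------------------------------

#: Sentinel MAF for database entries recorded by membership only (e.g. a
#: small control-exome set where presence, not frequency, is what matters).
PRESENT = None


@dataclass
class PopulationDB:
    """A variant catalogue: identity key → MAF, or presence-only.

    Lookup is exact on the (contig, pos, ref, alt) identity key; entries
    whose MAF is :data:`PRESENT` (``None``) carry membership semantics.
    """

    name: str
    entries: dict[VariantKey, Optional[float]] = field(default_factory=dict)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.entries

    def maf(self, key: VariantKey) -> Optional[float]:
        return self.entries.get(key)

    def excludes(self, key: VariantKey, maf_threshold: float = 0.0) -> bool:
        """True when presence in this database disqualifies the variant:
        any presence-only entry, or a recorded MAF >= ``maf_threshold``."""
        if key not in self.entries:
            return False
        maf = self.entries[key]
        return maf is PRESENT or maf >= maf_threshold

    def union(self, other: "PopulationDB", name: Optional[str] = None) -> "PopulationDB":
        merged = dict(self.entries)
        merged.update(other.entries)
        return PopulationDB(name or f"{self.name}+{other.name}", merged)


def read_population_db(path: PathLike, name: str) -> PopulationDB:
    """Read a population database TSV: ``contig pos ref alt maf [db_name]``.

    A blank MAF records presence without a frequency.  Duplicate keys with
    conflicting MAF values are an error; exact duplicates are tolerated.
    """
    entries: dict[VariantKey, Optional[float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected >=4 columns")
            contig, pos, ref, alt = fields[:4]
            maf_str = fields[4].strip() if len(fields) > 4 else ""
            key: VariantKey = (normalize_contig(contig), int(pos), ref.upper(), alt.upper())
            maf = float(maf_str) if maf_str else PRESENT
            if maf is not PRESENT and not (0.0 <= maf <= 1.0):
                raise FormatError(f"{path}:{lineno}: MAF {maf} outside [0,1]")
            if key in entries and entries[key] != maf:
                raise FormatError(
                    f"{path}:{lineno}: conflicting MAF for {key}: "
                    f"{entries[key]} vs {maf}"
                )
            entries[key] = maf
    return PopulationDB(name=name, entries=entries)


def write_population_db(db: PopulationDB, path: PathLike) -> None:
    with open(path, "w") as fh:
        for (contig, pos, ref, alt), maf in sorted(db.entries.items()):
            maf_str = "" if maf is PRESENT else repr(maf)
            fh.write(f"{contig}\t{pos}\t{ref}\t{alt}\t{maf_str}\t{db.name}\n")


# ---------------------------------------------------------------------------
# Gene panel, gene models, scores, domain map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenePanel:
    """Curated disease-gene list; symbols are case-normalized to upper."""

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        norm = tuple(dict.fromkeys(s.upper() for s in self.symbols))
        if not norm:
            raise FormatError("gene panel is empty")
        object.__setattr__(self, "symbols", norm)

    def __contains__(self, symbol: Optional[str]) -> bool:
        return symbol is not None and symbol.upper() in self.symbols


def read_gene_panel(path: PathLike) -> GenePanel:
    """One gene symbol per line; ``#`` comments and blank lines ignored."""
    symbols = []
    with open(path) as fh:
        for line in fh:
            token = line.split("#", 1)[0].strip()
            if token:
                symbols.append(token)
    return GenePanel(tuple(symbols))


def read_gene_models(path: PathLike) -> dict[str, GeneModel]:
    """Read gene models from JSON: a list of objects with keys ``symbol``,
    ``contig``, ``strand``, ``exons`` (list of [start, end]),
    ``cds_interval`` ([start, end]) and ``cds_sequence``."""
    with open(path) as fh:
        raw = json.load(fh)
    models: dict[str, GeneModel] = {}
    for obj in raw:
        g = GeneModel(
            symbol=obj["symbol"],
            contig=obj["contig"],
            strand=obj["strand"],
            exons=tuple(tuple(x) for x in obj["exons"]),
            cds_interval=tuple(obj["cds_interval"]),
            cds_sequence=obj["cds_sequence"],
        )
        if g.symbol in models:
            raise FormatError(f"{path}: duplicate gene model {g.symbol}")
        models[g.symbol] = g
    return models


def write_gene_models(models: Mapping[str, GeneModel], path: PathLike) -> None:
    payload = [
        {
            "symbol": g.symbol,
            "contig": g.contig,
            "strand": g.strand,
            "exons": [list(x) for x in g.exons],
            "cds_interval": list(g.cds_interval),
            "cds_sequence": g.cds_sequence,
        }
        for g in models.values()
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


@dataclass
class ScoreTable:
    """Pass-through in-silico annotations keyed by variant identity.

    Scores (conservation flag plus named predictor scores) are consumed as
    opaque numbers supplied by external tools, never computed here.
    """

    entries: dict[VariantKey, dict[str, Optional[float]]] = field(default_factory=dict)

    def get(self, key: VariantKey) -> Optional[dict[str, Optional[float]]]:
        return self.entries.get(key)


SCORE_COLUMNS = ("conserved", "sift", "polyphen2", "mupro")


def read_score_table(path: PathLike) -> ScoreTable:
    """TSV ``contig pos ref alt conserved sift polyphen2 mupro``; trailing
    score columns are optional and blank cells become ``None``."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=("contig", "pos", "ref", "alt") + SCORE_COLUMNS,
        dtype={"contig": str},
    )
    entries: dict[VariantKey, dict[str, Optional[float]]] = {}
    for row in df.itertuples(index=False):
        key: VariantKey = (
            normalize_contig(str(row.contig)),
            int(row.pos),
            str(row.ref).upper(),
            str(row.alt).upper(),
        )
        entries[key] = {
            col: (None if pd.isna(getattr(row, col)) else float(getattr(row, col)))
            for col in SCORE_COLUMNS
        }
    return ScoreTable(entries)


def read_domain_map(path: PathLike) -> dict[str, list[tuple[tuple[int, int], str]]]:
    """TSV ``gene aa_start aa_end label`` with 1-based inclusive residue
    coordinates; overlapping intervals within a gene are rejected."""
    by_gene: dict[str, list[tuple[tuple[int, int], str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            gene, start, end, label = fields
            by_gene.setdefault(gene.upper(), []).append(((int(start), int(end)), label))
    for gene, intervals in by_gene.items():
        intervals.sort()
        for i in range(len(intervals) - 1):
            if intervals[i + 1][0][0] <= intervals[i][0][1]:
                raise FormatError(f"{path}: overlapping domain intervals for {gene}")
    return by_gene


# ---------------------------------------------------------------------------
# Depth tracks and BED
# ---------------------------------------------------------------------------

def read_depth_track(path: PathLike) -> list[DepthTrack]:
    """Read per-base depths from a TSV ``contig pos depth`` (1-based pos).

    Returns one dense track per contig spanning the minimum to maximum
    observed position; positions absent from the file get depth 0.  Rows
    may arrive unsorted.  Negative depths are an error.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=("contig", "pos", "depth"), dtype={"contig": str},
    )
    if df.empty:
        return []
    if (df["depth"] < 0).any():
        bad = df[df["depth"] < 0].iloc[0]
        raise FormatError(f"{path}: negative depth at {bad.contig}:{bad.pos}")
    tracks = []
    for contig, group in df.groupby("contig", sort=True):
        lo, hi = int(group["pos"].min()), int(group["pos"].max())
        depths = np.zeros(hi - lo + 1, dtype=np.int64)
        depths[group["pos"].to_numpy(dtype=np.int64) - lo] = group["depth"].to_numpy(
            dtype=np.int64
        )
        tracks.append(DepthTrack(contig=str(contig), start=lo, depths=depths))
    return tracks


def write_depth_track(tracks: Iterable[DepthTrack], path: PathLike) -> None:
    with open(path, "w") as fh:
        for t in tracks:
            for offset, depth in enumerate(t.depths):
                fh.write(f"{t.contig}\t{t.start + offset}\t{int(depth)}\n")


def merge_intervals(
    intervals: Iterable[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    """Merge overlapping or abutting 1-based inclusive intervals per contig."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, start, end in intervals:
        by_contig.setdefault(contig, []).append((start, end))
    merged: list[tuple[str, int, int]] = []
    for contig in sorted(by_contig):
        spans = sorted(by_contig[contig])
        current = list(spans[0])
        for start, end in spans[1:]:
            if start <= current[1] + 1:
                current[1] = max(current[1], end)
            else:
                merged.append((contig, current[0], current[1]))
                current = [start, end]
        merged.append((contig, current[0], current[1]))
    return merged


def write_bed(intervals: Iterable[tuple[str, int, int]], path: PathLike) -> None:
    """Write 1-based inclusive intervals as sorted, merged BED3
    (0-based half-open)."""
    with open(path, "w") as fh:
        for contig, start, end in merge_intervals(intervals):
            fh.write(f"{contig}\t{start - 1}\t{end}\n")


def read_bed(path: PathLike) -> list[tuple[str, int, int]]:
    """Read BED3 back into 1-based inclusive intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            contig, start, end = line.split("\t")[:3]
            out.append((contig, int(start) + 1, int(end)))
    return out
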