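"""End-to-end orchestration and report writing.

``run_pipeline`` chains the stages for one family: per-affected-sample
filtering funnel → intersection across affected siblings → recessive
candidate calling → parental segregation → optional control carrier
counting and score joining.  The funnel table mirrors the layout of an
exome-study summary (stage rows × sample columns, with a shared-variants
row for sibling pairs); the candidate table mirrors a published mutation
table (position, cDNA and protein labels, domain, control counts,
predictor scores) split into a "Pathologic variant" section for confirmed
candidates and a "Variants with uncertain pathogenicity" section for the
rest.
"""

from __future__ import annotations

import enum
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .annotate import Annotation, annotate_variants, assign_domain
from .cascade import FilterFunnel, run_funnel, sample_variants, subtract_database
from .core import GeneModel, Pedigree, PipelineConfig, Variant, VariantKey, affected_samples
from .inheritance import (
    CandidateCall,
    ControlCohort,
    InheritanceModel,
    PhaseStatus,
    SegregationStatus,
    call_recessive,
    check_segregation,
    count_carriers,
    shared_variants,
)
from .io import GenePanel, PopulationDB, ScoreTable


class RunOutcome(enum.Enum):
    """Per-family triage outcome, also used as the process exit code."""

    CONFIRMED = 0       # trans-confirmed compound het or consistent homozygote
    UNCERTAIN = 3       # candidates exist but phase/segregation unresolved
    NONE = 4            # no reportable candidate

    @property
    def exit_code(self) -> int:
        return self.value


@dataclass
class PipelineResult:
    family_id: str
    funnels: dict[str, FilterFunnel]
    shared: list[Variant]
    calls: list[CandidateCall]
    annotations: dict[VariantKey, Annotation]
    carrier_counts: dict[VariantKey, tuple[int, int]]
    outcome: RunOutcome
    warnings: list[str] = field(default_factory=list)

    @property
    def reportable_calls(self) -> list[CandidateCall]:
        return [c for c in self.calls if c.reportable]


def _call_confirmed(call: CandidateCall) -> bool:
    if call.model is InheritanceModel.COMPOUND_HET:
        return (
            call.phase_status is PhaseStatus.TRANS_CONFIRMED
            and call.segregation_status is SegregationStatus.CONSISTENT
        )
    if call.model is InheritanceModel.HOMOZYGOUS:
        return call.segregation_status is SegregationStatus.CONSISTENT
    return False


def rank_calls(
    calls: Sequence[CandidateCall],
    annotations: Optional[Mapping[VariantKey, Annotation]] = None,
) -> list[CandidateCall]:
    """Trans-confirmed pairs first, then confirmed homozygotes, then calls
    with external scores attached; stable within ties."""

    def sort_key(call: CandidateCall) -> tuple:
        scored = 0
        if annotations is not None:
            scored = sum(
                1
                for v in call.variants
                if (a := annotations.get(v.key)) is not None and a.scores is not None
            )
        return (
            0 if call.phase_status is PhaseStatus.TRANS_CONFIRMED else 1,
            0 if _call_confirmed(call) else 1,
            -scored,
        )

    return sorted(calls, key=sort_key)


def run_pipeline(
    variants: Sequence[Variant],
    pedigree: Pedigree,
    panel: GenePanel,
    dbs: Sequence[PopulationDB],
    gene_models: Optional[Mapping[str, GeneModel]] = None,
    annotations: Optional[Mapping[VariantKey, Annotation]] = None,
    scores: Optional[ScoreTable] = None,
    domain_map: Optional[Mapping[str, list]] = None,
    cohort: Optional[ControlCohort] = None,
    late_dbs: Sequence[PopulationDB] = (),
    cfg: Optional[PipelineConfig] = None,
    family_id: str = "FAM",
) -> PipelineResult:
    """Run the full family analysis.

    ``dbs`` are subtracted inside each sample's funnel, in order;
    ``late_dbs`` are applied to the shared set *after* sibling
    intersection — the place for a frequency catalogue consulted only when
    vetting the final shared candidates.  Annotations may be supplied
    directly or computed from ``gene_models``.
    """
    cfg = cfg or PipelineConfig()
    if annotations is None:
        if gene_models is None:
            raise ValueError("need gene_models or precomputed annotations")
        annotations = annotate_variants(variants, gene_models, cfg)
    annotations = dict(annotations)
    if domain_map:
        annotations = {k: assign_domain(a, domain_map) for k, a in annotations.items()}

    affected = affected_samples(pedigree)
    warnings: list[str] = []
    if not affected:
        warnings.append("no affected sampled individuals; nothing to analyze")
    missing = [s for s in affected if not any(s in v.genotypes for v in variants)]
    if missing and variants:
        raise ValueError(f"affected samples absent from VCF: {missing}")

    funnels: dict[str, FilterFunnel] = {}
    per_sample_final: list[list[Variant]] = []
    for sample in affected:
        own = sample_variants(variants, sample)
        final, funnel = run_funnel(sample, own, annotations, dbs, panel, cfg, audit=True)
        funnels[sample] = funnel
        per_sample_final.append(final)

    shared = shared_variants(per_sample_final) if per_sample_final else []
    for db in late_dbs:
        shared = subtract_database(shared, db, cfg)

    calls = call_recessive(shared, annotations, pedigree)
    calls = [check_segregation(c, pedigree) for c in calls]

    if scores is not None:
        for key, ann in annotations.items():
            entry = scores.get(key)
            if entry is not None:
                ann.scores = dict(entry)

    carrier_counts: dict[VariantKey, tuple[int, int]] = {}
    if cohort is not None:
        for call in calls:
            for v in call.variants:
                carrier_counts[v.key] = count_carriers(v.key, cohort)

    reportable = [c for c in calls if c.reportable]
    if any(_call_confirmed(c) for c in reportable):
        outcome = RunOutcome.CONFIRMED
    elif reportable:
        outcome = RunOutcome.UNCERTAIN
    else:
        outcome = RunOutcome.NONE
    for funnel in funnels.values():
        warnings.extend(funnel.warnings)
    return PipelineResult(
        family_id=family_id,
        funnels=funnels,
        shared=shared,
        calls=rank_calls(calls, annotations),
        annotations=annotations,
        carrier_counts=carrier_counts,
        outcome=outcome,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------

FUNNEL_ROW_LABELS = {
    "n_total_variants": "Number of total variants",
    "n_coding_variants": "Number of coding variants",
    "mapping_quality": "After mapping-quality filtering",
    "impact_class": "Number of missense, nonsense, splice, and indel variants",
    "panel_genes": "Variants in reported deafness genes",
}


def funnel_frame(result: PipelineResult) -> pd.DataFrame:
    """Stage × sample table of retained counts, with a final shared row."""
    if not result.funnels:
        return pd.DataFrame()
    samples = list(result.funnels)
    stage_names = [name for name, _ in next(iter(result.funnels.values())).stages]
    rows = {}
    for stage in stage_names:
        label = FUNNEL_ROW_LABELS.get(
            stage, f"After {stage[6:]} filtering" if stage.startswith("after_") else stage
        )
        rows[label] = [result.funnels[s].count(stage) for s in samples]
    rows["Shared variants"] = [
        len(result.shared) if len(samples) > 1 else "-" for _ in samples
    ]
    return pd.DataFrame(rows, index=samples).T


def write_funnel(result: PipelineResult, path: str | Path) -> None:
    funnel_frame(result).to_csv(path, sep="\t", index_label="Parameter")


def candidate_frame(result: PipelineResult) -> pd.DataFrame:
    """Candidate report rows, one per variant of each reportable call."""
    rows = []
    for call in result.calls:
        if not call.reportable:
            continue
        section = (
            "Pathologic variant"
            if _call_confirmed(call)
            else "Variants with uncertain pathogenicity"
        )
        for v in call.variants:
            ann = result.annotations.get(v.key)
            scores = (ann.scores if ann else None) or {}
            carriers = result.carrier_counts.get(v.key)
            rows.append(
                {
                    "section": section,
                    "family": result.family_id,
                    "gene": call.gene,
                    "genomic_position": f"Chr{v.key[0]}:{v.pos}",
                    "nucleotide_change": (ann.cdna_label if ann else None) or "-",
                    "amino_acid_change": (
                        (ann.protein_label or ann.ivs_label) if ann else None
                    )
                    or "-",
                    "location": (ann.location if ann else None) or "-",
                    "domain": (ann.domain_label if ann else None) or "-",
                    "controls": f"{carriers[0]}/{carriers[1]}" if carriers else "-",
                    "conserved": scores.get("conserved", "-"),
                    "sift": scores.get("sift", "-"),
                    "polyphen2": scores.get("polyphen2", "-"),
                    "mupro": scores.get("mupro", "-"),
                    "model": call.model.value,
                    "phase": call.phase_status.value,
                    "segregation": call.segregation_status.value,
                    "flags": ";".join(call.flags) or "-",
                }
            )
    return pd.DataFrame(rows)


def write_candidates(result: PipelineResult, path: str | Path) -> None:
    candidate_frame(result).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record: config, seed, input/output digests, warnings.

    Two runs on identical inputs produce identical digests; timings are
    recorded but excluded from any equality comparison.
    """

    config: dict
    seed: int
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)

    def add_input(self, label: str, path: str | Path) -> None:
        self.inputs[label] = _digest(path)

    def add_output(self, label: str, path: str | Path) -> None:
        self.outputs[label] = _digest(path)

    def write(self, path: str | Path) -> None:
        payload = {
            "config": self.config,
            "seed": self.seed,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "warnings": self.warnings,
            "timings": self.timings,
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=str) + "\n")


class StageTimer:
    """Context-manager stopwatch feeding ``RunManifest.timings``."""

    def __init__(self, manifest: RunManifest, label: str) -> None:
        self.manifest, self.label = manifest, label

    def __enter__(self) -> "StageTimer":
        self._t0 = time.perf_counter()
        return self

    def __exit__(self, *exc) -> None:
        self.manifest.timings[self.label] = time.perf_counter() - self._t0
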