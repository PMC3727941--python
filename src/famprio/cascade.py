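"""The per-sample variant filtering funnel.

A raw exome carries tens of thousands of variants; a recessive-disease
candidate list is produced by filtering in a fixed stage order:

    mapping quality  →  protein-affecting impact  →  subtraction against
    each population database in the configured order  →  restriction to the
    disease gene panel

with the retained count recorded after every stage.  Database subtraction
works on variant identity (site + allele), not on genotypes: presence in a
catalogue — or a recorded frequency at or above the exclusion threshold —
removes the variant for every sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .core import ImpactClass, PipelineConfig, Variant, VariantKey
from .annotate import Annotation
from .io import GenePanel, PopulationDB

logger = logging.getLogger(__name__)


class StageOrderError(RuntimeError):
    """A stage ran before the one it depends on (e.g. impact before annotation)."""


@dataclass
class FilterFunnel:
    """Ordered per-stage retained counts for one sample (a funnel table row
    set).  In audit mode the retained variant keys per stage are kept too."""

    sample_id: str
    stages: list[tuple[str, int]] = field(default_factory=list)
    retained_keys: Optional[dict[str, list[VariantKey]]] = None
    warnings: list[str] = field(default_factory=list)
    _last_filter_count: Optional[int] = field(default=None, repr=False)

    def record(
        self, stage: str, variants: Sequence[Variant], descriptive: bool = False
    ) -> None:
        """Append a stage count.  Descriptive pre-stages (raw totals) do not
        participate in the non-increasing check that filtering stages obey."""
        if any(name == stage for name, _ in self.stages):
            raise ValueError(f"duplicate funnel stage {stage!r}")
        if not descriptive:
            if self._last_filter_count is not None and len(variants) > self._last_filter_count:
                raise ValueError(
                    f"funnel count increased at stage {stage!r}: "
                    f"{self._last_filter_count} -> {len(variants)}"
                )
            self._last_filter_count = len(variants)
        self.stages.append((stage, len(variants)))
        if self.retained_keys is not None:
            self.retained_keys[stage] = [v.key for v in variants]

    def count(self, stage: str) -> int:
        for name, n in self.stages:
            if name == stage:
                return n
        raise KeyError(stage)


def filter_quality(
    variants: Sequence[Variant],
    cfg: PipelineConfig,
    funnel: Optional[FilterFunnel] = None,
) -> list[Variant]:
    """Retain variants with mapping quality >= the configured minimum.

    A site with no reported MQ is retained (the caller may simply not emit
    one) but counted as a warning so the run manifest can surface it.
    """
    kept, missing_mq = [], 0
    for v in variants:
        if v.mapping_quality is None:
            missing_mq += 1
            kept.append(v)
        elif v.mapping_quality >= cfg.min_mapping_quality:
            kept.append(v)
    if missing_mq and funnel is not None:
        funnel.warnings.append(f"{missing_mq} variants retained with missing MQ")
    if missing_mq:
        logger.warning("%d variants have no MQ annotation; retained", missing_mq)
    return kept


def filter_impact(
    variants: Sequence[Variant],
    annotations: Mapping[VariantKey, Annotation],
    cfg: PipelineConfig,
) -> list[Variant]:
    """Retain protein-affecting classes (missense, nonsense, splice,
    indels under the defaults); synonymous, deep-intronic, UTR and
    intergenic variants are dropped."""
    kept = []
    for v in variants:
        ann = annotations.get(v.key)
        if ann is None:
            raise StageOrderError(f"variant {v.key} reached impact filter unannotated")
        if ann.impact_class in cfg.retained_impact_classes:
            kept.append(v)
    return kept


def subtract_database(
    variants: Sequence[Variant], db: PopulationDB, cfg: PipelineConfig
) -> list[Variant]:
    """Remove variants present in the database.

    Presence-only entries always exclude; entries with a recorded MAF
    exclude when MAF >= ``maf_exclusion_threshold`` (default 0.0: any
    catalogued frequency, however low, excludes).
    """
    return [
        v for v in variants if not db.excludes(v.key, cfg.maf_exclusion_threshold)
    ]


def restrict_to_panel(
    variants: Sequence[Variant],
    annotations: Mapping[VariantKey, Annotation],
    panel: GenePanel,
) -> list[Variant]:
    """Keep only variants in genes on the disease panel; variants without a
    gene assignment are dropped."""
    kept = []
    for v in variants:
        ann = annotations.get(v.key)
        if ann is not None and ann.gene in panel:
            kept.append(v)
    return kept


# Stage labels, in funnel-table order.  The first two are descriptive
# pre-stages (raw count and gene-overlapping count); filtering begins at
# the quality stage.
STAGE_TOTAL = "n_total_variants"
STAGE_CODING = "n_coding_variants"
STAGE_QUALITY = "mapping_quality"
STAGE_IMPACT = "impact_class"
STAGE_PANEL = "panel_genes"


def run_funnel(
    sample_id: str,
    variants: Sequence[Variant],
    annotations: Mapping[VariantKey, Annotation],
    dbs: Sequence[PopulationDB],
    panel: GenePanel,
    cfg: Optional[PipelineConfig] = None,
    audit: bool = False,
) -> tuple[list[Variant], FilterFunnel]:
    """Run the full filtering cascade for one sample.

    ``variants`` should already be restricted to sites this sample carries
    (use :func:`sample_variants`).  Databases are subtracted in the order
    given; each contributes one funnel stage named ``after_<db.name>``.
    Returns the surviving variants and the stage-count funnel.
    """
    cfg = cfg or PipelineConfig()
    funnel = FilterFunnel(sample_id, retained_keys={} if audit else None)
    funnel.record(STAGE_TOTAL, variants, descriptive=True)
    coding = [
        v
        for v in variants
        if (a := annotations.get(v.key)) is not None and a.gene is not None
    ]
    funnel.record(STAGE_CODING, coding, descriptive=True)

    current = filter_quality(list(variants), cfg, funnel)
    funnel.record(STAGE_QUALITY, current)
    current = filter_impact(current, annotations, cfg)
    funnel.record(STAGE_IMPACT, current)
    for db in dbs:
        current = subtract_database(current, db, cfg)
        funnel.record(f"after_{db.name}", current)
    current = restrict_to_panel(current, annotations, panel)
    funnel.record(STAGE_PANEL, current)
    for stage, n in funnel.stages:
        logger.info("%s: %s -> %d retained", sample_id, stage, n)
    return current, funnel


def sample_variants(variants: Sequence[Variant], sample_id: str) -> list[Variant]:
    """Variants for which ``sample_id`` carries at least one alternate
    allele (missing genotypes count as non-carrier)."""
    from .core import is_carrier

    return [v for v in variants if is_carrier(v.genotypes.get(sample_id))]
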