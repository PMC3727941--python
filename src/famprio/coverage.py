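"""Depth auditing: low-coverage gap detection and coverage summaries.

Exome capture leaves parts of the target poorly covered; variants there are
simply invisible to the caller, so a negative exome result is only
meaningful once those regions are enumerated for orthogonal (Sanger)
follow-up.  A *gap* is a maximal run of consecutive bases whose read depth
falls below a threshold (default 5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .core import GeneModel, PipelineConfig, normalize_contig


@dataclass
class DepthTrack:
    """Dense per-base read depths over one contiguous 1-based interval."""

    contig: str
    start: int
    depths: np.ndarray  # non-negative integers, one per base

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if self.depths.ndim != 1:
            raise ValueError("depth vector must be one-dimensional")
        if (self.depths < 0).any():
            raise ValueError("negative depth")

    @property
    def end(self) -> int:
        """Last covered position, 1-based inclusive."""
        return self.start + len(self.depths) - 1

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def depth_at(self, pos: int) -> int:
        """Depth at a 1-based position; 0 outside the track."""
        if self.start <= pos <= self.end:
            return int(self.depths[pos - self.start])
        return 0


@dataclass(frozen=True)
class CoverageSummary:
    """Mean depth plus the fraction of bases at or above each threshold."""

    mean_depth: float
    fraction_at_least: dict[int, float]
    n_bases: int

    def __post_init__(self) -> None:
        for t, frac in self.fraction_at_least.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction at {t}x outside [0,1]")


def find_gaps(
    track: DepthTrack, cfg: Optional[PipelineConfig] = None, threshold: Optional[int] = None
) -> list[tuple[int, int]]:
    """Maximal runs of bases with depth strictly below the gap threshold.

    Returns 1-based inclusive intervals within the track's own interval.
    With threshold 0 no base can qualify, so the result is empty.
    """
    if threshold is None:
        threshold = (cfg or PipelineConfig()).depth_gap_threshold
    low = track.depths < threshold
    if not low.any():
        return []
    # run-length boundaries of the boolean mask
    edges = np.flatnonzero(np.diff(np.concatenate(([False], low, [False]))))
    starts, ends = edges[::2], edges[1::2]
    return [(track.start + int(s), track.start + int(e) - 1) for s, e in zip(starts, ends)]


def summarize_coverage(
    tracks: Sequence[DepthTrack], cfg: Optional[PipelineConfig] = None
) -> CoverageSummary:
    """Pool all tracks: mean depth and, for each configured threshold t,
    the fraction of bases covered to at least t reads."""
    cfg = cfg or PipelineConfig()
    if not tracks:
        raise ValueError("no depth tracks supplied")
    depths = np.concatenate([t.depths for t in tracks])
    if depths.size == 0:
        raise ValueError("depth tracks contain no bases")
    fractions = {
        int(t): float(np.mean(depths >= t)) for t in cfg.coverage_thresholds
    }
    return CoverageSummary(
        mean_depth=float(depths.mean()),
        fraction_at_least=fractions,
        n_bases=int(depths.size),
    )


def gaps_for_gene(
    tracks: Iterable[DepthTrack], gene: GeneModel, cfg: Optional[PipelineConfig] = None
) -> list[tuple[str, int, int]]:
    """Low-coverage intervals over a gene's exons, each padded by the splice
    window so donor/acceptor sites are audited too.

    Bases not covered by any supplied track count as depth 0, so exons that
    fall entirely outside the tracks are reported whole.  Returns merged,
    sorted 1-based inclusive intervals tagged with the gene's contig,
    ready for :func:`famprio.io.write_bed`.
    """
    cfg = cfg or PipelineConfig()
    window = cfg.splice_window
    threshold = cfg.depth_gap_threshold
    on_contig = [
        t for t in tracks if normalize_contig(t.contig) == normalize_contig(gene.contig)
    ]
    gaps: list[tuple[str, int, int]] = []
    for exon_start, exon_end in gene.exons:
        lo, hi = exon_start - window, exon_end + window
        depths = np.zeros(hi - lo + 1, dtype=np.int64)
        for t in on_contig:
            a, b = max(lo, t.start), min(hi, t.end)
            if a <= b:
                depths[a - lo : b - lo + 1] = t.depths[a - t.start : b - t.start + 1]
        region = DepthTrack(contig=gene.contig, start=lo, depths=depths)
        gaps.extend((gene.contig, s, e) for s, e in find_gaps(region, threshold=threshold))
    from .io import merge_intervals  # local import to avoid a cycle

    return merge_intervals(gaps)
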