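"""Sex-determining-region delineation from heterogeneous mapped evidence.

The core rule: for each evidence class, find the minimal-length genomic
window that fully contains at least ``ceil(fraction * n)`` of that class's
markers (default fraction 0.9); then integrate the per-class windows and any
single point markers into a final region as their bounding hull. The
chromosome carrying the majority of all evidence is the predicted sex
chromosome.
"""

from __future__ import annotations

import heapq
import math
from collections import Counter
from dataclasses import dataclass, field

from .models import ConfigError, EvidenceMarker, GeneModel
from .util import round_half_up


@dataclass
class RegionWindow:
    cls: str
    chrom: str
    start: int
    end: int
    n_contained: int
    n_total: int

    @property
    def containment_pct(self) -> float:
        return round_half_up(100.0 * self.n_contained / self.n_total, 1)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SexRegion:
    chrom: str
    start: int
    end: int
    windows: list[RegionWindow] = field(default_factory=list)
    point_markers: list[EvidenceMarker] = field(default_factory=list)
    predicted_sex_chromosome: bool = True

    @property
    def length_mb(self) -> float:
        return round_half_up((self.end - self.start) / 1e6, 2)


def majority_chromosome(evidence: list[EvidenceMarker]) -> tuple[str, float]:
    """Chromosome holding the largest evidence share, with that share.

    A tie between chromosomes is ambiguous and raises.
    """
    if not evidence:
        raise ConfigError("no evidence markers")
    counts = Counter(m.chrom for m in evidence)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        tied = sorted(c for c, n in ranked if n == ranked[0][1])
        raise ConfigError(f"ambiguous sex chromosome: tie between {tied}")
    chrom, n = ranked[0]
    return chrom, n / len(evidence)


def minimal_covering_window(markers: list[EvidenceMarker],
                            fraction: float = 0.9) -> RegionWindow:
    """Shortest window fully containing at least ``ceil(fraction * n)`` markers.

    A marker counts only if its whole interval lies inside the window. The
    optimum is always anchored on marker boundaries, so candidate starts are
    marker starts and, for each, the k-th smallest end among markers starting
    at or after it is the tightest right edge (kept with a bounded max-heap).
    Among equal-length optima the leftmost wins.
    """
    if not markers:
        raise ConfigError("no markers to cover")
    if not (0.0 < fraction <= 1.0):
        raise ConfigError("fraction must be in (0, 1]")
    chroms = {m.chrom for m in markers}
    if len(chroms) > 1:
        raise ConfigError(f"markers span multiple chromosomes: {sorted(chroms)}")
    n = len(markers)
    k = max(1, math.ceil(fraction * n))

    by_start = sorted(markers, key=lambda m: (m.start, m.end))
    heap: list[int] = []  # max-heap (negated) of the k smallest ends
    best: tuple[int, int, int] | None = None  # (length, start, end)
    for m in reversed(by_start):
        heapq.heappush(heap, -m.end)
        if len(heap) > k:
            heapq.heappop(heap)
        if len(heap) == k:
            end = -heap[0]
            cand = (end - m.start, m.start, end)
            if best is None or cand[0] < best[0] or (cand[0] == best[0] and cand[1] <= best[1]):
                best = cand
    assert best is not None
    _, start, end = best
    contained = sum(1 for m in markers if m.start >= start and m.end <= end)
    cls = markers[0].cls if len({m.cls for m in markers}) == 1 else "other"
    return RegionWindow(cls=cls, chrom=by_start[0].chrom, start=start, end=end,
                        n_contained=contained, n_total=n)


def windows_by_class(evidence: list[EvidenceMarker], chrom: str,
                     fraction: float = 0.9, min_markers: int = 2,
                     ) -> tuple[list[RegionWindow], list[EvidenceMarker]]:
    """Per-class minimal windows on ``chrom``; classes with fewer than
    ``min_markers`` markers contribute their markers as points instead."""
    on_chrom = [m for m in evidence if m.chrom == chrom]
    windows: list[RegionWindow] = []
    points: list[EvidenceMarker] = []
    for cls in sorted({m.cls for m in on_chrom}):
        cls_markers = [m for m in on_chrom if m.cls == cls]
        if len(cls_markers) < min_markers:
            points.extend(cls_markers)
        else:
            windows.append(minimal_covering_window(cls_markers, fraction))
    return windows, points


def integrate_evidence(windows: list[RegionWindow],
                       points: list[EvidenceMarker] | None = None) -> SexRegion:
    """Bounding hull of every per-class window and point marker.

    Integration is a hull, not an intersection: the final region must contain
    all contributing evidence. Mixing chromosomes is an error.
    """
    points = points or []
    if not windows and not points:
        raise ConfigError("nothing to integrate")
    chroms = sorted({w.chrom for w in windows} | {p.chrom for p in points})
    if len(chroms) > 1:
        raise ConfigError(f"evidence on multiple chromosomes: {chroms}")
    start = min([w.start for w in windows] + [p.start for p in points])
    end = max([w.end for w in windows] + [p.end for p in points])
    return SexRegion(chrom=chroms[0], start=start, end=end,
                     windows=list(windows), point_markers=list(points))


def genes_in_region(genes: list[GeneModel], region: SexRegion,
                    known_chroms: set[str] | None = None,
                    mode: str = "overlap") -> list[GeneModel]:
    """Genes overlapping (default) or fully contained in the region, by start.

    ``known_chroms``, when given, guards against gene models from a different
    assembly.
    """
    if mode not in ("overlap", "contained"):
        raise ConfigError(f"unknown overlap mode {mode!r}")
    if known_chroms is not None:
        unknown = sorted({g.chrom for g in genes} - set(known_chroms))
        if unknown:
            raise ConfigError(f"genes on unknown chromosomes: {unknown}")
    if mode == "overlap":
        hits = [g for g in genes if g.chrom == region.chrom
                and g.start < region.end and g.end > region.start]
    else:
        hits = [g for g in genes if g.chrom == region.chrom
                and g.start >= region.start and g.end <= region.end]
    return sorted(hits, key=lambda g: g.start)


def delineate(evidence: list[EvidenceMarker], fraction: float = 0.9,
              min_markers: int = 2) -> SexRegion:
    """Full delineation: majority chromosome, per-class windows, hull."""
    chrom, _share = majority_chromosome(evidence)
    windows, points = windows_by_class(evidence, chrom, fraction, min_markers)
    return integrate_evidence(windows, points)
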