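"""Assembly and annotation summary statistics.

Contiguity statistics follow the common convention: Nx is the length of the
entry at which the descending cumulative sum first reaches x% of the total,
and Lx its 1-based rank. Percentages and densities are reported half-up at
two decimals, the print precision used for genome reports in this field.
"""

from __future__ import annotations

from dataclasses import dataclass

from .models import AssemblySkeleton, ConfigError
from .util import round_half_up


@dataclass
class AssemblyStats:
    total_bp: int
    n_contigs: int
    longest: int
    shortest: int
    mean: float
    N50: int
    L50: int
    N75: int
    L75: int
    N90: int
    L90: int
    gc_fraction: float | None = None


def _nx_lx(lengths_desc: list[int], total: int, x: int) -> tuple[int, int]:
    threshold = total * x / 100.0
    cum = 0
    for rank, length in enumerate(lengths_desc, start=1):
        cum += length
        if cum >= threshold:
            return length, rank
    return lengths_desc[-1], len(lengths_desc)  # unreachable for x <= 100


def assembly_stats(skeleton: AssemblySkeleton,
                   gc_fraction: float | None = None) -> AssemblyStats:
    """Contiguity statistics over chromosomes plus unplaced entries."""
    lengths = [l for _, l in skeleton.entries] + [l for _, l in skeleton.unplaced]
    if not lengths:
        raise ConfigError("assembly skeleton has no entries")
    lengths.sort(reverse=True)
    total = sum(lengths)
    n50, l50 = _nx_lx(lengths, total, 50)
    n75, l75 = _nx_lx(lengths, total, 75)
    n90, l90 = _nx_lx(lengths, total, 90)
    return AssemblyStats(
        total_bp=total, n_contigs=len(lengths), longest=lengths[0],
        shortest=lengths[-1], mean=total / len(lengths),
        N50=n50, L50=l50, N75=n75, L75=l75, N90=n90, L90=l90,
        gc_fraction=gc_fraction)


def anchoring_coverage(part_total: float, whole_total: float) -> float:
    """Percent of the whole captured by the part, half-up to 2 decimals.

    Used both for anchored bases / assembly bases and anchored genes /
    predicted genes.
    """
    if part_total <= 0 or whole_total <= 0:
        raise ConfigError("totals must be positive")
    if part_total > whole_total:
        raise ConfigError(f"part ({part_total}) exceeds whole ({whole_total})")
    return round_half_up(100.0 * part_total / whole_total, 2)


def gene_density(per_chrom_gene_counts: dict[str, int], skeleton: AssemblySkeleton,
                 ) -> tuple[dict[str, float], str, str]:
    """Genes per Mb by chromosome (2 decimals) plus the densest and sparsest.

    Ties on the extremes break by chromosome-name order.
    """
    lengths = skeleton.lengths
    unknown = sorted(set(per_chrom_gene_counts) - set(lengths))
    if unknown:
        raise ConfigError(f"gene counts reference unknown chromosomes: {unknown}")
    densities = {
        chrom: round_half_up(count / (lengths[chrom] / 1e6), 2)
        for chrom, count in per_chrom_gene_counts.items()}
    if not densities:
        raise ConfigError("no gene counts supplied")
    ordered = sorted(densities)  # name order breaks ties
    densest = max(ordered, key=lambda c: (densities[c], ))
    sparsest = min(ordered, key=lambda c: (densities[c], ))
    return densities, densest, sparsest


@dataclass
class LgChrMap:
    """Linkage-group to chromosome assignments with supporting-tag counts."""

    pairs: list[tuple[str, str, int]]  # (lg, chromosome, supporting tags)
    unresolved: list[str]              # LGs with no strict majority


def lg_chr_correspondence(tag_positions: list[tuple[str, str, int]]) -> LgChrMap:
    """Assign each linkage group the chromosome holding a strict majority of
    its mapped tags; ambiguous LGs are flagged, never silently assigned.

    ``tag_positions`` rows are ``(lg, chromosome, bp)``.
    """
    by_lg: dict[str, dict[str, int]] = {}
    for lg, chrom, _bp in tag_positions:
        by_lg.setdefault(lg, {}).setdefault(chrom, 0)
        by_lg[lg][chrom] += 1
    pairs: list[tuple[str, str, int]] = []
    unresolved: list[str] = []
    for lg in sorted(by_lg):
        counts = by_lg[lg]
        total = sum(counts.values())
        best = max(sorted(counts), key=lambda c: counts[c])
        if counts[best] * 2 > total:
            pairs.append((lg, best, counts[best]))
        else:
            unresolved.append(lg)
    return LgChrMap(pairs=pairs, unresolved=unresolved)
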