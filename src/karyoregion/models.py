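"""Core domain containers shared across the analysis modules.

Coordinates are 0-based, half-open throughout the in-memory layer; BED files
round-trip unchanged and GFF3 is converted at the IO boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

EVIDENCE_CLASSES = ("qtl", "rad_tag", "ssr", "scar", "other")


class ConfigError(ValueError):
    """Invalid configuration or malformed input."""


@dataclass(frozen=True)
class EvidenceMarker:
    """One mapped sex-linked evidence item (a QTL hit, RAD tag, SSR or SCAR).

    Point markers are stored as width-1 intervals (``end == start + 1``).
    """

    cls: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.cls not in EVIDENCE_CLASSES:
            raise ConfigError(f"unknown evidence class {self.cls!r}; expected one of {EVIDENCE_CLASSES}")
        if self.end <= self.start:
            raise ConfigError(f"marker interval [{self.start}, {self.end}) is empty")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AssemblySkeleton:
    """Chromosome (and optionally unplaced contig) names with lengths in bp."""

    entries: list[tuple[str, int]]
    unplaced: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries] + [n for n, _ in self.unplaced]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate sequence names in assembly skeleton")
        for name, length in self.entries + self.unplaced:
            if length <= 0:
                raise ConfigError(f"non-positive length for {name}: {length}")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.entries)

    @property
    def total_bp(self) -> int:
        return sum(length for _, length in self.entries)

    @property
    def total_with_unplaced_bp(self) -> int:
        return self.total_bp + sum(length for _, length in self.unplaced)


@dataclass
class GeneModel:
    """A gene with location, functional annotation and optional DEG status.

    ``go_terms`` holds ``(term, level2_category)`` pairs as given by the
    annotation input; no ontology traversal is done. ``log2fc_mf`` /
    ``log2fc_mp`` are log2 fold-changes of the male-vs-female and
    male-vs-pseudofemale contrasts and are present only when the gene is a
    DEG in that contrast.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    nr_description: str = ""
    go_terms: frozenset = frozenset()
    kegg_pathways: frozenset = frozenset()
    log2fc_mf: float | None = None
    log2fc_mp: float | None = None


@dataclass(frozen=True)
class SyntenyBlock:
    """One colinear aligned segment between two genomes (equal-length spans)."""

    species_a: str
    chrom_a: str
    start_a: int
    end_a: int
    species_b: str
    chrom_b: str
    start_b: int
    end_b: int

    def __post_init__(self) -> None:
        if self.species_a == self.species_b:
            raise ConfigError("synteny block must relate two distinct species")
        if self.end_a <= self.start_a or self.end_b <= self.start_b:
            raise ConfigError("synteny block spans must be non-empty")
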