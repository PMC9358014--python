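"""Simulation and run configuration objects.

The synthetic-data generators are driven by a single :class:`SimulationConfig`
whose defaults mirror the Ussuri-catfish study system: the 26-chromosome
karyotype, sex-linked evidence concentrated on chr08 with ~96% containment,
an F1 mapping family with a fully sex-linked locus, and a two-contrast DEG
layout whose concordant core is 65 male- plus 70 female-biased genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

from . import reference
from .models import ConfigError, EVIDENCE_CLASSES

DEFAULT_PLANTED_REGION = reference.SEX_REGION
DEFAULT_EVIDENCE_COUNTS = {"qtl": 57, "rad_tag": 326, "ssr": 1, "scar": 1}


@dataclass
class DegOverlapSpec:
    """Planted two-contrast DEG structure (counts of genes per compartment).

    ``concordant_*`` genes are DEGs in both contrasts with the same direction;
    ``discordant_*`` are DEGs in both with opposite directions (named by their
    male-vs-female direction); ``mf_only_*`` / ``mp_only_*`` appear in a single
    contrast. Defaults reproduce a cascade of 181 male-vs-female DEGs (85
    male- / 96 female-biased), 150 male-vs-pseudofemale DEGs and a concordant
    core of 135 (65 male- / 70 female-biased).
    """

    concordant_male: int = 65
    concordant_female: int = 70
    discordant_male: int = 8
    discordant_female: int = 7
    mf_only_male: int = 12
    mf_only_female: int = 19
    mp_only_male: int = 0
    mp_only_female: int = 0

    @classmethod
    def from_totals(cls, concordant_male: int, concordant_female: int,
                    discordant: int, single_contrast: int) -> "DegOverlapSpec":
        """Build a spec from four aggregate counts (splits alternate directions)."""
        return cls(
            concordant_male=concordant_male,
            concordant_female=concordant_female,
            discordant_male=discordant - discordant // 2,
            discordant_female=discordant // 2,
            mf_only_male=single_contrast - single_contrast // 2,
            mf_only_female=single_contrast // 2,
        )

    @property
    def total_genes(self) -> int:
        return sum(asdict(self).values())

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ConfigError(f"DEG overlap count {name} must be >= 0, got {value}")


def _default_synteny_history() -> dict[str, list[dict[str, Any]]]:
    # One fused and one split derived karyotype against the configured
    # ancestral skeleton; enough to exercise every relationship label.
    return {
        "derA": [{"type": "fusion", "parents": ["chr01", "chr02"], "derived": "chr01f"}],
        "derB": [{"type": "fission", "parent": "chr01", "breakpoint": 22_000_000,
                  "derived": ["chr01a", "chr01b"]}],
    }


@dataclass
class SimulationConfig:
    """Seeded configuration for every synthetic input the pipeline consumes."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(reference.DEFAULT_CHROM_LENGTHS))
    planted_region: tuple[str, int, int] = DEFAULT_PLANTED_REGION
    n_evidence_per_class: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_EVIDENCE_COUNTS))
    containment_fraction: float = 0.963
    # F1 mapping family (cross design is a declared simplification)
    n_offspring: int = 160
    n_markers: int = 200
    recomb_rate: float = 3.4  # cM per Mb
    female_heterogametic: bool = False
    # gene models
    n_region_genes: int = 554
    n_background_genes: int = 200
    # DEG layout
    deg_overlap: DegOverlapSpec = field(default_factory=DegOverlapSpec)
    # synteny
    ancestral_species: str = "anc"
    synteny_history: dict[str, list[dict[str, Any]]] = field(
        default_factory=_default_synteny_history)
    block_size: int = 1_000_000
    gc_fraction: float = 0.3933

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.chrom_lengths:
            raise ConfigError("chrom_lengths must not be empty")
        for name, length in self.chrom_lengths.items():
            if int(length) <= 0:
                raise ConfigError(f"chromosome {name} has non-positive length {length}")
        chrom, start, end = self.planted_region
        if chrom not in self.chrom_lengths:
            raise ConfigError(f"planted region chromosome {chrom!r} not in assembly")
        if not (0 <= start < end <= self.chrom_lengths[chrom]):
            raise ConfigError(
                f"planted region [{start}, {end}) outside chromosome {chrom} "
                f"(length {self.chrom_lengths[chrom]})")
        if not (0.0 < self.containment_fraction <= 1.0):
            raise ConfigError("containment_fraction must be in (0, 1]")
        for cls_name, n in self.n_evidence_per_class.items():
            if cls_name not in EVIDENCE_CLASSES:
                raise ConfigError(f"unknown evidence class {cls_name!r}")
            if n < 0:
                raise ConfigError(f"evidence count for {cls_name} must be >= 0")
        if self.n_offspring < 2 or self.n_markers < 1:
            raise ConfigError("need n_offspring >= 2 and n_markers >= 1")
        if self.recomb_rate <= 0:
            raise ConfigError("recomb_rate must be positive (cM/Mb)")
        if not (0.0 < self.gc_fraction < 1.0):
            raise ConfigError("gc_fraction must be in (0, 1)")
        if self.block_size <= 0:
            raise ConfigError("block_size must be positive")
        self.deg_overlap.validate()

    # --- serialisation -------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["planted_region"] = list(self.planted_region)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        if "planted_region" in d:
            d["planted_region"] = tuple(d["planted_region"])
        if isinstance(d.get("deg_overlap"), dict):
            d["deg_overlap"] = DegOverlapSpec(**d["deg_overlap"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
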