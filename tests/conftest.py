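"""Shared fixtures: small synthetic study systems generated at test time."""

from __future__ import annotations

import pytest

from karyoregion.config import DegOverlapSpec, SimulationConfig

SMALL_LENGTHS = {"chrA": 30_000_000, "chrB": 20_000_000, "chrC": 10_000_000}


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A three-chromosome system with the sex region planted on chrA."""
    kwargs = dict(
        seed=seed,
        chrom_lengths=dict(SMALL_LENGTHS),
        planted_region=("chrA", 5_000_000, 15_000_000),
        n_evidence_per_class={"qtl": 30, "rad_tag": 50},
        containment_fraction=0.95,
        n_offspring=100,
        n_markers=50,
        n_region_genes=60,
        n_background_genes=20,
        deg_overlap=DegOverlapSpec.from_totals(5, 5, 4, 4),
        synteny_history={
            "fused": [{"type": "fusion", "parents": ["chrB", "chrC"],
                       "derived": "chrBC"}],
            "split": [{"type": "fission", "parent": "chrA",
                       "breakpoint": 12_000_000, "derived": ["chrA1", "chrA2"]}],
        },
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture
def config():
    return small_config()


@pytest.fixture
def default_config():
    """The full-size default study system (26 chromosomes, chr08 region)."""
    return SimulationConfig(seed=0)
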