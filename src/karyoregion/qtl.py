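"""Binary-trait sex-association screen.

A deliberately simple single-marker association model stands in for full
interval mapping: the LOD score is the log10 likelihood ratio of the
saturated 2x2 multinomial (genotype x sex) against independence, and the
phenotypic variance explained (PVE) is the squared point-biserial
correlation (phi^2) between genotype and sex codes, in percent. Perfect
linkage therefore yields PVE = 100, matching the semantics used to select
fully sex-linked QTLs. Thresholds (chromosome-wide 5.2, genome-wide 7.0 by
default) are inputs, with an optional permutation routine to recompute them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import ConfigError
from .util import round_half_up


@dataclass(frozen=True)
class QtlRecord:
    lg: str
    position_cM: float
    lod: float
    pve_pct: float

    def __post_init__(self) -> None:
        if self.lod < 0 or not (0.0 <= self.pve_pct <= 100.0) or self.position_cM < 0:
            raise ConfigError(f"invalid QTL record: {self}")


@dataclass
class LodResult:
    lod: float | None
    pve_pct: float | None
    valid: bool
    reason: str = ""


def _contingency(genotypes: np.ndarray, sexes: np.ndarray) -> np.ndarray | None:
    genotypes = np.asarray(genotypes)
    sexes = np.asarray(sexes)
    if genotypes.shape != sexes.shape:
        raise ConfigError("genotypes and sexes must have equal length")
    g_levels = np.unique(genotypes)
    s_levels = np.unique(sexes)
    if len(g_levels) != 2 or len(s_levels) != 2:
        return None
    table = np.zeros((2, 2), dtype=float)
    for i, g in enumerate(g_levels):
        for j, s in enumerate(s_levels):
            table[i, j] = np.sum((genotypes == g) & (sexes == s))
    return table


def lod_from_table(table: np.ndarray) -> float:
    """log10 likelihood ratio: saturated 2x2 multinomial vs independence."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows * cols / n
    mask = table > 0
    return float(np.sum(table[mask] * np.log10(table[mask] / expected[mask])))


def pve_from_table(table: np.ndarray) -> float:
    """phi^2 (squared genotype-sex correlation) as a percentage."""
    a, b = table[0]
    c, d = table[1]
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    phi2 = (a * d - b * c) ** 2 / denom
    return 100.0 * float(phi2)


def binary_trait_lod(genotypes: np.ndarray, sexes: np.ndarray) -> LodResult:
    """Association LOD and PVE for one marker against phenotypic sex.

    Requires two genotype classes and both sexes; monomorphic markers return
    a flagged null rather than a score.
    """
    if len(np.asarray(genotypes)) < 4:
        raise ConfigError("need at least 4 individuals")
    table = _contingency(genotypes, sexes)
    if table is None:
        return LodResult(lod=None, pve_pct=None, valid=False,
                         reason="monomorphic marker or single-sex family")
    return LodResult(lod=lod_from_table(table), pve_pct=pve_from_table(table), valid=True)


def scan_markers(genotypes: np.ndarray, sexes: np.ndarray,
                 marker_map: pd.DataFrame, lg: str = "LG1") -> pd.DataFrame:
    """Per-marker association scan; returns a QTL table (lg, cM, lod, pve)."""
    rows = []
    for j in range(genotypes.shape[1]):
        res = binary_trait_lod(genotypes[:, j], sexes)
        rows.append({
            "marker": marker_map["marker"].iloc[j], "lg": lg,
            "position_cM": float(marker_map["cM"].iloc[j]),
            "lod": res.lod if res.valid else np.nan,
            "pve_pct": res.pve_pct if res.valid else np.nan,
        })
    return pd.DataFrame(rows)


@dataclass
class QtlScreenResult:
    n_total_pass_chromwide: int
    n_pass_genomewide: int
    pve_histogram: dict[str, int]
    selected: list[QtlRecord]
    span_cM: tuple[float, float, float] | None = field(default=None)


def filter_qtls(records: list[QtlRecord], lod_chromwide: float = 5.2,
                lod_genomewide: float = 7.0) -> QtlScreenResult:
    """Apply the two LOD thresholds and keep only PVE = 100% QTLs.

    The PVE histogram uses the reporting bins ``>90``, ``95-99.9`` and
    ``=100`` (the first bin includes the other two).
    """
    if lod_chromwide < 0 or lod_genomewide < lod_chromwide:
        raise ConfigError("need 0 <= lod_chromwide <= lod_genomewide")
    passed = [r for r in records if r.lod >= lod_chromwide]
    genomewide = [r for r in passed if r.lod >= lod_genomewide]
    hist = {
        ">90": sum(1 for r in passed if r.pve_pct > 90.0),
        "95-99.9": sum(1 for r in passed if 95.0 <= r.pve_pct <= 99.9),
        "100": sum(1 for r in passed if np.isclose(r.pve_pct, 100.0)),
    }
    selected = [r for r in passed if np.isclose(r.pve_pct, 100.0)]
    span = qtl_span_cM(selected) if selected else None
    return QtlScreenResult(
        n_total_pass_chromwide=len(passed), n_pass_genomewide=len(genomewide),
        pve_histogram=hist, selected=selected, span_cM=span)


def qtl_span_cM(selected: list[QtlRecord]) -> tuple[float, float, float]:
    """(min, max, width) of the selected QTL positions, 2 decimals.

    All records must sit on one linkage group.
    """
    if not selected:
        raise ConfigError("no selected QTLs")
    lgs = sorted({r.lg for r in selected})
    if len(lgs) > 1:
        raise ConfigError(f"selected QTLs span multiple linkage groups: {lgs}")
    lo = min(r.position_cM for r in selected)
    hi = max(r.position_cM for r in selected)
    return (round_half_up(lo, 2), round_half_up(hi, 2), round_half_up(hi - lo, 2))


def permutation_threshold(genotypes: np.ndarray, sexes: np.ndarray,
                          n_permutations: int = 1000, quantile: float = 0.95,
                          seed: int = 0) -> float:
    """Empirical genome-wide LOD threshold from sex-label permutations.

    Off by default in the screen; provided for users who prefer a
    data-driven threshold over the fixed 5.2 / 7.0 defaults.
    """
    rng = np.random.default_rng(seed)
    sexes = np.asarray(sexes)
    maxima = np.empty(n_permutations)
    for i in range(n_permutations):
        shuffled = sexes[rng.permutation(len(sexes))]
        lods = []
        for j in range(genotypes.shape[1]):
            res = binary_trait_lod(genotypes[:, j], shuffled)
            if res.valid:
                lods.append(res.lod)
        maxima[i] = max(lods) if lods else 0.0
    return float(np.quantile(maxima, quantile))
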