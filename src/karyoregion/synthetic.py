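"""Seeded generators for every input the pipeline consumes.

Each generator draws from its own substream of the root seed (fixed offsets),
so outputs are byte-reproducible and adding a generator never perturbs the
draws of another. The planted structure matches what the analysis assumes:
sex-linked evidence concentrated on one chromosome with a configurable
containment fraction, an F1 family whose sex is perfectly predicted by one
locus with recombination decay around it, DEG tables with an exact planted
overlap/concordance layout, and synteny blocks realising an explicit
fusion/fission history.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .models import AssemblySkeleton, ConfigError, EvidenceMarker, GeneModel
from .models import SyntenyBlock
from .util import (STREAM_ASSEMBLY, STREAM_DEG, STREAM_EVIDENCE, STREAM_GENES,
                   STREAM_GENOTYPES, round_half_up, substream)

#: evidence interval widths in bp; classes not listed are point markers
CLASS_WIDTHS = {"scar": 10_000}

_GO_POOL = [
    ("GO:0003700", "molecular_function"), ("GO:0005215", "molecular_function"),
    ("GO:0016301", "molecular_function"), ("GO:0005198", "molecular_function"),
    ("GO:0007049", "biological_process"), ("GO:0006629", "biological_process"),
    ("GO:0007165", "biological_process"), ("GO:0006955", "biological_process"),
    ("GO:0005634", "cellular_component"), ("GO:0016020", "cellular_component"),
    ("GO:0005737", "cellular_component"), ("GO:0005576", "cellular_component"),
]
_KEGG_POOL = [
    "Wnt signaling pathway", "TGF-beta signaling pathway", "PI3K-Akt signaling pathway",
    "Estrogen signaling pathway", "Ovarian steroidogenesis", "Cell cycle",
    "Metabolic pathways", "Ribosome", "Spliceosome", "Endocytosis", "Lysosome",
]
_NR_POOL = [
    "hypothetical protein", "zinc finger protein", "collagen alpha chain",
    "nuclear receptor", "protein kinase", "transmembrane transporter",
    "heat shock protein", "uncharacterized protein",
]


# --- assembly ----------------------------------------------------------------

def generate_assembly(config: SimulationConfig) -> AssemblySkeleton:
    """Assembly skeleton with exactly the configured chromosomes."""
    return AssemblySkeleton(entries=[(n, int(l)) for n, l in config.chrom_lengths.items()])


def generate_sequences(config: SimulationConfig) -> dict[str, str]:
    """Random nucleotide sequences matching the skeleton, at the configured GC.

    Intended for small test genomes; the full-size default karyotype is
    normally used as a coordinate frame only.
    """
    rng = substream(config.seed, STREAM_ASSEMBLY)
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    alphabet = np.array(list("ACGT"))
    return {name: "".join(alphabet[rng.choice(4, size=length, p=probs)])
            for name, length in config.chrom_lengths.items()}


# --- sex-linked evidence -----------------------------------------------------

def generate_evidence(config: SimulationConfig) -> list[EvidenceMarker]:
    """Evidence markers with an exact planted containment fraction per class.

    For each class, ``round(containment_fraction * n)`` markers are placed
    uniformly inside the planted region; the remainder fall uniformly on the
    other chromosomes (length-weighted), so the containment on the planted
    chromosome is exactly the configured share.
    """
    rng = substream(config.seed, STREAM_EVIDENCE)
    chrom, start, end = config.planted_region
    others = [(n, l) for n, l in config.chrom_lengths.items() if n != chrom]
    markers: list[EvidenceMarker] = []
    for cls_name in sorted(config.n_evidence_per_class):
        n = config.n_evidence_per_class[cls_name]
        if n == 0:
            continue
        width = CLASS_WIDTHS.get(cls_name, 1)
        if end - start <= width:
            raise ConfigError(f"planted region too short for class {cls_name!r} width {width}")
        n_inside = int(round_half_up(config.containment_fraction * n, 0))
        n_inside = min(n_inside, n)
        if n_inside < n and not others:
            raise ConfigError("cannot place outside evidence: genome has a single chromosome")
        for pos in rng.integers(start, end - width, size=n_inside):
            markers.append(EvidenceMarker(cls_name, chrom, int(pos), int(pos) + width))
        if n - n_inside:
            names = [n_ for n_, _ in others]
            weights = np.array([l for _, l in others], dtype=float)
            picks = rng.choice(len(others), size=n - n_inside, p=weights / weights.sum())
            for idx in picks:
                c_name, c_len = others[idx]
                if c_len <= width:
                    raise ConfigError(f"chromosome {c_name} shorter than marker width {width}")
                pos = int(rng.integers(0, c_len - width))
                markers.append(EvidenceMarker(cls_name, c_name, pos, pos + width))
    markers.sort(key=lambda m: (m.chrom, m.start, m.end, m.cls))
    return markers


# --- F1 genotypes ------------------------------------------------------------

@dataclass
class F1Dataset:
    """Genotypes (offspring x markers, 0/1), sexes ('M'/'F'), marker map."""

    genotypes: np.ndarray
    sexes: np.ndarray
    marker_map: pd.DataFrame  # columns: marker, chrom, bp, cM
    sex_locus_index: int


def haldane_r(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a map distance in cM (Haldane, no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM) / 100.0))


def generate_f1_genotypes(config: SimulationConfig) -> F1Dataset:
    """F1 family with one fully sex-linked locus and recombination decay.

    Markers are evenly spaced along the planted chromosome; the sex locus is
    the marker nearest the planted-region midpoint. In the default
    male-heterogametic (XX/XY) coding, genotype 1 marks the Y-bearing
    haplotype; each other marker inherits that haplotype with a flip
    probability given by the Haldane map function at its distance.
    """
    rng = substream(config.seed, STREAM_GENOTYPES)
    chrom, r_start, r_end = config.planted_region
    chrom_len = config.chrom_lengths[chrom]
    n, m = config.n_offspring, config.n_markers

    bp = ((np.arange(m) + 0.5) * chrom_len / m).astype(int)
    cM = bp / 1e6 * config.recomb_rate
    locus = int(np.argmin(np.abs(bp - (r_start + r_end) // 2)))

    sexes = np.full(n, "F", dtype="U1")
    order = rng.permutation(n)
    sexes[order[: n // 2]] = "M"

    het = sexes == ("F" if config.female_heterogametic else "M")
    r = np.asarray(haldane_r(np.abs(cM - cM[locus])))
    flips = rng.random((n, m)) < r[None, :]
    genotypes = (het[:, None] ^ flips).astype(np.int8)
    genotypes[:, locus] = het.astype(np.int8)  # the sex locus itself never recombines

    marker_map = pd.DataFrame({
        "marker": [f"m{j:04d}" for j in range(m)],
        "chrom": chrom, "bp": bp, "cM": np.round(cM, 4),
    })
    return F1Dataset(genotypes=genotypes, sexes=sexes, marker_map=marker_map,
                     sex_locus_index=locus)


# --- gene models -------------------------------------------------------------

def generate_gene_models(config: SimulationConfig) -> list[GeneModel]:
    """Annotated gene models: ``n_region_genes`` inside the planted region plus
    background genes spread over the other chromosomes."""
    rng = substream(config.seed, STREAM_GENES)
    chrom, start, end = config.planted_region
    genes: list[GeneModel] = []

    def annotate() -> tuple[str, frozenset, frozenset]:
        desc = _NR_POOL[int(rng.integers(len(_NR_POOL)))]
        n_go = int(rng.integers(0, 4))
        go = frozenset(_GO_POOL[i] for i in rng.choice(len(_GO_POOL), size=n_go, replace=False))
        n_kegg = int(rng.integers(0, 3))
        kegg = frozenset(_KEGG_POOL[i] for i in rng.choice(len(_KEGG_POOL), size=n_kegg,
                                                           replace=False))
        return desc, go, kegg

    n = config.n_region_genes
    if n > 0:
        step = (end - start) / n
        if step < 2:
            raise ConfigError("planted region too short for the requested gene count")
        for i in range(n):
            g_start = start + int(i * step)
            g_len = max(1, min(int(step) - 1, int(rng.integers(1_000, 15_000))))
            desc, go, kegg = annotate()
            genes.append(GeneModel(
                gene_id=f"{chrom}.{i + 1:03d}", chrom=chrom, start=g_start,
                end=min(g_start + g_len, end), strand="+" if rng.random() < 0.5 else "-",
                nr_description=desc, go_terms=go, kegg_pathways=kegg))

    others = sorted(n_ for n_ in config.chrom_lengths if n_ != chrom)
    counters = {c: 0 for c in others}
    for _ in range(config.n_background_genes):
        if not others:
            break
        c = others[int(rng.integers(len(others)))]
        c_len = config.chrom_lengths[c]
        g_len = int(rng.integers(1_000, 15_000))
        g_start = int(rng.integers(0, max(1, c_len - g_len)))
        counters[c] += 1
        desc, go, kegg = annotate()
        genes.append(GeneModel(
            gene_id=f"{c}.{counters[c]:03d}", chrom=c, start=g_start,
            end=g_start + g_len, strand="+" if rng.random() < 0.5 else "-",
            nr_description=desc, go_terms=go, kegg_pathways=kegg))
    return genes


# --- DEG tables --------------------------------------------------------------

def generate_deg_tables(config: SimulationConfig,
                        genes: list[GeneModel] | None = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two DEG tables (male-vs-female, male-vs-pseudofemale) with the exact
    planted overlap/concordance structure of ``config.deg_overlap``.

    Signs of log2 fold-changes encode direction (positive = male-biased).
    Returns ``(deg_mf, deg_mp)`` with columns ``gene_id`` and ``log2fc``.
    """
    rng = substream(config.seed, STREAM_DEG)
    spec = config.deg_overlap
    if genes is None:
        genes = generate_gene_models(config)
    chrom, start, end = config.planted_region
    pool = [g.gene_id for g in genes
            if g.chrom == chrom and g.start >= start and g.end <= end]
    if spec.total_genes > len(pool):
        raise ConfigError(
            f"DEG overlap spec needs {spec.total_genes} genes but only "
            f"{len(pool)} region genes are available")
    chosen = [pool[i] for i in rng.permutation(len(pool))[: spec.total_genes]]

    def mag() -> float:
        return float(np.round(rng.uniform(1.5, 9.0), 4))

    mf_rows: list[tuple[str, float]] = []
    mp_rows: list[tuple[str, float]] = []
    it = iter(chosen)

    def take(k):
        return [next(it) for _ in range(k)]

    for gid in take(spec.concordant_male):
        mf_rows.append((gid, mag())); mp_rows.append((gid, mag()))
    for gid in take(spec.concordant_female):
        mf_rows.append((gid, -mag())); mp_rows.append((gid, -mag()))
    for gid in take(spec.discordant_male):
        mf_rows.append((gid, mag())); mp_rows.append((gid, -mag()))
    for gid in take(spec.discordant_female):
        mf_rows.append((gid, -mag())); mp_rows.append((gid, mag()))
    for gid in take(spec.mf_only_male):
        mf_rows.append((gid, mag()))
    for gid in take(spec.mf_only_female):
        mf_rows.append((gid, -mag()))
    for gid in take(spec.mp_only_male):
        mp_rows.append((gid, mag()))
    for gid in take(spec.mp_only_female):
        mp_rows.append((gid, -mag()))

    deg_mf = pd.DataFrame(mf_rows, columns=["gene_id", "log2fc"]).sort_values(
        "gene_id", ignore_index=True)
    deg_mp = pd.DataFrame(mp_rows, columns=["gene_id", "log2fc"]).sort_values(
        "gene_id", ignore_index=True)
    return deg_mf, deg_mp


# --- synteny blocks ----------------------------------------------------------

def _apply_history(anc_lengths: dict[str, int],
                   events: list[dict]) -> dict[str, list[tuple[str, int, int]]]:
    """Derived karyotype as derived_chrom -> ordered ancestral segments."""
    karyotype: dict[str, list[tuple[str, int, int]]] = {
        name: [(name, 0, length)] for name, length in anc_lengths.items()}
    for ev in events:
        kind = ev.get("type")
        if kind == "fusion":
            parents = ev["parents"]
            for p in parents:
                if p not in karyotype:
                    raise ConfigError(f"fusion references unknown chromosome {p!r}")
            merged: list[tuple[str, int, int]] = []
            for p in parents:
                merged.extend(karyotype.pop(p))
            karyotype[ev["derived"]] = merged
        elif kind == "fission":
            parent = ev["parent"]
            if parent not in karyotype:
                raise ConfigError(f"fission references unknown chromosome {parent!r}")
            segments = karyotype.pop(parent)
            bp = int(ev["breakpoint"])
            total = sum(e - s for _, s, e in segments)
            if not (0 < bp < total):
                raise ConfigError(f"fission breakpoint {bp} outside chromosome {parent!r}")
            left: list[tuple[str, int, int]] = []
            right: list[tuple[str, int, int]] = []
            offset = 0
            for anc, s, e in segments:
                seg_len = e - s
                if offset + seg_len <= bp:
                    left.append((anc, s, e))
                elif offset >= bp:
                    right.append((anc, s, e))
                else:
                    cut = s + (bp - offset)
                    left.append((anc, s, cut))
                    right.append((anc, cut, e))
                offset += seg_len
            name_a, name_b = ev["derived"]
            karyotype[name_a] = left
            karyotype[name_b] = right
        else:
            raise ConfigError(f"unknown synteny event type {kind!r}")
    return karyotype


def generate_synteny_blocks(config: SimulationConfig) -> list[SyntenyBlock]:
    """Blocks tiling the ancestral chromosomes, re-addressed through the
    fusion/fission history of each derived species.

    Tiles are ``block_size`` long with sub-tile remainders attached to the
    last tile of each contiguous ancestral segment; both spans of every block
    have equal length.
    """
    blocks: list[SyntenyBlock] = []
    anc = config.ancestral_species
    for species in sorted(config.synteny_history):
        events = config.synteny_history[species]
        karyotype = _apply_history(config.chrom_lengths, events)
        for derived_chrom in sorted(karyotype):
            offset = 0
            for anc_chrom, seg_start, seg_end in karyotype[derived_chrom]:
                seg_len = seg_end - seg_start
                n_tiles = max(1, seg_len // config.block_size)
                edges = [seg_start + i * config.block_size for i in range(n_tiles)]
                edges.append(seg_end)  # remainder merges into the last tile
                for a, b in zip(edges[:-1], edges[1:]):
                    rel = a - seg_start
                    blocks.append(SyntenyBlock(
                        species_a=anc, chrom_a=anc_chrom, start_a=a, end_a=b,
                        species_b=species, chrom_b=derived_chrom,
                        start_b=offset + rel, end_b=offset + rel + (b - a)))
                offset += seg_len
    return blocks
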