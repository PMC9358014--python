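"""End-to-end orchestration: simulation, region track, synteny track, report.

A run executes stages in dependency order and writes every intermediate as a
plain-text file plus a consolidated JSON report with file checksums. The two
analysis tracks (sex-region delineation/screening vs synteny evolution) are
isolated: a failure in one is recorded in the report without aborting the
other. Reports contain no timestamps, so identical config + seed gives
byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__, io, reference
from .candidates import select_candidates
from .config import SimulationConfig
from .genome_summary import assembly_stats
from .models import ConfigError
from .qtl import QtlRecord, filter_qtls, scan_markers
from .region import delineate, genes_in_region
from .synteny import (build_homology_graph, classify_relationships,
                      find_evolution_clusters, flip_blocks, karyotype_inference)
from .synthetic import (generate_assembly, generate_deg_tables, generate_evidence,
                        generate_f1_genotypes, generate_gene_models,
                        generate_synteny_blocks)


@dataclass
class RunConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    outdir: str = "karyoregion_run"
    fraction: float = 0.9
    lod_chromwide: float = 5.2
    lod_genomewide: float = 7.0
    selection_rule: str = "union"
    min_coverage: float = 0.2
    min_block_bp: int = 50_000
    proto_n: int | None = None
    dry_run: bool = False

    def validate(self) -> None:
        if not (0.0 < self.fraction <= 1.0):
            raise ConfigError("fraction must be in (0, 1]")
        self.sim.validate()


STAGES = ("simulate", "summarize", "qtl", "region", "screen", "synteny")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured run; returns (and writes) the consolidated report."""
    config.validate()
    if config.dry_run:
        return {"version": __version__, "dry_run": True, "planned_stages": list(STAGES)}

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.sim.seed,
                    "config": config.sim.to_dict(), "stages": {}, "errors": {}}
    files: dict[str, Path] = {}

    # --- simulate ------------------------------------------------------
    skeleton = generate_assembly(config.sim)
    evidence = generate_evidence(config.sim)
    f1 = generate_f1_genotypes(config.sim)
    genes = generate_gene_models(config.sim)
    deg_mf, deg_mp = generate_deg_tables(config.sim, genes)
    blocks = generate_synteny_blocks(config.sim)

    io.write_skeleton(skeleton, outdir / "skeleton.tsv")
    io.write_evidence_bed(evidence, outdir / "evidence.bed")
    io.write_genotypes(f1.genotypes, list(f1.marker_map["marker"]), outdir / "genotypes.tsv")
    io.write_sexes(f1.sexes, outdir / "sexes.tsv")
    io.write_marker_map(f1.marker_map, outdir / "marker_map.tsv")
    io.write_gff3(genes, outdir / "genes.gff3")
    io.write_annotation_table(genes, outdir / "annotation.tsv")
    io.write_deg_table(deg_mf, outdir / "deg_male_vs_female.tsv")
    io.write_deg_table(deg_mp, outdir / "deg_male_vs_pseudofemale.tsv")
    io.write_synteny_blocks(blocks, outdir / "synteny_blocks.tsv")
    for name in ("skeleton.tsv", "evidence.bed", "genotypes.tsv", "sexes.tsv",
                 "marker_map.tsv", "genes.gff3", "annotation.tsv",
                 "deg_male_vs_female.tsv", "deg_male_vs_pseudofemale.tsv",
                 "synteny_blocks.tsv"):
        files[name] = outdir / name
    report["stages"]["simulate"] = {"n_evidence": len(evidence), "n_genes": len(genes),
                                    "n_blocks": len(blocks)}

    # --- summarize -----------------------------------------------------
    stats = assembly_stats(skeleton)
    report["stages"]["summarize"] = {
        "total_bp": stats.total_bp, "n_chromosomes": stats.n_contigs,
        "N50": stats.N50, "L50": stats.L50, "longest": stats.longest,
        "shortest": stats.shortest}

    # --- region track --------------------------------------------------
    try:
        scan = scan_markers(f1.genotypes, f1.sexes, f1.marker_map)
        records = [QtlRecord(lg=r.lg, position_cM=r.position_cM, lod=r.lod,
                             pve_pct=r.pve_pct)
                   for r in scan.dropna().itertuples()]
        qtl_result = filter_qtls(records, config.lod_chromwide, config.lod_genomewide)
        report["stages"]["qtl"] = {
            "n_pass_chromwide": qtl_result.n_total_pass_chromwide,
            "n_pass_genomewide": qtl_result.n_pass_genomewide,
            "pve_histogram": qtl_result.pve_histogram,
            "n_selected": len(qtl_result.selected),
            "span_cM": qtl_result.span_cM}

        region = delineate(evidence, fraction=config.fraction)
        hits = genes_in_region(genes, region, known_chroms=set(skeleton.lengths))
        (outdir / "sex_region.bed").write_text(
            f"{region.chrom}\t{region.start}\t{region.end}\tsex_region\n")
        files["sex_region.bed"] = outdir / "sex_region.bed"
        report["stages"]["region"] = {
            "chrom": region.chrom, "start": region.start, "end": region.end,
            "length_mb": region.length_mb,
            "windows": [{"cls": w.cls, "start": w.start, "end": w.end,
                         "containment_pct": w.containment_pct} for w in region.windows],
            "n_genes": len(hits)}

        screen = select_candidates(hits, deg_mf, deg_mp, rule=config.selection_rule)
        report["stages"]["screen"] = {
            "n_region_genes": screen.n_region_genes,
            "n_deg_mf": screen.n_deg_mf, "n_deg_mf_male": screen.n_deg_mf_male,
            "n_deg_mf_female": screen.n_deg_mf_female, "n_deg_mp": screen.n_deg_mp,
            "n_concordant": screen.n_concordant,
            "n_concordant_male": screen.n_concordant_male,
            "n_concordant_female": screen.n_concordant_female,
            "n_sex_specific_go_terms": len(screen.go_terms),
            "n_candidates": screen.n_candidates, "rule": screen.rule}
    except Exception:
        report["errors"]["region_track"] = traceback.format_exc()

    # --- synteny track -------------------------------------------------
    try:
        if blocks:
            relationship_lists = []
            for species in sorted({b.species_b for b in blocks}):
                sp_blocks = flip_blocks(b for b in blocks if b.species_b == species)
                relationship_lists.append(classify_relationships(
                    sp_blocks, min_coverage=config.min_coverage,
                    min_block_bp=config.min_block_bp,
                    chrom_lengths_b=config.sim.chrom_lengths))
            graph = build_homology_graph(relationship_lists)
            clusters = find_evolution_clusters(graph)
            karyotype = karyotype_inference(
                clusters, config.sim.ancestral_species,
                ancestral_n=len(config.sim.chrom_lengths), proto_n=config.proto_n)
            report["stages"]["synteny"] = {
                "n_clusters": len(clusters),
                "clusters": [{"members": sorted(f"{s}_{c}" for s, c in cl.members),
                              "events": {sp: list(ev) for sp, ev in cl.events.items()}}
                             for cl in clusters],
                "karyotype": karyotype.per_species}
        else:
            report["stages"]["synteny"] = {"n_clusters": 0, "clusters": [],
                                           "karyotype": {}}
    except Exception:
        report["errors"]["synteny_track"] = traceback.format_exc()

    report["checksums"] = {name: _sha256(path) for name, path in sorted(files.items())}
    report["printed_arithmetic_selftest"] = selftest()
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def selftest() -> dict:
    """Recompute the package's worked-example arithmetic from its printed
    inputs and compare with the expected published values."""
    from .genome_summary import anchoring_coverage, gene_density
    from .models import AssemblySkeleton, EvidenceMarker
    from .region import RegionWindow, integrate_evidence
    from .qtl import qtl_span_cM
    from .candidates import classify_directions
    from .synteny import homology_graph_from_edges
    from .util import round_half_up

    checks: dict[str, dict] = {}

    def check(name, computed, expected):
        checks[name] = {"computed": computed, "expected": expected,
                        "ok": computed == expected}

    windows = [RegionWindow(cls=cls, chrom=chrom, start=s, end=e,
                            n_contained=0, n_total=1)
               for cls, (chrom, s, e) in reference.EVIDENCE_WINDOWS.items()]
    points = [EvidenceMarker(cls, chrom, s, e)
              for cls, chrom, s, e in reference.POINT_MARKERS]
    region = integrate_evidence(windows, points)
    check("sex_region_length_mb", region.length_mb, reference.SEX_REGION_LENGTH_MB)
    check("sex_region_bounds", (region.chrom, region.start, region.end),
          reference.SEX_REGION)

    check("qtl_containment_pct",
          round_half_up(100 * reference.QTL_SUMMARY["n_pve_100_in_window"]
                        / reference.QTL_SUMMARY["n_pve_100_mapped"], 1), 96.5)
    check("tag_containment_pct", round_half_up(100 * 314 / 326, 1), 96.3)

    lo, hi = reference.QTL_SUMMARY["span_cM"]
    span = qtl_span_cM([QtlRecord("LG1", lo, 10.0, 100.0),
                        QtlRecord("LG1", hi, 10.0, 100.0)])
    check("qtl_span_cM", span[2], 69.93)

    skeleton = AssemblySkeleton(entries=sorted(reference.DEFAULT_CHROM_LENGTHS.items()))
    total_mb = round_half_up(skeleton.total_bp / 1e6, 2)
    check("anchored_total_mb", total_mb, 722.22)
    check("anchoring_coverage_pct",
          anchoring_coverage(skeleton.total_bp, reference.ASSEMBLY_TOTAL_BP), 97.34)
    check("gene_anchoring_pct",
          anchoring_coverage(reference.ANCHORED_GENES, reference.TOTAL_GENES), 98.29)
    counts = {chrom: n for chrom, _lg, _mb, _cm, n in reference.CHROMOSOME_TABLE}
    densities, densest, sparsest = gene_density(counts, skeleton)
    check("chr20_density", densities["chr20"], 39.51)
    check("density_extremes", (densest, sparsest), ("chr20", "chr13"))

    n_male, n_female = classify_directions(
        [fc for _gid, fc, _desc, _pw in reference.CANDIDATE_GENES])
    check("candidate_direction_split", (n_male, n_female), (10, 6))

    graph = homology_graph_from_edges(reference.HOMOLOGY_EDGES)
    clusters = find_evolution_clusters(graph)
    check("n_evolution_clusters", len(clusters), 4)
    karyotype = karyotype_inference(clusters, reference.ANCESTRAL_SPECIES,
                                    reference.ANCESTRAL_N, proto_n=reference.PROTO_N)
    check("inferred_haploid_numbers",
          {sp: karyotype.per_species[sp]["inferred_n"]
           for sp in reference.SPECIES_HAPLOID_N},
          dict(reference.SPECIES_HAPLOID_N))
    checks["all_ok"] = {"ok": all(c.get("ok", True) for c in checks.values())}
    return checks
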