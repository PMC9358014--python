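"""Published reference values for the *Pseudobagrus ussuriensis* study system.

These constants are the printed inputs of the worked examples shipped with the
package: the 26-chromosome karyotype of the Ussuri catfish assembly with its
linkage-group correspondence and gene counts, the mapped sex-linked evidence
windows on chr08, the sex-association QTL summary, the 16 candidate
sex-determining genes with their expression directions, and the chromosome
homology relations among five catfish genomes used for karyotype-evolution
inference. They are data consumed by the analysis functions, never results
assigned by them.
"""

from __future__ import annotations

# (chromosome, linkage group, physical length Mb, genetic length cM, no. genes)
CHROMOSOME_TABLE: list[tuple[str, str, float, float, int]] = [
    ("chr01", "LG4", 44.39, 100.28, 1555),
    ("chr02", "LG3", 42.31, 121.38, 1376),
    ("chr03", "LG2", 40.92, 134.97, 1231),
    ("chr04", "LG5", 37.81, 103.10, 1210),
    ("chr05", "LG8", 34.58, 85.47, 1074),
    ("chr06", "LG7", 33.77, 103.94, 1058),
    ("chr07", "LG9", 33.32, 102.64, 1090),
    ("chr08", "LG1", 32.06, 108.52, 912),
    ("chr09", "LG6", 29.58, 116.98, 967),
    ("chr10", "LG13", 29.44, 91.20, 751),
    ("chr11", "LG12", 28.53, 151.36, 978),
    ("chr12", "LG20", 28.21, 106.71, 965),
    ("chr13", "LG11", 27.56, 110.15, 648),
    ("chr14", "LG23", 26.75, 109.60, 860),
    ("chr15", "LG10", 26.48, 87.00, 868),
    ("chr16", "LG15", 25.77, 84.26, 805),
    ("chr17", "LG14", 22.93, 118.50, 879),
    ("chr18", "LG16", 22.81, 98.47, 822),
    ("chr19", "LG21", 22.37, 90.78, 848),
    ("chr20", "LG22", 22.30, 92.32, 881),
    ("chr21", "LG19", 19.40, 79.15, 649),
    ("chr22", "LG25", 19.03, 105.93, 681),
    ("chr23", "LG18", 18.56, 93.55, 559),
    ("chr24", "LG24", 18.43, 96.61, 684),
    ("chr25", "LG17", 17.46, 82.53, 633),
    ("chr26", "LG26", 17.45, 81.31, 680),
]

#: Default chromosome lengths in bp for the synthetic assembly.
DEFAULT_CHROM_LENGTHS: dict[str, int] = {
    chrom: int(round(mb * 1e6)) for chrom, _lg, mb, _cm, _n in CHROMOSOME_TABLE
}

ASSEMBLY_TOTAL_BP = 741_974_678      # whole Hi-C assembly, chromosomes + unplaced contigs
TOTAL_GENES = 24_075                 # predicted protein-coding genes
ANCHORED_GENES = 23_664              # genes placed on the 26 chromosomes

# Mapped sex-linked evidence on the sex chromosome (chr08), bp (0-based half-open).
# Per-class minimal >=90%-containment windows as reported, plus two point markers:
# the male-specific microsatellite PuGT54 and a male-specific SCAR sequence.
EVIDENCE_WINDOWS: dict[str, tuple[str, int, int]] = {
    "qtl": ("chr08", 7_200_000, 22_960_000),
    "rad_tag": ("chr08", 6_900_000, 23_730_000),
}
POINT_MARKERS: list[tuple[str, str, int, int]] = [
    ("ssr", "chr08", 19_480_000, 19_480_001),
    ("scar", "chr08", 8_360_000, 8_370_000),
]
SEX_REGION = ("chr08", 6_900_000, 23_730_000)
SEX_REGION_LENGTH_MB = 16.83

# Sex-association QTL screen on LG1 (chr08).
QTL_SUMMARY = {
    "n_pass_chromwide": 546,   # LOD >= 5.2
    "n_pass_genomewide": 539,  # LOD >= 7.0
    "n_pve_gt90": 317,
    "n_pve_95_999": 143,
    "n_pve_100": 62,
    "n_pve_100_mapped": 57,    # placed on the assembly
    "n_pve_100_in_window": 55, # within the 15.76 Mb window
    "span_cM": (11.56, 81.49),
    "lod_thresholds": (5.2, 7.0),
}

#: KEGG pathways treated as sex-related in the candidate screen (editable).
SEX_RELATED_KEGG = (
    "TGF-beta signaling pathway",
    "Wnt signaling pathway",
    "Estrogen signaling pathway",
    "Ovarian steroidogenesis",
    "PI3K-Akt signaling pathway",
    "Aldosterone synthesis and secretion",
    "Cholesterol metabolism",
    "Steroid hormone biosynthesis",
    "Progesterone-mediated oocyte maturation",
    "Oocyte meiosis",
    "Cortisol synthesis and secretion",
    "PPAR signaling pathway",
    "TNF signaling pathway",
    "RIG-I-like receptor signaling pathway",
    "Hedgehog signaling pathway",
    "Cell cycle",
)

# The 16 candidate sex-determining genes: (gene_id, log2 fold-change male/female,
# NR description, sex-related KEGG pathways).
CANDIDATE_GENES: list[tuple[str, float, str, tuple[str, ...]]] = [
    ("Chr08.223", 8.3753, "Nuclear receptor subfamily 4 group A member 2 (nr4a2)",
     ("Aldosterone synthesis and secretion",)),
    ("Chr08.303", 8.5218, "Low-density lipoprotein receptor-related protein 2 (lrp2)",
     ("Hedgehog signaling pathway", "Cholesterol metabolism")),
    ("Chr08.358", -2.4828, "Acyl-CoA-binding protein (acbp)",
     ("PPAR signaling pathway",)),
    ("Chr08.368", 4.4330, "Interferon-induced helicase C domain-containing protein 1 (ifih1)",
     ("RIG-I-like receptor signaling pathway",)),
    ("Chr08.399", 4.3033, "Caspase-8 (casp8)",
     ("TNF signaling pathway",)),
    ("Chr08.409", 10.8953, "Homeobox protein Hox-D3 (hoxd3a)", ()),
    ("Chr08.428", -7.3091, "Cell division cycle-associated protein 7 (cdca7)", ()),
    ("Chr08.520", -4.4996,
     "Serine/threonine-protein phosphatase 2A regulatory subunit B'' subunit beta (ppp2r3b)",
     ("PI3K-Akt signaling pathway",)),
    ("Chr08.527", -4.2231, "Cell division cycle protein 16 homolog (cdc16)",
     ("Cell cycle", "Oocyte meiosis", "Progesterone-mediated oocyte maturation")),
    ("Chr08.566", 3.5367, "Sterol 26-hydroxylase, mitochondrial (cyp27a1)",
     ("PPAR signaling pathway", "Cholesterol metabolism")),
    ("Chr08.570", 3.4892, "Collagen alpha-2(IV) chain (col4a2)",
     ("PI3K-Akt signaling pathway",)),
    ("Chr08.571", 4.4797, "Collagen alpha-2(IV) chain (col4a2)",
     ("PI3K-Akt signaling pathway",)),
    ("Chr08.572", 3.5372, "Collagen alpha-1(IV) chain (col4a1)",
     ("PI3K-Akt signaling pathway",)),
    ("Chr08.622", 3.2926, "3-Beta-hydroxysteroid dehydrogenase/Delta 5->4-isomerase (hsd3b)",
     ("Aldosterone synthesis and secretion", "Steroid hormone biosynthesis",
      "Ovarian steroidogenesis", "Cortisol synthesis and secretion")),
    ("Chr08.746", -4.8826, "Testis-expressed protein 30 (tex30)", ()),
    ("Chr08.760", -4.7110, "Frizzled-5 (fzd5)",
     ("Wnt signaling pathway",)),
]

# --- Chromosome homology across five catfish genomes -------------------------
# Species codes: Pu = P. ussuriensis, Pf = Pelteobagrus fulvidraco,
# Ip = Ictalurus punctatus (the Ictaluridae-like ancestral karyotype, n=29),
# Sm = Silurus meridionalis, Ph = Pangasianodon hypophthalmus.
SPECIES_HAPLOID_N = {"Pu": 26, "Pf": 26, "Ip": 29, "Sm": 29, "Ph": 30}
ANCESTRAL_SPECIES = "Ip"
ANCESTRAL_N = 29
PROTO_N = 25  # haploid number of the pre-Siluriformes proto-karyotype (reporting only)

# Homology edges of the four non-trivial evolution clusters: each edge joins a
# chromosome of one species to a homologous chromosome of another. Edges
# against Ip come from the per-cluster narratives; Pu-anchored edges are the
# published pairwise correspondence lists; remaining 1:1 edges follow from the
# cluster memberships. Conserved 1:1-only chromosome groups are not listed:
# they form no evolution cluster.
HOMOLOGY_EDGES: list[tuple[str, str, str, str]] = [
    # cluster with ancestral chromosomes Ip_chr10 / Ip_chr20 / Ip_chr21
    ("Pu", "chr1", "Ip", "chr10"), ("Pu", "chr1", "Ip", "chr20"), ("Pu", "chr21", "Ip", "chr21"),
    ("Pf", "chr2", "Ip", "chr10"), ("Pf", "chr2", "Ip", "chr21"), ("Pf", "chr23", "Ip", "chr20"),
    ("Sm", "chr9", "Ip", "chr10"), ("Sm", "chr20", "Ip", "chr20"), ("Sm", "chr19", "Ip", "chr21"),
    ("Ph", "chr11", "Ip", "chr10"), ("Ph", "chr21", "Ip", "chr20"), ("Ph", "chr20", "Ip", "chr21"),
    ("Pu", "chr1", "Pf", "chr2"), ("Pu", "chr1", "Pf", "chr23"), ("Pu", "chr21", "Pf", "chr2"),
    ("Pu", "chr1", "Sm", "chr9"), ("Pu", "chr1", "Sm", "chr20"), ("Pu", "chr21", "Sm", "chr19"),
    ("Pu", "chr1", "Ph", "chr11"), ("Pu", "chr1", "Ph", "chr21"), ("Pu", "chr21", "Ph", "chr20"),
    # cluster with ancestral chromosomes Ip_chr11 / chr12 / chr13 / chr25 / chr29
    ("Pu", "chr2", "Ip", "chr13"), ("Pu", "chr2", "Ip", "chr29"),
    ("Pu", "chr3", "Ip", "chr12"), ("Pu", "chr3", "Ip", "chr25"),
    ("Pu", "chr5", "Ip", "chr11"), ("Pu", "chr5", "Ip", "chr12"),
    ("Pf", "chr5", "Ip", "chr11"), ("Pf", "chr5", "Ip", "chr12"),
    ("Pf", "chr7", "Ip", "chr29"), ("Pf", "chr7", "Ip", "chr12"),
    ("Pf", "chr8", "Ip", "chr13"), ("Pf", "chr16", "Ip", "chr25"),
    ("Sm", "chr1", "Ip", "chr11"), ("Sm", "chr1", "Ip", "chr12"), ("Sm", "chr29", "Ip", "chr12"),
    ("Sm", "chr7", "Ip", "chr13"), ("Sm", "chr28", "Ip", "chr29"), ("Sm", "chr23", "Ip", "chr25"),
    ("Ph", "chr2", "Ip", "chr11"), ("Ph", "chr2", "Ip", "chr12"), ("Ph", "chr29", "Ip", "chr12"),
    ("Ph", "chr12", "Ip", "chr13"), ("Ph", "chr28", "Ip", "chr29"), ("Ph", "chr19", "Ip", "chr25"),
    ("Pu", "chr2", "Pf", "chr7"), ("Pu", "chr2", "Pf", "chr8"),
    ("Pu", "chr3", "Pf", "chr7"), ("Pu", "chr3", "Pf", "chr16"), ("Pu", "chr5", "Pf", "chr5"),
    ("Pu", "chr2", "Sm", "chr7"), ("Pu", "chr2", "Sm", "chr28"),
    ("Pu", "chr3", "Sm", "chr23"), ("Pu", "chr3", "Sm", "chr29"), ("Pu", "chr5", "Sm", "chr1"),
    ("Pu", "chr2", "Ph", "chr12"), ("Pu", "chr2", "Ph", "chr28"),
    ("Pu", "chr3", "Ph", "chr19"), ("Pu", "chr3", "Ph", "chr29"), ("Pu", "chr5", "Ph", "chr2"),
    # cluster with ancestral chromosomes Ip_chr2 / chr19 / chr22
    ("Pu", "chr9", "Ip", "chr2"), ("Pu", "chr9", "Ip", "chr22"),
    ("Pu", "chr18", "Ip", "chr2"), ("Pu", "chr13", "Ip", "chr19"),
    ("Pf", "chr9", "Ip", "chr2"), ("Pf", "chr9", "Ip", "chr22"),
    ("Pf", "chr19", "Ip", "chr2"), ("Pf", "chr15", "Ip", "chr19"),
    ("Sm", "chr18", "Ip", "chr2"), ("Sm", "chr18", "Ip", "chr19"),
    ("Sm", "chr27", "Ip", "chr2"), ("Sm", "chr14", "Ip", "chr22"),
    ("Ph", "chr30", "Ip", "chr2"), ("Ph", "chr18", "Ip", "chr2"),
    ("Ph", "chr24", "Ip", "chr22"), ("Ph", "chr13", "Ip", "chr19"),
    ("Pu", "chr9", "Sm", "chr18"), ("Pu", "chr9", "Sm", "chr27"), ("Pu", "chr13", "Sm", "chr18"),
    ("Pu", "chr9", "Ph", "chr24"), ("Pu", "chr9", "Ph", "chr30"),
    # cluster with ancestral chromosomes Ip_chr7 / Ip_chr27
    ("Pu", "chr4", "Ip", "chr7"), ("Pu", "chr23", "Ip", "chr27"),
    ("Pf", "chr1", "Ip", "chr7"), ("Pf", "chr1", "Ip", "chr27"),
    ("Sm", "chr6", "Ip", "chr7"), ("Sm", "chr26", "Ip", "chr27"),
    ("Ph", "chr4", "Ip", "chr7"), ("Ph", "chr25", "Ip", "chr27"),
    ("Pu", "chr4", "Pf", "chr1"), ("Pu", "chr23", "Pf", "chr1"),
]
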