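# Methods

This note documents the models and procedures implemented in `karyoregion`,
the parameters that matter, what the synthetic-data generators do and do not
emulate, and the design choices made where the design was genuinely open.

## Coordinate and reporting conventions

All in-memory intervals are 0-based half-open; BED round-trips unchanged,
GFF3 (1-based closed) is converted at the IO boundary. Point markers are
width-1 intervals. Strand is ignored for all containment logic. Megabase
lengths, percentages and densities are rounded half-up (not banker's) at the
reporting layer only — 2 decimals for Mb/percent/density, 1 decimal for
containment percentages, matching the precision genome reports in this
field print at. Internal arithmetic is never rounded.

## Region delineation

**Model.** Sex-linked evidence of class c on a chromosome is summarised by
the minimal-length window containing at least `⌈f·n_c⌉` whole markers
(default f = 0.9). "Containing" requires the full marker interval inside
the window; identically placed markers count with multiplicity. The scan
anchors candidate windows on marker boundaries (the optimum always is),
keeping the k smallest ends in a bounded heap for each candidate start —
O(n log k). Ties on length resolve to the leftmost window, making the
output unique and order-independent.

**Integration** is the bounding hull of all per-class windows and point
markers, not their intersection: the final region must contain every
contributing piece of evidence, and the hull is what makes the final region
equal the widest input window when one class dominates. Classes with fewer
than `min_markers` (default 2) markers on the majority chromosome skip the
window step and contribute their markers as points.

**Assumptions and limits.** The window rule is a declared operationalisation
of "region containing more than 90% of the evidence": it is the unique
parsimony-consistent reading, but other published analyses may have chosen
windows by eye, so exact window endpoints from raw positions are not
claimed — only the containment arithmetic and the hull are. A tie for the
majority chromosome raises rather than guessing.

## Sex-association screen

**Stand-in model.** Full interval mapping (mixture-model EM over genotype
probabilities) is out of scope; sex is a binary trait and each marker is
tested marginally. LOD = log10 of the likelihood ratio of the saturated
2x2 genotype-by-sex multinomial against the independence model (margins as
MLEs); this equals G/(2·ln 10) for the G-test statistic. PVE is defined as
phi² x 100 — the squared point-biserial correlation between genotype and
sex codes — which is symmetric under label swaps and reaches 100 exactly at
perfect linkage, reproducing the "PVE = 100%" selection semantics without
reimplementing a QTL-mapping package.

**Parameters.** Chromosome-wide and genome-wide LOD thresholds default to
5.2 and 7.0 (the values used for this study system) and are inputs, not
recomputed; an optional permutation routine (label shuffles, 95th
percentile of the per-scan maximum) is provided but off by default, because
the fixed thresholds are part of the reproduced analysis. PVE histogram
bins are the reporting bins `>90`, `95–99.9`, `=100` (the first includes
the others). cM values report at 2 decimals.

## Candidate screen

Direction is the sign of log2(male/female); exactly zero is flagged
ambiguous and excluded rather than assigned. Concordance requires presence
in both contrasts with equal direction, evaluated within the region gene
set. GO terms are compared at level 2 exactly as annotated — no ontology
traversal — and a term is sex-specific iff its concordant members are
non-empty and unanimous. The sex-related KEGG vocabulary is a shipped,
editable list (TGF-beta, Wnt, estrogen signaling, ovarian steroidogenesis,
PI3K-Akt, aldosterone synthesis and secretion, cholesterol metabolism,
steroid hormone biosynthesis, progesterone-mediated oocyte maturation,
oocyte meiosis, cortisol synthesis and secretion, PPAR, TNF, RIG-I-like,
Hedgehog, cell cycle), compared case-insensitively.

**Open design point.** The exact published rule combining GO and KEGG
evidence into a candidate list is not stated anywhere we could verify, and
the published candidate set is not the plain union of the two component
sets. The module therefore exposes the rule (`union` default, `go_only`,
`kegg_only`, `manual`) and always reports both component sets, rather than
guessing an unstated rule.

## Synteny and karyotype evolution

A partner chromosome survives when its summed aligned length (over blocks
at least `min_block_bp` = 50 kb) reaches `min_coverage` = 20% of the
shorter of the two chromosomes. Both defaults are configurable; they exist
to suppress repeat-driven noise blocks and were chosen as round values that
pass fused/split chromosome halves (coverage ~50–100%) while rejecting
incidental hits, since no threshold is published for this analysis — only
the resulting labels. Labels follow from surviving-partner structure in
both directions, so they are direction-consistent (a one-to-two chromosome
sees each partner as two-to-one from the other side).

Evolution clusters are connected components of the cross-species homology
graph that contain at least one non-bijective edge; all-bijective
components are reported separately as conserved groups. Event inference is
count-parsimony at cluster granularity: chromosome-count deficit = fusions,
excess = fissions, and equal counts with a non-bijective partnership toward
the ancestor = one fusion + one fission (a segment split off one ancestral
chromosome and joined another). No breakpoint-level reconstruction and no
Robertsonian/tandem discrimination is attempted. The ancestral species and
its haploid number are user inputs (defaults: the Ictaluridae-like genome,
n = 29); the proto-karyotype number (25) is reporting-only metadata for
trajectory strings like `25-29-26`.

The published correspondence lists enumerate non-trivial relations anchored
on one species; full cluster memberships additionally use the per-cluster
membership lists, with membership-implied 1:1 edges filled in. Only the
cluster count, per-species membership counts and the event/karyotype
arithmetic are treated as ground truth, not every individual edge pairing.

## Synthetic data: what it emulates, what it does not

One root seed drives independent substreams per generator (fixed spawn
keys), so adding a generator never perturbs another and equal seed + config
gives byte-identical files.

- **Assembly**: the 26 published chromosome lengths (Mb x 1e6) by default;
  optional random sequence at GC = 0.3933 for small test genomes.
- **Evidence**: exactly `round(f·n)` markers per class uniform inside the
  planted region (chr08 6.90–23.73 Mb by default, f = 0.963 — which
  reproduces both published containments, 55/57 and 314/326), the rest
  uniform over the *other* chromosomes, length-weighted. Placing outside
  evidence off the planted chromosome makes the containment denominator
  unambiguous; real mis-mapped markers could land anywhere, including the
  sex chromosome outside the region.
- **F1 family**: male-heterogametic XX/XY coding (flag for ZW), one marker
  fully sex-linked, others inherit the sex haplotype with a Haldane flip
  probability at their map distance. Defaults n_offspring = 160,
  n_markers = 200, 3.4 cM/Mb (LG1's 108.52 cM over 32.06 Mb). The real
  cross design behind the published map is not stated; this stand-in has
  no genotyping error, no segregation distortion and no interference, so
  passing tests certify the screen's logic, not robustness to those.
- **DEG tables**: exact planted compartment counts (concordant 65 male +
  70 female, discordant 8/7, single-contrast 12/19 by default), giving the
  full cascade 181 (85/96) → 150 → 135 (65/70). Magnitudes are uniform on
  [1.5, 9]; no count noise, dispersion or significance modelling — DEG
  status is taken as given, as in the consumed upstream tables.
- **Synteny blocks**: 1 Mb tiles of each ancestral chromosome re-addressed
  through an explicit fusion/fission event list per derived species
  (sub-tile remainders merge into the segment's last tile). No inversions,
  translocations, repeats or alignment noise: classifier tests on this
  output certify label logic, not alignment robustness.

Because the generators plant structure exactly, planted-truth tests are
sharp (exact counts, 100/100 chromosome recovery) but say nothing about
behaviour under mapping error or noisy alignments.

## Problem sizes in the test suite

The suite runs the window-vs-oracle comparison on 500 random instances
(n ≤ 30), contiguity statistics against a brute-force oracle on 1,000
random length lists, 100 seeded end-to-end delineation replicates at the
default evidence sizes (~385 markers), 100 seeded F1 scans (100 offspring x
50 markers), and 30 random fusion/fission histories on a 14-chromosome
toy ancestor — sizes at which the oracles are exact and the whole suite
completes in seconds.

## Known limitations

- The LOD/PVE stand-in is a single-marker association test, not interval
  mapping; LOD values are comparable within this package only.
- Genetic-map coverage (the published 98.93%) needs the unfiltered total
  map length, which is not printed; it is computed only when supplied.
- Event inference is count-level: it cannot separate one fission plus two
  fusions from two fusions when the count difference is the same, and
  assigns the count-neutral rearrangement case exactly one fusion + one
  fission by parsimony.
- GO "level 2" is whatever the annotation input calls level 2.
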