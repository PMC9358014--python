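"""Concordant-direction candidate-gene screen over two expression contrasts.

The cascade: genes in the delineated region are intersected with DEG tables
from a male-vs-female and a male-vs-pseudofemale contrast; genes differential
in both with the same direction are the concordant core; level-2 GO terms
whose concordant members are unanimous in direction are sex-specific; genes
on a curated sex-related KEGG pathway list are tagged; candidates are chosen
by a configurable rule (default: union of the GO and KEGG sets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .models import ConfigError, GeneModel
from .reference import SEX_RELATED_KEGG

MALE = "male-biased"
FEMALE = "female-biased"

SELECTION_RULES = ("union", "go_only", "kegg_only", "manual")


def direction_from_log2fc(log2fc: float) -> str:
    """Expression direction from the male-over-female log2 fold-change sign.

    Exactly zero is ambiguous and raises; callers exclude such genes.
    """
    if log2fc > 0:
        return MALE
    if log2fc < 0:
        return FEMALE
    raise ConfigError("log2 fold-change of exactly 0 has no direction")


@dataclass
class ConcordantGene:
    gene_id: str
    direction: str
    log2fc_mf: float
    log2fc_mp: float


def _check_unique(deg: pd.DataFrame, name: str) -> None:
    dup = deg["gene_id"][deg["gene_id"].duplicated()].tolist()
    if dup:
        raise ConfigError(f"duplicate gene ids in {name}: {sorted(set(dup))}")


def concordant_degs(region_gene_ids: list[str], deg_mf: pd.DataFrame,
                    deg_mp: pd.DataFrame) -> list[ConcordantGene]:
    """Region genes differential in both contrasts with the same direction.

    Zero fold-changes are flagged ambiguous and excluded.
    """
    _check_unique(deg_mf, "male-vs-female DEG table")
    _check_unique(deg_mp, "male-vs-pseudofemale DEG table")
    region = set(region_gene_ids)
    mf = {r.gene_id: float(r.log2fc) for r in deg_mf.itertuples() if r.gene_id in region}
    mp = {r.gene_id: float(r.log2fc) for r in deg_mp.itertuples() if r.gene_id in region}
    out: list[ConcordantGene] = []
    for gid in sorted(set(mf) & set(mp)):
        if mf[gid] == 0 or mp[gid] == 0:
            continue
        d_mf = direction_from_log2fc(mf[gid])
        if d_mf == direction_from_log2fc(mp[gid]):
            out.append(ConcordantGene(gene_id=gid, direction=d_mf,
                                      log2fc_mf=mf[gid], log2fc_mp=mp[gid]))
    return out


@dataclass
class GoTermResult:
    term: str
    category: str
    direction: str
    members: list[str]


def sex_specific_go_terms(concordant: list[ConcordantGene],
                          genes_by_id: dict[str, GeneModel]) -> list[GoTermResult]:
    """Level-2 GO terms whose concordant member genes are unanimous in
    direction (and non-empty). Terms are taken from the annotation as given;
    no ontology traversal."""
    members: dict[tuple[str, str], list[ConcordantGene]] = {}
    for cg in concordant:
        gene = genes_by_id.get(cg.gene_id)
        if gene is None:
            continue
        for term, category in sorted(gene.go_terms):
            members.setdefault((term, category), []).append(cg)
    results: list[GoTermResult] = []
    for (term, category), cgs in sorted(members.items()):
        directions = {cg.direction for cg in cgs}
        if len(directions) == 1:
            results.append(GoTermResult(
                term=term, category=category, direction=directions.pop(),
                members=sorted(cg.gene_id for cg in cgs)))
    return results


def sex_related_kegg_genes(concordant: list[ConcordantGene],
                           genes_by_id: dict[str, GeneModel],
                           pathways: tuple[str, ...] = SEX_RELATED_KEGG,
                           ) -> dict[str, list[str]]:
    """Concordant genes annotated to at least one sex-related KEGG pathway.

    Pathway names compare case-insensitively. Returns gene -> matched pathways.
    """
    lookup = {p.lower(): p for p in pathways}
    tagged: dict[str, list[str]] = {}
    for cg in concordant:
        gene = genes_by_id.get(cg.gene_id)
        if gene is None:
            continue
        hits = sorted(lookup[p.lower()] for p in gene.kegg_pathways
                      if p.lower() in lookup)
        if hits:
            tagged[cg.gene_id] = hits
    return tagged


@dataclass
class CandidateReport:
    n_region_genes: int
    n_annotated: int
    n_deg_mf: int
    n_deg_mf_male: int
    n_deg_mf_female: int
    n_deg_mp: int
    n_concordant: int
    n_concordant_male: int
    n_concordant_female: int
    go_terms: list[GoTermResult] = field(default_factory=list)
    candidates: list[dict] = field(default_factory=list)
    rule: str = "union"

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)


def select_candidates(region_genes: list[GeneModel], deg_mf: pd.DataFrame,
                      deg_mp: pd.DataFrame, rule: str = "union",
                      manual_ids: list[str] | None = None,
                      pathways: tuple[str, ...] = SEX_RELATED_KEGG) -> CandidateReport:
    """Run the full screen and select candidates by the configured rule.

    Rules: ``union`` (GO-sex-specific genes or sex-related-KEGG genes),
    ``go_only``, ``kegg_only``, or ``manual`` (an explicit id list filtered
    to the concordant set). The report always carries both component sets.
    """
    if rule not in SELECTION_RULES:
        raise ConfigError(f"unknown selection rule {rule!r}; expected one of {SELECTION_RULES}")
    genes_by_id = {g.gene_id: g for g in region_genes}
    if len(genes_by_id) != len(region_genes):
        raise ConfigError("duplicate gene ids among region genes")
    region_ids = list(genes_by_id)

    _check_unique(deg_mf, "male-vs-female DEG table")
    mf_region = [(r.gene_id, float(r.log2fc)) for r in deg_mf.itertuples()
                 if r.gene_id in genes_by_id and r.log2fc != 0]
    mf_male = sum(1 for _gid, fc in mf_region if fc > 0)
    _check_unique(deg_mp, "male-vs-pseudofemale DEG table")
    mp_region = [r.gene_id for r in deg_mp.itertuples() if r.gene_id in genes_by_id]

    concordant = concordant_degs(region_ids, deg_mf, deg_mp)
    go_results = sex_specific_go_terms(concordant, genes_by_id)
    kegg_tagged = sex_related_kegg_genes(concordant, genes_by_id, pathways)

    go_gene_ids = {gid for res in go_results for gid in res.members}
    if rule == "union":
        chosen = go_gene_ids | set(kegg_tagged)
    elif rule == "go_only":
        chosen = set(go_gene_ids)
    elif rule == "kegg_only":
        chosen = set(kegg_tagged)
    else:
        chosen = set(manual_ids or []) & {cg.gene_id for cg in concordant}

    by_id = {cg.gene_id: cg for cg in concordant}
    candidates = []
    for gid in sorted(chosen):
        cg = by_id.get(gid)
        if cg is None:
            continue
        gene = genes_by_id[gid]
        candidates.append({
            "gene_id": gid, "direction": cg.direction, "log2fc_mf": cg.log2fc_mf,
            "nr_description": gene.nr_description,
            "sex_related_pathways": kegg_tagged.get(gid, []),
            "in_go_set": gid in go_gene_ids,
        })

    n_annotated = sum(1 for g in region_genes
                      if g.nr_description or g.go_terms or g.kegg_pathways)
    n_conc_male = sum(1 for cg in concordant if cg.direction == MALE)
    return CandidateReport(
        n_region_genes=len(region_genes), n_annotated=n_annotated,
        n_deg_mf=len(mf_region), n_deg_mf_male=mf_male,
        n_deg_mf_female=len(mf_region) - mf_male, n_deg_mp=len(mp_region),
        n_concordant=len(concordant), n_concordant_male=n_conc_male,
        n_concordant_female=len(concordant) - n_conc_male,
        go_terms=go_results, candidates=candidates, rule=rule)


def classify_directions(log2fc_values: list[float]) -> tuple[int, int]:
    """Counts of (male-biased, female-biased) genes from log2(m/f) signs."""
    dirs = [direction_from_log2fc(v) for v in log2fc_values]
    n_male = sum(1 for d in dirs if d == MALE)
    return n_male, len(dirs) - n_male
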