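"""Chromosome-level synteny classification and karyotype-evolution inference.

Aggregated alignment blocks between two genomes define chromosome-to-
chromosome homology. Partners surviving a coverage threshold yield
relationship labels (one-to-one, one-to-two, two-to-one, one-to-many);
relationships across several species pairs build a homology graph whose
connected components containing at least one non-bijective edge are
evolution clusters. Within a cluster, fusion and fission events are counted
per species by parsimony against a designated ancestral karyotype, and the
per-species haploid number follows as ``ancestral_n - fusions + fissions``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .models import ConfigError, SyntenyBlock

Node = tuple[str, str]  # (species, chromosome)

LABELS = ("one-to-one", "one-to-two", "two-to-one", "one-to-many", "unassigned")


@dataclass
class SyntenyRelationship:
    species_a: str
    species_b: str
    chrom_a: str
    partners: list[tuple[str, int, float]]  # (chrom_b, aligned bp, coverage of shorter chrom)
    label: str


def _chrom_lengths_from_blocks(blocks: list[SyntenyBlock]) -> tuple[dict, dict]:
    len_a: dict[str, int] = {}
    len_b: dict[str, int] = {}
    for b in blocks:
        len_a[b.chrom_a] = max(len_a.get(b.chrom_a, 0), b.end_a)
        len_b[b.chrom_b] = max(len_b.get(b.chrom_b, 0), b.end_b)
    return len_a, len_b


def classify_relationships(blocks: list[SyntenyBlock], min_coverage: float = 0.2,
                           min_block_bp: int = 50_000,
                           chrom_lengths_a: dict[str, int] | None = None,
                           chrom_lengths_b: dict[str, int] | None = None,
                           ) -> list[SyntenyRelationship]:
    """Label each a-side chromosome by its surviving homology partners.

    A partner survives when its summed aligned bp (over blocks at least
    ``min_block_bp`` long) reaches ``min_coverage`` of the shorter of the two
    chromosomes; the cutoff suppresses repeat-driven noise blocks. Labels
    consider both directions: a chromosome whose two surviving partners each
    point only back at it is one-to-two; two chromosomes sharing their single
    partner are each two-to-one.
    """
    if not blocks:
        return []
    pairs = {(b.species_a, b.species_b) for b in blocks}
    if len(pairs) > 1:
        raise ConfigError(f"blocks span multiple species pairs: {sorted(pairs)}")
    (species_a, species_b), = pairs
    if chrom_lengths_a is None or chrom_lengths_b is None:
        inferred_a, inferred_b = _chrom_lengths_from_blocks(blocks)
        chrom_lengths_a = chrom_lengths_a or inferred_a
        chrom_lengths_b = chrom_lengths_b or inferred_b

    aligned: dict[tuple[str, str], int] = {}
    for b in blocks:
        if b.end_a - b.start_a < min_block_bp:
            continue
        key = (b.chrom_a, b.chrom_b)
        aligned[key] = aligned.get(key, 0) + (b.end_a - b.start_a)

    surviving: dict[tuple[str, str], tuple[int, float]] = {}
    for (ca, cb), bp in aligned.items():
        shorter = min(chrom_lengths_a.get(ca, bp), chrom_lengths_b.get(cb, bp))
        cov = bp / shorter if shorter else 0.0
        if cov >= min_coverage:
            surviving[(ca, cb)] = (bp, cov)

    partners_of_a: dict[str, list[str]] = {}
    partners_of_b: dict[str, list[str]] = {}
    for ca, cb in surviving:
        partners_of_a.setdefault(ca, []).append(cb)
        partners_of_b.setdefault(cb, []).append(ca)

    relationships = []
    for ca in sorted(set(b.chrom_a for b in blocks)):
        partner_names = partners_of_a.get(ca, [])
        partners = sorted(
            ((cb, *surviving[(ca, cb)]) for cb in partner_names),
            key=lambda t: (-t[1], t[0]))
        if not partners:
            label = "unassigned"
        elif len(partners) == 1:
            back = partners_of_b[partners[0][0]]
            label = "one-to-one" if len(back) == 1 else "two-to-one"
        elif len(partners) == 2 and all(len(partners_of_b[cb]) == 1 for cb, *_ in partners):
            label = "one-to-two"
        else:
            label = "one-to-many"
        relationships.append(SyntenyRelationship(
            species_a=species_a, species_b=species_b, chrom_a=ca,
            partners=[(cb, bp, round(cov, 4)) for cb, bp, cov in partners], label=label))
    return relationships


def flip_blocks(blocks: Iterable[SyntenyBlock]) -> list[SyntenyBlock]:
    """Swap the two sides of every block (to classify from the other genome)."""
    return [SyntenyBlock(b.species_b, b.chrom_b, b.start_b, b.end_b,
                         b.species_a, b.chrom_a, b.start_a, b.end_a) for b in blocks]


# --- homology graph ----------------------------------------------------------

def build_homology_graph(relationship_lists: Iterable[list[SyntenyRelationship]],
                         ) -> nx.Graph:
    """One node per (species, chromosome); one edge per surviving partner
    relation, annotated with whether it is bijective within its species pair."""
    graph = nx.Graph()
    for relationships in relationship_lists:
        seen: set[Node] = set()
        for rel in relationships:
            a: Node = (rel.species_a, rel.chrom_a)
            if a in seen:
                raise ConfigError(f"duplicate chromosome {a} within one relationship list")
            seen.add(a)
            graph.add_node(a)
            for chrom_b, bp, cov in rel.partners:
                graph.add_edge(a, (rel.species_b, chrom_b), aligned_bp=bp, coverage=cov)
    _annotate_bijectivity(graph)
    return graph


def homology_graph_from_edges(edges: Iterable[tuple[str, str, str, str]]) -> nx.Graph:
    """Graph directly from (species_a, chrom_a, species_b, chrom_b) tuples,
    e.g. published correspondence lists."""
    graph = nx.Graph()
    for sa, ca, sb, cb in edges:
        if sa == sb:
            raise ConfigError("homology edge within one species")
        graph.add_edge((sa, ca), (sb, cb))
    _annotate_bijectivity(graph)
    return graph


def _pair_degree(graph: nx.Graph, node: Node, other_species: str) -> int:
    return sum(1 for nb in graph.neighbors(node) if nb[0] == other_species)


def _annotate_bijectivity(graph: nx.Graph) -> None:
    for u, v, data in graph.edges(data=True):
        data["bijective"] = (_pair_degree(graph, u, v[0]) == 1
                             and _pair_degree(graph, v, u[0]) == 1)


# --- clusters and events -----------------------------------------------------

@dataclass
class EvolutionCluster:
    members: set[Node]
    species_counts: dict[str, int]
    graph: nx.Graph = field(repr=False, default=None)
    events: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


def find_evolution_clusters(graph: nx.Graph) -> list[EvolutionCluster]:
    """Connected components containing at least one non-bijective edge,
    ordered by size descending then lexicographically by members.

    Components whose edges are all bijective are conserved 1:1 groups, not
    evolution clusters (see :func:`conserved_groups`).
    """
    clusters = []
    for component in nx.connected_components(graph):
        sub = graph.subgraph(component)
        if any(not data["bijective"] for *_e, data in sub.edges(data=True)):
            counts: dict[str, int] = {}
            for species, _chrom in component:
                counts[species] = counts.get(species, 0) + 1
            clusters.append(EvolutionCluster(
                members=set(component), species_counts=counts, graph=sub))
    clusters.sort(key=lambda c: (-c.size, sorted(c.members)))
    return clusters


def conserved_groups(graph: nx.Graph) -> list[set[Node]]:
    """All-bijective connected components (chromosomes conserved 1:1)."""
    groups = []
    for component in nx.connected_components(graph):
        sub = graph.subgraph(component)
        if all(data["bijective"] for *_e, data in sub.edges(data=True)):
            groups.append(set(component))
    groups.sort(key=lambda g: sorted(g))
    return groups


def infer_events(cluster: EvolutionCluster, ancestral_species: str,
                 ) -> dict[str, tuple[int, int]]:
    """Count-parsimony fusion/fission events per species within one cluster.

    A species with fewer cluster chromosomes than the ancestor records the
    deficit as fusions; more records the excess as fissions. Equal counts
    with a non-bijective partnership toward the ancestor record one fusion
    plus one fission (a count-neutral rearrangement: a segment split off one
    ancestral chromosome and joined another).
    """
    species_in = set(cluster.species_counts)
    if ancestral_species not in species_in:
        raise ConfigError(f"ancestral species {ancestral_species!r} absent from cluster")
    k_anc = cluster.species_counts[ancestral_species]
    events: dict[str, tuple[int, int]] = {}
    for species in sorted(species_in - {ancestral_species}):
        k = cluster.species_counts[species]
        if k < k_anc:
            events[species] = (k_anc - k, 0)
        elif k > k_anc:
            events[species] = (0, k - k_anc)
        else:
            anc_edges = [data for u, v, data in cluster.graph.edges(data=True)
                         if {u[0], v[0]} == {species, ancestral_species}]
            rearranged = any(not data["bijective"] for data in anc_edges)
            events[species] = (1, 1) if rearranged else (0, 0)
    cluster.events = events
    return events


@dataclass
class KaryotypeInference:
    ancestral_species: str
    ancestral_n: int
    per_species: dict[str, dict]  # species -> {n_fusions, n_fissions, inferred_n}
    proto_n: int | None = None

    def trajectory(self, species: str) -> str:
        inferred = self.per_species[species]["inferred_n"]
        if self.proto_n is not None:
            return f"{self.proto_n}-{self.ancestral_n}-{inferred}"
        return f"{self.ancestral_n}-{inferred}"


def karyotype_inference(clusters: list[EvolutionCluster], ancestral_species: str,
                        ancestral_n: int, proto_n: int | None = None,
                        ) -> KaryotypeInference:
    """Sum cluster-level events into per-species haploid chromosome numbers.

    ``inferred_n = ancestral_n - total fusions + total fissions``; regions
    outside any cluster are 1:1-conserved and contribute nothing.
    """
    if ancestral_n < 1:
        raise ConfigError("ancestral_n must be >= 1")
    totals: dict[str, list[int]] = {}
    for cluster in clusters:
        for species, (fus, fis) in infer_events(cluster, ancestral_species).items():
            totals.setdefault(species, [0, 0])
            totals[species][0] += fus
            totals[species][1] += fis
    per_species = {
        species: {"n_fusions": fus, "n_fissions": fis,
                  "inferred_n": ancestral_n - fus + fis}
        for species, (fus, fis) in sorted(totals.items())}
    per_species[ancestral_species] = {"n_fusions": 0, "n_fissions": 0,
                                      "inferred_n": ancestral_n}
    return KaryotypeInference(ancestral_species=ancestral_species,
                              ancestral_n=ancestral_n, per_species=per_species,
                              proto_n=proto_n)
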