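"""Relationship classification, homology graph, clusters, karyotype events."""

from __future__ import annotations

import numpy as np
import pytest

from karyoregion import reference
from karyoregion.config import SimulationConfig
from karyoregion.models import ConfigError, SyntenyBlock
from karyoregion.synteny import (EvolutionCluster, build_homology_graph,
                                 classify_relationships, conserved_groups,
                                 find_evolution_clusters, flip_blocks,
                                 homology_graph_from_edges, infer_events,
                                 karyotype_inference)
from karyoregion.synthetic import generate_synteny_blocks

from conftest import small_config


def block(ca, cb, sa=0, ea=1_000_000, sb=0, eb=None, spa="A", spb="B"):
    eb = eb if eb is not None else sb + (ea - sa)
    return SyntenyBlock(spa, ca, sa, ea, spb, cb, sb, eb)


class TestClassifyRelationships:
    def test_full_length_pair_is_one_to_one(self):
        rels = classify_relationships([block("c1", "d1")])
        assert rels[0].label == "one-to-one"

    def test_one_to_two_and_back_references(self):
        blocks = [block("c1", "d1", 0, 6_000_000),
                  block("c1", "d2", 6_000_000, 12_000_000, 0)]
        rels = classify_relationships(blocks)
        assert rels[0].label == "one-to-two"
        flipped = classify_relationships(flip_blocks(blocks))
        assert {r.label for r in flipped} == {"two-to-one"}

    def test_noise_blocks_suppressed_by_thresholds(self):
        blocks = [block("c1", "d1", 0, 10_000_000),
                  block("c1", "d2", 10_000_000, 10_030_000, 0, 30_000)]  # tiny repeat hit
        rels = classify_relationships(blocks, min_block_bp=50_000,
                                      chrom_lengths_b={"d1": 10_000_000, "d2": 8_000_000})
        assert rels[0].label == "one-to-one"
        assert [p[0] for p in rels[0].partners] == ["d1"]

    def test_multiple_species_pairs_rejected(self):
        with pytest.raises(ConfigError):
            classify_relationships([block("c1", "d1"), block("c1", "e1", spb="C")])

    def test_published_derived_vs_ussuri_pattern(self):
        """A 26-chromosome karyotype whose chr01/chr02/chr03/chr09 each map to
        two derived chromosomes classifies as 22 one-to-one + 4 one-to-two."""
        cfg = SimulationConfig(seed=0, synteny_history={"der": [
            {"type": "fission", "parent": c, "breakpoint": bp, "derived": [f"{c}a", f"{c}b"]}
            for c, bp in (("chr01", 20_000_000), ("chr02", 21_000_000),
                          ("chr03", 18_000_000), ("chr09", 14_000_000))]})
        blocks = generate_synteny_blocks(cfg)
        rels = classify_relationships(blocks, chrom_lengths_a=cfg.chrom_lengths)
        labels = [r.label for r in rels]
        assert labels.count("one-to-one") == 22
        assert labels.count("one-to-two") == 4

    def test_direction_consistency_of_labels(self, config):
        blocks = generate_synteny_blocks(config)
        for species in config.synteny_history:
            sp_blocks = [b for b in blocks if b.species_b == species]
            fwd = {r.chrom_a: r for r in classify_relationships(
                sp_blocks, chrom_lengths_a=config.chrom_lengths)}
            rev = {r.chrom_a: r for r in classify_relationships(flip_blocks(sp_blocks))}
            for chrom, rel in fwd.items():
                if rel.label == "one-to-two":
                    for partner, *_ in rel.partners:
                        assert rev[partner].label == "two-to-one"

    def test_generated_histories_recovered_exactly(self):
        """Classifier applied to generated blocks reproduces the generating
        relationship spec for random fusion/fission histories."""
        rng = np.random.default_rng(21)
        lengths = {f"c{i:02d}": int(l) for i, l in
                   enumerate(rng.integers(8, 40, size=12) * 1_000_000)}
        for rep in range(20):
            rep_rng = np.random.default_rng(100 + rep)
            chroms = list(lengths)
            rep_rng.shuffle(chroms)
            fused = chroms[:2]
            split = chroms[2]
            history = {"sp": [
                {"type": "fusion", "parents": fused, "derived": "fus"},
                {"type": "fission", "parent": split,
                 "breakpoint": lengths[split] // 2, "derived": ["fa", "fb"]},
            ]}
            cfg = SimulationConfig(seed=rep, chrom_lengths=lengths,
                                   planted_region=(chroms[0], 0, lengths[chroms[0]]),
                                   synteny_history=history)
            rels = {r.chrom_a: r.label for r in classify_relationships(
                generate_synteny_blocks(cfg), chrom_lengths_a=lengths)}
            for c in lengths:
                if c == split:
                    assert rels[c] == "one-to-two"
                elif c in fused:
                    assert rels[c] == "two-to-one"
                else:
                    assert rels[c] == "one-to-one"


class TestHomologyGraph:
    def test_counts_for_two_bijective_pairs(self):
        rel_lists = []
        for spb in ("B", "C"):
            blocks = [block(f"c{i}", f"{spb.lower()}{i}", spb=spb) for i in range(3)]
            rel_lists.append(classify_relationships(blocks))
        graph = build_homology_graph(rel_lists)
        assert graph.number_of_nodes() == 9
        assert graph.number_of_edges() == 6

    def test_empty_input(self):
        graph = build_homology_graph([])
        assert graph.number_of_nodes() == 0

    def test_published_cluster_members_connected(self):
        import networkx as nx
        graph = homology_graph_from_edges(reference.HOMOLOGY_EDGES)
        assert nx.has_path(graph, ("Pu", "chr1"), ("Pu", "chr21"))
        assert nx.has_path(graph, ("Pu", "chr1"), ("Pf", "chr2"))

    def test_duplicate_chromosome_in_one_list_rejected(self):
        rels = classify_relationships([block("c1", "d1")])
        with pytest.raises(ConfigError, match="duplicate"):
            build_homology_graph([rels + rels])


class TestEvolutionClusters:
    def test_all_bijective_graph_has_no_clusters(self):
        rels = classify_relationships([block(f"c{i}", f"d{i}") for i in range(4)])
        graph = build_homology_graph([rels])
        assert find_evolution_clusters(graph) == []
        assert len(conserved_groups(graph)) == 4

    def test_published_edges_give_four_clusters(self):
        graph = homology_graph_from_edges(reference.HOMOLOGY_EDGES)
        clusters = find_evolution_clusters(graph)
        assert len(clusters) == 4
        assert [c.size for c in clusters] == [22, 16, 13, 9]
        # cluster memberships match the published per-species counts
        biggest = clusters[0].species_counts
        assert biggest == {"Pu": 3, "Pf": 4, "Ip": 5, "Sm": 5, "Ph": 5}
        assert clusters[1].species_counts == {"Pu": 3, "Pf": 3, "Ip": 3, "Sm": 3, "Ph": 4}
        assert clusters[3].species_counts == {"Pu": 2, "Pf": 1, "Ip": 2, "Sm": 2, "Ph": 2}

    def test_single_fusion_among_identity_maps(self):
        rel_lists = []
        fused_blocks = [block("c1", "fX", 0, 5_000_000, spb="F"),
                        block("c2", "fX", 0, 5_000_000, 5_000_000, spb="F"),
                        block("c3", "f3", 0, 5_000_000, spb="F")]
        rel_lists.append(classify_relationships(fused_blocks))
        for spb in ("G", "H"):
            blocks = [block(f"c{i}", f"{spb.lower()}{i}", 0, 5_000_000, spb=spb)
                      for i in (1, 2, 3)]
            rel_lists.append(classify_relationships(blocks))
        clusters = find_evolution_clusters(build_homology_graph(rel_lists))
        assert len(clusters) == 1
        assert clusters[0].species_counts == {"A": 2, "F": 1, "G": 2, "H": 2}

    def test_components_match_union_find_oracle(self):
        import networkx as nx

        def union_find_components(nodes, edges):
            parent = {n: n for n in nodes}

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for u, v in edges:
                parent[find(u)] = find(v)
            comps: dict = {}
            for n in nodes:
                comps.setdefault(find(n), set()).add(n)
            return sorted(sorted(c) for c in comps.values())

        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(2, 25))
            nodes = list(range(n))
            edges = [tuple(rng.choice(n, 2, replace=False))
                     for _ in range(int(rng.integers(0, 30)))]
            graph = nx.Graph()
            graph.add_nodes_from(nodes)
            graph.add_edges_from(edges)
            got = sorted(sorted(c) for c in nx.connected_components(graph))
            assert got == union_find_components(nodes, edges)


def reference_clusters():
    return find_evolution_clusters(homology_graph_from_edges(reference.HOMOLOGY_EDGES))


class TestInferEvents:
    def test_fission_in_hypophthalmus_cluster(self):
        cluster = next(c for c in reference_clusters()
                       if c.species_counts.get("Ph") == 4)
        events = infer_events(cluster, "Ip")
        assert events["Ph"] == (0, 1)          # one fission
        assert events["Pu"] == (1, 1)          # count-neutral rearrangement
        assert events["Sm"] == (1, 1)

    def test_fusion_in_ussuri_cluster(self):
        cluster = next(c for c in reference_clusters() if c.size == 13)
        events = infer_events(cluster, "Ip")
        assert events["Pu"] == (1, 0)
        assert events["Sm"] == (0, 0)          # bijective partners, no events

    def test_equal_counts_bijective_is_neutral(self):
        import networkx as nx
        graph = homology_graph_from_edges([("A", "c1", "B", "d1"),
                                           ("A", "c2", "B", "d2")])
        cluster = EvolutionCluster(members=set(graph.nodes),
                                   species_counts={"A": 2, "B": 2}, graph=graph)
        assert infer_events(cluster, "A")["B"] == (0, 0)

    def test_missing_ancestor_rejected(self):
        cluster = reference_clusters()[0]
        with pytest.raises(ConfigError):
            infer_events(cluster, "Zz")


class TestKaryotypeInference:
    def test_published_haploid_numbers(self):
        karyotype = karyotype_inference(reference_clusters(), "Ip", 29, proto_n=25)
        inferred = {sp: karyotype.per_species[sp]["inferred_n"]
                    for sp in karyotype.per_species}
        assert inferred == reference.SPECIES_HAPLOID_N
        assert karyotype.trajectory("Pu") == "25-29-26"
        assert karyotype.per_species["Pu"] == {"n_fusions": 4, "n_fissions": 1,
                                               "inferred_n": 26}

    def test_no_clusters_keeps_ancestral_number(self):
        karyotype = karyotype_inference([], "Ip", 29)
        assert karyotype.per_species == {
            "Ip": {"n_fusions": 0, "n_fissions": 0, "inferred_n": 29}}

    def test_event_conservation_on_simulated_histories(self):
        """Inferred haploid numbers equal the actual derived chromosome counts
        for simulated fusion/fission histories."""
        rng = np.random.default_rng(9)
        lengths = {f"c{i:02d}": int(l) for i, l in
                   enumerate(rng.integers(10, 30, size=10) * 1_000_000)}
        for rep in range(25):
            rep_rng = np.random.default_rng(rep)
            chroms = list(lengths)
            rep_rng.shuffle(chroms)
            n_fus = int(rep_rng.integers(0, 3))
            n_fis = int(rep_rng.integers(0, 3))
            events, used = [], 0
            for i in range(n_fus):
                events.append({"type": "fusion", "parents": chroms[used:used + 2],
                               "derived": f"fus{i}"})
                used += 2
            for i in range(n_fis):
                c = chroms[used]
                events.append({"type": "fission", "parent": c,
                               "breakpoint": lengths[c] // 2,
                               "derived": [f"fa{i}", f"fb{i}"]})
                used += 1
            cfg = SimulationConfig(seed=rep, chrom_lengths=lengths,
                                   planted_region=(chroms[-1], 0, lengths[chroms[-1]]),
                                   synteny_history={"sp": events})
            blocks = generate_synteny_blocks(cfg)
            rels = classify_relationships(blocks, chrom_lengths_a=lengths)
            clusters = find_evolution_clusters(build_homology_graph([rels]))
            karyotype = karyotype_inference(clusters, "anc", len(lengths))
            expected_n = len(lengths) - n_fus + n_fis
            actual_n = len({b.chrom_b for b in blocks})
            assert actual_n == expected_n
            inferred = karyotype.per_species.get(
                "sp", {"inferred_n": len(lengths)})["inferred_n"]
            assert inferred == expected_n
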