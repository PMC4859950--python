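"""Subgraph cleaning, single-path testing, contig assembly, and hybrid
graph construction/trimming."""

import random

import networkx as nx
import pytest

from focuslite.hybrid_graph import (CleanConfig, clean_subgraph,
                                    assemble_contig, is_single_path,
                                    remove_bubbles, remove_tips,
                                    select_representatives,
                                    transitive_reduction, trim_hybrid)
from focuslite.io_preprocess import Read
from focuslite.multilevel_graph import CoarsenConfig, build_overlap_graph, \
    coarsen_all
from focuslite.overlap_align import AlignConfig, all_vs_all_overlaps


def path_graph(weights, prefix="n"):
    g = nx.Graph()
    for i, w in enumerate(weights):
        g.add_edge(f"{prefix}{i}", f"{prefix}{i+1}", weight=w)
    return g


class TestTips:
    def test_spur_removed_path_kept(self):
        g = path_graph([10, 10, 10, 10])  # 5-node path
        g.add_edge("n2", "spur", weight=5)
        remove_tips(g, 3)
        assert "spur" not in g and g.number_of_nodes() == 5

    def test_long_branch_kept(self):
        g = path_graph([10, 10, 10, 10])
        g.add_edge("n2", "b0", weight=5)
        g.add_edge("b0", "b1", weight=5)
        g.add_edge("b1", "b2", weight=5)
        g.add_edge("b2", "b3", weight=5)
        remove_tips(g, 3)
        assert "b0" in g  # 4-node branch exceeds the threshold

    def test_plain_path_endpoints_not_tips(self):
        g = path_graph([10, 10])
        remove_tips(g, 3)
        assert g.number_of_nodes() == 3


class TestBubbles:
    def test_lighter_path_removed(self):
        # two parallel 2-node paths between s and t, total weights 30 vs 20
        g = nx.Graph()
        for a, b, w in [("s", "x1", 10), ("x1", "x2", 10), ("x2", "t", 10),
                        ("s", "y1", 7), ("y1", "y2", 6), ("y2", "t", 7)]:
            g.add_edge(a, b, weight=w)
        remove_bubbles(g, 5)
        assert "x1" in g and "y1" not in g and "y2" not in g

    def test_no_bubble_untouched(self):
        g = path_graph([10, 20, 30])
        before = sorted(g.edges)
        remove_bubbles(g, 5)
        assert sorted(g.edges) == before


class TestTransitiveReduction:
    def test_triangle_consistent_overlaps(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=60)
        g.add_edge("b", "c", weight=60)
        g.add_edge("a", "c", weight=20)  # implied by the two longer overlaps
        transitive_reduction(g)
        assert not g.has_edge("a", "c")
        assert g.has_edge("a", "b") and g.has_edge("b", "c")

    def test_symmetric_ties_keep_connectivity(self):
        # duplicate-read pattern: equal-weight edges to a common neighbor
        g = nx.Graph()
        g.add_edge("a", "b", weight=100)
        g.add_edge("a", "c", weight=60)
        g.add_edge("b", "c", weight=60)
        transitive_reduction(g)
        assert nx.is_connected(g) and g.number_of_edges() == 2

    @pytest.mark.parametrize("seed", range(6))
    def test_fixed_point_and_soundness_brute_force(self, seed):
        """On random graphs <= 10 nodes: reduction preserves connected
        components, removes only edges implied by a two-edge chain of
        heavier-or-equal overlaps, and leaves no removable edge (checked by
        brute force over all node triples)."""
        rng = random.Random(seed)
        g = nx.Graph()
        for i in range(10):
            for j in range(i + 1, 10):
                if rng.random() < 0.3:
                    g.add_edge(i, j, weight=rng.randint(1, 50))
        original = g.copy()
        transitive_reduction(g)
        assert (sorted(map(sorted, nx.connected_components(g)))
                == sorted(map(sorted, nx.connected_components(original))))
        removed = set(original.edges) - set(g.edges)
        for u, v in removed:
            w_uv = original.edges[u, v]["weight"]
            assert any(
                original.has_edge(u, w) and original.has_edge(w, v)
                and original.edges[u, w]["weight"] >= w_uv
                and original.edges[w, v]["weight"] >= w_uv
                for w in original.nodes if w not in (u, v)
            )
        for u, v in g.edges:
            w_uv = g.edges[u, v]["weight"]
            assert not any(
                g.has_edge(u, w) and g.has_edge(w, v)
                and g.edges[u, w]["weight"] >= w_uv
                and g.edges[w, v]["weight"] >= w_uv
                for w in g.nodes if w not in (u, v)
            )


class TestSinglePath:
    def test_path(self):
        assert is_single_path(path_graph([1, 1, 1]))

    def test_star(self):
        g = nx.Graph()
        for leaf in "abc":
            g.add_edge("hub", leaf, weight=1)
        assert not is_single_path(g)

    def test_disconnected(self):
        g = path_graph([1], prefix="p")
        h = path_graph([1], prefix="q")
        assert not is_single_path(nx.union(g, h))

    def test_singleton(self):
        g = nx.Graph()
        g.add_node("only")
        assert is_single_path(g)

    def test_cycle(self):
        g = nx.cycle_graph(4)
        assert not is_single_path(g)


def overlap_graph_from_reads(reads, cfg=None):
    cfg = cfg or AlignConfig(k=8, step=1, min_overlap=20)
    edges = all_vs_all_overlaps([reads], cfg)
    return build_overlap_graph(edges, reads=[r.id for r in reads])


class TestAssembleContig:
    def test_two_read_splice(self):
        a = Read(id="a", seq="AAAACGTACGTCCC"[:7])  # AAAACGT
        b = Read(id="b", seq="ACGTCCC")
        g = nx.Graph()
        g.add_edge("a", "b", weight=4, delta=3, du="a")
        assert assemble_contig(g, {"a": a, "b": b}) == "AAAACGTCCC"

    def test_single_node(self):
        g = nx.Graph()
        g.add_node("a")
        assert assemble_contig(g, {"a": Read(id="a", seq="ACGT")}) == "ACGT"

    def test_error_free_tiles_reconstruct_genome(self):
        rng = random.Random(10)
        genome = "".join(rng.choice("ACGT") for _ in range(1000))
        reads = [Read(id=f"t{i:03d}", seq=genome[s: s + 100])
                 for i, s in enumerate(range(0, 901, 30))]
        g0 = overlap_graph_from_reads(reads)
        sub = clean_subgraph(g0.g, CleanConfig())
        assert is_single_path(sub)
        contig = assemble_contig(sub, {r.id: r for r in reads})
        assert contig == genome

    def test_majority_consensus_fixes_errors(self):
        rng = random.Random(12)
        genome = "".join(rng.choice("ACGT") for _ in range(400))
        reads = []
        for i, s in enumerate(range(0, 301, 20)):
            seq = genome[s: s + 100]
            reads.append(Read(id=f"e{i:03d}", seq=seq))
        # plant one error in a single read; 5x depth outvotes it
        bad = reads[7]
        seq = list(bad.seq)
        seq[50] = "A" if seq[50] != "A" else "C"
        reads[7] = Read(id=bad.id, seq="".join(seq))
        g0 = overlap_graph_from_reads(
            reads, AlignConfig(k=8, step=1, min_overlap=20, min_identity=0.9)
        )
        sub = clean_subgraph(g0.g, CleanConfig())
        contig = assemble_contig(sub, {r.id: r for r in reads})
        assert contig == genome


class TestSelectRepresentatives:
    def _single_genome(self, n=400):
        rng = random.Random(13)
        genome = "".join(rng.choice("ACGT") for _ in range(n))
        reads = [Read(id=f"s{i:03d}", seq=genome[s: s + 100])
                 for i, s in enumerate(range(0, n - 99, 25))]
        return genome, reads

    def test_clean_coverage_single_representative(self):
        genome, reads = self._single_genome()
        g0 = overlap_graph_from_reads(reads)
        levels = coarsen_all(g0, CoarsenConfig(min_edge_weight=20,
                                               min_density=0.0))
        hset = select_representatives(levels, {r.id: r for r in reads})
        assert hset.hybrid.number_of_nodes() == 1
        (node,) = hset.nodes.values()
        assert node.contig == genome
        assert node.source_level == levels[-1].level

    def test_member_reads_partition_read_set(self):
        genome, reads = self._single_genome()
        g0 = overlap_graph_from_reads(reads)
        levels = coarsen_all(g0, CoarsenConfig(min_edge_weight=20,
                                               min_density=30.0))
        hset = select_representatives(levels, {r.id: r for r in reads})
        assert hset.hybrid.number_of_nodes() > 1
        all_members = [r for n in hset.nodes.values() for r in n.member_reads]
        assert sorted(all_members) == sorted(r.id for r in reads)

    def test_level_optimality(self):
        """No selected representative has an ancestor whose cleaned cluster
        is also a single path."""
        genome, reads = self._single_genome()
        g0 = overlap_graph_from_reads(reads)
        levels = coarsen_all(g0, CoarsenConfig(min_edge_weight=20,
                                               min_density=30.0))
        hset = select_representatives(levels, {r.id: r for r in reads})
        for hid, (lvl, v) in hset.selected_at.items():
            cur = v
            for upper in levels[lvl + 1:]:
                cur = levels[upper.level - 1].parent[cur]
                sub = clean_subgraph(g0.g.subgraph(upper.members[cur]))
                assert not is_single_path(sub)

    def test_shared_region_branches_in_hybrid(self, small_community):
        """A region shared between two genomes gets hybrid nodes with more
        than the two edges a unique path node carries."""
        cfg, genomes, truth, reads, result = small_community
        degrees = sorted(
            d for _, d in result.hybrid.hybrid.degree()
        )
        assert degrees[-1] >= 4

    def test_hybrid_level_set_nesting(self):
        genome, reads = self._single_genome()
        g0 = overlap_graph_from_reads(reads)
        levels = coarsen_all(g0, CoarsenConfig(min_edge_weight=20,
                                               min_density=30.0))
        hset = select_representatives(
            levels, {r.id: r for r in reads}, build_level_set=True
        )
        assert set(hset.level_graphs) == {lg.level for lg in levels}
        # G'_0 contains exactly the representatives
        g0p = hset.level_graphs[0]
        assert g0p.number_of_nodes() == len(hset.nodes)
        assert all(kind == "rep" for kind, _ in g0p.nodes)


class TestTrimHybrid:
    def test_contained_contig_removed(self, small_community):
        cfg, genomes, truth, reads, result = small_community
        hset = result.hybrid
        # plant a short node whose contig is a substring of a neighbor's
        big = max(hset.nodes, key=lambda k: len(hset.nodes[k].contig))
        sub = hset.nodes[big].contig[10:110]
        from focuslite.hybrid_graph import HybridNode
        hset.hybrid.add_node("fake")
        hset.hybrid.add_edge("fake", big, weight=10)
        hset.nodes["fake"] = HybridNode(
            id="fake", source_level=0, contig=sub,
            member_reads=frozenset(["fake_read"]),
        )
        trimmed = trim_hybrid(hset, CleanConfig(max_containment_len=200))
        assert "fake" not in trimmed.hybrid
        hset.hybrid.remove_node("fake")
        del hset.nodes["fake"]

    def test_non_contained_neighbors_kept(self):
        import focuslite.hybrid_graph as hg
        rng = random.Random(14)
        g = nx.Graph()
        nodes = {}
        for name in ("a", "b"):
            seq = "".join(rng.choice("ACGT") for _ in range(150))
            nodes[name] = hg.HybridNode(
                id=name, source_level=0, contig=seq,
                member_reads=frozenset([name]),
            )
            g.add_node(name)
        g.add_edge("a", "b", weight=5)
        hset = hg.HybridGraphSet(hybrid=g, nodes=nodes,
                                 selected_at={"a": (0, "a"), "b": (0, "b")})
        trimmed = trim_hybrid(hset, CleanConfig(max_containment_len=500))
        assert set(trimmed.hybrid.nodes) == {"a", "b"}

    def test_no_transitive_edges_after_trim(self, small_community):
        cfg, genomes, truth, reads, result = small_community
        g = result.hybrid.hybrid
        for u, v in g.edges:
            w_uv = g.edges[u, v]["weight"]
            assert not any(
                g.has_edge(u, w) and g.has_edge(w, v)
                and g.edges[u, w]["weight"] >= w_uv
                and g.edges[w, v]["weight"] >= w_uv
                for w in g.nodes if w not in (u, v)
            )
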