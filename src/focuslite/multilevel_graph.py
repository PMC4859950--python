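"""Multilevel overlap-graph coarsening by heavy edge matching.

The initial overlap graph G_0 has one node per read and one weighted edge
per detected overlap (weight = overlap length).  Repeated heavy edge
matching and node merging produce a set of increasingly coarse graphs
G_0 ... G_n.  Every node of a coarser graph represents a cluster of G_0
nodes and carries two bookkeeping weights: the cluster node weight ``nw``
(number of G_0 nodes in the cluster) and the cluster edge weight ``ew``
(summed weight of G_0 edges internal to the cluster).  Edges between super
nodes carry the summed weight of the inter-cluster G_0 edges, so total
weight is conserved at every level:

    sum(ew) + sum(edge weights at level l) == sum(edge weights of G_0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Sequence

import networkx as nx

from .overlap_align import OverlapEdge

Node = Hashable


@dataclass
class LevelGraph:
    """One graph in the multilevel set.

    ``g`` is an undirected networkx graph whose nodes carry ``nw``/``ew``
    attributes and whose edges carry ``weight``.  ``members`` maps every
    node to the set of G_0 nodes of its cluster; ``parent``/``children``
    link adjacent levels.
    """

    level: int
    g: nx.Graph
    members: dict[Node, frozenset[Node]]
    parent: dict[Node, Node] = field(default_factory=dict)
    children: dict[Node, tuple[Node, ...]] = field(default_factory=dict)

    def nw(self, v: Node) -> int:
        return self.g.nodes[v]["nw"]

    def ew(self, v: Node) -> float:
        return self.g.nodes[v]["ew"]

    @property
    def nodes(self):
        return self.g.nodes

    @property
    def edges(self):
        return self.g.edges

    def total_edge_weight(self) -> float:
        return sum(d["weight"] for _, _, d in self.g.edges(data=True))


@dataclass(frozen=True)
class CoarsenConfig:
    """Coarsening thresholds.

    ``min_density`` caps cluster compactness: for a path-like cluster at
    read coverage c (100 bp reads, >= 40 bp overlaps) the merged-cluster
    density is roughly 84 c / n for n member reads, so the default of 6
    stops unique-region clusters near n ~ 14 c reads (~1-2 kb of sequence
    at 20x) while denser multi-copy regions (repeats, shared elements)
    keep coalescing -- the graph keeps its branch structure mineable.
    Set min_density=0 for pure assembly (coarsen to one node per
    component).
    """

    min_edge_weight: float = 40.0
    min_density: float = 6.0
    n_passes: int = 4
    stop_ratio: float = 0.1
    max_levels: int = 64

    def __post_init__(self) -> None:
        if not 0 < self.stop_ratio < 1:
            raise ValueError("stop_ratio must be in (0, 1)")
        if self.n_passes < 1:
            raise ValueError("n_passes must be >= 1")


def build_overlap_graph(
    edges: Iterable[OverlapEdge],
    reads: Iterable[str] = (),
    lengths: dict[str, int] | None = None,
) -> LevelGraph:
    """Build G_0 from a deduplicated edge list.

    Every read appearing in an edge becomes a node; ``reads`` may list
    additional retained read ids to keep as isolated nodes.  Edge attributes
    keep the overlap length (as ``weight``), identity, and the layout offset
    ``delta`` of v relative to u for later contig construction.
    """
    g = nx.Graph()
    for r in reads:
        g.add_node(r)
    for e in edges:
        g.add_edge(e.u, e.v, weight=e.overlap_len, identity=e.identity,
                   delta=e.delta, du=e.u)
    for v in g.nodes:
        g.nodes[v]["nw"] = 1
        g.nodes[v]["ew"] = 0.0
        if lengths is not None and v in lengths:
            g.nodes[v]["length"] = lengths[v]
    members = {v: frozenset([v]) for v in g.nodes}
    return LevelGraph(level=0, g=g, members=members)


def merge_density(vi: Node, vj: Node, lg: LevelGraph) -> float:
    """Density of the super node that merging vi and vj would produce.

    This is the summed weight of the G_0 edges internal to the merged
    cluster divided by the edge count of the complete graph on the cluster's
    G_0 nodes:

        2 (ew[vi] + ew[vj] + w(vi, vj)) / ((nw[vi]+nw[vj]) (nw[vi]+nw[vj]-1))
    """
    w = lg.g.edges[vi, vj]["weight"]
    nw = lg.nw(vi) + lg.nw(vj)
    return 2.0 * (lg.ew(vi) + lg.ew(vj) + w) / (nw * (nw - 1))


def _sort_key(v: Node):
    return (str(type(v)), v)


def heavy_edge_matching(
    lg: LevelGraph, cfg: CoarsenConfig
) -> list[tuple[Node, Node]]:
    """Greedy maximal matching preferring heavy edges.

    Nodes are visited over ``n_passes`` passes, with nodes of larger maximum
    incident edge weight in earlier passes (quantile buckets over max edge
    weight; ascending node id inside a bucket).  For the visited node the
    neighbors are tried in order of decreasing edge weight (ties: smaller
    neighbor id).  An edge below ``min_edge_weight`` terminates the node's
    scan, leaving it unmatched; a candidate whose merge density is not above
    ``min_density`` is skipped and the scan continues.
    """
    g = lg.g
    maxw = {
        v: max((d["weight"] for _, _, d in g.edges(v, data=True)), default=0.0)
        for v in g.nodes
    }
    order = sorted(g.nodes, key=lambda v: (-maxw[v], _sort_key(v)))
    n = len(order)
    n_passes = min(cfg.n_passes, n) or 1
    base, extra = divmod(n, n_passes)
    visit: list[Node] = []
    pos = 0
    for p in range(n_passes):
        size = base + (1 if p < extra else 0)
        bucket = order[pos: pos + size]
        pos += size
        visit.extend(sorted(bucket, key=_sort_key))

    matched: set[Node] = set()
    matching: list[tuple[Node, Node]] = []
    for vi in visit:
        if vi in matched:
            continue
        nbrs = sorted(
            ((d["weight"], _sort_key(u), u) for u, d in g.adj[vi].items()),
            key=lambda t: (-t[0], t[1]),
        )
        for w, _, vj in nbrs:
            if vj in matched:
                continue
            if w < cfg.min_edge_weight:
                break  # edges only get lighter from here: vi stays unmatched
            if merge_density(vi, vj, lg) > cfg.min_density:
                matched.update((vi, vj))
                matching.append((vi, vj))
                break
    return matching


def contract(lg: LevelGraph, matching: Sequence[tuple[Node, Node]]) -> LevelGraph:
    """Merge matched pairs into super nodes, producing the next level.

    Matched pairs get nw/ew summed (plus the matched edge's weight into ew);
    unmatched nodes map through unchanged.  Parallel edges are combined by
    adding their weights; self-loops (the matched edges) disappear.
    """
    g = lg.g
    partner: dict[Node, Node] = {}
    for vi, vj in matching:
        partner[vi] = vj
        partner[vj] = vi
    new_id: dict[Node, int] = {}
    groups: list[tuple[Node, ...]] = []
    for v in sorted(g.nodes, key=_sort_key):
        if v in new_id:
            continue
        group = (v,) if v not in partner else tuple(
            sorted((v, partner[v]), key=_sort_key)
        )
        idx = len(groups)
        groups.append(group)
        for u in group:
            new_id[u] = idx

    ng = nx.Graph()
    members: dict[Node, frozenset[Node]] = {}
    parent: dict[Node, Node] = {}
    children: dict[Node, tuple[Node, ...]] = {}
    for idx, group in enumerate(groups):
        nw = sum(lg.nw(v) for v in group)
        ew = sum(lg.ew(v) for v in group)
        if len(group) == 2:
            ew += g.edges[group[0], group[1]]["weight"]
        ng.add_node(idx, nw=nw, ew=ew)
        members[idx] = frozenset().union(*(lg.members[v] for v in group))
        children[idx] = group
        for v in group:
            parent[v] = idx
    for a, b, d in g.edges(data=True):
        ia, ib = new_id[a], new_id[b]
        if ia == ib:
            continue
        if ng.has_edge(ia, ib):
            ng.edges[ia, ib]["weight"] += d["weight"]
        else:
            ng.add_edge(ia, ib, weight=d["weight"])
    lg.parent.update(parent)
    return LevelGraph(level=lg.level + 1, g=ng, members=members,
                      children=children)


def coarsen_all(g0: LevelGraph, cfg: CoarsenConfig | None = None) -> list[LevelGraph]:
    """Iterate heavy edge matching + contraction until the matched-node
    ratio falls below ``stop_ratio``; returns the full level list G_0..G_n."""
    cfg = cfg or CoarsenConfig()
    levels = [g0]
    while len(levels) <= cfg.max_levels:
        cur = levels[-1]
        if cur.g.number_of_nodes() == 0 or cur.g.number_of_edges() == 0:
            break
        matching = heavy_edge_matching(cur, cfg)
        ratio = 2 * len(matching) / cur.g.number_of_nodes()
        if ratio < cfg.stop_ratio:
            break
        levels.append(contract(cur, matching))
    return levels


def relabel_final(
    levels: Sequence[LevelGraph],
) -> tuple[LevelGraph, dict[Node, tuple[int, int]]]:
    """Renumber G_0 so each top-level cluster occupies a consecutive id block.

    Returns the relabeled copy of G_0 (G_final) and a mapping from each
    top-level super node to its half-open [start, stop) id range.
    """
    if not levels:
        raise ValueError("need at least one level")
    g0, top = levels[0], levels[-1]
    mapping: dict[Node, int] = {}
    ranges: dict[Node, tuple[int, int]] = {}
    nxt = 0
    for sup in sorted(top.g.nodes, key=_sort_key):
        start = nxt
        for r in sorted(top.members[sup], key=_sort_key):
            mapping[r] = nxt
            nxt += 1
        ranges[sup] = (start, nxt)
    gf = nx.relabel_nodes(g0.g, mapping, copy=True)
    members = {mapping[v]: frozenset([mapping[v]]) for v in g0.g.nodes}
    return LevelGraph(level=0, g=gf, members=members), ranges


# ---------------------------------------------------------------------------
# Export


def write_gfa(lg: LevelGraph, path: str | Path,
              contigs: dict[Node, str] | None = None) -> None:
    """Export one level as GFA1; S-lines carry nw/ew tags, L-lines weights."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for v in sorted(lg.g.nodes, key=_sort_key):
            seq = (contigs or {}).get(v, "*")
            fh.write(
                f"S\t{v}\t{seq}\tnw:i:{lg.nw(v)}\tew:i:{int(lg.ew(v))}\n"
            )
        for a, b, d in lg.g.edges(data=True):
            fh.write(f"L\t{a}\t+\t{b}\t+\t*\tWT:i:{int(d['weight'])}\n")


def write_level_tsv(lg: LevelGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("u\tv\tweight\n")
        for a, b, d in sorted(
            lg.g.edges(data=True),
            key=lambda t: (_sort_key(t[0]), _sort_key(t[1])),
        ):
            fh.write(f"{a}\t{b}\t{d['weight']}\n")
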