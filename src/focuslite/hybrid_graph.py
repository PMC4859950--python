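"""Hybrid graph: best-representative selection, contig assembly, trimming.

Starting from the most reduced level of the multilevel set, each super
node's read-level cluster subgraph is cleaned (short dead-end branches
removed, small bubbles resolved towards the heavier path, transitive edges
removed) and tested for being a single path.  A node passing the test
becomes the *best representative* of its read cluster at the most reduced
level possible; its descendants at lower levels are blocked.  The hybrid
graph G'_0 is the union of all best representatives, with edges weighted by
the summed inter-cluster overlap weights.  A final filter removes nodes
whose contigs are contained in a neighbor's contig, plus transitive edges.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import edlib
import networkx as nx

from .io_preprocess import Read
from .multilevel_graph import LevelGraph, Node, _sort_key


@dataclass
class HybridNode:
    """A best-representative node with its assembled contig."""

    id: Node
    source_level: int
    contig: str
    member_reads: frozenset[str]
    shannon: float | None = None


@dataclass(frozen=True)
class CleanConfig:
    max_tip_len: int = 3          # dead-end branch length, in nodes
    max_bubble_len: int = 5       # bubble path length bound, in nodes
    max_containment_len: int = 200
    containment_min_identity: float = 0.95


# ---------------------------------------------------------------------------
# Subgraph cleaning


def _branch_from(g: nx.Graph, anchor: Node, first: Node,
                 limit: int) -> list[Node] | None:
    """Chain of nodes leaving ``anchor`` via ``first`` while non-branching.

    Returns the chain if it dead-ends within ``limit`` nodes, else None
    (the branch continues, branches further, or is too long to be a tip).
    """
    chain = [first]
    prev, cur = anchor, first
    while len(chain) <= limit:
        deg = g.degree(cur)
        if deg == 1:
            return chain
        if deg != 2:
            return None
        (nxt,) = (u for u in g.adj[cur] if u != prev)
        chain.append(nxt)
        prev, cur = cur, nxt
    return None


def remove_tips(g: nx.Graph, max_tip_len: int) -> None:
    """Iteratively remove short dead-end branches at branching nodes.

    A tip is a chain of <= max_tip_len nodes that dead-ends off a node of
    degree >= 3 and is strictly shorter than some competing branch at that
    node (a branch that continues, or a longer dead end) -- so a clean path
    never clips its own ends, and of two equal dead ends neither is removed.
    """
    changed = True
    while changed:
        changed = False
        for anchor in [v for v in g.nodes if v in g and g.degree(v) >= 3]:
            branches = [
                _branch_from(g, anchor, nb, max_tip_len)
                for nb in sorted(g.adj[anchor], key=_sort_key)
            ]
            lengths = [len(b) if b is not None else None for b in branches]
            longest = max((l for l in lengths if l is not None), default=0)
            has_continuing = any(l is None for l in lengths)
            for b, l in zip(branches, lengths):
                if b is None:
                    continue
                if l <= max_tip_len and (has_continuing or l < longest):
                    g.remove_nodes_from(b)
                    changed = True


def _path_weight(g: nx.Graph, path: Sequence[Node]) -> float:
    return sum(g.edges[a, b]["weight"] for a, b in zip(path, path[1:]))


def remove_bubbles(g: nx.Graph, max_bubble_len: int) -> None:
    """Resolve small bubbles by deleting the path with smaller total weight.

    A bubble is a pair of node-disjoint paths (interior length bounded by
    max_bubble_len) sharing the same start and end nodes; the lighter path's
    interior nodes are removed.
    """
    queue = deque(sorted(g.nodes, key=_sort_key))
    queued = set(queue)
    while queue:
        s = queue.popleft()
        queued.discard(s)
        if s not in g or g.degree(s) < 2:
            continue
        found = _find_bubble(g, s, max_bubble_len)
        if found is None:
            continue
        p1, p2 = found
        drop = p2 if _path_weight(g, p1) >= _path_weight(g, p2) else p1
        if len(drop) == 2:
            # one arm is the direct s-t edge; drop just that edge
            g.remove_edge(*drop)
        else:
            g.remove_nodes_from(drop[1:-1])
        for v in set(p1) | set(p2):
            if v in g and v not in queued:
                queue.append(v)
                queued.add(v)
        if s in g and s not in queued:
            queue.appendleft(s)
            queued.add(s)


def _find_bubble(
    g: nx.Graph, s: Node, max_len: int
) -> tuple[list[Node], list[Node]] | None:
    """First pair of short node-disjoint paths out of s rejoining at a
    common node; deterministic via sorted neighbor order."""
    nbrs = sorted(g.adj[s], key=_sort_key)
    walks = {a: _walk(g, s, a, max_len) for a in nbrs}
    for i, a in enumerate(nbrs):
        for b in nbrs[i + 1:]:
            pa = walks[a]
            pb = walks[b]
            seen = {v: k for k, v in enumerate(pa[1:], 1) if v != s}
            # rejoin at the earliest common node along both arms (walks can
            # wrap around a cycle, so take the min-max-position candidate)
            best = None
            for k, v in enumerate(pb[1:], 1):
                if v in seen:
                    cand = (max(seen[v], k), seen[v] + k, _sort_key(v))
                    if best is None or cand < best[0]:
                        best = (cand, v, k)
            if best is None:
                continue
            _, v, k = best
            p1, p2 = pa[: seen[v] + 1], pb[: k + 1]
            if set(p1[1:-1]).isdisjoint(p2[1:-1]):
                return p1, p2
    return None


def _walk(g: nx.Graph, s: Node, first: Node, max_len: int) -> list[Node]:
    """Follow the chain s -> first while nodes are non-branching."""
    path = [s, first]
    prev, cur = s, first
    while len(path) <= max_len + 1:
        nbrs = [u for u in g.adj[cur] if u != prev]
        if len(nbrs) != 1:
            break
        path.append(nbrs[0])
        prev, cur = cur, nbrs[0]
    return path


def fold_contained_reads(g: nx.Graph) -> None:
    """Drop reads wholly contained in another read of the subgraph.

    A contained read adds no layout information and its edge-weight ties
    with the container make path resolution ambiguous (exact duplicates are
    mutual containments; the lexicographically smaller id survives).  Needs
    per-node ``length`` attributes; no-op without them.  At full overlap
    sensitivity every neighbor of a contained read also overlaps its
    container over the same span, so connectivity is preserved.
    """
    drop: set[Node] = set()
    for u, v, d in g.edges(data=True):
        lu = g.nodes[u].get("length")
        lv = g.nodes[v].get("length")
        if lu is None or lv is None:
            continue
        delta = d["delta"] if d["du"] == u else -d["delta"]
        v_in_u = delta >= 0 and delta + lv <= lu
        u_in_v = -delta >= 0 and -delta + lu <= lv
        if v_in_u and u_in_v:  # exact duplicates
            drop.add(max(u, v, key=_sort_key))
        elif v_in_u:
            drop.add(v)
        elif u_in_v:
            drop.add(u)
    g.remove_nodes_from(drop)


def transitive_reduction(g: nx.Graph) -> None:
    """Remove overlap edges implied by chains of heavier overlaps.

    An edge (u, v) is redundant when some common neighbor w carries it:
    w(u, w) >= w(u, v) and w(w, v) >= w(u, v) -- the short u-v overlap is
    explained by the two longer overlaps through w.  Edges are processed in
    increasing weight order (stable id tie-break) against the current graph,
    which resolves equal-weight ties deterministically and never disconnects
    the graph via simultaneous symmetric removals.
    """
    order = sorted(
        g.edges(data=True),
        key=lambda t: (t[2]["weight"], _sort_key(t[0]), _sort_key(t[1])),
    )
    for u, v, d in order:
        w_uv = d["weight"]
        for w in g.adj[u]:
            if w in (u, v) or w not in g.adj[v]:
                continue
            if g.edges[u, w]["weight"] >= w_uv and g.edges[w, v]["weight"] >= w_uv:
                g.remove_edge(u, v)
                break


def clean_subgraph(sub: nx.Graph, cfg: CleanConfig | None = None) -> nx.Graph:
    """Tip removal, bubble resolution, then transitive reduction, in place on
    a copy; returns the cleaned subgraph."""
    cfg = cfg or CleanConfig()
    g = sub.copy()
    fold_contained_reads(g)
    # Iterate to a fixed point: transitive reduction can expose new tips
    # (e.g. near-duplicate reads reduce to dangling single-node spurs).
    while True:
        before = (g.number_of_nodes(), g.number_of_edges())
        remove_tips(g, cfg.max_tip_len)
        remove_bubbles(g, cfg.max_bubble_len)
        transitive_reduction(g)
        if (g.number_of_nodes(), g.number_of_edges()) == before:
            return g


def is_single_path(sub: nx.Graph) -> bool:
    """True iff the subgraph is one simple path (a singleton counts)."""
    n = sub.number_of_nodes()
    if n == 0:
        return False
    if n == 1:
        return True
    if not nx.is_connected(sub):
        return False
    degs = Counter(dict(sub.degree()).values())
    return degs.get(1, 0) == 2 and degs.get(2, 0) == n - 2 and len(degs) <= 2


# ---------------------------------------------------------------------------
# Contig assembly


def assemble_contig(sub: nx.Graph, reads: dict[str, Read]) -> str:
    """Assemble a cleaned single-path read subgraph into a contig.

    Reads are laid out left-to-right using the per-edge layout offsets
    recorded during overlap alignment; the consensus takes the majority base
    per column, ties resolved by the first read (in layout order) covering
    the column.
    """
    if not is_single_path(sub):
        raise ValueError("subgraph is not a single path")
    nodes = sorted(sub.nodes, key=_sort_key)
    if len(nodes) == 1:
        return reads[nodes[0]].seq
    start = min((v for v in nodes if sub.degree(v) == 1), key=_sort_key)
    offsets = {start: 0}
    order = [start]
    prev, cur = None, start
    while True:
        nbrs = [u for u in sub.adj[cur] if u != prev]
        if not nbrs:
            break
        nxt = nbrs[0]
        d = sub.edges[cur, nxt]
        delta = d["delta"] if d["du"] == cur else -d["delta"]
        offsets[nxt] = offsets[cur] + delta
        order.append(nxt)
        prev, cur = cur, nxt
    base = min(offsets.values())
    length = max(offsets[v] + len(reads[v].seq) for v in order) - base
    votes: list[Counter] = [Counter() for _ in range(length)]
    first: list[str | None] = [None] * length
    for v in order:
        off = offsets[v] - base
        for i, ch in enumerate(reads[v].seq):
            votes[off + i][ch] += 1
            if first[off + i] is None:
                first[off + i] = ch
    out = []
    for col, f in zip(votes, first):
        if not col:
            raise ValueError("layout gap during contig assembly")
        top = col.most_common()
        best = max(n for _, n in top)
        winners = {ch for ch, n in top if n == best}
        out.append(f if f in winners else min(winners))
    return "".join(out)


# ---------------------------------------------------------------------------
# Representative selection


@dataclass
class HybridGraphSet:
    """Result of best-representative selection.

    ``hybrid`` is G'_0: one node per best representative, edges weighted by
    the summed inter-cluster G_0 edge weights.  ``nodes`` maps hybrid node
    id -> HybridNode; ``selected_at`` records (level, node-in-level) for each
    representative; ``level_graphs`` holds G'_n .. G'_0 keyed by level.
    """

    hybrid: nx.Graph
    nodes: dict[Node, HybridNode]
    selected_at: dict[Node, tuple[int, Node]]
    level_graphs: dict[int, nx.Graph] = field(default_factory=dict)

    def contigs(self) -> dict[Node, str]:
        return {k: n.contig for k, n in self.nodes.items()}


def select_representatives(
    levels: Sequence[LevelGraph],
    reads: dict[str, Read],
    cfg: CleanConfig | None = None,
    build_level_set: bool = False,
) -> HybridGraphSet:
    """Backtrack through the multilevel set selecting best representatives.

    Iterates levels from G_n down to G_0.  Each not-yet-blocked node's
    cluster subgraph (the G_0 subgraph induced by its member reads, as
    relabeled contiguously in G_final) is cleaned and tested; single-path
    clusters are selected and their descendants blocked.  Level-0 nodes are
    singleton clusters and always pass, so the member read sets of the
    selected representatives partition the retained read set.
    """
    cfg = cfg or CleanConfig()
    g0 = levels[0]
    selected: list[tuple[int, Node]] = []
    blocked: dict[int, set[Node]] = {lg.level: set() for lg in levels}
    rep_nodes: dict[Node, HybridNode] = {}
    selected_at: dict[Node, tuple[int, Node]] = {}
    owner: dict[str, Node] = {}
    not_selected: dict[int, list[Node]] = {}
    next_id = 0
    for lg in reversed(levels):
        lvl = lg.level
        not_selected[lvl] = []
        for v in sorted(lg.g.nodes, key=_sort_key):
            if v in blocked[lvl]:
                continue
            sub = clean_subgraph(g0.g.subgraph(lg.members[v]), cfg)
            if is_single_path(sub):
                contig = assemble_contig(sub, reads)
                hid = next_id
                next_id += 1
                rep_nodes[hid] = HybridNode(
                    id=hid, source_level=lvl, contig=contig,
                    member_reads=frozenset(lg.members[v]),
                )
                selected_at[hid] = (lvl, v)
                for r in lg.members[v]:
                    owner[r] = hid
                # block all descendants at lower levels
                frontier = [(lvl, v)]
                while frontier:
                    flvl, fv = frontier.pop()
                    if flvl == 0:
                        continue
                    kids = levels[flvl].children.get(fv, ())
                    blocked[flvl - 1].update(kids)
                    frontier.extend((flvl - 1, k) for k in kids)
            else:
                not_selected[lvl].append(v)

    hybrid = nx.Graph()
    hybrid.add_nodes_from(rep_nodes)
    for a, b, d in g0.g.edges(data=True):
        oa, ob = owner[a], owner[b]
        if oa == ob:
            continue
        if hybrid.has_edge(oa, ob):
            hybrid.edges[oa, ob]["weight"] += d["weight"]
        else:
            hybrid.add_edge(oa, ob, weight=d["weight"])

    result = HybridGraphSet(hybrid=hybrid, nodes=rep_nodes,
                            selected_at=selected_at)
    if build_level_set:
        result.level_graphs = _build_level_graphs(
            levels, g0, rep_nodes, selected_at, not_selected, owner
        )
    return result


def _build_level_graphs(levels, g0, rep_nodes, selected_at,
                        not_selected, owner) -> dict[int, nx.Graph]:
    """G'_l for every level: representatives selected at levels >= l plus
    the unblocked-but-not-selected nodes of level l, edges by summed
    inter-cluster weight."""
    out: dict[int, nx.Graph] = {}
    for lg in levels:
        lvl = lg.level
        gp = nx.Graph()
        cluster_of: dict[str, Node] = {}
        for hid, (slvl, _) in selected_at.items():
            if slvl >= lvl:
                gp.add_node(("rep", hid))
                for r in rep_nodes[hid].member_reads:
                    cluster_of[r] = ("rep", hid)
        for v in not_selected[lvl]:
            gp.add_node(("lvl", v))
            for r in lg.members[v]:
                cluster_of.setdefault(r, ("lvl", v))
        for a, b, d in g0.g.edges(data=True):
            ca, cb = cluster_of.get(a), cluster_of.get(b)
            if ca is None or cb is None or ca == cb:
                continue
            if gp.has_edge(ca, cb):
                gp.edges[ca, cb]["weight"] += d["weight"]
            else:
                gp.add_edge(ca, cb, weight=d["weight"])
        out[lvl] = gp
    return out


# ---------------------------------------------------------------------------
# Hybrid graph filter


def _contained_in(small: str, big: str, min_identity: float) -> bool:
    """Infix alignment: is `small` contained in `big` (or its neighbor's
    orientation) at >= min_identity?"""
    if len(small) > len(big):
        return False
    max_dist = int(len(small) * (1 - min_identity))
    res = edlib.align(small, big, mode="HW", task="distance", k=max_dist)
    return res["editDistance"] != -1


def trim_hybrid(
    hset: HybridGraphSet, cfg: CleanConfig | None = None
) -> HybridGraphSet:
    """Remove contained-contig nodes and transitive edges from G'_0.

    Nodes are visited in ascending contig length (id tie-break).  A node
    whose contig is shorter than ``max_containment_len`` and maps to a
    neighbor's contig at >= containment_min_identity is deleted with its
    incident edges; the sweep repeats until a fixed point, then transitive
    edges are removed.  Operates on (and returns) a trimmed copy.
    """
    cfg = cfg or CleanConfig()
    g = hset.hybrid.copy()
    nodes = dict(hset.nodes)
    changed = True
    while changed:
        changed = False
        order = sorted(g.nodes, key=lambda v: (len(nodes[v].contig), v))
        for v in order:
            contig = nodes[v].contig
            if len(contig) >= cfg.max_containment_len:
                continue
            for u in sorted(g.adj[v]):
                if _contained_in(contig, nodes[u].contig,
                                 cfg.containment_min_identity):
                    g.remove_node(v)
                    del nodes[v]
                    changed = True
                    break
            if changed:
                break
    transitive_reduction(g)
    return HybridGraphSet(
        hybrid=g, nodes=nodes,
        selected_at={k: v for k, v in hset.selected_at.items() if k in nodes},
        level_graphs=hset.level_graphs,
    )


# ---------------------------------------------------------------------------
# Export


def write_contigs(hset: HybridGraphSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for hid in sorted(hset.nodes):
            n = hset.nodes[hid]
            fh.write(
                f">{n.id} level={n.source_level} reads={len(n.member_reads)}\n"
            )
            for i in range(0, len(n.contig), 80):
                fh.write(n.contig[i: i + 80] + "\n")


def write_hybrid_gfa(hset: HybridGraphSet, path: str | Path,
                     shannon: dict[Node, float] | None = None) -> None:
    shannon = shannon or {}
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for hid in sorted(hset.hybrid.nodes):
            n = hset.nodes[hid]
            tags = f"LV:i:{n.source_level}"
            if hid in shannon:
                tags += f"\tSH:f:{shannon[hid]:.4f}"
            fh.write(f"S\t{hid}\t{n.contig}\t{tags}\n")
        for a, b, d in hset.hybrid.edges(data=True):
            fh.write(f"L\t{a}\t+\t{b}\t+\t*\tWT:i:{int(d['weight'])}\n")
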