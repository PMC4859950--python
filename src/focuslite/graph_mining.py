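"""Hybrid-graph mining: Shannon scoring, clustering, enrichment testing.

Every node of the trimmed hybrid graph is scored with Shannon's index of
its normalised incident-edge weight distribution,

    H = -sum_i (w_i / W_total) ln(w_i / W_total),

which is bounded by ln(n) for n incident edges and is high when a node has
many, evenly weighted edges -- the signature of a sequence region repeated
within a genome or shared between species.  High-scoring nodes annotated as
transposase-bearing are characterised by the genus composition of their
neighboring contigs, clustered on those composition vectors with k-means,
and each cluster's pooled 5-neighborhood is tested for gene-class
enrichment with a one-sided Fisher exact test under Benjamini-Hochberg FDR
correction.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.stats import fisher_exact
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

Node = Hashable

#: default threshold for a Shannon's index score to count as "high": ln(3)
#: (the maximum score of a node with three evenly weighted edges, guarding
#: against a spurious third edge pushing a two-edge node over ln(2)),
#: rounded down to one for simplicity.
HIGH_SCORE_THRESHOLD = 1.0


@dataclass(frozen=True)
class ShannonScore:
    node: Node
    n_edges: int
    H: float


@dataclass(frozen=True)
class TaxVector:
    """Length-weighted genus composition of a node's adjacent contigs."""

    node: Node
    x: Mapping[str, float]
    unknown_frac: float


@dataclass
class ClassEnrichment:
    gene_class: str
    inside_class: int
    inside_other: int
    outside_class: int
    outside_other: int
    odds_ratio: float
    p: float
    q: float = math.nan

    @property
    def stars(self) -> str:
        for cut, s in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
            if self.q < cut:
                return s
        return ""


@dataclass
class ClusterReport:
    cluster: int
    members: list[Node]
    mean_genus_distribution: dict[str, float]
    enrichments: list[ClassEnrichment] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Shannon's index


def shannon_index(weights: Sequence[float]) -> float:
    """Entropy (nats) of the normalised weight distribution; 0 for n <= 1."""
    ws = [w for w in weights]
    if any(w <= 0 for w in ws):
        raise ValueError("edge weights must be positive")
    if len(ws) <= 1:
        return 0.0
    total = sum(ws)
    return -sum((w / total) * math.log(w / total) for w in ws)


def score_all(g: nx.Graph) -> dict[Node, float]:
    """Shannon's index per node from its incident-edge weights."""
    return {
        v: shannon_index([d["weight"] for _, _, d in g.edges(v, data=True)])
        for v in g.nodes
    }


def select_high_nodes(
    scores: Mapping[Node, float],
    annotations: Mapping[Node, set[str]],
    tag: str = "transposase",
    threshold: float = HIGH_SCORE_THRESHOLD,
    g: nx.Graph | None = None,
    min_edge_weight_filter: float | None = None,
) -> list[Node]:
    """Nodes with H > threshold carrying ``tag``; optionally also requiring
    at least one incident edge of weight >= min_edge_weight_filter (a low
    coverage filter)."""
    out = []
    for v, h in scores.items():
        if h <= threshold or tag not in annotations.get(v, set()):
            continue
        if min_edge_weight_filter is not None:
            if g is None:
                raise ValueError("edge weight filter requires the graph")
            wmax = max(
                (d["weight"] for _, _, d in g.edges(v, data=True)), default=0
            )
            if wmax < min_edge_weight_filter:
                continue
        out.append(v)
    return sorted(out, key=str)


# ---------------------------------------------------------------------------
# Neighborhood taxonomy vectors


def tax_vector(
    node: Node,
    g: nx.Graph,
    contig_taxa: Mapping[Node, str],
    contig_len: Mapping[Node, int],
) -> TaxVector:
    """Genus shares over the node's distance-1 neighbors, weighted by
    neighbor contig length; contigs labeled "unknown" (or unlabeled)
    contribute to unknown_frac."""
    nbrs = list(g.adj[node])
    if not nbrs:
        raise ValueError(f"node {node!r} has no neighbors")
    total = sum(contig_len[u] for u in nbrs)
    shares: dict[str, float] = {}
    unknown = 0.0
    for u in nbrs:
        genus = contig_taxa.get(u, "unknown")
        frac = contig_len[u] / total
        if genus == "unknown":
            unknown += frac
        else:
            shares[genus] = shares.get(genus, 0.0) + frac
    return TaxVector(node=node, x=shares, unknown_frac=unknown)


def cluster_transposase_nodes(
    vectors: Sequence[TaxVector],
    k: int,
    max_unknown: float = 0.20,
    seed: int = 0,
    k_max: int | None = None,
    n_init: int = 50,
) -> tuple[dict[Node, int], list[tuple[int, float]]]:
    """K-means (Euclidean) over genus-composition vectors.

    Vectors with unknown_frac > max_unknown are excluded.  Returns the
    node -> cluster assignment for ``k`` clusters and the elbow data: the
    within-cluster sum of squares for each k' = 1..k_max (default: k).
    """
    eligible = [v for v in vectors if v.unknown_frac <= max_unknown]
    if len(eligible) < k:
        raise ValueError(
            f"{len(eligible)} eligible vectors but k={k} clusters requested"
        )
    genera = sorted({genus for v in eligible for genus in v.x})
    X = np.array(
        [[v.x.get(genus, 0.0) for genus in genera] for v in eligible]
    )
    k_max = k_max or k
    elbow: list[tuple[int, float]] = []
    assignment: dict[Node, int] = {}
    for kk in range(1, max(k, k_max) + 1):
        if kk > len(eligible):
            break
        km = KMeans(n_clusters=kk, n_init=n_init, random_state=seed)
        labels = km.fit_predict(X)
        if kk <= k_max:
            elbow.append((kk, float(km.inertia_)))
        if kk == k:
            assignment = {v.node: int(l) for v, l in zip(eligible, labels)}
    return assignment, elbow


def k_neighborhood(g: nx.Graph, node: Node, k: int = 5) -> set[Node]:
    """All nodes within path distance k of ``node`` (center included)."""
    return set(nx.single_source_shortest_path_length(g, node, cutoff=k))


# ---------------------------------------------------------------------------
# Gene-class enrichment


def enrichment_test(
    cluster_nodes: Mapping[int, Sequence[Node]],
    g: nx.Graph,
    gene_hits: Mapping[Node, Sequence[str]],
    radius: int = 5,
    tax_vectors: Mapping[Node, TaxVector] | None = None,
) -> list[ClusterReport]:
    """Per-cluster gene-class enrichment in pooled k-neighborhoods.

    For each cluster, the neighborhoods of its member nodes (radius
    ``radius``) are pooled into one deduplicated node set.  For each gene
    class a 2x2 table compares class hits vs other hits, inside the pooled
    neighborhood vs on all hybrid-graph contigs; hits are counted once per
    contig-class pair.  One-sided (greater) Fisher exact p-values are
    FDR-corrected across all (cluster, class) pairs with Benjamini-Hochberg.
    """
    # dedup: one count per (contig, class)
    contig_classes: dict[Node, set[str]] = {
        v: set(classes) for v, classes in gene_hits.items() if classes
    }
    all_classes = sorted({c for cs in contig_classes.values() for c in cs})
    totals = {
        c: sum(1 for cs in contig_classes.values() if c in cs)
        for c in all_classes
    }
    grand_total = sum(totals.values())

    reports: list[ClusterReport] = []
    flat: list[ClassEnrichment] = []
    for cid in sorted(cluster_nodes):
        members = list(cluster_nodes[cid])
        ball: set[Node] = set()
        for v in members:
            ball |= k_neighborhood(g, v, radius)
        inside = {
            c: sum(
                1 for v in ball for cc in (contig_classes.get(v, ()),)
                if c in cc
            )
            for c in all_classes
        }
        inside_total = sum(inside.values())
        mean_genus: dict[str, float] = {}
        if tax_vectors:
            vecs = [tax_vectors[v] for v in members if v in tax_vectors]
            for vec in vecs:
                for genus, frac in vec.x.items():
                    mean_genus[genus] = mean_genus.get(genus, 0.0) + frac
            mean_genus = {
                genus: s / len(vecs) for genus, s in mean_genus.items()
            }
        report = ClusterReport(
            cluster=cid, members=members, mean_genus_distribution=mean_genus
        )
        for c in all_classes:
            if totals[c] == 0:
                continue
            a = inside[c]
            b = inside_total - a
            cc = totals[c] - a
            d = (grand_total - inside_total) - cc
            odds, p = fisher_exact([[a, b], [cc, d]], alternative="greater")
            enr = ClassEnrichment(
                gene_class=c, inside_class=a, inside_other=b,
                outside_class=cc, outside_other=d,
                odds_ratio=float(odds), p=float(p),
            )
            report.enrichments.append(enr)
            flat.append(enr)
        reports.append(report)
    if flat:
        _, qvals, _, _ = multipletests(
            [e.p for e in flat], method="fdr_bh"
        )
        for e, q in zip(flat, qvals):
            e.q = float(q)
    return reports


# ---------------------------------------------------------------------------
# Annotation table IO and report output


def read_tag_tsv(path: str | Path) -> dict[str, set[str]]:
    """`contig_id <tab> tag` rows -> contig -> tag set."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            out.setdefault(row[0], set()).add(row[1])
    return out


def read_taxa_tsv(path: str | Path) -> dict[str, str]:
    """`contig_id <tab> genus` rows -> contig -> genus."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            out[row[0]] = row[1]
    return out


def read_gene_hits_tsv(path: str | Path) -> dict[str, list[str]]:
    """`contig_id <tab> gene_class [<tab> gene_name]` rows."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            out.setdefault(row[0], []).append(row[1])
    return out


def write_scores_tsv(scores: Mapping[Node, float], g: nx.Graph,
                     path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node\tn_edges\tshannon\n")
        for v in sorted(scores, key=str):
            fh.write(f"{v}\t{g.degree(v)}\t{scores[v]:.6f}\n")


def write_cluster_reports(reports: Sequence[ClusterReport],
                          tsv_path: str | Path,
                          json_path: str | Path | None = None) -> None:
    with open(tsv_path, "w") as fh:
        fh.write(
            "cluster\tgene_class\tinside_class\tinside_other\t"
            "outside_class\toutside_other\todds_ratio\tp\tq\tsignif\n"
        )
        for r in reports:
            for e in r.enrichments:
                fh.write(
                    f"{r.cluster}\t{e.gene_class}\t{e.inside_class}\t"
                    f"{e.inside_other}\t{e.outside_class}\t{e.outside_other}"
                    f"\t{e.odds_ratio:.4g}\t{e.p:.4g}\t{e.q:.4g}\t{e.stars}\n"
                )
    if json_path is not None:
        payload = [
            {
                "cluster": r.cluster,
                "members": [str(m) for m in r.members],
                "mean_genus_distribution": r.mean_genus_distribution,
                "enrichments": [
                    {
                        "gene_class": e.gene_class,
                        "table": [[e.inside_class, e.inside_other],
                                  [e.outside_class, e.outside_other]],
                        "odds_ratio": e.odds_ratio,
                        "p": e.p, "q": e.q, "signif": e.stars,
                    }
                    for e in r.enrichments
                ],
            }
            for r in reports
        ]
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1)


def write_elbow_csv(elbow: Sequence[tuple[int, float]],
                    path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("k,wss\n")
        for k, wss in elbow:
            fh.write(f"{k},{wss:.6g}\n")
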