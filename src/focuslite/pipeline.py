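"""End-to-end pipeline: reads -> overlap graph -> multilevel set -> hybrid
graph -> Shannon scores.  Thin orchestration over the stage modules."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .graph_mining import score_all
from .hybrid_graph import (CleanConfig, HybridGraphSet, select_representatives,
                           trim_hybrid)
from .io_preprocess import PreprocessStats, Read, TrimConfig, partition_reads, \
    preprocess_reads
from .multilevel_graph import (CoarsenConfig, LevelGraph, build_overlap_graph,
                               coarsen_all)
from .overlap_align import AlignConfig, OverlapEdge, all_vs_all_overlaps


@dataclass
class PipelineResult:
    reads: dict[str, Read]
    stats: PreprocessStats
    edges: list[OverlapEdge]
    levels: list[LevelGraph]
    hybrid: HybridGraphSet          # trimmed hybrid graph set
    shannon: dict[object, float]
    untrimmed: HybridGraphSet | None = None


def run_pipeline(
    raw_reads: Sequence[Read],
    trim: TrimConfig | None = None,
    align: AlignConfig | None = None,
    coarsen: CoarsenConfig | None = None,
    clean: CleanConfig | None = None,
    n_subsets: int = 1,
    keep_untrimmed: bool = False,
) -> PipelineResult:
    """Run every pipeline stage with the given configurations."""
    processed, stats = preprocess_reads(raw_reads, trim)
    reads = {r.id: r for r in processed}
    subsets = partition_reads(processed, n_subsets)
    edges = all_vs_all_overlaps(subsets, align)
    g0 = build_overlap_graph(
        edges, reads=reads.keys(),
        lengths={rid: len(r) for rid, r in reads.items()},
    )
    levels = coarsen_all(g0, coarsen)
    hset = select_representatives(levels, reads, clean)
    trimmed = trim_hybrid(hset, clean)
    shannon = score_all(trimmed.hybrid)
    for hid, h in shannon.items():
        trimmed.nodes[hid].shannon = h
    return PipelineResult(
        reads=reads, stats=stats, edges=edges, levels=levels,
        hybrid=trimmed, shannon=shannon,
        untrimmed=hset if keep_untrimmed else None,
    )
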