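"""Synthetic microbial communities with planted mobile elements.

The generator emulates the genomic features that give an assembly graph its
mineable structure: several random genomes ("genera") sharing an identical
transposase-like element (an insertion-sequence analog -- inverted repeats
flanking a core) inserted at a random locus of each carrier genome; an
rRNA-like segment repeated in multiple identical copies within each genome;
a "resistance-gene" segment of a named class planted a fixed distance
downstream of element copies; and background gene segments of a neutral
class scattered through unique sequence so that enrichment tests have a
non-degenerate background.  Reads are sampled uniformly from both strands
with i.i.d. substitution errors and Gaussian Phred qualities, and full
ground truth (per-read source coordinates, element/gene intervals) is
returned for every pipeline stage to test against.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_preprocess import REVCOMP_SUFFIX, Read

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class CommunityConfig:
    """Study conditions for the planted community.

    ``transposon_carriers`` is a tuple of carrier groups; each group is a
    tuple of genome indices sharing one identical element sequence.
    ``resistance_carriers`` selects the element copies (by genome index)
    that get a resistance segment planted ``resistance_offset`` bp
    downstream of the element's 3' end.
    """

    n_genomes: int = 3
    genome_len: int = 20_000
    transposon_len: int = 1_000
    transposon_carriers: tuple[tuple[int, ...], ...] = ((0, 1, 2),)
    ir_len: int = 30
    rrna_copies: int = 2
    rrna_len: int = 600
    resistance_offset: int = 1_500
    resistance_len: int = 400
    resistance_class: str = "tetracycline"
    resistance_carriers: tuple[int, ...] | None = None  # None: all carriers
    background_genes_per_genome: int = 6
    background_len: int = 400
    background_class: str = "housekeeping"
    coverage: float = 20.0
    read_len: int = 100
    error_rate: float = 0.0
    qual_mean: float = 30.0
    qual_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transposon_len >= self.genome_len / 10:
            raise ValueError("transposon_len must be < genome_len / 10")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        for group in self.transposon_carriers:
            for gi in group:
                if not 0 <= gi < self.n_genomes:
                    raise ValueError(f"carrier index {gi} out of range")


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a genome."""

    genome: int
    start: int
    stop: int
    label: str  # element group / gene class / feature name


@dataclass
class TruthTables:
    """Ground truth for a simulated community."""

    read_source: dict[str, tuple[int, int, int, str]] = field(
        default_factory=dict
    )  # read id -> (genome, start, stop, strand)
    elements: list[Interval] = field(default_factory=list)
    rrna: list[Interval] = field(default_factory=list)
    genes: list[Interval] = field(default_factory=list)  # label = gene class
    element_seqs: dict[str, str] = field(default_factory=dict)

    def genus_of(self, genome: int) -> str:
        return f"genus_{genome}"


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def simulate_community(
    cfg: CommunityConfig | None = None,
) -> tuple[list[str], TruthTables]:
    """Generate the community genomes and ground-truth tables.

    Genomes are uniform-random ACGT backbones into which the planted blocks
    (element [+ offset + resistance segment], rRNA copies, background
    genes) are spliced in random order, separated by unique spacers whose
    lengths are drawn to fill the configured genome length.  Element
    sequences are identical across the genomes of a carrier group and are
    flanked by an inverted repeat of ``ir_len``; rRNA copies are identical
    within a genome.  Deterministic under ``cfg.seed``.
    """
    cfg = cfg or CommunityConfig()
    rng = np.random.default_rng(cfg.seed)
    truth = TruthTables()

    # shared element per carrier group: IR + core + reverse-complemented IR
    group_seqs: list[str] = []
    for gidx, _ in enumerate(cfg.transposon_carriers):
        ir = _random_seq(rng, cfg.ir_len)
        core = _random_seq(rng, cfg.transposon_len - 2 * cfg.ir_len)
        seq = ir + core + _revcomp(ir)
        group_seqs.append(seq)
        truth.element_seqs[f"element_{gidx}"] = seq

    res_carriers = cfg.resistance_carriers
    if res_carriers is None:
        res_carriers = tuple(
            gi for group in cfg.transposon_carriers for gi in group
        )

    genomes: list[str] = []
    min_spacer = cfg.read_len  # keep planted blocks separated by unique seq
    for genome in range(cfg.n_genomes):
        blocks: list[list[tuple[int, str]]] = []  # [(len, label)] per block
        seqs: list[list[str]] = []
        for gidx, group in enumerate(cfg.transposon_carriers):
            if genome not in group:
                continue
            block = [(cfg.transposon_len, f"element_{gidx}")]
            bseq = [group_seqs[gidx]]
            if genome in res_carriers:
                block.append((cfg.resistance_offset, ""))
                bseq.append(_random_seq(rng, cfg.resistance_offset))
                block.append(
                    (cfg.resistance_len, f"gene:{cfg.resistance_class}")
                )
                bseq.append(_random_seq(rng, cfg.resistance_len))
            blocks.append(block)
            seqs.append(bseq)
        rrna_seq = _random_seq(rng, cfg.rrna_len)
        for _ in range(cfg.rrna_copies):
            blocks.append([(cfg.rrna_len, "rrna")])
            seqs.append([rrna_seq])
        for b in range(cfg.background_genes_per_genome):
            blocks.append(
                [(cfg.background_len, f"gene:{cfg.background_class}")]
            )
            seqs.append([_random_seq(rng, cfg.background_len)])

        block_total = sum(l for block in blocks for l, _ in block)
        n_spacers = len(blocks) + 1
        unique_total = cfg.genome_len - block_total
        if unique_total < n_spacers * min_spacer:
            raise ValueError(
                "planted blocks do not fit: genome_len too small for the "
                "configured elements and spacers"
            )
        weights = rng.random(n_spacers) + 0.5
        extra = unique_total - n_spacers * min_spacer
        spacer_lens = (min_spacer + np.floor(
            weights / weights.sum() * extra
        )).astype(int)
        spacer_lens[-1] += unique_total - int(spacer_lens.sum())

        order = rng.permutation(len(blocks))
        parts: list[str] = []
        pos = 0
        for i, bi in enumerate(order):
            spacer = _random_seq(rng, int(spacer_lens[i]))
            parts.append(spacer)
            pos += len(spacer)
            for (length, label), seg in zip(blocks[bi], seqs[bi]):
                parts.append(seg)
                iv = Interval(genome, pos, pos + length, label)
                if label.startswith("element_"):
                    truth.elements.append(iv)
                elif label == "rrna":
                    truth.rrna.append(iv)
                elif label.startswith("gene:"):
                    truth.genes.append(
                        Interval(genome, pos, pos + length,
                                 label.removeprefix("gene:"))
                    )
                pos += length
        parts.append(_random_seq(rng, int(spacer_lens[-1])))
        genomes.append("".join(parts))
        assert len(genomes[-1]) == cfg.genome_len
    return genomes, truth


def sample_reads(
    genomes: Sequence[str],
    cfg: CommunityConfig,
    truth: TruthTables | None = None,
) -> tuple[list[Read], TruthTables]:
    """Sample reads uniformly from both strands of each genome.

    Read count per genome is coverage * genome_len / read_len; substitution
    errors are i.i.d. at ``error_rate`` and Phred qualities are drawn from
    Normal(qual_mean, qual_sd) clamped to [2, 40].  Per-read source
    coordinates are recorded in the truth tables.
    """
    truth = truth if truth is not None else TruthTables()
    rng = np.random.default_rng(cfg.seed + 1)
    reads: list[Read] = []
    rl = cfg.read_len
    for genome, seq in enumerate(genomes):
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        n_reads = int(round(cfg.coverage * len(seq) / rl))
        starts = rng.integers(0, len(seq) - rl + 1, size=n_reads)
        # anchor the genome ends so the full sequence is covered at the
        # configured fold (uniform sampling alone leaves the tips ragged)
        if n_reads >= 2:
            starts[0] = 0
            starts[1] = len(seq) - rl
        strands = rng.random(n_reads) < 0.5
        quals = np.clip(
            np.rint(rng.normal(cfg.qual_mean, cfg.qual_sd, (n_reads, rl))),
            2, 40,
        ).astype(int)
        for i in range(n_reads):
            s = int(starts[i])
            sub = arr[s: s + rl].copy()
            if cfg.error_rate > 0:
                mask = rng.random(rl) < cfg.error_rate
                if mask.any():
                    shift = rng.integers(1, 4, size=int(mask.sum()))
                    idx = np.searchsorted(_BASES, sub[mask])
                    sub[mask] = _BASES[(idx + shift) % 4]
            read_seq = sub.tobytes().decode("ascii")
            strand = "-" if strands[i] else "+"
            if strand == "-":
                read_seq = _revcomp(read_seq)
            rid = f"g{genome}r{i:05d}"
            reads.append(Read(id=rid, seq=read_seq, qual=tuple(quals[i])))
            truth.read_source[rid] = (genome, s, s + rl, strand)
    return reads, truth


# ---------------------------------------------------------------------------
# Truth-based annotation of assembled hybrid nodes


def _source_read_id(read_id: str) -> str:
    return read_id.removesuffix(REVCOMP_SUFFIX)


def _member_intervals(
    member_reads: Iterable[str], truth: TruthTables
) -> dict[int, list[tuple[int, int]]]:
    per_genome: dict[int, list[tuple[int, int]]] = {}
    for rid in member_reads:
        src = truth.read_source.get(_source_read_id(rid))
        if src is None:
            continue
        genome, start, stop, _ = src
        per_genome.setdefault(genome, []).append((start, stop))
    return per_genome


def _overlaps(iv: Interval, spans: Mapping[int, list[tuple[int, int]]]) -> bool:
    for start, stop in spans.get(iv.genome, ()):
        if start < iv.stop and iv.start < stop:
            return True
    return False


def truth_annotations(
    truth: TruthTables,
    member_reads_by_node: Mapping[object, Iterable[str]],
) -> tuple[dict[object, str], dict[object, set[str]], dict[object, list[str]]]:
    """Annotate hybrid nodes from ground truth.

    Stands in for the external read-mapping and protein-alignment steps of a
    real workflow: each node is assigned the genus of the majority of its
    member reads' source genomes ("genus_<i>", or "unknown" when no member
    read has a source record); nodes whose member reads overlap a planted
    element interval are tagged "transposase" (rRNA intervals tag "rrna");
    gene-class hits are emitted for nodes overlapping planted gene segments.
    """
    taxa: dict[object, str] = {}
    tags: dict[object, set[str]] = {}
    gene_hits: dict[object, list[str]] = {}
    for node, members in member_reads_by_node.items():
        members = list(members)
        spans = _member_intervals(members, truth)
        if not spans:
            taxa[node] = "unknown"
            continue
        counts = {g: len(ivs) for g, ivs in spans.items()}
        majority = max(sorted(counts), key=lambda g: counts[g])
        taxa[node] = truth.genus_of(majority)
        node_tags: set[str] = set()
        for iv in truth.elements:
            if _overlaps(iv, spans):
                node_tags.add("transposase")
        for iv in truth.rrna:
            if _overlaps(iv, spans):
                node_tags.add("rrna")
        if node_tags:
            tags[node] = node_tags
        classes = []
        for iv in truth.genes:
            if _overlaps(iv, spans):
                classes.append(iv.label)
        if classes:
            gene_hits[node] = sorted(set(classes))
    return taxa, tags, gene_hits


# ---------------------------------------------------------------------------
# Presets and file output


PRESETS: dict[str, CommunityConfig] = {
    # shared transposase element across all three genomes, the headline
    # planted-structure study condition
    "shared-transposon": CommunityConfig(),
    # small community for quick runs
    "small": CommunityConfig(
        n_genomes=2, genome_len=8_000, transposon_len=500,
        transposon_carriers=((0, 1),), ir_len=25,
        rrna_copies=2, rrna_len=300, resistance_offset=800,
        resistance_len=300, background_genes_per_genome=3,
        background_len=250, coverage=15.0,
    ),
    # repeat-rich single genome: many rRNA-like copies, no shared element
    "repeatrich": CommunityConfig(
        n_genomes=1, genome_len=20_000, transposon_carriers=((0,),),
        rrna_copies=5, background_genes_per_genome=4,
    ),
}


def write_genomes_fasta(genomes: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(genomes):
            fh.write(f">genome_{i}\n")
            for j in range(0, len(seq), 80):
                fh.write(seq[j: j + 80] + "\n")


def write_truth_tables(truth: TruthTables, outdir: str | Path) -> None:
    outdir = Path(outdir)
    with open(outdir / "read_source.tsv", "w") as fh:
        fh.write("read_id\tgenome\tstart\tstop\tstrand\n")
        for rid in sorted(truth.read_source):
            genome, start, stop, strand = truth.read_source[rid]
            fh.write(f"{rid}\t{genome}\t{start}\t{stop}\t{strand}\n")
    with open(outdir / "features.tsv", "w") as fh:
        fh.write("kind\tgenome\tstart\tstop\tlabel\n")
        for kind, ivs in (
            ("element", truth.elements),
            ("rrna", truth.rrna),
            ("gene", truth.genes),
        ):
            for iv in ivs:
                fh.write(
                    f"{kind}\t{iv.genome}\t{iv.start}\t{iv.stop}\t{iv.label}\n"
                )


def write_annotation_tsvs(
    taxa: Mapping[object, str],
    tags: Mapping[object, set[str]],
    gene_hits: Mapping[object, list[str]],
    outdir: str | Path,
) -> None:
    outdir = Path(outdir)
    with open(outdir / "taxa.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for node in sorted(taxa, key=str):
            w.writerow([node, taxa[node]])
    with open(outdir / "tags.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for node in sorted(tags, key=str):
            for tag in sorted(tags[node]):
                w.writerow([node, tag])
    with open(outdir / "gene_hits.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for node in sorted(gene_hits, key=str):
            for cls in gene_hits[node]:
                w.writerow([node, cls, ""])
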