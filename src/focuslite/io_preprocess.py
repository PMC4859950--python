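"""Read input handling: trimming, reverse complements, and subset partitioning.

The preprocessor prepares a single-end FASTA/FASTQ read set for all-vs-all
overlap alignment.  Each read is optionally trimmed at fixed 5'/3' lengths
(adapter/tag removal), then quality-trimmed at the 3' end with a sliding
window, and finally its reverse complement is generated so that overlaps
between reads sampled from opposite strands can be found by direct
(same-orientation) comparison.  Reads that fall below a minimum length after
trimming are discarded together with their partners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: suffix appended to the id of a generated reverse-complement record so the
#: original/revcomp pairing is recoverable from any output file
REVCOMP_SUFFIX = "/rc"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class Read:
    """A (possibly trimmed) sequencing read.

    qual, when present, is a list of Phred quality scores of the same length
    as seq.  is_revcomp marks records generated by :func:`revcomp`.
    """

    id: str
    seq: str
    qual: tuple[int, ...] | None = None
    is_revcomp: bool = False

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TrimConfig:
    """Trimming parameters.

    l1/l2 are the fixed 5'/3' trim lengths in bp, w and q the quality-window
    length and minimum average window quality, and min_len the discard
    threshold applied after all trimming.
    """

    l1: int = 0
    l2: int = 0
    w: int = 10
    q: float = 25.0
    min_len: int = 75

    def __post_init__(self) -> None:
        if min(self.l1, self.l2, self.w, self.q, self.min_len) < 0:
            raise ValueError("trim parameters must be non-negative")
        if self.w < 1:
            raise ValueError("quality window length must be >= 1")


def trim_fixed(read: Read, l1: int, l2: int) -> Read:
    """Remove the first l1 and last l2 bases (and qualities) of a read.

    Over-trimming yields an empty read, which is flagged for discard by the
    downstream length filter rather than raising.
    """
    if l1 == 0 and l2 == 0:
        return read
    end = len(read.seq) - l2
    if end <= l1:
        return replace(read, seq="", qual=() if read.qual is not None else None)
    seq = read.seq[l1:end]
    qual = read.qual[l1:end] if read.qual is not None else None
    return replace(read, seq=seq, qual=qual)


def trim_quality(read: Read, w: int, q: float) -> Read:
    """3'-end quality trimming with a sliding window.

    A window of length ``w`` slides from the 3' end towards the 5' end with a
    step of 1 bp.  At the first window whose average quality is strictly
    greater than ``q`` the read is truncated at the window's right endpoint
    (the window itself is kept).  If no window qualifies the read becomes
    empty and is discarded downstream.  Reads without qualities (FASTA input)
    pass through unchanged.
    """
    if read.qual is None:
        return read
    n = len(read.qual)
    if n < w:
        return replace(read, seq="", qual=())
    window_sum = sum(read.qual[n - w:])
    for start in range(n - w, -1, -1):
        if start < n - w:
            window_sum += read.qual[start] - read.qual[start + w]
        if window_sum / w > q:
            end = start + w
            return replace(read, seq=read.seq[:end], qual=read.qual[:end])
    return replace(read, seq="", qual=())


def revcomp(read: Read) -> Read:
    """Reverse complement of a read: seq complemented and reversed, qualities
    reversed, is_revcomp flipped, id suffixed/unsuffixed with ``/rc``."""
    bad = set(read.seq) - set("ACGTN")
    if bad:
        raise ValueError(
            f"read {read.id!r} contains non-IUPAC characters: {sorted(bad)}"
        )
    seq = read.seq.translate(_COMPLEMENT)[::-1]
    qual = read.qual[::-1] if read.qual is not None else None
    if read.is_revcomp:
        new_id = read.id.removesuffix(REVCOMP_SUFFIX)
    else:
        new_id = read.id + REVCOMP_SUFFIX
    return Read(id=new_id, seq=seq, qual=qual, is_revcomp=not read.is_revcomp)


def partition_reads(reads: Sequence[Read], n_subsets: int) -> list[list[Read]]:
    """Deterministically split reads into n_subsets contiguous-by-order
    subsets whose sizes differ by at most one."""
    if n_subsets < 1:
        raise ValueError("n_subsets must be >= 1")
    n = len(reads)
    base, extra = divmod(n, n_subsets)
    subsets: list[list[Read]] = []
    pos = 0
    for i in range(n_subsets):
        size = base + (1 if i < extra else 0)
        subsets.append(list(reads[pos:pos + size]))
        pos += size
    return subsets


@dataclass
class PreprocessStats:
    n_input: int = 0
    n_discarded: int = 0
    n_output: int = 0
    quality_trim_skipped: bool = False


def preprocess_reads(
    reads: Iterable[Read], cfg: TrimConfig | None = None
) -> tuple[list[Read], PreprocessStats]:
    """Apply fixed and quality trimming, discard short reads, and append the
    reverse complement of every retained read.

    Trimming the original read's 5'/3' ends with l1/l2 and then generating
    its reverse complement is equivalent to trimming the corresponding 3'/5'
    ends of the reverse complement, so revcomp(trim(r)) is the processed
    partner record.  The output therefore satisfies orientation closure:
    every retained read has exactly one reverse-complement partner.
    """
    cfg = cfg or TrimConfig()
    stats = PreprocessStats()
    out: list[Read] = []
    warned = False
    for read in reads:
        stats.n_input += 1
        r = trim_fixed(read, cfg.l1, cfg.l2)
        if r.qual is None:
            if not warned:
                logger.info("reads carry no qualities; quality trimming skipped")
                warned = True
                stats.quality_trim_skipped = True
        else:
            r = trim_quality(r, cfg.w, cfg.q)
        if len(r) < cfg.min_len or len(r) == 0:
            stats.n_discarded += 1
            continue
        out.append(r)
        out.append(revcomp(r))
    stats.n_output = len(out)
    return out, stats


# ---------------------------------------------------------------------------
# FASTA/FASTQ IO


def load_reads(path: str | Path) -> list[Read]:
    """Read FASTA or FASTQ (Sanger Phred+33); format detected from the first
    character of the file."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    reads = []
    for rec in SeqIO.parse(str(path), fmt):
        qual = rec.letter_annotations.get("phred_quality")
        reads.append(
            Read(
                id=rec.id,
                seq=str(rec.seq).upper(),
                qual=tuple(qual) if qual is not None else None,
            )
        )
    return reads


def write_reads(reads: Iterable[Read], path: str | Path) -> None:
    """Write reads as FASTQ when qualities are present, FASTA otherwise."""
    reads = list(reads)
    with_qual = all(r.qual is not None for r in reads) and reads
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.seq), id=r.id, description="")
        if with_qual:
            rec.letter_annotations["phred_quality"] = list(r.qual)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq" if with_qual else "fasta")
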