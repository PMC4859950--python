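"""Pairwise read overlap detection by suffix-array seeding and banded alignment.

Each reference read subset is concatenated and indexed by a suffix array.
Query reads are scanned with a window of size ``k`` at a fixed step to
generate seeds, which are located exactly in the reference index.  A seed
fixes a diagonal; the implied overlapping region between the two reads is
aligned with a banded Needleman-Wunsch alignment around that diagonal and an
edge is emitted when the overlap meets the length and identity thresholds.

Edges are recorded once per unordered read pair with a layout offset
(``delta``: position of the second read's start in the first read's
coordinates) so that contig construction can later lay member reads out
without re-alignment.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_preprocess import Read


@dataclass(frozen=True)
class SeedHit:
    """An exact k-mer match between a query read and a reference read."""

    query_id: str
    ref_id: str
    query_pos: int
    ref_pos: int
    k: int


@dataclass(frozen=True)
class OverlapEdge:
    """A scored overlap between two reads.

    ``u`` < ``v`` lexicographically; ``delta`` is the offset of v's first
    base in u's coordinate system (negative when v starts before u), so a
    dovetail with v extending to the right has delta > 0 and a containment
    of v inside u has 0 <= delta <= len(u) - len(v).
    """

    u: str
    v: str
    overlap_len: int
    identity: float
    delta: int


@dataclass(frozen=True)
class AlignConfig:
    k: int = 16
    step: int = 4
    band: int = 10
    min_overlap: int = 40
    min_identity: float = 0.95

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("seed length k must be >= 8")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")


# ---------------------------------------------------------------------------
# Suffix array

# order-preserving digit alphabet for k-mer prefix codes
_DIGIT_OF = {"$": 0, "A": 1, "C": 2, "G": 3, "N": 4, "T": 5}
_DIGIT_TRANS = str.maketrans({c: chr(d) for c, d in _DIGIT_OF.items()})


def _suffix_array(text: str) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), vectorised)."""
    a = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    n = len(a)
    rank = a.astype(np.int64)
    k = 1
    order = np.argsort(rank, kind="stable")
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        changed = (rank[order][1:] != rank[order][:-1]) | (
            key2[order][1:] != key2[order][:-1]
        )
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.concatenate(([0], np.cumsum(changed)))
        rank = new_rank
        if n == 1 or rank[order[-1]] == n - 1:
            return order
        k *= 2


class SuffixArrayIndex:
    """Exact k-mer lookup over a set of reference reads.

    Reads are concatenated with ``$`` separators (no k-mer over {A,C,G,T,N}
    can span a read boundary) and the concatenation is indexed by a suffix
    array; lookup is binary search over the sorted suffixes.
    """

    def __init__(self, ref_reads: Sequence[Read]):
        if not ref_reads:
            raise ValueError("reference read set must be non-empty")
        self.ids = [r.id for r in ref_reads]
        self.starts = np.zeros(len(ref_reads), dtype=np.int64)
        parts = []
        pos = 0
        for i, r in enumerate(ref_reads):
            self.starts[i] = pos
            parts.append(r.seq)
            parts.append("$")
            pos += len(r.seq) + 1
        self.text = "".join(parts)
        self.sa = _suffix_array(self.text)
        self._digits = np.frombuffer(
            self.text.translate(_DIGIT_TRANS).encode("latin1"), dtype=np.uint8
        ).astype(np.int64)
        self._prefix_codes: dict[int, np.ndarray] = {}

    def _codes_for(self, k: int) -> np.ndarray:
        """Base-6 codes of the k-prefix of every suffix, in SA order.

        The digit alphabet preserves character order ($ < A < C < G < N < T),
        so the code sequence is non-decreasing along the suffix array and a
        k-mer lookup reduces to two binary searches on an integer array.
        """
        codes = self._prefix_codes.get(k)
        if codes is None:
            d = self._digits
            n = len(d)
            c = np.zeros(n, dtype=np.int64)
            for j in range(k):
                term = np.zeros(n, dtype=np.int64)
                term[: n - j] = d[j:]
                c += term * (6 ** (k - 1 - j))
            codes = c[self.sa]
            self._prefix_codes = {k: codes}  # keep one k at a time
        return codes

    def _bound(self, kmer: str, upper: bool) -> int:
        lo, hi = 0, len(self.sa)
        text = self.text
        k = len(kmer)
        while lo < hi:
            mid = (lo + hi) // 2
            s = text[self.sa[mid]: self.sa[mid] + k]
            if s < kmer or (upper and s == kmer):
                lo = mid + 1
            else:
                hi = mid
        return lo

    def find(self, kmer: str) -> list[tuple[str, int]]:
        """All (ref_id, offset) occurrences of kmer, position-sorted."""
        k = len(kmer)
        if k <= 24 and not (set(kmer) - set("ACGTN")):
            codes = self._codes_for(k)
            code = 0
            for ch in kmer:
                code = code * 6 + _DIGIT_OF[ch]
            lo = int(np.searchsorted(codes, code, side="left"))
            hi = int(np.searchsorted(codes, code, side="right"))
        else:
            lo = self._bound(kmer, upper=False)
            hi = self._bound(kmer, upper=True)
        if hi <= lo:
            return []
        positions = np.sort(self.sa[lo:hi])
        idx = np.searchsorted(self.starts, positions, side="right") - 1
        return [
            (self.ids[i], int(p - self.starts[i]))
            for i, p in zip(idx, positions)
        ]


def build_suffix_array(ref_reads: Sequence[Read]) -> SuffixArrayIndex:
    return SuffixArrayIndex(ref_reads)


# ---------------------------------------------------------------------------
# Banded Needleman-Wunsch

MATCH, MISMATCH, GAP = 1, -1, -2
_NEG = float("-inf")


def banded_needleman(
    a: str, b: str, band: int | None
) -> tuple[int, int, int]:
    """Global alignment of a vs b restricted to |i - j| <= band.

    Returns (score, matches, columns) for the optimal path; band=None means
    unbanded.  Conventional scores: match +1, mismatch -1, gap -2.
    """
    la, lb = len(a), len(b)
    if band is None:
        band = max(la, lb)
    if abs(la - lb) > band:
        band = abs(la - lb)  # end cell must be reachable
    score = [[_NEG] * (lb + 1) for _ in range(la + 1)]
    score[0][0] = 0.0
    for j in range(1, min(lb, band) + 1):
        score[0][j] = GAP * j
    for i in range(1, la + 1):
        jlo = max(1, i - band)
        jhi = min(lb, i + band)
        if i <= band:
            score[i][0] = GAP * i
        for j in range(jlo, jhi + 1):
            diag = score[i - 1][j - 1] + (
                MATCH if a[i - 1] == b[j - 1] else MISMATCH
            )
            up = score[i - 1][j] + GAP
            left = score[i][j - 1] + GAP
            score[i][j] = max(diag, up, left)
    # traceback to count matches and columns
    i, j = la, lb
    matches = columns = 0
    while i > 0 or j > 0:
        s = score[i][j]
        if (
            i > 0
            and j > 0
            and s
            == score[i - 1][j - 1]
            + (MATCH if a[i - 1] == b[j - 1] else MISMATCH)
        ):
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and s == score[i - 1][j] + GAP:
            i -= 1
        else:
            j -= 1
        columns += 1
    return int(score[la][lb]), matches, columns


# ---------------------------------------------------------------------------
# Overlap detection


def find_overlap(
    query: Read, ref: Read, seed: SeedHit, cfg: AlignConfig
) -> OverlapEdge | None:
    """Extend a seed into a dovetail/containment overlap edge, or None.

    The seed fixes the diagonal d = query_pos - ref_pos, i.e. the position of
    the reference read's start in query coordinates.  The implied overlapping
    region is aligned (exact comparison first, banded Needleman-Wunsch on
    mismatch) and the edge is returned iff overlap length and identity meet
    the configured thresholds.
    """
    d = seed.query_pos - seed.ref_pos
    if d >= 0:
        length = min(len(query.seq) - d, len(ref.seq))
        qsub = query.seq[d: d + length]
        rsub = ref.seq[:length]
    else:
        length = min(len(query.seq), len(ref.seq) + d)
        qsub = query.seq[:length]
        rsub = ref.seq[-d: -d + length]
    if length < cfg.min_overlap:
        return None
    if qsub == rsub:
        overlap_len, identity = length, 1.0
    else:
        # substitution-only fast path: when the gapless (Hamming) identity
        # already meets the threshold, the banded DP cannot do better than
        # the diagonal (each gap pair costs more than two mismatches)
        ham = sum(a == b for a, b in zip(qsub, rsub))
        if ham / length >= cfg.min_identity:
            overlap_len, identity = length, ham / length
        else:
            _, matches, columns = banded_needleman(qsub, rsub, cfg.band)
            overlap_len, identity = columns, matches / columns
    if overlap_len < cfg.min_overlap or identity < cfg.min_identity:
        return None
    if query.id <= ref.id:
        u, v, delta = query.id, ref.id, d
    else:
        u, v, delta = ref.id, query.id, -d
    return OverlapEdge(u=u, v=v, overlap_len=overlap_len,
                       identity=identity, delta=delta)


def _seed_kmers(read: Read, cfg: AlignConfig) -> Iterable[tuple[int, str]]:
    seq = read.seq
    for pos in range(0, len(seq) - cfg.k + 1, cfg.step):
        yield pos, seq[pos: pos + cfg.k]


def all_vs_all_overlaps(
    subsets: Sequence[Sequence[Read]], cfg: AlignConfig | None = None
) -> list[OverlapEdge]:
    """Scan every subset pair (including each subset against itself)
    query-vs-reference and return the deduplicated sorted edge list.

    Each unordered read pair is aligned at most once per seed diagonal
    (repeated k-mers inside a read pair can suggest several diagonals; each
    is tried until one yields an accepted overlap), with the
    lexicographically smaller read id in the query role; the result is
    therefore independent of the number of subsets and of pair processing
    order.
    """
    cfg = cfg or AlignConfig()
    by_id = {r.id: r for subset in subsets for r in subset}
    done: set[tuple[str, str]] = set()
    tried: dict[tuple[str, str], set[int]] = {}
    edges: list[OverlapEdge] = []
    n = len(subsets)
    for j in range(n):
        if not subsets[j]:
            continue
        index = SuffixArrayIndex(subsets[j])
        for i in range(j + 1):
            for query in subsets[i]:
                for qpos, kmer in _seed_kmers(query, cfg):
                    for ref_id, rpos in index.find(kmer):
                        if ref_id == query.id:
                            continue
                        pair = (min(query.id, ref_id), max(query.id, ref_id))
                        if pair in done:
                            continue
                        ref = by_id[ref_id]
                        # canonical roles: smaller id is the query
                        if query.id <= ref_id:
                            seed = SeedHit(query.id, ref_id, qpos, rpos, cfg.k)
                        else:
                            seed = SeedHit(ref_id, query.id, rpos, qpos, cfg.k)
                        diag = seed.query_pos - seed.ref_pos
                        seen = tried.setdefault(pair, set())
                        if diag in seen:
                            continue
                        seen.add(diag)
                        if query.id <= ref_id:
                            edge = find_overlap(query, ref, seed, cfg)
                        else:
                            edge = find_overlap(ref, query, seed, cfg)
                        if edge is not None:
                            edges.append(edge)
                            done.add(pair)
    return sort_dedup_edges(edges)


def sort_dedup_edges(edges: Iterable[OverlapEdge]) -> list[OverlapEdge]:
    """Order edges by u ascending then overlap length descending, keeping a
    single edge (the longest overlap) per unordered endpoint pair."""
    best: dict[tuple[str, str], OverlapEdge] = {}
    for e in edges:
        key = (min(e.u, e.v), max(e.u, e.v))
        cur = best.get(key)
        if cur is None or e.overlap_len > cur.overlap_len:
            if e.u != key[0]:  # normalise stored orientation
                e = OverlapEdge(u=key[0], v=key[1], overlap_len=e.overlap_len,
                                identity=e.identity, delta=-e.delta)
            best[key] = e
    return sorted(best.values(), key=lambda e: (e.u, -e.overlap_len, e.v))


# ---------------------------------------------------------------------------
# Edge list IO

EDGE_COLUMNS = ["query_id", "ref_id", "overlap_len", "identity", "delta"]


def write_edges(edges: Iterable[OverlapEdge], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(EDGE_COLUMNS)
        for e in edges:
            writer.writerow(
                [e.u, e.v, e.overlap_len, f"{e.identity:.6g}", e.delta]
            )


def read_edges(path: str | Path) -> list[OverlapEdge]:
    edges = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[:2] != EDGE_COLUMNS[:2]:
            raise ValueError(f"unexpected edge list header: {header}")
        for row in reader:
            edges.append(
                OverlapEdge(
                    u=row[0], v=row[1], overlap_len=int(row[2]),
                    identity=float(row[3]), delta=int(row[4]),
                )
            )
    return edges
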