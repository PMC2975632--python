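"""Read-half seeding: full-length removal, half alignment, match strings.

The built-in seeder replaces an external short-read aligner so the whole
pipeline is self-contained.  It finds every placement of a query with at most
``max_mismatches`` substitutions: candidate positions come from
``max_mismatches + 1`` disjoint exact k-mer anchors (pigeonhole: at least one
anchor is error-free), each candidate is then verified by a full comparison.
Queries too short for pigeonhole anchoring fall back to a brute-force scan,
so the placement set is complete under the mismatch policy either way.

Orientation is normalised so that, for downstream decoding, the aligned half
always comes *first* and the candidate spliced piece extends toward
increasing index: second-half and minus-strand placements are folded onto the
reverse-complement view of the genome.  All four half/strand cases thereby
reduce to one decoding problem.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._seq import encode_read, revcomp_codes
from .hmm import DEFAULT_BIN_EDGES, MatchString, bin_quality
from .io import Genome, Read

DEFAULT_REPEAT_THRESHOLD = 50
DEFAULT_MAX_MISMATCHES = 2
DEFAULT_INDEX_K = 7

_VERIFY_CHUNK = 8192


@dataclass
class HalfAlignment:
    """Placement of one read half on the genome.

    ``start`` is the 0-based forward-genome coordinate of the placed half
    (SAM-style: for minus-strand placements it is where the reverse
    complement of the half matches the forward genome).
    """

    read_id: str
    half: int  # 1 = first half of the read, 2 = second half
    chrom: str
    start: int
    strand: str
    repeat_count: int = 1


@dataclass
class Frame:
    """Orientation-normalised placement of the whole read.

    ``view`` selects the genome strand view ('+' forward, '-' reverse
    complement); ``q`` is the view coordinate of the first read base;
    ``oriented_seq``/``oriented_qual`` are the read (codes/Phreds) in view
    orientation, with the aligned half as the prefix of ``anchor_len`` bases.
    """

    read_id: str
    chrom: str
    view: str
    q: int
    oriented_seq: np.ndarray
    oriented_qual: np.ndarray
    anchor_len: int
    clen: int


class SeedIndex:
    """Exact k-mer index of the forward strand of every chromosome."""

    def __init__(self, genome: Genome, k: int = DEFAULT_INDEX_K):
        if k < 1:
            raise ValueError("k must be positive")
        self.k = k
        self.genome = genome
        self._idx: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in genome.chroms:
            arr = genome.forward(chrom)
            n = arr.size
            if n < k:
                empty = np.empty(0, dtype=np.int64)
                self._idx[chrom] = (empty, empty)
                continue
            a = np.where(arr >= 4, 0, arr).astype(np.int64)
            codes = np.zeros(n - k + 1, dtype=np.int64)
            for j in range(k):
                codes = codes * 4 + a[j : j + n - k + 1]
            bad = np.concatenate([[0], np.cumsum((arr >= 4).astype(np.int64))])
            codes[(bad[k:] - bad[:-k]) > 0] = -1
            order = np.argsort(codes, kind="stable").astype(np.int64)
            self._idx[chrom] = (codes[order], order)

    def lookup(self, chrom: str, code: int) -> np.ndarray:
        sc, pos = self._idx[chrom]
        lo = np.searchsorted(sc, code, side="left")
        hi = np.searchsorted(sc, code, side="right")
        return pos[lo:hi]


def _kmer_code(query: np.ndarray, off: int, k: int) -> int | None:
    w = query[off : off + k]
    if w.size < k or (w >= 4).any():
        return None
    code = 0
    for c in w:
        code = code * 4 + int(c)
    return code


def _count_mismatches(arr: np.ndarray, positions: np.ndarray, query: np.ndarray) -> np.ndarray:
    m = query.size
    out = np.empty(positions.size, dtype=np.int64)
    for i in range(0, positions.size, _VERIFY_CHUNK):
        block = positions[i : i + _VERIFY_CHUNK]
        win = arr[block[:, None] + np.arange(m)]
        out[i : i + _VERIFY_CHUNK] = (win != query).sum(axis=1)
    return out


def find_placements(
    genome: Genome,
    index: SeedIndex | None,
    query: np.ndarray,
    max_mismatches: int,
    first_only: bool = False,
) -> list[tuple[str, int, int]]:
    """All (chrom, pos, mismatches) where ``query`` matches the forward strand."""
    m = query.size
    results: list[tuple[str, int, int]] = []
    n_anchors = max_mismatches + 1
    for chrom in genome.chroms:
        arr = genome.forward(chrom)
        if m > arr.size:
            continue
        if index is not None and m >= n_anchors * index.k:
            step = m // n_anchors
            cands = []
            for i in range(n_anchors):
                off = i * step
                code = _kmer_code(query, off, index.k)
                if code is not None:
                    cands.append(index.lookup(chrom, code) - off)
            if not cands:
                continue
            cand = np.unique(np.concatenate(cands))
            cand = cand[(cand >= 0) & (cand <= arr.size - m)]
        else:
            cand = np.arange(arr.size - m + 1)
        if cand.size == 0:
            continue
        mm = _count_mismatches(arr, cand, query)
        keep = mm <= max_mismatches
        for p, c in zip(cand[keep], mm[keep]):
            results.append((chrom, int(p), int(c)))
            if first_only:
                return results
    return results


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def split_read(read: Read) -> tuple[Read, Read]:
    """Divide a read in half, rounding the first half down for odd lengths."""
    L = len(read)
    if L < 2:
        raise ValueError(f"read {read.id!r} too short to split")
    h = L // 2
    return (
        Read(f"{read.id}/h1", read.seq[:h], read.qual[:h]),
        Read(f"{read.id}/h2", read.seq[h:], read.qual[h:]),
    )


def remove_full_length(
    reads: Iterable[Read],
    genome: Genome,
    index: SeedIndex | None = None,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> tuple[list[Read], list[Read]]:
    """Partition reads into (junction candidates, full-length genomic matches).

    A read is full-length iff it aligns end-to-end somewhere on either strand
    with at most ``max_mismatches`` substitutions; such reads contain no
    junction and are dropped from the splice search.
    """
    if index is None:
        index = SeedIndex(genome)
    junction: list[Read] = []
    full: list[Read] = []
    for read in reads:
        enc = encode_read(read.seq)
        hit = find_placements(genome, index, enc, max_mismatches, first_only=True)
        if not hit:
            hit = find_placements(
                genome, index, revcomp_codes(enc), max_mismatches, first_only=True
            )
        (full if hit else junction).append(read)
    return junction, full


def align_halves(
    reads: Iterable[Read],
    genome: Genome,
    index: SeedIndex | None = None,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    repeat_threshold: int = DEFAULT_REPEAT_THRESHOLD,
) -> list[HalfAlignment]:
    """Align both halves of every read; drop halves seeding too repetitively.

    Every placement with <= ``max_mismatches`` substitutions is emitted unless
    a half has more than ``repeat_threshold`` placements, in which case all of
    its placements are discarded.  Both halves of one read may each produce
    alignments; they are carried through the pipeline independently.
    """
    if index is None:
        index = SeedIndex(genome)
    out: list[HalfAlignment] = []
    for read in reads:
        L = len(read)
        h = L // 2
        for half, seq in ((1, read.seq[:h]), (2, read.seq[h:])):
            enc = encode_read(seq)
            placements: list[tuple[str, int, str]] = []
            for strand, q in (("+", enc), ("-", revcomp_codes(enc))):
                for chrom, pos, _mm in find_placements(genome, index, q, max_mismatches):
                    placements.append((chrom, pos, strand))
            if not placements or len(placements) > repeat_threshold:
                continue
            n = len(placements)
            for chrom, pos, strand in placements:
                out.append(HalfAlignment(read.id, half, chrom, pos, strand, n))
    return out


def whole_read_match_string(
    aln: HalfAlignment,
    read: Read,
    genome: Genome,
    bin_edges: Sequence[int] = DEFAULT_BIN_EDGES,
) -> tuple[MatchString, Frame] | None:
    """Lay the whole read on the genome at a half's placement; emit matches.

    The read is oriented so the aligned half is the prefix (reverse
    complementing for second-half / minus-strand cases).  Returns ``None``
    (placement discarded) when the whole-read window runs off the chromosome.
    """
    L = len(read)
    h1 = L // 2
    h2 = L - h1
    clen = genome.length(aln.chrom)
    if aln.half == 1:
        orseq = encode_read(read.seq)
        orqual = np.asarray(read.qual)
        anchor = h1
        if aln.strand == "+":
            view, q = "+", aln.start
        else:
            view, q = "-", clen - (aln.start + h1)
    else:
        orseq = revcomp_codes(encode_read(read.seq))
        orqual = np.asarray(read.qual)[::-1]
        anchor = h2
        if aln.strand == "+":
            view, q = "-", clen - (aln.start + h2)
        else:
            view, q = "+", aln.start
    if q < 0 or q + L > clen:
        return None
    varr = genome.view(aln.chrom, view)
    flags = varr[q : q + L] == orseq
    ms = MatchString(flags, bin_quality(orqual, bin_edges))
    frame = Frame(read.id, aln.chrom, view, q, orseq, orqual, anchor, clen)
    return ms, frame
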