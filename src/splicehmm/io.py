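"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions: every genomic coordinate inside the package is 0-based
half-open, matching BED.  SAM input (1-based) is converted at the parse
boundary.  FASTQ qualities default to the Phred+33 (Sanger) dialect; the
offset is configurable because older Illumina runs used Phred+64.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

import numpy as np
import pysam
from Bio import SeqIO

from ._seq import encode, revcomp_codes


class MalformedRecordError(ValueError):
    """A record in an input file violates the format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Read:
    """One sequencing read with per-base Phred qualities."""

    id: str
    seq: str
    qual: np.ndarray  # integer Phred scores, same length as seq

    def __post_init__(self) -> None:
        self.qual = np.asarray(self.qual, dtype=np.int64)
        if len(self.seq) != len(self.qual):
            raise MalformedRecordError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


class Genome:
    """Reference sequences with cached integer encodings of both strands."""

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise MalformedRecordError("genome contains no sequences")
        self._seqs: dict[str, str] = {name: s.upper() for name, s in sequences.items()}
        self._fwd: dict[str, np.ndarray] = {}
        self._rev: dict[str, np.ndarray] = {}

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def seq(self, chrom: str) -> str:
        return self._seqs[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self._seqs[chrom][start:end]

    def forward(self, chrom: str) -> np.ndarray:
        if chrom not in self._fwd:
            self._fwd[chrom] = encode(self._seqs[chrom])
        return self._fwd[chrom]

    def reverse(self, chrom: str) -> np.ndarray:
        """Encoded reverse complement; position i is base length-1-i revcomp'd."""
        if chrom not in self._rev:
            self._rev[chrom] = revcomp_codes(self.forward(chrom))
        return self._rev[chrom]

    def view(self, chrom: str, strand: str) -> np.ndarray:
        return self.forward(chrom) if strand == "+" else self.reverse(chrom)


@dataclass
class BedJunction:
    """A unique intron with its two exonic anchor blocks, BED12-ready.

    ``start``/``end`` bound the whole feature (outer edges of the anchors);
    ``intron_start``/``intron_end`` delimit the excised intron, so
    ``block1 = [start, intron_start)`` and ``block2 = [intron_end, end)``.
    """

    chrom: str
    start: int
    end: int
    intron_start: int
    intron_end: int
    score: float
    strand: str = "."
    name: str = "junc"
    read_count: int = 1

    def __post_init__(self) -> None:
        if not (self.start < self.intron_start <= self.intron_end < self.end):
            raise ValueError(f"inconsistent junction blocks: {self}")
        if not (0.0 <= self.score <= 1200.0):
            raise ValueError(f"junction score {self.score} outside [0, 1200]")
        if self.strand not in "+-.":
            raise ValueError(f"bad strand {self.strand!r}")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def _as_handle(source, mode: str = "r"):
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False


def read_fastq(source, quality_offset: int = 33) -> Iterator[Read]:
    """Yield :class:`Read` records from a FASTQ stream in file order.

    Raises :class:`MalformedRecordError` naming the offending record when a
    record is truncated or its quality string length disagrees with its
    sequence length.
    """
    handle, close = _as_handle(source)
    try:
        while True:
            header = handle.readline()
            if not header:
                return
            header = header.rstrip("\n")
            if not header:
                continue
            if not header.startswith("@"):
                raise MalformedRecordError(f"expected '@' header, got {header!r}")
            rid = header[1:].split()[0] if len(header) > 1 else ""
            seq = handle.readline().rstrip("\n")
            plus = handle.readline()
            qual = handle.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise MalformedRecordError(f"record {rid!r}: missing '+' separator")
            if len(qual) != len(seq):
                raise MalformedRecordError(
                    f"record {rid!r}: quality length {len(qual)} != "
                    f"sequence length {len(seq)}"
                )
            quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int64)
            quals -= quality_offset
            if quals.size and quals.min() < 0:
                raise MalformedRecordError(
                    f"record {rid!r}: negative Phred score; wrong quality offset?"
                )
            yield Read(rid, seq.upper(), quals)
    finally:
        if close:
            handle.close()


def write_fastq(reads: Iterable[Read], dest, quality_offset: int = 33) -> None:
    handle, close = _as_handle(dest, "w")
    try:
        for r in reads:
            qual = "".join(chr(int(q) + quality_offset) for q in r.qual)
            handle.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(source) -> Genome:
    """Read a (multi-)FASTA stream into a :class:`Genome` (uppercased)."""
    handle, close = _as_handle(source)
    try:
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seqs:
                raise MalformedRecordError(f"duplicate sequence name {rec.id!r}")
            seqs[rec.id] = str(rec.seq)
        if not seqs:
            raise MalformedRecordError("empty FASTA input")
        return Genome(seqs)
    finally:
        if close:
            handle.close()


def write_fasta(genome: Genome, dest, width: int = 70) -> None:
    handle, close = _as_handle(dest, "w")
    try:
        for chrom in genome.chroms:
            handle.write(f">{chrom}\n")
            s = genome.seq(chrom)
            for i in range(0, len(s), width):
                handle.write(s[i : i + width] + "\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# SAM adapter for externally computed read-half alignments
# ---------------------------------------------------------------------------

def parse_sam_half_alignments(source, reads: Mapping[str, Read]):
    """Convert SAM records of aligned read halves into HalfAlignments.

    Query names must follow the documented convention ``<read_id>/h1`` (first
    half) or ``<read_id>/h2`` (second half).  Unmapped records are skipped;
    reverse-strand placements carry strand ``-``.  Positions are converted
    from SAM 1-based to the package's 0-based convention by pysam.
    """
    from .seeding import HalfAlignment  # local import to avoid a cycle

    if isinstance(source, _io.IOBase):
        raise TypeError("parse_sam_half_alignments requires a file path")
    out: list[HalfAlignment] = []
    with pysam.AlignmentFile(str(source), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            qname = rec.query_name or ""
            if "/" not in qname or qname.rsplit("/", 1)[1] not in ("h1", "h2"):
                raise MalformedRecordError(
                    f"SAM query name {qname!r} does not follow the "
                    "'<read_id>/h1|h2' convention"
                )
            rid, label = qname.rsplit("/", 1)
            if rid not in reads:
                raise MalformedRecordError(f"SAM query {qname!r}: unknown read id")
            out.append(
                HalfAlignment(
                    read_id=rid,
                    half=1 if label == "h1" else 2,
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    repeat_count=1,
                )
            )
    # repeat counts are per (read, half) across all placements
    counts: dict[tuple[str, int], int] = {}
    for aln in out:
        key = (aln.read_id, aln.half)
        counts[key] = counts.get(key, 0) + 1
    for aln in out:
        aln.repeat_count = counts[(aln.read_id, aln.half)]
    return out


# ---------------------------------------------------------------------------
# BED12
# ---------------------------------------------------------------------------

def write_bed(junctions: Iterable[BedJunction], dest, track_name: str | None = None) -> None:
    """Write junctions as BED12, deterministically sorted by intron position.

    Scores are written as computed, on the 0-1200 scale; values outside that
    range raise ``ValueError`` (enforced by :class:`BedJunction`).
    """
    js = sorted(junctions, key=lambda j: (j.chrom, j.intron_start, j.intron_end))
    handle, close = _as_handle(dest, "w")
    try:
        if track_name:
            handle.write(f'track name="{track_name}" useScore=1\n')
        for j in js:
            b1 = j.intron_start - j.start
            b2 = j.end - j.intron_end
            name = f"{j.name}|reads={j.read_count}"
            handle.write(
                "\t".join(
                    [
                        j.chrom,
                        str(j.start),
                        str(j.end),
                        name,
                        str(float(j.score)),
                        j.strand,
                        str(j.start),
                        str(j.end),
                        "0",
                        "2",
                        f"{b1},{b2}",
                        f"0,{j.intron_end - j.start}",
                    ]
                )
                + "\n"
            )
    finally:
        if close:
            handle.close()


def read_bed(source) -> list[BedJunction]:
    """Parse BED12 junction lines back into :class:`BedJunction` records.

    Also accepts plain BED3/BED6 intron intervals (no blocks), in which case
    the interval itself is taken as the intron with 1 bp dummy anchors --
    convenient for truth tables.
    """
    handle, close = _as_handle(source)
    out: list[BedJunction] = []
    try:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else "junc"
            score = float(f[4]) if len(f) > 4 else 0.0
            strand = f[5] if len(f) > 5 else "."
            count = 1
            if "|reads=" in name:
                name, _, c = name.rpartition("|reads=")
                count = int(c)
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                if len(sizes) != 2 or len(starts) != 2:
                    raise MalformedRecordError(f"expected 2 blocks: {line!r}")
                intron_start = start + starts[0] + sizes[0]
                intron_end = start + starts[1]
            else:
                # bare intron interval
                intron_start, intron_end = start, end
                start, end = start - 1, end + 1
            out.append(
                BedJunction(
                    chrom=chrom,
                    start=start,
                    end=end,
                    intron_start=intron_start,
                    intron_end=intron_end,
                    score=score,
                    strand=strand,
                    name=name,
                    read_count=count,
                )
            )
        return out
    finally:
        if close:
            handle.close()
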