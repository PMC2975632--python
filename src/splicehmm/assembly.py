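"""Second-piece placement and splice-site handling.

Once decoding fixes the split point inside a read, the remaining ("second")
piece is located downstream within the maximum intron distance: its initial
``anchor_size`` bases are matched exactly, with a fallback anchor at
positions ``anchor_size+1 .. 2*anchor_size`` to tolerate sequencing errors in
the first anchor.  The full piece is then compared at every anchor hit and
the unique minimum-mismatch placement wins.  Finally both intron edges can be
shifted by the same small offset to land on a canonical donor-acceptor pair
(GT-AG, GC-AG, AT-AC by default, in order of biological frequency), which
resolves the ambiguity created by sequence repeats across the splice
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import encode, revcomp
from .io import Genome
from .seeding import Frame

DEFAULT_MAX_SHIFT = 5
DEFAULT_ANCHOR_SIZE = 8
DEFAULT_MIN_SECOND = 8


@dataclass(frozen=True)
class SpliceSiteRule:
    """Ordered donor-acceptor pairs for adjustment; a subset is 'canonical'."""

    pairs: tuple[tuple[str, str], ...] = (("GT", "AG"), ("GC", "AG"), ("AT", "AC"))
    canonical: tuple[str, ...] = ("GT-AG", "GC-AG")

    def is_canonical(self, site: str) -> bool:
        return site in self.canonical


DEFAULT_RULE = SpliceSiteRule()


@dataclass
class JunctionCandidate:
    """One read's putative junction in its orientation-normalised frame.

    The layout is strand-normalised: the first (seeded) piece occupies view
    coordinates ``[q, q+split)``, the intron ``[q+split, s2)`` and the second
    piece ``[s2, s2 + L - split)``.  Forward-genome coordinates are derived
    properties.  ``status`` is one of placed / ambiguous_second /
    short_second / unplaced / rescued.
    """

    read_id: str
    chrom: str
    view: str
    q: int
    split: int
    s2: int | None
    oriented_seq: np.ndarray
    oriented_qual: np.ndarray
    clen: int
    status: str = "placed"
    second_mismatches: int = 0
    tied_split: bool = False
    adjust_shift: int = 0
    rescued: bool = False
    # filled by scoring / classification
    score: float = float("nan")
    sides: "object" = None
    site: str = ""
    canonical: bool = False
    strand: str = "."
    p1_flags: np.ndarray | None = field(default=None, repr=False)
    p2_flags: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def from_frame(cls, frame: Frame, split: int, s2: int | None, **kw) -> "JunctionCandidate":
        return cls(
            read_id=frame.read_id,
            chrom=frame.chrom,
            view=frame.view,
            q=frame.q,
            split=split,
            s2=s2,
            oriented_seq=frame.oriented_seq,
            oriented_qual=frame.oriented_qual,
            clen=frame.clen,
            **kw,
        )

    @property
    def length(self) -> int:
        return self.oriented_seq.size

    @property
    def second_len(self) -> int:
        return self.length - self.split

    @property
    def intron_view(self) -> tuple[int, int]:
        return self.q + self.split, self.s2

    @property
    def intron_fwd(self) -> tuple[int, int]:
        a, b = self.intron_view
        if self.view == "+":
            return a, b
        return self.clen - b, self.clen - a

    @property
    def key(self) -> tuple[str, int, int]:
        fs, fe = self.intron_fwd
        return self.chrom, fs, fe

    # left/right are in forward-genome orientation
    @property
    def left_len(self) -> int:
        return self.split if self.view == "+" else self.second_len

    @property
    def right_len(self) -> int:
        return self.second_len if self.view == "+" else self.split

    @property
    def left_matched(self) -> int:
        f = self.p1_flags if self.view == "+" else self.p2_flags
        return int(f.sum())

    @property
    def right_matched(self) -> int:
        f = self.p2_flags if self.view == "+" else self.p1_flags
        return int(f.sum())

    def refresh(self, genome: Genome) -> None:
        """(Re)compute per-piece match flags after placement or adjustment."""
        varr = genome.view(self.chrom, self.view)
        k = self.split
        self.p1_flags = varr[self.q : self.q + k] == self.oriented_seq[:k]
        if self.s2 is not None:
            self.p2_flags = (
                varr[self.s2 : self.s2 + self.second_len] == self.oriented_seq[k:]
            )
            self.second_mismatches = int(self.second_len - self.p2_flags.sum())


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _exact_hits(region: np.ndarray, pattern: np.ndarray) -> np.ndarray:
    n = region.size - pattern.size + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j, c in enumerate(pattern):
        ok &= region[j : j + n] == c
    return np.flatnonzero(ok).astype(np.int64)


def find_anchor_hits(
    second_piece: np.ndarray,
    view_arr: np.ndarray,
    search_start: int,
    min_intron: int,
    max_intron: int,
    anchor_size: int = DEFAULT_ANCHOR_SIZE,
) -> np.ndarray:
    """Candidate view positions for the second piece within the intron window.

    The window for the second-piece start is
    ``[search_start + min_intron, search_start + max_intron]`` (truncated at
    the chromosome end).  Hits are the union of exact matches of the primary
    anchor (bases 1..a) and of the fallback anchor (bases a+1..2a, shifted
    back by a), sorted and deduplicated.
    """
    m = second_piece.size
    a = anchor_size
    lo = search_start + min_intron
    hi = min(search_start + max_intron, view_arr.size - m)
    if hi < lo or m < a:
        return np.empty(0, dtype=np.int64)
    hits: list[np.ndarray] = []
    region = view_arr[lo : hi + m]
    hits.append(lo + _exact_hits(region[: hi - lo + a], second_piece[:a]))
    if m >= 2 * a:
        # fallback anchor: exact match of bases a..2a, candidate start = hit - a
        h2 = lo + _exact_hits(region, second_piece[a : 2 * a]) - a
        hits.append(h2[(h2 >= lo) & (h2 <= hi)])
    allhits = np.unique(np.concatenate(hits))
    return allhits


@dataclass
class SecondMatch:
    status: str  # "placed" | "ambiguous" | "none"
    position: int | None = None
    mismatches: int | None = None
    tied_positions: tuple[int, ...] = ()


def best_second_match(
    second_piece: np.ndarray, hits: np.ndarray, view_arr: np.ndarray
) -> SecondMatch:
    """Compare the full second piece at every anchor hit; fewest mismatches wins.

    A tied minimum yields ``ambiguous`` (eligible for rescue); no hits yields
    ``none``.
    """
    if hits.size == 0:
        return SecondMatch("none")
    m = second_piece.size
    win = view_arr[hits[:, None] + np.arange(m)]
    mm = (win != second_piece).sum(axis=1)
    best = mm.min()
    where = hits[mm == best]
    if where.size > 1:
        return SecondMatch("ambiguous", tied_positions=tuple(int(p) for p in where))
    return SecondMatch("placed", int(where[0]), int(best))


def _shift_order(max_shift: int):
    yield 0
    for d in range(1, max_shift + 1):
        yield d
        yield -d


def adjust_to_canonical(
    cand: JunctionCandidate,
    genome: Genome,
    rule: SpliceSiteRule = DEFAULT_RULE,
    max_shift: int = DEFAULT_MAX_SHIFT,
) -> JunctionCandidate:
    """Shift both intron edges by the same offset to reach a canonical site.

    Pairs are tried in rule order; shifts in order 0, +1, -1, ... +d before
    -d at equal magnitude.  A shift is only applied if the read bases it
    reassigns still match the genome on the side they join (no new
    mismatches), and each pair is accepted in either orientation (e.g. GT..AG
    forward or CT..AC, its reverse complement).  Junctions already canonical
    or with no qualifying shift are returned unchanged.
    """
    if cand.s2 is None:
        return cand
    varr = genome.view(cand.chrom, cand.view)
    orseq = cand.oriented_seq
    L = cand.length
    k0, s20 = cand.split, cand.s2
    for donor, acceptor in rule.pairs:
        d_enc = encode(donor)
        a_enc = encode(acceptor)
        rd_enc = encode(revcomp(donor))
        ra_enc = encode(revcomp(acceptor))
        for d in _shift_order(max_shift):
            k = k0 + d
            s2 = s20 + d
            if not (1 <= k <= L - 1):
                continue
            i_start, i_end = cand.q + k, s2
            if i_start < 0 or i_end + (L - k) > varr.size or i_end - i_start < 4:
                continue
            if d > 0:
                moved = orseq[k0:k]
                if not np.array_equal(varr[cand.q + k0 : cand.q + k], moved):
                    continue
            elif d < 0:
                moved = orseq[k:k0]
                if not np.array_equal(varr[s2 : s20], moved):
                    continue
            first2 = varr[i_start : i_start + 2]
            last2 = varr[i_end - 2 : i_end]
            fwd_ok = np.array_equal(first2, d_enc) and np.array_equal(last2, a_enc)
            rev_ok = np.array_equal(first2, ra_enc) and np.array_equal(last2, rd_enc)
            if fwd_ok or rev_ok:
                cand.split = k
                cand.s2 = s2
                cand.adjust_shift = d
                cand.refresh(genome)
                return cand
    return cand


def classify_splice_sites(
    chrom_or_cand,
    genome: Genome,
    rule: SpliceSiteRule = DEFAULT_RULE,
    intron: tuple[int, int] | None = None,
) -> tuple[str, bool, str]:
    """Classify intron edges: (site string, canonical flag, inferred strand).

    The site string is reported on the inferred strand: forward matches of a
    rule pair give '+', reverse-complement matches give '-', anything else is
    reported verbatim with strand '.'.
    """
    if isinstance(chrom_or_cand, JunctionCandidate):
        chrom = chrom_or_cand.chrom
        fs, fe = chrom_or_cand.intron_fwd
    else:
        chrom = chrom_or_cand
        fs, fe = intron
    seq = genome.seq(chrom)
    first2 = seq[fs : fs + 2]
    last2 = seq[fe - 2 : fe]
    for donor, acceptor in rule.pairs:
        site = f"{donor}-{acceptor}"
        if first2 == donor and last2 == acceptor:
            return site, rule.is_canonical(site), "+"
        if first2 == revcomp(acceptor) and last2 == revcomp(donor):
            return site, rule.is_canonical(site), "-"
    return f"{first2}-{last2}", False, "."
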