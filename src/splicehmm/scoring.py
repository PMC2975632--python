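"""Information-based junction scoring, duplicate resolution, rescue, collapse.

Each side of a junction read carries up to 2 bits per aligned base
(log2 of the four possible nucleotides), discounted by the probability that
the base call is correct given its Phred quality; mismatching positions carry
nothing.  The two side scores are multiplied, which strongly favours evenly
split reads, then corrected for resemblance to a full-length genomic
alignment and normalised to the 0-1200 range used in BED output.

Reads supporting the same intron are collapsed into one junction whose score
grows with *newly covered* bases only, so PCR duplicates add no support.
Junctions covered by a single read face a higher score threshold than
junctions covered by several.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .assembly import JunctionCandidate, SpliceSiteRule, DEFAULT_RULE, classify_splice_sites
from .io import BedJunction, Genome


@dataclass(frozen=True)
class ScoreParams:
    """Knobs of the scoring and filtering stages (defaults as documented)."""

    w: float = 2.0          # information per certain matching base (bits)
    F: float = 0.5          # weight of the full-length-resemblance correction
    ceiling: float = 1200.0
    duplicate_delta: float = 20.0
    threshold_single: float = 600.0
    threshold_multi: float = 400.0

    def __post_init__(self):
        if not 0.0 <= self.F <= 1.0:
            raise ValueError("F must be in [0, 1]")
        if self.threshold_single < 0 or self.threshold_multi < 0:
            raise ValueError("thresholds must be non-negative")


DEFAULT_SCORE_PARAMS = ScoreParams()


@dataclass
class SideScores:
    """Eq.-style side scores: h_a/h_b per side, primed = rescored adjacent."""

    h_a: float
    h_b: float
    h_a_prime: float
    h_b_prime: float


@dataclass
class CollapsedJunction:
    """A unique intron with aggregated read support."""

    chrom: str
    intron_start: int
    intron_end: int
    strand: str
    site: str
    canonical: bool
    score: float
    read_count: int
    max_left_matched: int
    max_right_matched: int
    max_left_len: int
    max_right_len: int
    read_ids: list[str] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, int]:
        return self.chrom, self.intron_start, self.intron_end

    def to_bed(self, name: str = "junc", ceiling: float = 1200.0) -> BedJunction:
        return BedJunction(
            chrom=self.chrom,
            start=self.intron_start - self.max_left_len,
            end=self.intron_end + self.max_right_len,
            intron_start=self.intron_start,
            intron_end=self.intron_end,
            score=min(self.score, ceiling),
            strand=self.strand,
            name=name,
            read_count=self.read_count,
        )


# ---------------------------------------------------------------------------
# per-read scoring
# ---------------------------------------------------------------------------

def p_correct(q):
    """Probability a base call is correct given its Phred score: 1 - 10^(-q/10)."""
    return 1.0 - 10.0 ** (-np.asarray(q, dtype=float) / 10.0)


def side_score(match_flags, p_corr, w: float = 2.0) -> float:
    """Sum of w * P(correct) over *matching* positions of one read piece."""
    flags = np.asarray(match_flags, dtype=bool)
    p = np.asarray(p_corr, dtype=float)
    return float(w * p[flags].sum())


def side_score_from_quals(match_flags, quals, w: float = 2.0) -> float:
    return side_score(match_flags, p_correct(quals), w)


def raw_junction_score(s: SideScores, F: float = 0.5) -> float:
    """Combine side scores and subtract the full-length-resemblance correction.

    score = h_a*h_b - F * max(h_a*h_b', h_a'*h_b), floored at zero: of the two
    hypothetical ungapped placements (right side pulled left-adjacent, or left
    side pulled right-adjacent) the better one is scored and F times it is
    subtracted.
    """
    raw = s.h_a * s.h_b - F * max(s.h_a * s.h_b_prime, s.h_a_prime * s.h_b)
    return max(raw, 0.0)


def normalize_score(raw: float, read_length: int, w: float = 2.0, ceiling: float = 1200.0) -> float:
    """Scale by 1200 over the theoretical maximum for this read length.

    The maximum side product is (w*L/2)^2 for even L and
    (w*floor(L/2)) * (w*ceil(L/2)) for odd L; results are capped at the
    ceiling.
    """
    if raw < 0:
        raise ValueError("raw score must be non-negative")
    half = read_length // 2
    mx = (w * half) * (w * (read_length - half))
    return min(raw * ceiling / mx, ceiling)


def compute_side_scores(cand: JunctionCandidate, genome: Genome, params: ScoreParams) -> SideScores:
    """Side scores for a placed candidate, including the primed rescorings.

    h_a is the seeded first piece at its placement, h_b the second piece at
    its match; h_b' rescores the second piece immediately adjacent to the
    first (the positions it would occupy in a full-length alignment) and h_a'
    rescores the first piece immediately left-adjacent to the second.  A
    hypothetical placement falling off the chromosome scores zero.
    """
    varr = genome.view(cand.chrom, cand.view)
    k = cand.split
    L = cand.length
    pc = p_correct(cand.oriented_qual)
    h_a = side_score(cand.p1_flags, pc[:k], params.w)
    h_b = side_score(cand.p2_flags, pc[k:], params.w)
    if cand.q + L <= varr.size:
        fl2 = varr[cand.q + k : cand.q + L] == cand.oriented_seq[k:]
        h_bp = side_score(fl2, pc[k:], params.w)
    else:
        h_bp = 0.0
    if cand.s2 - k >= 0:
        fl1 = varr[cand.s2 - k : cand.s2] == cand.oriented_seq[:k]
        h_ap = side_score(fl1, pc[:k], params.w)
    else:
        h_ap = 0.0
    return SideScores(h_a, h_b, h_ap, h_bp)


def score_candidate(
    cand: JunctionCandidate, genome: Genome, params: ScoreParams = DEFAULT_SCORE_PARAMS
) -> JunctionCandidate:
    if cand.p1_flags is None or cand.p2_flags is None:
        cand.refresh(genome)
    cand.sides = compute_side_scores(cand, genome, params)
    raw = raw_junction_score(cand.sides, params.F)
    cand.score = normalize_score(raw, cand.length, params.w, params.ceiling)
    return cand


# ---------------------------------------------------------------------------
# duplicate resolution, rescue, collapse, filtering
# ---------------------------------------------------------------------------

def resolve_read_duplicates(
    candidates: Sequence[JunctionCandidate], delta: float = 20.0
) -> tuple[list[JunctionCandidate], list[JunctionCandidate]]:
    """Resolve the multiple scored placements of a single read.

    Candidates converging on the identical intron are first merged (one copy,
    the best-scoring, survives).  If the best remaining candidate outscores
    the runner-up by at least ``delta`` it is kept; otherwise all are routed
    to the duplicates output set.
    """
    by_key: dict[tuple, JunctionCandidate] = {}
    for c in candidates:
        prev = by_key.get(c.key)
        if prev is None or c.score > prev.score:
            by_key[c.key] = c
    uniq = sorted(by_key.values(), key=lambda c: -c.score)
    if len(uniq) <= 1:
        return uniq, []
    if uniq[0].score - uniq[1].score >= delta:
        return [uniq[0]], []
    return [], uniq


def rescue(
    set_aside: Sequence[JunctionCandidate],
    accepted: Iterable[tuple[str, int, int]],
    genome: Genome,
) -> list[JunctionCandidate]:
    """Assign set-aside reads to accepted junctions sharing their fixed edge.

    A set-aside read (second piece too short, or ambiguously placed) has a
    known splice edge from its seeded half.  If exactly one accepted junction
    shares that edge and the read's entire second piece matches the acceptor
    exon sequence with zero mismatches, the read is assigned there and adds
    support; otherwise it stays unassigned.
    """
    by_start: dict[tuple[str, int], list[tuple[str, int, int]]] = {}
    by_end: dict[tuple[str, int], list[tuple[str, int, int]]] = {}
    for j in accepted:
        chrom, fs, fe = j
        by_start.setdefault((chrom, fs), []).append(j)
        by_end.setdefault((chrom, fe), []).append(j)
    out: list[JunctionCandidate] = []
    for c in set_aside:
        tail = c.oriented_seq[c.split :]
        if tail.size == 0:
            continue
        varr = genome.view(c.chrom, c.view)
        if c.view == "+":
            edge = c.q + c.split
            pool = by_start.get((c.chrom, edge), [])
            targets = [(j, j[2]) for j in pool]  # second piece starts at intron end
        else:
            edge = c.clen - (c.q + c.split)
            pool = by_end.get((c.chrom, edge), [])
            targets = [(j, c.clen - j[1]) for j in pool]  # view- coord of acceptor
        matches = []
        for j, s2 in targets:
            if s2 + tail.size <= varr.size and np.array_equal(
                varr[s2 : s2 + tail.size], tail
            ):
                matches.append((j, s2))
        if len(matches) != 1:
            continue
        _, s2 = matches[0]
        c.s2 = s2
        c.status = "rescued"
        c.rescued = True
        c.refresh(genome)
        out.append(c)
    return out


def collapse(candidates: Sequence[JunctionCandidate]) -> CollapsedJunction:
    """Merge all reads supporting one identical intron into a single junction.

    Candidates are processed in descending score order.  The top candidate
    sets the starting score and coverage extents; each further candidate
    contributes ``score * (newly covered bases / total covered bases)`` where
    coverage is counted as matched bases beyond the running per-side maxima.
    Identical reads therefore add nothing; complementary splits add a lot.
    """
    if not candidates:
        raise ValueError("collapse of empty candidate set")
    key = candidates[0].key
    for c in candidates:
        if c.key != key:
            raise ValueError("collapse requires candidates of one intron")
    order = sorted(
        candidates,
        key=lambda c: (-c.score, -(c.left_matched + c.right_matched), c.read_id),
    )
    top = order[0]
    score = top.score
    max_l, max_r = top.left_matched, top.right_matched
    max_ll, max_rl = top.left_len, top.right_len
    for c in order[1:]:
        l, r = c.left_matched, c.right_matched
        new = max(0, l - max_l) + max(0, r - max_r)
        max_l, max_r = max(max_l, l), max(max_r, r)
        max_ll, max_rl = max(max_ll, c.left_len), max(max_rl, c.right_len)
        total = max_l + max_r
        if new > 0 and total > 0:
            score += c.score * new / total
    chrom, fs, fe = key
    return CollapsedJunction(
        chrom=chrom,
        intron_start=fs,
        intron_end=fe,
        strand=top.strand,
        site=top.site,
        canonical=top.canonical,
        score=score,
        read_count=len(order),
        max_left_matched=max_l,
        max_right_matched=max_r,
        max_left_len=max_ll,
        max_right_len=max_rl,
        read_ids=[c.read_id for c in order],
    )


def collapse_all(
    candidates: Iterable[JunctionCandidate],
    genome: Genome | None = None,
    rule: SpliceSiteRule = DEFAULT_RULE,
) -> list[CollapsedJunction]:
    """Group candidates by intron, collapse each group, classify edges."""
    groups: dict[tuple, list[JunctionCandidate]] = {}
    for c in candidates:
        groups.setdefault(c.key, []).append(c)
    out = []
    for key in sorted(groups):
        cj = collapse(groups[key])
        if genome is not None:
            cj.site, cj.canonical, cj.strand = classify_splice_sites(
                cj.chrom, genome, rule, intron=(cj.intron_start, cj.intron_end)
            )
        out.append(cj)
    return out


def filter_junctions(
    collapsed: Iterable[CollapsedJunction],
    params: ScoreParams = DEFAULT_SCORE_PARAMS,
) -> tuple[list[CollapsedJunction], list[CollapsedJunction]]:
    """Apply the coverage-dependent score thresholds and split by site class.

    A junction is retained iff its score reaches the single-read threshold
    (one supporting read) or the multi-read threshold (several).  Retained
    junctions are partitioned into (canonical, non-canonical) output sets.
    """
    canonical: list[CollapsedJunction] = []
    noncanonical: list[CollapsedJunction] = []
    for j in collapsed:
        cut = params.threshold_single if j.read_count == 1 else params.threshold_multi
        if j.score >= cut:
            (canonical if j.canonical else noncanonical).append(j)
    return canonical, noncanonical
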