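"""Synthetic genomes, spliced transcripts, reads and evaluation utilities.

The generator emulates a simulation benchmark at desk scale: a random genome
of configurable GC content, non-overlapping multi-exon transcripts whose
intron ends are overwritten with donor/acceptor dinucleotides drawn from a
configurable splice-site mix, and reads sampled uniformly along the spliced
transcripts with quality-dependent substitution errors.  Truth tables of the
planted introns make sensitivity, false-positive rate and score-ROC
measurements exact.

What it does *not* model (deliberately): indels, GC-coverage bias, uneven
coverage within transcripts, paired-end insert sizes, or UTRs (reads start
and end inside exonic sequence, so terminal exons get less junction-spanning
coverage than interior ones -- the same edge effect a UTR-free benchmark
shows).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hmm import MatchString, SpliceHMM
from .io import Genome, Read

_BASES = np.array(list("ACGT"))

#: human splice-site frequencies; keys are donor-acceptor strings
DEFAULT_SITE_MIX: dict[str, float] = {"GT-AG": 0.983, "GC-AG": 0.015, "AT-AC": 0.002}


@dataclass
class TranscriptModel:
    """Ordered exons of one transcript on the forward strand."""

    id: str
    chrom: str
    exons: list[tuple[int, int]]  # 0-based half-open genomic intervals
    strand: str = "+"

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced_seq(self, genome: Genome) -> str:
        return "".join(genome.fetch(self.chrom, s, e) for s, e in self.exons)


@dataclass(frozen=True)
class TruthJunction:
    chrom: str
    intron_start: int
    intron_end: int
    transcript_id: str

    @property
    def key(self) -> tuple[str, int, int]:
        return self.chrom, self.intron_start, self.intron_end


@dataclass
class QualityModel:
    """Parametric Phred profile: linearly decaying mean with a low-quality tail.

    Mean quality declines from ``mean_start`` at the 5' end of the read to
    ``mean_end`` at the 3' end; per-base scores are normal around that mean,
    and a small fraction of bases (failed cycles) drop to a uniformly low
    score so every quality bin is populated, as in real Illumina data.
    Substitution errors are drawn per base at rate 10^(-q/10).
    """

    mean_start: float = 38.0
    mean_end: float = 25.0
    sd: float = 4.0
    low_fraction: float = 0.02
    low_range: tuple[int, int] = (2, 12)
    qmin: int = 2
    qmax: int = 40

    def sample(self, n_reads: int, read_length: int, rng: np.random.Generator) -> np.ndarray:
        mean = np.linspace(self.mean_start, self.mean_end, read_length)
        q = rng.normal(mean, self.sd, size=(n_reads, read_length))
        low = rng.random((n_reads, read_length)) < self.low_fraction
        q[low] = rng.uniform(*self.low_range, size=int(low.sum()))
        return np.clip(np.rint(q), self.qmin, self.qmax).astype(np.int64)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def make_genome(
    length: int, gc: float = 0.5, seed: int | np.random.Generator = 0, chrom: str = "chr1"
) -> Genome:
    """I.i.d. random genome at the requested GC fraction."""
    if length < 10_000:
        raise ValueError("genome length must be at least 10 kb")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(_BASES[rng.choice(4, size=length, p=p)])
    return Genome({chrom: seq})


def _sample_site(mix: dict[str, float], rng: np.random.Generator) -> tuple[str, str]:
    names = list(mix)
    probs = np.array([mix[n] for n in names], dtype=float)
    probs /= probs.sum()
    site = names[rng.choice(len(names), p=probs)]
    donor, acceptor = site.split("-")
    return donor, acceptor


def make_transcripts(
    genome: Genome,
    n: int,
    n_exons: tuple[int, int] = (3, 6),
    exon_length: tuple[int, int] = (80, 250),
    intron_length: tuple[int, int] = (60, 500),
    site_mix: dict[str, float] | None = None,
    intergenic: tuple[int, int] = (200, 1000),
    seed: int | np.random.Generator = 0,
) -> tuple[Genome, list[TranscriptModel], list[TruthJunction]]:
    """Plant ``n`` non-overlapping transcripts; overwrite splice dinucleotides.

    Exon and intron lengths are uniform over the given closed ranges.  The
    donor (first two) and acceptor (last two) bases of every intron are
    overwritten with a pair drawn from ``site_mix``, so the truth table's
    splice-site composition is exact by construction.  Returns the modified
    genome, the transcript models and one truth record per distinct intron.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if site_mix is None:
        site_mix = DEFAULT_SITE_MIX
    chrom = genome.chroms[0]
    seq = list(genome.seq(chrom))
    glen = len(seq)
    transcripts: list[TranscriptModel] = []
    truths: list[TruthJunction] = []
    cursor = int(rng.integers(*intergenic))
    for t in range(n):
        ne = int(rng.integers(n_exons[0], n_exons[1] + 1))
        exons: list[tuple[int, int]] = []
        pos = cursor
        for e in range(ne):
            elen = int(rng.integers(exon_length[0], exon_length[1] + 1))
            exons.append((pos, pos + elen))
            pos += elen
            if e < ne - 1:
                ilen = int(rng.integers(intron_length[0], intron_length[1] + 1))
                pos += ilen
        if pos >= glen:
            raise ValueError(
                f"genome too short: transcript {t} of {n} would end at {pos} > {glen}"
            )
        tm = TranscriptModel(id=f"tx{t}", chrom=chrom, exons=exons)
        for istart, iend in tm.introns:
            donor, acceptor = _sample_site(site_mix, rng)
            seq[istart : istart + 2] = list(donor)
            seq[iend - 2 : iend] = list(acceptor)
            truths.append(TruthJunction(chrom, istart, iend, tm.id))
        transcripts.append(tm)
        cursor = pos + int(rng.integers(*intergenic))
    return Genome({chrom: "".join(seq)}), transcripts, truths


def simulate_reads(
    genome: Genome,
    transcripts: Sequence[TranscriptModel],
    read_length: int = 50,
    coverage: float = 10.0,
    quality: QualityModel | None = None,
    error_free: bool = False,
    seed: int | np.random.Generator = 0,
) -> list[Read]:
    """Sample reads uniformly along spliced transcripts at the given coverage.

    Read orientation is random (unstranded library).  Per-base qualities come
    from the quality model; substitutions are introduced at each base with
    probability 10^(-q/10) unless ``error_free``.  Read ids encode the source
    transcript and spliced-transcript offset for truth tracking.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if quality is None:
        quality = QualityModel()
    reads: list[Read] = []
    comp = str.maketrans("ACGTN", "TGCAN")
    for tm in transcripts:
        tseq = tm.spliced_seq(genome)
        tlen = len(tseq)
        if tlen < read_length:
            continue
        n_reads = int(round(coverage * tlen / read_length))
        if n_reads == 0:
            continue
        starts = rng.integers(0, tlen - read_length + 1, size=n_reads)
        quals = quality.sample(n_reads, read_length, rng)
        flips = rng.random(n_reads) < 0.5
        for i, (s, flip) in enumerate(zip(starts, flips)):
            frag = tseq[s : s + read_length]
            if flip:
                frag = frag.translate(comp)[::-1]
            q = quals[i]
            if not error_free:
                arr = np.frombuffer(frag.encode(), dtype=np.uint8).copy()
                err = rng.random(read_length) < 10.0 ** (-q / 10.0)
                for j in np.flatnonzero(err):
                    choices = [b for b in b"ACGT" if b != arr[j]]
                    arr[j] = choices[rng.integers(3)]
                frag = arr.tobytes().decode()
            rid = f"{tm.id}:{int(s)}:{'r' if flip else 'f'}:{i}"
            reads.append(Read(rid, frag, q))
    return reads


def sample_match_strings(
    hmm: SpliceHMM,
    n: int,
    length: int,
    bin_probs: Sequence[float] | None = None,
    seed: int | np.random.Generator = 0,
) -> list[MatchString]:
    """Draw match strings from the generative splice-HMM (test oracle).

    With probability ``p12`` a string transitions at a split point uniform on
    1..L-1; otherwise it stays in State 1 throughout.  Bins are i.i.d. from
    ``bin_probs`` (defaults weighted toward high quality, as sequencers
    produce).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if bin_probs is None:
        bin_probs = (0.05, 0.10, 0.15, 0.30, 0.40)
    bp = np.asarray(bin_probs, dtype=float)
    bp /= bp.sum()
    B = rng.choice(5, size=(n, length), p=bp).astype(np.int8)
    has_split = rng.random(n) < hmm.p12
    ks = np.where(has_split, rng.integers(1, max(length, 2), size=n), length)
    pos = np.arange(length)
    in_state1 = pos[None, :] < ks[:, None]
    pm = np.where(in_state1, hmm.m1[B], hmm.m2[B])
    M = rng.random((n, length)) < pm
    return [MatchString(M[i], B[i]) for i in range(n)]


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalResult:
    n_truth: int
    n_predicted: int
    true_positives: int
    false_positives: int
    sensitivity: float
    fpr_percent: float  # share of predictions that are false, in percent
    auc: float | None
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)

    def to_tsv(self, dest) -> None:
        rows = [
            ("n_truth", self.n_truth),
            ("n_predicted", self.n_predicted),
            ("true_positives", self.true_positives),
            ("false_positives", self.false_positives),
            ("sensitivity", f"{self.sensitivity:.4f}"),
            ("fpr_percent", f"{self.fpr_percent:.4f}"),
            ("auc", "" if self.auc is None else f"{self.auc:.4f}"),
        ]
        close = False
        if isinstance(dest, str):
            dest = open(dest, "w")
            close = True
        try:
            for k, v in rows:
                dest.write(f"{k}\t{v}\n")
        finally:
            if close:
                dest.close()


def _intron_of(p) -> tuple[str, int, int]:
    if hasattr(p, "intron_start"):
        return p.chrom, p.intron_start, p.intron_end
    return tuple(p[:3])


def _score_of(p) -> float:
    return float(getattr(p, "score", 0.0))


def evaluate_junctions(predicted, truth, tolerance: int = 0) -> EvalResult:
    """Compare predicted introns with the truth table.

    A prediction is true iff a truth intron on the same chromosome matches
    both edges within ``tolerance`` bases.  Sensitivity counts distinct truth
    introns recovered; the false-positive rate is the share of predictions
    that match nothing, as a percentage.  AUC measures how well the score
    ranks true above false predictions (``None`` when only one class exists).
    """
    truth_keys = {(t.key if hasattr(t, "key") else tuple(t[:3])) for t in truth}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in truth_keys:
        by_chrom.setdefault(c, []).append((s, e))
    labels = []
    scores = []
    matched: set = set()
    for p in predicted:
        chrom, s, e = _intron_of(p)
        hit = None
        for ts, te in by_chrom.get(chrom, ()):
            if abs(ts - s) <= tolerance and abs(te - e) <= tolerance:
                hit = (chrom, ts, te)
                break
        labels.append(hit is not None)
        scores.append(_score_of(p))
        if hit is not None:
            matched.add(hit)
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    tp = int(labels.sum())
    fp = int((~labels).sum())
    n_pred = len(labels)
    auc = None
    if 0 < tp < n_pred:
        from sklearn.metrics import roc_auc_score

        auc = float(roc_auc_score(labels, scores))
    return EvalResult(
        n_truth=len(truth_keys),
        n_predicted=n_pred,
        true_positives=tp,
        false_positives=fp,
        sensitivity=len(matched) / len(truth_keys) if truth_keys else float("nan"),
        fpr_percent=100.0 * fp / n_pred if n_pred else 0.0,
        auc=auc,
        scores=scores,
        labels=labels,
    )


def splice_offset_profile(predicted, reference, max_offset: int = 15) -> dict:
    """Profile alternate splice-site usage against reference introns.

    For every prediction whose intron matches a reference intron exactly on
    one side while the other side differs by 1..``max_offset`` bases, the
    signed offset of the differing side is recorded (positive = intron edge
    moved away from the intron, i.e. bases removed from the exon).  The 5'
    side is the lower-coordinate intron edge.  Offsets divisible by three
    preserve the reading frame.
    """
    ref = [(t.key if hasattr(t, "key") else tuple(t[:3])) for t in reference]
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in ref:
        by_chrom.setdefault(c, []).append((s, e))
    five: dict[int, int] = {}
    three: dict[int, int] = {}
    frame_preserving = 0
    frame_shifting = 0
    for p in predicted:
        chrom, s, e = _intron_of(p)
        for ts, te in by_chrom.get(chrom, ()):
            d5 = ts - s  # positive: predicted donor edge extends into the exon
            d3 = e - te
            if d5 == 0 and d3 == 0:
                continue
            if te == e and 0 < abs(d5) <= max_offset:
                five[d5] = five.get(d5, 0) + 1
            elif ts == s and 0 < abs(d3) <= max_offset:
                three[d3] = three.get(d3, 0) + 1
            else:
                continue
            off = d5 if te == e else d3
            if off % 3 == 0:
                frame_preserving += 1
            else:
                frame_shifting += 1
    return {
        "five_prime": five,
        "three_prime": three,
        "frame_preserving": frame_preserving,
        "frame_shifting": frame_shifting,
    }
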