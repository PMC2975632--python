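"""End-to-end junction discovery: orchestration of all five pipeline stages.

Stage order: full-length removal -> half seeding -> HMM training -> split
decoding -> second-piece matching -> canonical-edge adjustment -> scoring ->
per-read duplicate resolution -> rescue -> collapse -> threshold filtering ->
canonical/non-canonical partition.  The run log accounts for every input
read in exactly one terminal category, and identical config + seed yields
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .assembly import (
    JunctionCandidate,
    SpliceSiteRule,
    adjust_to_canonical,
    best_second_match,
    classify_splice_sites,
    find_anchor_hits,
)
from .hmm import (
    DEFAULT_BIN_EDGES,
    MatchString,
    SpliceHMM,
    TrainingInfo,
    decode_split_batch,
    sample_training_set,
    train_baum_welch,
)
from .io import Genome, Read, write_bed
from .scoring import (
    CollapsedJunction,
    ScoreParams,
    collapse_all,
    filter_junctions,
    rescue,
    resolve_read_duplicates,
    score_candidate,
)
from .seeding import (
    Frame,
    HalfAlignment,
    SeedIndex,
    align_halves,
    remove_full_length,
    whole_read_match_string,
)

log = logging.getLogger("splicehmm")


@dataclass
class PipelineConfig:
    """All tunable knobs of the pipeline, with the documented defaults."""

    # seeding
    seed_max_mismatches: int = 2
    repeat_threshold: int = 50
    index_k: int = 7
    # intron geometry / second-piece search
    min_intron: int = 5
    max_intron: int = 80_000
    anchor_size: int = 8
    min_second_piece: int = 8
    max_shift: int = 5
    # HMM
    bin_edges: tuple[int, ...] = DEFAULT_BIN_EDGES
    train_subset_size: int = 10_000
    hmm_max_iter: int = 50
    hmm_tol: float = 1e-4
    init_set: str = "informed"  # "informed" or "uniform"
    # scoring / filtering
    w: float = 2.0
    F: float = 0.5
    score_threshold_single: float = 600.0
    score_threshold_multi: float = 400.0
    duplicate_delta: float = 20.0
    splice_pairs: tuple[tuple[str, str], ...] = (("GT", "AG"), ("GC", "AG"), ("AT", "AC"))
    canonical_sites: tuple[str, ...] = ("GT-AG", "GC-AG")
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_intron >= self.max_intron:
            raise ValueError("min_intron must be < max_intron")
        if self.anchor_size < 4:
            raise ValueError("anchor_size must be >= 4")
        if self.score_threshold_single < self.score_threshold_multi:
            raise ValueError("single-read threshold must be >= multi-read threshold")

    @property
    def rule(self) -> SpliceSiteRule:
        return SpliceSiteRule(self.splice_pairs, self.canonical_sites)

    @property
    def score_params(self) -> ScoreParams:
        return ScoreParams(
            w=self.w,
            F=self.F,
            duplicate_delta=self.duplicate_delta,
            threshold_single=self.score_threshold_single,
            threshold_multi=self.score_threshold_multi,
        )

    def initial_hmm(self) -> SpliceHMM:
        if self.init_set == "uniform":
            return SpliceHMM.initial_uniform(self.bin_edges)
        return SpliceHMM.initial_informed(self.bin_edges)


@dataclass
class PipelineResult:
    canonical: list[CollapsedJunction]
    noncanonical: list[CollapsedJunction]
    duplicates: list[CollapsedJunction]
    collapsed: list[CollapsedJunction]  # all support, pre-filter
    hmm: SpliceHMM
    training: TrainingInfo | None
    stats: dict

    def write(self, outdir, prefix: str = "junctions") -> dict[str, Path]:
        """Write the three BED result sets plus the trained model."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for label, js in (
            ("canonical", self.canonical),
            ("noncanonical", self.noncanonical),
            ("duplicates", self.duplicates),
        ):
            path = outdir / f"{prefix}.{label}.bed"
            beds = [j.to_bed(name=f"jx{i}") for i, j in enumerate(js)]
            write_bed(beds, str(path), track_name=f"splicehmm {label}")
            paths[label] = path
        hmm_path = outdir / f"{prefix}.hmm.txt"
        self.hmm.save(hmm_path)
        paths["hmm"] = hmm_path
        return paths


def run_pipeline(
    reads: Sequence[Read],
    genome: Genome,
    config: PipelineConfig | None = None,
    hmm: SpliceHMM | None = None,
    half_alignments: Sequence[HalfAlignment] | None = None,
) -> PipelineResult:
    """Run junction discovery over a read set.

    ``hmm`` may supply a pre-trained model (skips training); external SAM
    seeding is supported by passing ``half_alignments`` from
    :func:`splicehmm.io.parse_sam_half_alignments`.
    """
    if config is None:
        config = PipelineConfig()
    rng = np.random.default_rng(config.seed)
    rule = config.rule
    params = config.score_params
    stats: dict = {"n_reads": len(reads)}
    read_map = {r.id: r for r in reads}

    index = SeedIndex(genome, config.index_k)
    junction_reads, full_reads = remove_full_length(
        reads, genome, index, config.seed_max_mismatches
    )
    stats["full_length"] = len(full_reads)
    stats["junction_candidates_in"] = len(junction_reads)
    log.info("%d reads full-length, %d enter junction search",
             len(full_reads), len(junction_reads))

    if half_alignments is None:
        hals = align_halves(
            junction_reads, genome, index,
            config.seed_max_mismatches, config.repeat_threshold,
        )
    else:
        keep_ids = {r.id for r in junction_reads}
        hals = [
            a for a in half_alignments
            if a.read_id in keep_ids and a.repeat_count <= config.repeat_threshold
        ]
    stats["half_alignments"] = len(hals)

    msframes: list[tuple[MatchString, Frame]] = []
    n_off = 0
    for aln in hals:
        out = whole_read_match_string(aln, read_map[aln.read_id], genome, config.bin_edges)
        if out is None:
            n_off += 1
            continue
        msframes.append(out)
    stats["off_chromosome"] = n_off

    training = None
    if hmm is None:
        if not msframes:
            hmm = config.initial_hmm()
        else:
            sample = sample_training_set(msframes, config.train_subset_size, rng)
            hmm, training = train_baum_welch(
                [ms for ms, _fr in sample],
                config.initial_hmm(),
                config.hmm_max_iter,
                config.hmm_tol,
            )
            log.info("HMM trained: %d iterations, p12=%.3f", training.n_iter, hmm.p12)
            if training.undertrained_bins:
                log.warning("under-trained quality bins kept at initial values: %s",
                            training.undertrained_bins)

    # decode split points, batched by read length
    by_len: dict[int, list[int]] = {}
    for i, (ms, _fr) in enumerate(msframes):
        by_len.setdefault(len(ms), []).append(i)
    splits = np.zeros(len(msframes), dtype=np.int64)
    tied = np.zeros(len(msframes), dtype=bool)
    for L, idxs in by_len.items():
        M = np.stack([msframes[i][0].matches for i in idxs])
        B = np.stack([msframes[i][0].bins for i in idxs])
        ks, _lp, tie = decode_split_batch(hmm, M, B)
        splits[idxs] = ks
        tied[idxs] = tie

    placed: list[JunctionCandidate] = []
    set_aside: list[JunctionCandidate] = []
    counts = {"no_split": 0, "short_second": 0, "ambiguous_second": 0, "unplaced": 0}
    for i, (ms, frame) in enumerate(msframes):
        k = int(splits[i])
        L = len(ms)
        if k >= L:
            counts["no_split"] += 1
            continue
        second = frame.oriented_seq[k:]
        if second.size <= config.min_second_piece:
            counts["short_second"] += 1
            set_aside.append(
                JunctionCandidate.from_frame(frame, k, None, status="short_second",
                                             tied_split=bool(tied[i]))
            )
            continue
        varr = genome.view(frame.chrom, frame.view)
        hits = find_anchor_hits(
            second, varr, frame.q + k,
            config.min_intron, config.max_intron, config.anchor_size,
        )
        match = best_second_match(second, hits, varr)
        if match.status == "none":
            counts["unplaced"] += 1
            continue
        if match.status == "ambiguous":
            counts["ambiguous_second"] += 1
            set_aside.append(
                JunctionCandidate.from_frame(frame, k, None, status="ambiguous_second",
                                             tied_split=bool(tied[i]))
            )
            continue
        cand = JunctionCandidate.from_frame(
            frame, k, match.position, tied_split=bool(tied[i])
        )
        cand.refresh(genome)
        adjust_to_canonical(cand, genome, rule, config.max_shift)
        cand.site, cand.canonical, cand.strand = classify_splice_sites(cand, genome, rule)
        score_candidate(cand, genome, params)
        placed.append(cand)
    stats.update(counts)
    stats["placed_candidates"] = len(placed)

    # per-read duplicate resolution
    by_read: dict[str, list[JunctionCandidate]] = {}
    for c in placed:
        by_read.setdefault(c.read_id, []).append(c)
    kept: list[JunctionCandidate] = []
    duplicates: list[JunctionCandidate] = []
    for rid in sorted(by_read):
        k_, d_ = resolve_read_duplicates(by_read[rid], config.duplicate_delta)
        kept.extend(k_)
        duplicates.extend(d_)
    stats["kept_reads"] = len(kept)
    stats["duplicate_reads"] = len({c.read_id for c in duplicates})

    # rescue set-aside reads against the accepted junction set
    accepted = sorted({c.key for c in kept})
    rescued = rescue(set_aside, accepted, genome)
    for c in rescued:
        cand_site = classify_splice_sites(c, genome, rule)
        c.site, c.canonical, c.strand = cand_site
        score_candidate(c, genome, params)
    stats["rescued_reads"] = len(rescued)

    collapsed = collapse_all(kept + rescued, genome, rule)
    canonical, noncanonical = filter_junctions(collapsed, params)
    dup_collapsed = collapse_all(duplicates, genome, rule) if duplicates else []
    stats["collapsed_junctions"] = len(collapsed)
    stats["canonical_junctions"] = len(canonical)
    stats["noncanonical_junctions"] = len(noncanonical)

    # read-conservation accounting: each read lands in exactly one terminal
    # category, with precedence full_length > junction_called > duplicate >
    # rescued > discarded
    rescued_ids = {c.read_id for c in rescued}
    kept_ids = {c.read_id for c in kept}
    dup_ids = {c.read_id for c in duplicates} - kept_ids
    full_ids = {r.id for r in full_reads}
    cat: dict[str, str] = {}
    for rid in read_map:
        if rid in full_ids:
            cat[rid] = "full_length"
        elif rid in kept_ids:
            cat[rid] = "junction_called"
        elif rid in dup_ids:
            cat[rid] = "duplicate"
        elif rid in rescued_ids:
            cat[rid] = "rescued"
        else:
            cat[rid] = "discarded"
    stats["read_categories"] = {
        k: sum(1 for v in cat.values() if v == k)
        for k in ("full_length", "junction_called", "duplicate", "rescued", "discarded")
    }

    return PipelineResult(
        canonical=canonical,
        noncanonical=noncanonical,
        duplicates=dup_collapsed,
        collapsed=collapsed,
        hmm=hmm,
        training=training,
        stats=stats,
    )
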