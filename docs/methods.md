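# Methods

## Model

### The split-decoding HMM

A whole read laid on the genome at one of its half's placements yields a
*match string*: per position a match/mismatch flag and a quality bin. The
model has two states. In State 1 (aligned) the probability of a match,
`m1[b]`, depends on the quality bin `b`; in State 2 (past the splice) the
probability `m2[b]` is the genomic coincidence rate, essentially independent
of quality (≈ 0.25 for a balanced base composition; higher for skewed
genomes, e.g. ≈ 0.34 at 80 % AT). The read starts in State 1 and State 2 is
absorbing, so a hidden path is fully described by the split index
`k ∈ {1..L}` — the last position emitted in State 1, with `k = L` meaning
the read never leaves the aligned state.

We parameterise the transition as a per-string mixture: with probability
`p12` the string contains a splice, at a position a priori uniform on
`1..L−1`; with probability `1 − p12` it has none. The joint probability of a
string and split `k < L` is

    P(x, k) = p12/(L−1) · Π_{t≤k} e1(x_t) · Π_{t>k} e2(x_t),

and `P(x, L) = (1−p12) · Π e1(x_t)`. Training (Baum-Welch) is exact EM over
this posterior; `p12` converges to the fraction of strings that span a
splice, which in practice is 0.9–1.0 because full-length-aligned reads are
removed before training. This per-string parameterisation, rather than a
per-position geometric transition, is essential: with a geometric transition
at the trained rate the per-position survival penalty would overwhelm the
emission evidence and decoding would always split immediately. The uniform
prior constant `1/(L−1)` never changes *which* split wins but does arbitrate
split-vs-no-split, which is what lets EM recover the splice fraction
(verified by parameter recovery from a known generator to ±0.03 at the
default training size).

Decoding enumerates all `L` split points in log space — exact and O(L) per
string, since the single-transition structure makes the path space exactly
the split points. Ties within 1e-12 log units pick the largest `k`
(shortest second piece): a falsely short second piece can still be placed
and repaired by canonical adjustment, whereas false bases prepended to the
second piece usually make it unplaceable.

### Quality binning

Five fixed Phred bins: [0–9], [10–19], [20–26], [27–33], [34+]
(configurable). Fixed cut points keep models comparable across runs;
per-score bins leave rare scores under-trained. A bin absent from the
training sample keeps its initial value and is flagged in the training info.
Training uses Initial Value Set "informed" by default (`p12 = 0.5`,
`m1 = [0.4, 0.5, 0.7, 0.7, 0.7]` low→high, `m2 = 0.3`); a completely
uninformative all-0.5 start converges to the same fit (tested to ±0.02), so
the choice is cosmetic. EM stops after 50 iterations or when no parameter
moves by more than 1e-4.

### Scoring

Each side's score is the quality-discounted information of its matching
bases, `h = Σ_matching w·(1 − 10^(−q/10))` with `w = 2` bits per certain
base. The combined score multiplies the sides and subtracts a full-length
resemblance correction:

    score = max(0, h_a·h_b − F·max(h_a·h_b′, h_a′·h_b)),  F = 0.5,

where `h_b′` rescores the right piece immediately adjacent to the left piece
and `h_a′` the converse — the two possible ungapped placements of the whole
read. The primed rescorings use the same quality weighting as the unprimed
sides, for symmetry. Scores are normalised by `1200 / max_score(L)` where
`max_score` is `(w·L/2)²` for even `L` and `(w·⌊L/2⌋)·(w·⌈L/2⌉)` for odd
`L`, and capped at 1200 (the BED writer enforces 0–1200; collapse can push
a raw aggregate above the cap, and the cap is applied at output).

## Pipeline defaults

| parameter | default | meaning |
|---|---|---|
| seed_max_mismatches | 2 | substitutions allowed in full-length and half alignment |
| repeat_threshold | 50 | max placements per half before all are dropped |
| min_intron / max_intron | 5 / 80 000 bp | intron-length search window |
| anchor_size | 8 nt | exact anchor for the second piece (6 nt suits ≤ a few kb introns) |
| min_second_piece | 8 nt | shorter second pieces are set aside for rescue |
| max_shift | 5 nt | canonical-edge adjustment range (covers observed repeat offsets of 2–4) |
| train_subset_size | 10 000 | match strings sampled for Baum-Welch |
| w / F | 2 bits / 0.5 | score weight and full-length correction |
| thresholds | 600 / 400 | score cutoffs for single-/multi-read junctions |
| duplicate_delta | 20 | per-read score gap below which placements are duplicates |

The built-in seeder finds *every* placement within the mismatch policy using
pigeonhole anchoring (`max_mismatches + 1` disjoint exact k-mers over a
k = 7 index, each candidate verified in full; short queries fall back to a
brute-force scan). This completeness is what the brute-force equivalence
tests assert; an external aligner can replace it through the SAM adapter
(`<read_id>/h1|h2` query names) without changing any downstream contract.

Adjustment order: donor–acceptor pairs in frequency order (GT‑AG, GC‑AG,
AT‑AC), shifts by |d| ascending with +d before −d; a shift is accepted only
if the reassigned read bases still match the genome on the side they join —
this concretises "adjust where possible" and prevents adjustments that
manufacture mismatches. Collapse processes reads in descending score
(ties broken by coverage then read id), which makes the result independent
of arrival order; with more than two reads each further read contributes
`score × newly_covered / total_covered` against the running per-side maxima
of matched bases. A rescued read is assigned only when exactly one accepted
junction shares its fixed edge and its entire tail matches the acceptor
exon with zero mismatches; ties stay unassigned to avoid double counting.
Rescued reads are scored on their own bases and add coverage and read count
in collapse.

## Synthetic data

The generator plants non-overlapping multi-exon transcripts (default 3–6
exons of 80–250 bp, introns 60–500 bp, intergenic gaps 200–1000 bp) on an
i.i.d. random genome and overwrites each intron's terminal dinucleotides
with a donor–acceptor pair drawn from a configurable mix (default 98.3 %
GT‑AG, 1.5 % GC‑AG, 0.2 % AT‑AC, the human proportions). Reads are sampled
uniformly along the spliced transcripts, unstranded. Per-base qualities
follow a linearly decaying mean (38 → 25 along the read, sd 4) with a 2 %
"failed-cycle" tail drawn uniformly from Phred 2–12; the tail keeps every
quality bin populated, as real Illumina distributions are. Substitutions
are drawn per base at the Phred-implied rate, which makes the quality
model self-consistent by construction.

What the generator does **not** emulate: indels, GC-coverage bias, uneven
coverage within transcripts, inaccurate quality strings, paired-end
structure, genomic repeats/homologues, or UTRs (so terminal exons receive
less junction-spanning coverage, an edge effect a UTR-free benchmark
shares). Passing the benchmark therefore demonstrates the algorithm's
behaviour under its own model assumptions, not performance on real
libraries; on real data the repeat structure of the genome and miscalibrated
qualities will raise both miss and false-positive rates.

The standard benchmark (`splicehmm.benchmark`) uses a 1 Mb balanced genome,
100 transcripts and 50 bp reads with the compact-genome parameter set
(max intron 1 kb, anchor 6 nt, min intron 10 bp) — intron lengths are well
inside the search window so the measurements reflect the algorithm, not
window truncation. At these sizes a 5× run completes in a few seconds.
Observed behaviour: ≈ half of the planted junctions are recovered at 1×
coverage, > 95 % at 5×, with ≤ 2.5 % of filtered predictions false; the
residual false calls are error-induced near-misses a few bases off a true
junction whose shifted edges are non-canonical (they cannot be repaired by
the adjustment step without inventing mismatches). Score-ranking true vs
false predictions at 10× gives AUC > 0.99. The synthetic benchmark is
*easier* than a real mammalian dataset (no repeats, clean qualities), so
its sensitivities sit above what the same pipeline achieves on experimental
reads.

## Numerical and degenerate-input choices

- Probabilities are clipped to [1e-4, 1−1e-4] during EM (keeps logs finite;
  an all-match bin therefore trains to 0.9999, reported as ≈ 1).
- Decode ties use a 1e-12 log-unit tolerance as the floating-point surrogate
  for exact equality.
- Read 'N' bases mismatch every genome base (including genome 'N') and carry
  their stated quality.
- A whole-read window running off a chromosome discards that placement
  (logged, not fatal); a second-piece search window is truncated at the
  chromosome end.
- An empty training population is an error; when a run has no half
  alignments at all, the pipeline proceeds with the initial (untrained)
  model and necessarily reports no junctions.
- Reads shorter than 2 bases cannot be split and are rejected at the split
  stage.

## Known limitations

- Substitution-only alignment: indels in reads or polymorphic samples
  produce misses, not shifted calls.
- One junction per read: reads spanning two introns (possible when an
  internal exon is shorter than the read) decode only the first boundary
  and usually discard.
- Error-induced near-miss junctions a few bases off a true junction are the
  dominant false-positive class; they are single-read calls with
  non-canonical edges and can be suppressed by raising the single-read
  threshold at some sensitivity cost.
- The score's full-length correction assumes the two hypothetical ungapped
  placements are the only confusable alternatives; paralogous copies
  elsewhere in the genome are handled by the repeat threshold, not by the
  score.
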