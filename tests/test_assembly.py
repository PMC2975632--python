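"""Second-piece anchoring, canonical-edge adjustment, splice-site classes."""

import numpy as np
import pytest

from splicehmm._seq import encode_read
from splicehmm.assembly import (
    DEFAULT_RULE,
    JunctionCandidate,
    SpliceSiteRule,
    adjust_to_canonical,
    best_second_match,
    classify_splice_sites,
    find_anchor_hits,
)
from splicehmm.io import Genome
from splicehmm.seeding import SeedIndex, find_placements


def _genome_from(seq):
    return Genome({"chr1": seq})


class TestAnchorHits:
    def test_planted_piece_found_once(self, small_genome):
        varr = small_genome.forward("chr1")
        piece = varr[5000:5020]
        hits = find_anchor_hits(piece, varr, 4000, 10, 2000, anchor_size=8)
        assert 5000 in hits.tolist()

    def test_fallback_anchor_recovers_corrupted_first_eight(self, small_genome):
        varr = small_genome.forward("chr1")
        piece = varr[5000:5020].copy()
        piece[:8] = (piece[:8] + 1) % 4  # corrupt the primary anchor entirely
        hits = find_anchor_hits(piece, varr, 4000, 10, 2000, anchor_size=8)
        assert 5000 in hits.tolist()

    def test_multiple_exact_anchor_occurrences(self):
        sea = "C" * 3000
        anchor = "ACGTACGT"
        seq = sea[:500] + anchor + sea[500:900] + anchor + sea[900:1400] + anchor + sea[1400:]
        g = _genome_from(seq)
        piece = encode_read(anchor + "CCCC")
        hits = find_anchor_hits(piece, g.forward("chr1"), 0, 10, 2500, anchor_size=8)
        assert len(hits) == 3

    def test_window_truncated_at_chromosome_end(self, small_genome):
        varr = small_genome.forward("chr1")
        piece = varr[-20:]
        hits = find_anchor_hits(piece, varr, varr.size - 2000, 10, 100_000, anchor_size=8)
        assert (hits + 20 <= varr.size).all()


class TestBestSecondMatch:
    def test_fewest_mismatches_wins(self, small_genome):
        varr = small_genome.forward("chr1")
        piece = varr[6000:6020].copy()
        other = int(np.flatnonzero(
            (varr[5000:5500] != piece[0])
        )[0]) + 5000  # any position with >= 1 mismatch
        m = best_second_match(piece, np.array([other, 6000]), varr)
        assert m.status == "placed" and m.position == 6000 and m.mismatches == 0

    def test_tied_minimum_is_ambiguous(self):
        g = _genome_from("A" * 200 + "TTTTGGGG" + "A" * 200 + "TTTTGGGG" + "A" * 200)
        varr = g.forward("chr1")
        piece = encode_read("TTTTGGGG")
        m = best_second_match(piece, np.array([200, 408]), varr)
        assert m.status == "ambiguous"
        assert m.tied_positions == (200, 408)

    def test_no_hits_is_none(self, small_genome):
        varr = small_genome.forward("chr1")
        m = best_second_match(varr[100:120], np.empty(0, dtype=np.int64), varr)
        assert m.status == "none"


def _candidate(genome, read_enc, quals, q, split, s2, view="+"):
    cand = JunctionCandidate(
        read_id="r1",
        chrom="chr1",
        view=view,
        q=q,
        split=split,
        s2=s2,
        oriented_seq=read_enc,
        oriented_qual=quals,
        clen=genome.length("chr1"),
    )
    cand.refresh(genome)
    return cand


class TestAdjustment:
    def _fixture(self, donor="GT", acceptor="AG", repeat=True):
        """True intron [130, 600); optionally the acceptor exon's first two
        bases repeat the intron's first two, the ambiguity that offsets the
        decoded split."""
        rng = np.random.default_rng(8)
        seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, 12_000)))
        seq[130:132] = list(donor)
        seq[598:600] = list(acceptor)
        if repeat:
            seq[600:602] = list(donor)  # acceptor exon starts with the repeat
            seq[602] = "C" if seq[132] != "C" else "A"
            if seq[602] == seq[132]:
                seq[602] = "T"
        genome = _genome_from("".join(seq))
        read = genome.fetch("chr1", 100, 130) + genome.fetch("chr1", 600, 620)
        return genome, encode_read(read), np.full(50, 38)

    def test_already_canonical_unchanged(self):
        genome, read, quals = self._fixture(repeat=False)
        cand = _candidate(genome, read, quals, 100, 30, 600)
        adjust_to_canonical(cand, genome)
        assert cand.adjust_shift == 0
        assert cand.intron_fwd == (130, 600)

    def test_repeat_induced_offset_restored(self):
        """The split decoded two late because the intron start repeats the
        acceptor exon start; shifting both edges back by two restores the
        true donor-acceptor pair without introducing mismatches."""
        genome, read, quals = self._fixture(repeat=True)
        cand = _candidate(genome, read, quals, 100, 32, 602)
        assert cand.intron_fwd == (132, 602)
        adjust_to_canonical(cand, genome)
        assert cand.adjust_shift == -2
        assert cand.intron_fwd == (130, 600)
        assert cand.p1_flags.all() and cand.p2_flags.all()

    def test_non_canonical_intron_left_untouched(self):
        genome, read, quals = self._fixture(donor="CA", acceptor="AG", repeat=False)
        cand = _candidate(genome, read, quals, 100, 30, 600)
        before = cand.intron_fwd
        adjust_to_canonical(cand, genome)
        site, canonical, _ = classify_splice_sites(cand, genome)
        if cand.intron_fwd == before:  # no accidental canonical pair in range
            assert site == "CA-AG"
            assert not canonical

    def test_adjustment_preserves_intron_length(self):
        genome, read, quals = self._fixture(repeat=True)
        cand = _candidate(genome, read, quals, 100, 32, 602)
        a0, b0 = cand.intron_fwd
        adjust_to_canonical(cand, genome)
        a1, b1 = cand.intron_fwd
        assert b1 - a1 == b0 - a0


class TestClassification:
    def _mini(self, intron_seq):
        rng = np.random.default_rng(21)
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        return _genome_from(flank + intron_seq + flank)

    def test_forward_gt_ag(self):
        g = self._mini("GT" + "C" * 60 + "AG")
        site, canon, strand = classify_splice_sites("chr1", g, intron=(100, 164))
        assert (site, canon, strand) == ("GT-AG", True, "+")

    def test_reverse_complement_ct_ac(self):
        g = self._mini("CT" + "C" * 60 + "AC")
        site, canon, strand = classify_splice_sites("chr1", g, intron=(100, 164))
        assert (site, canon, strand) == ("GT-AG", True, "-")

    def test_at_ac_is_adjusted_but_not_canonical_output(self):
        g = self._mini("AT" + "C" * 60 + "AC")
        site, canon, strand = classify_splice_sites("chr1", g, intron=(100, 164))
        assert (site, canon, strand) == ("AT-AC", False, "+")

    def test_unknown_edges_reported_verbatim(self):
        g = self._mini("CA" + "C" * 60 + "AG")
        site, canon, strand = classify_splice_sites("chr1", g, intron=(100, 164))
        assert (site, canon, strand) == ("CA-AG", False, ".")


def test_reconstruction_conservation(small_genome):
    """genome[first piece) + genome[second piece) differs from the read by
    exactly the per-side mismatch counts."""
    rng = np.random.default_rng(30)
    varr = small_genome.forward("chr1")
    for _ in range(10):
        p1, ilen = int(rng.integers(0, 15_000)), int(rng.integers(50, 400))
        k = int(rng.integers(15, 36))
        read = varr[p1 : p1 + k].tolist() + varr[p1 + k + ilen : p1 + k + ilen + 50 - k].tolist()
        read = np.array(read, dtype=np.uint8)
        for pos in rng.choice(50, size=2, replace=False):  # two sequencing errors
            read[pos] = (read[pos] + 1) % 4
        cand = _candidate(small_genome, read, np.full(50, 35), p1, k, p1 + k + ilen)
        recon = np.concatenate(
            [varr[p1 : p1 + k], varr[p1 + k + ilen : p1 + k + ilen + 50 - k]]
        )
        assert int((recon != read).sum()) == (
            (k - cand.p1_flags.sum()) + (50 - k - cand.p2_flags.sum())
        )


def test_second_piece_uniqueness_rises_with_length(bench):
    """Unique mapping of a planted second piece within an 80 kb window becomes
    more likely as the piece grows; short pieces mostly map multiply.  (On an
    i.i.d. 1 Mb genome the unique/multiple crossover sits near 11 nt for an
    80 kb window; the qualitative monotone trend is the property of record.)"""
    genome = bench[1][1].genome
    varr = genome.forward("chr1")
    rng = np.random.default_rng(77)
    frac_unique = {}
    for ln in (6, 8, 10, 12, 14):
        unique = 0
        trials = 150
        for _ in range(trials):
            pos = int(rng.integers(40_000, varr.size - 40_000))
            piece = varr[pos : pos + ln]
            window = varr[pos - 40_000 : pos + 40_000]
            n = window.size - ln + 1
            ok = np.ones(n, dtype=bool)
            for j, c in enumerate(piece):
                ok &= window[j : j + n] == c
            if int(ok.sum()) == 1:
                unique += 1
        frac_unique[ln] = unique / trials
    assert frac_unique[6] < 0.1
    assert frac_unique[14] > 0.9
    vals = [frac_unique[k] for k in sorted(frac_unique)]
    assert all(b >= a for a, b in zip(vals, vals[1:]))
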