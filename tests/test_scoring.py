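"""Junction scoring, duplicate resolution, rescue, collapse and filtering."""

import random
from dataclasses import dataclass

import numpy as np
import pytest

from splicehmm._seq import encode_read
from splicehmm.assembly import JunctionCandidate
from splicehmm.io import Genome
from splicehmm.scoring import (
    CollapsedJunction,
    ScoreParams,
    SideScores,
    collapse,
    filter_junctions,
    normalize_score,
    p_correct,
    raw_junction_score,
    rescue,
    resolve_read_duplicates,
    side_score,
)


class TestPCorrect:
    @pytest.mark.parametrize("q,p", [(10, 0.9), (30, 0.999), (0, 0.0)])
    def test_phred_definition(self, q, p):
        assert p_correct(q) == pytest.approx(p)


class TestSideScore:
    def test_two_bits_per_certain_match(self):
        assert side_score([True] * 25, [1.0] * 25, w=2) == pytest.approx(50.0)

    def test_unit_weight_counts_matching_bases(self):
        # in per-base-weight-1 units an ideal 25/25 split multiplies to 625
        h = side_score([True] * 25, [1.0] * 25, w=1)
        assert h == pytest.approx(25.0)
        assert h * h == pytest.approx(625.0)

    def test_mismatches_contribute_nothing(self):
        flags = [True] * 10 + [False] * 2
        assert side_score(flags, p_correct(np.full(12, 10)), w=2) == pytest.approx(18.0)


class TestRawScore:
    def test_no_full_length_resemblance_keeps_product(self):
        s = SideScores(40.0, 30.0, 0.0, 0.0)
        assert raw_junction_score(s, F=0.5) == pytest.approx(1200.0)

    def test_full_length_lookalike_loses_half(self):
        s = SideScores(50.0, 50.0, 50.0, 50.0)
        assert raw_junction_score(s, F=0.5) == pytest.approx(1250.0)

    def test_floored_at_zero(self):
        s = SideScores(10.0, 10.0, 40.0, 40.0)
        assert raw_junction_score(s, F=0.5) == 0.0

    @pytest.mark.parametrize("a,b,product", [(10, 40, 400), (10, 60, 600),
                                             (25, 25, 625), (35, 35, 1225)])
    def test_evenness_bias_worked_examples(self, a, b, product):
        s = SideScores(float(a), float(b), 0.0, 0.0)
        assert raw_junction_score(s, F=0.5) == pytest.approx(product)

    def test_even_split_maximises_fixed_length_score(self):
        for L in (50, 70, 99):
            scores = [a * (L - a) for a in range(1, L)]
            best = max(range(1, L), key=lambda a: scores[a - 1])
            assert abs(best - L / 2) <= 0.5
            left = scores[: (L // 2)]
            assert all(b > a for a, b in zip(left, left[1:]))


class TestNormalize:
    def test_even_length_ideal_maps_to_ceiling(self):
        assert normalize_score(2500.0, 50) == pytest.approx(1200.0)

    def test_half_ideal_maps_to_600(self):
        assert normalize_score(1250.0, 50) == pytest.approx(600.0)

    def test_odd_length_ideal_maps_to_ceiling(self):
        assert normalize_score(44 * 46, 45) == pytest.approx(1200.0)

    def test_capped_at_ceiling(self):
        assert normalize_score(5000.0, 50) == 1200.0


@dataclass
class _Stub:
    """Minimal junction-candidate stand-in for collapse/duplicate logic."""

    read_id: str
    score: float
    left_matched: int = 25
    right_matched: int = 25
    left_len: int = 25
    right_len: int = 25
    key: tuple = ("chr1", 1000, 1500)
    strand: str = "+"
    site: str = "GT-AG"
    canonical: bool = True


class TestReadDuplicates:
    def test_identical_junction_positions_merged(self):
        a = _Stub("r1", 900.0)
        b = _Stub("r1", 880.0)
        kept, dups = resolve_read_duplicates([a, b], delta=20)
        assert kept == [a] and dups == []

    def test_clear_winner_kept(self):
        a = _Stub("r1", 900.0)
        b = _Stub("r1", 850.0, key=("chr1", 2000, 2400))
        kept, dups = resolve_read_duplicates([a, b], delta=20)
        assert kept == [a] and dups == []

    def test_close_scores_routed_to_duplicates(self):
        a = _Stub("r1", 900.0)
        b = _Stub("r1", 890.0, key=("chr1", 2000, 2400))
        kept, dups = resolve_read_duplicates([a, b], delta=20)
        assert kept == []
        assert sorted(d.score for d in dups) == [890.0, 900.0]


class TestCollapse:
    def test_complementary_splits_boost_score(self):
        """A 10/35 read at 800 plus a 35/10 read at 600 covers 25 new bases of
        70 total: the collapsed score is 800 + (25/70)*600."""
        a = _Stub("r1", 800.0, left_matched=10, right_matched=35,
                  left_len=10, right_len=35)
        b = _Stub("r2", 600.0, left_matched=35, right_matched=10,
                  left_len=35, right_len=10)
        j = collapse([a, b])
        assert j.score == pytest.approx(800.0 + (25 / 70) * 600.0)
        assert j.read_count == 2

    def test_identical_reads_do_not_boost(self):
        a = _Stub("r1", 600.0, left_matched=35, right_matched=10)
        b = _Stub("r2", 600.0, left_matched=35, right_matched=10)
        j = collapse([a, b])
        assert j.score == pytest.approx(600.0)
        assert j.read_count == 2

    def test_single_read_keeps_own_score(self):
        j = collapse([_Stub("r1", 750.0)])
        assert j.score == 750.0 and j.read_count == 1

    def test_order_independent(self):
        rng = random.Random(3)
        cands = [
            _Stub(f"r{i}", 400.0 + 37 * i,
                  left_matched=10 + 3 * i, right_matched=40 - 3 * i,
                  left_len=10 + 3 * i, right_len=40 - 3 * i)
            for i in range(6)
        ]
        ref = collapse(cands)
        for _ in range(5):
            shuffled = cands[:]
            rng.shuffle(shuffled)
            got = collapse(shuffled)
            assert got.score == pytest.approx(ref.score)
            assert got.read_count == ref.read_count

    def test_mixed_introns_rejected(self):
        with pytest.raises(ValueError):
            collapse([_Stub("r1", 500.0), _Stub("r2", 500.0, key=("chr1", 5, 9))])


def _cj(score, count, canonical=True):
    return CollapsedJunction(
        chrom="chr1", intron_start=100, intron_end=400, strand="+",
        site="GT-AG" if canonical else "CA-AG", canonical=canonical,
        score=score, read_count=count,
        max_left_matched=25, max_right_matched=25,
        max_left_len=25, max_right_len=25,
    )


class TestFilter:
    def test_single_read_junction_needs_higher_score(self):
        canon, nc = filter_junctions([_cj(580.0, 1)])
        assert canon == [] and nc == []

    def test_multi_read_junction_passes_lower_threshold(self):
        canon, _ = filter_junctions([_cj(450.0, 3)])
        assert len(canon) == 1

    def test_non_canonical_kept_in_separate_set(self):
        canon, nc = filter_junctions([_cj(700.0, 2, canonical=False)])
        assert canon == [] and len(nc) == 1

    def test_idempotent(self):
        js = [_cj(650.0, 1), _cj(450.0, 3), _cj(300.0, 5)]
        canon, nc = filter_junctions(js)
        again, nc2 = filter_junctions(canon)
        assert again == canon and nc2 == []


class TestRescue:
    def _setup(self, small_genome, tail_src, edge=None):
        """Set-aside read: first 45 bases seeded ending at the donor edge,
        5-base tail unplaced."""
        fs, fe = 8000, 8300
        read = small_genome.fetch("chr1", fs - 45, fs) + tail_src
        cand = JunctionCandidate(
            read_id="sa1", chrom="chr1", view="+", q=fs - 45, split=45, s2=None,
            oriented_seq=encode_read(read), oriented_qual=np.full(50, 35),
            clen=small_genome.length("chr1"), status="short_second",
        )
        return cand, (("chr1", fs, fe) if edge is None else edge)

    def test_matching_tail_assigned_to_shared_edge_junction(self, small_genome):
        tail = small_genome.fetch("chr1", 8300, 8305)
        cand, junc = self._setup(small_genome, tail)
        out = rescue([cand], [junc], small_genome)
        assert len(out) == 1
        assert out[0].key == junc
        assert out[0].status == "rescued"

    def test_non_matching_tail_unassigned(self, small_genome):
        tail = small_genome.fetch("chr1", 8300, 8305)
        bad = "".join({"A": "C", "C": "G", "G": "T", "T": "A"}[b] for b in tail)
        cand, junc = self._setup(small_genome, bad)
        assert rescue([cand], [junc], small_genome) == []

    def test_two_qualifying_junctions_leave_read_unassigned(self, small_genome):
        # two accepted junctions share the donor edge and both acceptor exons
        # start with the same 5 bases: the tie stays unassigned
        tail = small_genome.fetch("chr1", 8300, 8305)
        cand, junc = self._setup(small_genome, tail)
        idx = small_genome.seq("chr1").find(tail, 8306)
        assert idx != -1  # a 5-mer recurs in 20 kb of random sequence
        out = rescue([cand], [junc, ("chr1", 8000, idx)], small_genome)
        assert out == []


class TestScoreBoundsProperty:
    from hypothesis import given, settings, strategies as st

    @staticmethod
    @given(
        flags=st.lists(st.booleans(), min_size=1, max_size=80),
        data=st.data(),
    )
    @settings(derandomize=True, max_examples=60)
    def test_side_score_bounded_by_two_bits_per_base(flags, data):
        quals = data.draw(
            TestScoreBoundsProperty.st.lists(
                TestScoreBoundsProperty.st.integers(min_value=0, max_value=41),
                min_size=len(flags), max_size=len(flags),
            )
        )
        h = side_score(flags, p_correct(np.asarray(quals)), w=2.0)
        assert 0.0 <= h <= 2.0 * len(flags)

    @staticmethod
    @given(
        raw=st.floats(min_value=0, max_value=1e7, allow_nan=False),
        length=st.integers(min_value=2, max_value=150),
    )
    @settings(derandomize=True, max_examples=60)
    def test_normalized_score_always_in_bed_range(raw, length):
        assert 0.0 <= normalize_score(raw, length) <= 1200.0
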