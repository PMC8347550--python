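import random

import pytest
from hypothesis import given, strategies as st

from forktrap.genome_io import CircularGenome, reverse_complement
from forktrap.motif_scan import (
    best_hit_per_query,
    dedupe_hits,
    extract_flanks,
    filter_candidates,
    locate_dif,
    scan_circular,
    MotifHit,
)
from forktrap.queries import DIF_SEQUENCE

from conftest import random_sequence
from oracle_utils import brute_force_scan, brute_force_cluster_best


def paste(seq: str, insert: str, pos: int) -> str:
    """Overwrite insert into seq at pos, wrapping circularly."""
    buf = list(seq)
    for i, c in enumerate(insert):
        buf[(pos + i) % len(seq)] = c
    return "".join(buf)


@pytest.fixture()
def terA(query_map):
    return query_map["terA"]


class TestScanCircular:
    def test_forward_paste(self, terA):
        g = CircularGenome("g", paste("A" * 200, terA.sequence, 50), 0)
        hits = scan_circular(g, terA, 0)
        assert [(h.start, h.strand, h.mismatch_count) for h in hits] == [(50, "+", 0)]

    def test_reverse_paste(self, terA):
        g = CircularGenome("g", paste("A" * 200, reverse_complement(terA.sequence), 50), 0)
        hits = scan_circular(g, terA, 0)
        assert [(h.start, h.strand) for h in hits] == [(50, "-")]
        assert hits[0].matched_sequence == terA.sequence

    def test_wrap_span(self, terA):
        g = CircularGenome("g", paste("C" * 300, terA.sequence, 290), 0)
        hits = scan_circular(g, terA, 0)
        assert [(h.start, h.strand) for h in hits] == [(290, "+")]

    def test_minus_strand_mismatch_positions_in_query_coords(self, terA):
        seq = paste("A" * 200, reverse_complement(terA.sequence), 50)
        # damage the genomic base that corresponds to query position 3:
        # on the minus strand, query position p sits at offset 23 - p.
        buf = list(seq)
        offset = 50 + (23 - 3)
        original_query_base = terA.sequence[2]
        buf[offset] = reverse_complement("G" if original_query_base != "G" else "C")
        g = CircularGenome("g", "".join(buf), 0)
        (hit,) = scan_circular(g, terA, 1)
        assert hit.strand == "-" and hit.mismatch_positions == frozenset({3})

    def test_n_counts_as_mismatch(self, terA):
        g = CircularGenome("g", paste("A" * 100, terA.sequence, 10).replace("G", "G"), 0)
        seq = list(g.sequence)
        seq[10] = "N"
        g2 = CircularGenome("g", "".join(seq), 0)
        hits0 = scan_circular(g2, terA, 0)
        hits1 = scan_circular(g2, terA, 1)
        assert not [h for h in hits0 if h.start == 10]
        assert any(h.start == 10 and h.mismatch_positions == frozenset({1}) for h in hits1)

    def test_query_longer_than_genome(self, terA):
        g = CircularGenome("g", "ACGT", 0)
        with pytest.raises(ValueError):
            scan_circular(g, terA, 0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_on_random_genome(self, seed, terA):
        rng = random.Random(seed)
        seq = random_sequence(rng, 2000)
        seq = paste(seq, terA.sequence, rng.randrange(2000))
        g = CircularGenome("g", seq, 0)
        for budget in (0, 2, 4):
            got = {(h.start, h.strand, h.mismatch_count) for h in scan_circular(g, terA, budget)}
            assert got == brute_force_scan(seq, terA.sequence, budget)

    def test_monotone_in_budget(self, small_genome, terA):
        sets = [
            {(h.start, h.strand) for h in scan_circular(small_genome, terA, k)}
            for k in range(6)
        ]
        for lo, hi in zip(sets, sets[1:]):
            assert lo <= hi

    def test_strand_symmetry(self, terA):
        rng = random.Random(7)
        seq = paste(random_sequence(rng, 500), terA.sequence, 123)
        g = CircularGenome("g", seq, 0)
        gm = CircularGenome("g", reverse_complement(seq), 0)
        fwd = {(h.start, h.strand) for h in scan_circular(g, terA, 4)}
        mirrored = {
            ((len(seq) - h.start - h.span) % len(seq), "+" if h.strand == "-" else "-")
            for h in scan_circular(gm, terA, 4)
        }
        assert fwd == mirrored

    @given(r=st.integers(0, 499))
    def test_rotation_shifts_starts(self, terA, r):
        rng = random.Random(11)
        seq = paste(random_sequence(rng, 500), terA.sequence, 321)
        rotated = seq[r:] + seq[:r]
        base = {(h.start, h.strand, h.mismatch_count)
                for h in scan_circular(CircularGenome("g", seq, 0), terA, 3)}
        rot = {((h.start + r) % 500, h.strand, h.mismatch_count)
               for h in scan_circular(CircularGenome("g", rotated, 0), terA, 3)}
        assert base == rot


class TestDedupe:
    def _hit(self, name, start, mm, strand="+", span=23):
        return MotifHit(
            query_name=name, start=start, strand=strand, mismatch_count=mm,
            mismatch_positions=frozenset(range(1, mm + 1)),
            matched_sequence="A" * span, span=span,
        )

    def test_best_of_overlapping_pair_survives(self):
        out = dedupe_hits([self._hit("terA", 100, 3), self._hit("terA", 105, 1)], 1000)
        assert [(h.start, h.mismatch_count) for h in out] == [(105, 1)]

    def test_non_overlapping_retained(self):
        out = dedupe_hits([self._hit("terA", 100, 1), self._hit("terA", 400, 2)], 1000)
        assert len(out) == 2

    def test_different_queries_never_merged(self):
        out = dedupe_hits([self._hit("terA", 100, 3), self._hit("terB", 100, 1)], 1000)
        assert {h.query_name for h in out} == {"terA", "terB"}

    def test_wraparound_overlap_detected(self):
        out = dedupe_hits([self._hit("terA", 990, 2), self._hit("terA", 5, 1)], 1000)
        assert [(h.start, h.mismatch_count) for h in out] == [(5, 1)]

    def test_random_clusters_match_bruteforce(self):
        rng = random.Random(13)
        hits = [
            self._hit(rng.choice(["terA", "terB"]), rng.randrange(1000),
                      rng.randrange(5), rng.choice("+-"))
            for _ in range(50)
        ]
        got = {(h.query_name, h.start, h.strand) for h in dedupe_hits(hits, 1000)}
        assert got == brute_force_cluster_best(hits, 1000)


class TestFilterCandidates:
    def _hit(self, positions, name="terA"):
        return MotifHit(
            query_name=name, start=0, strand="+", mismatch_count=len(positions),
            mismatch_positions=frozenset(positions), matched_sequence="A" * 23, span=23,
        )

    def test_variable_only_passes(self, queries):
        (out,) = filter_candidates([self._hit({2, 21})], queries)
        assert out.filter_status == "pass"

    def test_critical_position_fails(self, queries):
        (out,) = filter_candidates([self._hit({6})], queries)
        assert out.filter_status == "fail" and "critical" in out.fail_reason

    def test_five_variable_mismatches_need_relaxed_budget(self, queries):
        hit = self._hit({1, 2, 3, 22, 23})
        (strict,) = filter_candidates([hit], queries, max_mismatch=4)
        (relaxed,) = filter_candidates([hit], queries, max_mismatch=5)
        assert strict.filter_status == "fail" and relaxed.filter_status == "pass"

    def test_one_core_mismatch_within_budget(self, queries):
        (out,) = filter_candidates([self._hit({15})], queries)
        assert out.filter_status == "pass"

    def test_two_core_mismatches_exceed_budget(self, queries):
        (out,) = filter_candidates([self._hit({10, 15})], queries)
        assert out.filter_status == "fail" and "core" in out.fail_reason

    def test_position7_not_counted_as_core(self, queries):
        (out,) = filter_candidates([self._hit({7, 15})], queries)
        assert out.filter_status == "pass"

    def test_failing_hits_retained(self, queries):
        hits = [self._hit({6}), self._hit({1})]
        out = filter_candidates(hits, queries)
        assert len(out) == 2


class TestLocateDif:
    def test_forward(self):
        g = CircularGenome("g", paste("A" * 400, DIF_SEQUENCE, 120), 0)
        hit = locate_dif(g, DIF_SEQUENCE)
        assert (hit.start, hit.strand, hit.mismatch_count) == (120, "+", 0)

    def test_reverse(self):
        g = CircularGenome("g", paste("A" * 400, reverse_complement(DIF_SEQUENCE), 120), 0)
        hit = locate_dif(g, DIF_SEQUENCE)
        assert (hit.start, hit.strand) == (120, "-")

    def test_absent(self):
        rng = random.Random(3)
        g = CircularGenome("g", random_sequence(rng, 1000), 0)
        assert locate_dif(g, DIF_SEQUENCE) is None

    def test_best_of_two(self):
        seq = paste("A" * 500, DIF_SEQUENCE, 100)
        imperfect = "C" + DIF_SEQUENCE[1:]
        seq = paste(seq, imperfect, 300)
        hit = locate_dif(CircularGenome("g", seq, 0), DIF_SEQUENCE)
        assert hit.start == 100 and hit.mismatch_count == 0


class TestExtractFlanks:
    def test_length(self, terA):
        g = CircularGenome("g", paste("A" * 300, terA.sequence, 100), 0)
        (hit,) = scan_circular(g, terA, 0)
        assert len(extract_flanks(g, hit, 25)) == 73

    def test_zero_flank_is_span(self, terA):
        g = CircularGenome("g", paste("A" * 300, terA.sequence, 100), 0)
        (hit,) = scan_circular(g, terA, 0)
        assert extract_flanks(g, hit, 0) == terA.sequence

    def test_wrap_matches_doubled_string(self, terA):
        seq = paste(random_sequence(random.Random(5), 300), terA.sequence, 2)
        g = CircularGenome("g", seq, 0)
        hit = next(h for h in scan_circular(g, terA, 0) if h.start == 2)
        flank = extract_flanks(g, hit, 25)
        doubled = seq + seq
        assert flank == doubled[300 + 2 - 25 : 300 + 2 + 23 + 25]

    def test_minus_strand_orientation(self, terA):
        g = CircularGenome("g", paste("A" * 300, reverse_complement(terA.sequence), 100), 0)
        (hit,) = scan_circular(g, terA, 0)
        flank = extract_flanks(g, hit, 10)
        assert flank[10:33] == terA.sequence

    def test_too_long(self, terA):
        g = CircularGenome("g", paste("A" * 60, terA.sequence, 10), 0)
        (hit,) = scan_circular(g, terA, 0)
        with pytest.raises(ValueError):
            extract_flanks(g, hit, 25)


def test_best_hit_per_query_prefers_fewest_mismatches():
    def hit(name, start, mm, strand="+"):
        return MotifHit(query_name=name, start=start, strand=strand,
                        mismatch_count=mm, mismatch_positions=frozenset(range(1, mm + 1)),
                        matched_sequence="A" * 23, span=23)

    best = best_hit_per_query([hit("terA", 500, 2), hit("terA", 100, 0), hit("terB", 9, 1)])
    assert best["terA"].start == 100 and best["terB"].start == 9
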