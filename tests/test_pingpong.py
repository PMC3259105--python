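import numpy as np
import pytest

from oracles import all_pairs_overlaps, random_hit_set
from pirnakit.model import AlignmentHit, Interval, reverse_complement
from pirnakit.pingpong import (
    OverlapPair,
    base_composition,
    density_map,
    enumerate_overlap_pairs,
    overlap_histogram,
    position_base_matrix,
    signature_fraction,
    u1a10_flag,
)


def _hit(seq, start, length, strand, contig="c"):
    return AlignmentHit(seq, Interval(contig, start, start + length, strand), 0)


def test_signature_geometry_overlap_ten():
    plus = _hit("T" + "G" * 27, 100, 28, "+")
    minus = _hit("T" + "G" * 27, 82, 28, "-")  # interval [82,110), 5' = 109
    (pair,) = enumerate_overlap_pairs([plus, minus])
    assert pair.minus_hit.five_prime == 109
    assert pair.overlap == 10


def test_no_pair_without_shared_position():
    plus = _hit("A" * 28, 100, 28, "+")
    minus = _hit("C" * 28, 130, 28, "-")
    assert enumerate_overlap_pairs([plus, minus]) == []


def test_pair_enumeration_matches_all_pairs_oracle(rng):
    for _ in range(3):
        hits = random_hit_set(rng, 300)
        got = {
            (id(p.plus_hit), id(p.minus_hit), p.overlap)
            for p in enumerate_overlap_pairs(hits)
        }
        expected = {(id(a), id(b), o) for a, b, o in all_pairs_overlaps(hits)}
        assert got == expected


def test_histogram_totals_and_empty():
    assert overlap_histogram([]) == {}
    plus = _hit("A" * 28, 100, 28, "+")
    minus = _hit("C" * 28, 82, 28, "-")
    pairs = enumerate_overlap_pairs([plus, minus])
    assert overlap_histogram(pairs) == {10: 1}


def test_histogram_invariant_under_reverse_complement(rng):
    """Reverse-complementing the whole dataset flips strands but leaves the
    overlap spectrum unchanged."""
    contig_length = 5000
    hits = random_hit_set(rng, 200, contig_length=contig_length)
    flipped = []
    for h in hits:
        iv = h.interval
        flipped.append(
            AlignmentHit(
                h.sequence_id,
                Interval(
                    iv.contig,
                    contig_length - iv.end,
                    contig_length - iv.start,
                    "-" if iv.strand == "+" else "+",
                ),
                h.mismatches,
            )
        )
    h1 = overlap_histogram(enumerate_overlap_pairs(hits))
    h2 = overlap_histogram(enumerate_overlap_pairs(flipped))
    assert h1 == h2


def test_signature_fraction_cases():
    plus = _hit("T" + "G" * 27, 100, 28, "+")
    minus = _hit("C" * 9 + "A" + "C" * 18, 82, 28, "-")
    pairs = enumerate_overlap_pairs([plus, minus])
    assert signature_fraction(pairs) == 1.0

    plus5 = _hit("A" * 28, 100, 28, "+")
    minus5 = _hit("C" * 28, 77, 28, "-")  # 5' = 104, overlap 5
    pairs5 = enumerate_overlap_pairs([plus5, minus5])
    assert {p.overlap for p in pairs5} == {5}
    assert signature_fraction(pairs5) == 0.0

    assert signature_fraction([]) is None


def test_signature_fraction_multiplicity_weighted():
    plus = _hit("T" + "G" * 27, 100, 28, "+")
    minus = _hit("C" * 9 + "A" + "C" * 18, 82, 28, "-")
    other_p = _hit("G" * 28, 1000, 28, "+")
    other_m = _hit("G" * 27 + "C", 995, 28, "-")  # overlap 22
    pairs = enumerate_overlap_pairs([plus, minus, other_p, other_m])
    assert signature_fraction(pairs) == pytest.approx(0.5)
    weights = {plus.sequence_id: 3, minus.sequence_id: 3}
    assert signature_fraction(pairs, weights=weights) == pytest.approx(6 / 8)


def test_base_composition_rows():
    plus = _hit("T" + "G" * 27, 100, 28, "+")
    minus = _hit("T" + "C" * 8 + "A" + "C" * 18, 82, 28, "-")
    pairs = enumerate_overlap_pairs([plus, minus])
    freq = base_composition(pairs)
    assert freq[10]["U"] == 1.0
    assert sum(freq[10].values()) == pytest.approx(1.0)


def test_position_base_matrix_uniform_row():
    rows = position_base_matrix(["AAAA", "CAAA", "GAAA", "TAAA"])
    assert rows[0] == {"A": 0.25, "C": 0.25, "G": 0.25, "U": 0.25}
    assert rows[1]["A"] == 1.0


def test_u1a10_flag_cases():
    plus = _hit("T" + "G" * 27, 100, 28, "+")
    minus_a10 = _hit("C" * 9 + "A" + "C" * 18, 82, 28, "-")
    (pair,) = enumerate_overlap_pairs([plus, minus_a10])
    assert u1a10_flag(pair) is True

    plus_g = _hit("G" * 28, 100, 28, "+")
    minus_g = _hit("G" * 28, 82, 28, "-")
    (pair_g,) = enumerate_overlap_pairs([plus_g, minus_g])
    assert u1a10_flag(pair_g) is False

    # the A10 side is symmetric: minus mate U1, plus mate A10
    plus_a10 = _hit("C" * 9 + "A" + "C" * 18, 100, 28, "+")
    minus_u1 = _hit("T" + "G" * 27, 82, 28, "-")
    (pair_s,) = enumerate_overlap_pairs([plus_a10, minus_u1])
    assert u1a10_flag(pair_s) is True


def test_u1a10_requires_ten_bases():
    # plus mate has U1, but the 5-nt minus mate cannot provide the A10 side
    plus = _hit("T" + "G" * 27, 100, 28, "+")
    short = AlignmentHit("AAAAA", Interval("c", 100, 105, "-"), 0)
    (pair,) = enumerate_overlap_pairs([plus, short], min_len=5)
    assert pair.overlap == 5
    assert u1a10_flag(pair) is False


def test_density_map_column_sums_match_strand_counts(rng):
    hits = random_hit_set(rng, 150, contig="ele", contig_length=2000)
    dm = density_map("ele", 2000, hits)
    plus_distinct = len(
        {(h.sequence_id, h.five_prime) for h in hits if h.interval.strand == "+"}
    )
    minus_distinct = len(
        {(h.sequence_id, h.five_prime) for h in hits if h.interval.strand == "-"}
    )
    assert sum(dm.sense_depth) == plus_distinct
    assert sum(dm.antisense_depth) == minus_distinct
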