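"""Ping-pong amplification signature statistics.

In the ping-pong cycle, reciprocal slicing produces sense/antisense piRNA
pairs whose 5' ends overlap by exactly 10 nt, with a 5'-U on one mate and an
A at position 10 of the other (U1/A10).  This module enumerates all
opposite-strand hit pairs sharing at least one genomic position, measures
the overlap-length spectrum (``overlap = minus 5' - plus 5' + 1``, the
convention under which the signature is exactly 10), the fraction of
participating sequences in a signature pair, per-overlap 5'-base
composition, and per-element density maps.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

from .model import AlignmentHit

SIGNATURE_LEN = 10


@dataclass(frozen=True)
class OverlapPair:
    plus_hit: AlignmentHit
    minus_hit: AlignmentHit

    @property
    def overlap(self) -> int:
        return self.minus_hit.five_prime - self.plus_hit.five_prime + 1

    @property
    def u1a10(self) -> bool:
        return u1a10_flag(self)


@dataclass
class OverlapProfile:
    histogram: Dict[int, int]
    base_freq: Dict[int, Dict[str, float]]
    signature_fraction: Optional[float]


@dataclass
class DensityMap:
    """Per-position 5'-end counts on a reference element, by strand, plus
    the midpoints of U1/A10 signature pairs."""

    element: str
    length: int
    sense_depth: List[int] = field(default_factory=list)
    antisense_depth: List[int] = field(default_factory=list)
    u1a10_positions: List[int] = field(default_factory=list)


def enumerate_overlap_pairs(
    hits: Sequence[AlignmentHit], min_len: int = 24
) -> List[OverlapPair]:
    """All (plus, minus) hit pairs on the same contig sharing >= 1 position.

    Input hits are restricted to reads of at least ``min_len`` nt.  A
    sequence may participate in many pairs.  A pair qualifies iff the two
    read intervals intersect and the minus 5' end is at or right of the
    plus 5' end (overlap >= 1); the shared-position condition bounds the
    overlap by ``len_plus + len_minus - 1``.
    """
    plus_by_contig: Dict[str, List[AlignmentHit]] = {}
    minus_by_contig: Dict[str, List[AlignmentHit]] = {}
    max_len = 0
    for h in hits:
        if h.interval.length < min_len:
            continue
        max_len = max(max_len, h.interval.length)
        target = plus_by_contig if h.interval.strand == "+" else minus_by_contig
        target.setdefault(h.interval.contig, []).append(h)

    pairs: List[OverlapPair] = []
    for contig, minus_hits in minus_by_contig.items():
        plus_hits = sorted(
            plus_by_contig.get(contig, []), key=lambda h: h.five_prime
        )
        if not plus_hits:
            continue
        plus_fp = [h.five_prime for h in plus_hits]
        for mh in sorted(minus_hits, key=lambda h: h.five_prime):
            m = mh.five_prime
            minus_start = mh.interval.start
            lo = bisect_left(plus_fp, m - 2 * max_len + 2)
            hi = bisect_right(plus_fp, m)
            for ph in plus_hits[lo:hi]:
                # shared position: plus interval must reach past minus start
                if ph.interval.end > minus_start:
                    pairs.append(OverlapPair(ph, mh))
    return pairs


def overlap_histogram(pairs: Iterable[OverlapPair]) -> Dict[int, int]:
    hist: Dict[int, int] = {}
    for p in pairs:
        hist[p.overlap] = hist.get(p.overlap, 0) + 1
    return dict(sorted(hist.items()))


def signature_fraction(
    pairs: Sequence[OverlapPair],
    signature_len: int = SIGNATURE_LEN,
    weights: Optional[Mapping[str, int]] = None,
) -> Optional[float]:
    """Fraction of pair-participating sequences in a signature-length pair.

    Denominator: distinct sequences in >= 1 pair; numerator: distinct
    sequences in >= 1 pair with overlap exactly ``signature_len``.  With
    ``weights`` (sequence -> read multiplicity) both sums are
    multiplicity-weighted instead.  Returns None for an empty denominator.
    """
    participants = set()
    in_signature = set()
    for p in pairs:
        for seq in (p.plus_hit.sequence_id, p.minus_hit.sequence_id):
            participants.add(seq)
            if p.overlap == signature_len:
                in_signature.add(seq)
    if not participants:
        return None
    if weights is None:
        return len(in_signature) / len(participants)
    wsum = sum(weights.get(s, 1) for s in participants)
    if wsum == 0:
        return None
    return sum(weights.get(s, 1) for s in in_signature) / wsum


_TO_RNA = {"A": "A", "C": "C", "G": "G", "T": "U"}


def base_composition(pairs: Sequence[OverlapPair]) -> Dict[int, Dict[str, float]]:
    """Per overlap length, the 5'-base frequency of participating sequences
    (distinct sequences; T reported as U).  Rows sum to 1."""
    by_len: Dict[int, set] = {}
    for p in pairs:
        by_len.setdefault(p.overlap, set()).update(
            (p.plus_hit.sequence_id, p.minus_hit.sequence_id)
        )
    out: Dict[int, Dict[str, float]] = {}
    for length, seqs in sorted(by_len.items()):
        counts = {"A": 0, "C": 0, "G": 0, "U": 0}
        for s in seqs:
            counts[_TO_RNA[s[0]]] += 1
        total = sum(counts.values())
        out[length] = {b: c / total for b, c in counts.items()}
    return out


def position_base_matrix(
    sequences: Iterable[str], n_positions: Optional[int] = None
) -> List[Dict[str, float]]:
    """Per-position base frequencies across sequences (T reported as U);
    each row sums to 1 over the sequences long enough to reach it."""
    seqs = list(sequences)
    if not seqs:
        return []
    if n_positions is None:
        n_positions = max(len(s) for s in seqs)
    rows: List[Dict[str, float]] = []
    for i in range(n_positions):
        counts = {"A": 0, "C": 0, "G": 0, "U": 0}
        n = 0
        for s in seqs:
            if len(s) > i:
                counts[_TO_RNA[s[i]]] += 1
                n += 1
        rows.append({b: (c / n if n else 0.0) for b, c in counts.items()})
    return rows


def u1a10_flag(pair: OverlapPair) -> bool:
    """True iff one mate starts with U and the other carries A at position
    10, each read in its own 5'->3' orientation; mates shorter than 10 nt
    cannot satisfy the A10 side."""
    a = pair.plus_hit.sequence_id
    b = pair.minus_hit.sequence_id
    return (a[0] == "T" and len(b) >= 10 and b[9] == "A") or (
        b[0] == "T" and len(a) >= 10 and a[9] == "A"
    )


def overlap_profile(
    pairs: Sequence[OverlapPair], signature_len: int = SIGNATURE_LEN
) -> OverlapProfile:
    return OverlapProfile(
        histogram=overlap_histogram(pairs),
        base_freq=base_composition(pairs),
        signature_fraction=signature_fraction(pairs, signature_len),
    )


def density_map(
    element: str,
    length: int,
    hits: Sequence[AlignmentHit],
    pairs: Sequence[OverlapPair] = (),
) -> DensityMap:
    """Distinct-sequence 5'-end density along one reference element.

    ``hits`` are placements on that element (one per distinct sequence per
    position); U1/A10 signature pairs contribute the midpoint of their
    overlap region.
    """
    sense = [0] * length
    antisense = [0] * length
    seen = set()
    for h in hits:
        if h.interval.contig != element:
            continue
        key = (h.sequence_id, h.five_prime, h.interval.strand)
        if key in seen:
            continue
        seen.add(key)
        if 0 <= h.five_prime < length:
            if h.interval.strand == "+":
                sense[h.five_prime] += 1
            else:
                antisense[h.five_prime] += 1
    u1a10 = [0] * length
    for p in pairs:
        if p.plus_hit.interval.contig != element or not p.u1a10:
            continue
        mid = (p.plus_hit.five_prime + p.minus_hit.five_prime) // 2
        if 0 <= mid < length:
            u1a10[mid] += 1
    return DensityMap(element, length, sense, antisense, u1a10)
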