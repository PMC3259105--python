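"""Independent brute-force oracles used by the test suite.

Each oracle recomputes an operation's result by the most literal method
available (exhaustive window scans, all-pairs enumeration, direct
recounting) and stays independent of the implementation paths it checks.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

from pirnakit.model import AlignmentHit, encode, reverse_complement


def exhaustive_align(
    sequence: str, contigs: Dict[str, str], max_mismatches: int
) -> Set[Tuple[str, int, str, int]]:
    """Every full-length placement by scanning all windows on both strands.

    Returns a set of (contig, start, strand, mismatches); reference N never
    matches any base.
    """
    out: Set[Tuple[str, int, str, int]] = set()
    queries = {"+": encode(sequence), "-": encode(reverse_complement(sequence))}
    L = len(sequence)
    for name, ref in contigs.items():
        enc = encode(ref)
        if enc.size < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(enc, L)
        for strand, q in queries.items():
            mm = (windows != q[None, :]).sum(axis=1)
            for s in np.nonzero(mm <= max_mismatches)[0]:
                out.add((name, int(s), strand, int(mm[s])))
    return out


def hits_as_tuples(hits: Sequence[AlignmentHit]) -> Set[Tuple[str, int, str, int]]:
    return {
        (h.interval.contig, h.interval.start, h.interval.strand, h.mismatches)
        for h in hits
    }


def brute_filter_removed(
    sequences: Sequence[str], references: Dict[str, str], max_mismatches: int
) -> Set[str]:
    """Sequences with any full-length reference match, by exhaustive scan."""
    return {
        s for s in sequences if exhaustive_align(s, references, max_mismatches)
    }


def all_pairs_overlaps(
    hits: Sequence[AlignmentHit], min_len: int = 24
) -> List[Tuple[AlignmentHit, AlignmentHit, int]]:
    """O(n^2) enumeration of opposite-strand pairs sharing >= 1 position."""
    out = []
    eligible = [h for h in hits if h.interval.length >= min_len]
    for a in eligible:
        if a.interval.strand != "+":
            continue
        for b in eligible:
            if b.interval.strand != "-":
                continue
            if a.interval.contig != b.interval.contig:
                continue
            if not (
                a.interval.start < b.interval.end
                and b.interval.start < a.interval.end
            ):
                continue
            overlap = b.five_prime - a.five_prime + 1
            if overlap >= 1:
                out.append((a, b, overlap))
    return out


def brute_window_counts(
    hits: Sequence[AlignmentHit], window_size: int
) -> Dict[str, Dict[int, int]]:
    """Direct recount of distinct sequences per window."""
    seen: Dict[str, Dict[int, set]] = {}
    for h in hits:
        w = h.five_prime // window_size
        seen.setdefault(h.interval.contig, {}).setdefault(w, set()).add(
            h.sequence_id
        )
    return {
        contig: {w: len(s) for w, s in per.items()}
        for contig, per in seen.items()
    }


def brute_cluster_intervals(
    hits: Sequence[AlignmentHit], window_size: int, threshold: int
) -> Set[Tuple[str, int, int]]:
    """Cluster intervals from first principles: qualify windows, merge
    adjacent runs, span the member reads."""
    counts = brute_window_counts(hits, window_size)
    out: Set[Tuple[str, int, int]] = set()
    for contig, per in counts.items():
        qualifying = sorted(w for w, c in per.items() if c >= threshold)
        run: List[int] = []
        for w in qualifying + [None]:
            if w is not None and (not run or w == run[-1] + 1):
                run.append(w)
                continue
            if run:
                members = [
                    h
                    for h in hits
                    if h.interval.contig == contig
                    and h.five_prime // window_size in run
                ]
                out.add(
                    (
                        contig,
                        min(h.interval.start for h in members),
                        max(h.interval.end for h in members),
                    )
                )
            run = [w] if w is not None else []
    return out


def interval_jaccard(a: Tuple[int, int], b: Tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union else 0.0


def random_hit_set(
    rng: np.random.Generator,
    n: int,
    contig: str = "c",
    contig_length: int = 5000,
    length_range: Tuple[int, int] = (24, 32),
) -> List[AlignmentHit]:
    """Random stranded hits with random sequence labels (for pair oracles)."""
    from pirnakit.model import Interval

    bases = np.array(list("ACGT"))
    hits = []
    for i in range(n):
        L = int(rng.integers(*length_range))
        start = int(rng.integers(0, contig_length - L))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = "".join(bases[rng.integers(0, 4, size=L)]) + f"#{i}"
        hits.append(AlignmentHit(seq, Interval(contig, start, start + L, strand), 0))
    return hits
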