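"""Full-length ungapped mapping with a mismatch budget.

The mapping contract is: report every placement of a read, on either strand,
whose full-length Hamming distance to the reference window is at most the
budget (default 2).  Reference N never matches any base.  This is the
effective behaviour of seed-and-extend short-read mappers when the seed is
at least as long as the read, stated as an explicit, testable rule.

The implementation uses a pigeonhole k-mer index (a read within Hamming
distance m of a window must share at least one of m+1 disjoint length-k
exact seeds with it, for k = floor(L/(m+1))) but is observationally
identical to an exhaustive window scan; the test suite enforces that
equivalence against a brute-force oracle.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Tuple

import numpy as np

from .model import (
    AlignmentHit,
    Assembly,
    Interval,
    Library,
    MappedSequence,
    encode,
    reverse_complement,
)

DEFAULT_MAX_MISMATCHES = 2

_MAX_K = 12  # cap so 4**k position buckets stay small


class ReferenceIndex:
    """k-mer position index over a set of reference sequences.

    One index is kept per seed length k (reads of different lengths need
    different pigeonhole seed sizes); indexes are built lazily and cached.
    """

    def __init__(self, references: Dict[str, str]):
        if not references:
            raise ValueError("empty reference set")
        self.names: List[str] = list(references)
        self.seqs: Dict[str, str] = {n: s.upper() for n, s in references.items()}
        self.encoded: Dict[str, np.ndarray] = {
            n: encode(s) for n, s in self.seqs.items()
        }
        self._indexes: Dict[int, Dict[str, Tuple[np.ndarray, np.ndarray]]] = {}

    @classmethod
    def from_assembly(cls, assembly: Assembly) -> "ReferenceIndex":
        idx = cls.__new__(cls)
        idx.names = list(assembly.contigs)
        idx.seqs = assembly.contigs
        idx.encoded = {n: assembly.encoded(n) for n in assembly.contigs}
        idx._indexes = {}
        return idx

    # -- index construction -------------------------------------------------

    def _index_for(self, k: int) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        per_contig = self._indexes.get(k)
        if per_contig is None:
            per_contig = {}
            for name, enc in self.encoded.items():
                per_contig[name] = _build_kmer_index(enc, k)
            self._indexes[k] = per_contig
        return per_contig

    # -- alignment ----------------------------------------------------------

    def align(
        self, sequence: str, max_mismatches: int = DEFAULT_MAX_MISMATCHES
    ) -> List[AlignmentHit]:
        """All full-length placements of ``sequence`` with Hamming distance
        <= ``max_mismatches``, both strands, sorted by (contig, start, strand).

        The hit's ``sequence_id`` is the sequence string itself (reads are
        collapsed and keyed by sequence throughout the pipeline).
        """
        seq = sequence.upper()
        if any(c not in "ACGT" for c in seq):
            raise ValueError(f"sequence contains non-ACGT characters: {seq!r}")
        L = len(seq)
        m = max_mismatches
        k = min(L // (m + 1), _MAX_K)
        hits: List[AlignmentHit] = []
        fwd = encode(seq)
        rev = encode(reverse_complement(seq))
        for name in self.names:
            enc = self.encoded[name]
            if L > enc.size:
                continue
            for strand, query in (("+", fwd), ("-", rev)):
                if k >= 1:
                    starts = self._candidates(name, query, k, m)
                else:  # read shorter than budget+1 seeds: scan every window
                    starts = np.arange(enc.size - L + 1)
                if starts.size == 0:
                    continue
                mm = _hamming_at(enc, query, starts)
                ok = starts[mm <= m]
                for s, d in zip(ok.tolist(), mm[mm <= m].tolist()):
                    hits.append(
                        AlignmentHit(
                            seq, Interval(name, s, s + L, strand), int(d)
                        )
                    )
        hits.sort(key=lambda h: h.sort_key)
        return hits

    def _candidates(
        self, name: str, query: np.ndarray, k: int, m: int
    ) -> np.ndarray:
        sorted_hash, sorted_pos = self._index_for(k)[name]
        L = query.size
        starts: List[np.ndarray] = []
        n_windows = self.encoded[name].size - L + 1
        if n_windows <= 0:
            return np.empty(0, dtype=np.int64)
        for j in range(m + 1):
            off = j * k
            h = _hash_kmer(query[off : off + k])
            if h < 0:
                continue
            lo = np.searchsorted(sorted_hash, h, side="left")
            hi = np.searchsorted(sorted_hash, h, side="right")
            pos = sorted_pos[lo:hi] - off
            starts.append(pos[(pos >= 0) & (pos < n_windows)])
        if not starts:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(starts))


def _build_kmer_index(enc: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Sorted (hash, position) arrays of all N-free k-mers of ``enc``."""
    n = enc.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    h = np.zeros(n, dtype=np.int64)
    for j in range(k):
        h = h * 4 + enc[j : j + n]
    # windows containing N (code 4) are invalid
    is_n = (enc == 4).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(is_n)))
    valid = (cs[k:] - cs[:-k]) == 0
    pos = np.nonzero(valid)[0]
    h = h[pos]
    order = np.argsort(h, kind="stable")
    return h[order], pos[order].astype(np.int64)


def _hash_kmer(query_k: np.ndarray) -> int:
    if (query_k >= 4).any():
        return -1
    h = 0
    for v in query_k.tolist():
        h = h * 4 + v
    return h


def _hamming_at(enc: np.ndarray, query: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Mismatch counts of ``query`` against windows of ``enc`` at ``starts``."""
    L = query.size
    windows = enc[starts[:, None] + np.arange(L)[None, :]]
    return (windows != query[None, :]).sum(axis=1)


# -- public operations ------------------------------------------------------


def align_full_length(
    sequence: str,
    references,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> List[AlignmentHit]:
    """Align one sequence against references (an :class:`Assembly`, a
    name->sequence mapping, or a prebuilt :class:`ReferenceIndex`)."""
    index = _as_index(references)
    return index.align(sequence, max_mismatches)


def _as_index(references) -> ReferenceIndex:
    if isinstance(references, ReferenceIndex):
        return references
    if isinstance(references, Assembly):
        return ReferenceIndex.from_assembly(references)
    return ReferenceIndex(dict(references))


def map_library(
    library: Library,
    assembly,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> Dict[str, MappedSequence]:
    """Map every collapsed read of a library; returns sequence -> placements.

    Hits are ordered deterministically (contig, start, strand); uniqueness
    status is derived from the best mismatch stratum.
    """
    index = _as_index(assembly)
    out: Dict[str, MappedSequence] = {}
    for seq, read in library.reads.items():
        out[seq] = MappedSequence(read, index.align(seq, max_mismatches))
    return out


def split_by_genome_mapping(
    library: Library,
    assembly,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> Tuple[Library, Library]:
    """Partition a library into (genome_mapped, genome_unmapped).

    The partition conserves the read multiset: every sequence lands in
    exactly one side with its full multiplicity.
    """
    index = _as_index(assembly)
    mapped_seqs, unmapped_seqs = [], []
    for seq in library.reads:
        if index.align(seq, max_mismatches):
            mapped_seqs.append(seq)
        else:
            unmapped_seqs.append(seq)
    return (
        library.subset(mapped_seqs, id=library.id),
        library.subset(unmapped_seqs, id=library.id),
    )


def unique_hits(mapped: Dict[str, MappedSequence]) -> List[AlignmentHit]:
    """The single best-stratum hit of every uniquely mapping sequence."""
    hits = []
    for ms in mapped.values():
        h = ms.unique_hit
        if h is not None:
            hits.append(h)
    hits.sort(key=lambda h: h.sort_key)
    return hits
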