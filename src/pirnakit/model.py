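"""Domain types shared by all pipeline stages.

Coordinate convention: 0-based half-open internally everywhere; TSV reports
convert to 1-based inclusive (see :mod:`pirnakit.io`).  All sequences are kept
in the DNA alphabet (U is normalized to T at ingest) so that reads, references
and annotations live in a single alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional

import numpy as np

#: Post-preprocessing read length bounds (gel excision window of small-RNA
#: library construction: roughly 16-35 nt).
MIN_READ_LEN = 16
MAX_READ_LEN = 35

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte -> small integer code; A,C,G,T -> 0..3, N -> 4 (never matches a base)
_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE_LUT[_b] = _i
    _ENCODE_LUT[_b + 32] = _i  # lower case


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0,C=1,G=2,T=3, anything else 4)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class SmallRead:
    """A collapsed unique small-RNA sequence with per-library multiplicity.

    ``counts`` maps library id -> multiplicity (>= 1 in every library where the
    sequence occurs).  The same sequence string appears at most once per
    :class:`Library`.
    """

    sequence: str
    counts: Dict[str, int] = field(default_factory=dict)
    id: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __post_init__(self) -> None:
        for lib, n in self.counts.items():
            if n < 1:
                raise ValueError(f"multiplicity for {lib!r} must be >= 1, got {n}")


@dataclass
class Library:
    """A small-RNA library: a collection of collapsed reads.

    ``reads`` is keyed by sequence string, which enforces the at-most-once
    invariant.  A merged multi-library object is also represented as a
    Library whose reads carry counts for several library ids.
    """

    id: str
    species: str = ""
    line: str = ""
    replicate_group: str = ""
    reads: Dict[str, SmallRead] = field(default_factory=dict)

    def add(self, sequence: str, count: int = 1, library_id: Optional[str] = None) -> None:
        lib = library_id if library_id is not None else self.id
        read = self.reads.get(sequence)
        if read is None:
            self.reads[sequence] = SmallRead(sequence, {lib: count})
        else:
            read.counts[lib] = read.counts.get(lib, 0) + count

    @property
    def total_reads(self) -> int:
        return sum(r.total for r in self.reads.values())

    @property
    def unique_sequences(self) -> int:
        return len(self.reads)

    def multiplicity(self, sequence: str, library_id: Optional[str] = None) -> int:
        read = self.reads.get(sequence)
        if read is None:
            return 0
        if library_id is None:
            return read.total
        return read.counts.get(library_id, 0)

    def subset(self, sequences: Iterable[str], id: Optional[str] = None) -> "Library":
        out = Library(id or self.id, self.species, self.line, self.replicate_group)
        for s in sequences:
            if s in self.reads:
                r = self.reads[s]
                out.reads[s] = SmallRead(r.sequence, dict(r.counts), r.id)
        return out


def merge_libraries(libraries: Iterable[Library], id: str = "combined") -> Library:
    """Merge several libraries into one object with per-library counts kept."""
    out = Library(id=id)
    for lib in libraries:
        for seq, read in lib.reads.items():
            for lid, n in read.counts.items():
                out.add(seq, n, library_id=lid)
    return out


class Assembly:
    """A multi-contig genome assembly over {A,C,G,T,N}.

    Encoded contig arrays are cached because the mapper touches them often.
    """

    def __init__(self, contigs: Mapping[str, str]):
        if len(set(contigs)) != len(contigs):
            raise ValueError("contig names must be unique")
        self.contigs: Dict[str, str] = {
            name: seq.upper() for name, seq in contigs.items()
        }
        for name, seq in self.contigs.items():
            if len(seq) < 1:
                raise ValueError(f"contig {name!r} is empty")
        self._encoded: Dict[str, np.ndarray] = {}

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def encoded(self, name: str) -> np.ndarray:
        arr = self._encoded.get(name)
        if arr is None:
            arr = encode(self.contigs[name])
            self._encoded[name] = arr
        return arr

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __iter__(self):
        return iter(self.contigs)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval with strand in {+, -, .}."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


GENE = "gene"
TE = "TE"
TE_CLASSES = ("retrotransposon", "DNA", "MITE", "other")


@dataclass
class Feature:
    """A gene or transposable-element annotation.

    ``te_class`` is one of ``retrotransposon``/``DNA``/``MITE``/``other`` for
    TEs and empty for genes.
    """

    interval: Interval
    kind: str
    name: str = ""
    te_class: str = ""

    def __post_init__(self) -> None:
        if self.kind == GENE and self.te_class:
            raise ValueError("gene features carry no TE class")
        if self.kind == TE and self.te_class not in TE_CLASSES:
            raise ValueError(f"TE feature needs a class, got {self.te_class!r}")


@dataclass(frozen=True)
class AlignmentHit:
    """A full-length ungapped placement of a read on a reference.

    ``five_prime`` is the genomic coordinate of the read's 5' base:
    ``interval.start`` on the plus strand, ``interval.end - 1`` on the minus
    strand (the rule that makes ping-pong overlap arithmetic work).
    """

    sequence_id: str
    interval: Interval
    mismatches: int

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("alignment hits must be stranded")
        if self.mismatches < 0:
            raise ValueError("negative mismatch count")

    @property
    def five_prime(self) -> int:
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def sort_key(self):
        return (self.interval.contig, self.interval.start, self.interval.strand)


UNIQUE = "unique"
MULTI = "multi"
UNMAPPED = "unmapped"


@dataclass
class MappedSequence:
    """A read with its genome placements and uniqueness status.

    Status is derived from the best (minimum-mismatch) stratum: ``unique``
    iff exactly one hit attains the minimum mismatch count, ``unmapped`` iff
    there are no hits, ``multi`` otherwise.  All strata are retained in
    ``hits`` for density maps.
    """

    read: SmallRead
    hits: List[AlignmentHit] = field(default_factory=list)

    @property
    def status(self) -> str:
        if not self.hits:
            return UNMAPPED
        best = min(h.mismatches for h in self.hits)
        n_best = sum(1 for h in self.hits if h.mismatches == best)
        return UNIQUE if n_best == 1 else MULTI

    @property
    def best_hits(self) -> List[AlignmentHit]:
        if not self.hits:
            return []
        best = min(h.mismatches for h in self.hits)
        return [h for h in self.hits if h.mismatches == best]

    @property
    def unique_hit(self) -> Optional[AlignmentHit]:
        best = self.best_hits
        return best[0] if len(best) == 1 else None
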