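"""Library preprocessing: adapter stripping, contaminant removal, size classes.

Small-RNA reads come off the sequencer as insert + 3' adapter.  The adapter
is found as the longest read suffix matching a prefix of the adapter
(suffix-prefix overlap scan, standard small-RNA practice), with a mismatch
budget proportional to the overlap.  Contaminants (rRNA-like, miRNA-like)
are removed by the same explicit full-length <=2-mismatch matching rule the
rest of the pipeline uses for database matching, which makes the filter
deterministic and testable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

from .mapping import DEFAULT_MAX_MISMATCHES, ReferenceIndex, _as_index
from .model import Library, MIN_READ_LEN

TRIMMED = "trimmed"
UNCHANGED = "unchanged"
REJECTED = "rejected"


@dataclass
class SizeClassRule:
    """Size-class boundaries (nt).

    Defaults encode the observed bimodal small-RNA length profile: a sharp
    endo-siRNA peak at 21 nt and a broad piRNA peak at 24-31 nt.  The
    open-ended ``pool_min`` class (>= 24 nt) exists because pool-diversity
    estimation uses "24 nt or larger" rather than the bounded piRNA window;
    both classes are exposed rather than guessing a single intent.
    """

    sirna_length: int = 21
    pirna_min: int = 24
    pirna_max: int = 31
    pool_min: int = 24

    def __post_init__(self) -> None:
        if not (self.sirna_length < self.pirna_min <= self.pirna_max):
            raise ValueError("size classes must satisfy sirna < pirna_min <= pirna_max")
        if self.pool_min > self.pirna_min:
            raise ValueError("pool_min must not exceed pirna_min")


def strip_adapter(
    sequence: str,
    adapter: str,
    min_overlap: int = 6,
    max_mismatch_per_10nt: int = 1,
    min_length: int = MIN_READ_LEN,
) -> Tuple[str, str]:
    """Strip a 3' adapter from one read.

    Returns ``(status, result)`` with status ``trimmed``/``unchanged``/
    ``rejected`` (rejected when the trimmed insert is shorter than
    ``min_length``).  The scan is repeated to a fixed point so the operation
    is idempotent on its own output.  Mismatch budget for an overlap of n nt
    is ``floor(n * max_mismatch_per_10nt / 10)``.
    """
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    seq = sequence
    status = UNCHANGED
    while True:
        cut = _find_adapter(seq, adapter, min_overlap, max_mismatch_per_10nt)
        if cut is None:
            break
        seq = seq[:cut]
        status = TRIMMED
        if len(seq) < min_length:
            return REJECTED, seq
    return status, seq


def _find_adapter(
    seq: str, adapter: str, min_overlap: int, max_mm_per_10: int
):
    """Smallest cut position whose suffix matches an adapter prefix, or None."""
    n = len(seq)
    for i in range(0, n - min_overlap + 1):
        overlap = min(n - i, len(adapter))
        budget = (overlap * max_mm_per_10) // 10
        mm = 0
        for a, b in zip(seq[i : i + overlap], adapter[:overlap]):
            if a != b:
                mm += 1
                if mm > budget:
                    break
        else:
            return i
    return None


def strip_library(
    library: Library,
    adapter: str,
    min_overlap: int = 6,
    max_mismatch_per_10nt: int = 1,
) -> Tuple[Library, Dict[str, int]]:
    """Adapter-strip every read of a library; returns (library, tally)."""
    out = Library(library.id, library.species, library.line, library.replicate_group)
    tally = {TRIMMED: 0, UNCHANGED: 0, REJECTED: 0}
    for seq, read in library.reads.items():
        status, trimmed = strip_adapter(seq, adapter, min_overlap, max_mismatch_per_10nt)
        tally[status] += read.total
        if status == REJECTED or len(trimmed) < MIN_READ_LEN:
            continue
        for lid, n in read.counts.items():
            out.add(trimmed, n, library_id=lid)
    return out, tally


def filter_matching(
    library: Library,
    reference_set,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> Tuple[Library, Library]:
    """Split a library into (kept, removed) by reference matching.

    A sequence is removed iff it has at least one full-length alignment
    (either strand) to any reference with <= ``max_mismatches``.  The two
    sides partition the input multiset.
    """
    index = _as_index(reference_set)
    kept, removed = [], []
    for seq in library.reads:
        if index.align(seq, max_mismatches):
            removed.append(seq)
        else:
            kept.append(seq)
    return library.subset(kept), library.subset(removed)


def partition_by_size(
    library: Library, rule: SizeClassRule = SizeClassRule()
) -> Dict[str, Library]:
    """Partition a library into size classes.

    ``sirna``/``pirna``/``other`` partition the library; ``pool_pirna``
    (everything >= ``pool_min``) overlaps ``pirna`` by construction and is
    the eligibility class for pool-size estimation.
    """
    classes: Dict[str, list] = {"sirna": [], "pirna": [], "pool_pirna": [], "other": []}
    for seq in library.reads:
        n = len(seq)
        if n == rule.sirna_length:
            classes["sirna"].append(seq)
        elif rule.pirna_min <= n <= rule.pirna_max:
            classes["pirna"].append(seq)
        else:
            classes["other"].append(seq)
        if n >= rule.pool_min:
            classes["pool_pirna"].append(seq)
    return {
        name: library.subset(seqs, id=f"{library.id}:{name}")
        for name, seqs in classes.items()
    }
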