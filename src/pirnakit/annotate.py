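"""Target classification, TE-family tallies, gene ranking, transgene piRNAs.

Two distinct targeting pathways are kept apart on purpose: genomic
annotation overlap (a read's hit intersects an annotated gene/TE interval)
drives the gene/TE/both/neither classification and the gene density ranking,
while consensus matching (full-length alignment of the read to a TE family
consensus sequence) drives the family tallies.  The two disagree by
construction and both are biologically meaningful.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

from .mapping import ReferenceIndex, _as_index
from .model import (
    AlignmentHit,
    Assembly,
    Feature,
    GENE,
    Interval,
    Library,
    MappedSequence,
    TE,
    reverse_complement,
)

logger = logging.getLogger("pirnakit")

CATEGORIES = ("gene", "TE", "both", "neither")


def _build_trees(features: Sequence[Feature]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for f in features:
        trees.setdefault(f.interval.contig, IntervalTree()).addi(
            f.interval.start, f.interval.end, f
        )
    return trees


def _hits_feature(trees: Dict[str, IntervalTree], hit: AlignmentHit) -> bool:
    tree = trees.get(hit.interval.contig)
    return bool(tree and tree.overlap(hit.interval.start, hit.interval.end))


def classify_targets(
    mapped: Mapping[str, MappedSequence],
    gene_features: Sequence[Feature],
    te_features: Sequence[Feature],
) -> Tuple[Dict[str, str], List[dict]]:
    """Assign each mapped sequence to gene/TE/both/neither.

    A sequence is "gene" if any retained hit overlaps a gene annotation by
    >= 1 bp, "TE" likewise, "both" if both, else "neither".  Also returns a
    length x category table (distinct sequences and read multiplicities).
    """
    gene_trees = _build_trees(gene_features)
    te_trees = _build_trees(te_features)
    categories: Dict[str, str] = {}
    table: Dict[int, Dict[str, List[int]]] = {}
    for seq, ms in mapped.items():
        if not ms.hits:
            continue
        in_gene = any(_hits_feature(gene_trees, h) for h in ms.hits)
        in_te = any(_hits_feature(te_trees, h) for h in ms.hits)
        cat = (
            "both" if (in_gene and in_te) else "gene" if in_gene else "TE" if in_te else "neither"
        )
        categories[seq] = cat
        row = table.setdefault(len(seq), {c: [0, 0] for c in CATEGORIES})
        row[cat][0] += 1
        row[cat][1] += ms.read.total
    rows = []
    for length in sorted(table):
        r = {"length": length}
        for c in CATEGORIES:
            r[f"{c}_distinct"] = table[length][c][0]
            r[f"{c}_reads"] = table[length][c][1]
        rows.append(r)
    return categories, rows


def genome_occupancy(
    gene_features: Sequence[Feature],
    te_features: Sequence[Feature],
    assembly: Assembly,
) -> Dict[str, float]:
    """Per-base genome fractions occupied by genes, TEs, both, or neither."""
    totals = {c: 0 for c in CATEGORIES}
    for contig, length in assembly.lengths.items():
        gene_mask = np.zeros(length, dtype=bool)
        te_mask = np.zeros(length, dtype=bool)
        for f in gene_features:
            if f.interval.contig == contig:
                gene_mask[f.interval.start : f.interval.end] = True
        for f in te_features:
            if f.interval.contig == contig:
                te_mask[f.interval.start : f.interval.end] = True
        both = gene_mask & te_mask
        totals["both"] += int(both.sum())
        totals["gene"] += int((gene_mask & ~te_mask).sum())
        totals["TE"] += int((te_mask & ~gene_mask).sum())
        totals["neither"] += int((~gene_mask & ~te_mask).sum())
    genome = assembly.total_length
    return {c: totals[c] / genome for c in CATEGORIES}


@dataclass
class TEConsensus:
    name: str
    sequence: str
    te_class: str  # retrotransposon | DNA | MITE | other


def tally_te_families(
    library: Library,
    te_consensus: Sequence[TEConsensus],
    max_mismatches: int = 2,
) -> Tuple[List[dict], List[dict]]:
    """Tally sequences matching TE family consensus sequences.

    A sequence counts toward a family if it aligns full length (either
    strand, <= ``max_mismatches``) to that family's consensus; it counts
    once per family it matches, once per class, and once in the TE total.
    Returns (class_table, family_table); both carry read-multiplicity and
    distinct-sequence counts with percentages of the library totals, and the
    percentages are re-derivable from the emitted counts.
    """
    index = ReferenceIndex({c.name: c.sequence for c in te_consensus})
    class_of = {c.name: c.te_class for c in te_consensus}
    fam_counts: Dict[str, List[int]] = {c.name: [0, 0] for c in te_consensus}
    cls_counts: Dict[str, List[int]] = {
        c: [0, 0] for c in ("retrotransposon", "DNA", "MITE", "other")
    }
    te_total = [0, 0]
    for seq, read in library.reads.items():
        hits = index.align(seq, max_mismatches)
        fams = sorted({h.interval.contig for h in hits})
        if not fams:
            continue
        te_total[0] += 1
        te_total[1] += read.total
        for fam in fams:
            fam_counts[fam][0] += 1
            fam_counts[fam][1] += read.total
        for cls in sorted({class_of[f] for f in fams}):
            cls_counts[cls][0] += 1
            cls_counts[cls][1] += read.total
    total_distinct = library.unique_sequences
    total_reads = library.total_reads

    def _pct(n: int, d: int) -> float:
        return round(100.0 * n / d, 2) if d else 0.0

    class_table = [
        {
            "category": "Total",
            "reads": total_reads,
            "distinct": total_distinct,
            "pct_reads": _pct(total_reads, total_reads),
            "pct_distinct": _pct(total_distinct, total_distinct),
        },
        {
            "category": "TE",
            "reads": te_total[1],
            "distinct": te_total[0],
            "pct_reads": _pct(te_total[1], total_reads),
            "pct_distinct": _pct(te_total[0], total_distinct),
        },
    ]
    for cls in ("retrotransposon", "DNA", "MITE", "other"):
        d, r = cls_counts[cls]
        class_table.append(
            {
                "category": cls,
                "reads": r,
                "distinct": d,
                "pct_reads": _pct(r, total_reads),
                "pct_distinct": _pct(d, total_distinct),
            }
        )
    family_table = [
        {
            "family": c.name,
            "te_class": c.te_class,
            "reads": fam_counts[c.name][1],
            "distinct": fam_counts[c.name][0],
            "pct_reads": _pct(fam_counts[c.name][1], total_reads),
            "pct_distinct": _pct(fam_counts[c.name][0], total_distinct),
        }
        for c in sorted(te_consensus, key=lambda c: (-fam_counts[c.name][1], c.name))
    ]
    return class_table, family_table


def sense_antisense(
    mapped: Mapping[str, MappedSequence],
    features: Sequence[Feature],
) -> Dict[str, float]:
    """Sense/antisense orientation fractions of hits relative to stranded
    features, over read multiplicities and over distinct sequences.

    A sequence hitting features in both orientations contributes once per
    orientation occurrence.  Unstranded features are excluded with a warning.
    """
    stranded = [f for f in features if f.interval.strand in ("+", "-")]
    if len(stranded) < len(features):
        warnings.warn(
            f"excluded {len(features) - len(stranded)} unstranded features",
            stacklevel=2,
        )
    trees = _build_trees(stranded)
    sense_d = anti_d = sense_r = anti_r = 0
    for seq, ms in mapped.items():
        orientations = set()
        for h in ms.hits:
            tree = trees.get(h.interval.contig)
            if not tree:
                continue
            for iv in tree.overlap(h.interval.start, h.interval.end):
                f: Feature = iv.data
                orientations.add(
                    "sense" if h.interval.strand == f.interval.strand else "antisense"
                )
        mult = ms.read.total
        if "sense" in orientations:
            sense_d += 1
            sense_r += mult
        if "antisense" in orientations:
            anti_d += 1
            anti_r += mult
    td, tr = sense_d + anti_d, sense_r + anti_r
    return {
        "sense_fraction_distinct": sense_d / td if td else 0.0,
        "antisense_fraction_distinct": anti_d / td if td else 0.0,
        "sense_fraction_reads": sense_r / tr if tr else 0.0,
        "antisense_fraction_reads": anti_r / tr if tr else 0.0,
    }


@dataclass
class GeneDensityRow:
    gene_id: str
    gene_length: int
    unique_pirna_count: int
    density: float  # count / length
    sense_percent: int
    antisense_percent: int
    in_cluster: bool

    @property
    def density_1dp(self) -> float:
        return round(self.density, 1)


def rank_gene_density(
    gene_features: Sequence[Feature],
    unique_hits: Sequence[AlignmentHit],
    clusters=(),
) -> List[GeneDensityRow]:
    """Rank genes by uniquely mapping piRNA density (count / gene length).

    Gene spans are the full annotated extents (UTRs, introns and exons).  A
    read counts toward a gene when the 5' end of its single hit falls inside
    the span.  Strand percents are sense/antisense relative to the gene and
    sum to 100.  Zero-length genes are rejected at Feature construction.
    """
    rows: List[GeneDensityRow] = []
    cluster_trees: Dict[str, IntervalTree] = {}
    for c in clusters:
        cluster_trees.setdefault(c.interval.contig, IntervalTree()).addi(
            c.interval.start, c.interval.end
        )
    for gene in gene_features:
        if gene.kind != GENE:
            continue
        iv = gene.interval
        count = sense = 0
        for h in unique_hits:
            if h.interval.contig == iv.contig and iv.start <= h.five_prime < iv.end:
                count += 1
                if h.interval.strand == iv.strand:
                    sense += 1
        density = count / iv.length
        sense_pct = round(100 * sense / count) if count else 0
        tree = cluster_trees.get(iv.contig)
        in_cluster = bool(tree and tree.overlap(iv.start, iv.end))
        rows.append(
            GeneDensityRow(
                gene.name, iv.length, count, density, sense_pct, 100 - sense_pct, in_cluster
            )
        )
    rows.sort(key=lambda r: (-r.density, r.gene_id))
    return rows


@dataclass(frozen=True)
class TransgeneHit:
    sequence: str
    plasmid: str
    position: int  # 0-based on the plasmid
    strand: str  # relative to the plasmid forward orientation / ORF
    ambiguous: bool  # matches more than one plasmid


def detect_transgene_pirnas(
    library: Library,
    assembly,
    plasmids: Mapping[str, str],
    max_mismatches_genome: int = 2,
    circular: bool = True,
    orf_strand: Optional[Mapping[str, str]] = None,
) -> Tuple[List[TransgeneHit], Dict[str, Dict[str, Tuple[int, int]]]]:
    """Find piRNAs derived from introduced (transformation plasmid) sequence.

    Candidates are sequences with zero genome hits at the configured budget;
    a candidate is retained iff it matches a plasmid exactly (full length,
    0 mismatches, either strand), treating plasmids as circular by default
    (origin-spanning matches found by appending the first L-1 bases).
    Sequences matching more than one plasmid are flagged ambiguous (reported
    parenthesized in the count matrix, mirroring the artifact-mapping
    convention of such tables).  Returns (hits, matrix) with
    ``matrix[library_id][plasmid] = (unambiguous, ambiguous)`` distinct-
    sequence counts; output is invariant to plasmid record order.
    """
    genome_index = _as_index(assembly)
    orf_strand = dict(orf_strand or {})
    max_len = max((len(s) for s in library.reads), default=0)
    extended: Dict[str, str] = {}
    for name in sorted(plasmids):
        seq = plasmids[name].upper()
        if circular and max_len > 1:
            seq = seq + seq[: max_len - 1]
        extended[name] = seq

    per_seq_matches: Dict[str, List[Tuple[str, int, str]]] = {}
    for seq in library.reads:
        if genome_index.align(seq, max_mismatches_genome):
            continue  # maps to the genome: cannot be attributed to the plasmid
        matches: List[Tuple[str, int, str]] = []
        rc = reverse_complement(seq)
        for name in sorted(plasmids):
            plen = len(plasmids[name])
            ext = extended[name]
            positions = set()
            for query, strand in ((seq, "+"), (rc, "-")):
                start = ext.find(query)
                while start != -1:
                    positions.add((start % plen, strand))
                    start = ext.find(query, start + 1)
            for pos, strand in sorted(positions):
                if orf_strand.get(name) == "-":
                    strand = "-" if strand == "+" else "+"
                matches.append((name, pos, strand))
        if matches:
            per_seq_matches[seq] = matches

    hits: List[TransgeneHit] = []
    matrix: Dict[str, Dict[str, Tuple[int, int]]] = {}
    lib_ids = sorted(
        {lid for read in library.reads.values() for lid in read.counts}
    )
    counts: Dict[Tuple[str, str], List[int]] = {
        (lid, p): [0, 0] for lid in lib_ids for p in plasmids
    }
    for seq, matches in sorted(per_seq_matches.items()):
        plasmid_names = {m[0] for m in matches}
        ambiguous = len(plasmid_names) > 1
        for name, pos, strand in matches:
            hits.append(TransgeneHit(seq, name, pos, strand, ambiguous))
        read = library.reads[seq]
        for lid in read.counts:
            for name in plasmid_names:
                counts[(lid, name)][1 if ambiguous else 0] += 1
    for lid in lib_ids:
        matrix[lid] = {
            p: (counts[(lid, p)][0], counts[(lid, p)][1]) for p in sorted(plasmids)
        }
    return hits, matrix
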