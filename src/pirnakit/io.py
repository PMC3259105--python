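"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ parsing goes through Biopython, SAM through pysam, annotations
through a small GFF3/BED reader.  Reports are written as TSV (genomic
coordinates 1-based inclusive, matching how such tables are conventionally
printed) or JSON (coordinates kept 0-based half-open).
"""

from __future__ import annotations

import json
import logging
import warnings
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import pysam
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .model import (
    Assembly,
    Feature,
    GENE,
    Interval,
    Library,
    TE,
    TE_CLASSES,
    reverse_complement,
)

logger = logging.getLogger("pirnakit")

_RNA2DNA = str.maketrans("Uu", "Tt")


def _normalize(seq: str) -> str:
    """U -> T, upper-case; all downstream logic is in the DNA alphabet."""
    return seq.translate(_RNA2DNA).upper()


def read_sequences(path, format: str, library_id: str) -> Library:
    """Read a small-RNA library from FASTA or FASTQ.

    Identical sequence strings are collapsed into one read with summed
    multiplicity; the result is independent of record order.  A malformed
    record raises with its index; an empty file yields an empty library with
    a warning.
    """
    fmt = format.lower()
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    lib = Library(id=library_id)
    n = 0
    try:
        if fmt == "fastq":
            with open(path) as fh:
                for n, (_title, seq, _qual) in enumerate(
                    FastqGeneralIterator(fh), start=1
                ):
                    lib.add(_normalize(seq))
        else:
            for n, record in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
                lib.add(_normalize(str(record.seq)))
    except ValueError as exc:
        raise ValueError(f"malformed {fmt.upper()} record #{n + 1} in {path}: {exc}")
    if n == 0:
        warnings.warn(f"no sequences read from {path}", stacklevel=2)
        logger.warning("no sequences read from %s", path)
    return lib


def read_fasta(path) -> Dict[str, str]:
    """Read a FASTA file into an ordered name -> sequence mapping."""
    return {
        rec.id: _normalize(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(records: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_library_fasta(library: Library, path) -> None:
    """Write a collapsed library; multiplicity is encoded in the header as
    ``id_count`` so a round-trip preserves the (sequence, multiplicity)
    multiset."""
    with open(path, "w") as fh:
        for i, (seq, read) in enumerate(sorted(library.reads.items())):
            fh.write(f">s{i}_x{read.total}\n{seq}\n")


def read_collapsed_fasta(path, library_id: str) -> Library:
    """Inverse of :func:`write_library_fasta` (``_xN`` suffix = multiplicity)."""
    lib = Library(id=library_id)
    for rec in SeqIO.parse(str(path), "fasta"):
        count = 1
        if "_x" in rec.id:
            try:
                count = int(rec.id.rsplit("_x", 1)[1])
            except ValueError:
                count = 1
        lib.add(_normalize(str(rec.seq)), count)
    return lib


def read_features(
    path,
    format: str,
    kind: str,
    class_map: Optional[Mapping[str, str]] = None,
) -> List[Feature]:
    """Read gene or TE annotations from GFF3 or BED.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open;
    BED is taken as-is.  For TEs, ``class_map`` resolves family names to
    classes (unresolved families fall back to ``other``).  Records whose
    interval is empty after conversion are rejected with a warning.
    """
    fmt = format.lower()
    if fmt not in ("gff3", "gff", "bed"):
        raise ValueError(f"unsupported annotation format {format!r}")
    class_map = dict(class_map or {})
    features: List[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                if fmt in ("gff3", "gff"):
                    contig = cols[0]
                    start = int(cols[3]) - 1  # 1-based inclusive -> 0-based
                    end = int(cols[4])
                    strand = cols[6] if cols[6] in ("+", "-") else "."
                    name = _gff_name(cols[8]) if len(cols) > 8 else ""
                else:
                    contig = cols[0]
                    start = int(cols[1])
                    end = int(cols[2])
                    name = cols[3] if len(cols) > 3 else ""
                    strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "."
            except (IndexError, ValueError) as exc:
                raise ValueError(f"malformed {fmt.upper()} line {lineno} in {path}: {exc}")
            if end <= start:
                warnings.warn(
                    f"rejected empty interval at line {lineno} of {path}",
                    stacklevel=2,
                )
                continue
            te_class = ""
            if kind == TE:
                te_class = class_map.get(name, "other")
                if te_class not in TE_CLASSES:
                    te_class = "other"
            features.append(
                Feature(Interval(contig, start, end, strand), kind=kind, name=name, te_class=te_class)
            )
    return features


def _gff_name(attributes: str) -> str:
    fields = dict(
        kv.split("=", 1) for kv in attributes.split(";") if "=" in kv
    )
    return fields.get("Name", fields.get("ID", ""))


def write_features_gff3(features: Sequence[Feature], path, source: str = "pirnakit") -> None:
    """Write features as GFF3 (internal 0-based half-open -> 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            iv = f.interval
            ftype = "gene" if f.kind == GENE else "transposable_element"
            attrs = f"ID={f.name};Name={f.name}"
            if f.te_class:
                attrs += f";te_class={f.te_class}"
            fh.write(
                "\t".join(
                    [
                        iv.contig,
                        source,
                        ftype,
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand if iv.strand != "." else ".",
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def ingest_sam(path, assembly: Assembly):
    """Read externally produced alignments from a SAM file.

    Records must be full-length ungapped matches: any CIGAR with I/D/N/S/H/P
    operations is skipped (counted).  POS is converted from 1-based to
    0-based; for reverse-strand records the 5' coordinate is the rightmost
    aligned base.  The NM tag provides the mismatch count when present,
    otherwise it is recomputed against the assembly.

    Returns ``(hits, skipped)`` where ``hits`` is a list of
    :class:`~pirnakit.model.AlignmentHit` and ``skipped`` counts rejected
    records.
    """
    from .model import AlignmentHit

    hits: List[AlignmentHit] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for name in sam.references:
            if name not in assembly:
                raise ValueError(f"SAM contig {name!r} absent from assembly")
        for rec in sam:
            if rec.is_unmapped:
                continue
            if rec.cigartuples is None or any(op != 0 for op, _ in rec.cigartuples):
                skipped += 1
                continue
            contig = rec.reference_name
            start = rec.reference_start
            length = sum(n for _, n in rec.cigartuples)
            end = start + length
            strand = "-" if rec.is_reverse else "+"
            if rec.has_tag("NM"):
                nm = int(rec.get_tag("NM"))
            else:
                ref = assembly.contigs[contig][start:end]
                query = rec.query_sequence or ""
                if rec.is_reverse:
                    query = reverse_complement(query)
                nm = sum(1 for a, b in zip(ref, query) if a != b)
            hits.append(
                AlignmentHit(rec.query_name, Interval(contig, start, end, strand), nm)
            )
    if skipped:
        logger.warning("ingest_sam: skipped %d gapped/clipped records", skipped)
    return hits, skipped


def write_sam(hits, library: Library, assembly: Assembly, path) -> None:
    """Export ungapped hits as SAM with NM tags, for interoperability."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": name, "LN": length} for name, length in assembly.lengths.items()
        ],
    }
    refs = list(assembly.lengths)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for hit in hits:
            a = pysam.AlignedSegment()
            a.query_name = hit.sequence_id
            if hit.sequence_id in library.reads:
                read_seq = hit.sequence_id
            else:  # fall back to the reference slice
                read_seq = assembly.contigs[hit.interval.contig][
                    hit.interval.start : hit.interval.end
                ]
            # SAM stores the query as aligned to the forward reference strand
            qseq = (
                reverse_complement(read_seq)
                if hit.interval.strand == "-"
                else read_seq
            )
            a.query_sequence = qseq
            a.flag = 16 if hit.interval.strand == "-" else 0
            a.reference_id = refs.index(hit.interval.contig)
            a.reference_start = hit.interval.start
            a.mapping_quality = 255
            a.cigartuples = [(0, hit.interval.length)]
            a.set_tag("NM", hit.mismatches)
            out.write(a)


_COORD_COLUMNS = {"start"}  # columns shifted to 1-based in TSV reports


def write_report(
    table: Sequence[Mapping],
    path,
    dialect: str = "TSV",
    sort_by: Optional[Sequence[str]] = None,
    columns: Optional[Sequence[str]] = None,
) -> None:
    """Write a report table deterministically.

    Rows must share a schema (the first row fixes column order; ``columns``
    supplies it for an empty table, which is written header-only).
    ``sort_by`` names the sort-key columns; without it, row order is the
    caller's.  In TSV output any column named ``start`` is emitted 1-based
    (inclusive coordinates, as such tables are printed); JSON keeps internal
    0-based half-open coordinates.
    """
    rows = [dict(r) for r in table]
    schema = list(rows[0]) if rows else list(columns or [])
    if rows:
        for r in rows:
            if list(r) != schema:
                raise ValueError("report rows do not share a schema")
        if sort_by:
            rows.sort(key=lambda r: tuple(r[c] for c in sort_by))
    dialect = dialect.upper()
    if dialect == "TSV":
        with open(path, "w") as fh:
            if schema:
                fh.write("\t".join(schema) + "\n")
                for r in rows:
                    out = []
                    for col, val in r.items():
                        if col in _COORD_COLUMNS and isinstance(val, int):
                            val = val + 1
                        out.append(_fmt(val))
                    fh.write("\t".join(out) + "\n")
    elif dialect == "JSON":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1, sort_keys=False)
            fh.write("\n")
    else:
        raise ValueError(f"unsupported report dialect {dialect!r}")


def _fmt(val) -> str:
    if isinstance(val, float):
        return format(val, ".6g")
    return str(val)


def write_bed(intervals: Iterable[Interval], names: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for iv, name in zip(intervals, names):
            strand = iv.strand if iv.strand != "." else "."
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t0\t{strand}\n")
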