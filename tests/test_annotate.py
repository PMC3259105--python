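import numpy as np
import pytest

from pirnakit.annotate import (
    TEConsensus,
    classify_targets,
    detect_transgene_pirnas,
    genome_occupancy,
    rank_gene_density,
    sense_antisense,
    tally_te_families,
)
from pirnakit.clusters import PiRNACluster
from pirnakit.mapping import map_library
from pirnakit.model import (
    AlignmentHit,
    Assembly,
    Feature,
    GENE,
    Interval,
    Library,
    MappedSequence,
    SmallRead,
    TE,
    reverse_complement,
)
from pirnakit.pipeline import check_percentages


def _mapped(seq, contig, start, strand="+", count=1):
    read = SmallRead(seq, {"lib1": count})
    hit = AlignmentHit(seq, Interval(contig, start, start + len(seq), strand), 0)
    return seq, MappedSequence(read, [hit])


def test_classify_targets_categories():
    gene = [Feature(Interval("c", 100, 500, "+"), GENE, "g1")]
    te = [Feature(Interval("c", 200, 300, "-"), TE, "t1", "DNA")]
    mapped = dict(
        [
            _mapped("A" * 28, "c", 120),  # gene only
            _mapped("C" * 28, "c", 250),  # TE nested in gene -> both
            _mapped("G" * 28, "c", 800),  # neither
        ]
    )
    categories, table = classify_targets(mapped, gene, te)
    assert categories == {"A" * 28: "gene", "C" * 28: "both", "G" * 28: "neither"}
    (row,) = table
    assert row["gene_distinct"] == 1 and row["both_distinct"] == 1
    assert row["neither_distinct"] == 1 and row["TE_distinct"] == 0


def test_classify_targets_matches_brute_reclassification(rng):
    features_g = [
        Feature(Interval("c", int(s), int(s) + 200, "+"), GENE, f"g{s}")
        for s in rng.integers(0, 9000, size=12)
    ]
    features_t = [
        Feature(Interval("c", int(s), int(s) + 150, "-"), TE, f"t{s}", "DNA")
        for s in rng.integers(0, 9000, size=12)
    ]
    def label(i):  # distinct ACGT-only sequence per index
        digits = "ACGT"
        tag = ""
        for _ in range(8):
            tag += digits[i % 4]
            i //= 4
        return "A" * 20 + tag

    mapped = dict(
        _mapped(label(i), "c", int(s))
        for i, s in enumerate(rng.integers(0, 9500, size=100))
    )
    categories, _ = classify_targets(mapped, features_g, features_t)
    for seq, ms in mapped.items():
        h = ms.hits[0].interval
        in_g = any(h.overlaps(f.interval) for f in features_g)
        in_t = any(h.overlaps(f.interval) for f in features_t)
        expected = "both" if in_g and in_t else "gene" if in_g else "TE" if in_t else "neither"
        assert categories[seq] == expected


def test_genome_occupancy_quarters():
    asm = Assembly({"c": "A" * 200})
    gene = [Feature(Interval("c", 0, 100, "+"), GENE, "g")]
    te = [Feature(Interval("c", 50, 150, "+"), TE, "t", "DNA")]
    occ = genome_occupancy(gene, te, asm)
    assert occ == {"gene": 0.25, "TE": 0.25, "both": 0.25, "neither": 0.25}
    assert sum(occ.values()) == pytest.approx(1.0)


def test_tally_te_families_counts_and_percentages(library_factory, rng):
    bases = np.array(list("ACGT"))
    cons = [
        TEConsensus("famA", "".join(bases[rng.integers(0, 4, size=500)]), "retrotransposon"),
        TEConsensus("famB", "".join(bases[rng.integers(0, 4, size=400)]), "DNA"),
    ]
    lib = library_factory(
        [
            (cons[0].sequence[10:38], 5),
            (reverse_complement(cons[1].sequence[100:127]), 2),
            ("T" * 28, 3),  # matches nothing
        ]
    )
    class_table, family_table = tally_te_families(lib, cons)
    by_cat = {r["category"]: r for r in class_table}
    assert by_cat["TE"]["reads"] == 7 and by_cat["TE"]["distinct"] == 2
    assert by_cat["retrotransposon"]["reads"] == 5
    assert by_cat["DNA"]["distinct"] == 1
    assert by_cat["MITE"]["reads"] == 0
    ok, problems = check_percentages(class_table)
    assert ok, problems
    fams = {r["family"]: r for r in family_table}
    assert fams["famA"]["reads"] == 5 and fams["famB"]["reads"] == 2


def test_tally_no_matches_all_zero(library_factory):
    cons = [TEConsensus("famA", "ACGT" * 100, "DNA")]
    lib = library_factory([("TTTTTTTTTTGGGGGGGGGGCCCCCCC", 4)])
    class_table, family_table = tally_te_families(lib, cons)
    by_cat = {r["category"]: r for r in class_table}
    assert by_cat["TE"]["reads"] == 0 and by_cat["TE"]["pct_reads"] == 0.0
    assert family_table[0]["reads"] == 0


def test_sense_antisense_orientation():
    te = [Feature(Interval("c", 0, 1000, "+"), TE, "t", "DNA")]
    mapped = dict(
        [
            _mapped("A" * 28, "c", 100, strand="-", count=3),
            _mapped("C" * 28, "c", 200, strand="-", count=1),
        ]
    )
    out = sense_antisense(mapped, te)
    assert out["antisense_fraction_distinct"] == 1.0
    assert out["antisense_fraction_reads"] == 1.0

    mixed = dict(
        [
            _mapped("A" * 28, "c", 100, strand="+"),
            _mapped("C" * 28, "c", 200, strand="-"),
        ]
    )
    out = sense_antisense(mixed, te)
    assert out["sense_fraction_distinct"] == 0.5


def test_sense_antisense_warns_on_unstranded():
    feats = [Feature(Interval("c", 0, 100, "."), TE, "t", "DNA")]
    with pytest.warns(UserWarning, match="unstranded"):
        out = sense_antisense({}, feats)


def test_rank_gene_density_counts_and_flags():
    genes = [
        Feature(Interval("c", 0, 100, "+"), GENE, "dense"),
        Feature(Interval("c", 1000, 3000, "+"), GENE, "sparse"),
        Feature(Interval("c", 5000, 5100, "-"), GENE, "empty"),
    ]
    hits = [
        AlignmentHit(f"s{i}" + "A" * 24, Interval("c", 10 + i, 38 + i, "+"), 0)
        for i in range(10)
    ] + [AlignmentHit("x" + "A" * 27, Interval("c", 1500, 1528, "-"), 0)]
    clusters = [PiRNACluster(Interval("c", 0, 400, "."))]
    rows = rank_gene_density(genes, hits, clusters)
    assert [r.gene_id for r in rows] == ["dense", "sparse", "empty"]
    dense = rows[0]
    assert dense.unique_pirna_count == 10
    assert dense.density_1dp == 0.1
    assert (dense.sense_percent, dense.antisense_percent) == (100, 0)
    assert dense.in_cluster is True
    assert rows[1].antisense_percent == 100 and rows[1].in_cluster is False
    assert rows[2].density == 0.0


def _transgene_fixture(rng):
    bases = np.array(list("ACGT"))
    genome = Assembly({"chr": "".join(bases[rng.integers(0, 4, size=5000)])})
    shared = "".join(bases[rng.integers(0, 4, size=200)])
    pA = "".join(bases[rng.integers(0, 4, size=1500)]) + shared
    pB = "".join(bases[rng.integers(0, 4, size=1200)]) + shared
    plasmids = {"pA": pA, "pB": pB}
    plasmid_only = pA[100:128]
    genome_and_plasmid = genome.contigs["chr"][50:78]
    plasmids["pA"] = pA[:500] + genome_and_plasmid + pA[500:]
    shared_read = shared[20:48]
    return genome, plasmids, plasmid_only, genome_and_plasmid, shared_read


def test_transgene_filter_semantics(rng, library_factory):
    genome, plasmids, plasmid_only, genome_and_plasmid, shared_read = (
        _transgene_fixture(rng)
    )
    lib = library_factory([plasmid_only, genome_and_plasmid, shared_read, "A" * 28])
    hits, matrix = detect_transgene_pirnas(lib, genome, plasmids)
    seqs = {h.sequence for h in hits}
    assert plasmid_only in seqs and shared_read in seqs
    assert genome_and_plasmid not in seqs  # genome-mapping reads are excluded
    assert all(h.ambiguous for h in hits if h.sequence == shared_read)
    assert matrix["lib1"]["pA"] == (1, 1)
    assert matrix["lib1"]["pB"] == (0, 1)


def test_transgene_order_invariance_and_circularity(rng, library_factory):
    genome, plasmids, plasmid_only, _, shared_read = _transgene_fixture(rng)
    lib = library_factory([plasmid_only, shared_read])
    _, m1 = detect_transgene_pirnas(lib, genome, plasmids)
    _, m2 = detect_transgene_pirnas(
        lib, genome, dict(reversed(list(plasmids.items())))
    )
    assert m1 == m2
    # origin-spanning read on a circular plasmid
    pA = plasmids["pA"]
    wrap = pA[-14:] + pA[:14]
    lib2 = library_factory([wrap])
    hits, _ = detect_transgene_pirnas(lib2, genome, plasmids)
    assert any(h.plasmid == "pA" and h.position == len(pA) - 14 for h in hits)
    none, _ = detect_transgene_pirnas(lib2, genome, plasmids, circular=False)
    assert none == []
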