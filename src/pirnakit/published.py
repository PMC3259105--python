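"""Published summary statistics from the Ae. aegypti whole-adult small-RNA
survey, used as arithmetic inputs.

These printed values (cluster coordinates, category tallies, gene rows,
library metadata) are the survey's reported outputs; the package re-derives
the percentages, sizes and densities from the raw counts and coordinates to
verify that its reporting conventions reproduce the printed numbers.
Coordinates are 1-based inclusive as printed.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

#: Top-30 piRNA cluster coordinates: (rank, supercontig, start, stop) with
#: the printed unique-piRNA count.
CLUSTER_TABLE: List[Tuple[int, str, int, int, int]] = [
    (1, "supercont1.478", 490638, 568444, 116897),
    (2, "supercont1.1", 1151499, 1278727, 94452),
    (3, "supercont1.286", 1260644, 1444752, 89740),
    (4, "supercont1.943", 196392, 264127, 21576),
    (5, "supercont1.209", 235416, 285783, 19243),
    (6, "supercont1.20", 3110107, 3224809, 18814),
    (7, "supercont1.402", 860224, 953549, 17519),
    (8, "supercont1.1145", 61909, 94822, 13440),
    (9, "supercont1.435", 926765, 972082, 10856),
    (10, "supercont1.379", 15854, 108077, 9550),
    (11, "supercont1.555", 368190, 374829, 8823),
    (12, "supercont1.209", 305189, 366980, 7140),
    (13, "supercont1.109", 91700, 129810, 7083),
    (14, "supercont1.697", 504405, 552871, 6382),
    (15, "supercont1.164", 1210657, 1248495, 6154),
    (16, "supercont1.83", 1415166, 1433185, 5799),
    (17, "supercont1.41", 2610658, 2644427, 5422),
    (18, "supercont1.2", 275115, 329629, 4663),
    (19, "supercont1.38", 3097699, 3148574, 4653),
    (20, "supercont1.192", 1700025, 1763125, 4631),
    (21, "supercont1.38", 2995043, 3039699, 4629),
    (22, "supercont1.109", 1912714, 1927564, 4339),
    (23, "supercont1.194", 895141, 974760, 4320),
    (24, "supercont1.226", 725419, 748642, 4280),
    (25, "supercont1.518", 151663, 158105, 4164),
    (26, "supercont1.38", 2572763, 2684616, 4119),
    (27, "supercont1.90", 907728, 931721, 4004),
    (28, "supercont1.2", 1423334, 1464722, 3928),
    (29, "supercont1.192", 551266, 584318, 3859),
    (30, "supercont1.1", 1420282, 1453931, 3827),
]

#: Printed cluster sizes in kb, same order as CLUSTER_TABLE.
CLUSTER_SIZES_KB: List[int] = [
    78, 127, 184, 68, 50, 115, 93, 33, 45, 92, 7, 62, 38, 48, 38,
    18, 34, 55, 51, 63, 45, 15, 80, 23, 6, 112, 24, 41, 33, 34,
]

#: Category tallies: counts are (read-multiplicity, distinct-sequence),
#: keyed by (species, size class, category).  Printed alongside percentages
#: of the class total that the pipeline re-derives.
TALLY_COUNTS: Dict[Tuple[str, str, str], Tuple[int, int]] = {
    ("aaeg", "pirna", "total"): (11_173_973, 5_860_037),
    ("aaeg", "pirna", "TE"): (2_177_176, 1_240_908),
    ("aaeg", "pirna", "retrotransposon"): (1_987_059, 1_114_018),
    ("aaeg", "pirna", "DNA"): (113_030, 73_584),
    ("aaeg", "pirna", "MITE"): (29_558, 25_324),
    ("aaeg", "pirna", "other"): (47_529, 27_982),
    ("dmel", "pirna", "total"): (271_626, 205_307),
    ("dmel", "pirna", "TE"): (135_387, 110_068),
    ("dmel", "pirna", "retrotransposon"): (129_418, 105_485),
    ("dmel", "pirna", "DNA"): (5_969, 4_583),
    ("aaeg", "sirna", "total"): (765_132, 446_834),
    ("aaeg", "sirna", "TE"): (216_859, 154_465),
    ("aaeg", "sirna", "retrotransposon"): (133_042, 100_067),
    ("aaeg", "sirna", "DNA"): (28_578, 18_692),
    ("aaeg", "sirna", "MITE"): (32_623, 23_667),
    ("aaeg", "sirna", "other"): (22_616, 12_039),
    ("dmel", "sirna", "total"): (86_620, 54_049),
    ("dmel", "sirna", "TE"): (15_870, 13_280),
    ("dmel", "sirna", "retrotransposon"): (15_276, 12_720),
    ("dmel", "sirna", "DNA"): (594, 560),
}

#: Printed percentages (read-weighted) for spot checks, same keys.
TALLY_PERCENTS: Dict[Tuple[str, str, str], float] = {
    ("aaeg", "pirna", "TE"): 19.48,
    ("aaeg", "pirna", "retrotransposon"): 17.78,
    ("aaeg", "pirna", "DNA"): 1.01,
    ("aaeg", "pirna", "MITE"): 0.26,
    ("aaeg", "pirna", "other"): 0.43,
    ("dmel", "pirna", "TE"): 49.84,
    ("aaeg", "sirna", "TE"): 28.34,
    ("dmel", "sirna", "TE"): 18.32,
}

#: Gene piRNA-density rows: gene id -> (length bp, unique piRNA count,
#: printed density at 1 decimal).  The AAEL011224 row is internally
#: inconsistent as printed (16488/303 = 54.4, printed 54.6); every other row
#: recomputes exactly.
GENE_DENSITY_TABLE: Dict[str, Tuple[int, int, float]] = {
    "AAEL011224": (303, 16488, 54.6),
    "AAEL007866": (1334, 10651, 8.0),
    "AAEL007861": (1182, 4356, 3.7),
    "AAEL010454": (1425, 4084, 2.9),
    "AAEL000120": (1020, 1432, 1.4),
    "AAEL005277": (4038, 4891, 1.2),
    "AAEL001004": (6251, 7009, 1.1),
    "AAEL007686": (2253, 2439, 1.1),
    "AAEL006843": (21911, 17268, 0.8),
    "AAEL010887": (60098, 34174, 0.6),
    "AAEL000276": (71446, 36638, 0.5),
}

#: Library id -> line (transformation plasmid or wild type); libraries from
#: the same line are sequencing replicates.
LIBRARY_LINES: Dict[str, str] = {
    "1": "pMos3DB2Her",
    "4": "pMos3DB2Her",
    "2": "pBac3EB2Mos",
    "6": "pBac3EB2Mos",
    "10": "wild type",
    "11": "auto-Hermes 257",
    "12": "pMos3DBhspPBac",
}

#: Reported mosquito pool-size estimate (mean, min, max) over 19 pairs.
POOL_ESTIMATE_AAEG: Tuple[float, float, float] = (1.7e7, 5.5e6, 2.3e7)


def cluster_size_kb(start_1based: int, stop_1based: int) -> int:
    """Reported cluster size in kb from printed 1-based inclusive bounds."""
    return round((stop_1based - start_1based + 1) / 1000)


def percent(count: int, total: int, decimals: int = 2) -> float:
    """Percentage at the printed precision (half-up at ``decimals``)."""
    from decimal import Decimal, ROUND_HALF_UP

    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP)
    )


def nonreplicate_pair_count(lines: Dict[str, str]) -> int:
    """Number of unordered library pairs drawn from different lines."""
    ids = sorted(lines)
    return sum(
        1
        for i, a in enumerate(ids)
        for b in ids[i + 1 :]
        if lines[a] != lines[b]
    )
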